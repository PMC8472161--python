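"""PrAMA-style enzyme-activity deconvolution.

Under [S] << Km each substrate's pseudo-first-order cleavage rate is linear in
the active enzyme concentrations,

    k_obs[s] = sum_e eff[s, e] * c[e],

with ``eff`` the substrates x enzymes catalytic-efficiency matrix (M^-1 s^-1)
and ``c`` the effective active concentrations (M). Inference is nonnegative
least squares; an optional inhibitor-differential layer attributes rate to
protease classes from (uninhibited - inhibited) rate differentials.

The bundled default matrix covers MMP-2/-8/-9 against the five FRET peptides;
entries published as "no activity" are exactly 0. Predicted cleavers without
rate constants (cathepsins, elastase-2, MMP-20 ...) are carried as annotation
metadata only and cannot enter the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .plate_io import SUBSTRATES

NM_PER_M = 1e9

#: default catalytic efficiencies, M^-1 s^-1, substrates x (MMP2, MMP8, MMP9)
TABLE2_ENZYMES = ("MMP2", "MMP8", "MMP9")
TABLE2_EFFICIENCIES = {
    "PepA": {"MMP2": 3.2e5, "MMP8": 1.4e5, "MMP9": 2.2e5},
    "PepB": {"MMP2": 2.9e4, "MMP8": 2.4e4, "MMP9": 8.5e5},
    "PepC": {"MMP2": 1.7e5, "MMP8": 2.6e4, "MMP9": 6.0e5},
    "PepD": {"MMP2": 2.4e3, "MMP8": 0.0, "MMP9": 0.0},
    "PepE": {"MMP2": 6.3e3, "MMP8": 4.8e3, "MMP9": 0.0},
}
TABLE2_CLASSES = {"MMP2": "metallo", "MMP8": "metallo", "MMP9": "metallo"}
#: predicted cleavers without published rate constants — metadata only
TABLE2_ANNOTATIONS = {
    "PepA": "Cys: cathepsin K; Met: MMP-9; Ser: chymotrypsin A",
    "PepB": "Met: MMP-2",
    "PepC": "Cys: cathepsin K; Met: MMP-9; Ser: elastase-2/cathepsin G; prolyl peptidase",
    "PepD": "Cys: cathepsin K; predicted MMP-20 activity",
    "PepE": "Asp: cathepsin D/E; Met: MMP-2; Ser: cathepsin G",
}

PROTEASE_CLASSES = ("metallo", "cysteine", "serine", "aspartic", "calpain", "other")

#: inhibitor group -> protease classes it removes
GROUP_TARGETS = {
    "NONE": frozenset(),
    "MMPi": frozenset({"metallo"}),
    "COMi": frozenset({"cysteine", "serine", "calpain"}),
    "BOTHi": frozenset({"metallo", "cysteine", "serine", "calpain"}),
}


class DeconvolutionError(ValueError):
    pass


@dataclass
class SpecificityMatrix:
    substrates: tuple[str, ...]
    enzymes: tuple[str, ...]
    eff: np.ndarray  # substrates x enzymes, M^-1 s^-1
    class_of: dict[str, str]
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.eff = np.asarray(self.eff, dtype=float)
        if self.eff.shape != (len(self.substrates), len(self.enzymes)):
            raise DeconvolutionError("efficiency matrix shape mismatch")
        if np.any(self.eff < 0):
            raise DeconvolutionError("catalytic efficiencies must be >= 0")
        for e in self.enzymes:
            if self.class_of.get(e) not in PROTEASE_CLASSES:
                raise DeconvolutionError(f"enzyme {e!r}: unknown protease class")

    def column(self, enzyme: str) -> np.ndarray:
        return self.eff[:, self.enzymes.index(enzyme)]

    def submatrix(self, enzymes: list[str]) -> "SpecificityMatrix":
        idx = [self.enzymes.index(e) for e in enzymes]
        return SpecificityMatrix(
            self.substrates,
            tuple(enzymes),
            self.eff[:, idx],
            {e: self.class_of[e] for e in enzymes},
            self.annotations,
        )

    def enzymes_of_class(self, classes: frozenset[str] | set[str]) -> list[str]:
        return [e for e in self.enzymes if self.class_of[e] in classes]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "substrate": s,
                "enzyme": e,
                "efficiency_M_per_s": self.eff[i, j],
                "class": self.class_of[e],
            }
            for i, s in enumerate(self.substrates)
            for j, e in enumerate(self.enzymes)
        ]
        return pd.DataFrame(rows)


@dataclass
class ActivityEstimate:
    enzymes: tuple[str, ...]
    conc_nM: np.ndarray
    residual_norm: float
    identifiable: bool

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.enzymes, self.conc_nM))


def build_specificity_matrix(source: pd.DataFrame | None = None) -> SpecificityMatrix:
    """Build a SpecificityMatrix from a (substrate, enzyme, efficiency, class)
    table; with no argument, return the bundled MMP-2/-8/-9 default."""
    if source is None:
        eff = np.array(
            [[TABLE2_EFFICIENCIES[s][e] for e in TABLE2_ENZYMES] for s in SUBSTRATES]
        )
        return SpecificityMatrix(
            SUBSTRATES, TABLE2_ENZYMES, eff, dict(TABLE2_CLASSES), dict(TABLE2_ANNOTATIONS)
        )
    if len(source) == 0:
        raise DeconvolutionError("empty specificity table")
    needed = {"substrate", "enzyme", "efficiency_M_per_s", "class"}
    if not needed.issubset(source.columns):
        raise DeconvolutionError(f"specificity table needs columns {sorted(needed)}")
    if source.duplicated(["substrate", "enzyme"]).any():
        raise DeconvolutionError("duplicate (substrate, enzyme) pair")
    if (source["efficiency_M_per_s"] < 0).any():
        raise DeconvolutionError("negative efficiency")
    substrates = tuple(dict.fromkeys(source["substrate"]))
    enzymes = tuple(dict.fromkeys(source["enzyme"]))
    eff = np.zeros((len(substrates), len(enzymes)))
    class_of: dict[str, str] = {}
    for _, row in source.iterrows():
        i = substrates.index(row["substrate"])
        j = enzymes.index(row["enzyme"])
        eff[i, j] = float(row["efficiency_M_per_s"])
        class_of[str(row["enzyme"])] = str(row["class"])
    return SpecificityMatrix(substrates, enzymes, eff, class_of)


def _identifiable(eff: np.ndarray) -> bool:
    active_rows = eff[np.any(eff > 0, axis=1)]
    if active_rows.size == 0:
        return False
    return int(np.linalg.matrix_rank(active_rows)) == eff.shape[1]


def infer_activities(
    kobs_vector: np.ndarray,
    matrix: SpecificityMatrix,
    ridge: float = 0.0,
) -> ActivityEstimate:
    """NNLS solve of ``min ||eff c - kobs||_2, c >= 0``; conc reported in nM.

    ``ridge`` adds a Tikhonov penalty (same solve with sqrt(ridge)*I stacked
    below the matrix) for near-collinear substrate panels; default off.
    """
    kobs = np.asarray(kobs_vector, dtype=float)
    if kobs.shape != (len(matrix.substrates),):
        raise DeconvolutionError(
            f"kobs vector length {kobs.size} != {len(matrix.substrates)} substrates"
        )
    A, b = matrix.eff, kobs
    if ridge > 0:
        A = np.vstack([A, np.sqrt(ridge) * np.eye(A.shape[1])])
        b = np.concatenate([b, np.zeros(A.shape[1])])
    conc_M, _ = optimize.nnls(A, b)
    residual = float(np.linalg.norm(matrix.eff @ conc_M - kobs))
    return ActivityEstimate(
        enzymes=matrix.enzymes,
        conc_nM=conc_M * NM_PER_M,
        residual_norm=residual,
        identifiable=_identifiable(matrix.eff),
    )


@dataclass
class ClassConstrainedResult:
    by_class: dict[str, ActivityEstimate]
    unattributed_kobs_per_s: np.ndarray  # per substrate, BOTHi-surviving rate
    disinhibition: dict[str, list[str]]  # group -> substrates with negative differential


def class_constrained_inference(
    kobs_by_group: dict[str, np.ndarray],
    matrix: SpecificityMatrix,
    ridge: float = 0.0,
) -> ClassConstrainedResult:
    """Attribute rates to protease classes from inhibitor differentials.

    Metallo-class enzymes are fitted to the (NONE - MMPi) rate differential and
    CSC-class (cysteine/serine/calpain) enzymes to (NONE - COMi); negative
    differentials — inhibited well faster than its control — are floored at 0
    and recorded as disinhibition evidence. The per-substrate rate surviving
    BOTHi is the unattributed residual (activity outside both inhibitor
    spectra). Missing inhibitor groups skip their class with a warning entry.
    """
    if "NONE" not in kobs_by_group:
        raise DeconvolutionError("uninhibited (NONE) rate vector is required")
    none = np.asarray(kobs_by_group["NONE"], dtype=float)
    n_sub = len(matrix.substrates)
    if none.shape != (n_sub,):
        raise DeconvolutionError("NONE kobs vector length mismatch")

    plan = {"metallo": "MMPi", "csc": "COMi"}
    class_sets = {
        "metallo": frozenset({"metallo"}),
        "csc": frozenset({"cysteine", "serine", "calpain"}),
    }
    by_class: dict[str, ActivityEstimate] = {}
    disinhibition: dict[str, list[str]] = {}
    for label, group in plan.items():
        enzymes = matrix.enzymes_of_class(class_sets[label])
        if group not in kobs_by_group:
            continue
        inhibited = np.asarray(kobs_by_group[group], dtype=float)
        diff = none - inhibited
        neg = diff < 0
        if neg.any():
            disinhibition[group] = [
                matrix.substrates[i] for i in np.flatnonzero(neg)
            ]
        diff = np.maximum(diff, 0.0)
        if enzymes:
            by_class[label] = infer_activities(diff, matrix.submatrix(enzymes), ridge)
        else:
            by_class[label] = ActivityEstimate(
                enzymes=(), conc_nM=np.zeros(0), residual_norm=float(
                    np.linalg.norm(diff)
                ), identifiable=False,
            )

    if "BOTHi" in kobs_by_group:
        unattributed = np.asarray(kobs_by_group["BOTHi"], dtype=float)
    else:
        unattributed = none.copy()
    return ClassConstrainedResult(
        by_class=by_class,
        unattributed_kobs_per_s=np.maximum(unattributed, 0.0),
        disinhibition=disinhibition,
    )
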