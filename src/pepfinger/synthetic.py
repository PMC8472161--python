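"""Synthetic plate-reader time courses and two-group cohorts.

The generator emulates the de-quenching assay physics: with total
pseudo-first-order rate ``k_obs`` against a substrate, the well signal is

    F(t) = baseline + gain * S0 * (1 - exp(-k_obs t)) * exp(-lambda t) + eps,

with ``S0`` the substrate amount in well (default 200 nM, i.e. 10 pmol in
50 uL), ``gain`` the fluorescence yield per nM cleaved, ``lambda`` a
photobleaching decay and ``eps`` seeded Gaussian reader noise. Reads every
5 min for 1 h. Inhibitor groups remove protease classes by an efficacy map
(default: MMPi removes metallo completely, COMi removes cysteine/serine/
calpain, BOTHi the union); an optional interaction map multiplies surviving
classes' rates when a class is inhibited, which phenomenologically reproduces
disinhibition (factor > 1) and sub-additive combined inhibition.

Cohorts draw per-subject, per-substrate uninhibited activities from lognormal
distributions (heavily right-skewed clinical activity distributions: the
published SDs approach or exceed the means) and split the rate across protease
classes by group-specific composition profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deconvolution import GROUP_TARGETS, TABLE2_CLASSES, TABLE2_EFFICIENCIES
from .plate_io import INHIBITOR_GROUPS, SUBSTRATES, WellRecord

DEFAULT_TIME_GRID = tuple(range(0, 61, 5))  # minutes, read every 5 min for 1 h
SALIVA_DILUTION = 20.0
BIOPSY_DILUTION = 750.0

#: 10 pmol substrate in 50 uL -> 200 nM in-well concentration
SUBSTRATE_PMOL = 10.0
WELL_VOLUME_UL = 50.0
DEFAULT_S0_NM = SUBSTRATE_PMOL * 1e-12 / (WELL_VOLUME_UL * 1e-6) * 1e9


class SimulationError(ValueError):
    pass


@dataclass
class Enzyme:
    name: str
    protease_class: str
    conc_nM: float
    efficiency: dict[str, float]  # substrate -> M^-1 s^-1

    def __post_init__(self) -> None:
        if self.conc_nM < 0:
            raise SimulationError(f"{self.name}: negative concentration")
        if any(v < 0 for v in self.efficiency.values()):
            raise SimulationError(f"{self.name}: negative efficiency")


def table2_enzyme(name: str, conc_nM: float) -> Enzyme:
    """An MMP-2/-8/-9 enzyme at the published per-substrate efficiencies."""
    if name not in TABLE2_CLASSES:
        raise SimulationError(f"no bundled efficiencies for {name!r}")
    return Enzyme(
        name=name,
        protease_class=TABLE2_CLASSES[name],
        conc_nM=conc_nM,
        efficiency={s: TABLE2_EFFICIENCIES[s][name] for s in SUBSTRATES},
    )


@dataclass
class SimulationConfig:
    """Plate physics and assay-condition parameters."""

    enzymes: list[Enzyme] = field(default_factory=list)
    substrate_S0_nM: float = DEFAULT_S0_NM
    gain_au_per_nM: float = 1.0
    baseline_au: float = 0.0
    bleach_rate_per_min: float = 0.0
    noise_sd_au: float = 0.0
    #: group -> class -> fraction of that class's rate removed
    inhibitor_efficacy: dict[str, dict[str, float]] = field(default_factory=dict)
    #: inhibited class -> multiplicative factor on surviving classes' rates
    interaction: dict[str, float] = field(default_factory=dict)
    time_grid_min: tuple[float, ...] = DEFAULT_TIME_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.substrate_S0_nM < 0 or self.gain_au_per_nM < 0:
            raise SimulationError("S0 and gain must be >= 0")
        if self.noise_sd_au < 0 or self.bleach_rate_per_min < 0:
            raise SimulationError("noise sd and bleach rate must be >= 0")
        for g, m in self.inhibitor_efficacy.items():
            if g not in INHIBITOR_GROUPS:
                raise SimulationError(f"unknown inhibitor group {g!r}")
            for c, f in m.items():
                if not 0 <= f <= 1:
                    raise SimulationError(f"efficacy {g}/{c} outside [0, 1]")
        if any(f <= 0 for f in self.interaction.values()):
            raise SimulationError("interaction factors must be > 0")

    def efficacy(self, group: str, protease_class: str) -> float:
        """Fraction of a class's rate removed under an inhibitor group."""
        override = self.inhibitor_efficacy.get(group, {})
        if protease_class in override:
            return override[protease_class]
        return 1.0 if protease_class in GROUP_TARGETS[group] else 0.0


def _interaction_factor(
    config: SimulationConfig, group: str, protease_class: str
) -> float:
    """Cross-class rate modulation on a surviving class under a group."""
    factor = 1.0
    for inhibited_class, f in config.interaction.items():
        if (
            config.efficacy(group, inhibited_class) > 0
            and protease_class != inhibited_class
        ):
            factor *= f
    return factor


def class_rates_kobs_per_s(
    config: SimulationConfig, substrate: str, group: str
) -> dict[str, float]:
    """Per-class pseudo-first-order rate (s^-1) surviving an inhibitor group."""
    rates: dict[str, float] = {}
    for enz in config.enzymes:
        eff = enz.efficiency.get(substrate, 0.0)
        base = eff * enz.conc_nM * 1e-9
        rates[enz.protease_class] = rates.get(enz.protease_class, 0.0) + base
    out = {}
    for cls, k in rates.items():
        survive = 1.0 - config.efficacy(group, cls)
        out[cls] = k * survive * _interaction_factor(config, group, cls)
    return out


def signal_from_kobs(
    config: SimulationConfig,
    kobs_per_s: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Evaluate the well signal model on the configured time grid."""
    t_min = np.asarray(config.time_grid_min, dtype=float)
    k_per_min = kobs_per_s * 60.0
    clean = (
        config.baseline_au
        + config.gain_au_per_nM
        * config.substrate_S0_nM
        * (1.0 - np.exp(-k_per_min * t_min))
        * np.exp(-config.bleach_rate_per_min * t_min)
    )
    if config.noise_sd_au > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        clean = clean + rng.normal(0.0, config.noise_sd_au, size=t_min.size)
    return clean


def simulate_timecourse(
    config: SimulationConfig,
    substrate: str,
    inhibitor_group: str,
    well_id: str = "SIM01",
    sample_id: str = "SIM",
    sample_type: str = "saliva",
    dilution_factor: float = SALIVA_DILUTION,
    rng: np.random.Generator | None = None,
) -> WellRecord:
    """One simulated assay well for a substrate under an inhibitor group."""
    if substrate not in SUBSTRATES:
        raise SimulationError(f"unknown substrate {substrate!r}")
    if inhibitor_group not in INHIBITOR_GROUPS:
        raise SimulationError(f"unknown inhibitor group {inhibitor_group!r}")
    kobs = sum(class_rates_kobs_per_s(config, substrate, inhibitor_group).values())
    return WellRecord(
        well_id=well_id,
        sample_id=sample_id,
        sample_type=sample_type,
        substrate=substrate,
        inhibitor_group=inhibitor_group,
        dilution_factor=dilution_factor,
        time_min=np.asarray(config.time_grid_min, dtype=float),
        fluorescence_au=signal_from_kobs(config, kobs, rng),
    )


def simulate_controls(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[WellRecord]:
    """Per-substrate positive (near-instant complete cleavage, a trypsin well)
    and negative (baseline + bleach only) control wells."""
    t_min = np.asarray(config.time_grid_min, dtype=float)
    wells = []
    for i, s in enumerate(SUBSTRATES):
        pos = signal_from_kobs(config, 1e-2, rng)  # ~full cleavage by first read
        neg = (
            config.baseline_au
            * np.exp(-config.bleach_rate_per_min * t_min)
            * np.ones_like(t_min)
        )
        if config.noise_sd_au > 0 and rng is not None:
            neg = neg + rng.normal(0.0, config.noise_sd_au, size=t_min.size)
        wells.append(
            WellRecord(
                f"POS_{s}", "control", "pos_control", s, "NONE", 1.0, t_min, pos
            )
        )
        wells.append(
            WellRecord(
                f"NEG_{s}", "control", "neg_control", s, "NONE", 1.0, t_min, neg
            )
        )
    return wells


# --- cohort layer ---------------------------------------------------------

#: pooled per-substrate saliva mean Vmax (a.u./min) and SD
POOLED_SALIVA_VMAX = {
    "PepA": (552.7, 459.0),
    "PepB": (465.1, 390.0),
    "PepC": (2140.7, 1487.0),
    "PepD": (335.5, 352.0),
    "PepE": (1246.3, 1275.0),
}
#: group-specific PepE means: elevated absolute turnover in active caries
CARIES_PEPE_MEAN = 1500.2
HEALTHY_PEPE_MEAN = 601.8

#: class-composition profiles: fraction of total rate per protease class.
#: healthy saliva from the pooled MMPi/COMi inhibition percentages; caries
#: saliva mirrors the MMP-enriched biopsy profile (lesion-derived activity
#: carries over into saliva).
HEALTHY_CLASS_PROFILE = {
    "PepA": {"metallo": 0.21, "csc": 0.34},
    "PepB": {"metallo": 0.26, "csc": 0.17},
    "PepC": {"metallo": 0.13, "csc": 0.19},
    "PepD": {"metallo": 0.09, "csc": 0.14},
    "PepE": {"metallo": 0.00, "csc": 0.08},
}
CARIES_CLASS_PROFILE = {
    "PepA": {"metallo": 0.33, "csc": 0.34},
    "PepB": {"metallo": 0.21, "csc": 0.22},
    "PepC": {"metallo": 0.15, "csc": 0.12},
    "PepD": {"metallo": 0.11, "csc": 0.24},
    "PepE": {"metallo": 0.16, "csc": 0.15},
}
#: biopsy per-substrate mean Vmax (a.u./min) and SD
BIOPSY_VMAX = {
    "PepA": (163.1, 137.6),
    "PepB": (83.5, 97.9),
    "PepC": (723.0, 1013.0),
    "PepD": (150.1, 261.8),
    "PepE": (481.6, 845.0),
}

_CSC_CLASS = "cysteine"  # representative CSC class label for simulated rate
_OTHER_CLASS = "other"


@dataclass
class CohortSpec:
    """Two-group cohort description (active caries vs caries-free)."""

    n_caries: int = 32
    n_healthy: int = 13
    mean_vmax: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            "caries": {
                **POOLED_SALIVA_VMAX,
                "PepE": (CARIES_PEPE_MEAN, 1275.0),
            },
            "healthy": {
                **POOLED_SALIVA_VMAX,
                "PepE": (HEALTHY_PEPE_MEAN, 601.8),
            },
        }
    )
    class_profile: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=lambda: {
            "caries": CARIES_CLASS_PROFILE,
            "healthy": HEALTHY_CLASS_PROFILE,
        }
    )
    biopsy_fraction: float = 0.69  # matched biopsies per caries subject
    biopsy_vmax: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(BIOPSY_VMAX)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_caries < 0 or self.n_healthy < 0:
            raise SimulationError("cohort sizes must be >= 0")
        for grp in self.mean_vmax.values():
            for m, sd in grp.values():
                if m < 0 or sd < 0:
                    raise SimulationError("means and SDs must be >= 0")
        if not 0 <= self.biopsy_fraction <= 1:
            raise SimulationError("biopsy_fraction outside [0, 1]")


def _lognormal(
    rng: np.random.Generator, mean: float, sd: float
) -> float:
    """Draw from a lognormal parameterised by its arithmetic mean and SD."""
    if mean <= 0:
        return 0.0
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def _subject_wells(
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_id: str,
    sample_type: str,
    dilution: float,
    vmax_targets: dict[str, float],
    class_profile: dict[str, dict[str, float]],
) -> tuple[list[WellRecord], dict[str, dict[str, float]]]:
    """All 5 substrates x 4 inhibitor groups wells for one specimen.

    The target uninhibited initial rate V (a.u./min) maps to a total rate
    k_obs = V / (gain * S0) per minute, split across protease classes by the
    composition profile; inhibitor groups then remove classes per the config's
    efficacy and interaction settings.
    """
    wells = []
    truth: dict[str, dict[str, float]] = {}
    denom = config.gain_au_per_nM * config.substrate_S0_nM
    for s in SUBSTRATES:
        v_target = vmax_targets[s]
        k_total_per_s = v_target / denom / 60.0
        prof = class_profile.get(s, {})
        f_met = prof.get("metallo", 0.0)
        f_csc = prof.get("csc", 0.0)
        rates = {
            "metallo": k_total_per_s * f_met,
            _CSC_CLASS: k_total_per_s * f_csc,
            _OTHER_CLASS: k_total_per_s * max(0.0, 1.0 - f_met - f_csc),
        }
        truth[s] = {"vmax_target": v_target, **{f"k_{c}": r for c, r in rates.items()}}
        for g in INHIBITOR_GROUPS:
            kobs = sum(
                r
                * (1.0 - config.efficacy(g, c))
                * _interaction_factor(config, g, c)
                for c, r in rates.items()
            )
            wells.append(
                WellRecord(
                    well_id=f"{sample_id}_{sample_type}_{s}_{g}",
                    sample_id=sample_id,
                    sample_type=sample_type,
                    substrate=s,
                    inhibitor_group=g,
                    dilution_factor=dilution,
                    time_min=np.asarray(config.time_grid_min, dtype=float),
                    fluorescence_au=signal_from_kobs(config, kobs, rng),
                )
            )
    return wells, truth


def simulate_cohort(
    spec: CohortSpec, config: SimulationConfig
) -> tuple[list[WellRecord], pd.DataFrame]:
    """Simulate a labelled two-group cohort of full well sets plus controls.

    Returns the well collection and a truth table with one row per specimen:
    label, generative per-substrate target Vmax and per-class rates. Fully
    reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    wells: list[WellRecord] = []
    truth_rows: list[dict[str, object]] = []

    def add_subject(sid: str, label: str) -> None:
        targets = {
            s: _lognormal(rng, *spec.mean_vmax[label][s]) for s in SUBSTRATES
        }
        w, truth = _subject_wells(
            config, rng, sid, "saliva", SALIVA_DILUTION, targets,
            spec.class_profile[label],
        )
        wells.extend(w)
        row: dict[str, object] = {"sample_id": sid, "specimen": "saliva", "label": label}
        for s in SUBSTRATES:
            for k, v in truth[s].items():
                row[f"{s}_{k}"] = v
        truth_rows.append(row)
        if label == "caries" and rng.random() < spec.biopsy_fraction:
            btargets = {s: _lognormal(rng, *spec.biopsy_vmax[s]) for s in SUBSTRATES}
            bw, btruth = _subject_wells(
                config, rng, sid, "biopsy", BIOPSY_DILUTION, btargets,
                spec.class_profile[label],
            )
            wells.extend(bw)
            brow: dict[str, object] = {
                "sample_id": sid, "specimen": "biopsy", "label": label,
            }
            for s in SUBSTRATES:
                for k, v in btruth[s].items():
                    brow[f"{s}_{k}"] = v
            truth_rows.append(brow)

    for i in range(spec.n_caries):
        add_subject(f"CAR{i + 1:03d}", "caries")
    for i in range(spec.n_healthy):
        add_subject(f"HLT{i + 1:03d}", "healthy")
    wells.extend(simulate_controls(config, rng))
    return wells, pd.DataFrame(truth_rows)
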