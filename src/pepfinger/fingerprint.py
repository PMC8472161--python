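"""Per-sample proteolytic fingerprints from per-well kinetic fits.

A fingerprint summarises one sample's behaviour across the five-peptide panel
and the three inhibitor conditions:

* absolute activity — uninhibited Vmax per substrate (a.u./min);
* relative contribution — percent of the summed uninhibited Vmax;
* residual / inhibition percentages per inhibitor group, relative to the
  uninhibited control (residual > 100% marks *disinhibition*);
* inhibitor-attributable contribution (NONE - inhibited, signed, a.u./min);
* MP/CSC ratio — MMPi-attributable over COMi-attributable contribution;
* additivity defect — shortfall of combined inhibition against the better
  single inhibitor; negative values mark the sub-additive interaction
  signature attributed to protease-protease interactions.

Feature columns follow the ``PepE_COMi_ABS_CONT`` naming scheme so heatmaps
and classifiers line up with the published figure labels. Undefined ratios use
NaN as the sentinel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .kinetics import KineticFit, fit_well
from .plate_io import SUBSTRATES, WellRecord

INHIBITED_GROUPS = ("MMPi", "COMi", "BOTHi")


class FingerprintError(ValueError):
    pass


def relative_contributions(abs_vmax: Sequence[float]) -> np.ndarray:
    """Percent share of each substrate in the summed uninhibited Vmax."""
    v = np.asarray(abs_vmax, dtype=float)
    if np.any(v < 0):
        raise FingerprintError("absolute activities must be >= 0")
    total = v.sum()
    if total == 0:
        return np.zeros_like(v)
    return 100.0 * v / total


def inhibition_profile(
    vmax_none: float, vmax_inhibited: float
) -> tuple[float, float, bool]:
    """(residual %, inhibition %, disinhibited) of one inhibited well.

    residual = 100 * Vmax(inhibited) / Vmax(NONE); inhibition = 100 - residual.
    A residual above 100% (the inhibited well outran its control) is flagged
    as disinhibition. Undefined for a zero uninhibited control.
    """
    if not vmax_none > 0:
        raise FingerprintError("uninhibited Vmax must be > 0 for an inhibition profile")
    residual = 100.0 * vmax_inhibited / vmax_none
    return residual, 100.0 - residual, residual > 100.0


def mp_csc_ratio(contrib_mmpi: float, contrib_comi: float) -> float:
    """Metalloprotease-to-CSC attributable-contribution ratio.

    Negative (disinhibited) contributions clamp to 0 here only; a zero CSC
    contribution yields NaN as the undefined sentinel.
    """
    mp = max(contrib_mmpi, 0.0)
    csc = max(contrib_comi, 0.0)
    if csc == 0:
        return math.nan
    return mp / csc


def additivity_defect(
    vmax_none: float, vmax_mmpi: float, vmax_comi: float, vmax_bothi: float
) -> float:
    """Combined-inhibitor inhibition minus the better single inhibitor.

    Negative values are the sub-additivity signature: the dual-inhibitor well
    retained more activity than the best single inhibitor removed.
    """
    _, inh_m, _ = inhibition_profile(vmax_none, vmax_mmpi)
    _, inh_c, _ = inhibition_profile(vmax_none, vmax_comi)
    _, inh_b, _ = inhibition_profile(vmax_none, vmax_bothi)
    return inh_b - max(inh_m, inh_c)


@dataclass
class SampleFingerprint:
    sample_id: str
    sample_type: str
    abs_vmax: dict[str, float]
    rel_contrib: dict[str, float]
    residual_pct: dict[str, dict[str, float]]
    inhibition_pct: dict[str, dict[str, float]]
    contribution_vmax: dict[str, dict[str, float]]
    mp_csc: dict[str, float]
    disinhibited: dict[str, dict[str, bool]]
    additivity: dict[str, float]
    total_activity: float
    qc_notes: list[str] = field(default_factory=list)


def fingerprint_sample(
    sample_id: str,
    sample_type: str,
    vmax: Mapping[tuple[str, str], float],
) -> SampleFingerprint:
    """Assemble a fingerprint from per-(substrate, inhibitor group) Vmax values.

    ``vmax`` maps (substrate, group) to a.u./min; uninhibited (NONE) wells are
    required per substrate, inhibited groups are optional. Substrates whose
    uninhibited Vmax is 0 are excluded from inhibition aggregates with a QC
    note rather than dividing by zero.
    """
    notes: list[str] = []
    abs_vmax = {}
    for s in SUBSTRATES:
        if (s, "NONE") not in vmax:
            raise FingerprintError(f"sample {sample_id!r}: no uninhibited well for {s}")
        abs_vmax[s] = float(vmax[(s, "NONE")])
    rel = dict(zip(SUBSTRATES, relative_contributions([abs_vmax[s] for s in SUBSTRATES])))
    total = float(sum(abs_vmax.values()))
    if total == 0:
        notes.append("all-zero uninhibited activity")

    residual: dict[str, dict[str, float]] = {s: {} for s in SUBSTRATES}
    inhibition: dict[str, dict[str, float]] = {s: {} for s in SUBSTRATES}
    contribution: dict[str, dict[str, float]] = {s: {} for s in SUBSTRATES}
    disinhibited: dict[str, dict[str, bool]] = {s: {} for s in SUBSTRATES}
    for s in SUBSTRATES:
        for g in INHIBITED_GROUPS:
            if (s, g) not in vmax:
                continue
            v_g = float(vmax[(s, g)])
            contribution[s][g] = abs_vmax[s] - v_g
            if abs_vmax[s] > 0:
                res, inh, dis = inhibition_profile(abs_vmax[s], v_g)
                residual[s][g], inhibition[s][g], disinhibited[s][g] = res, inh, dis
            else:
                notes.append(f"{s}/{g}: undefined profile (zero uninhibited Vmax)")

    mp_csc = {}
    additivity: dict[str, float] = {}
    for s in SUBSTRATES:
        if {"MMPi", "COMi"}.issubset(contribution[s]):
            mp_csc[s] = mp_csc_ratio(contribution[s]["MMPi"], contribution[s]["COMi"])
        if abs_vmax[s] > 0 and {"MMPi", "COMi", "BOTHi"}.issubset(residual[s]):
            additivity[s] = additivity_defect(
                abs_vmax[s],
                vmax[(s, "MMPi")],
                vmax[(s, "COMi")],
                vmax[(s, "BOTHi")],
            )

    return SampleFingerprint(
        sample_id=sample_id,
        sample_type=sample_type,
        abs_vmax=abs_vmax,
        rel_contrib=rel,
        residual_pct=residual,
        inhibition_pct=inhibition,
        contribution_vmax=contribution,
        mp_csc=mp_csc,
        disinhibited=disinhibited,
        additivity=additivity,
        total_activity=total,
        qc_notes=notes,
    )


def build_fingerprints(
    wells: Iterable[WellRecord],
    fits: Mapping[str, KineticFit] | None = None,
) -> list[SampleFingerprint]:
    """Fingerprint every (sample, specimen type) present in a plate.

    If ``fits`` (well_id -> KineticFit) is not supplied, wells are fitted here
    with per-substrate negative-control background subtraction.
    """
    wells = list(wells)
    if fits is None:
        neg = {
            w.substrate: w for w in wells if w.sample_type == "neg_control"
        }
        fits = {
            w.well_id: fit_well(w, neg.get(w.substrate))
            for w in wells
            if w.sample_type in ("saliva", "biopsy")
        }
    by_sample: dict[tuple[str, str], dict[tuple[str, str], float]] = {}
    for w in wells:
        if w.sample_type not in ("saliva", "biopsy") or w.well_id not in fits:
            continue
        key = (w.sample_id, w.sample_type)
        by_sample.setdefault(key, {})[(w.substrate, w.inhibitor_group)] = fits[
            w.well_id
        ].vmax_au_per_min
    return [
        fingerprint_sample(sid, stype, vmax_map)
        for (sid, stype), vmax_map in sorted(by_sample.items())
    ]


def fingerprint_table(fingerprints: Sequence[SampleFingerprint]) -> pd.DataFrame:
    """Flatten fingerprints to one row per sample with the published feature
    naming scheme (PepX_ABS, PepX_REL, PepX_<group>_RES/_INH/_ABS_CONT,
    PepX_MPCSC, PepX_ADD_DEF, PepX_<group>_DISINH, TOTAL_ABS)."""
    rows = []
    for fp in fingerprints:
        row: dict[str, object] = {
            "sample_id": fp.sample_id,
            "sample_type": fp.sample_type,
            "TOTAL_ABS": fp.total_activity,
        }
        for s in SUBSTRATES:
            row[f"{s}_ABS"] = fp.abs_vmax[s]
            row[f"{s}_REL"] = fp.rel_contrib[s]
            for g in INHIBITED_GROUPS:
                row[f"{s}_{g}_RES"] = fp.residual_pct[s].get(g, math.nan)
                row[f"{s}_{g}_INH"] = fp.inhibition_pct[s].get(g, math.nan)
                row[f"{s}_{g}_ABS_CONT"] = fp.contribution_vmax[s].get(g, math.nan)
                row[f"{s}_{g}_DISINH"] = float(fp.disinhibited[s].get(g, False))
            row[f"{s}_MPCSC"] = fp.mp_csc.get(s, math.nan)
            row[f"{s}_ADD_DEF"] = fp.additivity.get(s, math.nan)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class EnrichmentRecord:
    """Dilution-normalised biopsy-vs-saliva activity comparison."""

    sample_id: str
    saliva_norm: dict[str, float]
    biopsy_norm: dict[str, float]
    enrichment_ratio: dict[str, float]


def enrichment(
    saliva_fp: SampleFingerprint,
    biopsy_fp: SampleFingerprint,
    saliva_dilution: float,
    biopsy_dilution: float,
) -> EnrichmentRecord:
    """Biopsy-over-saliva activity enrichment after dilution normalisation.

    Normalised activity = raw Vmax x dilution factor (back to the undiluted
    specimen scale); the ratio is NaN where the saliva activity is zero.
    """
    if saliva_fp.sample_id != biopsy_fp.sample_id:
        raise FingerprintError(
            f"sample mismatch: {saliva_fp.sample_id!r} vs {biopsy_fp.sample_id!r}"
        )
    sal = {s: saliva_fp.abs_vmax[s] * saliva_dilution for s in SUBSTRATES}
    bio = {s: biopsy_fp.abs_vmax[s] * biopsy_dilution for s in SUBSTRATES}
    ratio = {
        s: (bio[s] / sal[s]) if sal[s] > 0 else math.nan for s in SUBSTRATES
    }
    return EnrichmentRecord(saliva_fp.sample_id, sal, bio, ratio)
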