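"""Per-well kinetics for de-quenching FRET progress curves.

A cleaved, de-quenched substrate accumulates fluorescence as

    F(t) = A * (1 - exp(-k_obs * t)) * exp(-lambda * t)

where ``A = gain * S0`` is the full-cleavage amplitude, ``k_obs`` the
pseudo-first-order cleavage rate (k_obs = (kcat/Km) * [E] when [S] << Km) and
``lambda`` a photobleaching decay applied to accumulated signal. The assay
summary statistic is Vmax: the maximum slope over all windows of four
consecutive timepoints of the background-subtracted series, in a.u./min.
Minutes are used at the API boundary; k_obs is reported in s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .plate_io import WellRecord

SECONDS_PER_MINUTE = 60.0

#: last-window slope below this fraction of Vmax flags substrate depletion
SATURATION_FRACTION = 0.10


class KineticsError(ValueError):
    pass


@dataclass
class KineticFit:
    """Kinetic summary of one background-subtracted well."""

    vmax_au_per_min: float
    window_start_index: int
    r2_window: float
    bleach_rate_per_min: float = 0.0
    kobs_per_s: float = 0.0
    amplitude_au: float = 0.0
    turnover_rate_au_per_min: float = 0.0
    qc_flags: set[str] = field(default_factory=set)


def subtract_background(well: WellRecord, neg_control: WellRecord) -> np.ndarray:
    """Subtract the negative-control (substrate-only) signal, pointwise.

    Both wells must carry the same substrate on an identical time grid.
    """
    if well.substrate != neg_control.substrate:
        raise KineticsError(
            f"substrate mismatch: {well.substrate} vs {neg_control.substrate}"
        )
    if not np.array_equal(well.time_min, neg_control.time_min):
        raise KineticsError("time grids differ between well and negative control")
    return well.fluorescence_au - neg_control.fluorescence_au


def window_slopes(series: np.ndarray, time_min: np.ndarray, width: int = 4) -> np.ndarray:
    """OLS slope of every window of ``width`` consecutive points (a.u./min)."""
    series = np.asarray(series, dtype=float)
    time_min = np.asarray(time_min, dtype=float)
    n = series.size
    if n < width:
        raise KineticsError(f"need >= {width} points, got {n}")
    slopes = np.empty(n - width + 1)
    for i in range(n - width + 1):
        t, y = time_min[i : i + width], series[i : i + width]
        dt = t - t.mean()
        slopes[i] = np.dot(dt, y - y.mean()) / np.dot(dt, dt)
    return slopes


def fit_vmax_four_point(
    series: np.ndarray, time_min: np.ndarray, width: int = 4
) -> KineticFit:
    """Maximum four-point sliding-window slope of a corrected series.

    Ties break to the earliest window; negative maxima clamp to 0 with a
    ``below_noise`` flag. ``r2_window`` is the OLS R^2 of the winning window.
    """
    series = np.asarray(series, dtype=float)
    time_min = np.asarray(time_min, dtype=float)
    slopes = window_slopes(series, time_min, width)
    best = int(np.argmax(slopes))  # argmax returns the first maximum
    vmax = float(slopes[best])

    flags: set[str] = set()
    if np.any(np.diff(series) < 0):
        flags.add("nonmonotone")
    if vmax <= 0:
        flags.add("below_noise")
        vmax = max(vmax, 0.0)
    elif slopes[-1] < SATURATION_FRACTION * vmax:
        flags.add("saturated")

    t, y = time_min[best : best + width], series[best : best + width]
    yhat = slopes[best] * (t - t.mean()) + y.mean()
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)

    return KineticFit(
        vmax_au_per_min=vmax,
        window_start_index=best,
        r2_window=r2,
        qc_flags=flags,
    )


def estimate_bleach_rate(series: np.ndarray, time_min: np.ndarray) -> float:
    """Photobleaching decay constant (per minute) by log-linear regression.

    Fit ``log F = log F0 - lambda * t`` on a plateau or negative-control
    baseline; a non-decaying series (slope >= 0) returns 0.
    """
    series = np.asarray(series, dtype=float)
    time_min = np.asarray(time_min, dtype=float)
    if np.any(series <= 0):
        raise KineticsError("bleach estimation needs strictly positive values")
    slope = np.polyfit(time_min, np.log(series), 1)[0]
    return float(max(0.0, -slope))


def fit_progress_curve(
    series: np.ndarray,
    time_min: np.ndarray,
    bleach_rate_per_min: float = 0.0,
) -> KineticFit:
    """Depletion-aware fit of ``A * (1 - exp(-k t)) * exp(-lambda t)``.

    ``lambda`` is fixed to the supplied bleach rate; ``A`` (amplitude, a.u.)
    and ``k`` are fitted by nonlinear least squares. The initial turnover rate
    ``A * k`` (a.u./min, the t->0 slope for lambda = 0) corrects the four-point
    Vmax for substrate depletion. Non-convergence or an all-zero series yields
    a flagged zero fit rather than an exception.
    """
    series = np.asarray(series, dtype=float)
    time_min = np.asarray(time_min, dtype=float)
    if series.size < 4:
        raise KineticsError("need >= 4 points for a progress-curve fit")

    fit = fit_vmax_four_point(series, time_min)
    fit.bleach_rate_per_min = float(bleach_rate_per_min)
    if np.allclose(series, 0.0):
        fit.qc_flags.add("below_noise")
        return fit

    lam = float(bleach_rate_per_min)

    def model(t: np.ndarray, amp: float, k_per_min: float) -> np.ndarray:
        return amp * (1.0 - np.exp(-k_per_min * t)) * np.exp(-lam * t)

    amp0 = max(float(np.max(series)), 1e-9)
    vmax0 = max(fit.vmax_au_per_min, 1e-12)
    k0 = min(max(vmax0 / amp0, 1e-8), 10.0)
    try:
        popt, _ = optimize.curve_fit(
            model,
            time_min,
            series,
            p0=(amp0, k0),
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=20000,
        )
        amp, k_per_min = float(popt[0]), float(popt[1])
    except (RuntimeError, optimize.OptimizeWarning):
        fit.qc_flags.add("nonconverged")
        return fit

    fit.amplitude_au = amp
    fit.kobs_per_s = k_per_min / SECONDS_PER_MINUTE
    fit.turnover_rate_au_per_min = amp * k_per_min
    return fit


def estimate_catalytic_efficiency(
    kobs_per_s: float, enzyme_conc_molar: float
) -> float:
    """kcat/Km (M^-1 s^-1) from a pseudo-first-order rate at known [E]."""
    if not enzyme_conc_molar > 0:
        raise KineticsError("enzyme concentration must be positive")
    return kobs_per_s / enzyme_conc_molar


def fit_well(
    well: WellRecord,
    neg_control: WellRecord | None = None,
    bleach_rate_per_min: float | None = None,
) -> KineticFit:
    """Full per-well pipeline: background subtraction, bleach, progress fit."""
    if neg_control is not None:
        corrected = subtract_background(well, neg_control)
        if bleach_rate_per_min is None:
            base = neg_control.fluorescence_au
            bleach_rate_per_min = (
                estimate_bleach_rate(base, neg_control.time_min)
                if np.all(base > 0)
                else 0.0
            )
    else:
        corrected = well.fluorescence_au.astype(float)
    return fit_progress_curve(
        corrected, well.time_min, bleach_rate_per_min or 0.0
    )
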