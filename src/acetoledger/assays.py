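"""Photometric enzyme assays and growth-curve fitting.

Specific activities follow the 2-umol-electron unit convention: one unit
(U) is the transfer of 2 umol electrons per minute. An absorbance slope
at the chromophore's wavelength (340 nm for NAD(P)H, epsilon =
6.3 mM-1 cm-1; 430 nm for ferredoxin, epsilon = 13.1 mM-1 cm-1) is
converted through Beer–Lambert to a concentration rate, scaled by cuvette
volume, electrons per chromophore and protein mass.

Growth rates come from an ordinary least-squares fit of ln(OD600) against
time over an exponential window; the doubling time is ln 2 / mu.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AssayTrace",
    "GrowthCurve",
    "ActivityResult",
    "GrowthFit",
    "GrowthFitError",
    "specific_activity",
    "fold_change",
    "fit_growth",
    "auto_window",
    "growth_consistency",
]

#: umol electrons per enzyme unit (the unit definition used throughout).
ELECTRONS_PER_UNIT = 2.0


@dataclass(frozen=True)
class AssayTrace:
    """A spectrophotometric time course with the constants needed for Beer–Lambert."""

    times_min: np.ndarray
    absorbance: np.ndarray
    epsilon_mM_cm: float
    path_cm: float = 1.0
    volume_ml: float = 1.0
    protein_mg: float = 0.1
    electrons_per_chromophore: int = 2

    def __post_init__(self) -> None:
        times = np.asarray(self.times_min, dtype=float)
        absorbance = np.asarray(self.absorbance, dtype=float)
        if times.shape != absorbance.shape or times.ndim != 1:
            raise ValueError("times and absorbance must be 1-D arrays of equal length")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not self.epsilon_mM_cm > 0:
            raise ValueError("epsilon must be > 0")
        if not self.path_cm > 0 or not self.volume_ml > 0:
            raise ValueError("path length and volume must be > 0")
        if not self.protein_mg > 0:
            raise ValueError("protein mass must be > 0")
        if self.electrons_per_chromophore < 1:
            raise ValueError("electrons_per_chromophore must be >= 1")
        object.__setattr__(self, "times_min", times)
        object.__setattr__(self, "absorbance", absorbance)


@dataclass(frozen=True)
class ActivityResult:
    """Signed specific activity with the fitted slope; direction flags consumption."""

    activity_u_per_mg: float
    slope_a_per_min: float
    r_squared: float
    direction: str  # "production", "consumption" or "flat"


def specific_activity(trace: AssayTrace, window: slice | None = None) -> ActivityResult:
    """Specific activity (U/mg) from the least-squares absorbance slope.

    slope [A/min] -> / (epsilon * path) [mM/min] -> * volume [umol/min]
    -> * electrons_per_chromophore [umol e-/min] -> / 2 [U] -> / protein [U/mg].
    A negative slope (chromophore consumed) yields a signed activity with
    ``direction = "consumption"``.
    """
    times = trace.times_min if window is None else trace.times_min[window]
    absorbance = trace.absorbance if window is None else trace.absorbance[window]
    if times.size < 3:
        raise ValueError("need >= 3 points in the linear window")
    fit = stats.linregress(times, absorbance)
    slope = float(fit.slope)
    rate_mM_per_min = slope / (trace.epsilon_mM_cm * trace.path_cm)
    umol_per_min = rate_mM_per_min * trace.volume_ml  # mM * mL = umol
    umol_electrons_per_min = umol_per_min * trace.electrons_per_chromophore
    units = umol_electrons_per_min / ELECTRONS_PER_UNIT
    activity = units / trace.protein_mg
    if slope > 0:
        direction = "production"
    elif slope < 0:
        direction = "consumption"
    else:
        direction = "flat"
    r_squared = float(fit.rvalue**2) if np.std(absorbance) > 0 else 1.0
    return ActivityResult(activity, slope, r_squared, direction)


def fold_change(a: float, b: float, rounded: bool = False) -> float:
    """Activity ratio a/b, optionally rounded to the nearest integer for report parity."""
    if not b > 0:
        raise ValueError(f"denominator activity must be > 0, got {b!r}")
    ratio = a / b
    if rounded:
        # round half away from zero, matching printed n-fold statements
        return float(math.floor(ratio + 0.5) if ratio >= 0 else math.ceil(ratio - 0.5))
    return ratio


@dataclass(frozen=True)
class GrowthCurve:
    """An OD600 time series (hours) with an optional exponential-phase window."""

    times_h: np.ndarray
    od600: np.ndarray
    window: slice | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times_h, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        if times.shape != od.shape or times.ndim != 1:
            raise ValueError("times and OD must be 1-D arrays of equal length")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times_h", times)
        object.__setattr__(self, "od600", od)


class GrowthFitError(ValueError):
    """Raised when no exponential growth rate can be fitted."""


@dataclass(frozen=True)
class GrowthFit:
    """Specific growth rate mu (1/h), doubling time ln2/mu (h) and fit quality."""

    mu_per_h: float
    doubling_time_h: float
    r_squared: float


def fit_growth(curve: GrowthCurve, window: slice | None = None) -> GrowthFit:
    """OLS fit of ln(OD600) vs time over the window; td = ln 2 / mu."""
    win = window if window is not None else curve.window
    times = curve.times_h if win is None else curve.times_h[win]
    od = curve.od600 if win is None else curve.od600[win]
    if times.size < 3:
        raise GrowthFitError("need >= 3 points in the fit window")
    if np.any(od <= 0):
        raise GrowthFitError("OD must be positive within the fit window")
    fit = stats.linregress(times, np.log(od))
    mu = float(fit.slope)
    if mu <= 0:
        raise GrowthFitError(f"no positive growth rate in window (mu = {mu:.4g} 1/h)")
    r_squared = float(fit.rvalue**2) if np.std(np.log(od)) > 0 else 1.0
    return GrowthFit(mu_per_h=mu, doubling_time_h=math.log(2.0) / mu, r_squared=r_squared)


def auto_window(curve: GrowthCurve, min_points: int = 3, r2_threshold: float = 0.99) -> slice:
    """The longest contiguous window with positive OD and log-linear R^2 >= threshold."""
    n = curve.times_h.size
    best: tuple[int, int] | None = None
    for start in range(n - min_points + 1):
        for stop in range(start + min_points, n + 1):
            od = curve.od600[start:stop]
            if np.any(od <= 0):
                continue
            fit = stats.linregress(curve.times_h[start:stop], np.log(od))
            if fit.slope > 0 and fit.rvalue**2 >= r2_threshold:
                if best is None or stop - start > best[1] - best[0]:
                    best = (start, stop)
    if best is None:
        raise GrowthFitError("no log-linear window found")
    return slice(*best)


def growth_consistency(mu_per_h: float, doubling_time_h: float, rel_tol: float = 0.01) -> dict:
    """Cross-derive mu and td from each other and flag printed pairs that disagree.

    A reported pair like td = 12.4 h with mu = 0.055 1/h is internally
    inconsistent at three decimals (ln 2 / 12.4 = 0.0559); both derived
    values are returned together with a consistency flag rather than
    silently preferring one.
    """
    if not mu_per_h > 0 or not doubling_time_h > 0:
        raise ValueError("mu and doubling time must be > 0")
    td_from_mu = math.log(2.0) / mu_per_h
    mu_from_td = math.log(2.0) / doubling_time_h
    consistent = abs(td_from_mu - doubling_time_h) <= rel_tol * doubling_time_h
    return {
        "mu_per_h": mu_per_h,
        "doubling_time_h": doubling_time_h,
        "td_from_mu_h": td_from_mu,
        "mu_from_td_per_h": mu_from_td,
        "consistent": consistent,
    }
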