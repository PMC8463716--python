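"""Decay-curve models: the single-loop-of-current (SLC) source, comparison
regressions, screen extrapolation, analytic gradients, and threshold-distance
solving.

The SLC model idealizes a button magnet (phone speaker or microphone) as a
circular current loop of radius r carrying current I around a core of
relative permeability µ_r, buried at half the phone thickness T below the
screen.  On the loop axis,

    B(z) = µ_r µ0 I r² / (2 [(z + T/2)² + r²]^(3/2)),

with z measured from the screen.  µ_r multiplies the free-space loop field
as a plain scalar (an idealization, not a magnetostatic boundary-value
solution) and is degenerate with I, so it is held fixed (5000) and never
fitted.  Two conventional regressions, exponential a·e^(−bz) and power-law
a·z^(−b), are provided for comparison; all three are fit by unweighted least
squares on the original µT scale (a 1/Uc² weighted option exists but is off
by default), and R² is reported on that same scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize

from .constants import G_THRESHOLD_MT_PER_MM, MU0, MU_R_DEFAULT
from .fieldmap import DecayCurve

__all__ = [
    "SLCFit",
    "RegressionFit",
    "FitConvergenceError",
    "ThresholdDistance",
    "slc_field",
    "slc_gradient",
    "fit_slc",
    "fit_exponential",
    "fit_power",
    "compare_fits",
    "threshold_distance",
    "induced_rate_estimate",
]


class FitConvergenceError(RuntimeError):
    """Raised when a regression fails to converge; carries the best residual."""

    def __init__(self, message: str, best_cost: float | None = None):
        super().__init__(message)
        self.best_cost = best_cost


@dataclass(frozen=True)
class SLCFit:
    """Fitted (or prescribed) single-loop-of-current source parameters."""

    r_mm: float
    I_mA: float
    T_mm: float
    mu_r: float = MU_R_DEFAULT
    r_squared: float = math.nan

    def __post_init__(self) -> None:
        if self.r_mm <= 0:
            raise ValueError("loop radius must be positive")
        if self.I_mA <= 0:
            raise ValueError("loop current must be positive")
        if self.T_mm <= 0:
            raise ValueError("phone thickness must be positive")

    @property
    def B_at_0_uT(self) -> float:
        return float(slc_field(0.0, self))

    @property
    def B_at_0_mT(self) -> float:
        """Field magnitude extrapolated to the screen surface, mT."""
        return self.B_at_0_uT / 1e3


@dataclass(frozen=True)
class RegressionFit:
    """Exponential or power-law comparison regression.

    Unit conventions follow the reporting convention for these fits: the
    exponential amplitude ``a`` is in mT (it *is* B@0) with ``b`` in 1/mm;
    the power-law amplitude ``a`` is in µT (with z in mm) and ``b`` is
    dimensionless.  The power law diverges at z=0, so it has no finite B@0.
    """

    family: str  # "exponential" | "power"
    a: float
    b: float
    r_squared: float = math.nan

    def __post_init__(self) -> None:
        if self.family not in ("exponential", "power"):
            raise ValueError("family must be 'exponential' or 'power'")

    @property
    def B_at_0_mT(self) -> float:
        return self.a if self.family == "exponential" else math.inf

    def predict_uT(self, z_mm):
        z = np.asarray(z_mm, dtype=float)
        if self.family == "exponential":
            return self.a * 1e3 * np.exp(-self.b * z)
        return self.a * z ** (-self.b)


def _slc_field_uT(z_mm, r_mm: float, I_mA: float, T_mm: float, mu_r: float):
    """Closed-form on-axis loop field, µT.  Lengths mm, current mA.

    With I in mA and lengths in mm the SI prefactors cancel so that
    B[T] = µ_r µ0 I_mA r² / (2 d³) with r, d numerically in mm.
    """
    u = np.asarray(z_mm, dtype=float) + T_mm / 2.0
    return 1e6 * mu_r * MU0 * I_mA * r_mm**2 / (2.0 * (u * u + r_mm * r_mm) ** 1.5)


def slc_field(z_mm, fit: SLCFit):
    """Evaluate the SLC model at height(s) z above the screen, in µT."""
    z = np.asarray(z_mm, dtype=float)
    if np.any(z < -fit.T_mm / 2.0):
        raise ValueError("z below the loop plane (z < -T/2)")
    out = _slc_field_uT(z, fit.r_mm, fit.I_mA, fit.T_mm, fit.mu_r)
    return float(out) if np.isscalar(z_mm) else out


def slc_gradient(z_mm, fit: SLCFit):
    """Analytic dB/dz of the SLC model, µT/mm (signed; negative above loop).

    dB/dz = −3 µ_r µ0 I r² (z + T/2) / (2 [(z + T/2)² + r²]^(5/2)); zero at
    the loop plane by symmetry.
    """
    z = np.asarray(z_mm, dtype=float)
    if np.any(z < -fit.T_mm / 2.0):
        raise ValueError("z below the loop plane (z < -T/2)")
    u = z + fit.T_mm / 2.0
    out = (
        -3e6 * fit.mu_r * MU0 * fit.I_mA * fit.r_mm**2 * u
        / (2.0 * (u * u + fit.r_mm**2) ** 2.5)
    )
    return float(out) if np.isscalar(z_mm) else out


def _r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("constant curve: R² undefined (no decay to fit)")
    return 1.0 - ss_res / ss_tot


def _weights(curve: DecayCurve, weighted: bool) -> np.ndarray:
    if not weighted:
        return np.ones_like(curve.B_uT)
    if curve.Uc_uT is None or np.any(curve.Uc_uT <= 0):
        raise ValueError("weighted fit requires strictly positive Uc on every point")
    return 1.0 / curve.Uc_uT


def _check_fittable(curve: DecayCurve) -> None:
    if len(curve) < 3:
        raise ValueError("need at least 3 points to fit a decay model")
    if np.any(curve.B_uT <= 0):
        raise ValueError("decay-curve values must be positive")


_R_BOUNDS_MM = (1.0, 30.0)
_I_BOUNDS_MA = (0.05, 200.0)


def fit_slc(
    curve: DecayCurve,
    T_mm: float,
    mu_r: float = MU_R_DEFAULT,
    weighted: bool = False,
    max_restarts: int = 5,
) -> SLCFit:
    """Least-squares fit of (r, I) on the untransformed µT scale.

    Starts from r0 = 8 mm with I0 chosen to match the first curve point
    exactly, restarting with r0 jittered by up to ±50% (deterministically)
    if the optimizer does not converge.  µ_r stays fixed throughout.
    """
    _check_fittable(curve)
    w = _weights(curve, weighted)
    z, B = curve.z_mm, curve.B_uT
    if np.sum((B - B.mean()) ** 2) == 0:
        raise ValueError("constant curve: nothing to fit")
    # the current bounds assume the default core; only mu_r * I is physical,
    # so rescale them when fitting with a different permeability
    i_bounds = tuple(b * MU_R_DEFAULT / mu_r for b in _I_BOUNDS_MA)

    def residuals(params):
        r, I = params
        return (_slc_field_uT(z, r, I, T_mm, mu_r) - B) * w

    def initial_current(r0: float) -> float:
        unit = _slc_field_uT(z[0], r0, 1.0, T_mm, mu_r)
        return float(np.clip(B[0] / unit, *i_bounds))

    rng = np.random.default_rng(20210924)
    best = None
    r0 = 8.0
    for attempt in range(max_restarts + 1):
        res = optimize.least_squares(
            residuals,
            x0=[r0, initial_current(r0)],
            bounds=([_R_BOUNDS_MM[0], i_bounds[0]], [_R_BOUNDS_MM[1], i_bounds[1]]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        if best is None or res.cost < best.cost:
            best = res
        if res.success:
            break
        r0 = float(np.clip(8.0 * (1.0 + rng.uniform(-0.5, 0.5)), *_R_BOUNDS_MM))
    if best is None or not best.success:
        raise FitConvergenceError(
            "SLC fit did not converge", best_cost=None if best is None else best.cost
        )
    r, I = best.x
    fit = SLCFit(r_mm=float(r), I_mA=float(I), T_mm=T_mm, mu_r=mu_r)
    return replace(fit, r_squared=_r_squared(B, slc_field(z, fit)))


def fit_exponential(curve: DecayCurve, weighted: bool = False) -> RegressionFit:
    """Fit B = a·e^(−bz) by least squares on the µT scale; a reported in mT."""
    _check_fittable(curve)
    w = _weights(curve, weighted)
    z, B = curve.z_mm, curve.B_uT
    # log-linear start, refined on the original scale
    slope, intercept = np.polyfit(z, np.log(B), 1)
    p0 = [math.exp(intercept), -slope]
    try:
        popt, _ = optimize.curve_fit(
            lambda zz, a, b: a * np.exp(-b * zz), z, B, p0=p0, sigma=1.0 / w, maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise FitConvergenceError(f"exponential fit did not converge: {exc}") from exc
    a_uT, b = popt
    fit = RegressionFit(family="exponential", a=float(a_uT) / 1e3, b=float(b))
    return replace(fit, r_squared=_r_squared(B, fit.predict_uT(z)))


def fit_power(curve: DecayCurve, weighted: bool = False) -> RegressionFit:
    """Fit B = a·z^(−b) by least squares on the µT scale; a in µT, z in mm."""
    _check_fittable(curve)
    if np.any(curve.z_mm <= 0):
        raise ValueError("power-law fit requires all z > 0")
    w = _weights(curve, weighted)
    z, B = curve.z_mm, curve.B_uT
    slope, intercept = np.polyfit(np.log(z), np.log(B), 1)
    p0 = [math.exp(intercept), -slope]
    try:
        popt, _ = optimize.curve_fit(
            lambda zz, a, b: a * zz ** (-b), z, B, p0=p0, sigma=1.0 / w, maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover
        raise FitConvergenceError(f"power fit did not converge: {exc}") from exc
    fit = RegressionFit(family="power", a=float(popt[0]), b=float(popt[1]))
    return replace(fit, r_squared=_r_squared(B, fit.predict_uT(z)))


def compare_fits(
    curve: DecayCurve, T_mm: float, mu_r: float = MU_R_DEFAULT, weighted: bool = False
) -> pd.DataFrame:
    """Fit all three families and rank them by R² (descending).

    Columns: family, a, b (regression families), r_mm, I_mA (SLC), r_squared,
    B_at_0_mT (infinite for the power law).  ``df.attrs['low_dof']`` flags
    curves with fewer than two residual degrees of freedom.
    """
    slc = fit_slc(curve, T_mm=T_mm, mu_r=mu_r, weighted=weighted)
    expo = fit_exponential(curve, weighted=weighted)
    power = fit_power(curve, weighted=weighted)
    rows = [
        {
            "family": "slc",
            "a": math.nan,
            "b": math.nan,
            "r_mm": slc.r_mm,
            "I_mA": slc.I_mA,
            "r_squared": slc.r_squared,
            "B_at_0_mT": slc.B_at_0_mT,
        },
        {
            "family": "exponential",
            "a": expo.a,
            "b": expo.b,
            "r_mm": math.nan,
            "I_mA": math.nan,
            "r_squared": expo.r_squared,
            "B_at_0_mT": expo.B_at_0_mT,
        },
        {
            "family": "power",
            "a": power.a,
            "b": power.b,
            "r_mm": math.nan,
            "I_mA": math.nan,
            "r_squared": power.r_squared,
            "B_at_0_mT": power.B_at_0_mT,
        },
    ]
    df = (
        pd.DataFrame(rows)
        .sort_values("r_squared", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    df.attrs["low_dof"] = len(curve) - 2 < 2
    return df


class ThresholdDistance(NamedTuple):
    """Result of solving |dB/dz| = threshold; z is 0 when the gradient is
    already below the threshold at the screen surface."""

    z_mm: float
    above_at_screen: bool


def threshold_distance(
    fit: SLCFit,
    g_threshold_mT_per_mm: float = G_THRESHOLD_MT_PER_MM,
    z_max_mm: float = 200.0,
) -> ThresholdDistance:
    """Distance from the screen out to which |dB/dz| exceeds a threshold.

    Solved by bisection (scipy brentq, 1e-3 mm tolerance) on [0, z_max].
    The gradient magnitude has at most one interior maximum (at
    z = r/2 − T/2 when that is positive) and then decreases monotonically,
    so a single sign change is guaranteed whenever |dB/dz|(0) > threshold
    > |dB/dz|(z_max); the bracket is verified before solving.
    """
    if g_threshold_mT_per_mm <= 0:
        raise ValueError("threshold must be positive")
    thr_uT = g_threshold_mT_per_mm * 1e3

    def excess(z):
        return abs(slc_gradient(z, fit)) - thr_uT

    if excess(0.0) <= 0:
        return ThresholdDistance(z_mm=0.0, above_at_screen=False)
    if excess(z_max_mm) >= 0:
        raise ValueError(
            f"gradient still above threshold at z={z_max_mm} mm; "
            "threshold too small for the search interval"
        )
    z_star = optimize.brentq(excess, 0.0, z_max_mm, xtol=1e-3)
    return ThresholdDistance(z_mm=float(z_star), above_at_screen=True)


def induced_rate_estimate(B_peak_mT: float, motion_duration_s: float) -> float:
    """Order-of-magnitude dB/dt (mT/s) for bringing the phone to the head.

    Moving the phone through its peak field in ``motion_duration_s`` seconds
    produces a transient rate of change ~ B_peak / duration, to be compared
    with the 2.7 T/s reference level for motion-induced electric fields.
    """
    if B_peak_mT <= 0 or motion_duration_s <= 0:
        raise ValueError("peak field and duration must be positive")
    return B_peak_mT / motion_duration_s
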