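"""Four-component measurement uncertainty budget.

The combined uncertainty on a mapped |B| value is the quadrature sum of
four sources: (1) repeatability, the sample SD of the triplicate
magnitudes; (2) the sensor zeroing error (bounded by 2 µT); (3) the
fractional calibration error (0.5% of the reading); and (4) the
z-positioning error, |dB/dz| times the 1.5-1.7 mm height uncertainty.
No sensitivity-coefficient machinery beyond this fixed quadrature is
implemented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import DELTA_Z_MM, U_CAL_FRACTION, U_ZERO_UT
from .fieldmap import DecayCurve

__all__ = [
    "UncertaintyBudget",
    "combine",
    "gradient_uncertainty",
    "finite_difference_gradient",
]


@dataclass(frozen=True)
class UncertaintyBudget:
    """The four uncertainty components (µT) attached to one |B| reading.

    ``u_cal_uT`` is already the product of the calibration fraction and the
    reading.  ``u_c_uT`` is their quadrature combination.
    """

    B_uT: float
    sd_uT: float
    u_zero_uT: float
    u_cal_uT: float
    u_grad_uT: float

    def __post_init__(self) -> None:
        for name in ("B_uT", "sd_uT", "u_zero_uT", "u_cal_uT", "u_grad_uT"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")

    @property
    def u_c_uT(self) -> float:
        return math.sqrt(
            self.sd_uT**2 + self.u_zero_uT**2 + self.u_cal_uT**2 + self.u_grad_uT**2
        )


def combine(
    B_uT: float,
    sd_uT: float,
    u_zero_uT: float = U_ZERO_UT,
    u_cal_fraction: float = U_CAL_FRACTION,
    u_grad_uT: float = 0.0,
) -> UncertaintyBudget:
    """Build the budget for one reading; ``u_cal = u_cal_fraction * B``.

    The calibration term applies to the measured |B| at the node (the
    sensor scales its reading, background included), not to a background-
    free truth.
    """
    if u_cal_fraction < 0:
        raise ValueError("u_cal_fraction must be non-negative")
    return UncertaintyBudget(
        B_uT=B_uT,
        sd_uT=sd_uT,
        u_zero_uT=u_zero_uT,
        u_cal_uT=u_cal_fraction * B_uT,
        u_grad_uT=u_grad_uT,
    )


def gradient_uncertainty(dBdz_uT_per_mm: float, delta_z_mm: float = DELTA_Z_MM) -> float:
    """Uncertainty (µT) from the field gradient crossed with the z error."""
    if delta_z_mm < 0:
        raise ValueError("delta_z must be non-negative")
    if delta_z_mm > 5.0:
        raise ValueError("delta_z outside the credible 0-5 mm range")
    return abs(dBdz_uT_per_mm) * delta_z_mm


def finite_difference_gradient(curve: DecayCurve) -> np.ndarray:
    """First-difference slopes of a measured decay curve.

    Returns an (n-1, 2) array of (z midpoint mm, dB/dz µT/mm), one row per
    interval.  This model-free estimate feeds the U_grad budget term before
    any regression exists; the fitted-model gradient can replace it later.
    """
    dz = np.diff(curve.z_mm)
    if np.any(dz == 0):
        raise ValueError("duplicate z values in decay curve")
    slopes = np.diff(curve.B_uT) / dz
    z_mid = 0.5 * (curve.z_mm[:-1] + curve.z_mm[1:])
    return np.column_stack([z_mid, slopes])
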