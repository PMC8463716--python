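"""Built-in survey of five consumer phone models (2013-2018).

For each phone: outer dimensions, the screen locations of its magnetic hot
spots (the speaker magnet near the top of the screen, the microphone magnet
near the bottom; one model has no detectable lower spot), the measured
|B|max ± combined uncertainty at 15 mm and 55 mm above the screen, and the
parameters of the three decay regressions fitted to the measured curves —
exponential a·e^(−bz) (a in mT), power-law a·z^(−b) (a in µT), and the
single-loop-of-current model (r in mm, I in mA, µ_r = 5000).

These values are the package's standard worked inputs: screen extrapolation,
gradient and threshold-distance calculations, and head-surface dosimetry all
start from this table when no user measurements are supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import MU_R_DEFAULT
from .decay_models import RegressionFit, SLCFit
from .fieldmap import PhoneGeometry
from .synthetic_data import GroundTruthPhone, LoopSource

__all__ = ["HotSpotRecord", "PhoneRecord", "REFERENCE_PHONES", "all_hotspots", "truth_from_record"]


@dataclass(frozen=True)
class HotSpotRecord:
    """One hot spot: location, measured peaks, and fitted decay models."""

    label: str
    x_mm: float
    y_mm: float
    B15_uT: float
    Uc15_uT: float
    B55_uT: float
    Uc55_uT: float
    slc: SLCFit
    exponential: RegressionFit
    power: RegressionFit


@dataclass(frozen=True)
class PhoneRecord:
    model: str
    geometry: PhoneGeometry
    hotspots: tuple[HotSpotRecord, ...]


def _hs(label, x, y, b15, u15, b55, u55, T, exp_a, exp_b, exp_r2, pow_a, pow_b, pow_r2, r, I, slc_r2):
    return HotSpotRecord(
        label=label,
        x_mm=x,
        y_mm=y,
        B15_uT=b15,
        Uc15_uT=u15,
        B55_uT=b55,
        Uc55_uT=u55,
        slc=SLCFit(r_mm=r, I_mA=I, T_mm=T, mu_r=MU_R_DEFAULT, r_squared=slc_r2),
        exponential=RegressionFit("exponential", a=exp_a, b=exp_b, r_squared=exp_r2),
        power=RegressionFit("power", a=pow_a, b=pow_b, r_squared=pow_r2),
    )


REFERENCE_PHONES: tuple[PhoneRecord, ...] = (
    PhoneRecord(
        model="1",
        geometry=PhoneGeometry(L_mm=146.9, W_mm=70.9, T_mm=8.4, model_label="MODEL 1"),
        hotspots=(
            _hs("UPPER", 0.0, 70.0, 381.9, 81.4, 17.5, 2.6, 8.4,
                0.93, 0.074, 0.982, 250029.0, 2.369, 0.995, 8.0, 17.2, 0.998),
            _hs("LOWER", 0.0, -60.0, 705.3, 123.9, 30.9, 3.4, 8.4,
                1.77, 0.075, 0.981, 537816.0, 2.419, 0.995, 10.0, 22.6, 0.998),
        ),
    ),
    PhoneRecord(
        model="2",
        geometry=PhoneGeometry(L_mm=143.6, W_mm=70.9, T_mm=7.7, model_label="MODEL 2"),
        hotspots=(
            _hs("UPPER", -10.0, 60.0, 584.7, 111.5, 32.4, 3.1, 7.7,
                1.32, 0.069, 0.974, 262720.0, 2.236, 0.998, 9.5, 19.8, 0.998),
            _hs("LOWER", 30.0, -60.0, 59.8, 12.8, 3.5, 2.2, 7.7,
                0.13, 0.068, 0.962, 23115.0, 2.196, 0.999, 8.0, 2.59, 0.998),
        ),
    ),
    PhoneRecord(
        model="3",
        geometry=PhoneGeometry(L_mm=142.3, W_mm=71.0, T_mm=7.8, model_label="MODEL 3"),
        hotspots=(
            _hs("UPPER", -20.0, 50.0, 820.2, 139.2, 40.2, 3.4, 7.8,
                2.10, 0.073, 0.985, 537666.0, 2.350, 0.993, 10.0, 26.0, 0.996),
            # no lower hot spot detected for this model
        ),
    ),
    PhoneRecord(
        model="4",
        geometry=PhoneGeometry(L_mm=133.9, W_mm=68.7, T_mm=7.5, model_label="MODEL 4"),
        hotspots=(
            _hs("UPPER", 0.0, 60.0, 242.3, 50.0, 11.1, 2.3, 7.5,
                0.77, 0.082, 0.948, 109264.0, 2.228, 0.996, 6.0, 16.0, 0.997),
            _hs("LOWER", 30.0, -50.0, 404.8, 72.8, 29.6, 2.7, 7.5,
                1.12, 0.070, 0.948, 77710.0, 1.949, 0.997, 11.0, 11.6, 0.998),
        ),
    ),
    PhoneRecord(
        model="5",
        geometry=PhoneGeometry(L_mm=139.6, W_mm=69.7, T_mm=9.1, model_label="MODEL 5"),
        hotspots=(
            _hs("UPPER", 0.0, 60.0, 222.0, 43.9, 9.2, 2.5, 9.1,
                0.58, 0.077, 0.983, 203089.0, 2.478, 0.995, 7.0, 13.2, 0.997),
            _hs("LOWER", -20.0, -50.0, 361.0, 63.9, 16.4, 2.6, 9.1,
                0.92, 0.075, 0.985, 266219.0, 2.399, 0.994, 8.0, 17.0, 0.997),
        ),
    ),
)


def all_hotspots() -> list[tuple[PhoneRecord, HotSpotRecord]]:
    """Flat (phone, hot spot) pairs over the whole survey (nine in total)."""
    return [(p, h) for p in REFERENCE_PHONES for h in p.hotspots]


def truth_from_record(phone: PhoneRecord) -> GroundTruthPhone:
    """Ground-truth generator input using the fitted loops as real sources."""
    return GroundTruthPhone(
        geometry=phone.geometry,
        loops=tuple(
            LoopSource(label=h.label, x_mm=h.x_mm, y_mm=h.y_mm, r_mm=h.slc.r_mm, I_mA=h.slc.I_mA)
            for h in phone.hotspots
        ),
        mu_r=MU_R_DEFAULT,
    )
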