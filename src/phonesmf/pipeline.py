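"""End-to-end study orchestration.

``run_pipeline`` drives the full analysis: simulate (or load) a mapping
campaign, average the triplicates component-wise, vector-subtract the
averaged background map, take magnitudes, detect the hot spots on the
lowest-z map and hold their (x, y) fixed across heights, assemble decay
curves with the four-term uncertainty budget, fit the three decay models,
extrapolate to the screen, and solve gradient threshold distances — writing
plain-text reports shaped like the study's summary tables.  Outputs are
bit-stable under a fixed seed.

All physical constants (µ_r, gradient threshold, u_zero, u_cal, delta_z,
skull depth) live in :class:`StudyConfig` with the study defaults and are
never hard-coded in stage logic.
"""

from __future__ import annotations

import logging
import math
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import constants
from .decay_models import (
    SLCFit,
    compare_fits,
    slc_field,
    slc_gradient,
    threshold_distance,
)
from .fieldmap import (
    DecayCurve,
    FieldMap,
    GridSpec,
    HotSpot,
    PhoneGeometry,
    average_replicates,
    detect_hotspots,
    extract_decay_curve,
    magnitude,
    subtract_background,
)
from .gridio import read_grid_csv, write_grid_csv, write_magnitude_csv  # noqa: F401  (public surface)
from .synthetic_data import (
    GroundTruthPhone,
    LoopSource,
    NoiseModel,
    StudyDataset,
    simulate_study,
)
from .uncertainty import combine, finite_difference_gradient, gradient_uncertainty

__all__ = [
    "StudyConfig",
    "HotSpotAnalysis",
    "ReportBundle",
    "analyze_study",
    "run_pipeline",
    "load_study",
    "read_grid_csv",
    "write_grid_csv",
]

log = logging.getLogger("phonesmf.pipeline")


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to reproduce one pipeline run."""

    phone: GroundTruthPhone
    z_list_mm: tuple[float, ...] = constants.Z_LEVELS_MM
    n_replicates: int = 3
    background_uT: tuple[float, float, float] = constants.GMF_TYPICAL_UT
    noise: NoiseModel = field(default_factory=NoiseModel)
    grid: GridSpec = field(default_factory=GridSpec)
    mu_r: float = constants.MU_R_DEFAULT
    g_threshold_mT_per_mm: float = constants.G_THRESHOLD_MT_PER_MM
    u_zero_uT: float = constants.U_ZERO_UT
    u_cal_fraction: float = constants.U_CAL_FRACTION
    delta_z_mm: float = constants.DELTA_Z_MM
    skull_depth_mm: float = constants.SKULL_DEPTH_MM
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "z_list_mm", tuple(float(z) for z in self.z_list_mm))
        object.__setattr__(
            self, "background_uT", tuple(float(c) for c in self.background_uT)
        )
        for name in (
            "mu_r",
            "g_threshold_mT_per_mm",
            "u_zero_uT",
            "u_cal_fraction",
            "delta_z_mm",
            "skull_depth_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    # -- serialization ------------------------------------------------------

    def to_toml(self) -> str:
        g = self.phone.geometry
        n = self.noise
        lines = [
            "[phone]",
            f'model_label = "{g.model_label}"',
            f"L_mm = {g.L_mm!r}",
            f"W_mm = {g.W_mm!r}",
            f"T_mm = {g.T_mm!r}",
            "",
        ]
        for lp in self.phone.loops:
            lines += [
                "[[phone.loops]]",
                f'label = "{lp.label}"',
                f"x_mm = {lp.x_mm!r}",
                f"y_mm = {lp.y_mm!r}",
                f"r_mm = {lp.r_mm!r}",
                f"I_mA = {lp.I_mA!r}",
                "",
            ]
        lines += [
            "[study]",
            f"z_list_mm = {list(self.z_list_mm)!r}",
            f"n_replicates = {self.n_replicates}",
            f"background_uT = {list(self.background_uT)!r}",
            f"seed = {self.seed}",
            f'outdir = "{self.outdir}"' if self.outdir else 'outdir = ""',
            "",
            "[grid]",
            f"x_extent_mm = {self.grid.x_extent_mm!r}",
            f"y_extent_mm = {self.grid.y_extent_mm!r}",
            f"pitch_mm = {self.grid.pitch_mm!r}",
            "",
            "[noise]",
            f"sensor_noise_rms_uT = {n.sensor_noise_rms_uT!r}",
            f"zero_offset_bound_uT = {n.zero_offset_bound_uT!r}",
            f"cal_scale_error = {n.cal_scale_error!r}",
            f"z_offset_sd_mm = {n.z_offset_sd_mm!r}",
            f"z_jitter_sd_mm = {n.z_jitter_sd_mm!r}",
            f"seed = {n.seed}",
            "",
            "[constants]",
            f"mu_r = {self.mu_r!r}",
            f"g_threshold_mT_per_mm = {self.g_threshold_mT_per_mm!r}",
            f"u_zero_uT = {self.u_zero_uT!r}",
            f"u_cal_fraction = {self.u_cal_fraction!r}",
            f"delta_z_mm = {self.delta_z_mm!r}",
            f"skull_depth_mm = {self.skull_depth_mm!r}",
            "",
        ]
        return "\n".join(lines)

    @classmethod
    def from_toml(cls, text: str) -> "StudyConfig":
        doc = tomllib.loads(text)
        ph = doc["phone"]
        geometry = PhoneGeometry(
            L_mm=ph["L_mm"], W_mm=ph["W_mm"], T_mm=ph["T_mm"], model_label=ph.get("model_label", "")
        )
        consts = doc.get("constants", {})
        phone = GroundTruthPhone(
            geometry=geometry,
            loops=tuple(
                LoopSource(lp["label"], lp["x_mm"], lp["y_mm"], lp["r_mm"], lp["I_mA"])
                for lp in ph.get("loops", [])
            ),
            mu_r=consts.get("mu_r", constants.MU_R_DEFAULT),
        )
        study = doc.get("study", {})
        grid_doc = doc.get("grid", {})
        noise_doc = doc.get("noise", {})
        kwargs = dict(
            phone=phone,
            z_list_mm=tuple(study.get("z_list_mm", constants.Z_LEVELS_MM)),
            n_replicates=study.get("n_replicates", 3),
            background_uT=tuple(study.get("background_uT", constants.GMF_TYPICAL_UT)),
            noise=NoiseModel(**noise_doc) if noise_doc else NoiseModel(),
            grid=GridSpec(**grid_doc) if grid_doc else GridSpec(),
            seed=study.get("seed", 0),
            outdir=study.get("outdir") or None,
        )
        for name in (
            "mu_r",
            "g_threshold_mT_per_mm",
            "u_zero_uT",
            "u_cal_fraction",
            "delta_z_mm",
            "skull_depth_mm",
        ):
            if name in consts:
                kwargs[name] = consts[name]
        return cls(**kwargs)


def load_study(path) -> StudyDataset:
    """Load a dataset written by :func:`phonesmf.synthetic_data.write_study`."""
    path = Path(path)
    doc = tomllib.loads((path / "manifest.toml").read_text())
    ph = doc["phone"]
    truth = GroundTruthPhone(
        geometry=PhoneGeometry(ph["L_mm"], ph["W_mm"], ph["T_mm"], ph.get("model_label", "")),
        loops=tuple(
            LoopSource(lp["label"], lp["x_mm"], lp["y_mm"], lp["r_mm"], lp["I_mA"])
            for lp in ph.get("loops", [])
        ),
        mu_r=ph.get("mu_r", constants.MU_R_DEFAULT),
    )
    study = doc["study"]
    noise = NoiseModel(**doc["noise"])
    z_list = tuple(float(z) for z in study["z_list_mm"])
    n_rep = int(study["n_replicates"])
    phone_maps = {}
    for z in z_list:
        maps = []
        for rep in range(n_rep):
            m = read_grid_csv(path / "maps" / f"phone_z{z:g}_rep{rep}.csv", z_nominal_mm=z)
            maps.append(replace(m, phone=truth.geometry, replicate_id=rep))
        phone_maps[z] = tuple(maps)
    background_maps = tuple(
        replace(read_grid_csv(path / "maps" / f"background_rep{rep}.csv"), replicate_id=rep)
        for rep in range(n_rep)
    )
    return StudyDataset(
        truth=truth,
        z_list_mm=z_list,
        n_replicates=n_rep,
        background_uT=tuple(study["background_uT"]),
        noise=noise,
        phone_maps=phone_maps,
        background_maps=background_maps,
    )


@dataclass(frozen=True)
class HotSpotAnalysis:
    """Per-hot-spot products of the pipeline."""

    spot: HotSpot
    curve: DecayCurve
    budgets: dict[float, object]
    fits: pd.DataFrame  # ranked compare_fits table
    slc: SLCFit
    grad_at_screen_mT_per_mm: float
    threshold_z_mm: float
    above_threshold_at_screen: bool
    skull_exposure_above_thresholds: bool


@dataclass(frozen=True)
class ReportBundle:
    """DataFrame reports of one pipeline run."""

    hotspot_levels: pd.DataFrame  # per (hot spot, z): B, budget components, Uc
    fits: pd.DataFrame  # per (hot spot, family): parameters, R², B@0
    gradients: pd.DataFrame  # per hot spot: screen gradient, threshold distance
    analyses: tuple[HotSpotAnalysis, ...]

    def write(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.hotspot_levels.to_csv(outdir / "hotspot_levels.csv", index=False, float_format="%.6g")
        self.fits.to_csv(outdir / "fits.csv", index=False, float_format="%.6g")
        self.gradients.to_csv(outdir / "gradients.csv", index=False, float_format="%.6g")
        return outdir


def _round_sig(x: float, n: int) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, n - 1 - int(math.floor(math.log10(abs(x)))))


def analyze_study(dataset: StudyDataset, config: StudyConfig) -> ReportBundle:
    """Run the processing/fitting stages on an in-memory dataset."""
    model = dataset.truth.geometry.model_label
    # stage: average replicates, subtract averaged background, magnitudes
    if dataset.n_replicates >= 2:
        bg_mean, _ = average_replicates(dataset.background_maps)
    else:
        bg_mean = dataset.background_maps[0]
    mags: dict[float, object] = {}
    for z in dataset.z_list_mm:
        maps = dataset.phone_maps[z]
        if len(maps) >= 2:
            mean, sd = average_replicates(maps)
        else:
            mean, sd = maps[0], np.zeros((maps[0].grid.ny, maps[0].grid.nx))
        sub = subtract_background(mean, bg_mean)
        mag = magnitude(sub)
        mags[z] = replace(mag, sd=sd)
    log.info(
        "stage=process model=%r z_levels=%d replicates=%d seed=%d",
        model, len(dataset.z_list_mm), dataset.n_replicates, dataset.noise.seed,
    )

    # stage: hot spots on the lowest-z map, positions held fixed across z
    z_lo = min(dataset.z_list_mm)
    spots = detect_hotspots(mags[z_lo], dataset.truth.geometry)
    log.info("stage=hotspots model=%r found=%d", model, len(spots))

    level_rows, fit_rows, grad_rows, analyses = [], [], [], []
    for spot in spots:
        raw = extract_decay_curve(list(mags.values()), spot, require_z=dataset.z_list_mm)
        grads = finite_difference_gradient(raw)
        budgets = {}
        for i, z in enumerate(raw.z_mm):
            # conservative: steeper of the two adjacent interval slopes
            adjacent = [grads[j, 1] for j in (i - 1, i) if 0 <= j < len(grads)]
            u_grad = gradient_uncertainty(max(abs(s) for s in adjacent), config.delta_z_mm)
            iy, ix = mags[z].grid.node_index(spot.x_mm, spot.y_mm)
            sd = float(mags[z].sd[iy, ix]) if mags[z].sd is not None else 0.0
            budgets[float(z)] = combine(
                B_uT=float(raw.B_uT[i]),
                sd_uT=sd,
                u_zero_uT=config.u_zero_uT,
                u_cal_fraction=config.u_cal_fraction,
                u_grad_uT=u_grad,
            )
        curve = extract_decay_curve(list(mags.values()), spot, budgets=budgets)
        spot = replace(
            spot,
            peak_by_z=tuple(
                (float(z), float(b), float(u))
                for z, b, u in zip(curve.z_mm, curve.B_uT, curve.Uc_uT)
            ),
        )
        for z, b, u in zip(curve.z_mm, curve.B_uT, curve.Uc_uT):
            bud = budgets[float(z)]
            level_rows.append(
                {
                    "model": model,
                    "hotspot": spot.label,
                    "x_mm": spot.x_mm,
                    "y_mm": spot.y_mm,
                    "z_mm": z,
                    "B_uT": b,
                    "sd_uT": bud.sd_uT,
                    "u_zero_uT": bud.u_zero_uT,
                    "u_cal_uT": bud.u_cal_uT,
                    "u_grad_uT": bud.u_grad_uT,
                    "u_c_uT": u,
                }
            )

        fits = compare_fits(curve, T_mm=dataset.truth.geometry.T_mm, mu_r=config.mu_r)
        slc_row = fits[fits["family"] == "slc"].iloc[0]
        slc = SLCFit(
            r_mm=float(slc_row["r_mm"]),
            I_mA=float(slc_row["I_mA"]),
            T_mm=dataset.truth.geometry.T_mm,
            mu_r=config.mu_r,
            r_squared=float(slc_row["r_squared"]),
        )
        for _, row in fits.iterrows():
            fit_rows.append({"model": model, "hotspot": spot.label, **row.to_dict()})

        g0_mT = abs(slc_gradient(0.0, slc)) / 1e3
        thr = threshold_distance(slc, config.g_threshold_mT_per_mm)
        z_skull = config.skull_depth_mm
        skull_ok = (
            abs(slc_gradient(z_skull, slc)) / 1e3 > config.g_threshold_mT_per_mm
            and slc_field(z_skull, slc) / 1e3 > constants.B_THRESHOLD_MT
        )
        grad_rows.append(
            {
                "model": model,
                "hotspot": spot.label,
                "B_at_0_mT": _round_sig(slc.B_at_0_mT, 3),
                "grad_at_screen_mT_per_mm": _round_sig(g0_mT, 2),
                "threshold_z_mm": round(thr.z_mm),
                "above_threshold_at_screen": thr.above_at_screen,
                "skull_exposure_above_thresholds": skull_ok,
            }
        )
        analyses.append(
            HotSpotAnalysis(
                spot=spot,
                curve=curve,
                budgets=budgets,
                fits=fits,
                slc=slc,
                grad_at_screen_mT_per_mm=g0_mT,
                threshold_z_mm=thr.z_mm,
                above_threshold_at_screen=thr.above_at_screen,
                skull_exposure_above_thresholds=skull_ok,
            )
        )
        log.info(
            "stage=fit model=%r hotspot=%s r=%.3f I=%.3f R2=%.5f B0=%.4g mT",
            model, spot.label, slc.r_mm, slc.I_mA, slc.r_squared, slc.B_at_0_mT,
        )

    return ReportBundle(
        hotspot_levels=pd.DataFrame(level_rows),
        fits=pd.DataFrame(fit_rows),
        gradients=pd.DataFrame(grad_rows),
        analyses=tuple(analyses),
    )


def run_pipeline(config: StudyConfig) -> ReportBundle:
    """Simulate a campaign per the config, analyze it, optionally write reports."""
    noise = replace(config.noise, seed=config.seed)
    log.info(
        "stage=simulate model=%r z=%s n=%d seed=%d",
        config.phone.geometry.model_label, config.z_list_mm, config.n_replicates, config.seed,
    )
    dataset = simulate_study(
        config.phone,
        z_list_mm=config.z_list_mm,
        n_replicates=config.n_replicates,
        background=config.background_uT,
        noise=noise,
        grid=config.grid,
    )
    bundle = analyze_study(dataset, config)
    if config.outdir:
        bundle.write(config.outdir)
        log.info("stage=report outdir=%s", config.outdir)
    return bundle
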