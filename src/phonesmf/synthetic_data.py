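"""Simulated magnetometer grid-map datasets and mesh fixtures.

The generator reproduces the statistical structure of a bench mapping
campaign: tri-axial field maps on a 13 x 21 node grid (10 mm pitch) at a
series of heights above the phone, in triplicate, over a uniform
geomagnetic background, with four corruption mechanisms mirroring the
measurement uncertainty budget:

* white per-reading sensor noise (0.1 µT rms per axis, the ambient AC
  noise level);
* a per-axis constant zeroing offset, one uniform draw within ±2 µT per
  dataset — a bias, not white noise;
* a constant multiplicative calibration error, one draw within ±0.5%;
* a systematic height error, one Gaussian draw per dataset (sd 1.6 mm, the
  stated z-position uncertainty of the spacer-stack apparatus) shifting the
  true evaluation height of *every* map coherently while the recorded
  nominal z stays uncorrupted — the physical origin of the U_grad budget
  term;
* a small independent per-map height jitter (sd 0.15 mm), the residual
  level consistent with the near-unity R² of the measured decay fits.

The phone's sources are ideal current loops buried at depth T/2 below the
screen, evaluated through the 3D Biot-Savart engine, so every downstream
stage (averaging, background subtraction, hot-spot detection, decay fits,
head maps) can be tested against a known ground truth without measured
data.  Identical seed and parameters give bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .constants import GMF_TYPICAL_UT, MU_R_DEFAULT, Z_LEVELS_MM
from .fieldmap import FieldMap, GridSpec, PhoneGeometry
from .headfield import Loop3D, loop_field_at_points

__all__ = [
    "NoiseModel",
    "ZERO_NOISE",
    "LoopSource",
    "GroundTruthPhone",
    "StudyDataset",
    "simulate_map",
    "simulate_background_map",
    "simulate_study",
    "make_head_mesh",
    "write_study",
]

_SALT = 0x5AF0  # domain separation for this module's seed streams


@dataclass(frozen=True)
class NoiseModel:
    """Corruption parameters of the simulated magnetometer session."""

    sensor_noise_rms_uT: float = 0.1
    zero_offset_bound_uT: float = 2.0
    cal_scale_error: float = 0.005
    z_offset_sd_mm: float = 1.6
    z_jitter_sd_mm: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "sensor_noise_rms_uT",
            "zero_offset_bound_uT",
            "z_offset_sd_mm",
            "z_jitter_sd_mm",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.cal_scale_error <= 0.05:
            raise ValueError("cal_scale_error must lie in [0, 0.05]")


ZERO_NOISE = NoiseModel(0.0, 0.0, 0.0, 0.0, 0.0, seed=0)


@dataclass(frozen=True)
class LoopSource:
    """One hot-spot source: a loop at (x, y) on the screen, radius r, current I."""

    label: str
    x_mm: float
    y_mm: float
    r_mm: float
    I_mA: float

    def __post_init__(self) -> None:
        if self.r_mm <= 0:
            raise ValueError("loop radius must be positive")
        if self.I_mA == 0:
            raise ValueError("loop current must be nonzero")


@dataclass(frozen=True)
class GroundTruthPhone:
    """A phone geometry with its generating loop sources."""

    geometry: PhoneGeometry
    loops: tuple[LoopSource, ...] = ()
    mu_r: float = MU_R_DEFAULT

    def __post_init__(self) -> None:
        object.__setattr__(self, "loops", tuple(self.loops))
        for lp in self.loops:
            if abs(lp.x_mm) > self.geometry.W_mm / 2.0 or abs(lp.y_mm) > self.geometry.L_mm / 2.0:
                raise ValueError(
                    f"loop {lp.label!r} at ({lp.x_mm}, {lp.y_mm}) outside the phone footprint"
                )

    def loops3d(self) -> list[Loop3D]:
        """The sources as 3D loops in the phone frame (buried at z = -T/2)."""
        return [
            Loop3D(
                center_mm=np.array([lp.x_mm, lp.y_mm, -self.geometry.T_mm / 2.0]),
                axis=np.array([0.0, 0.0, 1.0]),
                radius_mm=lp.r_mm,
                current_mA=lp.I_mA,
                mu_r=self.mu_r,
            )
            for lp in self.loops
        ]


def _session_rng(noise: NoiseModel) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([_SALT, int(noise.seed), 0]))


def _map_rng(noise: NoiseModel, z_mm: float, replicate_index: int, background: bool):
    z_key = int(round(float(z_mm) * 1000.0))
    return np.random.default_rng(
        np.random.SeedSequence(
            [_SALT, int(noise.seed), 1, z_key, int(replicate_index), int(background)]
        )
    )


def _session_draws(noise: NoiseModel) -> tuple[np.ndarray, float, float]:
    """Per-dataset constants: zero offsets (µT, per axis), calibration scale,
    and the systematic height offset (mm)."""
    rng = _session_rng(noise)
    offsets = rng.uniform(-noise.zero_offset_bound_uT, noise.zero_offset_bound_uT, size=3)
    scale = 1.0 + rng.uniform(-noise.cal_scale_error, noise.cal_scale_error)
    z_offset = rng.normal(0.0, noise.z_offset_sd_mm) if noise.z_offset_sd_mm > 0 else 0.0
    return offsets, scale, z_offset


def _simulate(
    truth: GroundTruthPhone | None,
    z_mm: float,
    grid: GridSpec,
    background: np.ndarray,
    noise: NoiseModel,
    replicate_index: int,
    n_segments: int,
    is_background_map: bool,
) -> FieldMap:
    if z_mm < 0:
        raise ValueError("mapping height z must be non-negative")
    offsets, scale, z_offset = _session_draws(noise)
    rng = _map_rng(noise, z_mm, replicate_index, is_background_map)

    jitter = rng.normal(0.0, noise.z_jitter_sd_mm) if noise.z_jitter_sd_mm > 0 else 0.0
    z_true = z_mm + z_offset + jitter
    X, Y = np.meshgrid(grid.x_mm, grid.y_mm)
    pts = np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, z_true)])

    true_field = np.tile(np.asarray(background, dtype=float), (len(pts), 1))
    if truth is not None:
        for loop in truth.loops3d():
            true_field += loop_field_at_points(loop, pts, n_segments=n_segments)

    measured = scale * true_field + offsets
    if noise.sensor_noise_rms_uT > 0:
        measured = measured + rng.normal(0.0, noise.sensor_noise_rms_uT, size=measured.shape)

    return FieldMap(
        grid=grid,
        z_nominal_mm=float(z_mm),
        values=measured.reshape(grid.ny, grid.nx, 3),
        phone=None if truth is None else truth.geometry,
        replicate_id=replicate_index,
    )


def simulate_map(
    truth: GroundTruthPhone,
    z_mm: float,
    grid: GridSpec = GridSpec(),
    background=(0.0, 0.0, 0.0),
    noise: NoiseModel = ZERO_NOISE,
    replicate_index: int = 0,
    n_segments: int = 360,
) -> FieldMap:
    """Simulate one grid map of the phone at nominal height z (mm).

    Each node holds the background plus the Biot-Savart field of every
    ground-truth loop, corrupted per the noise model; the recorded nominal
    z is the uncorrupted one.
    """
    return _simulate(truth, z_mm, grid, background, noise, replicate_index, n_segments, False)


def simulate_background_map(
    grid: GridSpec = GridSpec(),
    background=GMF_TYPICAL_UT,
    noise: NoiseModel = ZERO_NOISE,
    replicate_index: int = 0,
) -> FieldMap:
    """Simulate one ambient (no phone) map at the mapping level."""
    return _simulate(None, 0.0, grid, background, noise, replicate_index, 0, True)


@dataclass(frozen=True)
class StudyDataset:
    """All replicate maps of one simulated mapping campaign."""

    truth: GroundTruthPhone
    z_list_mm: tuple[float, ...]
    n_replicates: int
    background_uT: tuple[float, float, float]
    noise: NoiseModel
    phone_maps: dict[float, tuple[FieldMap, ...]] = field(repr=False, default_factory=dict)
    background_maps: tuple[FieldMap, ...] = field(repr=False, default=())


def simulate_study(
    truth: GroundTruthPhone,
    z_list_mm=Z_LEVELS_MM,
    n_replicates: int = 3,
    background=GMF_TYPICAL_UT,
    noise: NoiseModel = NoiseModel(),
    grid: GridSpec = GridSpec(),
    n_segments: int = 360,
) -> StudyDataset:
    """Simulate the full campaign: replicates at every height plus ambient maps.

    All maps derive from one seed stream; each (z, replicate) map gets a
    deterministic sub-seed, so the dataset is bit-reproducible.
    """
    z_list = tuple(float(z) for z in z_list_mm)
    if not z_list:
        raise ValueError("z_list must not be empty")
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    phone_maps = {
        z: tuple(
            simulate_map(truth, z, grid, background, noise, rep, n_segments)
            for rep in range(n_replicates)
        )
        for z in z_list
    }
    background_maps = tuple(
        simulate_background_map(grid, background, noise, rep) for rep in range(n_replicates)
    )
    return StudyDataset(
        truth=truth,
        z_list_mm=z_list,
        n_replicates=n_replicates,
        background_uT=tuple(float(c) for c in np.asarray(background, dtype=float)),
        noise=noise,
        phone_maps=phone_maps,
        background_maps=background_maps,
    )


def make_head_mesh(
    a_mm: float, b_mm: float, c_mm: float, n_subdivisions: int = 3
) -> trimesh.Trimesh:
    """Watertight triangulated ellipsoid head stand-in (icosphere based).

    Synthetic fixture: an ellipsoid with semi-axes (a, b, c) mm along
    (x, y, z) replaces an anatomical head surface.  Face count is
    20·4^n_subdivisions; vertex normals point outward.
    """
    if min(a_mm, b_mm, c_mm) <= 0:
        raise ValueError("semi-axes must be positive")
    if n_subdivisions < 0:
        raise ValueError("n_subdivisions must be non-negative")
    mesh = trimesh.creation.icosphere(subdivisions=n_subdivisions, radius=1.0)
    mesh.apply_scale([a_mm, b_mm, c_mm])
    return mesh


def write_study(dataset: StudyDataset, outdir) -> Path:
    """Write a dataset as grid CSVs plus a plain-text manifest.

    Layout: ``maps/phone_z{z}_rep{i}.csv`` and ``maps/background_rep{i}.csv``
    in the grid-CSV dialect, and ``manifest.toml`` recording geometry,
    sources, heights, noise parameters, and the seed.
    """
    from .gridio import write_grid_csv  # local import: gridio has no deps on us

    outdir = Path(outdir)
    (outdir / "maps").mkdir(parents=True, exist_ok=True)
    for z, maps in dataset.phone_maps.items():
        for m in maps:
            write_grid_csv(m, outdir / "maps" / f"phone_z{z:g}_rep{m.replicate_id}.csv")
    for m in dataset.background_maps:
        write_grid_csv(m, outdir / "maps" / f"background_rep{m.replicate_id}.csv")

    g = dataset.truth.geometry
    n = dataset.noise
    lines = [
        "[phone]",
        f'model_label = "{g.model_label}"',
        f"L_mm = {g.L_mm!r}",
        f"W_mm = {g.W_mm!r}",
        f"T_mm = {g.T_mm!r}",
        f"mu_r = {dataset.truth.mu_r!r}",
        "",
    ]
    for lp in dataset.truth.loops:
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
        f"z_list_mm = {list(dataset.z_list_mm)!r}",
        f"n_replicates = {dataset.n_replicates}",
        f"background_uT = {list(dataset.background_uT)!r}",
        "",
        "[noise]",
        f"sensor_noise_rms_uT = {n.sensor_noise_rms_uT!r}",
        f"zero_offset_bound_uT = {n.zero_offset_bound_uT!r}",
        f"cal_scale_error = {n.cal_scale_error!r}",
        f"z_offset_sd_mm = {n.z_offset_sd_mm!r}",
        f"z_jitter_sd_mm = {n.z_jitter_sd_mm!r}",
        f"seed = {n.seed}",
        "",
    ]
    (outdir / "manifest.toml").write_text("\n".join(lines))
    return outdir
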