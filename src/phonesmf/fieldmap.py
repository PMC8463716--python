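"""Grid-map containers and processing: averaging, background subtraction,
magnitude maps, hot-spot detection, and decay-curve assembly.

A *field map* is one rectangular grid of magnetic-field 3-vectors measured
(or simulated) on a plane at a fixed height ``z`` above a phone screen.
The coordinate frame has its origin at the screen center: x across the
width, y along the length (positive toward the speaker end), z along the
outward screen normal.  The processing order is fixed and deliberate:
replicates are averaged component-wise, the (averaged) background map is
subtracted as a vector, and only then is the magnitude taken — ``|mean(B)
- B_bg|`` is not ``mean(|B|) - |B_bg|``, and the vector route preserves
directional information for as long as possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "GridSpec",
    "PhoneGeometry",
    "FieldMap",
    "MagnitudeMap",
    "HotSpot",
    "DecayCurve",
    "average_replicates",
    "subtract_background",
    "magnitude",
    "detect_hotspots",
    "extract_decay_curve",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a rectangular mapping grid centered on the screen.

    The default is the 120 x 200 mm grid at 10 mm pitch (13 x 21 nodes)
    used for all maps in the study.
    """

    x_extent_mm: float = 120.0
    y_extent_mm: float = 200.0
    pitch_mm: float = 10.0
    origin: str = "center"

    def __post_init__(self) -> None:
        if self.pitch_mm <= 0:
            raise ValueError("grid pitch must be positive")
        for name in ("x_extent_mm", "y_extent_mm"):
            extent = getattr(self, name)
            if extent <= 0:
                raise ValueError(f"{name} must be positive (zero-extent grid)")
            ratio = extent / self.pitch_mm
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(f"{name}={extent} is not a multiple of pitch {self.pitch_mm}")
        if self.origin != "center":
            raise ValueError(f"unsupported grid origin convention: {self.origin!r}")

    @property
    def nx(self) -> int:
        return int(round(self.x_extent_mm / self.pitch_mm)) + 1

    @property
    def ny(self) -> int:
        return int(round(self.y_extent_mm / self.pitch_mm)) + 1

    @property
    def x_mm(self) -> np.ndarray:
        return np.linspace(-self.x_extent_mm / 2.0, self.x_extent_mm / 2.0, self.nx)

    @property
    def y_mm(self) -> np.ndarray:
        return np.linspace(-self.y_extent_mm / 2.0, self.y_extent_mm / 2.0, self.ny)

    def node_index(self, x_mm: float, y_mm: float, tol: float = 1e-6) -> tuple[int, int]:
        """Return the (row, col) index of the node at physical (x, y) mm."""
        ix = int(np.argmin(np.abs(self.x_mm - x_mm)))
        iy = int(np.argmin(np.abs(self.y_mm - y_mm)))
        if abs(self.x_mm[ix] - x_mm) > tol or abs(self.y_mm[iy] - y_mm) > tol:
            raise ValueError(f"({x_mm}, {y_mm}) mm is not a grid node")
        return iy, ix


@dataclass(frozen=True)
class PhoneGeometry:
    """Outer dimensions of a phone: length L, width W, thickness T (mm)."""

    L_mm: float
    W_mm: float
    T_mm: float
    model_label: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.T_mm < self.W_mm < self.L_mm):
            raise ValueError("phone geometry must satisfy 0 < T < W < L")


def _as_readonly(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    a.setflags(write=False)
    return a


@dataclass(frozen=True)
class FieldMap:
    """One grid of field 3-vectors at a fixed nominal height above the screen.

    ``values`` has shape (ny, nx, 3) holding (Bx, By, Bz) in µT, row-major in
    y.  ``phone`` is absent for background (no-phone) maps.
    """

    grid: GridSpec
    z_nominal_mm: float
    values: np.ndarray
    phone: PhoneGeometry | None = None
    replicate_id: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _as_readonly(self.values))
        expected = (self.grid.ny, self.grid.nx, 3)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != grid shape {expected}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field map contains non-finite values")


@dataclass(frozen=True)
class MagnitudeMap:
    """Per-node |B| (µT) on a grid, with optional per-node repeatability SD."""

    grid: GridSpec
    z_nominal_mm: float
    values: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _as_readonly(self.values))
        if self.values.shape != (self.grid.ny, self.grid.nx):
            raise ValueError("magnitude map shape does not match grid")
        if np.any(self.values < 0):
            raise ValueError("magnitudes must be non-negative")
        if self.sd is not None:
            object.__setattr__(self, "sd", _as_readonly(self.sd))
            if self.sd.shape != self.values.shape:
                raise ValueError("sd shape does not match grid")


@dataclass(frozen=True)
class HotSpot:
    """A local |B| maximum on the mapped plane, at a fixed (x, y) node.

    ``peak_by_z`` collects (z mm, |B| µT, Uc µT) triples once the decay
    analysis has run; it is empty right after detection.
    """

    label: str  # "UPPER" (y > 0) or "LOWER" (y < 0)
    x_mm: float
    y_mm: float
    peak_by_z: tuple[tuple[float, float, float], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.label not in ("UPPER", "LOWER"):
            raise ValueError("hot-spot label must be UPPER or LOWER")
        if self.label == "UPPER" and self.y_mm <= 0:
            raise ValueError("UPPER hot spot must have y > 0")
        if self.label == "LOWER" and self.y_mm >= 0:
            raise ValueError("LOWER hot spot must have y < 0")


@dataclass(frozen=True)
class DecayCurve:
    """|B| at a fixed hot-spot node as a function of mapping height z."""

    z_mm: np.ndarray
    B_uT: np.ndarray
    Uc_uT: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "z_mm", _as_readonly(self.z_mm))
        object.__setattr__(self, "B_uT", _as_readonly(self.B_uT))
        if self.z_mm.ndim != 1 or self.z_mm.shape != self.B_uT.shape:
            raise ValueError("z and B must be 1-D arrays of equal length")
        if len(self.z_mm) < 2:
            raise ValueError("a decay curve needs at least 2 points")
        if np.any(np.diff(self.z_mm) <= 0):
            raise ValueError("z values must be strictly increasing")
        if self.Uc_uT is not None:
            object.__setattr__(self, "Uc_uT", _as_readonly(self.Uc_uT))
            if self.Uc_uT.shape != self.z_mm.shape:
                raise ValueError("Uc length does not match curve")

    def __len__(self) -> int:
        return len(self.z_mm)


def _check_same_grid(maps: Sequence[FieldMap]) -> None:
    g0, z0 = maps[0].grid, maps[0].z_nominal_mm
    for m in maps[1:]:
        if m.grid != g0:
            raise ValueError("maps have mismatched grids")
        if m.z_nominal_mm != z0:
            raise ValueError("maps have mismatched nominal z")


def average_replicates(maps: Sequence[FieldMap]) -> tuple[FieldMap, np.ndarray]:
    """Average replicate maps node-by-node.

    Returns the component-wise mean map and the per-node sample standard
    deviation (ddof=1) of the replicate *magnitudes* — the repeatability
    entering the uncertainty budget, matching the |B| ± Uc presentation of
    the results.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 replicate maps to average")
    _check_same_grid(maps)
    stack = np.stack([m.values for m in maps])  # (n, ny, nx, 3)
    mean = FieldMap(
        grid=maps[0].grid,
        z_nominal_mm=maps[0].z_nominal_mm,
        values=stack.mean(axis=0),
        phone=maps[0].phone,
        replicate_id=None,
    )
    mags = np.linalg.norm(stack, axis=-1)  # (n, ny, nx)
    sd = mags.std(axis=0, ddof=1)
    return mean, sd


def subtract_background(map: FieldMap, background: FieldMap) -> FieldMap:
    """Vector-subtract an ambient (no-phone) map, preserving phone metadata."""
    if map.grid != background.grid:
        raise ValueError("background grid does not match map grid")
    if not np.all(np.isfinite(background.values)):
        raise ValueError("background contains non-finite values")
    return replace(map, values=map.values - background.values)


def magnitude(map: FieldMap) -> MagnitudeMap:
    """Per-node Euclidean norm of the field vectors."""
    return MagnitudeMap(
        grid=map.grid,
        z_nominal_mm=map.z_nominal_mm,
        values=np.linalg.norm(map.values, axis=-1),
    )


def detect_hotspots(
    mag: MagnitudeMap,
    phone: PhoneGeometry | None = None,
    min_prominence_uT: float | None = None,
) -> list[HotSpot]:
    """Locate the upper and lower hot spots on a background-subtracted map.

    A candidate is a strict local maximum over its 8-neighborhood whose value
    exceeds the map median by at least ``min_prominence_uT`` (default: three
    times the median per-node SD when available, else 0 — on noiseless maps
    any strict maximum qualifies).  At most one hot spot is returned per half
    plane: the best candidate with y > 0 is labelled UPPER, the best with
    y < 0 LOWER.  Ties break toward larger |B|, then smaller |y|.  An empty
    list signals a field-free map.
    """
    v = mag.values
    if min_prominence_uT is None:
        min_prominence_uT = 3.0 * float(np.median(mag.sd)) if mag.sd is not None else 0.0
    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False  # strict maximum over the 8-neighborhood
    neighbor_max = ndimage.maximum_filter(v, footprint=footprint, mode="constant", cval=-np.inf)
    is_peak = v > neighbor_max
    is_peak &= v >= float(np.median(v)) + min_prominence_uT

    y = mag.grid.y_mm
    spots: list[HotSpot] = []
    for label, half in (("UPPER", y > 0), ("LOWER", y < 0)):
        rows = np.where(half)[0]
        cands = [
            (float(-v[iy, ix]), abs(float(y[iy])), iy, ix)
            for iy in rows
            for ix in np.where(is_peak[iy])[0]
        ]
        if cands:
            _, _, iy, ix = min(cands)
            spots.append(
                HotSpot(label=label, x_mm=float(mag.grid.x_mm[ix]), y_mm=float(y[iy]))
            )
    return spots


def extract_decay_curve(
    mags: Sequence[MagnitudeMap],
    spot: HotSpot,
    budgets: dict[float, "object"] | None = None,
    require_z: Sequence[float] | None = None,
) -> DecayCurve:
    """Read |B| at the hot spot's fixed (x, y) node across heights.

    ``budgets`` optionally maps z (mm) to an
    :class:`~phonesmf.uncertainty.UncertaintyBudget` whose combined
    uncertainty is attached to each point.  ``require_z`` lists heights that
    must be present; missing ones raise with their values named.
    """
    mags = sorted(mags, key=lambda m: m.z_nominal_mm)
    zs = [m.z_nominal_mm for m in mags]
    if require_z is not None:
        missing = sorted(set(float(z) for z in require_z) - set(zs))
        if missing:
            raise ValueError(f"missing z levels: {missing} mm")
    B = []
    Uc = []
    for m in mags:
        iy, ix = m.grid.node_index(spot.x_mm, spot.y_mm)
        B.append(float(m.values[iy, ix]))
        if budgets is not None:
            try:
                Uc.append(float(budgets[m.z_nominal_mm].u_c_uT))
            except KeyError:
                raise ValueError(f"no uncertainty budget for z={m.z_nominal_mm} mm") from None
    return DecayCurve(
        z_mm=np.asarray(zs, dtype=float),
        B_uT=np.asarray(B, dtype=float),
        Uc_uT=np.asarray(Uc, dtype=float) if budgets is not None else None,
    )
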