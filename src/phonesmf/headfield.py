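"""3D loop-source field engine.

Evaluates the magnetostatic field of positioned, oriented circular current
loops by Biot-Savart integration over a polygonal discretization of the
wire, superposes loops and a uniform geomagnetic background on the vertices
of a triangulated head mesh, and searches for hypomagnetic (near-zero
|B_total|) zones where the phone's field cancels the background.

The loop's core-permeability multiplier µ_r scales the free-space field as
a uniform prefactor, exactly as in the on-axis closed form — an idealization
of the magnet core, not a boundary-value solution.  The midpoint polygon
rule converges to the circular-loop field as ~n_segments^-2, giving <0.1%
on-axis error at 360 segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .constants import GMF_RANGE_UT, MU_R_DEFAULT
from .decay_models import SLCFit
from .fieldmap import HotSpot, PhoneGeometry

__all__ = [
    "Loop3D",
    "UniformField",
    "HeadFieldResult",
    "WireSingularityError",
    "loop_field_at_point",
    "loop_field_at_points",
    "place_loops_from_fits",
    "ear_call_pose",
    "field_on_mesh",
    "find_hypomagnetic_zones",
]


class WireSingularityError(ValueError):
    """An evaluation point lies (numerically) on the loop wire."""

    def __init__(self, message: str, indices: np.ndarray | None = None):
        super().__init__(message)
        self.indices = indices


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length axis vector")
    return v / n


@dataclass(frozen=True)
class Loop3D:
    """A positioned, oriented circular current loop (the 3D source primitive).

    ``center_mm`` is the loop center, ``axis`` its unit normal (the direction
    of positive on-axis field for positive current, right-hand rule),
    ``radius_mm`` > 0, ``current_mA`` the loop current, and ``mu_r`` the
    core-permeability multiplier.
    """

    center_mm: np.ndarray
    axis: np.ndarray
    radius_mm: float
    current_mA: float
    mu_r: float = MU_R_DEFAULT

    def __post_init__(self) -> None:
        c = np.asarray(self.center_mm, dtype=float).reshape(3)
        a = _unit(np.asarray(self.axis, dtype=float).reshape(3))
        c.setflags(write=False)
        a.setflags(write=False)
        object.__setattr__(self, "center_mm", c)
        object.__setattr__(self, "axis", a)
        if self.radius_mm <= 0:
            raise ValueError("loop radius must be positive")

    def frame(self) -> tuple[np.ndarray, np.ndarray]:
        """Two unit vectors spanning the loop plane."""
        helper = np.array([1.0, 0.0, 0.0])
        if abs(self.axis @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e1 = _unit(np.cross(self.axis, helper))
        e2 = np.cross(self.axis, e1)
        return e1, e2

    def wire_distance_mm(self, points: np.ndarray) -> np.ndarray:
        """Exact distance from each point to the circular wire."""
        d = np.atleast_2d(points) - self.center_mm
        z_loc = d @ self.axis
        rho = np.linalg.norm(d - np.outer(z_loc, self.axis), axis=1)
        return np.hypot(rho - self.radius_mm, z_loc)


@dataclass(frozen=True)
class UniformField:
    """A uniform background field vector (µT), typically the geomagnetic one."""

    vector_uT: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vector_uT, dtype=float).reshape(3)
        v.setflags(write=False)
        object.__setattr__(self, "vector_uT", v)
        mag = self.magnitude_uT
        if mag > 100.0:
            raise ValueError(f"background magnitude {mag:.1f} µT exceeds 100 µT")
        if mag > 0 and not (GMF_RANGE_UT[0] <= mag <= GMF_RANGE_UT[1]):
            warnings.warn(
                f"background magnitude {mag:.1f} µT outside the typical "
                f"geomagnetic range {GMF_RANGE_UT[0]}-{GMF_RANGE_UT[1]} µT",
                stacklevel=3,
            )

    @property
    def magnitude_uT(self) -> float:
        return float(np.linalg.norm(self.vector_uT))


def loop_field_at_points(
    loop: Loop3D,
    points_mm: np.ndarray,
    n_segments: int = 360,
    min_wire_distance_mm: float = 1e-6,
) -> np.ndarray:
    """Biot-Savart field (µT) of one loop at an (N, 3) array of points.

    The wire is discretized into ``n_segments`` straight elements evaluated
    at their midpoints: B = µ_r µ0 I/(4π) Σ dl × r / |r|³.  Points closer
    than ``min_wire_distance_mm`` to the wire raise
    :class:`WireSingularityError` (the integrand diverges there).
    """
    if n_segments < 8:
        raise ValueError("n_segments must be at least 8")
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    if pts.shape[1] != 3:
        raise ValueError("points must be (N, 3)")

    dist = loop.wire_distance_mm(pts)
    bad = np.where(dist < min_wire_distance_mm)[0]
    if bad.size:
        raise WireSingularityError(
            f"{bad.size} evaluation point(s) within {min_wire_distance_mm} mm "
            f"of the loop wire (first index {bad[0]})",
            indices=bad,
        )

    theta = np.linspace(0.0, 2.0 * np.pi, n_segments + 1)
    e1, e2 = loop.frame()
    ring = (
        loop.center_mm
        + loop.radius_mm * (np.outer(np.cos(theta), e1) + np.outer(np.sin(theta), e2))
    )  # (n+1, 3)
    dl = np.diff(ring, axis=0)  # (n, 3)
    mid = 0.5 * (ring[:-1] + ring[1:])

    rvec = pts[:, None, :] - mid[None, :, :]  # (N, n, 3)
    r3 = np.linalg.norm(rvec, axis=2) ** 3  # (N, n)
    contrib = np.cross(np.broadcast_to(dl, rvec.shape), rvec) / r3[:, :, None]
    # with lengths in mm and current in mA: B[µT] = 0.1 µ_r I Σ dl×r/|r|³
    return 0.1 * loop.mu_r * loop.current_mA * contrib.sum(axis=1)


def loop_field_at_point(
    loop: Loop3D,
    point_mm,
    n_segments: int = 360,
    min_wire_distance_mm: float = 1e-6,
) -> np.ndarray:
    """Field 3-vector (µT) at a single point."""
    return loop_field_at_points(
        loop, np.asarray(point_mm, dtype=float).reshape(1, 3), n_segments, min_wire_distance_mm
    )[0]


def _check_rigid(pose: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pose = np.asarray(pose, dtype=float)
    if pose.shape != (4, 4) or not np.allclose(pose[3], [0, 0, 0, 1]):
        raise ValueError("pose must be a 4x4 homogeneous transform")
    R, t = pose[:3, :3], pose[:3, 3]
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-9) or not np.isclose(
        np.linalg.det(R), 1.0, atol=1e-9
    ):
        raise ValueError("pose is not a rigid (proper orthogonal) transform")
    return R, t


def place_loops_from_fits(
    phone_pose: np.ndarray,
    geometry: PhoneGeometry,
    hotspots: list[HotSpot],
    fits: list[SLCFit],
) -> list[Loop3D]:
    """Build 3D loops from fitted hot-spot sources and a phone pose.

    In the phone frame each loop sits at the hot spot's (x, y) at depth T/2
    below the screen plane with its axis along the screen normal; the rigid
    ``phone_pose`` (4x4, phone frame -> world/head frame) then positions it.
    """
    if len(hotspots) != len(fits):
        raise ValueError("need exactly one fit per hot spot")
    R, t = _check_rigid(phone_pose)
    loops = []
    for spot, fit in zip(hotspots, fits):
        center_local = np.array([spot.x_mm, spot.y_mm, -geometry.T_mm / 2.0])
        loops.append(
            Loop3D(
                center_mm=R @ center_local + t,
                axis=R @ np.array([0.0, 0.0, 1.0]),
                radius_mm=fit.r_mm,
                current_mA=fit.I_mA,
                mu_r=fit.mu_r,
            )
        )
    return loops


def ear_call_pose(mesh, up=(0.0, 0.0, 1.0), contact_xy_mm=(0.0, 0.0)) -> np.ndarray:
    """Default phone pose for head maps: screen tangent to the mesh at the
    "ear" point (maximum-x vertex), screen normal pointing into the head,
    phone length axis (toward the upper hot spot) along the projection of
    ``up`` onto the tangent plane.  ``contact_xy_mm`` is the phone-frame
    screen point pressed against the ear — pass the upper hot spot's (x, y)
    to model an ongoing call with the speaker at the ear.  Returns a 4x4
    phone->head transform.
    """
    vertices = np.asarray(mesh.vertices, dtype=float)
    normals = np.asarray(mesh.vertex_normals, dtype=float)
    ear = int(np.argmax(vertices[:, 0]))
    n = _unit(normals[ear])
    z_axis = -n  # screen normal points toward the head interior
    up = np.asarray(up, dtype=float)
    y_axis = up - (up @ z_axis) * z_axis
    if np.linalg.norm(y_axis) < 1e-9:
        raise ValueError("up direction is parallel to the ear normal")
    y_axis = _unit(y_axis)
    x_axis = np.cross(y_axis, z_axis)
    pose = np.eye(4)
    pose[:3, 0], pose[:3, 1], pose[:3, 2] = x_axis, y_axis, z_axis
    contact = np.array([contact_xy_mm[0], contact_xy_mm[1], 0.0])
    pose[:3, 3] = vertices[ear] - pose[:3, :3] @ contact
    return pose


@dataclass(frozen=True)
class HeadFieldResult:
    """Per-vertex field of a set of loops (plus optional background) on a mesh."""

    mesh: object
    vectors_uT: np.ndarray
    background: UniformField | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors_uT, dtype=float)
        v.setflags(write=False)
        object.__setattr__(self, "vectors_uT", v)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] != len(self.mesh.vertices):
            raise ValueError("vectors must be (n_vertices, 3)")

    @property
    def magnitudes_uT(self) -> np.ndarray:
        return np.linalg.norm(self.vectors_uT, axis=1)


def field_on_mesh(
    loops: list[Loop3D],
    mesh,
    background: UniformField | None = None,
    n_segments: int = 360,
    min_wire_distance_mm: float = 1e-3,
) -> HeadFieldResult:
    """Superpose all loop fields (plus a uniform background) on mesh vertices."""
    pts = np.asarray(mesh.vertices, dtype=float)
    total = np.zeros_like(pts)
    for loop in loops:
        try:
            total += loop_field_at_points(loop, pts, n_segments, min_wire_distance_mm)
        except WireSingularityError as exc:
            raise WireSingularityError(
                f"mesh vertex on loop wire: {exc}", indices=exc.indices
            ) from exc
    if background is not None:
        total = total + background.vector_uT
    return HeadFieldResult(mesh=mesh, vectors_uT=total, background=background)


def _total_field_mags(
    loops: list[Loop3D], background: UniformField, pts: np.ndarray, n_segments: int
) -> np.ndarray:
    total = np.tile(background.vector_uT, (len(pts), 1))
    for loop in loops:
        total += loop_field_at_points(loop, pts, n_segments)
    return np.linalg.norm(total, axis=1)


def find_hypomagnetic_zones(
    loops: list[Loop3D],
    background: UniformField,
    region_mm: tuple,
    resolution_mm: float = 2.0,
    epsilon_uT: float = 1.0,
    n_segments: int = 360,
) -> np.ndarray:
    """Points where the loop fields nearly cancel the background.

    Scans |B_total| on a coarse grid over the axis-aligned box ``region_mm``
    = ((x0, y0, z0), (x1, y1, z1)), picks the local minima, refines each by
    a bounded Nelder-Mead descent (0.01 mm positional tolerance), and keeps
    the refined points with |B_total| < epsilon, deduplicated to one per
    coarse cell.  Returns a (k, 3) array (possibly empty).
    """
    if epsilon_uT <= 0:
        raise ValueError("epsilon must be positive")
    if background.magnitude_uT <= 0:
        raise ValueError("background magnitude must be positive")
    lo = np.asarray(region_mm[0], dtype=float)
    hi = np.asarray(region_mm[1], dtype=float)
    if np.any(hi <= lo):
        raise ValueError("empty search region")

    axes = [np.arange(lo[d], hi[d] + resolution_mm / 2.0, resolution_mm) for d in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    mags = _total_field_mags(loops, background, pts, n_segments).reshape(X.shape)

    footprint = np.ones((3, 3, 3), dtype=bool)
    local_min = mags <= ndimage.minimum_filter(mags, footprint=footprint, mode="nearest")
    cand_idx = np.argwhere(local_min)
    # refine only plausible minima, best-first, capped for tractability
    order = np.argsort(mags[local_min])
    cand_idx = cand_idx[order][:20]

    found: list[np.ndarray] = []
    for idx in cand_idx:
        x0 = np.array([axes[d][idx[d]] for d in range(3)])
        res = optimize.minimize(
            lambda p: _total_field_mags(loops, background, p.reshape(1, 3), n_segments)[0],
            x0=x0,
            method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options={"xatol": 0.01, "fatol": 1e-6 * background.magnitude_uT, "maxiter": 400},
        )
        if res.fun < epsilon_uT:
            p = np.clip(res.x, lo, hi)
            if all(np.linalg.norm(p - q) > resolution_mm for q in found):
                found.append(p)
    return np.array(found).reshape(-1, 3)
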