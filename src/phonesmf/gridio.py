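"""Grid CSV dialect: lossless plain-text serialization of field maps.

One file per map, header ``x_mm,y_mm,Bx_uT,By_uT,Bz_uT``, one row per
node in canonical order (y-major, both coordinates ascending), values at
6 significant digits.  Magnitude maps use ``x_mm,y_mm,Bmag_uT[,sd_uT]``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .fieldmap import FieldMap, GridSpec, MagnitudeMap

__all__ = ["read_grid_csv", "write_grid_csv", "write_magnitude_csv"]

_COLUMNS = ["x_mm", "y_mm", "Bx_uT", "By_uT", "Bz_uT"]


def write_grid_csv(map: FieldMap, path) -> Path:
    """Write a field map in canonical row order at 6 significant digits."""
    X, Y = np.meshgrid(map.grid.x_mm, map.grid.y_mm)
    df = pd.DataFrame(
        {
            "x_mm": X.ravel(),
            "y_mm": Y.ravel(),
            "Bx_uT": map.values[:, :, 0].ravel(),
            "By_uT": map.values[:, :, 1].ravel(),
            "Bz_uT": map.values[:, :, 2].ravel(),
        }
    ).sort_values(["y_mm", "x_mm"], kind="stable")
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def _infer_axis(values: np.ndarray, name: str) -> np.ndarray:
    axis = np.unique(values)
    if len(axis) > 1:
        pitches = np.diff(axis)
        if not np.allclose(pitches, pitches[0], atol=1e-6):
            raise ValueError(f"non-uniform {name} spacing in grid file")
    return axis


def read_grid_csv(path, z_nominal_mm: float = 0.0) -> FieldMap:
    """Read a grid CSV back into a :class:`FieldMap`.

    The file must be a complete rectangle; a missing node raises an error
    naming the (x, y) gap, duplicate nodes and missing columns are reported
    distinctly.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in _COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"grid CSV missing columns: {missing_cols}")
    df[_COLUMNS] = df[_COLUMNS].astype(float)
    x_axis = _infer_axis(df["x_mm"].to_numpy(), "x")
    y_axis = _infer_axis(df["y_mm"].to_numpy(), "y")

    keys = list(zip(df["x_mm"], df["y_mm"]))
    if len(set(keys)) != len(keys):
        dupes = df[df.duplicated(["x_mm", "y_mm"])].iloc[0]
        raise ValueError(f"duplicate grid node at ({dupes['x_mm']}, {dupes['y_mm']})")
    if len(df) != len(x_axis) * len(y_axis):
        have = set(keys)
        for y in y_axis:
            for x in x_axis:
                if (x, y) not in have:
                    raise ValueError(f"non-rectangular grid: missing node at ({x}, {y})")

    pitch = float(x_axis[1] - x_axis[0]) if len(x_axis) > 1 else float(y_axis[1] - y_axis[0])
    grid = GridSpec(
        x_extent_mm=float(x_axis[-1] - x_axis[0]),
        y_extent_mm=float(y_axis[-1] - y_axis[0]),
        pitch_mm=pitch,
    )
    if not (np.allclose(x_axis, grid.x_mm, atol=1e-6) and np.allclose(y_axis, grid.y_mm, atol=1e-6)):
        raise ValueError("grid is not centered on the screen origin")
    df = df.sort_values(["y_mm", "x_mm"], kind="stable")
    values = df[["Bx_uT", "By_uT", "Bz_uT"]].to_numpy().reshape(grid.ny, grid.nx, 3)
    return FieldMap(grid=grid, z_nominal_mm=float(z_nominal_mm), values=values)


def write_magnitude_csv(mag: MagnitudeMap, path) -> Path:
    X, Y = np.meshgrid(mag.grid.x_mm, mag.grid.y_mm)
    data = {"x_mm": X.ravel(), "y_mm": Y.ravel(), "Bmag_uT": mag.values.ravel()}
    if mag.sd is not None:
        data["sd_uT"] = mag.sd.ravel()
    df = pd.DataFrame(data).sort_values(["y_mm", "x_mm"], kind="stable")
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.6g")
    return path
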