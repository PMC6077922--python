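"""First-order light-field estimation from cubic illuminance.

From the six face illuminances of a cubic meter the first-order description
of the local light field follows in closed form (Cuttle's cubic-illuminance
equations).  Writing ``E+`` / ``E-`` for the measurements on opposite faces
of an axis:

    E_a       = E_a+ - E_a-                 (light-vector component, per axis)
    E_vector  = |(E_x, E_y, E_z)|           (light-vector magnitude)
    ~E_a      = (E_a+ + E_a- - |E_a|) / 2   (symmetric part, per axis)
    E_sym     = (~E_x + ~E_y + ~E_z) / 3    (symmetric illuminance)
    E_scalar  = E_vector / 4 + E_sym        (mean/scalar illuminance)
    D         = 1 - (E_vector / E_scalar) / 4

``D`` is the normalized diffuseness: 0 for a fully collimated beam, 1 for a
Ganzfeld (perfectly isotropic field).  The light direction is the unit
light vector, pointing toward the dominant source.

A lattice of such samples forms a :class:`LightFieldGrid`; the vector field
is interpolated component-wise (trilinear by default) and integrated into
*light tubes* — streamlines whose radius is inversely proportional to the
local scalar illuminance — for visualization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .scene_radiometry import FACE_NAMES, CubeMeter, SceneConfig, measure_cube

__all__ = [
    "LightFieldSample",
    "LightFieldGrid",
    "LightTube",
    "first_order_properties",
    "interpolate_field",
    "trace_tubes",
    "field_to_dataframe",
    "grid_from_dataframe",
    "measure_grid",
    "tubes_to_json",
    "tubes_to_vtk",
]


@dataclass
class LightFieldSample:
    """First-order light-field properties at one position."""

    position: np.ndarray
    faces: np.ndarray  # (Ex+, Ex-, Ey+, Ey-, Ez+, Ez-)
    E_xyz: np.ndarray  # light-vector components
    E_vector: float
    tilde: np.ndarray  # per-axis symmetric parts
    E_symmetric: float
    E_scalar: float
    D: float
    light_direction: np.ndarray | None  # unit vector, None when E_vector == 0


def first_order_properties(faces, position=(0.0, 0.0, 0.0)) -> LightFieldSample:
    """Derive the first-order light-field sample from six face illuminances.

    Parameters
    ----------
    faces : sequence of 6 scalars
        (Ex+, Ex-, Ey+, Ey-, Ez+, Ez-), all >= 0, not all zero.
    """
    f = np.asarray(faces, dtype=float)
    if f.shape != (6,):
        raise ValueError("need exactly six face illuminances")
    if np.any(f < 0) or not np.all(np.isfinite(f)):
        raise ValueError("face illuminances must be finite and >= 0")
    if np.all(f == 0):
        raise ValueError("dark point: all six illuminances are zero")
    # work on a max-normalized copy so extreme absolute levels cannot
    # underflow the vector norm; all quantities except D scale linearly
    scale = float(f.max())
    fn = f / scale
    plus, minus = fn[0::2], fn[1::2]
    e_xyz_n = plus - minus
    e_vector_n = float(np.linalg.norm(e_xyz_n))
    tilde_n = (plus + minus - np.abs(e_xyz_n)) / 2.0
    e_sym_n = float(tilde_n.mean())
    e_scalar_n = e_vector_n / 4.0 + e_sym_n  # >= 1/4 since max(fn) == 1
    d = 1.0 - (e_vector_n / e_scalar_n) / 4.0
    e_xyz = scale * e_xyz_n
    e_vector = scale * e_vector_n
    tilde = scale * tilde_n
    e_sym = scale * e_sym_n
    e_scalar = scale * e_scalar_n
    direction = e_xyz / e_vector if e_vector > 0 else None
    return LightFieldSample(
        position=np.asarray(position, dtype=float),
        faces=f,
        E_xyz=e_xyz,
        E_vector=e_vector,
        tilde=tilde,
        E_symmetric=e_sym,
        E_scalar=float(e_scalar),
        D=float(d),
        light_direction=direction,
    )


class LightFieldGrid:
    """First-order samples on a rectilinear lattice (nx, ny, nz >= 2).

    ``mode`` selects the interpolation: "trilinear" (default; reproduces
    any field linear in position exactly) or "tricubic" (smoothed, needs
    at least four nodes per axis).
    """

    def __init__(self, x, y, z, samples, mode: str = "trilinear"):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.z = np.asarray(z, dtype=float)
        for ax in (self.x, self.y, self.z):
            if ax.ndim != 1 or len(ax) < 2:
                raise ValueError("each grid axis needs >= 2 nodes")
            if np.any(np.diff(ax) <= 0):
                raise ValueError("grid axes must be strictly increasing")
        self.shape = (len(self.x), len(self.y), len(self.z))
        samples = np.asarray(samples, dtype=object)
        if samples.shape != self.shape:
            raise ValueError(
                f"samples shape {samples.shape} != lattice shape {self.shape}"
            )
        if any(s is None for s in samples.flat):
            raise ValueError("samples must be complete (no missing nodes)")
        self.samples = samples
        vec = np.empty(self.shape + (3,))
        scal = np.empty(self.shape)
        for idx in np.ndindex(self.shape):
            vec[idx] = samples[idx].E_xyz
            scal[idx] = samples[idx].E_scalar
        method = {"trilinear": "linear", "tricubic": "cubic"}.get(mode)
        if method is None:
            raise ValueError(f"unknown interpolation mode {mode!r}")
        if mode == "tricubic" and min(self.shape) < 4:
            raise ValueError("tricubic interpolation needs >= 4 nodes per axis")
        pts = (self.x, self.y, self.z)
        self._vec_interp = RegularGridInterpolator(pts, vec, method=method)
        self._scal_interp = RegularGridInterpolator(pts, scal, method=method)

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.x[0], self.y[0], self.z[0]])
        hi = np.array([self.x[-1], self.y[-1], self.z[-1]])
        return lo, hi

    def contains(self, point) -> bool:
        p = np.asarray(point, dtype=float)
        lo, hi = self.bounds
        return bool(np.all(p >= lo) and np.all(p <= hi))

    @property
    def min_spacing(self) -> float:
        return float(
            min(np.diff(self.x).min(), np.diff(self.y).min(), np.diff(self.z).min())
        )


def interpolate_field(grid: LightFieldGrid, point) -> tuple[np.ndarray, float]:
    """Interpolated (light vector, E_scalar) at an interior point."""
    p = np.asarray(point, dtype=float)
    if not grid.contains(p):
        raise ValueError(f"point {p} is out of volume")
    return grid._vec_interp(p)[0], float(grid._scal_interp(p)[0])


@dataclass
class LightTube:
    """Streamline polyline with a per-point display radius."""

    points: np.ndarray  # (n, 3)
    radii: np.ndarray  # (n,)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if len(self.points) != len(self.radii) or len(self.points) < 2:
            raise ValueError("tube needs >= 2 points with one radius each")
        if np.any(self.radii <= 0):
            raise ValueError("tube radii must be > 0")


def _integrate(grid, seed, step, max_steps, sign):
    pts = []
    p = np.asarray(seed, dtype=float)
    for _ in range(max_steps):
        v, _ = interpolate_field(grid, p)
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            break  # stagnation point: tube terminates here
        p2 = p + sign * step * (v / nv)
        if not grid.contains(p2):
            break
        pts.append(p2)
        p = p2
    return pts


def trace_tubes(
    grid: LightFieldGrid,
    seeds: Sequence,
    step: float | None = None,
    max_steps: int = 200,
    display_radius: float = 0.05,
) -> list[LightTube]:
    """Trace bidirectional streamlines of the normalized light-vector field.

    Fixed-step Euler integration from each seed (default step: a quarter of
    the minimum grid spacing), forward and backward, until the polyline
    leaves the volume, stagnates, or reaches ``max_steps`` per direction.
    Radii are ``c / E_scalar`` (thick where the field is dim), with ``c``
    chosen so the median radius over all tubes equals ``display_radius``.
    """
    if step is None:
        step = grid.min_spacing / 4.0
    if step <= 0:
        raise ValueError("step must be > 0")
    polylines = []
    for seed in seeds:
        s = np.asarray(seed, dtype=float)
        if not grid.contains(s):
            raise ValueError(f"seed {s} is out of volume")
        back = _integrate(grid, s, step, max_steps, -1.0)
        fwd = _integrate(grid, s, step, max_steps, +1.0)
        poly = np.array(back[::-1] + [s] + fwd)
        if len(poly) >= 2:
            polylines.append(poly)
    scalars = [
        np.array([interpolate_field(grid, p)[1] for p in poly]) for poly in polylines
    ]
    all_s = np.concatenate(scalars) if scalars else np.array([1.0])
    all_s = np.maximum(all_s, 1e-12)
    c = display_radius * float(np.median(all_s))
    return [
        LightTube(points=poly, radii=c / np.maximum(sc, 1e-12))
        for poly, sc in zip(polylines, scalars)
    ]


# ---------------------------------------------------------------------------
# Grid construction and serialization
# ---------------------------------------------------------------------------

def measure_grid(
    scene: SceneConfig, x, y, z, mode: str = "trilinear"
) -> LightFieldGrid:
    """Measure a cubic meter at every lattice node of a zoned scene."""
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    samples = np.empty((len(x), len(y), len(z)), dtype=object)
    for i, xi in enumerate(x):
        for j, yj in enumerate(y):
            for k, zk in enumerate(z):
                pos = np.array([xi, yj, zk])
                faces = measure_cube(CubeMeter(pos), scene)
                samples[i, j, k] = first_order_properties(faces, position=pos)
    return LightFieldGrid(x, y, z, samples, mode=mode)


_FIELD_COLUMNS = (
    ["x", "y", "z"]
    + list(FACE_NAMES)
    + ["Ex", "Ey", "Ez", "E_vector", "E_symmetric", "E_scalar", "D",
       "dir_x", "dir_y", "dir_z"]
)


def field_to_dataframe(grid: LightFieldGrid) -> pd.DataFrame:
    rows = []
    for idx in np.ndindex(grid.shape):
        s = grid.samples[idx]
        direction = s.light_direction
        if direction is None:
            direction = np.full(3, np.nan)
        rows.append(
            list(s.position) + list(s.faces) + list(s.E_xyz)
            + [s.E_vector, s.E_symmetric, s.E_scalar, s.D] + list(direction)
        )
    return pd.DataFrame(rows, columns=_FIELD_COLUMNS)


def grid_from_dataframe(df: pd.DataFrame, mode: str = "trilinear") -> LightFieldGrid:
    """Rebuild a lattice from a field table written by field_to_dataframe."""
    missing = [c for c in _FIELD_COLUMNS[:9] if c not in df.columns]
    if missing:
        raise ValueError(f"field table is missing columns {missing}")
    x = np.unique(df["x"].to_numpy())
    y = np.unique(df["y"].to_numpy())
    z = np.unique(df["z"].to_numpy())
    samples = np.empty((len(x), len(y), len(z)), dtype=object)
    for _, row in df.iterrows():
        i = int(np.searchsorted(x, row["x"]))
        j = int(np.searchsorted(y, row["y"]))
        k = int(np.searchsorted(z, row["z"]))
        faces = row[list(FACE_NAMES)].to_numpy(dtype=float)
        samples[i, j, k] = first_order_properties(
            faces, position=np.array([row["x"], row["y"], row["z"]])
        )
    if any(s is None for s in samples.flat):
        raise ValueError("field table does not cover a complete lattice")
    return LightFieldGrid(x, y, z, samples, mode=mode)


def tubes_to_json(tubes: Sequence[LightTube]) -> str:
    return json.dumps(
        {
            "tubes": [
                {"points": t.points.tolist(), "radii": t.radii.tolist()}
                for t in tubes
            ]
        }
    )


def tubes_to_vtk(tubes: Sequence[LightTube]) -> str:
    """Legacy-ASCII VTK polydata (polylines + per-point radius scalars)."""
    npts = sum(len(t.points) for t in tubes)
    lines = [
        "# vtk DataFile Version 3.0",
        "light tubes",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {npts} float",
    ]
    for t in tubes:
        for p in t.points:
            lines.append(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
    size = sum(len(t.points) + 1 for t in tubes)
    lines.append(f"LINES {len(tubes)} {size}")
    offset = 0
    for t in tubes:
        n = len(t.points)
        lines.append(" ".join([str(n)] + [str(offset + i) for i in range(n)]))
        offset += n
    lines += [f"POINT_DATA {npts}", "SCALARS radius float 1", "LOOKUP_TABLE default"]
    for t in tubes:
        for r in t.radii:
            lines.append(f"{r:.9g}")
    return "\n".join(lines) + "\n"
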