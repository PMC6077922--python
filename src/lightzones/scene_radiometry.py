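"""Direct-illumination radiometry for zoned scenes.

The scenes studied here contain small spherical sources (approximated as
points), luminous rectangular panels, and planar rectangular shades that
carve a scene into *light zones* — half-scenes whose dominant light
direction differs.  Illuminance at a sensor face follows the inverse-square
cosine law with binary occlusion; a constant isotropic ambient term stands
in for interreflections.  A cubic illuminance meter (six faces along the
scene axes) measured in such a scene is the input to the first-order
light-field estimation in :mod:`lightzones.lightfield_core`.

Coordinate convention (used throughout the package): right-handed, +z up,
the viewer of a rendered image looks along +y so the picture plane is the
xz-plane; azimuth is measured in the xy-plane counterclockwise from +x and
elevation from the horizontal plane.  Light direction vectors point from
the measurement position toward the source.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LightSource",
    "Occluder",
    "SceneConfig",
    "CubeMeter",
    "Exp2Scene",
    "FACE_NORMALS",
    "FACE_NAMES",
    "visibility",
    "face_illuminance",
    "measure_cube",
    "build_experiment2_scene",
    "camera_azimuth_deg",
    "view_rotation_deg",
]

_COPLANAR_TOL = 1e-9
# open-segment tolerance for occlusion: an endpoint exactly on a shade plane
# (e.g. a probe on the zone border) is not considered blocked
_SEG_EPS = 1e-9


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} must be finite")
    return v


def _check_quad(corners, name: str) -> np.ndarray:
    c = np.asarray(corners, dtype=float)
    if c.shape != (4, 3):
        raise ValueError(f"{name} must be 4 corner points (shape (4, 3))")
    u = c[1] - c[0]
    v = c[3] - c[0]
    n = np.cross(u, v)
    area = np.linalg.norm(n)
    if area <= _COPLANAR_TOL:
        raise ValueError(f"{name} is degenerate (zero area)")
    # fourth corner must lie in the plane of the first three
    off = abs(np.dot(c[2] - c[0], n / area))
    scale = max(1.0, np.abs(c).max())
    if off > 1e-9 * scale:
        raise ValueError(f"{name} corners are not coplanar (offset {off:.3g})")
    return c


@dataclass
class LightSource:
    """A point-like spherical source or a luminous rectangular panel.

    ``radiant_intensity`` is the total intensity; a panel is expanded into
    ``subdivision**2`` point patches of intensity ``I / subdivision**2``.
    """

    kind: str  # "spherical_point" | "rectangular_panel"
    position: np.ndarray
    radiant_intensity: float
    panel_corners: np.ndarray | None = None
    subdivision: int = 4

    def __post_init__(self):
        if self.kind not in ("spherical_point", "rectangular_panel"):
            raise ValueError(f"unknown source kind {self.kind!r}")
        self.position = _as_vec3(self.position, "source position")
        self.radiant_intensity = float(self.radiant_intensity)
        if self.radiant_intensity < 0:
            raise ValueError("radiant_intensity must be >= 0")
        if self.kind == "rectangular_panel":
            if self.panel_corners is None:
                raise ValueError("panel source requires panel_corners")
            self.panel_corners = _check_quad(self.panel_corners, "panel_corners")
            if int(self.subdivision) < 1:
                raise ValueError("subdivision must be >= 1")
            self.subdivision = int(self.subdivision)

    def patches(self) -> list[tuple[np.ndarray, float]]:
        """Point patches (position, intensity) representing this source."""
        if self.kind == "spherical_point":
            return [(self.position, self.radiant_intensity)]
        s = self.subdivision
        c = self.panel_corners
        u = c[1] - c[0]
        v = c[3] - c[0]
        ii = (np.arange(s) + 0.5) / s
        out = []
        per_patch = self.radiant_intensity / (s * s)
        for a in ii:
            for b in ii:
                out.append((c[0] + a * u + b * v, per_patch))
        return out


@dataclass
class Occluder:
    """A planar rectangular shade.  ``mode`` is descriptive metadata only;
    the geometry alone decides occlusion."""

    corners: np.ndarray
    mode: str = "partial"  # "partial" | "full"

    def __post_init__(self):
        if self.mode not in ("partial", "full"):
            raise ValueError(f"unknown occluder mode {self.mode!r}")
        self.corners = _check_quad(self.corners, "occluder corners")
        c = self.corners
        self._origin = c[0]
        self._u = c[1] - c[0]
        self._v = c[3] - c[0]
        self._normal = np.cross(self._u, self._v)
        # Gram matrix inverse for in-plane coordinates (u, v need not be
        # orthogonal: any planar parallelogram is supported)
        g = np.array(
            [[self._u @ self._u, self._u @ self._v],
             [self._v @ self._u, self._v @ self._v]]
        )
        self._ginv = np.linalg.inv(g)


@dataclass
class SceneConfig:
    """Ground-truth scene: sources, shades and an isotropic ambient term."""

    sources: list[LightSource] = field(default_factory=list)
    occluders: list[Occluder] = field(default_factory=list)
    ambient_illuminance: float = 0.0
    label: str = ""

    def __post_init__(self):
        self.ambient_illuminance = float(self.ambient_illuminance)
        if self.ambient_illuminance < 0:
            raise ValueError("ambient_illuminance must be >= 0")
        if not self.sources and self.ambient_illuminance == 0.0:
            raise ValueError("scene needs at least one source or ambient light")


@dataclass
class CubeMeter:
    """A cubic illuminance meter: six co-located sensors facing +-x, +-y, +-z."""

    position: np.ndarray

    def __post_init__(self):
        self.position = _as_vec3(self.position, "meter position")


FACE_NAMES = ("Ex_plus", "Ex_minus", "Ey_plus", "Ey_minus", "Ez_plus", "Ez_minus")
FACE_NORMALS = np.array(
    [
        [1.0, 0.0, 0.0],
        [-1.0, 0.0, 0.0],
        [0.0, 1.0, 0.0],
        [0.0, -1.0, 0.0],
        [0.0, 0.0, 1.0],
        [0.0, 0.0, -1.0],
    ]
)


def visibility(point, source_point, occluders: Sequence[Occluder]) -> int:
    """1 if the open segment point->source_point misses every shade, else 0.

    Endpoints lying exactly on a shade plane do not count as blocked, so a
    probe standing on a zone border still sees both sources.
    """
    p = _as_vec3(point, "point")
    s = _as_vec3(source_point, "source_point")
    d = s - p
    if np.linalg.norm(d) == 0.0:
        raise ValueError("point and source_point coincide")
    for occ in occluders:
        denom = occ._normal @ d
        if abs(denom) < 1e-300:
            continue  # segment parallel to the shade plane
        t = (occ._normal @ (occ._origin - p)) / denom
        if not (_SEG_EPS < t < 1.0 - _SEG_EPS):
            continue
        x = p + t * d - occ._origin
        a, b = occ._ginv @ np.array([occ._u @ x, occ._v @ x])
        if -1e-12 <= a <= 1 + 1e-12 and -1e-12 <= b <= 1 + 1e-12:
            return 0
    return 1


def face_illuminance(face_center, face_normal, scene: SceneConfig) -> float:
    """Illuminance on one sensor face: ambient + sum of I cos(theta) V / d^2.

    Panels contribute through their point patches; contributions with the
    source behind the face (cos(theta) <= 0) are clamped to zero.
    """
    c = _as_vec3(face_center, "face_center")
    n = _as_vec3(face_normal, "face_normal")
    nn = np.linalg.norm(n)
    if abs(nn - 1.0) > 1e-9:
        raise ValueError("face_normal must be unit length")
    e = scene.ambient_illuminance
    for src in scene.sources:
        for pos, intensity in src.patches():
            r = pos - c
            d2 = r @ r
            if d2 == 0.0:
                raise ValueError("source at sensor")
            cos_t = (n @ r) / np.sqrt(d2)
            if cos_t <= 0.0 or intensity == 0.0:
                continue
            if visibility(c, pos, scene.occluders):
                e += intensity * cos_t / d2
    return e


def measure_cube(meter: CubeMeter, scene: SceneConfig) -> np.ndarray:
    """Six face illuminances (Ex+, Ex-, Ey+, Ey-, Ez+, Ez-) at one position."""
    return np.array(
        [face_illuminance(meter.position, nrm, scene) for nrm in FACE_NORMALS]
    )


# ---------------------------------------------------------------------------
# Zoned-scene generators (the two-source / shade arrangements of the
# two-zone probing experiment)
# ---------------------------------------------------------------------------

# Desk-scale geometry: scene objects within radius ~1, sources at distance
# ~9.9 so the inverse-square variation across the scene is mild.  All
# sources sit at exactly 45 degrees elevation with respect to the scene
# center and ground plane.
_SRC_H = 7.0          # horizontal offset of a source along its axis
_SRC_DY = 0.1         # small lateral offset away from a full shade's plane
_DEFAULT_INTENSITY = 100.0
_DEFAULT_AMBIENT = 0.05

TWO_ZONE_VIEWS = ("LR", "FB")
SINGLE_ZONE_VIEWS = ("F", "R", "B", "L")


def _source(x: float, y: float, intensity: float) -> LightSource:
    z = float(np.hypot(x, y))  # 45 deg elevation: height equals horiz. distance
    return LightSource("spherical_point", np.array([x, y, z]), intensity)


def _divider_x() -> Occluder:
    # partial shade: vertical divider in the x=0 plane; blocks each lateral
    # source's light to the opposite half without shading its own half
    return Occluder(
        corners=[[0, -2, 0], [0, 2, 0], [0, 2, 8], [0, -2, 8]], mode="partial"
    )


def _divider_y() -> Occluder:
    return Occluder(
        corners=[[-2, 0, 0], [2, 0, 0], [2, 0, 8], [-2, 0, 8]], mode="partial"
    )


def _full_shade_east() -> Occluder:
    # blocks the +x (east) source's rays into the y<0 half
    return Occluder(
        corners=[[1.2, 0, 0], [12, 0, 0], [12, 0, 12], [1.2, 0, 12]], mode="full"
    )


def _full_shade_west() -> Occluder:
    # blocks the -x (west) source's rays into the y>0 half
    return Occluder(
        corners=[[-12, 0, 0], [-1.2, 0, 0], [-1.2, 0, 12], [-12, 0, 12]],
        mode="full",
    )


@dataclass
class Exp2Scene:
    """One test image of the two-zone experiment: the physical scene plus
    the view geometry and the veridical zone light directions.

    ``zone_directions`` maps group labels (``zone1``/``zone2``, or ``zone``
    for the single-source condition) to unit vectors in the scene frame
    pointing from the scene center toward the zone's source.  ``zone1`` is
    the left zone of an LR view and the front zone of an FB view.
    """

    condition: int
    view: str
    scene: SceneConfig
    camera_azimuth_deg: float
    zone_directions: dict[str, np.ndarray]


def _toward(src: LightSource, origin=(0.0, 0.0, 0.25)) -> np.ndarray:
    v = src.position - np.asarray(origin, dtype=float)
    return v / np.linalg.norm(v)


def camera_azimuth_deg(condition: int, view: str) -> float:
    """Scene-frame azimuth of the viewing direction for a (condition, view).

    Chosen so that the physical-zone correspondence between views matches
    the zone arrangement of the study: for condition 1 the left zone of the
    LR view is the front zone of the FB view, while for conditions 2 and 3
    the left zone of the LR view is the *back* zone of the FB view.
    """
    table = {
        (1, "LR"): 90.0, (1, "FB"): 0.0,
        (2, "LR"): 0.0, (2, "FB"): 90.0,
        (3, "LR"): 0.0, (3, "FB"): 90.0,
        (4, "B"): 0.0, (4, "R"): 90.0, (4, "F"): 180.0, (4, "L"): 270.0,
    }
    try:
        return table[(condition, view)]
    except KeyError:
        raise ValueError(f"invalid condition/view combination ({condition}, {view!r})")


def view_rotation_deg(cam_azimuth_deg: float) -> float:
    """Rotation about +z taking scene coordinates into view coordinates
    (viewer looking along +y, +x to the viewer's right)."""
    return 90.0 - cam_azimuth_deg


def build_experiment2_scene(
    condition: int,
    view: str,
    intensity: float = _DEFAULT_INTENSITY,
    ambient: float = _DEFAULT_AMBIENT,
) -> Exp2Scene:
    """Build one of the ten two-zone test images.

    Conditions 1-3 use two identical point sources at 45 deg elevation;
    condition 4 a single source.  Condition 1: a partial divider shade so
    each source lights only its closer half (zones split by x=0, lit from
    opposite sides).  Condition 2: full shades so each source lights one
    lateral half (zones split by y=0, lit along the border).  Condition 3:
    the combination — one divider-type and one full-type shade, the front
    zone lit from the front and the back zone laterally.  The same physical
    scene serves both views of a condition; only the camera differs.
    """
    cam = camera_azimuth_deg(condition, view)  # validates the combination
    east = _source(_SRC_H, _SRC_DY, intensity)
    west = _source(-_SRC_H, -_SRC_DY, intensity)
    south = _source(0.0, -_SRC_H, intensity)

    if condition == 1:
        scene = SceneConfig(
            sources=[east, west],
            occluders=[_divider_x()],
            ambient_illuminance=ambient,
            label=f"cond1-{view}",
        )
        zones = {"x_neg": _toward(west), "x_pos": _toward(east)}
        # LR view (camera +y): left = -x.  FB view (camera +x): front = -x.
        zmap = {"zone1": zones["x_neg"], "zone2": zones["x_pos"]}
    elif condition == 2:
        scene = SceneConfig(
            sources=[east, west],
            occluders=[_full_shade_east(), _full_shade_west()],
            ambient_illuminance=ambient,
            label=f"cond2-{view}",
        )
        # east source lights the y>0 half, west source the y<0 half
        if view == "LR":  # camera +x: left = +y
            zmap = {"zone1": _toward(east), "zone2": _toward(west)}
        else:  # camera +y: front = -y
            zmap = {"zone1": _toward(west), "zone2": _toward(east)}
    elif condition == 3:
        scene = SceneConfig(
            sources=[south, east],
            occluders=[_divider_y(), _full_shade_east()],
            ambient_illuminance=ambient,
            label=f"cond3-{view}",
        )
        # south source lights y<0 (direction toward the front for the FB
        # camera), east source lights y>0 (lateral direction)
        if view == "LR":  # camera +x: left = +y
            zmap = {"zone1": _toward(east), "zone2": _toward(south)}
        else:  # camera +y: front = y<0
            zmap = {"zone1": _toward(south), "zone2": _toward(east)}
    elif condition == 4:
        scene = SceneConfig(
            sources=[east],
            occluders=[],
            ambient_illuminance=ambient,
            label=f"cond4-{view}",
        )
        zmap = {"zone": _toward(east)}
    else:
        raise ValueError(f"invalid condition/view combination ({condition}, {view!r})")

    return Exp2Scene(
        condition=condition,
        view=view,
        scene=scene,
        camera_azimuth_deg=cam,
        zone_directions=zmap,
    )
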