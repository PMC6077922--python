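"""Synthetic observers for the zoned-scene probing experiments.

The paper-style analysis needs observer probe settings; no human data ship
with the package, so this module generates settings tables with the
statistical structure the analysis assumes:

* directions: the veridical (physically measured) light direction of each
  probe, corrupted by von Mises-Fisher (vMF) noise of concentration
  ``kappa_dir``;
* intensities: the veridical scalar illuminance and diffuseness, display
  normalized, with truncated-Gaussian noise applied on the E_scalar and D
  scales and mapped back to (directed, ambient) intensities;
* zone confusion: with probability ``zone_confusion_p`` a setting on a
  probe in the *back* zone of a front-back oriented two-zone image is made
  according to the *front* zone's veridical direction instead — the
  idiosyncratic behavior observed for FB-oriented light zones.

Everything is reproducible from a single master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .lightfield_core import LightFieldGrid, LightFieldSample, measure_grid
from .probe_settings import (
    SETTINGS_COLUMNS,
    ProbeDesign,
    settings_to_vectors,
    vector_to_direction,
)
from .scene_radiometry import (
    Exp2Scene,
    build_experiment2_scene,
    measure_cube,
    CubeMeter,
    view_rotation_deg,
)
from .lightfield_core import first_order_properties

__all__ = [
    "ObserverProfile",
    "ConditionDesign",
    "ExperimentDesign",
    "sample_vmf",
    "estimate_kappa",
    "generate_settings",
    "experiment2_design",
    "experiment1_design",
    "pooled_kappa_estimate",
    "estimate_zone_confusion",
    "rotate_z",
]

DEFAULT_CONFUSION_VIEWS = ("FB",)


@dataclass
class ObserverProfile:
    """Generative parameters of one synthetic observer.

    kappa_dir
        vMF concentration of the directional noise (> 0); the angular
        standard deviation is roughly ``1/sqrt(kappa)`` radians.
    sd_intensity, sd_diffuseness
        Truncated-Gaussian noise on the normalized scalar-illuminance and
        diffuseness scales (both live in [0, 1]).
    zone_confusion_p
        Probability that a back-zone probe of an FB-oriented two-zone image
        is set according to the front zone's veridical direction.
    """

    observer_id: str
    kappa_dir: float = 20.0
    sd_intensity: float = 0.05
    sd_diffuseness: float = 0.10
    zone_confusion_p: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.kappa_dir <= 0:
            raise ValueError("kappa_dir must be > 0")
        if self.sd_intensity < 0 or self.sd_diffuseness < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not 0.0 <= self.zone_confusion_p <= 1.0:
            raise ValueError("zone_confusion_p must be in [0, 1]")


@dataclass
class ConditionDesign:
    """One condition image: probes, view geometry and veridical field."""

    condition_id: str
    view: str
    camera_azimuth_deg: float
    probes: ProbeDesign
    probe_zone: dict[str, str]  # probe_id -> zone1 | middle | zone2
    veridical: dict[str, LightFieldSample]  # scene frame
    zone_directions: dict[str, np.ndarray]  # scene frame
    gain: float
    two_zone: bool
    extra_repetitions: dict[str, int] = field(default_factory=dict)

    def repetitions_for(self, probe_id: str) -> int:
        return self.probes.repetitions + self.extra_repetitions.get(probe_id, 0)


@dataclass
class ExperimentDesign:
    conditions: list[ConditionDesign]

    def trials_per_observer(self) -> int:
        return sum(
            c.repetitions_for(pid) for c in self.conditions for pid in c.probes.probe_ids
        )

    def condition(self, condition_id: str) -> ConditionDesign:
        for c in self.conditions:
            if c.condition_id == condition_id:
                return c
        raise KeyError(condition_id)


# ---------------------------------------------------------------------------
# von Mises-Fisher sampling and concentration estimation
# ---------------------------------------------------------------------------

def _orthonormal_frame(mu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(mu @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(mu, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(mu, e1)
    return e1, e2


def sample_vmf(mu, kappa: float, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` i.i.d. vMF(mu, kappa) unit vectors on the sphere.

    The polar angle about ``mu`` is drawn by inverting the vMF CDF for
    ``w = cos(theta)`` (density proportional to ``exp(kappa * w)``):
    ``w = 1 + log(u + (1 - u) exp(-2 kappa)) / kappa``; the azimuth about
    ``mu`` is uniform.  ``seed`` may be an int or a numpy Generator.
    """
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    mu = np.asarray(mu, dtype=float)
    mu = mu / np.linalg.norm(mu)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(n)
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    w = np.clip(w, -1.0, 1.0)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(np.maximum(0.0, 1.0 - w * w))
    e1, e2 = _orthonormal_frame(mu)
    return (
        w[:, None] * mu[None, :]
        + (s * np.cos(phi))[:, None] * e1[None, :]
        + (s * np.sin(phi))[:, None] * e2[None, :]
    )


def estimate_kappa(vectors) -> float:
    """Concentration estimate from unit vectors: R(3 - R^2)/(1 - R^2).

    The standard approximation to the maximum-likelihood vMF estimator on
    the sphere, with R the mean resultant length.
    """
    v = np.asarray(vectors, dtype=float)
    if v.ndim != 2 or v.shape[1] != 3 or len(v) < 2:
        raise ValueError("need >= 2 unit 3-vectors")
    rbar = float(np.linalg.norm(v.mean(axis=0)))
    if rbar >= 1.0 - 1e-12:
        raise ValueError("infinite concentration: all vectors identical")
    return rbar * (3.0 - rbar**2) / (1.0 - rbar**2)


def rotate_z(vectors, angle_deg: float) -> np.ndarray:
    """Rotate 3-vectors about +z by ``angle_deg`` (counterclockwise)."""
    a = np.deg2rad(angle_deg)
    rot = np.array(
        [[np.cos(a), -np.sin(a), 0.0], [np.sin(a), np.cos(a), 0.0], [0.0, 0.0, 1.0]]
    )
    v = np.asarray(vectors, dtype=float)
    return v @ rot.T


# ---------------------------------------------------------------------------
# Experiment designs
# ---------------------------------------------------------------------------

_PROBE_XY = {
    "q1": (0.5, 0.5),
    "q2": (-0.5, 0.5),
    "q3": (-0.5, -0.5),
    "q4": (0.5, -0.5),
    "c": (0.0, 0.0),
}
_PROBE_Z = 0.25
_PEAK_TARGET = 0.8  # display-normalized peak probe luminance at veridical


def _condition_from_scene(
    exp2: Exp2Scene, condition_id: str, repetitions: int
) -> ConditionDesign:
    probe_ids = list(_PROBE_XY)
    positions = np.array([[x, y, _PROBE_Z] for x, y in _PROBE_XY.values()])
    probes = ProbeDesign(
        condition_id=condition_id,
        positions=positions,
        probe_ids=probe_ids,
        repetitions=repetitions,
    )
    veridical = {}
    for pid, pos in zip(probe_ids, positions):
        faces = measure_cube(CubeMeter(pos), exp2.scene)
        veridical[pid] = first_order_properties(faces, position=pos)
    alpha = view_rotation_deg(exp2.camera_azimuth_deg)
    two_zone = exp2.condition in (1, 2, 3)
    # zone membership from the view-frame probe coordinate along the
    # border-normal axis: x_view (left/right) for LR and single-source
    # views, y_view (front/back) for FB
    probe_zone = {}
    for pid, pos in zip(probe_ids, positions):
        pv = rotate_z(pos, alpha)
        coord = pv[1] if (two_zone and exp2.view == "FB") else pv[0]
        if abs(coord) < 1e-9:
            probe_zone[pid] = "middle"
        else:
            probe_zone[pid] = "zone1" if coord < 0 else "zone2"
    if two_zone:
        zone_dirs = dict(exp2.zone_directions)
    else:
        d = exp2.zone_directions["zone"]
        zone_dirs = {"zone1": d, "zone2": d}
    peak = max(
        s.E_scalar * (4.0 - 3.0 * s.D) for s in veridical.values()
    )  # I_dir + I_amb = E_scalar (4 - 3 D)
    return ConditionDesign(
        condition_id=condition_id,
        view=exp2.view,
        camera_azimuth_deg=exp2.camera_azimuth_deg,
        probes=probes,
        probe_zone=probe_zone,
        veridical=veridical,
        zone_directions=zone_dirs,
        gain=_PEAK_TARGET / peak,
        two_zone=two_zone,
    )


def experiment2_design(
    repetitions: int = 3, intensity: float = 100.0, ambient: float = 0.05
) -> ExperimentDesign:
    """The full two-zone design: 10 condition images (6 two-zone, 4
    single-zone), 5 probes each, ``repetitions`` settings per probe."""
    combos = [
        (1, "LR"), (1, "FB"), (2, "LR"), (2, "FB"), (3, "LR"), (3, "FB"),
        (4, "F"), (4, "R"), (4, "B"), (4, "L"),
    ]
    conditions = []
    for cond, view in combos:
        exp2 = build_experiment2_scene(cond, view, intensity=intensity, ambient=ambient)
        conditions.append(_condition_from_scene(exp2, f"{cond}{view}", repetitions))
    return ExperimentDesign(conditions=conditions)


_EXP1_REPEAT_NODES = [(1, 1, 1), (1, 3, 1), (3, 1, 1), (3, 3, 1), (2, 2, 1)]


def experiment1_design(
    intensity: float = 100.0, ambient: float = 0.05
) -> tuple[ExperimentDesign, dict[str, LightFieldGrid]]:
    """Grid-probing design over the abstract zoned scenes.

    Two conditions — zones split left-right and front-back — each probed on
    a 5 x 5 x 3 lattice (one setting per node, three for the five repeat
    probes: two per zone plus the center).  Returns the design and the
    measured physical light-field grid of each condition.
    """
    x = np.linspace(-1.0, 1.0, 5)
    y = np.linspace(-1.0, 1.0, 5)
    z = np.linspace(0.2, 1.0, 3)
    scenes = {
        "Exp1-LR": build_experiment2_scene(1, "LR", intensity, ambient),
        "Exp1-FB": build_experiment2_scene(3, "FB", intensity, ambient),
    }
    conditions = []
    grids = {}
    for cid, exp2 in scenes.items():
        grid = measure_grid(exp2.scene, x, y, z)
        grids[cid] = grid
        probe_ids, positions, veridical, probe_zone = [], [], {}, {}
        for i in range(5):
            for j in range(5):
                for k in range(3):
                    pid = f"g{i}{j}{k}"
                    probe_ids.append(pid)
                    s = grid.samples[i, j, k]
                    positions.append(s.position)
                    veridical[pid] = s
                    idx = i if exp2.view == "LR" else j
                    probe_zone[pid] = (
                        "zone1" if idx < 2 else "middle" if idx == 2 else "zone2"
                    )
        probes = ProbeDesign(
            condition_id=cid,
            positions=np.array(positions),
            probe_ids=probe_ids,
            repetitions=1,
        )
        peak = max(s.E_scalar * (4.0 - 3.0 * s.D) for s in veridical.values())
        conditions.append(
            ConditionDesign(
                condition_id=cid,
                view=exp2.view,
                camera_azimuth_deg=exp2.camera_azimuth_deg,
                probes=probes,
                probe_zone=probe_zone,
                veridical=veridical,
                zone_directions=dict(exp2.zone_directions),
                gain=_PEAK_TARGET / peak,
                two_zone=True,
                extra_repetitions={
                    f"g{i}{j}{k}": 2 for i, j, k in _EXP1_REPEAT_NODES
                },
            )
        )
    return ExperimentDesign(conditions=conditions), grids


# ---------------------------------------------------------------------------
# Settings generation
# ---------------------------------------------------------------------------

def generate_settings(
    design: ExperimentDesign,
    profiles: Sequence[ObserverProfile],
    master_seed: int,
    confusion_views: tuple[str, ...] = DEFAULT_CONFUSION_VIEWS,
) -> pd.DataFrame:
    """Settings table for every observer x condition x probe x repetition.

    The realized direction is vMF noise about the probe's veridical
    direction — or, for back-zone probes of FB-oriented two-zone images,
    about the front zone's direction with probability ``zone_confusion_p``.
    Directions are reported in the view frame of each condition's camera.
    Fully reproducible from ``master_seed``.
    """
    if not profiles:
        raise ValueError("need at least one observer profile")
    rows = []
    for oi, prof in enumerate(profiles):
        entropy = prof.seed if prof.seed is not None else master_seed
        rng = np.random.default_rng(np.random.SeedSequence([int(entropy) % (2**31), oi]))
        for cond in design.conditions:
            alpha = view_rotation_deg(cond.camera_azimuth_deg)
            for pid in cond.probes.probe_ids:
                ver = cond.veridical[pid]
                base_dir = (
                    ver.light_direction
                    if ver.light_direction is not None
                    else np.array([0.0, 0.0, 1.0])
                )
                confusable = (
                    cond.two_zone
                    and cond.probe_zone[pid] == "zone2"
                    and cond.view in confusion_views
                )
                es_ver = cond.gain * ver.E_scalar
                for rep in range(1, cond.repetitions_for(pid) + 1):
                    target = base_dir
                    if confusable and rng.random() < prof.zone_confusion_p:
                        target = cond.zone_directions["zone1"]
                    d_scene = sample_vmf(target, prof.kappa_dir, 1, rng)[0]
                    az, el = vector_to_direction(rotate_z(d_scene, alpha))
                    es = float(
                        np.clip(rng.normal(es_ver, prof.sd_intensity), 1e-3, 1.0)
                    )
                    dd = float(np.clip(rng.normal(ver.D, prof.sd_diffuseness), 0.0, 1.0))
                    i_dir = float(np.clip(4.0 * es * (1.0 - dd), 0.0, 1.0))
                    i_amb = float(np.clip(es * dd, 0.0, 1.0))
                    rows.append(
                        (
                            prof.observer_id,
                            cond.condition_id,
                            pid,
                            rep,
                            az,
                            el,
                            i_dir,
                            i_amb,
                            bool(i_dir + i_amb > 1.0),
                        )
                    )
    return pd.DataFrame(rows, columns=SETTINGS_COLUMNS)


# ---------------------------------------------------------------------------
# Recovery oracles
# ---------------------------------------------------------------------------

def _unaffected(cond: ConditionDesign, pid: str, confusion_views) -> bool:
    return not (
        cond.two_zone
        and cond.probe_zone[pid] == "zone2"
        and cond.view in confusion_views
    )


def pooled_kappa_estimate(
    settings: pd.DataFrame,
    design: ExperimentDesign,
    confusion_views: tuple[str, ...] = DEFAULT_CONFUSION_VIEWS,
) -> float:
    """Recover the directional concentration from confusion-free cells.

    Each setting's cosine with its probe's veridical direction (view frame)
    is pooled; with the mean direction known, ``mean(cos)`` estimates the
    vMF mean cosine A(kappa), inverted with the same approximation as
    :func:`estimate_kappa`.
    """
    cos = []
    for cond in design.conditions:
        alpha = view_rotation_deg(cond.camera_azimuth_deg)
        sub = settings[settings["condition_id"] == cond.condition_id]
        for pid, grp in sub.groupby("probe_id", sort=True):
            if not _unaffected(cond, pid, confusion_views):
                continue
            ver = cond.veridical[pid].light_direction
            if ver is None:
                continue
            mu = rotate_z(ver, alpha)
            cos.extend(settings_to_vectors(grp) @ mu)
    if len(cos) < 2:
        raise ValueError("not enough confusion-free settings")
    rbar = float(np.clip(np.mean(cos), 0.0, 1.0 - 1e-12))
    return rbar * (3.0 - rbar**2) / (1.0 - rbar**2)


def estimate_zone_confusion(
    settings: pd.DataFrame,
    design: ExperimentDesign,
    confusion_views: tuple[str, ...] = DEFAULT_CONFUSION_VIEWS,
) -> tuple[float, int]:
    """(estimated confusion probability, n trials classified).

    Every setting on a confusable probe is assigned to the nearer of the
    two zone veridical directions; the confusion estimate is the fraction
    assigned to the opposite (front) zone.
    """
    n = 0
    confused = 0
    for cond in design.conditions:
        if not cond.two_zone or cond.view not in confusion_views:
            continue
        alpha = view_rotation_deg(cond.camera_azimuth_deg)
        own = rotate_z(cond.zone_directions["zone2"], alpha)
        other = rotate_z(cond.zone_directions["zone1"], alpha)
        sub = settings[settings["condition_id"] == cond.condition_id]
        sub = sub[sub["probe_id"].map(cond.probe_zone) == "zone2"]
        if sub.empty:
            continue
        v = settings_to_vectors(sub)
        confused += int(np.sum(v @ other > v @ own))
        n += len(v)
    if n == 0:
        raise ValueError("no confusable settings in the table")
    return confused / n, n
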