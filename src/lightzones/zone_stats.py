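"""Directional statistics for probe-setting analysis.

Settings are unit vectors on the sphere; the spread of a group is
parameterized by the dispersion ``1/R``, with ``R`` the mean resultant
length (1 when all vectors agree, 0 for a balanced spread, so the
dispersion runs from 1 to infinity).  Groups are compared against the
veridical physical directions (angular deviation), against each other
after 90-degree view rotations or mirror flips (two-sample Watson U2 on
top-view azimuths), and with classical paired t tests on summary scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .probe_settings import settings_to_vectors

__all__ = [
    "DirectionalSummary",
    "GroupedSettings",
    "mean_direction_and_R",
    "sd_ellipse",
    "angular_difference",
    "slice_grid",
    "group_probes_exp2",
    "rotate_settings_azimuth",
    "mirror_settings",
    "watson_u2",
    "paired_t",
    "circular_histogram",
    "deviation_report",
]


@dataclass
class DirectionalSummary:
    """Mean direction, resultant length and dispersion of a set of unit
    vectors; the SD ellipse lives on the tangent plane at the mean."""

    n: int
    mean_direction: np.ndarray | None  # None when R == 0
    R: float
    dispersion: float  # 1/R, inf when R == 0
    ellipse: tuple[float, float, float] | None = None  # sd_major, sd_minor, deg


@dataclass
class GroupedSettings:
    label: str
    settings: pd.DataFrame

    def __len__(self) -> int:
        return len(self.settings)


def mean_direction_and_R(vectors) -> DirectionalSummary:
    """Spherical mean and mean resultant length R = |sum v| / n."""
    v = np.asarray(vectors, dtype=float)
    if v.ndim != 2 or v.shape[1] != 3 or len(v) == 0:
        raise ValueError("need a non-empty (n, 3) array of unit vectors")
    resultant = v.sum(axis=0)
    r = float(np.linalg.norm(resultant)) / len(v)
    if r == 0.0:
        return DirectionalSummary(n=len(v), mean_direction=None, R=0.0,
                                  dispersion=math.inf)
    return DirectionalSummary(
        n=len(v),
        mean_direction=resultant / np.linalg.norm(resultant),
        R=r,
        dispersion=1.0 / r,
    )


def sd_ellipse(vectors) -> tuple[float, float, float]:
    """Standard-deviation ellipse of directions on the tangent plane.

    Vectors are projected onto an orthonormal basis of the plane normal to
    the mean direction; the 2x2 covariance eigendecomposition gives
    (sd_major, sd_minor, orientation), orientation in degrees of the major
    axis from the first basis vector.
    """
    v = np.asarray(vectors, dtype=float)
    if len(v) < 3:
        raise ValueError("need >= 3 vectors for an SD ellipse")
    summ = mean_direction_and_R(v)
    if summ.mean_direction is None:
        raise ValueError("no mean direction (R = 0)")
    mu = summ.mean_direction
    helper = np.array([0.0, 0.0, 1.0])
    if abs(mu @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(helper, mu)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(mu, e1)
    coords = np.column_stack([v @ e1, v @ e2])
    cov = np.cov(coords, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.maximum(evals, 0.0)
    major = np.sqrt(evals[1])
    minor = np.sqrt(evals[0])
    orient = float(np.rad2deg(np.arctan2(evecs[1, 1], evecs[0, 1]))) % 180.0
    return float(major), float(minor), orient


def angular_difference(v1, v2) -> float:
    """Angle between two unit vectors in degrees, in [0, 180]."""
    d = float(np.clip(np.dot(v1, v2), -1.0, 1.0))
    return float(np.rad2deg(np.arccos(d)))


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------

def slice_grid(
    settings: pd.DataFrame,
    grid,
    slice_axis: str,
    probe_positions: dict[str, np.ndarray],
) -> list[GroupedSettings]:
    """Partition grid-probe settings into the five slices along an axis.

    Slices are planes of the lattice parallel to the zone border: along x
    for left-right zones (parallel to the viewing direction), along y for
    front-back zones (parallel to the picture plane).  ``probe_positions``
    maps each probe_id to its scene position, which must coincide with a
    lattice node.
    """
    if slice_axis not in ("x", "y"):
        raise ValueError("slice_axis must be 'x' or 'y'")
    coords = getattr(grid, slice_axis)
    if len(coords) != 5:
        raise ValueError(f"grid must have 5 nodes along {slice_axis}")
    axis_i = {"x": 0, "y": 1}[slice_axis]
    groups = [[] for _ in coords]
    for row_i, probe in enumerate(settings["probe_id"]):
        try:
            pos = probe_positions[probe]
        except KeyError:
            raise ValueError(f"unknown probe_id {probe!r}")
        c = float(np.asarray(pos, dtype=float)[axis_i])
        dist = np.abs(coords - c)
        j = int(dist.argmin())
        if dist[j] > 1e-9:
            raise ValueError(f"probe {probe!r} is not on the lattice along {slice_axis}")
        groups[j].append(row_i)
    return [
        GroupedSettings(label=f"slice{j + 1}", settings=settings.iloc[idx])
        for j, idx in enumerate(groups)
    ]


def group_probes_exp2(settings: pd.DataFrame, condition_design) -> list[GroupedSettings]:
    """Group the five probes of a condition image into zone1 (the left or
    front pair), middle (the center probe) and zone2 (the right or back
    pair)."""
    if len(condition_design.probes.probe_ids) != 5:
        raise ValueError("the two-zone design uses exactly 5 probes")
    zone_of = condition_design.probe_zone
    unknown = set(settings["probe_id"]) - set(zone_of)
    if unknown:
        raise ValueError(f"unknown probe_id(s) {sorted(unknown)}")
    out = []
    for label in ("zone1", "middle", "zone2"):
        pids = [p for p, z in zone_of.items() if z == label]
        out.append(
            GroupedSettings(
                label=label, settings=settings[settings["probe_id"].isin(pids)]
            )
        )
    return out


def rotate_settings_azimuth(settings: pd.DataFrame, angle_deg: float) -> pd.DataFrame:
    """Shift all azimuths by ``angle_deg`` modulo 360; elevations unchanged.
    Used to align views before cross-view comparisons."""
    out = settings.copy()
    out["azimuth_deg"] = (out["azimuth_deg"] + angle_deg) % 360.0
    return out


def mirror_settings(settings: pd.DataFrame, plane: str = "lr") -> pd.DataFrame:
    """Mirror azimuths: 'lr' flips left-right (az -> 180 - az), 'fb' flips
    front-back (az -> -az).  Elevations unchanged."""
    out = settings.copy()
    if plane == "lr":
        out["azimuth_deg"] = (180.0 - out["azimuth_deg"]) % 360.0
    elif plane == "fb":
        out["azimuth_deg"] = (-out["azimuth_deg"]) % 360.0
    else:
        raise ValueError("plane must be 'lr' or 'fb'")
    return out


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

def _u2_statistic(a: np.ndarray, b: np.ndarray) -> float:
    n, m = len(a), len(b)
    big_n = n + m
    pooled = np.concatenate([a, b])
    is_a = np.concatenate([np.ones(n, dtype=bool), np.zeros(m, dtype=bool)])
    order = np.argsort(pooled, kind="stable")
    lab = is_a[order]
    d = np.cumsum(np.where(lab, 1.0 / n, 0.0)) - np.cumsum(np.where(lab, 0.0, 1.0 / m))
    return float(n * m / big_n**2 * (np.sum(d * d) - np.sum(d) ** 2 / big_n))


# mean and variance of the limiting null distribution of U2
_U2_LIMIT_MEAN = 1.0 / 12.0
_U2_LIMIT_VAR = 1.0 / 360.0


@lru_cache(maxsize=256)
def _u2_null_moments(n: int, m: int) -> tuple[float, float]:
    """Exact mean and variance of U2 under the permutation null (no ties).

    With ties broken by pooled order, U2 = ztilde' M ztilde / (n m), where
    ztilde is the centered sample-A indicator over the pooled ranks and
    M = L' (I - J/N) L with L lower-triangular ones.  The moments of this
    quadratic form under simple random sampling without replacement follow
    from the joint central moments of the indicators, grouped by index
    coincidence pattern.  (Verified against exhaustive enumeration over all
    C(N, n) assignments in the test suite.)
    """
    big_n = n + m
    q = n / big_n
    lower = np.tril(np.ones((big_n, big_n)))
    center = np.eye(big_n) - np.ones((big_n, big_n)) / big_n
    mat = lower.T @ center @ lower
    # raw moments: P(r specified pooled positions all come from sample A)
    mu = [1.0]
    for t in range(4):
        mu.append(mu[-1] * (n - t) / (big_n - t))
    def cm(r):  # central moment over r distinct indices
        return sum((-q) ** (r - j) * comb(r, j) * mu[j] for j in range(r + 1))
    m2, m3, m4 = cm(2), cm(3), cm(4)
    v = q * (1.0 - q)
    e4 = (1 - 2 * q) ** 2 * v + v**2
    e22 = (1 - 2 * q) ** 2 * m2 + v**2
    e31 = ((1 - 2 * q) ** 2 + v) * m2
    e211 = (1 - 2 * q) * m3 + v * m2
    d = np.diag(mat)
    r = mat.sum(axis=1)
    s1, s2 = d.sum(), mat.sum()
    sd2, ssq = (d**2).sum(), (mat**2).sum()
    sdr, sr2 = (d * r).sum(), (r**2).sum()
    a1 = sd2
    a2 = s1**2 - sd2
    a3 = 2 * (ssq - sd2)
    a4 = 4 * (sdr - sd2)
    a5 = 2 * (s1 * s2 - s1**2 - 2 * sdr + 2 * sd2)
    a6 = 4 * (sr2 - 2 * sdr + 2 * sd2 - ssq)
    a7 = s2**2 - (a1 + a2 + a3 + a4 + a5 + a6)
    eq = v * np.trace(mat) + m2 * (s2 - np.trace(mat))
    eq2 = e4 * a1 + e22 * (a2 + a3) + e31 * a4 + e211 * (a5 + a6) + m4 * a7
    nm = n * m
    return eq / nm, (eq2 - eq**2) / nm**2


def _u2_series_p(u2: float, terms: int = 60) -> float:
    k = np.arange(1, terms + 1)
    p = 2.0 * np.sum((-1.0) ** (k - 1) * np.exp(-2.0 * k**2 * np.pi**2 * u2))
    return float(np.clip(p, 0.0, 1.0))


def _u2_asymptotic_p(u2: float, n: int | None = None, m: int | None = None) -> float:
    """P(U2 > u2) from the limiting series, with a finite-sample moment
    correction when (n, m) are given: the statistic is mapped affinely so
    that its exact permutation-null mean and variance match those of the
    limiting distribution (1/12 and 1/360)."""
    if n is not None and m is not None:
        mean_n, var_n = _u2_null_moments(n, m)
        u2 = _U2_LIMIT_MEAN + (u2 - mean_n) * math.sqrt(_U2_LIMIT_VAR / var_n)
        u2 = max(u2, 0.0)
    return _u2_series_p(u2)


def watson_u2(
    angles_a,
    angles_b,
    mode: str = "asymptotic",
    n_perm: int = 999,
    seed=None,
) -> tuple[float, float]:
    """Two-sample Watson U2 test for circular distributions (azimuths in
    degrees).  Returns (U2, p).

    ``mode="asymptotic"`` uses the limiting null distribution
    ``P(U2 > u) = 2 sum_k (-1)^(k-1) exp(-2 k^2 pi^2 u)`` after an exact
    finite-sample moment correction (see :func:`_u2_null_moments`);
    ``mode="permutation"`` draws a seeded pooled-relabeling null, the
    package's in-repo oracle for the asymptotic p value.
    """
    a = np.asarray(angles_a, dtype=float) % 360.0
    b = np.asarray(angles_b, dtype=float) % 360.0
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 angles")
    u2 = _u2_statistic(a, b)
    if mode == "asymptotic":
        return u2, _u2_asymptotic_p(u2, len(a), len(b))
    if mode != "permutation":
        raise ValueError("mode must be 'asymptotic' or 'permutation'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    n = len(a)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if _u2_statistic(perm[:n], perm[n:]) >= u2 - 1e-12:
            count += 1
    return u2, (count + 1) / (n_perm + 1)


def paired_t(a, b) -> tuple[float, float]:
    """Classical paired Student's t on the difference scores, df = n - 1.

    Coded directly from the textbook formula t = dbar / (s_d / sqrt(n));
    the two-sided p uses the t distribution's survival function.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-d samples with n >= 2")
    d = a - b
    n = len(d)
    dbar = d.mean()
    sd = math.sqrt(np.sum((d - dbar) ** 2) / (n - 1))
    if sd == 0.0:
        raise ValueError("zero variance of differences")
    t = dbar / (sd / math.sqrt(n))
    p = 2.0 * float(_sstats.t.sf(abs(t), df=n - 1))
    return float(t), p


def circular_histogram(azimuths_deg, n_bins: int = 24) -> np.ndarray:
    """Counts over equal-width azimuth bins starting at 0 degrees."""
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    az = np.asarray(azimuths_deg, dtype=float) % 360.0
    counts, _ = np.histogram(az, bins=np.linspace(0.0, 360.0, n_bins + 1))
    return counts


# ---------------------------------------------------------------------------
# Deviation / spread report
# ---------------------------------------------------------------------------

def _wrapped_az_diff(a_deg: np.ndarray, b_deg: np.ndarray) -> np.ndarray:
    d = np.abs((a_deg - b_deg + 180.0) % 360.0 - 180.0)
    return d


def deviation_report(
    groups: list[GroupedSettings],
    veridical_dirs: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Per-group spread and veridicality summary.

    For each group: between-observer dispersion (all settings pooled),
    within-observer dispersion (per observer, then averaged), the mean
    angular deviation from each probe's veridical direction (full 3-D
    angle and top-view azimuthal angle), and the standard deviations of
    the implied scalar-illuminance and diffuseness settings.
    ``veridical_dirs`` must be in the same frame as the settings (the view
    frame), keyed by probe_id.
    """
    rows = []
    for grp in groups:
        df = grp.settings
        if df.empty:
            rows.append([grp.label, 0] + [math.nan] * 6)
            continue
        missing = set(df["probe_id"]) - set(veridical_dirs)
        if missing:
            raise ValueError(f"missing veridical direction for {sorted(missing)}")
        v = settings_to_vectors(df)
        between = mean_direction_and_R(v).dispersion
        within = []
        for _, sub in df.groupby("observer_id", sort=True):
            within.append(mean_direction_and_R(settings_to_vectors(sub)).dispersion)
        ver = np.array([veridical_dirs[p] for p in df["probe_id"]])
        ver = ver / np.linalg.norm(ver, axis=1, keepdims=True)
        dev3d = np.rad2deg(np.arccos(np.clip(np.sum(v * ver, axis=1), -1.0, 1.0)))
        ver_az = np.rad2deg(np.arctan2(ver[:, 1], ver[:, 0])) % 360.0
        dev_top = _wrapped_az_diff(df["azimuth_deg"].to_numpy(dtype=float), ver_az)
        i_dir = df["I_directed"].to_numpy(dtype=float)
        i_amb = df["I_ambient"].to_numpy(dtype=float)
        e_scalar = i_dir / 4.0 + i_amb
        with np.errstate(divide="ignore", invalid="ignore"):
            dvals = 1.0 - (i_dir / e_scalar) / 4.0
        rows.append(
            [
                grp.label,
                len(df),
                between,
                float(np.mean(within)),
                float(np.mean(dev3d)),
                float(np.mean(dev_top)),
                float(np.std(e_scalar, ddof=1)) if len(df) > 1 else 0.0,
                float(np.std(dvals, ddof=1)) if len(df) > 1 else 0.0,
            ]
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group",
            "n",
            "between_dispersion",
            "within_dispersion",
            "mean_dev_3d_deg",
            "mean_dev_topview_deg",
            "sd_intensity",
            "sd_diffuseness",
        ],
    )
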