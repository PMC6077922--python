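"""Observer probe settings and their light-field interpretation.

An observer adjusts a matte white probe sphere until it appears to belong
to the scene: a light *direction* (azimuth/elevation), a *directed*
intensity and an *ambient* intensity, both display-normalized to [0, 1].
The directed and ambient settings are read as the magnitudes of E_vector
and E_symmetric of the inferred light field, from which scalar illuminance
and diffuseness follow exactly as for physical cubic measurements.

Settings tables are plain pandas DataFrames with the columns of
:data:`SETTINGS_COLUMNS` — the pipeline's central exchange format.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ObserverSetting",
    "ProbeDesign",
    "SETTINGS_COLUMNS",
    "direction_to_vector",
    "vector_to_direction",
    "setting_to_field_properties",
    "lambertian_probe_luminance",
    "settings_to_vectors",
]

SETTINGS_COLUMNS = [
    "observer_id",
    "condition_id",
    "probe_id",
    "repetition",
    "azimuth_deg",
    "elevation_deg",
    "I_directed",
    "I_ambient",
    "clipped",
]


@dataclass
class ObserverSetting:
    """One probe adjustment."""

    observer_id: str
    condition_id: str
    probe_id: str
    repetition: int
    azimuth: float  # degrees in [0, 360)
    elevation: float  # degrees in [-90, 90]
    I_directed: float  # [0, 1]
    I_ambient: float  # [0, 1]
    clipped: bool = False

    def __post_init__(self):
        if not -90.0 <= self.elevation <= 90.0:
            raise ValueError("elevation must be in [-90, 90] degrees")
        self.azimuth = float(self.azimuth) % 360.0
        for name in ("I_directed", "I_ambient"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if int(self.repetition) < 1:
            raise ValueError("repetition must be >= 1")


@dataclass
class ProbeDesign:
    """Probe layout of one condition image."""

    condition_id: str
    positions: np.ndarray  # (n_probes, 3)
    probe_ids: list[str]
    repetitions: int = 1

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n, 3)")
        if len(self.probe_ids) != len(self.positions):
            raise ValueError("one probe_id per position required")
        if len(np.unique(self.positions, axis=0)) != len(self.positions):
            raise ValueError("probe positions must be distinct")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


def direction_to_vector(azimuth_deg: float, elevation_deg: float) -> np.ndarray:
    """Unit vector for (azimuth, elevation) in degrees.

    Azimuth counterclockwise from +x in the horizontal plane, elevation
    from the horizontal plane toward +z.
    """
    el = np.deg2rad(elevation_deg)
    if not -np.pi / 2 - 1e-12 <= el <= np.pi / 2 + 1e-12:
        raise ValueError("elevation must be in [-90, 90] degrees")
    az = np.deg2rad(azimuth_deg)
    return np.array(
        [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
    )


def vector_to_direction(v) -> tuple[float, float]:
    """(azimuth, elevation) in degrees for a 3-vector; azimuth 0 at the poles."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector has no direction")
    v = v / n
    el = float(np.rad2deg(np.arcsin(np.clip(v[2], -1.0, 1.0))))
    if abs(abs(v[2]) - 1.0) < 1e-12:
        return 0.0, el
    az = float(np.rad2deg(np.arctan2(v[1], v[0]))) % 360.0
    return az, el


def setting_to_field_properties(
    setting: ObserverSetting | None = None,
    I_directed: float | None = None,
    I_ambient: float | None = None,
) -> tuple[float, float, float, float]:
    """(E_vector, E_symmetric, E_scalar, D) implied by a probe setting.

    The directed intensity is taken as E_vector, the ambient intensity as
    E_symmetric.  Clipped settings are not numerically corrected; the
    ``clipped`` flag on the setting preserves auditability.
    """
    if setting is not None:
        I_directed, I_ambient = setting.I_directed, setting.I_ambient
    if I_directed == 0.0 and I_ambient == 0.0:
        raise ValueError("dark setting: both intensities are zero")
    e_vector = float(I_directed)
    e_sym = float(I_ambient)
    e_scalar = e_vector / 4.0 + e_sym
    d = 1.0 - (e_vector / e_scalar) / 4.0
    return e_vector, e_sym, e_scalar, d


def lambertian_probe_luminance(setting: ObserverSetting, surface_normal) -> float:
    """Luminance of a matte probe point under the directed + ambient model.

    ``L = I_ambient + I_directed * max(0, n . d)``; a value above 1 exceeds
    the display range and marks the setting as clipped.
    """
    n = np.asarray(surface_normal, dtype=float)
    n = n / np.linalg.norm(n)
    d = direction_to_vector(setting.azimuth, setting.elevation)
    lum = setting.I_ambient + setting.I_directed * max(0.0, float(n @ d))
    if lum > 1.0:
        setting.clipped = True
    return lum


def settings_to_vectors(settings: pd.DataFrame) -> np.ndarray:
    """Unit direction vectors (n, 3) for the rows of a settings table."""
    az = np.deg2rad(settings["azimuth_deg"].to_numpy(dtype=float))
    el = np.deg2rad(settings["elevation_deg"].to_numpy(dtype=float))
    return np.column_stack(
        [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
    )
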