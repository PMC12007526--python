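"""MEG forward model: current dipoles in a conducting sphere, axial
gradiometer pickup.

The magnetic field of a current dipole in a spherically symmetric conductor
is given in closed form (Sarvas' formula); it depends only on the dipole's
tangential component, so radial dipoles are magnetically silent. Sensors
are first-order axial gradiometers: the radial field difference between two
coaxial coils separated by a 50-mm baseline, which suppresses distant
sources.

Head coordinates: origin at the sphere center, x right, y anterior,
z superior, millimetres. Fields are returned in tesla per nAm of dipole
moment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HeadModel", "SensorArray", "DipoleSource", "dipole_field",
           "forward_field", "leadfield_xyz"]

_MU0_4PI = 1e-7  # T·m/A


@dataclass(frozen=True)
class HeadModel:
    """Single-sphere volume conductor."""

    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius_mm: float = 90.0

    def contains(self, position_mm: np.ndarray, margin: float = 0.0) -> bool:
        r = np.linalg.norm(np.asarray(position_mm) - np.asarray(self.center_mm))
        return r < self.radius_mm * (1.0 - margin)


@dataclass
class SensorArray:
    """Helmet of axial gradiometers.

    ``positions_mm`` are inner-coil centres, ``normals`` the outward coil
    axes (unit vectors); the outer coil sits ``baseline_mm`` further out
    along the normal. ``disabled`` lists channels excluded from analysis.
    """

    positions_mm: np.ndarray
    normals: np.ndarray
    baseline_mm: float = 50.0
    disabled: list[int] = field(default_factory=list)
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions_mm = np.atleast_2d(np.asarray(self.positions_mm, float))
        self.normals = np.atleast_2d(np.asarray(self.normals, float))
        self.normals /= np.linalg.norm(self.normals, axis=1, keepdims=True)
        if not self.names:
            self.names = [f"MEG{i:03d}" for i in range(len(self.positions_mm))]

    @property
    def n_total(self) -> int:
        return len(self.positions_mm)

    @property
    def usable_index(self) -> np.ndarray:
        mask = np.ones(self.n_total, bool)
        mask[self.disabled] = False
        return np.flatnonzero(mask)

    @property
    def n_usable(self) -> int:
        return len(self.usable_index)

    @classmethod
    def ctf_like(cls, n_channels: int = 151, radius_mm: float = 110.0,
                 max_polar_deg: float = 115.0,
                 disabled: list[int] | None = None) -> "SensorArray":
        """Deterministic 151-channel helmet on a spherical cap.

        Channels follow a Fibonacci spiral from the vertex down to
        ``max_polar_deg``, approximating whole-head coverage. One channel
        (index 42 by default) is marked disabled, leaving 150 usable.
        """
        z_lo = np.cos(np.deg2rad(max_polar_deg))
        i = np.arange(n_channels)
        z = 1.0 - (1.0 - z_lo) * (i + 0.5) / n_channels
        phi = i * np.pi * (3.0 - np.sqrt(5.0))
        s = np.sqrt(1.0 - z**2)
        pts = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
        return cls(positions_mm=pts * radius_mm, normals=pts,
                   disabled=[42] if disabled is None else disabled)


@dataclass
class DipoleSource:
    """Point current source: position, fixed orientation, moment course."""

    position_mm: np.ndarray
    orientation: np.ndarray
    moment_nAm: np.ndarray

    def __post_init__(self) -> None:
        self.position_mm = np.asarray(self.position_mm, float)
        o = np.asarray(self.orientation, float)
        n = np.linalg.norm(o)
        if n == 0:
            raise ValueError("orientation must be a nonzero vector")
        self.orientation = o / n


def dipole_field(position_m: np.ndarray, q_am: np.ndarray,
                 sensors_m: np.ndarray) -> np.ndarray:
    """Magnetic field (tesla) of a current dipole in a conducting sphere.

    ``position_m`` and ``sensors_m`` are relative to the sphere center, in
    meters; ``q_am`` is the moment vector in A·m. Vectorized over sensor
    points; singular if a sensor coincides with the dipole (never the case
    for sensors outside the scalp).
    """
    r0 = np.asarray(position_m, float)
    r = np.atleast_2d(np.asarray(sensors_m, float))
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    rn = np.linalg.norm(r, axis=1)
    r0_dot_r = r @ r0
    a_dot_r = np.einsum("ij,ij->i", a_vec, r)
    F = a * (rn * a + rn**2 - r0_dot_r)
    gradF = ((a**2 / rn + a_dot_r / a + 2 * a + 2 * rn)[:, None] * r
             - (a + 2 * rn + a_dot_r / a)[:, None] * r0)
    q_x_r0 = np.cross(q_am, r0)
    B = _MU0_4PI / F[:, None] ** 2 * (F[:, None] * q_x_r0
                                      - (r @ q_x_r0)[:, None] * gradF)
    return B


def forward_field(position_mm: np.ndarray, orientation: np.ndarray,
                  head: HeadModel, array: SensorArray) -> np.ndarray:
    """Gradiometer signal pattern of a unit (1 nAm) dipole.

    Returns one value per usable channel, in tesla. Raises if the dipole
    lies outside the conducting sphere.
    """
    pos = np.asarray(position_mm, float)
    if not head.contains(pos):
        raise ValueError("dipole lies outside the conducting sphere")
    center = np.asarray(head.center_mm)
    idx = array.usable_index
    inner = (array.positions_mm[idx] - center) * 1e-3
    outer = inner + array.normals[idx] * array.baseline_mm * 1e-3
    q = np.asarray(orientation, float) * 1e-9  # 1 nAm
    rel = (pos - center) * 1e-3
    b_in = np.einsum("ij,ij->i", dipole_field(rel, q, inner), array.normals[idx])
    b_out = np.einsum("ij,ij->i", dipole_field(rel, q, outer), array.normals[idx])
    return b_in - b_out


def leadfield_xyz(position_mm: np.ndarray, head: HeadModel,
                  array: SensorArray) -> np.ndarray:
    """(n_usable, 3) lead field for unit moments along x, y, z (1 nAm)."""
    cols = [forward_field(position_mm, e, head, array) for e in np.eye(3)]
    return np.column_stack(cols)
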