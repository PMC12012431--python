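"""Complex electric-field sources for the lead-tip voltage integral.

Two sources are provided:

* :class:`UniformBLinearEField` — an analytic field consistent with a
  spatially uniform RF magnetic field ``B = -b1 ŷ`` oscillating as
  ``e^{+iωt}``:  ``E(r) = (0, 0, -iω b1 x)``.  It satisfies Faraday's law
  ``∇×E = -iωB`` exactly and captures the qualitative structure of the body
  coil's field in a torso phantom: the z-component dominates and grows with
  lateral distance from isocenter, while the x-component vanishes on the
  midline, so R/L-running straight wires pick up essentially no tangential
  field.
* :class:`GriddedField` — any complex vector field sampled on a regular
  Cartesian grid (e.g. exported from a full-wave simulation), evaluated by
  trilinear interpolation.  The HDF5 container layout is
  ``/grid/{x,y,z}`` (axis vectors, m) and ``/field/{Ex,Ey,Ez}/{re,im}``
  (V/m).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import h5py
import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "UniformBLinearEField",
    "GriddedField",
    "evaluate_analytic_field",
    "tangential_component",
    "load_grid_field",
    "save_grid_field",
    "sample_grid_field",
    "bake_analytic_field",
]


@dataclass(frozen=True)
class UniformBLinearEField:
    """Analytic E-field of a uniform RF magnetic field along -y.

    ``E(x, y, z) = (0, 0, -i ω b1 x)`` with ω = 2πf.  b1 is the RF magnetic
    field amplitude in tesla; predictions are relative, so the default 1 µT
    is simply a convenient scale.
    """

    b1_amplitude: float = 1e-6
    frequency: float = 63.87e6

    def __post_init__(self) -> None:
        if self.b1_amplitude <= 0:
            raise ValueError("b1_amplitude must be positive")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")

    @property
    def angular_frequency(self) -> float:
        return 2.0 * math.pi * self.frequency

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        return evaluate_analytic_field(self, points)


def evaluate_analytic_field(
    field: UniformBLinearEField, points: np.ndarray
) -> np.ndarray:
    """Complex E (V/m) at one point (3,) or many points (M, 3)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    E = np.zeros((pts.shape[0], 3), dtype=complex)
    E[:, 2] = -1j * field.angular_frequency * field.b1_amplitude * pts[:, 0]
    return E[0] if np.asarray(points).ndim == 1 else E


def tangential_component(E: np.ndarray, segment_direction: np.ndarray) -> complex:
    """Complex projection ``E · t̂`` of the field on a unit wire direction."""
    d = np.asarray(segment_direction, dtype=float)
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("segment direction has zero length")
    if abs(n - 1.0) > 1e-9:
        raise ValueError(f"segment direction must be unit-norm, |d| = {n}")
    return complex(np.asarray(E, dtype=complex) @ d)


class GriddedField:
    """Complex vector field on a rectilinear grid, trilinearly interpolated."""

    def __init__(
        self, x: np.ndarray, y: np.ndarray, z: np.ndarray, E: np.ndarray
    ) -> None:
        """``x, y, z``: strictly increasing axis vectors (m), each of length
        >= 2; ``E``: complex array of shape (nx, ny, nz, 3) in V/m."""
        axes = []
        for name, ax in zip("xyz", (x, y, z)):
            ax = np.asarray(ax, dtype=float)
            if ax.ndim != 1 or ax.size < 2:
                raise ValueError(f"axis {name} must be 1-D with at least 2 points")
            if np.any(np.diff(ax) <= 0):
                raise ValueError(f"axis {name} must be strictly increasing")
            axes.append(ax)
        E = np.asarray(E, dtype=complex)
        expected = (axes[0].size, axes[1].size, axes[2].size, 3)
        if E.shape != expected:
            raise ValueError(f"field shape {E.shape} does not match axes {expected}")
        self.x, self.y, self.z = axes
        self.E = E
        # trilinear interpolation, applied to re and im alike via complex dtype
        self._interp = RegularGridInterpolator(
            (self.x, self.y, self.z), E, method="linear", bounds_error=True
        )

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        return sample_grid_field(self, points)


def sample_grid_field(field: GriddedField, points: np.ndarray) -> np.ndarray:
    """Trilinearly interpolated complex E at one (3,) or many (M, 3) points.

    Raises ``ValueError`` naming the offending coordinate for points outside
    the grid bounding box.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    for i, (name, ax) in enumerate(zip("xyz", (field.x, field.y, field.z))):
        below = pts[:, i] < ax[0]
        above = pts[:, i] > ax[-1]
        if below.any() or above.any():
            bad = pts[below | above][0]
            raise ValueError(
                f"point {tuple(bad)} outside grid: {name}-coordinate "
                f"{bad[i]} not in [{ax[0]}, {ax[-1]}]"
            )
    out = field._interp(pts)
    return out[0] if np.asarray(points).ndim == 1 else out


def save_grid_field(field: GriddedField, path) -> None:
    """Write a gridded field to HDF5 (groups /grid and /field, units m, V/m)."""
    with h5py.File(path, "w") as f:
        g = f.create_group("grid")
        for name, ax in zip("xyz", (field.x, field.y, field.z)):
            g.create_dataset(name, data=ax)
        fld = f.create_group("field")
        for i, comp in enumerate(("Ex", "Ey", "Ez")):
            grp = fld.create_group(comp)
            grp.create_dataset("re", data=field.E[..., i].real)
            grp.create_dataset("im", data=field.E[..., i].imag)


def load_grid_field(path) -> GriddedField:
    """Read a gridded field from the HDF5 layout written by `save_grid_field`."""
    with h5py.File(path, "r") as f:
        x = f["grid/x"][()]
        y = f["grid/y"][()]
        z = f["grid/z"][()]
        comps = []
        for comp in ("Ex", "Ey", "Ez"):
            comps.append(f[f"field/{comp}/re"][()] + 1j * f[f"field/{comp}/im"][()])
    E = np.stack(comps, axis=-1)
    return GriddedField(x, y, z, E)


def bake_analytic_field(
    analytic: UniformBLinearEField,
    n: int = 21,
    half_extent: float = 0.3,
) -> GriddedField:
    """Sample the analytic field onto a cubic n³ grid spanning ±half_extent m."""
    if n < 2:
        raise ValueError("need at least 2 grid points per axis")
    ax = np.linspace(-half_extent, half_extent, n)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    E = evaluate_analytic_field(analytic, pts).reshape(n, n, n, 3)
    return GriddedField(ax, ax, ax, E)
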