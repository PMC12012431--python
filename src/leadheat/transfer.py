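"""Transfer functions and the lead-tip voltage line integral.

The lead-tip voltage is the transfer-function-weighted complex line
integral of the tangential incident electric field along the wire,

    V = ∫_0^d h(l) E(l) · dl,

with arc length l measured from the exposed lead tip.  Three transfer
functions are supported:

* ``unity`` — h = 1, the long-wavelength approximation;
* ``sem``   — simple exponential model, h(l) = e^{-ikl}, a single decaying
  wave with the complex King wavenumber k (Im k <= 0);
* ``tlm``   — adapted transmission-line model, which adds a wave reflected
  from the capped IPG end (at l = d) with real reflection coefficient Γ:

      h(l) = e^{-ikl} (1 - Γ e^{-2ik(d-l)}) / (1 - Γ e^{-2ikd}),

  normalized to h(0) = 1 and reducing to the SEM at Γ = 0.

The predicted temperature rise is ΔT = scale · |V|², with the scale fitted
to data (see :mod:`leadheat.fitting`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import WirePath

__all__ = [
    "TransferModel",
    "HeatingPrediction",
    "transfer_value",
    "lead_tip_voltage",
    "temperature_rise",
    "edge_contributions",
    "voltage_from_contributions",
]

_KINDS = ("unity", "sem", "tlm")


@dataclass(frozen=True)
class TransferModel:
    """A transfer function h(l) of kind 'unity', 'sem' or 'tlm'.

    ``k`` is the complex King wavenumber (rad/m, Im k <= 0), ``total_length_d``
    the wire length (m), and ``reflection_gamma`` the real IPG-end reflection
    coefficient in [0, 1) (TLM only; ignored otherwise).
    """

    kind: str
    k: complex = 0.0
    total_length_d: float = 0.0
    reflection_gamma: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.kind != "unity":
            if self.total_length_d <= 0:
                raise ValueError("total_length_d must be positive for sem/tlm")
            if complex(self.k).imag > 0:
                raise ValueError(f"Im(k) must be <= 0 (loss convention), got {self.k}")
        if self.kind == "tlm" and not 0.0 <= self.reflection_gamma < 1.0:
            raise ValueError(
                f"reflection_gamma must be in [0, 1), got {self.reflection_gamma}"
            )

    def with_gamma(self, gamma: float) -> "TransferModel":
        return TransferModel(self.kind, self.k, self.total_length_d, gamma)

    def with_length(self, d: float) -> "TransferModel":
        return TransferModel(self.kind, self.k, d, self.reflection_gamma)


@dataclass(frozen=True)
class HeatingPrediction:
    """Predicted lead-tip voltage and (scaled) temperature rise for one wire."""

    name: str
    voltage: complex
    scale: float = 1.0

    @property
    def vsq(self) -> float:
        return abs(self.voltage) ** 2

    @property
    def delta_t(self) -> float:
        return self.scale * self.vsq


def transfer_value(model: TransferModel, l) -> complex | np.ndarray:
    """Evaluate h(l) at scalar or array arc length l in [0, d].

    For the unity model any finite l is accepted (d may be unset).
    """
    arr = np.asarray(l, dtype=float)
    if model.kind == "unity":
        out = np.ones(arr.shape, dtype=complex)
        return complex(out) if arr.ndim == 0 else out
    d = model.total_length_d
    if np.any(arr < -1e-12) or np.any(arr > d * (1 + 1e-9) + 1e-12):
        raise ValueError(f"arc length outside [0, {d}]")
    k = complex(model.k)
    h = np.exp(-1j * k * arr)
    if model.kind == "tlm":
        g = model.reflection_gamma
        h = h * (1.0 - g * np.exp(-2j * k * (d - arr))) / (1.0 - g * np.exp(-2j * k * d))
    return complex(h) if arr.ndim == 0 else h


def edge_contributions(path: WirePath, field) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge arc-length midpoints and field weights ``(E·t̂)Δl``.

    Separates the (model-independent) field part of the discrete line
    integral from the transfer function, so the voltage can be re-evaluated
    cheaply for many models (e.g. during a Γ search):
    ``V = Σ h(l_mid) * weight``.
    """
    tangents = path.edge_tangents
    E = field.evaluate(path.edge_midpoints)
    weights = np.einsum("ij,ij->i", E, tangents) * path.edge_lengths
    return path.edge_arc_midpoints, weights


def voltage_from_contributions(
    model: TransferModel, arc_midpoints: np.ndarray, weights: np.ndarray
) -> complex:
    """Discrete line-integral voltage from precomputed edge contributions."""
    h = transfer_value(model, arc_midpoints)
    return complex(np.sum(h * weights))


def lead_tip_voltage(path: WirePath, field, model: TransferModel) -> complex:
    """Discrete lead-tip voltage V = Σ_edges h(l_mid) (E(mid)·t̂) Δl.

    Edges are ordered tip → IPG end; h is evaluated at each edge's
    arc-length midpoint (midpoint rule, O(step²) accurate).  ``field`` is
    any object with an ``evaluate(points)`` method returning complex (M, 3)
    E-vectors (`UniformBLinearEField` or `GriddedField`).
    """
    if model.kind != "unity":
        d_path = path.total_length
        if abs(model.total_length_d - d_path) > 1e-6 + 1e-4 * d_path:
            raise ValueError(
                f"model total_length_d = {model.total_length_d} does not match "
                f"path arc length {d_path}"
            )
    l_mid, w = edge_contributions(path, field)
    return voltage_from_contributions(model, l_mid, w)


def temperature_rise(V: complex, scale: float) -> float:
    """Scaled temperature rise ΔT = scale·|V|² (°C)."""
    if scale < 0:
        raise ValueError(f"scale must be >= 0, got {scale}")
    return scale * abs(V) ** 2
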