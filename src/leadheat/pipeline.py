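"""High-level prediction workflow: wire specs + field + model → heating table.

Glues the geometry, field and transfer modules together for the common
"predict relative heating for a set of wires" task used by the CLI, the
examples and the model-comparison statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import LARMOR_FREQUENCY_1P5T
from .geometry import WireSpec, build_wire_path
from .transfer import (
    TransferModel,
    edge_contributions,
    voltage_from_contributions,
)
from .wavenumbers import (
    InsulatedWireCrossSection,
    MediumProperties,
    insulator_wavenumber,
    king_wavenumber,
    lossy_medium_wavenumber,
)

__all__ = ["default_king_wavenumber", "WireSetDesign", "predict_heating"]


def default_king_wavenumber(
    conductivity: float = 0.47,
    relative_permittivity: float = 80.0,
    insulator_permittivity: float = 2.3,
    inner_radius_a: float = 0.390e-3,
    outer_radius_b: float = 0.625e-3,
    frequency: float = LARMOR_FREQUENCY_1P5T,
) -> complex:
    """King wavenumber for the reference bench setup.

    Defaults: ASTM gel (σ = 0.47 S/m, ε_r = 80), silicone-like insulation
    (ε_i = 2.3) with a = 0.390 mm, b = 0.625 mm, at the 1.5 T Larmor
    frequency — giving k ≈ 6.7454 − 0.6840i rad/m.
    """
    medium = MediumProperties(conductivity, relative_permittivity, frequency)
    re_kt, im_kt = lossy_medium_wavenumber(medium)
    k_i = insulator_wavenumber(insulator_permittivity, frequency)
    xs = InsulatedWireCrossSection(inner_radius_a, outer_radius_b, insulator_permittivity)
    return king_wavenumber(complex(re_kt, -im_kt), k_i, xs)


@dataclass
class WireSetDesign:
    """Precomputed per-wire line-integral pieces for a fixed field.

    Splitting the field part (edge weights) from the transfer function makes
    re-evaluating all wires at many Γ values cheap, which the TLM fit needs.
    """

    names: list[str]
    lengths: list[float]
    arc_midpoints: list[np.ndarray]
    weights: list[np.ndarray]

    @classmethod
    def from_specs(
        cls, specs: Sequence[WireSpec], field, max_step: float = 1e-3
    ) -> "WireSetDesign":
        names, lengths, mids, wts = [], [], [], []
        for spec in specs:
            path = build_wire_path(spec, max_step=max_step)
            l_mid, w = edge_contributions(path, field)
            names.append(spec.name)
            lengths.append(path.total_length)
            mids.append(l_mid)
            wts.append(w)
        return cls(names, lengths, mids, wts)

    def voltages(self, kind: str, k: complex = 0.0, gamma: float = 0.0) -> np.ndarray:
        """Complex lead-tip voltage per wire for the given transfer model."""
        out = np.empty(len(self.names), dtype=complex)
        for i, (d, l_mid, w) in enumerate(
            zip(self.lengths, self.arc_midpoints, self.weights)
        ):
            model = TransferModel(kind, k, d, gamma)
            out[i] = voltage_from_contributions(model, l_mid, w)
        return out

    def vsq(self, kind: str, k: complex = 0.0, gamma: float = 0.0) -> np.ndarray:
        return np.abs(self.voltages(kind, k, gamma)) ** 2


def predict_heating(
    specs: Sequence[WireSpec],
    field,
    kind: str = "sem",
    k: complex | None = None,
    gamma: float = 0.0,
    scale: float = 1.0,
    max_step: float = 1e-3,
) -> pd.DataFrame:
    """Predict lead-tip voltages and scaled ΔT for a set of wires.

    Returns a DataFrame with columns ``name, length_m, re_v, im_v, vsq,
    delta_t`` (ΔT = scale·|V|²; with the default scale = 1 the ΔT column is
    simply |V|², a relative-heating surrogate).
    """
    if k is None and kind != "unity":
        k = default_king_wavenumber()
    design = WireSetDesign.from_specs(specs, field, max_step=max_step)
    v = design.voltages(kind, k if k is not None else 0.0, gamma)
    vsq = np.abs(v) ** 2
    return pd.DataFrame(
        {
            "name": design.names,
            "length_m": design.lengths,
            "re_v": v.real,
            "im_v": v.imag,
            "vsq": vsq,
            "delta_t": scale * vsq,
        }
    )
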