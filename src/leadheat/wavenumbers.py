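"""Complex propagation constants for insulated wires in lossy tissue.

Three wavenumbers govern the transfer-function models:

* the wavenumber of the surrounding lossy medium (tissue or phantom gel),
  whose real and imaginary magnitudes follow from its conductivity and
  permittivity;
* the real wavenumber of the lossless insulator sleeve, ``ω·sqrt(ε_i·μ)``;
* the King wavenumber of the composite insulated-wire waveguide, which
  mixes the two through a Hankel-function ratio evaluated at the outer
  insulator radius.

Sign convention: time dependence is ``e^{+iωt}`` and travelling waves go as
``e^{-ikl}``, so a lossy wavenumber carries a non-positive imaginary part
(``|e^{-ikl}|`` decays with distance).  Outgoing cylindrical waves under this
convention are Hankel functions of the second kind.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import hankel2

from .constants import VACUUM_PERMEABILITY, VACUUM_PERMITTIVITY

__all__ = [
    "MediumProperties",
    "InsulatedWireCrossSection",
    "lossy_medium_wavenumber",
    "insulator_wavenumber",
    "king_wavenumber",
    "king_wavelength",
]


@dataclass(frozen=True)
class MediumProperties:
    """Electromagnetic bulk properties of a lossy dielectric medium.

    Parameters
    ----------
    conductivity : float
        σ in S/m, >= 0.  The ASTM phantom gel uses 0.47 S/m.
    relative_permittivity : float
        ε_r (dimensionless), >= 1.  Gel value: 80.
    frequency : float
        RF frequency in Hz, > 0.
    relative_permeability : float
        μ_r, defaults to 1 (biological tissue is non-magnetic).
    """

    conductivity: float
    relative_permittivity: float
    frequency: float
    relative_permeability: float = 1.0

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError(f"frequency must be positive, got {self.frequency}")
        if self.conductivity < 0:
            raise ValueError(f"conductivity must be >= 0, got {self.conductivity}")
        if self.relative_permittivity < 1:
            raise ValueError(
                f"relative_permittivity must be >= 1, got {self.relative_permittivity}"
            )

    @property
    def angular_frequency(self) -> float:
        return 2.0 * math.pi * self.frequency


@dataclass(frozen=True)
class InsulatedWireCrossSection:
    """Insulated-wire cross section: conductor radius a, insulator radius b.

    ``inner_radius_a`` and ``outer_radius_b`` are in metres with
    ``0 < a < b``; ``insulator_relative_permittivity`` is the relative
    permittivity of the (lossless) insulation sleeve.
    """

    inner_radius_a: float
    outer_radius_b: float
    insulator_relative_permittivity: float

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius_a < self.outer_radius_b:
            raise ValueError(
                "require 0 < a < b, got "
                f"a={self.inner_radius_a}, b={self.outer_radius_b}"
            )
        if self.insulator_relative_permittivity < 1:
            raise ValueError("insulator relative permittivity must be >= 1")


def lossy_medium_wavenumber(medium: MediumProperties) -> tuple[float, float]:
    """Real and imaginary magnitudes of the lossy-medium wavenumber.

    Returns the pair ``(Re k_t, Im k_t)`` of non-negative magnitudes

    .. math::

        \\omega \\sqrt{\\varepsilon\\mu/2}\\,
        \\Big[\\sqrt{1 + (\\sigma/\\varepsilon\\omega)^2} \\pm 1\\Big]^{1/2}

    (``+`` for the real part, ``-`` for the imaginary part).  The caller
    forms the complex number with the loss sign convention, i.e.
    ``k_t = Re - i*Im`` so that ``e^{-i k_t l}`` decays.

    For σ = 0 this reduces to ``(ω·sqrt(εμ), 0)``.
    """
    w = medium.angular_frequency
    eps = medium.relative_permittivity * VACUUM_PERMITTIVITY
    mu = medium.relative_permeability * VACUUM_PERMEABILITY
    loss_tangent = medium.conductivity / (eps * w)
    root = math.sqrt(1.0 + loss_tangent**2)
    scale = w * math.sqrt(eps * mu / 2.0)
    return scale * math.sqrt(root + 1.0), scale * math.sqrt(root - 1.0)


def insulator_wavenumber(eps_r_i: float, frequency: float) -> float:
    """Wavenumber ``k_i = ω·sqrt(ε_i μ0)`` of the lossless insulator, rad/m."""
    if eps_r_i < 1:
        raise ValueError(f"eps_r_i must be >= 1, got {eps_r_i}")
    if frequency <= 0:
        raise ValueError(f"frequency must be positive, got {frequency}")
    w = 2.0 * math.pi * frequency
    return w * math.sqrt(eps_r_i * VACUUM_PERMITTIVITY * VACUUM_PERMEABILITY)


def king_wavenumber(
    k_t: complex,
    k_i: float,
    cross_section: InsulatedWireCrossSection,
) -> complex:
    """King's complex wavenumber of a thin insulated wire in a lossy medium.

    .. math::

        k = k_i \\Big(1 + \\frac{F(k_t b)}{\\ln(b/a)}\\Big)^{1/2},
        \\qquad F(z) = \\frac{H_0(z)}{z\\,H_1(z)}

    with ``H_n`` the outgoing cylindrical (Hankel) functions for the
    ``e^{+iωt}`` time convention, i.e. of the second kind, matching the
    loss convention ``Im(k_t) <= 0`` of `lossy_medium_wavenumber`.  The
    square-root branch is chosen so the result has ``Im(k) <= 0``.

    Parameters
    ----------
    k_t : complex
        Lossy-medium wavenumber with ``Im(k_t) <= 0`` (form it as
        ``Re - 1j*Im`` from the magnitudes of `lossy_medium_wavenumber`).
    k_i : float
        Insulator wavenumber, rad/m.
    cross_section : InsulatedWireCrossSection
        Radii a, b of the insulation annulus.
    """
    if k_t == 0:
        raise ValueError("k_t must be nonzero")
    a = cross_section.inner_radius_a
    b = cross_section.outer_radius_b
    log_ratio = math.log(b / a)  # a < b guaranteed, so > 0
    z = complex(k_t) * b
    F = hankel2(0, z) / (z * hankel2(1, z))
    k = k_i * np.sqrt(1.0 + F / log_ratio)
    if k.imag > 0:
        k = -k
    return complex(k)


def king_wavelength(k: complex) -> float:
    """Guided wavelength ``2π / Re(k)`` in metres.

    The real part of the King wavenumber sets the phase-oscillation period
    along the wire; the imaginary part only attenuates.
    """
    if k.real <= 0:
        raise ValueError(f"Re(k) must be positive, got {k.real}")
    return 2.0 * math.pi / k.real
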