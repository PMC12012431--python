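"""Physical constants (SI) used throughout the package."""

import math

VACUUM_PERMITTIVITY = 8.8541878128e-12
"""ε0, F/m."""

VACUUM_PERMEABILITY = 4e-7 * math.pi
"""μ0, H/m."""

SPEED_OF_LIGHT = 2.99792458e8
"""c, m/s."""

LARMOR_FREQUENCY_1P5T = 63.87e6
"""Proton Larmor frequency at 1.5 T, Hz (default RF frequency)."""
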