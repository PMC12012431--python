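"""Closed-form loop and straight-section voltages in the long-wavelength limit.

Under h = 1 and a spatially uniform RF magnetic field of amplitude b1,
Faraday's law turns the line integral over a closed loop of area A into a
flux term of magnitude ``V_loop = A ω b1``.  A straight section of length
d_section at representative lateral offset x from isocenter instead picks
up ``V_straight ≈ x d_section ω b1`` from the linearly growing E_z.  A
fixed length L of wire wound into N coincident turns has per-turn area
smaller by N², so the net loop voltage scales as 1/N — the analytic basis
for the benefit of multi-turn loops.
"""

from __future__ import annotations

import math

__all__ = [
    "loop_voltage",
    "multi_turn_voltage",
    "straight_voltage",
    "loop_vs_straight_ratio",
]


def _omega(frequency: float) -> float:
    if frequency <= 0:
        raise ValueError(f"frequency must be positive, got {frequency}")
    return 2.0 * math.pi * frequency


def loop_voltage(area: float, b1: float, frequency: float) -> float:
    """|V| = A·ω·b1 induced around a closed loop of area A (m²)."""
    if area < 0 or b1 < 0:
        raise ValueError("area and b1 must be non-negative")
    return area * _omega(frequency) * b1


def multi_turn_voltage(wire_length: float, turns: int, b1: float, frequency: float) -> float:
    """|V| of a wire of length L closed into N coincident circular turns.

    Each turn has radius L/(2πN) and area π(L/2πN)², and the N turns add,
    giving ``L² ω b1 / (4πN)`` — exactly 1/N of the single-turn value.
    """
    if turns < 1 or int(turns) != turns:
        raise ValueError(f"turns must be an integer >= 1, got {turns}")
    if wire_length < 0 or b1 < 0:
        raise ValueError("wire_length and b1 must be non-negative")
    radius = wire_length / (2.0 * math.pi * turns)
    return turns * math.pi * radius**2 * _omega(frequency) * b1


def straight_voltage(x_offset: float, d_section: float, b1: float, frequency: float) -> float:
    """|V| ≈ |x|·d_section·ω·b1 along a straight section at lateral offset x.

    Exact for the linear-in-x analytic field; an order-of-magnitude estimate
    otherwise.
    """
    if d_section <= 0:
        raise ValueError(f"d_section must be positive, got {d_section}")
    if b1 < 0:
        raise ValueError("b1 must be non-negative")
    return abs(x_offset) * d_section * _omega(frequency) * b1


def loop_vs_straight_ratio(
    loop_area: float, x_offset: float, d_section: float
) -> float:
    """Ratio A/(x·d_section) of loop to straight voltage contributions.

    Values below 1 flag the usual regime in which replacing straight run
    with a loop reduces the lead-tip voltage.  Raises when the straight
    term vanishes (e.g. a midline R/L wire, where x = 0 and loops dominate
    unconditionally).
    """
    denom = abs(x_offset) * d_section
    if denom == 0:
        raise ZeroDivisionError(
            "straight-section voltage is zero (x·d_section = 0): loop "
            "contribution dominates unconditionally"
        )
    if loop_area < 0:
        raise ValueError("loop_area must be non-negative")
    return loop_area / denom
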