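"""Discretized 3D wire trajectories: straight runs plus coplanar circular loops.

A wire is declared as an ordered list of segments walked from the exposed
lead tip (arc length ``l = 0``) to the capped IPG end (``l = d``).  Straight
segments advance along a direction vector; loop segments insert ``N``
coincident circular turns tangent to the current direction of travel,
returning to the entry point so they add electrical length without net
displacement.  All fixtures lie in the coronal mid-plane ``y = 0`` of the
scanner, with x = patient right→left, y = anterior→posterior, z =
inferior→superior and the origin at isocenter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

__all__ = [
    "StraightSegment",
    "LoopSegment",
    "SegmentSpec",
    "WireSpec",
    "WirePath",
    "build_wire_path",
    "arc_length",
    "directed_extent",
    "table1_fixtures",
]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class StraightSegment:
    """A straight run of given length (m) along a unit direction."""

    run_length: float
    direction: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.run_length <= 0:
            raise ValueError(f"run_length must be positive, got {self.run_length}")
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("direction must be nonzero")
        object.__setattr__(self, "direction", tuple(d / n))


@dataclass(frozen=True)
class LoopSegment:
    """``turns`` coincident circular turns of given diameter (m).

    The circle is tangent to the incoming direction of travel at the entry
    point, lies in the y = 0 plane, and is displaced to the side given by
    ``side_offset_sign`` (along ``ŷ × t̂`` for travel direction ``t̂``).
    ``winding_sense`` = -1 traverses the circle the opposite way, flipping
    the sign of the enclosed-flux contribution.
    """

    turns: int
    diameter: float
    winding_sense: int = 1
    side_offset_sign: int = 1

    def __post_init__(self) -> None:
        if self.turns < 1 or int(self.turns) != self.turns:
            raise ValueError(f"turns must be an integer >= 1, got {self.turns}")
        if self.diameter <= 0:
            raise ValueError(f"diameter must be positive, got {self.diameter}")
        if self.winding_sense not in (-1, 1) or self.side_offset_sign not in (-1, 1):
            raise ValueError("winding_sense and side_offset_sign must be +1 or -1")


SegmentSpec = Union[StraightSegment, LoopSegment]


@dataclass(frozen=True)
class WireSpec:
    """Declarative wire layout, ordered from lead tip to capped IPG end.

    ``expected_length_cm`` / ``expected_extent_cm`` are optional published
    reference values carried as metadata (not used in construction);
    ``extent_axis`` names the axis of the quoted extent.
    """

    name: str
    tip_position: tuple[float, float, float]
    segments: tuple[SegmentSpec, ...]
    expected_length_cm: float | None = None
    expected_extent_cm: float | None = None
    extent_axis: str = "z"

    def __post_init__(self) -> None:
        if len(self.segments) == 0:
            raise ValueError(f"wire {self.name!r}: segment list is empty")
        object.__setattr__(self, "segments", tuple(self.segments))
        object.__setattr__(self, "tip_position", tuple(map(float, self.tip_position)))


@dataclass(frozen=True)
class WirePath:
    """Discretized polyline with arc length measured from the lead tip."""

    vertices: np.ndarray  # (M, 3) m
    arc_lengths: np.ndarray  # (M,) cumulative from the tip, arc_lengths[0] = 0
    name: str = ""

    @property
    def total_length(self) -> float:
        return float(self.arc_lengths[-1])

    @property
    def edge_vectors(self) -> np.ndarray:
        return np.diff(self.vertices, axis=0)

    @property
    def edge_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.edge_vectors, axis=1)

    @property
    def edge_tangents(self) -> np.ndarray:
        v = self.edge_vectors
        return v / np.linalg.norm(v, axis=1)[:, None]

    @property
    def edge_midpoints(self) -> np.ndarray:
        return 0.5 * (self.vertices[:-1] + self.vertices[1:])

    @property
    def edge_arc_midpoints(self) -> np.ndarray:
        return 0.5 * (self.arc_lengths[:-1] + self.arc_lengths[1:])


def _loop_vertices(
    entry: np.ndarray,
    travel_dir: np.ndarray,
    seg: LoopSegment,
    max_step: float,
) -> np.ndarray:
    """Vertices of a tangent circular loop group, excluding the entry point.

    The closing vertex coincides with the entry point so the group adds
    zero net displacement.  Each turn gets at least 160 edges (inscribed-
    polygon arc-length error (pi/n)^2/6 < 1e-4) and enough to keep edge
    chords below ``max_step``.
    """
    y_hat = np.array([0.0, 1.0, 0.0])
    side_normal = np.cross(y_hat, travel_dir)
    n = np.linalg.norm(side_normal)
    if n < 1e-12:
        raise ValueError("loop travel direction may not be parallel to y (A/P) axis")
    side_normal /= n
    radius = seg.diameter / 2.0
    center = entry + seg.side_offset_sign * radius * side_normal
    radial0 = (entry - center) / radius  # unit, points from center to entry

    per_turn = max(160, math.ceil(math.pi * seg.diameter / max_step))
    theta = np.linspace(0.0, 2.0 * math.pi * seg.turns, per_turn * seg.turns + 1)[1:]
    pts = (
        center[None, :]
        + radius * np.cos(theta)[:, None] * radial0[None, :]
        + seg.winding_sense * radius * np.sin(theta)[:, None] * travel_dir[None, :]
    )
    pts[-1] = entry  # close exactly despite float round-off
    return pts


def build_wire_path(spec: WireSpec, max_step: float = 1e-3) -> WirePath:
    """Discretize a wire spec into a polyline with tip-referenced arc length.

    Parameters
    ----------
    spec : WireSpec
        Segments ordered tip → IPG end.
    max_step : float
        Maximum edge length in metres (default 1 mm); loops additionally get
        at least 64 edges per turn.
    """
    if max_step <= 0:
        raise ValueError(f"max_step must be positive, got {max_step}")
    pos = np.asarray(spec.tip_position, dtype=float)
    verts = [pos]
    travel_dir: np.ndarray | None = None
    for seg in spec.segments:
        if isinstance(seg, StraightSegment):
            travel_dir = np.asarray(seg.direction, dtype=float)
            n_edges = max(1, math.ceil(seg.run_length / max_step))
            steps = np.linspace(0.0, seg.run_length, n_edges + 1)[1:]
            verts.append(pos[None, :] + steps[:, None] * travel_dir[None, :])
            pos = pos + seg.run_length * travel_dir
        elif isinstance(seg, LoopSegment):
            if travel_dir is None:
                # loop-only wire: conventional travel direction along +z
                travel_dir = np.array([0.0, 0.0, 1.0])
            pts = _loop_vertices(pos, travel_dir, seg, max_step)
            verts.append(pts)
            pos = pts[-1]
        else:  # pragma: no cover - guarded by SegmentSpec typing
            raise TypeError(f"unknown segment type {type(seg).__name__}")
    vertices = np.vstack([np.atleast_2d(v) for v in verts])
    seg_len = np.linalg.norm(np.diff(vertices, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    return WirePath(vertices=vertices, arc_lengths=arc, name=spec.name)


def arc_length(path: WirePath) -> float:
    """Total polyline arc length in metres."""
    return float(path.edge_lengths.sum())


def directed_extent(path: WirePath, axis: str | int = "z") -> float:
    """Max-minus-min vertex coordinate along an axis ('x'|'y'|'z' or 0..2)."""
    idx = _AXES[axis] if isinstance(axis, str) else int(axis)
    coords = path.vertices[:, idx]
    return float(coords.max() - coords.min())


# --------------------------------------------------------------------------
# Published 20-wire fixture set
# --------------------------------------------------------------------------

_VERTICAL_OFFSET_X = -0.10
"""Lateral placement (m) of vertical fixtures: off-midline on the
patient-right side of the phantom where |Ez| is large."""

# Fraction of the straight run, measured from the tip, at which a loop group
# is inserted: 'top' loops sit in the quarter nearest the lead tip, 'bottom'
# loops in the quarter nearest the IPG end.
_LOOP_POSITION_FRACTION = {"top": 0.25, "middle": 0.5, "bottom": 0.75}

# name -> (run height cm, loop position, turns, loop diameter cm,
#          winding_sense, side_offset_sign, published length, published extent)
_VERTICAL_TABLE = [
    ("Straight", 25.0, None, 0, 0.0, 1, 1, 25.0, 25.0),
    ("Bottom single", 25.0, "bottom", 1, 5.0, 1, 1, 40.7, 25.0),
    ("Middle single", 25.0, "middle", 1, 5.0, 1, 1, 40.7, 25.0),
    ("Top single", 25.0, "top", 1, 5.0, 1, 1, 40.7, 25.0),
    ("Bottom double", 25.0, "bottom", 2, 5.0, 1, 1, 56.4, 25.0),
    ("Middle double", 25.0, "middle", 2, 5.0, 1, 1, 56.4, 25.0),
    ("Top double", 25.0, "top", 2, 5.0, 1, 1, 56.4, 25.0),
    ("Straight long", 40.7, None, 0, 0.0, 1, 1, 40.7, 40.7),
    ("Middle single large loop long", 25.0, "middle", 1, 7.0, 1, 1, 47.0, 25.0),
    ("Middle single back", 25.0, "middle", 1, 5.0, 1, -1, 40.7, 25.0),
    ("Middle single flipped", 25.0, "middle", 1, 5.0, -1, 1, 40.7, 25.0),
    ("Straight xlong", 47.0, None, 0, 0.0, 1, 1, 47.0, 47.0),
    ("Middle single large loop", 18.7, "middle", 1, 7.0, 1, 1, 40.7, 18.7),
    ("Middle single short", 9.3, "middle", 1, 5.0, 1, 1, 25.0, 9.3),
    ("Middle double long", 15.5, "middle", 2, 5.0, 1, 1, 47.0, 15.5),
]

# name -> (total length cm, turns, loop diameter cm, published extent along x)
_HORIZONTAL_TABLE = [
    ("H straight", 40.0, 0, 0.0, 40.0),
    ("H single short", 40.0, 1, 5.5, 25.5),
    ("H single long", 54.8, 1, 5.5, 8.2),
    ("H double short", 40.0, 2, 5.5, 40.0),
    ("H double long", 72.1, 2, 5.5, 40.0),
]


def _vertical_spec(
    name: str,
    height_cm: float,
    loop_pos: str | None,
    turns: int,
    diameter_cm: float,
    winding: int,
    side: int,
    length_cm: float,
    extent_cm: float,
) -> WireSpec:
    h = height_cm / 100.0
    # S/I-centered: tip (exposed end) at the superior end, run goes inferior
    tip = (_VERTICAL_OFFSET_X, 0.0, h / 2.0)
    down = (0.0, 0.0, -1.0)
    segments: list[SegmentSpec] = []
    if loop_pos is None:
        segments.append(StraightSegment(h, down))
    else:
        frac = _LOOP_POSITION_FRACTION[loop_pos]
        segments.append(StraightSegment(frac * h, down))
        segments.append(LoopSegment(turns, diameter_cm / 100.0, winding, side))
        segments.append(StraightSegment((1.0 - frac) * h, down))
    return WireSpec(
        name=name,
        tip_position=tip,
        segments=tuple(segments),
        expected_length_cm=length_cm,
        expected_extent_cm=extent_cm,
        extent_axis="z",
    )


def _horizontal_spec(
    name: str, length_cm: float, turns: int, diameter_cm: float, extent_cm: float
) -> WireSpec:
    # Straight run along x (R/L), centered on isocenter, tip at patient right
    # (-x); any loop group sits at the run midpoint.  The published extents of
    # the looped variants depend on figure-level layout details and are kept
    # as metadata only.
    total = length_cm / 100.0
    run = total - turns * math.pi * diameter_cm / 100.0
    if run <= 0:
        raise ValueError(f"wire {name!r}: loops exceed total length")
    tip = (-run / 2.0, 0.0, 0.0)
    right_to_left = (1.0, 0.0, 0.0)
    segments: list[SegmentSpec] = []
    if turns == 0:
        segments.append(StraightSegment(run, right_to_left))
    else:
        segments.append(StraightSegment(run / 2.0, right_to_left))
        segments.append(LoopSegment(turns, diameter_cm / 100.0))
        segments.append(StraightSegment(run / 2.0, right_to_left))
    return WireSpec(
        name=name,
        tip_position=tip,
        segments=tuple(segments),
        expected_length_cm=length_cm,
        expected_extent_cm=extent_cm,
        extent_axis="x",
    )


def table1_fixtures() -> list[WireSpec]:
    """The 20 published test-wire configurations.

    Fifteen vertical (S/I-oriented) wires centered on isocenter at
    x = -10 cm, and five horizontal (R/L-oriented) midline wires.  Loop
    groups are tangent circles that add arc length but no net displacement,
    so every vertical fixture's S/I extent equals its straight-run height.
    """
    specs = [_vertical_spec(*row) for row in _VERTICAL_TABLE]
    specs += [_horizontal_spec(*row) for row in _HORIZONTAL_TABLE]
    return specs
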