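"""YAML wire-spec files and CSV measurement tables.

Wire-spec files use centimetres (the natural bench unit); everything is
converted to metres on load.  Schema::

    wires:
      - name: Bottom single
        tip_position_cm: [-10.0, 0.0, 12.5]
        segments:
          - kind: straight
            length_cm: 18.75
            direction: [0, 0, -1]
          - kind: loops
            turns: 1
            diameter_cm: 5.0
            winding_sense: 1       # optional, default 1
            side_offset_sign: 1    # optional, default 1

Measurement CSVs have columns ``name, delta_t`` and optionally ``error``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .fitting import MeasurementSet
from .geometry import LoopSegment, SegmentSpec, StraightSegment, WireSpec

__all__ = [
    "load_wire_specs",
    "dump_wire_specs",
    "load_measurements",
    "dump_measurements",
]


def _segment_from_dict(d: dict) -> SegmentSpec:
    kind = d.get("kind")
    if kind == "straight":
        return StraightSegment(
            run_length=float(d["length_cm"]) / 100.0,
            direction=tuple(float(c) for c in d["direction"]),
        )
    if kind == "loops":
        return LoopSegment(
            turns=int(d["turns"]),
            diameter=float(d["diameter_cm"]) / 100.0,
            winding_sense=int(d.get("winding_sense", 1)),
            side_offset_sign=int(d.get("side_offset_sign", 1)),
        )
    raise ValueError(f"unknown segment kind {kind!r}")


def _segment_to_dict(seg: SegmentSpec) -> dict:
    if isinstance(seg, StraightSegment):
        return {
            "kind": "straight",
            "length_cm": seg.run_length * 100.0,
            "direction": [float(c) for c in seg.direction],
        }
    return {
        "kind": "loops",
        "turns": seg.turns,
        "diameter_cm": seg.diameter * 100.0,
        "winding_sense": seg.winding_sense,
        "side_offset_sign": seg.side_offset_sign,
    }


def load_wire_specs(path) -> list[WireSpec]:
    """Read a list of wire specs from a YAML file (cm units)."""
    with open(path) as f:
        doc = yaml.safe_load(f)
    if not isinstance(doc, dict) or "wires" not in doc:
        raise ValueError(f"{path}: expected a top-level 'wires' list")
    specs = []
    for w in doc["wires"]:
        specs.append(
            WireSpec(
                name=str(w["name"]),
                tip_position=tuple(float(c) / 100.0 for c in w["tip_position_cm"]),
                segments=tuple(_segment_from_dict(s) for s in w["segments"]),
                expected_length_cm=w.get("expected_length_cm"),
                expected_extent_cm=w.get("expected_extent_cm"),
                extent_axis=w.get("extent_axis", "z"),
            )
        )
    return specs


def dump_wire_specs(specs, path) -> None:
    """Write wire specs to a YAML file (cm units)."""
    doc = {
        "wires": [
            {
                "name": s.name,
                "tip_position_cm": [c * 100.0 for c in s.tip_position],
                "segments": [_segment_to_dict(seg) for seg in s.segments],
                **(
                    {"expected_length_cm": s.expected_length_cm}
                    if s.expected_length_cm is not None
                    else {}
                ),
                **(
                    {"expected_extent_cm": s.expected_extent_cm,
                     "extent_axis": s.extent_axis}
                    if s.expected_extent_cm is not None
                    else {}
                ),
            }
            for s in specs
        ]
    }
    with open(path, "w") as f:
        yaml.safe_dump(doc, f, sort_keys=False)


def load_measurements(path) -> MeasurementSet:
    """Read a measurement CSV with columns name, delta_t [, error]."""
    df = pd.read_csv(path)
    if not {"name", "delta_t"} <= set(df.columns):
        raise ValueError(f"{path}: need columns 'name' and 'delta_t'")
    errors = df["error"].to_numpy(float) if "error" in df.columns else None
    return MeasurementSet(
        names=tuple(df["name"].astype(str)),
        delta_t=df["delta_t"].to_numpy(float),
        errors=errors,
    )


def dump_measurements(ms: MeasurementSet, path) -> None:
    """Write a measurement set to CSV."""
    df = pd.DataFrame({"name": ms.names, "delta_t": ms.delta_t})
    if ms.errors is not None:
        df["error"] = np.asarray(ms.errors)
    df.to_csv(path, index=False)
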