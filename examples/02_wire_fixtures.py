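"""Build the 20 bench wire configurations and tabulate their geometry.

Each wire is a straight run plus optional tangent circular loop groups in
the coronal plane; loops add arc ("electrical") length without changing the
straight-run extent.
"""

import leadheat as lh
from leadheat.geometry import LoopSegment

print(f"{'wire':32s} {'length cm':>9s} {'extent cm':>9s} {'loops':>5s}")
for spec in lh.table1_fixtures():
    path = lh.build_wire_path(spec, max_step=1e-3)
    loops = sum(s.turns for s in spec.segments if isinstance(s, LoopSegment))
    print(
        f"{spec.name:32s} {lh.arc_length(path) * 100:9.1f} "
        f"{lh.directed_extent(path, spec.extent_axis) * 100:9.1f} {loops:5d}"
    )

# Loop-bearing wires of equal 25 cm height differ only in where the extra
# 15.7 cm (one 5 cm turn) or 31.4 cm (two turns) of path length sits; that
# placement is what the transfer-function models act on.
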