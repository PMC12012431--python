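"""Long-wavelength closed forms: why loops usually help, and when they don't.

With h = 1 and a uniform RF magnetic field, a loop contributes A*omega*b1,
a straight section x*d*omega*b1, and N coincident turns of fixed wire
length scale as 1/N.  The closed forms are checked against the numeric line
integral they approximate.
"""

import math

import leadheat as lh

F0 = 63.87e6
B1 = 1e-6

A = math.pi * 0.025**2  # one 5 cm loop
v_loop = lh.loop_voltage(A, B1, F0)
v_straight = lh.straight_voltage(0.1, 0.157, B1, F0)  # same 15.7 cm, straight
print(f"V_loop (5 cm loop)              = {v_loop:.4f} V")
print(f"V_straight (15.7 cm at x=10 cm) = {v_straight:.4f} V")
print(f"ratio A/(x*d)                   = "
      f"{lh.loop_vs_straight_ratio(A, 0.1, 0.157):.3f}  (<1: loop helps)")

print("\n1/N multi-turn scaling, 40 cm of wire:")
for n in range(1, 5):
    print(f"  N={n}: {lh.multi_turn_voltage(0.4, n, B1, F0):.4f} V")

# cross-check against the discrete line integral in the analytic field
field = lh.UniformBLinearEField()
spec = lh.WireSpec("loop", (0.025, 0, 0), (lh.LoopSegment(1, 0.05),))
V = lh.lead_tip_voltage(
    lh.build_wire_path(spec), field, lh.TransferModel("unity")
)
print(f"\nnumeric loop integral: {abs(V):.4f} V (closed form {v_loop:.4f} V)")

# On the R/L midline x = 0, the straight term vanishes and the comparison
# inverts: there, any loop *adds* voltage.
try:
    lh.loop_vs_straight_ratio(A, 0.0, 0.25)
except ZeroDivisionError as e:
    print(f"\nx = 0: {e}")
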