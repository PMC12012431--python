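"""Predict relative lead-tip heating for all bench wires.

Evaluates the transfer-function-weighted line integral of the analytic
uniform-B/linear-E field along every wire, for the simple exponential model
(SEM), and prints |V|^2 - the relative-heating surrogate (dT = scale*|V|^2).
"""

import leadheat as lh

field = lh.UniformBLinearEField()  # 1 uT, 63.87 MHz
k = lh.default_king_wavenumber()

df = lh.predict_heating(lh.table1_fixtures(), field, kind="sem", k=k)
df["vsq_rel"] = df["vsq"] / df["vsq"].max()
print(df[["name", "length_m", "vsq", "vsq_rel"]].to_string(index=False))

v = df.set_index("name")["vsq"]
print()
print(f"straight 40.7 cm vs looped 40.7 cm wires: "
      f"{v['Straight long']:.1f} vs {v['Bottom single']:.1f} / "
      f"{v['Middle single']:.1f} / {v['Top single']:.1f}")
print("-> adding a loop to a vertical wire reduces predicted heating;")
print(f"horizontal wires: straight {v['H straight']:.2g}, one loop "
      f"{v['H single short']:.2f}, two loops {v['H double short']:.2f}")
print("-> on the R/L midline the straight run picks up no tangential field,")
print("   so there loops *increase* heating.")
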