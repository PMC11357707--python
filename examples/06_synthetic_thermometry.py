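"""Generate experiment-like synthetic thermometry and recover its structure.

Runs a quick coarse simulation of the warmed 80 W protocol, draws 60
replicate two-channel logs with probe-placement uncertainty, initial
cooling drift and sensor noise, then summarizes them and shows the negative
placement-distance vs final-temperature association the forward channel
must exhibit for an outward-decaying heating field.
"""

import numpy as np

import dmwasim as d

protocol = d.standard_protocols()["80W_3.5min_37C"]
params = d.DirectionalSourceParams(absorbed_fraction=0.09)
field, _ = d.simulate_protocol(params=params, protocol=protocol)

batch = d.generate_batch(field, d.PlacementModel(), d.NoiseModel(),
                         n=60, seed=1234, profile="warmed")
records = [
    d.ReplicateRecord(condition=(80.0, 3.5, 37.0), logs=channels)
    for channels in batch.logs
]
summary = d.summarize_replicates(records)
print("recovered per-condition summary (mean +/- sample SD):")
for ch in ("T1", "T2"):
    m = summary[f"{ch}_initial_C_mean"].iloc[0]
    s = summary[f"{ch}_initial_C_std"].iloc[0]
    mf = summary[f"{ch}_final_C_mean"].iloc[0]
    sf = summary[f"{ch}_final_C_std"].iloc[0]
    print(f"  {ch}: initial {m:5.1f} +/- {s:4.1f} C, final {mf:5.1f} +/- {sf:4.1f} C")

table = d.recover_placement_effect(batch, field)
t1 = table.query("channel == 'T1'")
corr = np.corrcoef(t1["distance_m"], t1["final_temperature_C"])[0, 1]
print(f"\nT1 placement-distance vs final-temperature correlation: {corr:+.2f}")
print("(negative: probes placed farther forward read cooler, the direction")
print(" expected when placement error biases measured T1 low)")

mean_mm = t1["distance_m"].mean() * 1e3
print(f"mean drawn T1 distance: {mean_mm:.1f} mm "
      "(placement model centered on the histology-derived 10.1 mm)")
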