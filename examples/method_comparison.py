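"""Slope method versus traditional ionization-ratio method, by simulation.

Simulates 36 monthly QA sessions for the 6/9/12/15 MeV beams with realistic
noise — 0.5% reading reproducibility and a 0.3 mm per-session depth setup
error — and compares the spread of the two constancy statistics.
"""

from eslope import NoiseModel, compare_methods

noise = NoiseModel(reading_sd=0.005, depth_sd=0.03)
result = compare_methods(months=36, noise=noise, seed=1)

print("energy   slope SD (%)   ratio SD (%)")
for energy, summaries in sorted(result.items()):
    print(f"{energy:4.0f} MeV   {summaries['slope'].sd:8.2f}    "
          f"{summaries['ratio'].sd:10.2f}")

print()
print("The slope statistic differences two readings on the straight descent,")
print("so a common chamber setup offset cancels; the ratio's deep reading")
print("sits on the steep limb, where the same offset becomes signal error.")
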