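"""Convert millimetre I50 tolerances into percent slope-change levels.

Uses the published exponential calibrations E = 32.311*exp(0.0247*M) and
I50 = 13.714*exp(0.0246*M): for each nominal energy, the baseline slope is
the energy calibration's inverse, and the tolerance is the relative slope
change whose predicted I50 moves by 1 mm (warning) or 2 mm (action).
"""

from eslope import CalibrationModel, slope_from_prediction, tolerance_entry

energy_model = CalibrationModel(32.311, 0.0247, "energy")
i50_model = CalibrationModel(13.714, 0.0246, "i50")

print("energy  baseline slope   % change/1 mm   % change/2 mm")
for nominal in (6.0, 9.0, 12.0, 15.0):
    m_ref = slope_from_prediction(energy_model, nominal)
    entry = tolerance_entry(nominal, i50_model, m_ref)
    print(f"{nominal:4.0f} MeV   {m_ref:8.2f} %/cm"
          f"   {entry.pct_per_1mm:8.1f}        {entry.pct_per_2mm:8.1f}")

print()
print("At 12-15 MeV a 1 mm I50 shift corresponds to a ~2% slope change and")
print("2 mm to ~4% — the usual warning and action levels for monthly QA.")
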