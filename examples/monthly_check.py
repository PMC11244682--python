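"""Evaluate one monthly energy-constancy measurement against its baseline.

The baseline comes from a synthetic 15 MeV commissioning scan; the monthly
measurement is three readings at the reference/70%/30% depths plus one at
the I50 depth for the traditional ratio method.
"""

from eslope import (
    Baseline,
    BeamSpec,
    commissioned_points,
    evaluate_record,
    generate_curve,
)
from eslope.simulate import baseline_from_curve

spec = BeamSpec.from_energy(15.0)
points = commissioned_points(spec)
slope_m, ratio = baseline_from_curve(generate_curve(spec), points, spec.r50)
baseline = Baseline(
    energy_label=15.0, points=points, i50_depth=spec.r50,
    slope_m=slope_m, ratio=ratio,
)

# a monthly session whose 70%/30% readings are stretched about the midpoint,
# i.e. a slightly steepened descent (energy decrease)
record = evaluate_record(
    date="2026-09-01",
    reading_ref=100.0, reading_70=70.45, reading_30=29.55,
    reading_i50depth=49.1,
    baseline=baseline,
)

print(f"monthly slope    = {record.slope_m:.3f} %/cm "
      f"(baseline {baseline.slope_m:.3f})")
print(f"slope change     = {record.slope_change:+.2f} % of baseline")
print(f"ratio change     = {record.ratio_change:+.2f} %")
print(f"status           = {record.status}")
print()
print("A |slope change| below 2% passes; 2-4% is a warning (about a 1 mm")
print("I50 shift); beyond 4% calls for action (about 2 mm).")
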