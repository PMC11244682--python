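# Methods

## The slope statistic

An electron percent-depth-ionization (PDI) curve in water rises through a
build-up region to its maximum at `d_max`, falls almost linearly through the
half-value depth `I50`, and levels off in a low bremsstrahlung tail. The
monthly constancy statistic is the secant slope between the commissioned
depths of the 70% and 30% ionization levels,

    M = (Ion70% − Ion30%) / (d70 − d30)   [%/cm],

with both readings normalized (×100) to a reference reading taken on the
flat portion of the curve, by default at the commissioned `d_max`. The two
depths are equidistant from `I50` on an ideal linear descent, so `M` is the
tangent slope at `I50`.

The method's central assumption is **local linearity of the descent**: the
PDI is straight, to measurement precision, between the 70% and 30% levels.
Two consequences follow and are used throughout:

1. Interpolation between scan samples is linear everywhere in this package;
   on the straight limb that is exact, elsewhere (build-up, blend, tail) the
   error is second order in the grid step.
2. A depth-positioning offset common to both measurement points slides both
   readings along the same line and cancels in the numerator of `M`.
   Conversely — and this is a mathematical fact with practical import — a
   **rigid translation of a perfectly straight limb is invisible to the
   fixed-depth slope statistic**. What the statistic detects is a *change of
   gradient*, which is precisely what a physical energy change produces
   (higher energy → shallower descent). The drift model below reflects this.

Relative change from baseline is signed as `100·(M − M_ref)/|M_ref|`: since
slopes are negative, a steeper limb (energy decrease) gives a negative
percentage, matching the sign of the energy change.

## Calibrations and tolerance conversion

Across a linac's electron beams, slope maps to beam quality through
exponential fits to commissioning data:

    E   = A_E  · exp(B_E  · M),    I50 = A_50 · exp(B_50 · M).

Fitting is ordinary least squares on `ln(target)` versus `M` (exact on
noiseless exponential data for any n ≥ 2); the reported R² is computed on
the linear target scale against the fitted exponential. The published
constants `E = 32.311·e^(0.0247·M)` and `I50 = 13.714·e^(0.0246·M)` are used
as reference models in tests and the worked examples.

Tolerance conversion inverts the `I50` calibration: starting from the
baseline slope (itself obtained by inverting the energy calibration at the
nominal energy when no measured baseline is supplied — measured baselines
take precedence), displace the predicted `I50` by a chosen shift (default
+1 mm and +2 mm, i.e. deeper) and report the absolute relative slope change
this requires. At 12 and 15 MeV this yields the common 2% (warning) and 4%
(action) levels; at 6 MeV the calibration-derived value is ≈2.3%/1 mm.
Because the exponential is locally almost linear, the ±shift asymmetry is
below 15% relative at clinical baselines. Tabulated tolerances are rounded
to one decimal place.

## Status bands, screening, drift

A record's status is decided on the absolute slope change: pass below the
warning level (default 2%), warning from 2% to below 4%, action at 4% and
above — the bands partition the real line. Outlier screening uses Z-scores
with the sample (n−1) standard deviation, flagging |Z| > 2; a zero-spread
series is defined to have all-zero Z-scores. Screening and summaries are
per energy and per method; callers may exclude known drift periods from the
spread summary, and exclusions are bookkept explicitly. Sustained drift is
flagged when a configurable number of consecutive records (default 3)
exceed the warning level with a common sign — a deliberately simple rule;
no CUSUM/EWMA control charting is attempted.

## The synthetic beam family

`BeamSpec.from_energy(E)` lays out one beam from nominal energy alone:

| parameter | default | rationale |
|---|---|---|
| `r50` | `E/2.33` cm | the TG-25 energy–range relation, inverted |
| `rp` | `1.25·r50` | clinical Rp/R50 proportion; puts the 6 MeV 70/30 gradient near −70 %/cm, consistent with the published energy calibration |
| `d_max` | `0.6·r50` | clinical beams show `d_max/R50` ≈ 0.55–0.6 from 6 to 15 MeV; leaves a broad flat shoulder at the peak, the premise of reference-depth normalization |
| `surface_level` | 80% | typical electron surface dose |
| `tail_level` | `1 + 0.2·E` % | bremsstrahlung grows with energy |
| `grid_step` | 0.05 cm | typical scan resolution |

The generated curve is piecewise: a quadratic build-up (zero slope at
`d_max`), a monotone cubic shoulder from `d_max` to the 85% crossing, an
**exactly linear** segment through `(r50, 50%)` with gradient
`g = (tail − 50)/(rp − r50)` — which therefore reaches the tail level
precisely at `rp` — and a constant tail beyond. The peak depth is inserted
into the depth grid so the maximum reading is exactly 100. By construction
`i50 = r50`, the 70/30 crossings sit at `r50 ± 20/|g|`, and the
descent/tail line intersection is `rp`; the curve-analysis routines recover
all of these to float precision, which the acceptance suite asserts at
1e−6 cm.

The shoulder's junction slope is clamped to three times its secant (the
monotone-Hermite bound), so the blend is monotone for any admissible
geometry; when clamping is active the junction is value-continuous with a
small derivative break, which no extracted metric is sensitive to. The
build-up and shoulder shapes are cosmetic — nothing is calibrated against
measured build-up data — and curves are phenomenological, not transport
calculations.

An early version used a deeper peak (`d_max = r50 − 0.9·(rp − r50)`, i.e.
`0.775·r50`); that geometry leaves no flat region at the reference depth —
the shoulder begins ~1 mm beyond the peak — which contradicts both clinical
curve shapes and the method's normalization premise, and it makes the
reference reading, not the method, dominate every simulated statistic. The
clinical proportion replaced it.

## Noise model

Two error sources, per the stated measurement conditions:

- **reading reproducibility**: independent multiplicative Gaussian noise
  per electrometer reading, SD 0.5% (reported reproducibility is <1%,
  usually <0.5%);
- **depth positioning**: Gaussian, SD 0.3 mm (0.03 cm), the stated overall
  position uncertainty.

In the monthly simulation the depth error is drawn **once per session** and
applied to all four depths visited that month: the chamber is set up once
against the water surface, and the mechanical stepper's relative moves
(0.01 mm scale) are an order of magnitude more precise than the setup. This
session-correlated structure is what the slope method exploits — the common
offset cancels on the straight limb — and what makes the ratio method's
deep reading, sitting on that limb, inherit the full positioning error.
Modelling the two points as independently positioned would instead describe
two separate setups, and under that model differencing two steep-limb
readings is *less* stable than the ratio; the session model is the one that
matches both the described measurement procedure and the observed stability
ordering. The single-measurement `measure_at` treats each call as its own
positioning, and its spread obeys the standard propagation formula
`sqrt(reading_sd² + (g·depth_sd/value)²)`, which a simulation test checks.

All randomness flows through one seeded `numpy` generator; identical seeds
reproduce series bit for bit.

## Drift model

`drift_beam` shifts `I50` by a requested number of millimetres in one of
two modes:

- **rigid** — translate `r50`, `rp`, `d_max` together. Exact for range
  bookkeeping (`I50` moves by precisely the request), but on a straight
  limb it leaves the fixed-depth slope statistic unchanged, so it cannot
  model a *detectable* energy drift.
- **energy** (default for drift studies) — rescale the descending limb to
  the nominal energy whose `R50` equals the shifted one, keeping `d_max`
  and the build-up fixed (for millimetre drifts the depth of maximum is
  insensitive; what moves is the descending portion). `I50` still moves by
  exactly the request, and the gradient steepens or relaxes as a physical
  energy change does.

For converting measured slope changes to millimetres, the calibration is
fitted locally: `calibration_from_drifts` generates energy-mode beams
spanning ±2 mm of `I50` around the working point, measures each scan's
gradient and `I50` with the curve-analysis routines, and fits the
exponential. Over that narrow span the exponential is locally exact, so a
noiseless −1 mm drift measured at the commissioned depths converts back to
−1.0 mm within 0.1 mm at every default energy (asserted by the acceptance
suite). A *global* fit across the full 6–15 MeV family is also available
(it is what the `baseline` CLI command does, mirroring commissioning
practice) but the synthetic family's `ln I50` is visibly convex in slope
over that wide range, so a global fit misstates the local sensitivity; real
machines reported R² ≈ 0.9997 over their families, a property of measured
beams that the default synthetic family does not share.

## Numerical and interface choices

- Depths are cm everywhere; `I50` shifts are expressed in mm only at the
  presentation layer (1 mm = 0.1 cm). Scan files store depths to 4 decimal
  places, readings to 6 significant digits.
- Level crossings are searched on the descending limb only (first crossing
  beyond the maximal region); build-up crossings of the same level are
  ignored. An exact sample hit returns that sample's depth. On a value
  plateau, `d_max` is the plateau midpoint (deterministic tie-break).
- `Rp` is the intersection of two least-squares lines: one through the
  samples between the 70% and 30% crossings, one through the tail window,
  which by default starts half a `d_max`-to-`I50` distance beyond the 5%
  crossing (explicit depth bounds can override, e.g. when the tail exceeds
  5%). Near-parallel fits and intersections not beyond the 30% depth raise
  a degenerate-fit error.
- The effective-point-of-measurement shift moves depths toward the surface
  by half the chamber radius, refuses double application, and warns (but
  proceeds) if samples move above the surface.
- The NACP energy–range relation is implemented as
  `0.22 + 1.98·Rp + 0.0025·Rp²` (quadratic); the ratio method's convention
  is fixed as `d_max` reading over deep reading.
- Exponential-fit amplitude and rate are required positive: for electron
  beams, shallower slope always means higher energy and deeper `I50`.

## Problem sizes

Simulation-based checks use 36 monthly sessions per beam, four beams
(6/9/12/15 MeV), and ten seeds for the stability comparison — enough for
stable sample SDs (relative SD of an SD estimate ≈ 12% at n = 36) while the
full suite runs in seconds.

## Limitations

- Ionization is never converted to dose; no stopping-power ratios are
  applied. All statistics are relative constancy checks, not absolute
  energy determinations.
- The synthetic build-up region is cosmetic; conclusions about real scans
  hold only for descending-limb and tail behaviour.
- Simulated noise is Gaussian and stationary; real series contain
  electrometer warm-up, water-level and temperature effects the model does
  not emulate. Passing the simulation tests shows the statistics behave as
  designed under the stated error budget, not that real machines achieve
  the simulated SDs.
- Per-machine calibrations are required; no attempt is made to transfer a
  slope→I50 calibration across linacs or vendors.
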