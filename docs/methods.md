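# Methods

## Clearance model

The donor compartment is modelled as a well-stirred volume drained by a
peristaltic pump. If a constant fraction *c* of the current volume is
removed per minute, the continuous-time limit is first-order decay,

    V(t) = V0 · exp(−β t),    β = −ln(1 − c)   [min⁻¹],

so an 11 %/min clearance gives β = 0.117 min⁻¹ and 16 %/min gives
β = 0.174 min⁻¹. A protocol with several pump settings is represented as
an ordered list of constant-clearance regimes over half-open intervals
[t_k, t_{k+1}); each regime starts from the volume the previous one left,
making V(t) continuous and piecewise exponential. The standard operating
protocol is 300 µL cleared at 16 %/min for 2 min (a simulated reflex
response to instillation, pump at 48 µL/min) followed by 11 %/min for
13 min (basal turnover, 33 µL/min). Pump flow and fractional rate are
related by `flow = c × reference volume`; the human basal tear flow of
≈1.1 µL/min over a 7–10 µL tear volume is what motivates the 11–16 %/min
range.

**Units.** β is carried per minute throughout. (Reports of these
coefficients sometimes carry an s⁻¹ label; only per-minute units are
consistent with values such as 17.29 % remaining after 15 min, so the
label is treated as a typo.)

**Rounding conventions.** Two conventions are implemented because both
occur in practice:

* *canonical mode* (default): β is rounded half-up to three decimals
  before any evaluation. This reproduces the conventional figures —
  17.29 % and 7.35 % remaining after 15 min at 11 and 16 %/min, 211.83 µL
  at the two-stage switch, 15.43 % after the full run. An `--exact-beta`
  flag (or `rounded=False`) keeps full precision.
* *discrete compounding*: `V0 (1 − c)^k` after k whole minutes (89 %,
  79.21 %, 70.50 % at 11 %/min). With unrounded β the two conventions
  coincide exactly at integer minutes, since (1 − c)^k = e^(−βk); with
  rounded β they differ in the last printed digit (70.50 vs a sometimes
  quoted 70.51), which is why reported percentages carry a ±0.02
  percentage-point tolerance and switch volumes ±0.2 µL.

Percentages are reported half-up at two decimals, coefficients at three;
raw values are kept internally.

**Derived quantities.** The exposure AUC ∫₀ᵀ V dt is evaluated in closed
form per regime, `V_k (1 − e^(−β_k Δ))/β_k`, with the rectangle limit at
β = 0. `fit_beta` recovers β as the least-squares slope of −ln(V/V0)
against t; on noiseless single-regime data it is exact to machine
precision, and under 1 % multiplicative noise with 100 samples the median
relative error stays below 5 %. Trajectory exports default to a grid of
dt = 0.01 min; the committed example trajectory uses dt = 0.05 min purely
to keep the repository CSV compact.

**Numerical checks.** The closed form is validated against an independent
Euler-compounding oracle (V ← V(1 − βh) per step), whose error shrinks
roughly linearly in h; trajectories assert mass balance
(volume + drained = V0 to 1e−9 relative) and monotone decay; evaluation is
continuous across regime switches.

## Donor-compartment geometry

Five glass prototypes are described by nine dimensions (mm). The ratio
columns d_out/d_in and H_in/H_out are *truncated* (not rounded) to two
decimals — the only convention that reproduces all ten tabulated values
(10.8/11.5 = 0.9391 → 0.93; 5.00/2.43 = 2.0576 → 2.05). The flow angle is
stored categorically (right angle vs acute) because no numeric acute angle
is specified; a missing base widening is modelled as absent, not zero.

Selection criteria, codified from the design narrative: a prototype is
eligible if its flow angle is acute *and* it has a widened base (better
eyeball coupling); eligible prototypes rank by H_in/H_out descending (a
larger inlet/outlet height gap discourages fluid damming), ties broken by
larger base height H_b, then lower version number. On the packaged table
this selects version 5. The relative weighting of the criteria is a design
choice of this package — the original choice was narrative — so the ranking
should be read as a codification, not a hydrodynamic model.

## Drug assay inversion

The fluconazole calibration is linear, `area = 30 676·c + 2843.9`, over
0.5–10 µg/mL with LOD 0.007 and LOQ 0.021 µg/mL. Back-calculated
concentrations are flagged against a partition of the axis closed on the
informative side: c < LOD → `not_detected` (reported as 0, not NaN, so
downstream statistics stay defined); LOD ≤ c < LOQ →
`detected_not_quantifiable`; LOQ ≤ c ≤ range top → `quantifiable`; above
the range the linear model is extrapolation and raises unless explicitly
overridden (`out_of_range`). Amounts are `c ×` extraction volume (default
5 mL) and optionally per diffusional area (1.0 cm² in the static cell).
The LOD/LOQ are taken as assay constants; the σ they were derived from is
not recoverable, so they are not re-derived here. The dynamic-arm donor
concentration is recorded as 60 µg/mL (the protocol figure; the
formulation label of 0.2 % w/v would imply a much higher value — the two
are inconsistent at source, and the protocol figure is used).

## Synthetic permeation experiments

No public record-level penetration dataset exists, so the generator
emulates the experiment: 7 formulations × {static: 5, dynamic: 4}
replicates, amounts in µg/cm² drawn from a lognormal parameterised by a
true mean and CV (mean m, CV v → μ = ln m − σ²/2, σ² = ln(1 + v²)), fully
reproducible from a recorded seed. Default CV is 25 %, a typical
between-replicate spread for ex vivo corneal assays; no replicate
variances are published to calibrate against, so one shared CV is used
(per-formulation override available).

Default true means encode the qualitative findings the two arms resolve:
static ≈ 3.0 µg/cm² for every formulation (the static protocol cannot
separate them); dynamic ≈ 0.5 µg/cm² for the solution and poloxamer-only
gels (washout-dominated, independent of poloxamer percentage) and
≈ 1.5 µg/cm² for chitosan gels (mucoadhesion resists clearance). These
imply static/dynamic overestimation ratios of ≈6× for non-mucoadhesive
formulations (reported as "more than five times") and 2× for chitosan
gels (reported as "about twice").

What the generator does **not** emulate: any mechanistic link from the
clearance trajectory to penetrated amount (none is established),
tissue-to-tissue covariance, the temperature difference between arms
(32 °C static vs room-temperature dynamic), or within-chitosan
dose-response. Passing tests therefore demonstrate that the pipeline
detects the intended pattern at the design's replicate numbers — not that
real corneas behave lognormally.

## Statistics

Arms are analysed separately (different apparatus and temperature; no
pooled two-way model). Per arm: classical one-way ANOVA from definitional
sums of squares, then all-pairs Tukey HSD on the pooled within-group
variance at α = 0.05 (the post hoc procedure is not specified at source;
Tukey HSD is the standard all-pairs choice, and Games–Howell is available
when variances should not be pooled). Significance is starred at two
tiers (\* p < 0.05, \*\* p < 0.01). Degenerate inputs — a single group,
groups with one replicate, zero within-group variance — raise explicit
errors rather than returning 0/0 statistics. Overestimation ratios are
per-formulation static/dynamic mean ratios; they report, but do not
adjust for, the arm-to-arm temperature confound.

Calibration is verified by simulation: under a null where all seven
groups share one distribution (2000 datasets), the ANOVA rejection rate
at α = 0.05 stays within 0.05 ± 0.02; the implementation is also checked
against an independent ANOVA routine on random small datasets.

## Power of the default design

With the default means, CV and replicate numbers, across 500 generator
seeds: all nine dynamic-arm chitosan-vs-poloxamer Tukey comparisons are
simultaneously significant in ≈89 % of seeds, and at least one of the
three poloxamer-concentration pairs is falsely significant in far fewer
than 10 % (familywise control keeps it near zero). Seed-averaged
overestimation ratios land at ≈6× (poloxamer-only) and ≈2.0–2.1×
(chitosan). These problem sizes — 500 seeds for the pattern, 100 for the
ratios, 2000 for the null calibration — are the package's standing
simulation sizes and keep the whole suite fast on a single CPU.

## Known limitations

* The washout model assumes a well-stirred donor compartment; plug-flow
  or channelled drainage in the physical glassware is not modelled, nor
  is evaporation.
* The prototype ranking codifies narrative criteria; it is not a fluid
  dynamics calculation.
* Synthetic data cannot validate biological claims; they validate the
  pipeline's sensitivity under stated noise assumptions.
* No in vivo bioavailability prediction is attempted or implied.
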