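# Methods

## Signal model of the synthetic generator

One acquisition is a continuous resistance trace over five heater-voltage
steps (cycles) of 80 s each, sampled at 1 s. Within cycle *k* the clean
signal starts at the previous cycle's end value (the first cycle draws a
log-normal baseline, default mean 20 000 Ω, sd 1 500 Ω), falls to
`start − gap_k` along a normalized exponential
`start − gap_k · (1 − e^(−τ/θ)) / (1 − e^(−F_k/θ))` with `θ = F_k/5`,
reaching the drawn minimum exactly at the drawn fall time `F_k`, then
recovers linearly to `start − (1 − ρ)·gap_k` by cycle end
(recovery fraction ρ = 0.85 by default). White measurement noise
(default sd 5 Ω) is added last and samples are clipped positive. There is
no baseline reset between cycles, matching the continuous trace an
instrument produces.

Drop amplitudes `gap_k ~ N(μ[class, sensor, k], σ[class, sensor, k])`
truncated at 0; fall times `F_k ~ N(15 s, 2 s)` truncated to
(2·Δt, 40 s). Truncated draws use one inverse-CDF uniform each, so the
random stream length is input-independent and cohorts are bit-reproducible.
Each subject draws from a substream keyed `(seed, subject index)`
(NumPy PCG64 via `default_rng([seed, idx])`), making a subject's traces
independent of cohort ordering.

### Default class separation

The defaults emulate a 64-subject study (32 cancer / 32 control,
5 sensors) whose discriminative signal sits in sensor 2:

| sensor × cycle | non-cancer gap | cancer gap | binormal AUC | optimal cut-off |
|---|---|---|---|---|
| S2 cycle 1 | N(27.5, 10) Ω | N(32.5, 10) Ω | 0.64 | 30 Ω |
| S2 cycle 4 | N(815.3, 150) Ω | N(908.7, 150) Ω | 0.67 | 862 Ω |
| all others | N(500, 80) Ω | N(500, 80) Ω | 0.50 | — |

Means and sds were chosen once so that (a) the population AUCs equal the
two discriminative-feature AUCs the design targets, and (b) the
equal-variance binormal Youden point — the midpoint of the class means —
lands exactly on the conventional cut-offs 30 and 862 Ω. The ohm scale of
those cut-offs is itself a convention (the raw instrument scale is not
standardized); only ratios of gap to its spread matter downstream. Under
these defaults the two-rule combined score has population AUC ≈ 0.66
versus ≈ 0.60/0.62 for the single rules — the panel-beats-components
ordering, which is the qualitative claim the simulation supports.

`theoretical_feature_auc` returns
`Φ(Δμ / √(σ_c² + σ_n² + 2·noise_sd²))`: the extracted gap is a
difference of two sampled resistances, so each endpoint contributes one
`noise_sd` of measurement noise. The formula ignores truncation at 0 and
is therefore exact only when class means sit several sd above zero (true
of all defaults except marginally S2 cycle 1, where the truncated mass is
< 0.3%).

### What the generator does not emulate

Real e-nose data exhibit baseline drift across a session, humidity and
temperature confounding, sensor aging, inter-subject variation in urine
headspace concentration, and correlated responses across sensors exposed
to the same gas mixture. The generator produces none of these: features
are conditionally independent across sensors and cycles given the class.
Passing tests therefore demonstrate correctness of the statistical
machinery under known separation, not field performance of any sensor.

## Feature extraction

Cycles are segmented by the protocol schedule (half-open
`[(k−1)·80 s, k·80 s)` windows), not by detecting voltage edges — trace
files carry no voltage channel. A trailing partial cycle is dropped with
a warning; a trace shorter than one cycle is an error. Within a cycle,
the minimum *A* is the first-occurring smallest sample and *B* is the
first-occurring maximum at or before *A*; `gap = R(B) − R(A)`,
`t = t(A) − t(B)`, `SL = gap/t` with `SL = 0` when `t = 0` so flat traces
produce valid rows. Taking *B* as the pre-minimum maximum (rather than
the cycle-onset value) is robust to drift within a cycle and reduces to
the onset value for the generator's monotone-decay shape. `t` is measured
from *B* to *A*, not from cycle onset. With a fall time `F` between
sample points the sampled minimum exceeds the drawn minimum by at most
one sample interval's local slope; with `θ = F/5` the relative gap error
is below 1% at default settings.

## Statistical cascade

- **t test**: Student pooled-variance by default (Welch by flag).
  Zero-variance degenerate input returns p = 1 (equal means) or p → 0.
- **AUC**: the Mann–Whitney estimator (ties count ½), oriented so higher
  score ⇒ cancer; features with AUC < 0.5 are reported as-is, never
  flipped, because every published-style rule is "≥ cut-off".
- **AUC inference**: Hanley–McNeil SE by default — the standard
  nonparametric default in clinical software — with DeLong's
  placement-variance SE by flag; CI = AUC ± 1.96·SE clipped to [0, 1];
  p from z = (AUC − 0.5)/SE.
- **Youden cut-off**: candidates are the distinct observed scores;
  maximize J, break ties by higher accuracy, then by the smaller
  cut-off. All tie-breaks are deterministic.
- **2×2 metrics**: exact ratios; PPV/NPV are NaN on empty denominators;
  OR is +inf when FN·FP = 0; the Woolf CI and Wald p require all cells
  positive and are NaN otherwise.
- **Logistic regression**: univariable intercept+slope ML fit by IRLS to
  a 1e-8 step tolerance (max 100 iterations). Complete separation is
  detected up front (non-overlapping class ranges) and quasi-complete
  separation by coefficient divergence (|β| > 40); both raise instead of
  returning a misleading estimate. For a binary predictor the fit's OR
  equals the cross-product OR and the Wald CI equals the Woolf CI — used
  as an internal identity test.
- **Screening**: stage 1 t-tests all features; stage 2 computes ROC
  inference for stage-1 passes plus any explicitly forced features
  (supporting the practice of carrying a near-significant candidate);
  stage 3 computes Youden cut-offs for significant-ROC features. Raw
  p ≤ α with no multiplicity correction is the default cascade, matching
  the single-threshold convention of the emulated analysis; a
  Benjamini–Hochberg column is available for reference and never alters
  the cascade.
- **Combined biomarker**: the count of satisfied (feature ≥ cut-off)
  rules, an ordinal 0…R score fed to the same logistic/ROC machinery.
  Subjects missing any rule feature are excluded with a logged count.
- **Three-group comparisons** (cancer / other disease / normal) are
  pairwise t tests, consistent with the two-group machinery, not ANOVA.

## Numerical and design choices

- Reconstruction of a 2×2 table from printed rates uses
  half-away-from-zero rounding of `rate × n`; at n = 32 this is exact for
  all printed one-decimal percentages.
- Report CSVs round percentages to 1 decimal and OR/AUC to 2 decimals;
  the JSON/Python API always carries full precision.
- Pipeline artifacts are byte-deterministic under fixed seed and config;
  wall-clock timestamps appear only in `manifest.json`.
- Validation findings (schema, monotone time, positive resistance, label
  coverage) are returned with severities rather than raised, so callers
  can distinguish fatal from cosmetic issues; the pipeline treats
  error-severity findings as fatal.

## Problem sizes used by the test suite and acceptance script

Simulation-based checks use 32+32-subject cohorts: 500 seeds for AUC
recovery and CI coverage (standard error of the mean AUC ≈ 0.003, well
inside the ±0.02 assertion), 10–12 null cohorts (≥ 1000 feature tests;
the 5% flag-rate band is widened to [2%, 8%] because min/gap/t/SL of a
cycle are mutually correlated, reducing the effective number of
independent tests), and 8–30 cohorts for ordering comparisons. The
brute-force extraction oracle runs on 1000 short two-cycle traces, half
integer-valued to force exact ties.

## Known limitations

- The IRLS fit covers a single predictor by design; multi-coefficient
  models are out of scope.
- DeLong inference is implemented for one curve; correlated-curve AUC
  comparison is not provided.
- The binormal AUC oracle is approximate under heavy zero-truncation or
  non-normal gap configurations.
- Cut-off selection at n = 64 is noisy: the sample Youden point can sit
  far from the population optimum (visible in the demo's cut-off table),
  which is a property of the method at this sample size, not of the
  implementation.
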