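# Methods

This note records the statistical models, the synthetic-data assumptions,
the numerical choices and the known limitations of `chromval`. It states
nothing that the test suite or `scripts/acceptance.py` does not itself
compute.

## Scope and data model

The package validates a targeted small-molecule quantification: caffeine in
coffee grains by GC-FID, external calibration over 10–1000 mg/L, sample
preparation 0.5 g → 10 mL (content factor ×20 between extract mg/L and
sample mg/kg; 1 %w/w = 10000 mg/kg exactly). All contents are carried as
mass fractions internally and formatted as %w/w or mg/kg at I/O. The
organic back-extraction (10 mL → 10 mL) is treated as volume-preserving;
any partition loss is absorbed by the recovery bias term rather than
modelled chemically.

## Synthetic data generator

The generator defines the study conditions; downstream estimators are
tested against its ground truth.

* **Chromatograms.** A single Gaussian analyte peak (default retention
  9.5 min, σ = 0.05 min) on white Gaussian baseline noise. Peak area is the
  linear response `b·conc + a` times `(1 + ε)`, `ε ~ N(0, injection_cv)`
  (default CV 1%). The trace generator requires ≥ 20 samples per peak σ so
  quadrature error stays below the 0.5% tolerance asserted in tests. No
  co-eluting matrix peaks, drift programs or detector saturation are
  modelled: passing tests demonstrate correctness of the integration and
  calibration chain, not robustness to pathological real chromatograms.
* **Fortified studies.** Measured content at level *l*, day *d*, replicate
  *r* is `(background + recovery_l·spike_l)·(1 + δ_{l,d})·(1 + ε_{l,d,r})`
  with `δ ~ N(0, between_day_cv_l)` and `ε ~ N(0, within_day_cv_l)`;
  negative draws truncate at 0. The error model is multiplicative because
  every performance figure in this domain is a relative SD. Day effects are
  drawn independently per (level, day) — a deliberate simplification that
  leaves each level's marginal model unchanged while making levels
  independent in repeated-study simulations. Defaults encode the study
  conditions: background 1.3 %w/w; spikes 0.5/1.0/2.0 %w/w; 3 replicates ×
  2 days; true recoveries 0.935/0.967/1.020; within-day CVs
  0.041/0.025/0.020 with between-day CVs `√(RSD_R² − RSDr²)` =
  0.0185/0.0230/0.0092, so total CVs are 0.045/0.034/0.022.
* **QC series.** Gaussian around the QC sample's true content (default
  2.3 %w/w — the 1.0 %w/w spike over background — at CV 0.034), indexed
  every 5 runs; injected mean shifts are recorded as ground truth.
* **Determinism.** Every generator accepts a seed or Generator; the
  pipeline spawns independent substreams from one root seed via
  `numpy.random.SeedSequence`, so a fixed configuration reproduces
  byte-identical reports.

A consequence worth noting: because noise scales with *total* content, the
per-replicate recovery SD at the smallest spike is large
(≈ total·CV/spike ≈ 16% at 0.5 %w/w), and the expected HORRAT_r there is
≈ 1.7. Single simulated studies (6 measurements per level, 4 within-day
degrees of freedom) therefore fail the strict HORRAT < 2 or the 80–120%
recovery band in a sizeable fraction of seeds. This is a property of the
small regulatory design, not an estimator defect; the repeated-study
simulation (2000 replicates) shows the estimators unbiased to well within
one percentage point.

## Estimators and decision rules

* **Calibration** is unweighted OLS (statsmodels), with an optional 1/x
  weighting exposed but off by default; residual SD uses n − 2 df. Tests
  check the parameter SEs against the closed-form textbook expressions as
  an independent oracle. LOD/LOQ use the intercept's standard error
  (3.3/slope and 10/slope factors), *not* the residual SD — the definition
  this validation protocol prescribes. Inverse prediction reports
  `s_x0 = (s/b)√(1/m + 1/n + (x0 − x̄)²/Sxx)`; predictions outside the
  calibrated range are flagged as extrapolated but not rejected, since
  fortified extracts legitimately exceed 1000 mg/L (the flag propagates to
  the report).
* **Slope comparison** uses `t = Δb/√(SE₁² + SE₂²)` with df = n₁ + n₂ − 4
  (Welch–Satterthwaite selectable), two-sided at α = 0.05. For equal
  designs and equal noise this statistic is exactly t-distributed, which
  the acceptance suite verifies empirically (type-I rate 5% at 10⁴
  replicates). Perfect fits (zero SEs, detected with a relative floor of
  1e−10 on the SE scale) are reported with a degeneracy caveat.
* **Precision** uses balanced one-way ANOVA variance components with day as
  factor; a negative between-day component truncates to 0, which enforces
  RSD_R ≥ RSDr. Single-day studies report RSD_R as undefined rather than
  guessing. The Horwitz concentration argument defaults to the **total**
  content (background + spike), the standard HORRAT convention; a
  spike-only basis is selectable because fortification-level conventions
  differ. No low-level (Thompson 22%) plateau is applied — caffeine
  contents here are orders of magnitude above that regime. HORRAT passes
  strictly below 2.
* **Recovery** is `100·(measured_total − background)/spike` per replicate;
  the background comes from unspiked replicates in the same study when
  present, otherwise from an explicit or configured value. Acceptance is
  mean recovery in [80, 120]%.
* **IQC chart** uses the classical Shewhart multiples (warning ±2σ, action
  ±3σ); the ≤5% warning rule is evaluated over the full evaluated series,
  not a moving window. Chart limits require ≥ 8 baseline points (or a
  fixed center/SD spec, which also covers noise-free simulations whose
  baseline SD would be zero). A 7-point one-sided run rule is reported as
  an advisory trend flag only — the in-control verdict uses exactly the
  two stated rules.
* **Uncertainty budget** combines five relative components in quadrature
  with k = 2: mass and volume from rectangular (÷√3) tolerances (balance
  0.0005 g, class-A 10 mL ± 0.02 mL, water expansion 2.1·10⁻⁴/°C over
  ±4 °C), calibration from `s_x0/conc`, bias from the recovery tests and
  precision as RSD_R unchanged. The default bias variant is
  `√(bias² + SE(recovery)²)`; bias-magnitude-only and SE-only variants are
  selectable, as the Eurachem guide permits several. An optional
  stock-standard component (default 0) is accepted. When mass and volume
  jointly contribute < 1% of the combined variance the budget annotates
  them as negligible rather than asserting it. Reported expanded
  uncertainties from a synthetic run are not expected to equal any
  particular published figures — the underlying calibration inputs of a
  real instrument are not reproducible — so tests treat such figures only
  as upper bounds for component subsets.
* **Intake** is `content/100 × cup mass × cups/day`; the default 80 mg of
  coffee per cup is kept verbatim from the scenario it reproduces (with
  1.3 %w/w it yields 1.04 mg/day and 7.28 ≈ 7.3 mg/week at 2 significant
  figures) even though it is unusually small for a real serving; it is a
  plain config field. The 150 mg/L "high caffeine content" labeling test is
  strict (> 150) and annotates that coffee itself is exempt.

## Numerical choices

* Baseline estimation is morphological opening (rolling minimum then
  maximum, width 0.5 min) followed by a rolling mean: it removes peaks
  narrower than the window, preserves ramps exactly, and never exceeds the
  signal beyond smoothing tolerance. Peak boundaries walk outward from the
  apex to baseline return (1% of apex height) or the inter-peak valley;
  integration is the trapezoid rule (robust on irregular sampling) with
  negative samples clipped at 0. Retention-time matching uses ±0.1 min and
  breaks exact ties toward the larger area, caffeine being the dominant
  peak near its retention time.
* The pipeline verdict is the conjunction the protocol states: all
  recoveries acceptable AND all HORRATs < 2 AND chart in control. The
  matrix-effect test result is reported but does not enter the verdict
  (it selects the quantification mode).

## Problem sizes

The repeated-study simulation uses 2000 study replicates; the type-I-error
and QC tail checks use 10⁴ replicates/points; the bootstrap oracle for the
calibration uncertainty uses 4000 draws. These sizes put Monte-Carlo error
well inside the asserted tolerances (3σ bands) while keeping the whole
suite fast on one CPU.

## Known limitations

* No overlapping-peak deconvolution, retention-index calibration or
  nonlinear (quadratic) calibration; the method's range is asserted linear.
* The generator's Gaussian-peak/white-noise chromatograms are idealised;
  integrator robustness on real noisy baselines is only partially probed.
* Recovery-SD magnitudes at low spikes follow from the multiplicative
  total-content noise model and will exceed what a study reports if its
  replicate noise is dominated by the spike measurement itself.
* The Welch df option for the slope test is approximate; the default
  pooled df is exact only for equal designs with equal residual variance.
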