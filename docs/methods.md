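# Methods

This note documents the generative model, the analysis chain, and the
numerical and design choices behind `mmnadd`, in the spirit of a methods
section: what is modeled, what is assumed, and what the validation
experiments do and do not establish.

## Paradigm construction

Two block types are generated deterministically from a seed.

**Complex musical multi-feature blocks** consist of four-tone Alberti-bass
patterns (lowest–highest–middle–highest) at a 205 ms stimulus onset
asynchrony.  A block contains 3 iterations over the 12 chromatic pitch
levels A♯2–A3 (equal temperament, A4 = 440 Hz, 116.54–220.00 Hz); at each
pitch level the 7 deviant types occur once in a seeded permutation, each in
a slot of 3 standard patterns followed by one pattern whose third tone is
the deviant.  A block therefore has 3·12·7·4·4 = 4032 tones, lasts
826.56 s (13 min 47 s), and contains 36 deviants per type; four blocks give
144 per type.  Pitch-level orders are seeded shuffles constrained so the
same level never repeats back-to-back across iteration boundaries — the
most conservative reading of "pseudo-random" that still guarantees uniform
marginals.

**Simple control blocks** are a classical oddball at a 400 ms SOA: 4
iterations × 12 pitch levels × 7 deviant types, each deviant preceded by
3–5 standards drawn uniformly.  48 deviants per type per block (144 over
three blocks); expected duration 7·12·4·5·0.4 = 672 s ≈ 11 min.

**Analysis standards.**  Only the third standard tone after each deviant is
flagged as an analysis standard.  In the complex paradigm the flag goes to
the position-3 tone of the third standard *pattern* after each deviant
pattern, so analysed standards occupy the same within-pattern position and
local acoustic context as the deviants.  A block-final deviant with fewer
than three trailing standards contributes no standard trial; blocks are
separated by breaks, so no borrowing across blocks occurs.

## Generative model of the sensor data

Sensor sites (planar-gradiometer pairs, default 51; validation runs use 24)
are laid out on a golden-angle spiral over a spherical cap of radius
0.09 m.  Each site carries two orthogonal channels.  An evoked field u at a
site is emitted as (√2·u·cos ψ, √2·u·sin ψ) with a fixed per-site angle ψ,
so the root-mean-square combination √((a²+b²)/2) returns |u| exactly.

The evoked field of condition d for a subject of group g is

    E(d) = S + (1 − κ(g, d)) · Σ_{f ∈ constituents(d)} β_f · b_f · w_f(t)

* **Standard response S**: Gaussian component, latency 100 ms, width 40 ms,
  amplitude 20 (arbitrary units, nominally fT/cm), topography a compactly
  supported bump (support radius 0.030 m) at the vertex.
* **Mismatch components**: per feature f ∈ {F, I, L}, a Gaussian component
  with latency 156 ms, width 30 ms and amplitude 12 at the best sensor;
  topographies are compact bumps (radius 0.045 m) centred on two bilateral
  supratemporal hotspots, displaced ~1 cm per feature to mimic spatially
  separate sources, and normalized to unit sensor maximum so the configured
  amplitude is the amplitude actually seen at the peak sensor regardless of
  layout density.
* **Subadditivity κ** multiplies the *summed* mismatch by (1 − κ),
  uniformly over channels and time — a one-parameter ground truth the
  empirical−modeled contrast estimates directly.  Defaults: κ = 0.4 for
  the frequency-containing combinations (FI, LF, FIL) in the musician
  group and the complex paradigm; zero elsewhere.  Amplitudes are not
  reported quantities of any dataset; they are synthetic choices that put
  the single-trial peak signal-to-noise ratio at 12/40 = 0.3.

Two structural choices make the bookkeeping exact rather than approximate
on the rectified (RMS-combined) scale: all three mismatch components share
one temporal waveform by default, and the standard-response support is
spatially disjoint from the mismatch supports.  Under these defaults the
additive identity `MMNm(FI) = MMNm(F) + MMNm(I)` holds sample-for-sample
through the *entire* nonlinear chain for noise-free κ = 0 data (the suite
asserts < 1e−8), which pins down what the pipeline should recover.  Real
MEG violates both choices (N1/P2 responses to standards overlap mismatch
topographies, and feature MMNms differ somewhat in latency); passing tests
therefore certify the pipeline's arithmetic, not the physiology.

**Noise** is stationary Gaussian with separable structure: spatial
covariance exp(−d/λ) across sites (λ = 0.04 m), applied independently to
the two orientations of each pair (perfectly correlated pair noise — the
literal reading of a covariance on coincident positions — would be
degenerate under RMS combination); AR(1) over time with lag-one
autocorrelation φ = 0.6 at 250 Hz, initialized at stationarity; single-trial
SD σ = 40 per channel.  Subject amplitude heterogeneity is one log-normal
gain per subject (mean 1, CV 0.2).  No 1/f background, no physiological
artifacts (ocular/cardiac cleaning is outside scope); the only artifact
model is an optional SQUID-like step (probability 0.02 per trial, amplitude
2000 = 50 σ) used to exercise trial rejection.

Epochs span −100…+400 ms at 250 Hz (126 samples).  Noise is generated in
single precision for speed; the analysis chain is double precision.

## Preprocessing

1. **Jump rejection** (z cutoff 30): per channel, absolute first
   differences are z-scored against their pooled mean/SD over all trials
   and samples; a trial is discarded when its maximum z exceeds the cutoff.
   The rule is deliberately simple — sensitive to steps, insensitive to
   slow components — and is validated only against the synthetic step
   artifacts (injected trials are recovered exactly at default settings).
2. **Band-pass 1–40 Hz**: zero-phase (two-pass) 4th-order Butterworth,
   applied after symmetric reflection padding to 3 s total length.  The
   1 Hz high-pass removes roughly a quarter of a 30 ms-wide Gaussian
   pulse's peak; nominal amplitudes above are pre-filter values.
3. **Condition averaging** over trials (standards restricted to the flagged
   analysis standards).
4. **Planar combination**: √((a²+b²)/2) per pair, yielding a nonnegative
   combined channel.  The √(a²+b²) convention is available
   (`convention="sum"`); it is a global factor √2 with no inferential
   consequence.
5. **Baseline correction** over −50…0 ms, i.e. the baseline of the
   rectified signal.

Ordering: rejection and filtering act on raw trials; the RMS combination is
applied to condition *averages*.  Combining single trials before averaging
— a literal reading of some preprocessing descriptions — makes the evoked
response the mean of rectified noisy trials, which at single-trial SNR 0.3
is a nearly quadratic function of the underlying field; that provably
destroys both the additive identity and any linear-scale parameter
recovery, so this package fixes combine-after-average (the convention in
which combined planar gradients are normally computed from timelocked
averages).  All MMNm subtraction happens after combination.  Because
filtering, averaging and baseline are linear, the fast path used in the
experiments (filtering condition averages instead of each trial) is exactly
equivalent and is asserted equal to the trial-wise chain to < 1e−9.

## MMNm construction and sensor selection

Empirical MMNm: deviant average minus the same paradigm's analysis-standard
average.  Modeled MMNm: sum of the constituent single-deviant empirical
MMNms (doubles and triple only).  The additivity contrast is
empirical − modeled; negative values on the combined scale mean
subadditivity.

Sensor selection follows the grand-average recipe: empirical MMNms of all
subjects, conditions and paradigms are averaged; per lateral hemisphere the
combined pair with the largest grand-average amplitude in the 100–300 ms
window is taken, plus its eight nearest same-hemisphere pairs by Euclidean
distance (ties broken by lowest pair id), giving 2 × 9 = 18 analysis
sensors.  Cross-hemisphere neighbours are never used; a hemisphere with
fewer than nine pairs is an error rather than a silent midline crossing.

## Cluster-based permutation tests

Sample-wise t statistics (pooled-variance independent-samples t between
groups, or one-sample t on paired differences within subjects) are
computed on the 18-pair × 100–300 ms grid.  Samples exceeding the
two-tailed critical value at the cluster-forming α = 0.05 are joined into
clusters when neighbours in time (same pair, adjacent samples) and/or space
(same sample, pairs within the distance threshold); following the
minimum-two-neighbour-sensor rule, assemblies whose pair set does not
contain at least two mutually neighbouring pairs are discarded.  This is an
admissibility rule on whole clusters, not FieldTrip's per-sample
`minnbchan`.  The cluster statistic is the signed sum of t values; the
observed per-sign extrema are compared against per-sign Monte Carlo nulls
built from random group-label permutations (independent design) or random
per-subject sign flips (dependent design).  Monte Carlo p-values use the
(b+1)/(m+1) estimator (never zero, valid at any m); when the requested
permutation count covers all distinct relabelings the test switches to
exhaustive enumeration and reports the exact p = b/m (the enumeration
includes the observed labeling).  The neighbourhood distance threshold
defaults to the smallest distance giving a mean of at least three
neighbours per selected pair, and is logged in the report provenance.

Two-sidedness is handled by sign-separated nulls, each compared at half the
overall level; `alpha_inference` in a `TestSpec` is the per-tail level.
Conventions used by `run_study`: presence (deviant > standard) and ordering
(triple > double > single) validity checks are one-sided at uncorrected
α = 0.05; the four additivity-by-expertise interaction tests are two-sided
at the Bonferroni-corrected per-tail α = 0.025/4 = 0.00625; simple effects
of additivity are reported per group at per-tail α = 0.025 (flags are
always re-derivable from the stored p and α columns).

## Validation experiments

The experiments simulate at reduced, documented sizes chosen to make the
Monte Carlo error small relative to the effects being checked:

* **Type-I error**: 200 replicate null cohorts (both groups share the same
  κ), 10 subjects per group, 144 trials per deviant, 24 sensor pairs,
  interaction test with 500 permutations; a replicate is a false positive
  when any cluster reaches p ≤ α/2 on either tail (overall α = 0.05).  The
  observed rate's 95 % Clopper–Pearson interval is required to contain the
  nominal level.
* **Power**: detection probability of the interaction (per-tail α = 0.025)
  as a function of κ ∈ {0, 0.2, 0.4} under the feature-selective default
  (musicians get κ on FI/LF/FIL; IL and non-musicians stay at zero), 12
  subjects per group, common random numbers across the grid.  Checks:
  monotone non-decreasing power in κ; FI and LF reach high power at
  κ = 0.4 while IL stays at the null rate.
* **κ recovery**: the estimator described below, 25 subjects, trial counts
  72/144/288; requires |bias| < 0.05 at 144 trials and strictly decreasing
  RMSE.

For speed these experiments draw each condition's *trial mean* directly
(the mean of n iid realizations of a Gaussian process is one realization at
σ/√n), which is distributionally identical to simulating trials and
averaging on artifact-free data; jump rejection is exercised separately by
its own tests.  The full-trial path (with artifact injection and rejection)
is what `run_study` uses.

## The subadditivity estimator

κ̂ is a regression-style inner-product ratio between empirical and modeled
waves over the analysis sensors × window, with three choices that remove
known biases:

1. **Linear scale**: maps are built from the *uncombined* gradiometer
   channels (averaged, filtered, baselined, not rectified).  On the
   combined scale the rectification of evoked-level noise is
   signal-dependent and biases the ratio; on the raw channels the additive
   model is exactly linear.
2. **Split-half cross-validation**: empirical and modeled waves are built
   twice from disjoint trial halves (standards split too).  Same-half
   products are biased — the modeled autocovariance is inflated by its own
   noise (attenuation) and empirical×modeled shares the standard average —
   whereas cross-half products are unbiased.
3. **Group-mean ratio**: the half-maps are averaged across subjects before
   the ratio, suppressing subject-level noise×noise terms by n²;
   κ̂ = 1 − (⟨ē₁, m̄₂⟩ + ⟨ē₂, m̄₁⟩) / (2⟨m̄₁, m̄₂⟩).

On noise-free data κ̂ = κ exactly; at the default SNR the measured bias is
below 0.01 with RMSE ≈ 0.02 at 144 trials (n = 25).

## Degenerate inputs, tie-breaks, tolerances

* Peak and neighbour ties in sensor selection break to the lowest pair id.
* A t denominator of zero yields t = 0 (no spurious clusters from
  zero-variance samples).
* All Monte Carlo machinery is seeded; a study run derives every stage seed
  from one master seed via seed sequences, making report files
  byte-identical across runs.
* The additivity identity is asserted at 1e−8 absolute on default-scale
  data; linear-stage equivalences at 1e−9; oracle equalities exact to
  rounding.

## Known limitations

* The generative model is deliberately minimal: no overlap between
  standard-response and mismatch topographies, a single shared mismatch
  latency/width, no secondary 200–300 ms component by default, no 1/f or
  physiological noise.  Conclusions from passing tests concern the
  analysis machinery, not auditory physiology.
* The jump-rejection rule is validated only against the synthetic step
  artifact model.
* No source reconstruction, no continuous-recording artifacts
  (head-movement compensation, tSSS, ICA cleaning), and no ingestion of
  vendor MEG file formats; the HDF5/TSV containers are the exchange
  boundary.
* Exhaustive permutation is limited to 14 subjects (independent) or 16
  pairs (dependent) by combinatorial growth.
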