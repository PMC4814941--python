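# Methods

`pulsedx` analyses radial-artery pulse recordings taken at the six
traditional palpation sites (zuo/you = left/right wrist; cun, guan, chi =
distal to proximal): band-limiting, heart-cycle segmentation, multi-cycle
harmonic modelling, a fixed 193-parameter feature vector, and three
two-group classifiers. A synthetic-cohort generator with exact ground truth
makes every stage testable. This note records the models, the parameters
that matter, the numerical choices, and what the synthetic experiments do
and do not demonstrate.

## Pretreatment

Each channel is band-limited to 0.5–48 Hz by masking in the cosine-transform
domain: orthonormal DCT-II of the whole record, coefficients with equivalent
frequency f_k = k·fs/(2N) outside [lo, hi] zeroed (the k = 0 term always
when lo > 0), inverse transform back. The lower edge removes respiratory
baseline wander and DC; the upper edge removes sensor noise while keeping
every harmonic of a ≤180 bpm pulse up to order 12 (12 × 3 Hz = 36 Hz < 48).

Masking is an orthogonal projection, hence exactly linear and idempotent.
Two consequences are worth knowing:

* a sub-band tone is removed essentially completely *as a spectral
  component* (< 0.2 % residual at 0.2 Hz), but the hard mask rings near the
  record edges — for a worst-phase 0.2 Hz tone, broadband residual RMS is
  2.5–3.6 % concentrated in the first/last ~2 s, ~1 % in the interior. No
  projection filter can avoid this; an optional raised-cosine band edge
  (`taper_hz`) is available but in practice keeps *more* near-cutoff
  leakage;
* the mask edges are inclusive, and the frequency mapping above is the
  DCT-II convention; both are configuration, not physics.

Baseline alignment (`zero_align`) subtracts the piecewise-linear
interpolation of the signal values at the detected cycle onsets, so every
cycle starts at zero without changing intra-cycle amplitude differences.
Before segmentation a record-minimum fallback exists for visualization only.

## Cycle segmentation

Onsets (pulse feet) come from the signal's speed and acceleration. The
signal is smoothed by a ~20 ms moving average; systolic upstrokes are the
dominant maxima of its first derivative, thresholded at half the median
upstroke speed with a refractory distance of 60/hr_max s. The refractory
distance is then locked to the dominant cardiac period estimated from the
signal autocorrelation over the 40–180 bpm band — the fundamental lag always
beats its subharmonics because the odd-harmonic energy contributes
negatively at half-period lags, which prevents double detection on
bisferiens-like waveforms with a very strong second harmonic.

Each foot is localized by the intersecting-tangent rule: the tangent at the
point of maximal speed is intersected with the level of the preceding
diastolic minimum, then refined to the local minimum within ±25 ms. The raw
argmin of the nearly flat diastolic tail jitters by ~6 samples under 2 %
noise; the tangent-plus-refinement estimate is accurate to ~1 sample.

Cycles are half-open sample intervals [onset_i, onset_{i+1}), 0-based; the
partial head and tail are discarded; cycles whose period falls outside
60/180–60/40 s are dropped and counted (a `permissive` flag keeps them).

## Harmonic model and aggregation

Every cycle of length L is fitted separately by ordinary least squares to

    y_t = a0 + Σ_{k=1..12} ( a_k cos(2πkt/L) + b_k sin(2πkt/L) ),  t = 0..L−1,

which requires L ≥ 25. Per-channel coefficients are aggregated across the n
cycles with period weights T_i / T (T = Σ T_i):

    a_k = Σ_i (T_i/T) a_{i,k},   b_k = Σ_i (T_i/T) b_{i,k},

giving one representative cycle model per channel; amplitudes
C_k = √(a_k²+b_k²) and phases F_k = atan2(b_k, a_k) ∈ (−π, π] (radians)
follow. On noiseless cycles the per-cycle fit is exact to machine precision
and the aggregate recovers a common generating template to < 1e−6 relative
error; under i.i.d. noise the coefficient standard error is the OLS
closed form σ·√(2/L).

## Time-domain landmarks

Landmarks are read from the reconstruction of the aggregated model over the
mean cycle length (smooth and band-limited by construction). The main
(percussion) wave is the global maximum (h1, t1; amplitudes measured above
the cycle-onset value). The dicrotic notch is the deepest local minimum in
the window [0.22 T, 0.65 T] — the inter-wave dip sits earlier and
aggregation ripple lives later — giving h4, t4; the next local maximum is
the dicrotic wave (h5, t5). The tidal wave (h3) is the highest local
maximum between main peak and notch, or, when it is only a shoulder, the
flattest point of the descent (flagged). If no notch exists at all (e.g. a
near-sinusoidal cycle) it is placed at the point of maximal upward
curvature in the window and all three landmarks are flagged; landmark
extraction degrades to flagged fallbacks, never to an exception. w is the
width of the region around the main peak where the amplitude stays above
(2/3)·h1, with sub-sample interpolation at the crossings (the classical
"width at one third from the top"; the fraction is configurable).

Small local minima are ignored: extrema whose excursion is below 2 % of h1
are treated as ripple.

Amplitude landmarks are homogeneous of degree 1 under waveform scaling;
times, widths and amplitude ratios of degree 0.

## The 193-parameter vector

Per channel: C1..C12, F1..F12, and eight time-domain parameters
{h1, t1, h3/h1, h4/h1, h5/h1, w, t4, t5} — 32 parameters × 6 channels — plus
one global parameter t, the mean cycle period across channels: 193 named
scalars in a fixed order (`pulsedx.io.feature_names()`). Names follow
`<param>_<side><place>` (e.g. `C2_zuocun`, `t4_zuochi`); the global period
is named `t`. The eight-parameter set is the package's reading of the
standard sphygmogram family; which parameters beyond {h1, t1, h4/h1, h5/h1,
w, t4} fill the count, and that the global period is the "+1", are
documented choices.

## Classifiers

All three operate on the feature matrix with columns centred (and, for PCA
and LASSO, scaled to unit SD) on the training rows only; raw feature scales
span four orders of magnitude (C ~10³ instrument units vs ratios ~1), so
unscaled PCA would be meaningless.

**PCA thresholding.** Principal components of the standardized matrix;
for a chosen component (or each of the first ten in search mode) the score
cut minimizing training misclassification is found by brute force over
midpoints of adjacent sorted scores. A two-component mode classifies by
Fisher's linear discriminant on a score pair.

**Designed-regressand least squares with EFBLS.** The regressand
Y = (n2,…,n2, −n1,…,−n1) (value n2 on the n1 group-1 rows, −n1 on the n2
group-2 rows) sums to zero and makes OLS equivalent to the
canonical-correlation-optimal two-group discriminant. Regressors are chosen
by a greedy forward search — at each step add the feature with the largest
residual-sum-of-squares reduction, computed by Gram–Schmidt projection so
collinear candidates contribute nothing — followed by a backward pass that
drops any feature whose removal costs less than 1e−4 of the current RSS.
Selection stops at 7 regressors (the small-cohort overfitting cap), when no
gain exceeds the tolerance, or when the fit is numerically perfect
(RSS ≤ 1e−12·‖Y‖²). As an alternative to the fixed cap,
`calibrate_k_max` lowers the cap until label-permuted data no longer yields
held-out accuracy above 0.65 — a permutation guard with the same intent.

**LASSO.** min_β ‖Y − Zβ‖² + λ Σ|β_j|, solved by cyclic coordinate descent
with soft-thresholding; convergence when the largest coefficient change in
a full sweep is below 1e−8 (full sweeps alternate with cheap active-set
sweeps). The path-entry bound consistent with this objective is
λ_max = 2·max_j |Z_jᵀY|; above it β = 0 exactly, and at λ = 0 the solution
equals unpenalized least squares on full-rank designs. λ is chosen by
K-fold cross-validation (default 10 folds) on a 100-point grid log-spaced
four decades down from λ_max, under the one-standard-error rule (largest λ
within one SE of the minimum CV error); the path stops early once the
active set exceeds 0.9 n, where the solution is no longer unique and never
competitive in CV. CV-internal solves use a tolerance of 1e−6 scaled by
max|Y|.

**Evaluation.** Classification by predicted index: group 1 when Ŷ > 0 (the
regressand's mean), orientation auto-corrected and recorded; accuracy and
misclassification sum to 1 exactly. Group separation gets a two-sided
label-permutation p-value on the difference of group means of Ŷ with
add-one smoothing, p = (b+1)/(n_perm+1). Feature stability is reported over
R = 20 rounds of stratified 75/25 train/holdout subsampling: "used times"
(rounds selecting the feature, of R), "importance" (mean absolute
standardized coefficient over selecting rounds), and the raw feature mean
and SD over all subjects — the latter computed over the pooled cohort, a
documented reading since per-group moments would be equally defensible.

## Synthetic cohorts

The generator emulates what the pipeline must survive: quasi-periodic
cycle trains with beat-to-beat period jitter, respiratory baseline wander,
sensor noise, and rich between-subject morphological variability.

A canonical cycle shape is defined by landmark knots (onset, systolic peak,
inter-wave dip, tidal wave, dicrotic notch, dicrotic wave, diastolic tail)
joined by monotone piecewise-cubic (PCHIP) interpolation — so each interior
knot is an exact local extremum — and projected onto 12 harmonics; the 25
coefficients are the generating template and rendering is their exact
evaluation, so ground truth is available in the same vocabulary the
extractor measures. Defaults (order-of-magnitude ADC units, peak ≈ 1000):

| parameter | default | meaning |
|---|---|---|
| fs, duration | 200 Hz, 40 s | instrument-like record |
| mean period | 0.8 s ± 0.04 between subjects | resting 75 bpm cohort |
| beat jitter | 0.02 s SD, truncated to 40–180 bpm | "periods are not exactly the same" |
| wander | 0.25 Hz, amplitude 150 | breathing baseline |
| noise | SD 20 (2 % of peak) | sensor noise |
| knot jitter | 8 ms time SD, 5 % amplitude SD | per-subject landmark variation |
| harmonic jitter | 5 %·√k amplitude, 0.02·k rad phase | per-subject shape detail |
| channel gain | 5 % SD | per-site coupling |

Three modelling decisions matter for interpretation:

* **systolic timing is rate-insensitive in seconds** — peak/notch/dicrotic
  knots keep their absolute timing while diastole absorbs the subject's
  period, matching the physiology of ejection time and making t4 an
  informative feature rather than a proxy for heart rate;
* **templates are foot-aligned** — after any coefficient surgery the global
  minimum is rotated to t = 0, because rendered cycles start at t = 0 and
  the extractor references every phase and landmark to the detected foot;
* **shapes are screened for plausibility** — jitter draws producing a
  pre-systolic dip (no well-defined foot) are redrawn, up to 20 times; this
  is the analogue of the quality screening any real collection protocol
  applies.

Group effects are planted on named features of the generating template:
C_k shifts scale the harmonic-k amplitude, F_k shifts rotate its phase, and
time-feature shifts move the corresponding knot by an anchored
piecewise-linear warp (neighbours move proportionally, landmark ordering
preserved). The default contrasts mirror the kind of sparse discriminants
the pipeline is designed to mine: an FLD-like group shifted on
{C2_zuocun +130, t4_zuochi −0.13 s, F2_youchi −0.55 rad} and a
cirrhosis-like group on {C2_youguan −100, F1_youchi −0.45 rad}. These sizes
realize ≈4–6 within-group SDs per feature — a deliberately large effect,
the largest that keeps every waveform a single-footed pulse (pushing C2
much further produces bisferiens-like double feet).

One cohort seed governs everything; per-subject substreams derive
deterministically from (seed, subject id), so any subject regenerates
identically in isolation.

## What the synthetic experiments show — and what they do not

On these cohorts the pipeline (a) recovers generating coefficients to
machine precision without noise and to <1e−6 after aggregation, (b) finds
≥95 % of cycle onsets within ±3 samples at 5 % period jitter and 2 % noise
(in practice ~100 % within 2), and (c) at the study-scale group sizes
(98 vs 38) both EFBLS and cross-validated LASSO select all planted features
in ≥18 of 20 subsampling rounds with held-out accuracy above 0.95, while on
effect-free cohorts all three classifiers average 0.40–0.60 held-out
accuracy over 20 independent cohorts (chance, as they should).

Caveats. First, selection stability is a property of the cohort
realization, not only of the method: across independent cohorts one planted
feature occasionally drops to ~14/20 rounds for EFBLS (about one cohort in
seven at these effect sizes), because greedy forward selection saturates
once another feature's realized contrast is extreme; LASSO's selection was
stable in every cohort tried. The packaged experiment therefore fixes one
canonical cohort. Second, group sizes matter: with 193 candidate features
and ~30 training rows, the best of ~190 spurious partial correlations
(~0.5) rivals a 3-SD planted feature's residual signal — stable recovery of
a three-feature set is statistically ill-posed at 20 subjects per group and
well-posed at the study's sizes. Third, the generator is a waveform
phantom, not hemodynamics: no Windkessel/transmission-line physics, no
pathophysiology of liver disease, effect sizes are constructions. Passing
these tests shows the *pipeline* is correct and well calibrated; it says
nothing about how real patient groups differ.

## Degenerate inputs and numerical conventions

Cycles shorter than 25 samples are rejected (12-harmonic identifiability);
flat signals raise segmentation/feature errors; zero-variance feature
columns are centred, given unit scale, and flagged; rank-deficient or
duplicate regressors contribute zero forward gain and are skipped; LASSO
with λ above the entry bound returns the exact zero vector; leave-one-out
CV on tiny cohorts runs with degenerate folds. Phases are radians in
(−π, π]; sample indexing is 0-based; cycle intervals are half-open. CSVs
are written with 17 significant digits and read with round-trip float
parsing so file round-trips are bitwise exact.
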