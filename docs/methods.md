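# Methods

This note documents the models, procedures and numerical choices behind
`lumifrontal`, in the order the pipeline applies them, followed by the
synthetic-data model and its limits.

## Stimulus protocols and alignment

A step session presents each of 7 log intensities (default grid
9.4–15.4 log photons cm⁻² s⁻¹, melanopsin quantum catch as the intensity
proxy) as 20 repetitions of 10 s light / 10 s darkness, ascending, for a
2800 s stimulation block; a 10 s dark lead-in precedes the first pulse so
the first repetition's baseline window lies inside the recording. A ramp
session repeats a bi-phasic epoch in which log intensity rises linearly
over 30 s (default 2-log span) and falls symmetrically over the next 30 s.
Commanded onsets precede actual light emission by a measured 116 ms;
`align_stimulus` shifts all onsets once (a flag guards against double
application).

## PSTHs and window rates

Spikes are binned into half-open bins [t, t+Δ) with edges aligned to light
onset, over the window [−4, +16] s (4 s pre-onset, the 10 s stimulus, 6 s
post-offset); the default Δ is 0.1 s, so total spike count is conserved
exactly and rate = count/Δ. Repetitions whose pre-window precedes the
recording start are excluded and recorded. Baseline normalisation subtracts
each repetition's mean rate over [−3, 0) s from all its bins (response
minus baseline; the opposite sign convention would invert every figure one
would draw from it). Window rates: FR₀ over [−3, 0), FR₁ over [0, 1), FR₂
over [4, 10) s. Units with session-wide mean rate not exceeding 0.5 Hz are
dropped (strict inequality).

## Light-responsiveness

Per intensity, up to 3 outlier response records (of 20) are removed from
the early and steady-state records separately, by the scaled-MAD rule
|v − median| > 3 × 1.4826 × MAD, most extreme first; when MAD = 0 any value
differing from the median counts as an outlier. Removing a response record
removes its baseline partner for that test only, preserving pairing. The
surviving pairs from the three highest intensities are pooled (≤ 60) and a
paired two-sided permutation t-test (sign-flipping the paired differences;
exhaustive when 2ⁿ ≤ n_perm, else 10,000 Monte-Carlo flips with the
add-one-corrected p) decides transient (FR₀ vs FR₁) and persistent
(FR₀ vs FR₂) responsiveness at α = 0.05. Units with fewer than 6 surviving
pairs are flagged unclassifiable.

## Intensity encoding

The mean FR₂ per intensity (baseline-subtracted by default; an absolute-FR
mode exists for pooled-population curves) is fitted with the Naka–Rushton
function R(E) = R_max·10^(nE)/(10^(nE)+10^(nK)), evaluated in the
overflow-safe form R_max/(1+10^(n(K−E))). Response direction is the sign of
the Spearman correlation (ties → increasing); decreasing responses are
negated before fitting and reported with direction −1. The fit is bounded
least squares (trust-region reflective with analytic Jacobian; init
R_max = max|response|, n = 1, K = median intensity; bounds n ∈ [0.05, 10],
K ∈ [E_min−3, E_max+3], R_max ∈ [0, 10·max|response|]). Optimiser failure
yields converged = False and infinite RMSE, excluding the unit downstream.

The encoding test refits 100 random permutations of the responses along the
intensity axis (drawn uniformly with replacement; the identity permutation
is allowed) and flags the unit when the real RMSE is strictly below the 5th
percentile of the null RMSEs. The percentile uses the lower order statistic
(the 5th smallest of 100), which makes the false-positive probability
exactly 5/101 ≈ 4.95% under exchangeability; an interpolated percentile
would slightly exceed the nominal 5% bound. Inside the test, the real curve
and every shuffle are fitted by one shared batched routine (a projected
Levenberg–Marquardt over all curves simultaneously, with the same bounds
and initialisation as the single-curve fit) so that the comparison stays
exchangeable under the null; the reported parameter estimates come from the
scipy fit. The batched and single-curve fits agree to a median RMSE ratio
of 1.0 on noisy data, and the batching is what makes 2000-unit calibration
runs take seconds rather than hours.

Threshold intensity at criterion c is the exact inverse
E* = K + (1/n)·log10(c/(R_max − c)), defined for c < R_max. The dynamic
range is reported as the interval over which the cumulative integral of
dR/dE accumulates from 10% to 90% of its total; because that cumulative
integral is proportional to R itself, the interval is where R crosses
0.1·R_max and 0.9·R_max, i.e. K ∓ log10(9)/n with width (2/n)·log10(9).
(The alternative reading — percentiles of the derivative's values — has no
natural interval interpretation; the mass-quantile reading is a documented
package decision.)

Ramp epochs are analysed by fitting the same sigmoid to the 1 s-binned mean
FR against the instantaneous log intensity within each phase, with the same
shuffle-null significance rule. The transition lag is the time from the
intensity peak (30 s) to the trace's extremum (maximum for enhanced,
minimum for suppressed; censored when the extremum sits on a trace edge).
The light-history test compares per-unit mean FR over [23, 30) vs
[30, 37) s (7 bins each) with the paired permutation t-test.

## Functional typing

Features are baseline-subtracted mean PSTHs at the highest intensity,
re-binned at 0.2 s (100 bins). PCA is centred, unscaled; the smallest
number of components reaching ≥ 85% cumulative variance is retained.
Full-covariance Gaussian mixtures with k = 1..8 are fitted to the scores
and the k minimising AIC is selected. Each mixture is fitted by a single
k-means-initialised EM run (deterministic per seed) with a covariance ridge
of 1% of the mean per-dimension score variance. Two alternatives were
evaluated and rejected: best-of-10-restarts EM systematically inflates the
likelihood of over-large k (verified on ideal, well-separated Gaussian
clusters at n = 240, where it selects 5–8 components in most runs) and
thereby destabilises the AIC minimum; and a purely nominal ridge (1e-6)
leaves AIC at the knife edge between k and k+1. With the single-run EM and
the variance-scaled ridge, the generative component count is recovered
reliably. Cluster-to-archetype names come from greedy best-correlation
matching between cluster-mean PSTHs and noiseless archetype templates;
assignment of new units projects through the frozen PCA and takes the
maximum posterior responsibility, ties breaking to the lower component
index.

## Cell class, dynamics, anatomy, statistics, photometry

Waveform metrics (spontaneous FR, trough-to-peak duration, trough-to-peak
ratio, trough half duration) are min–max normalised to [0, 1], reduced by
PCA to ≥ 95% variance, and split into two Ward-linkage clusters; the
cluster with the shorter mean trough-to-peak duration is FS. The linkage
choice (unstated in the underlying protocol) is Ward on Euclidean distances
in PC space.

Timing descriptors operate on across-rep mean PSTHs; the "1 SD" criterion
uses the SD across the baseline bins of the mean PSTH (across-bin rather
than across-rep, since all descriptors are defined on mean traces). The
late-response latency localises the largest sustained supra-1-SD epoch
within [1, 10] s and walks back to the start of its crossing run. The
ON-peak latency is the time of the extremum of a 10 ms-binned mean PSTH
within [0, 2] s, valid only if it exceeds baseline + 1 SD; on a bright
transient the first 1-SD crossing precedes the peak by tens of
milliseconds, so the peak time — not the crossing — is the quantity
comparable to reported ON-peak latencies. Decay time is the first
post-offset bin re-entering the baseline ± 1 SD band and staying for ≥ 2
bins, censored at 6 s. Ramp traces are smoothed with a 5 s centred moving
average (truncated at edges); local extrema are prominence-filtered sign
changes of the first difference.

The probe track is the first principal axis of the annotation cloud
(total least squares); units sit at their nearest recording site's
arc-length position on the line (50 µm site spacing), extrapolated and
flagged beyond the annotated extent. Affiliation draws 100,000 points from
an axis-aligned Gaussian with SDs (32, 85, 39) µm on (AP, DV, ML); the
probability per region is the fraction of points in that region's voxels
(floor(coord/voxel), 0-based), with remaining mass under "outside", so the
probabilities partition unity exactly. Incidence is reported per session
(fraction flagged, mean ± SD across sessions) and pooled per region after
max-probability hard assignment, optionally keeping only units whose
winning probability exceeds 0.9.

Permutation tests use the Welch t statistic (robust to the
heteroscedasticity that motivates permutation testing in the first place),
with exhaustive enumeration whenever the permutation space fits within
n_perm (the exact tail fraction is then reported; otherwise the add-one
corrected Monte-Carlo p). tmax correction records, per joint permutation,
the maximum |t*| across the family. χ² is Pearson without continuity
correction; φ for 2×2, Cramér's V otherwise; η² = SS_between/SS_total for
the one-way permutation ANOVA.

Pigment templates follow the Govardovskii A1 nomogram (α band plus the
Gaussian β band), peak-normalised; default λ_max: rod 498, M-cone 508,
S-cone 360, melanopsin 480 nm. Quantum catch is the trapezoidal integral of
irradiance × lens transmission × sensitivity on a common 1 nm grid
(linear resampling; zero outside support). The shipped lens-transmission
curve is a smooth synthetic logistic template for tests and demos, not a
measured curve. Photoisomerization rates scale the per-µm² catch by the
collecting area (rod 0.85 µm², cone 1 µm²).

## Synthetic-data model

Each unit is an inhomogeneous Poisson process with rate
r(t) = max(0, baseline + onPeak + offPeak + sustained), drawn exactly by
thinning against a constant upper bound. The sustained component's
asymptote at intensity E is ±Naka–Rushton(E; R_max, n, K), approached with
a first-order time constant τ and decaying likewise after light offset.
ON/OFF transients are gamma-shaped bumps with mode at the peak latency
(0.09 s) and SD equal to the width parameter (0.05 s), their amplitude
scaled by a second, more sensitive sigmoid (rod/cone-driven transients
saturate below the melanopsin-driven sustained component; gain K 12.5,
slope 1). Under ramp protocols the sustained drive is the Naka–Rushton
value of the instantaneous intensity passed through a first-order low-pass
(exponential-integrator stepping at 20 Hz), which for a triangular log-
intensity input yields a closed-form transition lag of τ·ln 2; ramp
responses carry no transients.

Default archetypes: E_on-off (baseline 2 Hz, ON/OFF peaks 45/30 Hz,
R_max 6, n 1.5, K 13.2, τ 0.5 s), S_on-off (8 Hz, 35/25 Hz, R_max 5, n 1.5,
K 13.4, τ 0.5 s), E_on (2 Hz, ON peak 6 Hz, R_max 8, n 1.2, K 13.6,
τ 2 s), S_on (8 Hz, ON peak 5 Hz, R_max 4, n 1.0, K 13.8, τ 2 s), plus a
NULL archetype (3 Hz, no response). Baselines are RS-like (2 Hz) for
enhanced and FS-like (8 Hz) for suppressed archetypes — suppression needs
headroom above the zero-rate floor; K values span 13.0–14.0 and slopes
1.0–2.0, consistent with reported thresholds and latencies. Prominent
ON/OFF transients for the ON-OFF archetypes and small ON peaks for the slow
ON archetypes are what make the four types separable in PSTH space, as they
are in recordings.

Per-unit heterogeneity has two parts. Parameter jitter is Gaussian
(baseline ±10%, R_max ±7%, n ±5%, K ±0.12 log units, transient amplitudes
±7%, τ ±20%, ON-peak latency ±10%, clipped to valid ranges): within-type
variability is unimodal around the type's centre, which is also what a
mixture model assumes of real type scatter. Second, each unit carries an
idiosyncratic response fingerprint: a zero-mean Gaussian process (RBF
kernel, SD 0.3, length scale 0.8 s) over [0, 16] s after onset, riding the
sustained component's rise/decay envelope with a per-archetype gain
(9 spikes/s for enhanced, 2.5–3.5 for suppressed — the firing floor leaves
suppressed units less modulation room), tapered at the window edges and
constrained to exactly zero mean over the steady-state window. The
fingerprint gives the population the many-dimensional response variability
real populations show (no two neurons share an identical response kernel)
— without it, 85% of population variance collapses onto one or two
principal components and mixture-order selection becomes unstable — while
the zero-steady-state-mean constraint leaves every FR₂-based quantity
(responsiveness, sigmoid fits, K recovery) untouched. NULL units have no
fingerprint; the fingerprint is part of the light-evoked response.

The calibration generator for the encoding test draws each unit's 7
per-intensity mean FR₂ values i.i.d. from a Gamma(4) distribution with
mean 3 spikes/s (a realistic steady-state rate scale; the calibration is
distribution-free under exchangeability, so the choice only sets the
noise scale the fitter sees).

What the generator does not emulate: bursting and refractory structure
(spiking is Poisson), slow non-stationarities and behavioural-state
drift, spike-sorting artifacts, correlated noise across units, and
electrode drift. Tests passing on this generator therefore validate the
analysis arithmetic and its statistical calibration under the stated
assumptions — not robustness to those real-data complications (the
outlier-removal step exists for exactly such contamination but is
exercised here only with constructed outliers).

Waveform metrics are drawn from two separated 4-D Gaussians (FS: narrow
trough-to-peak ≈ 0.29 ms, high spontaneous rate ≈ 11 Hz; RS: broad
≈ 0.68 ms, low ≈ 2.5 Hz), clipped at small positive floors. The miniature
atlas is an integer-labelled voxel volume built from named non-overlapping
boxes, with annotation points sampled along a ground-truth line plus
isotropic jitter — a synthetic stand-in for a reference atlas volume,
sufficient for testing affiliation arithmetic; real NRRD atlas volumes are
read through the same interface.

## Problem sizes and determinism

Population experiments use 60 units per archetype (240 total) for typing,
200 units for semi-saturation recovery, and 2000 units for the encoding
false-positive calibration; the full test suite and the acceptance script
each complete in well under a minute of CPU. Every stochastic stage takes
an explicit seed; populations derive per-unit streams from a master
generator, so identical configurations reproduce byte-identical outputs.

## Known limitations

- The encoding classifier's null uses shuffles with replacement, so at
  B = 100 the attainable significance resolution is 0.01 and duplicate
  permutations are possible.
- AIC-based mixture-order selection remains a finite-sample procedure; the
  single-run-EM + scaled-ridge configuration recovers the generative k
  reliably at n ≈ 240, but very unbalanced or strongly non-Gaussian type
  structures could still shift the minimum.
- Latency/decay descriptors are defined on mean PSTHs and quantised to the
  bin width; on noisy single units the 1 SD criterion can trigger on noise
  (the descriptors are meant for units already classified as responsive).
- `pre_post_transition_compare` assumes all units share the ramp timing;
  protocols with unit-specific timing are out of scope.
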