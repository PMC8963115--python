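# Methods

This note documents the models and numerical choices behind `cyresick`:
what each stage assumes, which parameters matter, and what the synthetic
generator does and does not emulate.

## Scene registry and contrasts

The packaged table (`data/scenes.csv`) encodes 52 flight-navigation VR
scenes over two backgrounds (urban, astrospace), simple (single-component)
or complex camera movement built from yaw/roll/pitch rotations and
forward/backward/lateral/vertical translations, translation speeds of 4 or
9.2 m/s, optional acceleration ramping to 160% of the initial speed,
internal fields of view of 30/45/90°, an optional cockpit frame reference,
nominal durations of 13 or 24 s, and a controllability flag.  Controllable
scenes end when the user reaches the endpoint, so their durations are mean
measured experience times, marked by `duration_measured`; their category
total (144.8 s) is likewise a measured mean, while the uncontrollable
categories total exactly 234 s (18 × 13) and 371 s (23 × 13 + 3 × 24).
Rotation rates are deliberately not modelled — the scenes vary rotation
*presence*, not rate — and six scenes (S219–S223, S226) are carried in the
table without entering any contrast.

`validate_contrast` replays the matched-pair design mechanically: within
every cross-condition pair all comparable attributes must be equal except
those mapped to the contrast's factor.  The controllability factor also
releases duration fields, since controllable durations are measured rather
than nominal.

## Ordinal rating model (synthetic)

Ratings are generated by a cumulative-link (thresholded-latent) model: for
participant i and scene j,

    z_ij = 1 + motion(j) + modifiers(j) + w_s · z_MSSQ(i)
           + w_ac · [middle-aged(i) ∧ controllable(j)] + ε_ij,
    ε_ij ~ N(0, σ²),   score = 1 + #{c ∈ {1.5, 2.5, 3.5, 4.5} : z_ij > c}

The motion term pools per-component severity weights sublinearly (largest
weight plus 0.15 × the rest), reflecting that complex motion is worse than
simple motion but far from additively so.  Default weights (latent units):
yaw 1.13, roll 2.04, pitch 1.90, forward 0.11, backward 0.28, lateral 0.15,
upward 0.31, downward 0.26; fast speed +0.42, acceleration +0.30, long
duration +0.55; small FOV −0.10, frame reference −0.28, controllability
−0.45; susceptibility weight 0.25 per panel SD of the MSSQ total;
age × controllability interaction +0.50; noise σ = 0.75.  With cut points
at k + 0.5 and symmetric noise the expected score approximately equals the
latent value in mid-range, so the simple-motion condition means land in the
1.1–3.0 band typical of such studies and every within-factor direction
(roll > pitch > yaw; backward > forward; vertical > forward; faster,
accelerating and longer worse; small FOV, frame reference and control
protective) is realized.  Two caveats: floor effects inflate means near 1,
and complex-motion scenes come out higher (~3.3) than real studies report
for their FOV-baseline conditions, because real rating data are strongly
non-additive across factors; the package therefore asserts within-contrast
directions, never cross-factor absolute levels.

The panel reproduces a 154-participant demographic composition (43 young
men, 63 young women, 28 middle-aged men, 20 middle-aged women; "young" is
under 30) by largest-remainder apportionment, so other panel sizes deviate
from the mix by at most one per cell.  Synthetic SSQ responses reuse the
same latent severity per scene category, converted to 16 clipped-Poisson
item levels, which propagates the susceptibility and age × controllability
structure into every subscale.

## Frames and ground-truth motion

`render_scene_motion` advects a smoothed random-dot texture by the analytic
flow each camera component induces under a pinhole model: translations give
uniform lateral/vertical flow or radial expansion/contraction scaled by
speed (ratio 9.2/4 = 2.3 between the fast and moderate settings), yaw and
pitch give near-uniform lateral/vertical flow, roll rotates about the image
center, the FOV scales the projection, and acceleration ramps the
translational magnitude linearly to the terminal rate (1.6) by the final
field.  Frames are produced by inverse-warping the base texture along the
accumulated displacement — exact for uniform flow, a small-displacement
approximation for spatially varying flow.  Gains are set so displacements
stay within a few pixels per frame on the default 64×64 grid, inside the
comfortable range of dense flow estimators.  Ground-truth fields are
returned alongside the frames; all feature-level guarantees are therefore
estimator-independent via the passthrough backend.  Dense estimation uses
scikit-image's iterative Lucas–Kanade by default (TV-L1 available), which
recovers a 2 px translation on these textures to within a few percent.
The generator does not attempt photorealism, depth structure, independent
object motion, or head-motion reafference.

## Visual features

The six features follow the percentile-pooling definitions exactly: all
variances are population variances (divide by the pooled count, T·N or
T·⌊N·p⌋), matching the mean-pooling normalizers.  Percentile sets are
selected per frame (the thresholds are frame-indexed), with k = ⌊N·p⌋
forced to at least 1, and exact-k rank selection with ties broken by
ascending pixel index so set sizes are deterministic.  When features are
computed from T frames via estimation, the T of the equations is the T−1
flow fields.  Invariants asserted in tests: f3 ≥ f1 ≥ f5, and scaling all
vectors by s scales (f1, f3, f5) by s and (f2, f4, f6) by s².

## EEG model and pipeline

Synthetic EEG sums band-limited Gaussian noise per channel with relative
band powers following channel-specific linear trends in the sickness level,
centered at level 3.  The six default trends mirror the band-power features
known to track cybersickness severity: delta share rising on Fp1
(+0.020/level), Fp2 (+0.020) and T4 (+0.015); beta share falling on Fp1 and
T4 (−0.012); gamma share falling on Fp2 (−0.008).  Unconfigured bands are
rescaled to keep the five disjoint shares summing to one, so configured
shares are realized exactly and slope recovery is unbiased up to filter
leakage (~±5%).  Optional eye-blink surrogates — correlated ~0.3 s
high-amplitude Gaussian bursts on the two frontal channels — exercise the
artifact-rejection path.

Preprocessing band-passes to 1–59 Hz with a 513-tap zero-phase FIR
(Hamming); the FIR's narrow transition bands make the operation
spectrally idempotent to well under 1% in relative band power, so features
are insensitive to whether an epoch arrived pre-filtered.  ICA is
scikit-learn's FastICA with 8 components and a fixed seed; the single
component with maximum sample kurtosis is removed.  On artifact-free
epochs the sources are near-Gaussian, where the fixed-point iteration
cannot converge *in principle*; the implementation retries once with a
fallback seed and then accepts the decomposition, since removing one
near-Gaussian component is low-energy (mean channel correlation with the
input ≥ 0.9) while a genuine high-kurtosis artifact is isolated well
before full convergence (burst-window variance reduced > 50% in tests).

Relative band power uses Welch PSD with 2 s Hann windows and 50% overlap —
long enough to resolve the 1–3.99 Hz delta band on 13 s epochs.  Bands are
half-open ([1,4), [4,8), [8,16), [16,32), [32,59), mu [8,12) as a sub-band
of alpha), and the denominator is total power over 1–59 Hz, so the five
disjoint shares sum to 1.  Mains notch filtering is assumed done at
acquisition and is not applied.

## ECG, GSR

Synthetic ECG is a stylized QRS template train (R wave with Q/S side
lobes, sampled on a peak-centered grid so jitter-free trains are
sample-exact) over a slow baseline wander; RR intervals are 60/bpm plus
Gaussian jitter.  Detection detrends, high-passes at 0.5 Hz, and picks
peaks above half the 99.5th-percentile amplitude with a 0.3 s refractory
distance.  SDNN and RMSSD use population denominators — this is what makes
the alternating-RR closed forms exact (RR alternating 0.9/1.1 s gives SDNN
0.1 s and RMSSD 0.2 s).  GSR is a tonic level plus phasic bumps, both
scaling with the sickness level; the feature is the time mean of the
moving-average-smoothed trace (edge-corrected so constants are preserved).

## Statistics

MOS applies the IQR rule (drop outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR]) per
analysis cell, then averages.  Factor contrasts average a participant's
scene replicates (the background twins) before the paired t-test;
Bonferroni families default to the number of comparisons within the factor
under test.  The three-step screen bins trials by score, runs one-way
ANOVA over populated groups, pairwise independent t-tests (adjacent level
pairs by default, matching the usual reporting; all 10 pairs behind a
flag) Bonferroni-adjusted by the number of tests performed, and fits the
group means on levels 1–5 by OLS (raw-trial regression available).
Under-populated groups (< 2 trials) yield NaN pairwise entries rather than
errors.  Both procedures hold their empirical type-I error at 5% ± 2% on
permuted data (verified over 1000 replicates).  Group comparisons are
plain independent two-sample t-tests per (timepoint, subscale) with star
flags at 0.05/0.01/0.001.

Percent effects are reported in two conventions used in this literature:
`percent_increase` (100·(a−b)/b, one decimal) for MOS differences and
`ratio_percent` (100·a/b, integer) for "x% more severe" group ratios.

## Prediction

Features are standardized with train-set statistics and fitted with an
epsilon-SVR (RBF kernel, C = 1, ε = 0.1, gamma = "scale"); hyperparameters
are fixed, not searched, and recorded in `SVR_PARAMS`.  Splits are by
participant — ⌊0.8·P⌋ participants train, the rest test, all rows of a
participant on one side — because the row counts of such studies
(123 × 52 / 31 × 52) are exact participant multiples; every trial asserts
the absence of participant leakage.  Labels are treated as numeric for
regression; evaluation is rank-based (SROCC) plus PLCC, and means over
trials are reported.  Per-trial seeds derive from the master seed through
`numpy.random.SeedSequence`, making summaries bit-for-bit reproducible.
Note that with integer labels a perfect SROCC of 1.0 is only attainable
when prediction ties coincide with label ties — e.g. when labels are a
function of the scene alone so duplicate feature rows receive duplicate
predictions — which is how the rank-preservation guarantee is tested.

## Problem sizes in the verification scripts

`scripts/acceptance.py` uses 200 random fields (N ≤ 1000, T ≤ 30) for the
feature-equation oracle, 100 EEG epochs per level (6 s each) for trend
recovery, 1000 replicates for type-I calibration, 100 CV trials on a
20 × 52 null dataset, and a 40-participant end-to-end synthetic study with
ground-truth flow features; the full run completes in about a minute on
one CPU.  These sizes are the package's own verification defaults — all
statistics scale in the usual √n manner if raised.

## Known limitations

* The generator's effect sizes are package defaults in latent units; no
  published number constrains the latent scale itself, so only directions
  and orderings — not absolute condition means — should be compared with
  real studies.
* EEG synthesis is spectral, not biophysical: no volume conduction, no 1/f
  background, no cross-channel source structure beyond the shared blink
  artifact, so ICA here faces an easier problem than on recorded EEG.
* Flow rendering composes spatially varying fields by summing per-frame
  displacements, a small-displacement approximation.
* MSSQ section scores are accepted as already computed; raw-item scoring
  conventions differ between questionnaire revisions and are out of scope.
* Statistical procedures are the classical ones (paired/independent t,
  ANOVA, OLS, Bonferroni); ordinal-regression or mixed-model reanalysis is
  deliberately not offered.
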