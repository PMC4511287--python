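# Methods

This note documents the models, defaults, and design choices behind
`taskneg`, and what the synthetic validation does and does not establish.

## Experimental protocol and design matrices

A run is a block design: each of several covert-task conditions appears in
five 21-s blocks, every block followed by a 12-s quiet-rest period, at
TR = 3 s. The repetitive-speech (RS) run carries three conditions
(3 × 5 × 33 s = 495 s = 8.25 min, 165 volumes, 15 rest epochs); the
verbal-fluency (VF) run carries four (660 s = 11 min, 220 volumes, 20 rest
epochs). Block order is pseudorandom per seed (the original order is not
public); a literal order can be supplied. Onsets are snapped to the volume
grid by rounding onset/TR, which is a no-op for the shipped durations.

Regressors are unit boxcars over a condition's epochs, shifted by a
hemodynamic lag and convolved with a canonical double-gamma HRF (response
gamma peaking at 5 s, undershoot gamma at 15 s, peak:undershoot ratio 6,
internal sampling 0.1 s), sampled at TR and peak-normalized. The lag is a
configurable onset shift, default 4.5 s, the midpoint of the 3–6 s range
assumed per participant; `glm.select_lag` optionally picks the lag in
{3, 4.5, 6} s that maximizes a subject's mean absolute task t, reproducing a
per-participant lag assumption without inventing a fitting scheme. The
sub-1.1-s auditory cues at epoch onsets are absorbed into baseline by
default (an optional cue regressor exists); there is no indication they were
modeled in the original analysis.

Rest is never a regressor. The intercept then estimates the pooled mean of
*all* rest periods, so a unit contrast on a task column is exactly the
"task versus average rest" comparison. The design adds six motion columns
(three translations mm, three rotations deg) when a trace is supplied, and
is checked for full column rank (collinear columns are named in the error).

## Preprocessing

* **High-pass**: per-voxel OLS projection onto sine/cosine pairs at 1–2
  cycles per run (default 2), constant preserved. A basis-regression filter
  rather than FFT-bin zeroing keeps the operation in the GLM family, is
  exactly idempotent, and handles any volume count.
* **Smoothing**: separable Gaussian, FWHM 6 mm default,
  σ = FWHM/(2√(2 ln 2)) per axis, reflection padding (avoids rim attenuation
  on small grids; configurable). Order of operations is high-pass then
  smoothing (the order is not stated in the source analysis; it is
  configurable and the two nearly commute here).
* **Concatenation control**: per-run voxelwise mean subtraction, temporal
  concatenation, and recording of run boundaries, so rest periods of
  different runs can be pooled into one baseline.

## Subject GLM and group inference

Plain OLS per voxel; serial correlation is *not* modeled — a known fidelity
limit (no autocorrelation correction is described for the original
single-subject GLMs either). The practical consequence, visible in the
simulations, is mild anticonservatism of single-subject t's under AR(1)
noise; the distribution analysis is symmetric in sign, so the antagonism
index is unbiased by it. Volumes around translational motion steps > 1 mm
are excluded from the fit (motion correction itself is upstream of this
package; traces are inputs). df = used volumes − rank(X). Zero-variance
voxels get NaN t with the betas retained.

Group maps are random-effects one-sample t's over per-subject contrast
values, df = N − 1. Degenerate voxels (zero between-subject variance,
nonzero mean) yield ±inf with a warning rather than an exception.

## Monte-Carlo cluster threshold

Per iteration: white N(0,1) noise on the mask grid → Gaussian smoothing at
the nominal preprocessing FWHM (6 mm; residual-smoothness estimation is
deliberately not implemented, the choice is logged and configurable) →
re-standardization to unit variance inside the mask (smoothing shrinks the
variance; without this step the voxel-p threshold would be conservative) →
two-tailed |z| thresholding → maximum cluster size under face adjacency
(connectivity 6 default; 18/26 available since the original estimator's
convention is unpublished). The minimum significant extent is the smallest
k with P(max cluster ≥ k) ≤ α over the null ensemble. α below 1/iterations
is refused. The published 98/116-voxel thresholds depend on the real data's
mask and smoothness and are out of scope; the estimator's *calibration* is
what is validated (fresh-null family-wise rate, monotonicity in FWHM and
voxel p).

## Voxel-distribution analysis

Histograms use bins from −6 to 6 in steps of 1; out-of-range t's are
clipped into the outermost bins by default so each subject's counts sum to
the mask size (the conservation makes the error-bar machinery well-defined;
drop-instead-of-clip is available and reported). Within-subject error bars:
Cousineau normalization (subtract the subject's mean over conditions, add
the grand mean) then SEM across subjects, inflated by √(C/(C−1)) (Morey's
correction), C = number of conditions.

Significant-voxel counting uses a single criterion `t_crit` on both signs;
the shipped default 2.819 equals the two-tailed α = 0.01 Student quantile at
df 22. The source analysis prints this value alongside "P < 0.05", so its
df/α provenance is ambiguous; both knobs are exposed and the quantile
function is tested at several (df, α, tails) combinations. The antagonism
index A = (n_pos − n_neg)/(n_pos + n_neg) is undefined when a subject has no
significant voxels of either sign; such subjects are dropped pairwise from
the cross-task paired test with a warning. Paired tests are classic
two-tailed paired t's (delegated to scipy behind the package surface).

## ROI analysis

"Within 10³ mm of the activity center" is read as a **1000 mm³ volume cap**
(consistent with reported ROI sizes of ~890 voxels at 1 mm³ resolution; a
1000-mm radius is physically meaningless). The center is the peak
(max-|t|) suprathreshold voxel — peak rather than center-of-mass, the
unstated alternative. Growth adds voxels of the peak's suprathreshold
connected component in order of Euclidean mm distance (ties lexicographic)
while the volume stays within the cap; at 3-mm voxels the cap admits at most
⌊1000/27⌋ = 37 voxels. Time courses are ROI-mean percent signal change
versus the mean of rest volumes, windowed from the pre-onset rest through
the post-offset rest, averaged over blocks, and re-zeroed on the pre-onset
window. The sustained ("plateau") response averages 6–21 s post onset,
skipping the hemodynamic rise (configurable). Plateau group tests are
one-sample t's with a Bonferroni family of 4 (two ROIs × two conditions) by
default.

## Questionnaire and respiration

The 17 retained items are identified as q01–q17 (the original wording is
unpublished); q01–q07 form "Thoughts", q08–q10 "Sensations", the rest
"other". Category scores are unweighted means and require every member item
(a 6-item Thoughts mean would be a different statistic → error). Pearson
correlations are computed **across subjects** per Thoughts × Sensations item
pair — the only unit consistent with one rating per subject per item — and
summarized as mean ± SD over the 21 pairs.

The questionnaire generator draws a latent multivariate normal per
condition: within-category correlation 0.3, cross-category correlation set
so that the *observed* discretized correlation hits the target (Rest default
−0.24, task −0.04 — the anti-correlation collapse). Discretization uses
fixed latent cut-points at {−1.5, −0.5, 0.5, 1.5} SD mapping to ratings
1–5; its analytic linear attenuation factor (≈0.911 for these cut-points)
pre-boosts the latent correlation. Default task effects shift Thoughts by
−1.0 and Sensations by −0.7 latent SD (no published effect sizes exist;
values chosen once for testable, realistic Likert separations).

Respiration traces are one sine cycle per breath (positive lobe = inhale),
per-breath period multiplied by a lognormal jitter factor (σ = 0.05
default) to avoid degenerate periodicity, plus white measurement noise.
Breath extraction takes maximal positive-flow runs whose peak exceeds 5% of
the trace SD (a hysteresis guard against zero-crossing chatter), discards
boundary-truncated runs, and computes: pace = 60 / mean onset-to-onset
interval; mean inhale duration; mean per-inhale peak, mean flow, and
trapezoidal integral. Closed forms for a half-sine of amplitude A and
period T (peak A, mean 2A/π, integral AT/π) are recovered within 1%.
Condition comparisons are paired t's, Bonferroni family 5.

## The simulator and what the tests show

Forward model per voxel:
`baseline × (1 + amplitude/100 × regressor) + drift + AR(1) noise + motion-coupled component`,
baseline 1000. Amplitudes are percent signal change (matching the ROI
plots' units); noise sd is also in percent of baseline, so SNR =
amplitude/white_sd. Defaults define the study conditions: 20³ grid of 3-mm
voxels (the real voxel size at a desk-scale extent), 10% responders per
sign, ±1% amplitude, white sd 1% (SNR 1), AR(1) 0.3, one-cycle cosine
drift at 1% (inside the high-pass stopband), motion-coupled component 0.2%,
23 subjects. Responders are placed as ~4 round clusters per sign
(cortical responses are spatially coherent; fully random placement is
available). The gating regime zeroes the positive fraction, making the
ideal antagonism index −1; the balanced antagonistic regime's ideal is 0.
All generators are pure functions of (parameters, seed); per-subject streams
are seeded by CRC32 of the subject id under the base seed.

What the simulations do **not** emulate: physiological (cardiac/respiratory)
noise coupling into BOLD, EPI distortions and dropout, anatomical cortical
geometry, spatially varying smoothness, and between-subject anatomical
variability. Recovery and separation results on these cohorts therefore
validate the *computational chain* (that the statistics measure what they
claim under the stated noise model), not the physiological interpretation of
real data, and the published real-data values (cluster sizes 98/116, the
specific P values) are not reproduction targets.

Problem sizes used in the shipped validation: regime separation runs 50
replicate pairs of 23-subject cohorts (the reproduction script reports 10
replicates); cluster-MC calibration uses 1000 null iterations plus 200
fresh nulls; null-calibration suites use 1000 simulated cohorts each.
Numerical tie-breaks and degenerate inputs (zero-variance voxels, subjects
without significant voxels, constant questionnaire items, boundary-truncated
breaths) are handled by sentinel-plus-warning rather than silent exclusion,
and every such rule is unit-tested.
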