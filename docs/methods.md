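# Methods

This package implements a wingbeat-resolved analysis pipeline for motor
cortical recordings from freely flying bats, together with a synthetic
session generator that plants every quantity the pipeline is supposed to
recover.  This note documents the models, the numerical choices, and what
the synthetic data does and does not emulate.

## The behavioral model

A session is a sequence of flights separated by rest epochs on a perch.
Flights follow one of a small set of 3D path templates (a shared-prefix
fork pair by default, plus U-turn / straight / climb templates) traversed
at a constant cruise speed (default 4.5 m/s) with short takeoff and landing
ramps, a smooth per-flight perturbation (Gaussian-filtered noise, default
sd 4 cm) and white measurement noise (2 mm).  Wingbeats run at 8 Hz with
i.i.d. Gaussian per-cycle period jitter (default sd 3 ms, truncated at
±3 sd), matching the empirically narrow period distribution of real flight.
Rest epochs of 2 s make flight segmentation unambiguous.

Twenty keypoints oscillate dorsoventrally in the body frame as
`A_k · E_side(t) · sin θ(t)`, with per-keypoint amplitudes growing distally
(wingtip 13 cm) and an envelope `E_side(t) = 1 ± g·ω̂(t)` coupled to the
normalized signed angular velocity ω̂ with opposite signs for the left and
right wing (default gain g = 0.5).  The head/tail and shoulder keypoints
are rigid in the body frame so that body axes reconstructed from them
(forward = head − tail, lateral = shoulder difference) coincide exactly
with the generative frame.  The dorsoventral accelerometer channel carries
gravity plus `2 g · sin θ` and white noise (0.05 g); the **phase
convention** everywhere is θ = 0 at the upward zero-crossing of the
band-limited dorsoventral acceleration.

## Unit classes

* `tonic_phase_locked` — inhomogeneous Poisson with rate
  `r₀ · exp(κ cos(θ − φ)) / I₀(κ)`, so the flight-spike phase distribution
  is von Mises with resultant vector length I₁(κ)/I₀(κ) and mean rate r₀.
* `kinematic_glm` — per-cycle counts are Poisson with log-mean
  `log(r₀ T_cycle) + w·x`, where x is the z-scored per-cycle kinematic
  feature vector the generator computes from its own noiseless signals.
  The linear drive is clipped at ±3.5 to keep rare extreme cycles
  physiological; rates above 1 kHz reject the specification.
* `group_selective` — a fixed number of spikes (default 2) at a fixed
  wingbeat phase, jittered by a Gaussian with millisecond-scale sd, emitted
  only on the unit's active wingbeat groups; silent elsewhere.
* `unmodulated` — homogeneous Poisson.

A shared low-rank latent process (independent squared-exponential GPs,
unit variance, timescales 150–600 ms, loading sd 0.2) multiplies the rates
of the tonic and unmodulated units, giving the population genuine shared
variance without contaminating the GLM units' generative model.

What the generator does **not** emulate: aerodynamics, pose-estimation
error structure (keypoint noise is white, real tracking errors are not),
spike-sorting contamination, electrode drift, or behavioral variability in
path choice.  Passing recovery tests therefore demonstrates correctness of
the estimators under the assumed statistical structure, not robustness to
every artifact of real recordings.

## Analysis choices

**Flight segmentation** thresholds smoothed speed (zero-phase Gaussian,
sd 25 ms on positions, 50 ms on speed) at 1 m/s for ≥ 1 s and pads each
interval outward to the takeoff/landing speed minima, stopping once speed
falls below 10% of the threshold.  **Path clustering** is average-linkage
agglomerative clustering on RMS distance between trajectories resampled to
200 points, cut at 0.5 m; temporal orientation is preserved so reversed
paths form distinct clusters.  Reproducibility is the Pearson correlation
of each flight's feature traces (positions range-normalized 0–1) against
the leave-one-out mean of its path, pooled over features — leave-one-out
rather than all-pairs to avoid self-inflation.

**Wingbeat detection** band-passes the dorsoventral accelerometer
(Butterworth order 3, 4–14 Hz, filtfilt), takes the analytic-signal phase,
and cuts cycles at the upward zero-crossing.  Cycles with band-passed
amplitude below 20% of the flight median are rejected, and a flight whose
band-passed variance is less than 30% of its total variance is treated as
having no coherent oscillation (this is what rejects pure noise).  Period
errors are sub-millisecond in the interior; the first and last cycle of a
trace carry analytic-signal edge effects of a couple of milliseconds.

**Wingbeat grouping** runs k-means on [per-cycle adaptation vector;
per-cycle kinematic means; normalized ordinal], with k = the median cycle
count per flight.  The kinematic block is scaled to unit total variance
and the ordinal coordinate is weighted (default 50) so that the noiseless
case reproduces grouping by ordinal position exactly — the regime the
analyses assume, where group ≈ the i-th cycle of each flight — with
k-means initialized at per-ordinal centroids and refined by kinematic
similarity.  Labels are renamed by mean ordinal; the order-preservation
score is the Spearman correlation of label versus ordinal.

**Permutation tests** use the (1 + #null ≥ obs)/(1 + N) convention.  The
flight-modulation statistic is the mean pairwise Pearson correlation of
per-flight rate traces (10 ms bins, 25 ms Gaussian smoothing, resampled to
200 points); the null circularly shifts each flight's spikes by an
independent uniform offset of at least one wingbeat period.  BH-FDR is
applied across units at q = 0.01 (a unit tested on several paths keeps its
Bonferroni-adjusted minimum).  The phase-locking statistic is the RVL of
spike phases; the null applies an independent uniform circular rotation
per flight, preserving within-flight structure, with BH within each path
at q = 0.05 and a 20-spike minimum.  "Flight active" (the criterion being
config-exposed) means ≥ 1 spike in ≥ 5% of flights and ≥ 0.2 Hz mean
flight rate.

**Recruitment decoding** uses a linear SVM (C = 1, one-vs-rest,
class-balanced) on binary barcodes with stratified 5-fold CV; groups
smaller than the fold count merge into their ordinal neighbor.  Band-b
accuracy sums the confusion matrix within |true − predicted| ≤ b.  The
shuffle null re-runs the full pipeline per label permutation (100
iterations at full scale; fewer in the quick configurations).  Similarity
curves use per-cycle spike-count vectors by default (barcodes also
supported); cross-path divergence z-scores per-unit mean rates with pooled
two-path statistics and averages |Δz| in 250 ms windows stepped by 5 ms,
with odd-versus-even flights of one path as the within-path control.

**Phase decoding across paths** regresses [sin θ, cos θ] on binned,
smoothed, z-scored population rates of continuously active (silent
fraction < 0.2), phase-locked units; θ̂ = atan2.  The score is a circular
R² (one minus residual circular variance about the decoded phase, relative
to the circular mean) on the test path, normalized by the
leave-one-flight-out CV R² within the training path.  The normalization
denominator is this package's definition; scores with a non-positive
denominator are flagged undefined.

**Poisson GLM encoding.** The default 17-feature registry is speed,
g-force, angular velocity, flight-path angle, the three velocity and three
acceleration components, turn curvature, upper envelopes of both wrists
and both wingtips, the wrist upper-envelope asymmetry, and the cycle
period.  (The registry is config-exposed; vertical speed is omitted
because it duplicates the vz component exactly.)  Selection fits a Poisson
elastic-net path (mixing 0.5, intercept unpenalized) over 12
logarithmically spaced penalties spanning three decades below the KKT
null-model bound, picks the penalty by 5-fold CV deviance with the 1-SE
rule, and refits the surviving features without penalty.  cv pseudo-R² is
1 − D_cv(model)/D_cv(intercept-only) pooled over folds.  The weight
participation ratio is computed on squared weights (variance-like
quantities) and normalized by the number of selected features.

**PCA / dPCA / GPFA.**  The group-mean matrix warps each cycle onto equal
phase bins (12 per cycle), averages within group, concatenates groups, and
drops groups with < 4 cycles and units whose odd/even split-half
correlation is below 0.3.  n90 is the smallest PC count reaching 90%
cumulative EV; participation ratios are computed separately on the core
subspace (PCs carrying the first 50% of EV) and the extended subspace (all
remaining PCs), each normalized by its size.  dPCA marginalizes the
trial-averaged tensor into a condition-invariant (time-only) part and a
condition-specific part (group + group×time, fitted jointly — the split
components of one rank-limited signal are not separately decodable), fits
reduced-rank ridge components per marginalization (ridge chosen by CV on
held-out trial halves; an analytic 1e-6 fallback covers the single-trial
case), and reports EV per marginalization plus the specific/invariant
ratio.  GPFA is fit by EM on binned activity: linear-Gaussian observations
with diagonal private noise and one squared-exponential GP prior per
factor (jitter 1e-6), loadings initialized from PCA, timescales re-optimized
every second iteration by bounded 1-D search; the EM aborts if the marginal
likelihood decreases beyond numerical tolerance.  Dimensionality is chosen
by leave-one-neuron-out prediction error — each unit predicted from
latents inferred without it, scored on held-out trials — taking all
dimensions within 1% of the minimum error.  With distinct planted
timescales and more than one factor the likelihood is nearly invariant to
factor rotations, so individual timescales are only identifiable up to
mixing; single-factor timescale recovery is accurate to tens of
milliseconds.

## Problem sizes

The test and acceptance configurations use sessions of 2 paths × 4–8
flights with 12–40 units, 200-unit null populations with 200 permutation
shuffles, 500-cycle GLM simulations, and GPFA datasets of 20 units ×
24 trials × 20 bins with a 1–5 factor grid.  These sizes give the recovery
statistics comfortable margins (binomial standard errors are quoted in the
tests) while keeping a full run on one CPU in the minutes range.

## Known limitations

* The analytic-signal phase inherits a small constant lag (~0.2 rad at
  120 Hz sampling) relative to the generative phase; RVL and all
  consistency-based statistics are invariant to it, but absolute preferred
  phases are reported in the detector's convention.
* dPCA explained-variance capture is limited by what is linearly decodable
  from the data; sub-marginalization (group vs group×time) EV is reported
  from the exact algebraic decomposition instead.
* The elastic-net path refits from cold at every penalty (no warm starts),
  which bounds how dense the penalty grid can affordably be.
* `cross_path_divergence` truncates both paths to the shorter takeoff-
  aligned duration; structure after the truncation point is not compared.
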