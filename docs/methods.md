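# Methods

`phenoconn` reconstructs, on fully synthetic data, a study design that
fuses three data streams collected from the same young-adult subjects:
passive smartphone sensing (screen time and circadian regularity), brief
PHQ depression surveys, and seed-based resting-state functional
connectivity (RSFC) from the subgenual cingulate cortex (sgCC). The
question the workflow answers is whether across-subject variation in a
phone-derived behavior (mean daily unlock duration) correlates, voxel by
voxel, with the strength of sgCC connectivity — and whether a cluster found
in one cohort replicates inside its own footprint in a second,
independently sampled cohort.

## Phone features

**Unlock duration.** An unlock session is the interval from unlock to
relock. Daily unlock minutes are the summed session durations per calendar
day, with sessions crossing midnight split at the boundary so that daily
and epoch totals are conserved. A day counts toward a subject only when
its *quality coverage* — the number of distinct clock hours touched by any
event or heartbeat — reaches 16 h; a subject enters the analysis only with
at least 20 valid days. (Coverage is not defined operationally in the
source description; counting event-touched hours is this package's
definition.) Epoch features use three fixed windows of the local, naive
clock: day 09:00–18:00, evening 18:00–24:00, night 00:00–09:00; half-open
intervals, no daylight-saving handling — determinism was preferred over
calendar fidelity, and the synthetic clock has no transitions anyway.

**Duty-cycled sampling.** Cohort 2's stream is observed only during 1-min
windows at the head of each 10-min cycle, extended to 3 min when a
conversation is detected (Bernoulli per cycle in the generator; no
conversation statistics are specified anywhere, so independence is an
assumption). Because the windows tile epochs exactly, realized coverage is
exactly 10 % with no extensions and 30 % with all cycles extended.
Observed epoch minutes are upscaled by dividing by the realized coverage
fraction — an unbiased estimate when sessions are independent of the
sampling phase, which holds in the generator by construction.

**Unique locations** snap coordinates to a ~100 m square grid (local
equirectangular projection) and count distinct cells per (day, epoch);
the grid size is a package choice, as only "number of unique locations" is
specified.

## Circadian similarity (NaN-tolerant ICC)

A subject's day × epoch matrix (n valid days × 3 epochs) is scored with a
two-way, single-measure, *consistency* intraclass correlation — ICC(3,1) —
with the three epochs as targets and days as raters:

    ICC = (MS_epochs − MS_error) / (MS_epochs + (k − 1)·MS_error),

k being the average number of raters (days) per epoch. Missing cells are
ignored in all means and sums and the error degrees of freedom are reduced
by the number of missing cells — the NaN-operator substitution of the
balanced formulas. Degenerate variance (e.g. an all-constant matrix)
yields an undefined marker (NaN), not an exception, so exclusion is
handled uniformly downstream. The orientation (epochs as targets) is
recorded in every output, and `transpose=True` scores the other
orientation; no claim is made about which orientation the original
implementation used. On complete data the statistic agrees with a textbook
ANOVA-table ICC and with `pingouin`'s ICC(C,1) to 1e-10 (tested).

## PHQ scoring

PHQ-8 (8 items) and PHQ-4 (4 items; the first two form the PHQ-2) are
ordinal 0–3 item sets summed into totals. Repeated EMA administrations are
averaged; a single response suffices for inclusion; zero responses exclude
the subject. Item-level missingness is rejected rather than prorated.
PHQ-8 severity categories use the Kroenke cutpoints 0–4 / 5–9 / 10–14 /
15–19 / 20–24, stored as a configuration table
(`phenoconn.config.SEVERITY_CUTPOINTS`) because they come from an external
instrument definition rather than from this analysis.

## RSFC denoising stream

Each BOLD run passes through, in order (the order is asserted by a stage
log): **censor → regress → interpolate → band-pass → correlate on
uncensored frames**.

* **Framewise displacement** is the sum of absolute differentiated
  realignment parameters, rotations converted to arc length on a 50 mm
  sphere (the radius is a convention recorded in config; the FD definition
  leaves it open). FD of the first frame is 0.
* **Censoring**: frames with FD > 0.25 mm are censored; surviving
  contiguous segments shorter than 5 frames are censored too; a run needs
  ≥ 50 uncensored frames, a subject ≥ 5 min of uncensored data (both
  boundaries inclusive).
* **Nuisance regression** uses 43 columns: a Volterra expansion of the six
  motion parameters (raw, squared, two lags, two lags squared — 36
  columns, lag columns zero-filled at run start), CSF / white-matter /
  whole-brain mean signals, their first derivatives (backward difference,
  zero at frame 0), and a constant. Coefficients are fit by least squares
  on uncensored frames only; residuals are formed at all frames, so
  censored frames never influence the fit. Beyond the constant column no
  additional detrending is applied.
* **Spectral interpolation** reconstitutes censored frames from the
  frequency content of the uncensored, non-uniformly sampled series: sine
  and cosine amplitudes on a Lomb–Scargle frequency grid (spacing
  1/(8·span), i.e. oversampling 8, up to Nyquist) are fit jointly by
  penalized least squares, with penalty (f/f_Nyquist)^4 (floor 1e-4,
  weight 1.0). The penalty suppresses high-frequency ringing inside
  censored gaps; values 0.1–10 give indistinguishable reconstructions of a
  test sinusoid (≈ 1 % RMS), so the weight is not a sensitive tuning. The
  normal equations are solved in the dual (n_uncensored-dimensional)
  space, making the cost linear in voxels. Only censored frames are
  replaced; uncensored frames pass through bit-identical.
* **Band-pass** 0.009–0.08 Hz is an FFT-domain mask with a 0.002 Hz
  raised-cosine edge taper and DC removal, applied to the now uniformly
  sampled series; zero phase by construction.
* **Seed maps**: the mean time course of the 4 mm sphere at MNI
  (0, 25, −10) — 7 voxels on the 3 mm grid — is Pearson-correlated with
  every voxel over uncensored frames only, then Fisher z-transformed with
  r clipped to ±(1 − 1e-7). Zero-variance voxels get z = 0 and a flag;
  seed voxels are flagged as self-correlations.

## Group statistics

Per voxel, Fisher-z values are Pearson-correlated across subjects with the
behavioral covariate; t = r√(N−2)/√(1−r²), p two-tailed. Multiple
comparisons use a cluster-extent threshold calibrated by Monte Carlo
simulation of white-noise fields smoothed with a Gaussian kernel matched
to the maps' estimated smoothness, with face-adjacent (6-neighbor)
components labelled and the maximum extent recorded per iteration. Two
null modes exist. The single-field mode (``n_subjects = 0``) thresholds
one smoothed, mask-standardized z field per iteration at the voxel-p
quantile. The correlation-field mode (``n_subjects = n``, used throughout
the group workflow) simulates the statistic the group stage actually
computes: n smoothed white-noise subject volumes are correlated voxelwise
with a random covariate and the r field is thresholded at the parametric
voxel-p quantile. The distinction matters at small n: every voxel's r is
the projection of its subject vector onto the same random covariate
direction, so the suprathreshold *count* of a null correlation field is
heavily overdispersed relative to any single Gaussian field, and its
maximum cluster extent is correspondingly heavier-tailed — a single-field
null measured a corrected false-positive rate of ~0.10–0.12 where the
correlation-field null achieves ~0.03–0.05 at α = 0.05 on full-pipeline
null datasets.

The reported threshold is the smallest extent k with null exceedance
probability ≤ α — the survival form rather than a ceiling of the quantile,
because the extent distribution is discrete and the quantile form can be
badly anticonservative (measured corrected false-positive rate 0.13
instead of 0.05 on one probe). Smoothness is estimated as the Gaussian
kernel-equivalent FWHM from the lag-1 spatial autocorrelation
ρ = 1 − var(Δ)/(2·var), using σ² = −Δ²/(4 ln ρ) — the convention in which
"FWHM f" means "white noise convolved with a Gaussian of FWHM f", kept
consistent between estimator and null simulator. This simulated null
is a documented, self-contained replacement for AFNI 3dClustSim's
mixed-ACF model; the two differ, and every report carries the calibration
parameters. Cluster-forming thresholds are two-tailed by default;
replication masking is one-sided positive (the replication question is
directional), exposed as a flag.

**Replication** thresholds cohort 2's map only inside cohort 1's corrected
cluster, with the extent threshold re-calibrated for the smaller search
volume. Overlap reports give pairwise and all-way voxel intersections.

## The synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions.

* **Latent severity** is a standard-normal per-subject trait. Daily unlock
  totals are `180 + 40·severity + N(0, 25²)` minutes (session-level
  log-normal durations with a time-of-day profile — the source describes
  no session distribution, so this is an assumption, and is flagged as
  such). PHQ items threshold the trait's normal CDF at quantiles
  0.70/0.85/0.95, giving a predominantly-minimal severity distribution
  (PHQ-8 mean ≈ 4–6) like the young-adult samples the design emulates.
* **Epoch profiles** (still minutes, location counts) mix a subject-level
  epoch offset scaled by √c with day-level noise scaled by √(1−c), where c
  is `icc_consistency`; the realized circadian ICC then tracks c
  (monotone; ≈ 1 at c = 1, ≈ 0 at c = 0; tested at three grid points).
* **BOLD runs** are sums of unit-variance band-limited (0.01–0.08 Hz)
  components, so the analysis band-pass does not destroy planted
  structure: seed voxels carry a shared latent signal, target voxels carry
  that signal scaled by the subject's connectivity weight plus independent
  noise (amplitude 0.2), all brain voxels share a global physiological
  signal (amplitude 0.25), and everything sits on a 1000-baseline at ~1 %
  signal scale. The global component is essential for fairness: without
  it, the whole-brain mean is dominated by the planted latent signal
  (independent noise averages away) and global-signal regression strips
  the very coupling under test.
* **Connectivity weights** are `0.5 + 0.3·(r·severity + √(1−r²)·e)` for
  `effect_r = r ≠ 0`, so the across-subject correlation between behavior
  and planted coupling is exactly `effect_r` with intercept and slope
  recorded. `effect_r = 0` requests the global-null construction: every
  weight is exactly zero, so the target region carries no coherent
  across-subject signal — neither behavioral nor the finite-frame sampling
  coherence a constant nonzero coupling would leave — and null calibration
  of the cluster statistics is clean. These amplitudes were calibrated so
  that the full pipeline recovers a planted effect_r = 0.5 at a group
  correlation near 0.5 — i.e. measurement noise does not dominate the
  planted individual differences.
* **Motion** is a slow random walk (translation steps 0.01 mm, rotation
  steps 2e-4 rad — FD stays far below 0.25 mm) plus single-frame
  displacement pulses of ≥ 0.6 mm at `motion_spike_rate`, each of which
  exceeds the censoring threshold.
* **Determinism**: all draws flow from `rng_seed` through fixed
  `SeedSequence` spawn keys per (domain, subject), so regeneration is
  byte-identical and adding a stage never perturbs another stage's draws.

What the generator does **not** emulate: hemodynamics, physiological
noise spectra (cardiac/respiratory), spatial smoothness of BOLD noise,
realistic GPS trajectories, scanner drift, or session-level phone-use
dynamics. Passing tests therefore demonstrate correctness of the
*pipeline* under known ground truth — inclusion rules, censoring, spectral
reconstitution, calibration of the cluster null, recovery of planted
effects — not that the original biological effect would reproduce.

## Problem sizes and evaluation runs

The evaluation module runs two standing checks at desk scale. Both
enforce the study's data-retention rules (≥ 50 uncensored frames per run,
≥ 5 minutes per subject) on every generated subject: beyond fidelity,
those rules bound the across-subject spread of map measurement noise,
which the equal-weight group correlation implicitly assumes — at run
lengths too short to satisfy them, censoring heterogeneity alone produced
2× spreads in subject map noise and visibly inflated the cluster
false-positive rate.

* **Null calibration**: 200 independent cohorts of 12 subjects
  (20×24×20 grid, 150-frame runs, effect_r = 0, which plants no coupling
  at all — the global-null construction) through the full generator →
  denoising → group path; the voxelwise p < 0.05 fraction sits at ≈ 0.05
  and the corrected cluster false-positive rate at ≈ 0.03–0.05
  (α = 0.05). Replicates must be independent datasets: redrawing
  covariates over one fixed cohort measures a *conditional* rate that can
  be badly inflated by that cohort's shared spatial structure.
* **Recovery and replication**: 50 two-cohort replicates (80
  subjects/cohort, 12×14×12 grid, 150-frame runs, effect_r = 0.5,
  cohort 2 duty-cycled), correlating seed maps against the latent behavior
  covariate (the quantity the phone features estimate; the phone → feature
  path itself is exercised end to end by `workbench.run_study` and the
  numbered analysis scripts). Mean recovery lands near 0.4–0.5 and the
  cohort-1-masked cohort-2 replication covers ≥ 50 % of the planted
  region in well over 80 % of replicates.

## Known limitations

* The Gaussian-FWHM cluster null underestimates long-range spatial
  dependence (e.g. global-signal residuals); it is calibrated for the
  generator's maps, and on real data an ACF-style heavy-tailed model would
  be more conservative.
* The ICC orientation and the original stream's treatment of
  midnight-spanning sessions are undocumented in the source material; both
  choices here are explicit and switchable, but not claimed to match.
* Coverage upscaling is unbiased only when phone use is independent of the
  duty-cycle phase; bursty real usage violates this mildly.
* Tissue-mask erosion fallbacks, acquisition-stage preprocessing (slice
  timing, realignment, normalization) and surface-based analysis are out
  of scope; masks and aligned volumes arrive from the generator.
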