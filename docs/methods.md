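# Methods

## Scientific background

Regional homogeneity (ReHo) quantifies the local synchrony of spontaneous
BOLD fluctuations: each voxel is assigned Kendall's coefficient of
concordance W computed over the time series of the voxel and its immediate
neighbors (7, 19 or 27 voxels including the center). *Dynamic* ReHo (dReHo)
drops the assumption that this synchrony is stationary over the scan: W is
recomputed inside overlapping sliding windows (default 30 TR long, advanced
1 TR at a time, TR = 2 s) and each voxel is summarized by the across-window
variability of its windowed ReHo — by default the sample standard deviation,
optionally the coefficient of variation. Regions whose local coupling waxes
and wanes over the scan score high; regions with steady coupling score low.

The package implements the full analysis that a clinical resting-state study
of this quantity runs: per-subject temporal preprocessing, the dReHo map,
map normalization and smoothing, voxelwise covariate-adjusted two-sample
inference with Gaussian-random-field (GRF) cluster correction, Pearson
correlation of cluster means against clinical measures, and a leave-one-out
cross-validated linear SVM that asks whether the cluster means separate
patients from controls. Because no patient data ship with the package, a
synthetic-cohort generator with *known, injected* dynamic-coherence effects
makes every stage testable end to end.

## Kendall's W

For K series of length n, with R_i the across-series rank sum at time point
i and T_j the usual tie correction for series j,

    W = 12 S / (K^2 (n^3 - n) - K * sum_j T_j),   S = sum_i (R_i - Rbar)^2.

Ties are handled with mid-ranks. The whole-brain windowed engine exploits
the mid-rank identity T_j = (n^3 - n) - 12 sum_i (r_ij - (n+1)/2)^2, which
turns both S and the tie term into quantities that can be accumulated over a
3x3x3 neighborhood with separable box filters; one pass computes every voxel
and window simultaneously. Ranks take the fast argsort path whenever a
single sorted sweep proves the series tie-free (ties inside any window imply
a repeated value in the full series). The engine is verified voxel-by-voxel
against a brute-force per-neighborhood implementation, including tied data
and reduced neighborhoods at mask edges (K shrinks there; neighborhoods are
never zero-padded).

Degenerate inputs: a voxel whose whole neighborhood is constant has an
undefined W and is reported as 0; a constant series inside an otherwise
valid neighborhood simply contributes mid-ranks.

## Preprocessing

Per subject: drop the first 10 volumes (scanner equilibration), remove the
per-voxel least-squares linear trend (re-adding the temporal mean), then
apply an ideal frequency-domain band-pass of 0.01–0.08 Hz (Fourier
components strictly outside the band, including DC, are zeroed). An ideal
filter was chosen over an IIR design because it is a projection — exactly
testable on pure tones — and matches the convention of the resting-state
toolchains this pipeline mirrors. The filter additionally annihilates the
in-band leakage of a linear ramp, so detrend-plus-filter is itself an exact
projection and the temporal pipeline is idempotent after the first pass.

Motion: six rigid-body parameters per volume are consumed, not estimated.
A subject is excluded when any translation exceeds 1.5 mm or any single-axis
rotation exceeds 1.5 degrees at any point in the scan. The scalar motion
nuisance covariate for the group model is the mean Power-style framewise
displacement: the sum of absolute frame-to-frame differences of the six
parameters with rotations converted to arc length on a 50 mm sphere. A
between-subject design needs one scalar per subject; mean FD is the field's
default choice.

## Map normalization and smoothing

The dReHo variability map is divided by its whole-brain (in-mask) mean; a
z-score variant and a mean-division-then-z-score variant are selectable
(`--norm {mean-div, zscore, both}`) because reasonable pipelines differ
here. Smoothing comes last: a separable Gaussian kernel of 6 mm FWHM
(sigma = FWHM / (2 sqrt(2 ln 2)), converted to voxels by the voxel size)
whose weights are renormalized over the in-mask support, so constants are
preserved and nothing bleeds across the mask boundary.

## Group inference

Per voxel, ordinary least squares with design [group, age, education, mean
FD, intercept]; the statistic is the t for the group column with
dof = n - rank(design). The t-map is converted to z by two-sided probability
matching (a treat-t-as-z switch exists; at the dof of a realistically sized
study the two are nearly identical).

Cluster correction follows standard random-field practice:

* Smoothness: residual images are normalized voxelwise to unit sum of
  squares across subjects; the per-axis variance g of their spatial finite
  differences is inverted through the Gaussian autocorrelation
  rho(d) = exp(-d^2 / 4 sigma^2), i.e. sigma^2 = -1 / (4 ln(1 - g/2)),
  FWHM = 2 sqrt(2 ln 2) sigma. The exact inversion avoids the bias of the
  small-kernel derivative approximation. Resels = in-mask voxels / product
  of per-axis FWHMs.
* Extent threshold: with u the Gaussian quantile of the voxel p (halved for
  two-tailed inference, applied per tail), the expected cluster count is
  E[m] = R (4 ln 2)^{3/2} (2 pi)^{-2} (u^2 - 1) exp(-u^2/2) and the cluster
  size tail is P(size >= k) = exp(-beta k^{2/3}) with
  beta = (Gamma(5/2) / E[n])^{2/3}, E[n] the expected voxels per cluster.
  The reported k is the smallest with 1 - exp(-E[m] P(size >= k)) below the
  cluster p (0.05 by default, per tail).
* Clusters: connected components (26-connectivity by default; 6 and 18
  available) of suprathreshold voxels with size >= k, reported with peak t,
  0-based peak voxel index and world-mm peak coordinates via the affine,
  ordered by |peak t| with coordinate tie-breaks.

Empirical calibration (500 simulated null cohorts, 16^3 grid, 20+20
subjects, 6 mm smoothing) puts the family-wise error of the whole chain at
the nominal 0.05 within Monte-Carlo error; the acceptance script recomputes
this rate on every run.

Inference is restricted to voxels at least 2 voxels inside the map mask
(`mask_erosion_vox`). Windowed-concordance maps are rougher and noisier
right at the boundary — neighborhoods are clipped and the smoothing kernel
renormalized there — which violates the stationary-smoothness assumption of
random-field theory and, untreated, produces occasional boundary false
positives. One voxel of erosion restores complete neighborhoods; the second
covers the kernel support.

## Association and classification

Group demographics are compared with Welch's unequal-variance t-test
(recomputing a published demographics table from its printed summaries
reproduces the printed t-values only under Welch, so that is the default
and only implementation). Cluster-mean dReHo values are correlated with
clinical variables (patients only) by Pearson r with the exact t-based
two-sided p; the screen is reported uncorrected by default, with an
optional Benjamini–Hochberg column. Scoring rules: MoCA gains one point
when education < 12 years, capped at 30; AHI bands are normal < 5,
mild 5–<15, moderate 15–<30, severe >= 30 (the conventional bands quote
"< 30" and "> 30", leaving 30 uncovered; it is assigned to severe here);
ESS bands use strict "greater than" cut-offs at 6, 11 and 16.

Classification is a soft-margin linear SVM (squared hinge, C = 1 — the
library defaults) evaluated by leave-one-out cross-validation; features are
standardized with training-fold statistics only (margin classifiers are
scale-sensitive; a flag disables this for strict replication of pipelines
that skip it). Patient is the positive class; accuracy, precision,
sensitivity and specificity are pooled over folds, and the ROC/AUC is built
from the pooled signed decision scores with tie-grouping, making the AUC
identical to the Mann–Whitney statistic. Using clusters defined on the full
sample as LOOCV features inherits a mild circularity from the study design
this package mirrors; the model interface also exposes the feature matrix
so a fully nested scheme can be run externally.

Note one well-known artifact checked by the tests: on label-permuted (null)
data, LOOCV accuracy sits *below* the majority-class rate, because removing
the held-out subject tilts the training balance against its class. Null
behavior is therefore asserted as "at or below the majority rate", not "at
chance".

## Synthetic cohorts

The generator emulates a two-group clinical resting-state study.

**Clinical table.** Each variable is drawn per group from a range-censored
Gaussian whose underlying parameters are moment-matched (2-parameter least
squares on the censored-normal moments) so that sample means and SDs
converge to the configured values; defaults follow a published
moderate/severe-OSA vs healthy-control demographics table (AHI 54.0 ± 21.7
vs 2.2 ± 1.2, etc.). Censoring rather than rejection truncation is
deliberate: variables such as percent sleep time below 90% SaO2 have a
point mass at 0 in real data and a coefficient of variation above 1, which
no rejection-truncated normal can reproduce. Variables named in `coupling`
are instead drawn as mu + sd (rho z + sqrt(1-rho^2) z') where z is the
subject's standardized modulation-depth jitter, enabling recovery tests of
the correlation stage. MoCA subscores are generated as continuous values;
only the scale-level ranges the record contract requires (percentages,
total score, ESS, AHI) are enforced.

**Scans.** Voxel series are unit-variance band-limited (0.01–0.08 Hz) noise
plus, inside each spherical effect region, a shared signal with
time-varying mixing weight a(t) = clip(a0 + d sin(2 pi t / P + phi), 0,
0.95); wideband noise (sd 0.3), a linear scanner drift and a 1000-unit mean
are added on top so the preprocessing stages have real work to do. The
instantaneous inter-voxel correlation is a(t)^2, so windowed W tracks the
envelope and its across-window variability grows with the modulation depth
d. Controls have d = 0.20–0.25 (base depth); patients differ by the
region's sign times its amplitude; per-subject jitter (sd 0.04 by default)
makes depth a subject-level trait the coupled covariates can correlate
with. Defaults: a0 = 0.45, P = 100 s (window 60 s, so each window sees a
fraction of a cycle), grid 24 x 24 x 16 voxels of 3 mm, 240 volumes at
TR 2 s, an ellipsoidal in-grid mask. The shared signal is band-limited
noise by default; a deterministic in-band tone and an aligned (fixed)
envelope phase are selectable for tests that need the per-subject
measurement to be nearly noise-free. The injected amplitudes are free
parameters of the generator — nothing calibrates them to any particular
disease — and the effect region is kept to a few percent of the mask: with
global mean-division normalization, a large affected fraction couples the
normalizer to the group difference and induces compensatory opposite-signed
shifts elsewhere (visible in pilot simulations as boundary clusters of the
opposite sign).

**Motion.** Smoothed random walks over six parameters, rescaled to peak
amplitudes strictly below the 1.5 mm / 1.5 degree limits, or above them
when a to-be-excluded subject is requested.

**What the generator does not emulate:** anatomy, physiological noise and
its regressors, scanner artifacts, spatial normalization error,
inter-regional connectivity, or realistic effect sizes for any disease.
Passing recovery tests therefore demonstrate that the pipeline measures
what the generator injects — not that any particular clinical effect is
detectable at these sample sizes.

## Problem sizes in the test suite

The Monte-Carlo studies run at desk scale, chosen as the smallest sizes at
which the tested property is statistically identifiable: null calibration
on 500 cohorts of 40 smoothed-noise maps (16^3); effect recovery on 20
cohorts of 10+10 subjects (16 x 16 x 12 grid, 160 volumes, one radius-2
sphere, amplitude 0.3); the accuracy/depth curve on 20 cohorts of 8+8
subjects (12 x 12 x 10, 110 volumes) per depth, using the injected region's
mean dReHo as the classification feature (at low depths no cluster survives
correction, so the generator's known effect support is the only feature
definition available at every depth). The same studies, at the same sizes,
are what `scripts/acceptance.py` recomputes.

## Numerical choices and edge cases

* Window schedule: half-open [i*step, i*step + length) index pairs; the
  count is floor((n - length) / step) + 1; a single window is an error for
  a variability map.
* dReHo variability uses the sample (ddof = 1) standard deviation across
  windows.
* Normalization fails loudly when the in-mask mean is numerically zero
  (mean-division) or the in-mask variance is zero (z-scoring).
* The GLM refuses rank-deficient designs rather than silently dropping
  columns; constant classifier features are dropped with a warning.
* Smoothness estimation floors each axis FWHM at 0.5 voxels (fields rougher
  than the grid cannot be resolved).
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; per-subject streams are keyed by (cohort
  seed, stream tag, subject index), so any subject's scan can be
  regenerated in isolation, bit-identically.

## Known limitations

* GRF cluster inference assumes stationary smoothness; the mask-erosion
  default mitigates but does not remove nonstationarity for maps whose
  roughness varies inside the brain. A permutation-based correction is out
  of scope.
* The Euler-characteristic density used is the Gaussian one (after
  probability-matching the t-map); a t-field density is available behind
  the `gaussianize=False` flag only in the sense of treating t as z, not as
  a t-field EC.
* Anatomical labeling of clusters (atlas lookup) is not implemented; peaks
  are reported in world mm only.
* The LOOCV feature definition follows the mirrored study design (clusters
  from the full-sample contrast), with the circularity caveat above.
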