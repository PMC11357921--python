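# Methods

## The signal model

Multi-b-value diffusion-weighted MRI of heterogeneous tumour tissue
decays non-mono-exponentially.  The continuous-time random-walk (CTRW)
picture models water displacement as a random walk with heavy-tailed
waiting times and step lengths, which yields the magnitude signal

    S(b) = S0 * E_alpha( -(b * D)^beta ),

where `E_alpha` is the one-parameter Mittag-Leffler function
`E_a(z) = sum_k z^k / Gamma(a k + 1)`, `D` (mm²/s) is an anomalous
diffusion coefficient associated with cellularity, and
`alpha, beta in (0, 1]` are temporal and spatial diffusion-heterogeneity
exponents.  `alpha = beta = 1` recovers the mono-exponential (Gaussian)
model with `D = ADC`.  The conventional ADC is computed from exactly two
points, the b = 0 and b = 800 s/mm² images, as `ln(S0/S800)/800`.

The reference acquisition emulated throughout is an 11-b-value bladder
protocol, b = 0, 50, 100, 200, 400, 800, 1000, 1500, 2000, 2500,
3000 s/mm², with per-b excitation counts (NEX) 1, 1, 1, 1, 1, 2, 4, 6,
8, 14, 16.

## Mittag-Leffler evaluation

`ml_eval` is a double-precision evaluator for real arguments with an
absolute-error contract of 1e-12 on the model's working domain
(`alpha in (0,1]`, `z in [-100, 0]`):

* `|z| <= 1`: the defining Taylor series (largest term is O(1), so the
  alternating sum is stable).
* `alpha <= 1, z < -1`: trapezoidal quadrature of the inverse Laplace
  transform `(1/2 pi i) \int e^s s^{a-1}/(s^a - z) ds` on the parabolic
  contour `s(u) = mu (1 + iu)^2`.  The contour scale `mu = 6`, step
  `h = 0.08` and truncation `|u| <= 3.2` balance three error sources:
  quadrature truncation (`exp(mu(1 - u_max^2)) ~ 1e-24`), trapezoidal
  discretisation (the integrand is analytic in a strip of half-width ~1
  in u, limited by the branch point of `s^a`), and roundoff
  (`~exp(mu) * eps ~ 1e-13`, which caps how large `mu` may usefully be).
  Validated against the high-precision reference to a worst-case error
  of 2e-14 over `alpha in [0.05, 1] x z in [-100, -1]`.
* `alpha in (1, 2], z < -5`: the pole-pair/branch-cut decomposition
  `E_a(-x) = (2/a) e^{x^{1/a} cos(pi/a)} cos(x^{1/a} sin(pi/a)) +`
  branch-cut integral, the integral evaluated by adaptive quadrature
  split at its near-resonance `r = x^{1/a}`.  At `alpha = 2` the
  integral vanishes and the expression is exactly `cos(sqrt(x))`.
  Orders above 1 exist for closed-form cross-checks only; the CTRW
  model never uses them.
* `z > 0`: log-space term summation (all terms positive); values beyond
  double range raise.

The independent reference `ml_reference` sums the series in
arbitrary-precision arithmetic with guard digits sized to the largest
term (`~|z|^{1/alpha} / ln 10` digits of cancellation).  Where the term
count makes that impractical (small `alpha`, large `|z|`: the largest
term sits at `k ~ |z|^{1/alpha}/alpha`), it switches to mpmath's
high-precision Talbot inversion of the Laplace transform
`s^{a-1}/(s^a - z)`.  The two routes agree to below 1e-43 on
overlapping arguments.

## Segmented voxelwise fitting

Fitting all four of (S0, D, alpha, beta) jointly from 11 noisy points is
ill-conditioned, so the standard segmented procedure is used:

1. **D stage** — bounded least squares of `S0 e^{-bD}` on the b <= 1000
   s/mm² images, in the linear signal domain, initialised by log-linear
   regression (exact on noiseless mono-exponential data).  Bounds:
   `D in (1e-6, 1e-2)` mm²/s.
2. **alpha/beta stage** — bounded trust-region least squares (the
   bound-respecting analogue of Levenberg-Marquardt) of the full CTRW
   model over all b, with D and S0 frozen at the stage-1 estimates,
   starting from `alpha0 = beta0 = 0.9` (the centre of the range seen in
   tumour tissue).  Bounds: `(0.01, 1]`; the upper bound is an
   admissible value (the mono-exponential limit), so only the lower
   bound marks a fit as clipped.  Tolerances 1e-12, max 200 residual
   evaluations; non-convergence is reported as a failed status with the
   best iterate retained.

**Known bias.**  The CTRW decay is not mono-exponential on b <= 1000
(for `beta < 1` it is not even analytic at b = 0), so the stage-1 D is a
mono-exponential *summary* of a non-mono-exponential curve: at the
low-grade median tissue (D = 1.583e-3, alpha = 0.898, beta = 0.870) the
noiseless stage-1 estimate is ~6 % low, which propagates to ~0.02-0.06
offsets in the fitted exponents.  This is intrinsic to the segmented
procedure, not an optimiser artifact: with D fixed at truth the
exponents are recovered to ~1e-14 on noiseless data.  Recovery tests are
therefore phrased per stage (stage 1 on mono-exponential data, stage 2
with D fixed), and the noisy-phantom test checks *consistency* of the
full pipeline against a Monte-Carlo oracle of repeated single-voxel
simulate-and-fit runs rather than absolute truth recovery.

ADC maps flag voxels with non-positive signal as NaN instead of raising;
ROI statistics exclude NaN voxels, mirroring how unusable (necrotic /
cystic) regions are excluded from manually drawn ROIs.

## Synthetic data

No clinical images ship with the package; generators reproduce the
statistical structure of the emulated study.

**Phantom.**  A labelled grid (default 32x32x1, four quadrants at the
median tissues of the low-grade, high-grade, pure-urothelial and
variant-histology groups, S0 = 1000) is pushed through the forward model
at the 11-b protocol.  Noise is Rician: per excitation the magnitude of
`(S + g1, g2)` with `g1, g2 ~ N(0, (S0/snr)^2)`, then averaged over the
b-value's NEX.  `snr` is the single-excitation b = 0 SNR.  The phantom
reproduces the Rician mean to Monte-Carlo accuracy and the `sqrt(NEX)`
noise reduction; it does not emulate anatomy, partial volume, motion, or
spatially correlated noise, so phantom results speak to estimator
behaviour under noise, not to in-vivo robustness.

**Enrollment.**  A subject table with one exclusion flag each; the
default funnel screens 107 subjects and retains 81 (12 without
pathological confirmation, 1 poor image quality, 4 sub-5-mm lesions,
9 with incomplete pathology).

**Cohort.**  81 lesions: 15 low-grade, 66 high-grade, of which 30 carry
variant histology (variants are high-grade by convention, so all
low-grade lesions are pure urothelial carcinoma).  Stages pTa/pT1/pT2/
pT3/pT4 = 4/39/16/11/11, assigned independently of grade.  Each lesion's
true (ADC, D, alpha, beta) is drawn independently per parameter from a
log-normal calibrated to its cell's published median and IQR via
`mu = ln(median)`, `sigma = IQR/(median * 2 * Phi^-1(0.75))` — median
exact, IQR correct to first order in sigma (<0.5 % error at these
sigmas).  Cells: low-grade row, high-grade row, variant-histology row;
the two published marginal tables (by grade and by histology) cannot
both be matched exactly by any joint assignment, so the grade-contrast
"high" group is a 36:30 mixture of the high-grade and VH cells — its
effective medians sit within ~1 % of the published high-grade row.

alpha/beta draws are clipped into (0, 1].  Every cell's upper quartile
lies below 1, so clipping does not disturb the calibrated quantiles; the
overall clip rate is ~2-3 % (dominated by the low-grade beta cell, whose
median 0.870 with IQR 0.148 places ~13 % of its mass above 1) and is
recorded in `DataFrame.attrs['clip_rate']`, with a 10 % guard that only
a misconfigured spec can trip.

**Reader noise.**  Two readers observe each truth plus independent
Gaussian noise with sd equal to a per-parameter fraction of the cell
median: ADC 7.1 %, D 9.2 %, alpha 3.2 %, beta 2.5 %.  These fractions
are calibrated so the population two-reader ICC(2,1) of each parameter
matches the published interobserver agreement (0.936, 0.947, 0.900,
0.887); a single common fraction cannot do this because the
between-lesion spreads differ by a factor of ~6 across parameters.
They are emulation constants, not reader-variability measurements.

**Fidelity limits.**  Parameters are independent within a lesion; the
real within-patient correlation of ADC, D and alpha is not reported and
not emulated.  One measurable consequence: under this emulation the
grading AUCs of D and ADC are analytically indistinguishable (binormal
values 0.870 vs 0.871 on pure grade cells), so the published small D >
ADC advantage is not reproduced — only the robust ordering (alpha best,
beta at chance) is.  Combined-marker (D + alpha) AUCs are likewise
optimistic relative to a correlated world, since independent markers
combine more favourably.

## ROI and agreement statistics

ROI means are arithmetic means over mask voxels, excluding NaN/failed
voxels and reporting the count used; the two readers' per-lesion means
are averaged for analysis.  Interobserver agreement is ICC(2,1) —
two-way random effects, absolute agreement, single measure — computed
from the ANOVA mean squares, with the McGraw-Wong F-based 95 % interval,
and banded on the conventional 0.20-wide scale (<0.20 poor to 0.81-1.00
perfect).  Degenerate inputs (no between-lesion variance) return a
flagged result.

## Group statistics

Two-group comparisons gate on Shapiro-Wilk (0.05, both groups): Student's
t (equal variance) if both pass, two-sided Mann-Whitney U otherwise;
summaries are formatted mean ± sd or median (IQR) to match the gate.
Constant groups route to the Mann-Whitney branch (Shapiro-Wilk is
undefined there).

ROC analysis is fully empirical.  The AUC is the tie-corrected
Mann-Whitney statistic `U/(n1 n2)` (verified identical to the
trapezoidal empirical ROC area on every input); its 95 % CI uses the
DeLong placement-value variance.  The operating point maximises the
Youden index over thresholds placed midway between adjacent distinct
scores (plus open extremes); ties in J are broken toward higher
sensitivity.  Sensitivity, specificity and accuracy are reported in
percent at that cutoff.  Diffusion parameters enter with the clinical
orientation (lower value = positive class), so a marker worse than
chance can report AUC < 0.5 rather than being silently flipped.

The paired DeLong test compares correlated AUCs via the covariance of
placement values; a zero-variance difference (e.g. comparing a marker
with a monotone transform of itself) is flagged degenerate with p = 1.
Against R's pROC on a fixed dataset the AUC, its DeLong CI and the
paired p-value agree to 1e-12.

Marker combination: univariate logistic regression per feature (Wald
p); features with p < 0.05 enter a multivariate logistic model whose
linear predictor is the combined score.  If none qualify the single
best feature is used; exactly collinear features are dropped and
flagged; perfect separation is flagged and the final iterate still
yields a usable ranking score.  `run_study_analysis` orchestrates both
contrasts (grade, histology) over a cohort table and emits a JSON
report plus flat CSV tables, including the DeLong comparison of the
combined CTRW marker against ADC.

Calibration of these engines is tested by simulation: under matched
nulls both the DeLong test and the univariate logistic Wald test hold
5 % type-I error within two binomial standard errors over 2000
replicates at the cohort's 15/66 group sizes.

## Problem sizes in the test suite

The default suite fits an 8x8 noiseless and a 32x32 SNR-50 phantom
(~1000 voxel fits plus a 600-fit Monte-Carlo oracle), uses 2000
replicates for null calibrations and the calibrated-AUC check, and 501
cohort seeds for the ordering summary; the full suite runs in well
under a minute of numerics plus the fitting time above.

## Known limitations

* The stage-1 D bias described above is inherited from the published
  two-stage procedure and is not corrected.
* `ml_eval` guarantees 1e-12 only on the model's domain; for
  `alpha in (1, 2]` accuracy is ~1e-9 (series/decomposition switching),
  adequate for its closed-form-test role.
* The cohort emulation draws parameters independently within a lesion
  and cannot reproduce between-marker AUC gaps that depend on
  within-patient correlation (see Fidelity limits).
* ROIs are consumed as given masks; delineation itself is out of scope.
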