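# Methods

This note records the statistical model behind `lrbsf`, the defaults and why
they were chosen, and the limits of what the synthetic benchmark shows.

## Signal model and GLM

A voxel's BOLD time series is modeled as a linear combination of explanatory
time courses plus white Gaussian noise,

    Y_j = x_{j1} β_1 + … + x_{jL} β_L + ε_j,   ε ~ N(0, σ²) i.i.d.,

fitted per voxel by ordinary least squares. Two design layouts are built:

* **condition**: one HRF-convolved regressor per stimulus condition plus
  nuisance columns and a constant baseline — for a five-condition experiment
  with six realignment parameters this is the classic 5 + 6 + 1 = 12-column
  design;
* **beta_series**: one HRF-convolved regressor per *trial* in a single model
  ("least-squares-all"). The literature offers several trial-wise estimation
  schemes (LS-all, LS-separate); LS-all was chosen because the trial count per
  session (260) stays well below the number of volumes, so the single model
  remains well conditioned, and it needs one fit instead of 260.

Stimulus boxcars are convolved with the canonical double-gamma hemodynamic
response (peak 6 s, undershoot 16 s, peak/undershoot ratio 1/6), taken from
nilearn's SPM-style implementation at 50× oversampling. Nuisance columns pass
through unconvolved; the baseline is a constant-1 column.

Numerics: the solve is by thin QR (not normal equations) for conditioning;
rank is declared deficient below 1e-10 × the largest singular value, and the
offending columns are named via pivoted QR. Residual variance is RSS/(J − L);
values at round-off scale (≤ 1e-20 × mean Y²) are snapped to exact zero so
that noiseless simulations are recognized as exact interpolations. In such
degenerate voxels the t statistic is ±∞ with the sign of the effect (0 if the
effect itself is at round-off scale), and the voxel is flagged. No
prewhitening or AR(1) modeling is applied — the noise model is white by
assumption, matching the generator; real fMRI noise is autocorrelated, so on
real data the t statistics would be mildly optimistic.

## Voxel selection

Voxels are ordered by |t| descending (ties broken by ascending linear index,
making the order total and deterministic) and the top N kept. The operating
range N ∈ [50, 5000] can be enforced on request; the default pipeline uses
N = 450, the middle of the empirically best 400–500 band. The ranking
statistic is the pooled condition-vs-baseline t — inside cross-validation
folds, the one-sample t of the training trials' betas against zero. This is
deliberate: it finds *responsive* voxels without using class labels, so it
cannot leak pairwise class information into the selection. An optional
uncorrected p < 0.001 pre-filter can be applied before ranking (off by
default), and a `fixed` mode ranks once on all trials before splitting for
comparison with whole-data selection protocols; the default recomputes the
ranking inside every training fold.

## Cumulant features

For a trial's selected-voxel vector x(n), empirical moments are
M_pq = (1/N) Σ x(n)^(p−q) x*(n)^q with the expectation as the sample mean.
Betas are real, so conjugation is the identity: M20 = M21 = mean(x²) and
M40 = M41 = M42 = mean(x⁴). Two conventions for the fourth-order features are
implemented:

* **paper** (default): Ψ40 = M40 − 3M20², Ψ41 = M40 − 3M20·M21,
  Ψ42 = M42 − M20² − 2M21. Ψ41 built from M40 and the unsquared 2M21 term in
  Ψ42 deviate from textbook cumulant algebra; they are retained verbatim as
  the default because published results using this feature set may rest on
  either reading.
* **standard**: the textbook forms Ψ41 = M41 − 3M21·M20,
  Ψ42 = M42 − M20² − 2M21², under which all three fourth-order features
  vanish in expectation for zero-mean Gaussian input (the property the
  Gaussian-limit test checks).

The default output is the five Ψ features. The composition of the optional
eight-feature variant is a convention of this package: it appends the raw
moments M20, M21, M42. For real input Ψ20 = Ψ21 numerically; both are kept so
the feature layout is stable across conventions. Features are permutation-
invariant in the voxels and scale as c² (second order) / c⁴ (fourth order)
under x → c·x. No per-trial centering or normalization is applied by default;
a z-scoring flag exists (it fixes Ψ21 ≡ 1 and removes amplitude information,
so it is off).

## KDE likelihood-ratio decoder

Class-conditional densities are estimated per (class, feature) by a
Gaussian-kernel KDE with Silverman bandwidth
h = 0.9 · min(sd, IQR/1.34) · n^(−1/5). If both spread measures vanish (all
training values identical) the bandwidth falls back to 1e-3 · (|value| + 1);
if only one vanishes the positive one is used. Densities are floored at
1e-300 and all ratios are computed in the log domain, so scores stay finite
arbitrarily far from the training support. Features are z-scored with
training-fold statistics stored in the model and applied to every test
vector.

The fused score of test vector Y for class c is Σₖ log p_c(yₖ) — a product of
per-feature marginals. Independence fusion was chosen over a full
multivariate KDE because K ≤ 8 features are estimated from ~47 training
trials per class, where a K-dimensional KDE is badly undersmoothed; a joint
multivariate mode (via scipy's `gaussian_kde`) is available as a config
option. Binary decisions follow the likelihood-ratio rule: class_a (the H₀
side) iff log LR ≥ log θ, with θ = 1 by default — the maximum-likelihood
decision, with the boundary going to H₀. At θ = 1 the binary rule coincides
exactly with the multiclass argmax; ties go to the lowest class label.

## Monte-Carlo cross-validation

Default protocol: 100 repetitions; each draws a stratified 90/10 split
(per-class test count is round-half-up of 0.1·n_c, at least 1, at most
n_c − 1), re-runs selection on the training rows, transforms, fits, and
scores the test rows; the report carries per-repetition accuracies, their
mean and sd. Accuracy is overall percent correct; a balanced-accuracy option
exists for unbalanced tables. Each repetition uses an independent
counter-derived RNG stream (`SeedSequence((seed, rep))`), so repetition k is
identical whether 10 or 1000 repetitions are requested, and identical
config + seed reproduces reports byte-for-byte. Pairwise decoding runs the
protocol on each of the C(n,2) class pairs (10 for five classes) and reports
the grand mean; "100 trials" is read as 100 Monte-Carlo repetitions per
decoding task.

## Synthetic data generator

The generator emulates a five-category event-related visual experiment:
260 trials (5 × 52), TR 2 s, 1 s stimulus duration, ISIs uniform on 4–8 s
(the emulated study's exact timing is not published; these are typical
rapid-event-related values, declared once here), 10 s lead-in and 20 s
final rest. Each voxel's series is baseline (100) + Σ trials
β_true · (boxcar ⊗ HRF) + N(0, noise_sd). Ground truth: β_true equals the
trial's class effect size inside that class's active cluster, 0 elsewhere.

The default grid is a down-scaled 16 × 16 × 12 (3072 voxels) so the full
pipeline runs in seconds; the full 63 × 53 × 46 acquisition geometry is one
argument away. The default active cluster is a compact 10 × 10 × 4 corner
block — 400 informative voxels, matching the 400–500 selection sweet spot —
shared by all classes, with per-class amplitudes 0.5, 1.0, …, 2.5 against
unit noise. Amplitude coding (rather than location coding) is deliberate:
the cumulant features are permutation-invariant across voxels, so classes
that differ only in *which* equally-sized voxel set activates are
indistinguishable after compression; what the decoder can use is the
distribution of values, which amplitude differences shift.

What the generator does **not** model: temporal autocorrelation, hemodynamic
variability, physiological noise, motion, spatial smoothness of noise, and
between-subject variability. Passing tests therefore demonstrate the
pipeline's internal correctness and statistical calibration under its own
assumptions — not decoding performance on real scanner data, where noise
structure and HRF mismatch will lower accuracy.

## Problem sizes used in the checks

The bundled verification runs use the down-scaled grid: five-class null and
separable end-to-end runs at 260 trials × 3072 voxels with 100 Monte-Carlo
repetitions; OLS sampling covariance over 500 independent noise
realizations of a 400-scan design; t calibration over 1e5 null voxels;
KDE-vs-Bayes on 1000 training and 2500 test samples per class; the Gaussian
cumulant limit at n = 1e5 (the delta-method standard error of Ψ̂40 under
N(0,1) is √(24/n)). These sizes keep every Monte-Carlo standard error small
relative to the tolerance being checked.

## Known limitations

* Plain OLS degrees of freedom; no SPM-style effective-dof correction.
* The LR orientation keeps H₀ in the numerator; which experimental class a
  user maps to H₀ is their choice (at θ = 1 the labeling is symmetric).
* Third-order and cross-voxel cumulants are out of scope.
* Complex-valued signals are unsupported (conjugation is assumed trivial).
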