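# lrbsf — cumulant-feature fMRI decoding with likelihood-ratio score fusion

`lrbsf` is a multivariate pattern analysis (MVPA) toolkit for decoding which
stimulus category a subject was viewing from event-related fMRI. It targets
the regime where a session yields a few hundred trials but thousands of
candidate voxels: instead of feeding hundreds of selected voxel features to a
classifier directly, it compresses each trial's voxel pattern into at most
eight higher-order statistics and classifies those with a nonparametric
likelihood-ratio test.

The pipeline, stage by stage:

1. **Trial-wise GLM.** Each voxel's BOLD time series Y is regressed on a
   design matrix X (one double-gamma-HRF-convolved regressor per trial, plus
   nuisance regressors and a baseline): Y = Xβ + ε, solved per voxel by OLS.
   The per-trial β̂ values are the raw features.
2. **Voxel selection.** Voxels are ranked by |t| of a condition-vs-baseline
   contrast and the top N kept (N ∈ [50, 5000]; 400–500 is the sweet spot).
   Inside cross-validation, ranking uses training trials only.
3. **Cumulant compression.** Each trial's N-voxel β vector x(n) is reduced to
   the moments M_pq = E[x^(p−q)(x*)^q] and the second/fourth-order cumulant
   features Ψ₂₀, Ψ₂₁, Ψ₄₀ = M₄₀ − 3M₂₀², Ψ₄₁, Ψ₄₂ — five features (eight with
   the raw moments appended), whatever N was.
4. **KDE likelihood-ratio decoding.** Per class and feature, a Gaussian-kernel
   density (Silverman bandwidth) is fitted to the training features. A test
   vector Y is scored by fused log likelihoods Σₖ log p_c(yₖ); binary
   decisions threshold the likelihood ratio LR = p(Y|H₀)/p(Y|H₁) at θ
   (default 1), multiclass decoding takes the argmax over classes.
5. **Monte-Carlo cross-validation.** 100 repetitions of stratified 90/10
   train/test splits, accuracies averaged; one-vs-one decoding over all
   C(5,2) = 10 class pairs, and five-class decoding against a 20% chance
   level.

Because suitable public data with this exact structure is not bundled, the
package ships a synthetic BOLD generator (`lrbsf.synthetic`) that emulates the
design: 5 balanced classes × 52 trials, TR 2 s, randomized 4–8 s ISIs,
class-specific activation amplitudes in a compact 400-voxel cluster, Gaussian
scanner noise, with full ground truth for every stage.

## Worked example

Decode a synthetic session in the fast path (trial betas drawn directly,
skipping the BOLD forward model), at a noise level where classes overlap:

```python
from lrbsf import SyntheticSpec, make_beta_table, PipelineSettings, McCvConfig
from lrbsf.evaluation import pairwise_decode, monte_carlo_cv

spec = SyntheticSpec(noise_sd=5.0, seed=42)  # 5 classes x 52 trials, 16x16x12 grid
table = make_beta_table(spec)                # trials x voxels matrix of trial betas

report = pairwise_decode(table, PipelineSettings(n_features=450),
                         McCvConfig(reps=100, seed=0))
print(report.to_frame().to_string(index=False))
print(f"mean pairwise accuracy: {report.mean_accuracy:.2f}%")

multi = monte_carlo_cv(table, PipelineSettings(n_features=450),
                       McCvConfig(reps=100, seed=0))
print(f"five-class accuracy: {multi.mean_accuracy:.2f}% (chance 20%)")
```

Output:

```
 class_a  class_b  mean_accuracy        sd
       1        2           53.4 13.796501
       1        3           62.0 14.564382
       1        4           69.1 14.361495
       1        5           88.5  8.689364
       2        3           60.0 13.926212
       2        4           71.8 14.728520
       2        5           83.7 10.885539
       3        4           65.6 14.655643
       3        5           76.3 12.922066
       4        5           61.6 14.888135
mean pairwise accuracy: 69.20%
five-class accuracy: 42.36% (chance 20%)
```

Each row is one class pair's mean accuracy over 100 Monte-Carlo repetitions
(sd across repetitions). Classes are coded by activation amplitude (class 1
weakest, class 5 strongest), so widely separated pairs such as 1-vs-5 decode
best, adjacent pairs hover nearer chance, and the five-class accuracy sits
between chance (20%) and the pairwise mean — exactly the qualitative
behavior expected of amplitude-coded patterns under heavy noise.

The same chain runs from the shell on NIfTI + TSV inputs:

```bash
lrbsf simulate --seed 7 --out data/
lrbsf glm --bold data/bold.nii --events data/events.tsv --out betas.csv
lrbsf crossval --config config.yaml        # full pipeline from one YAML file
lrbsf sweep --config config.yaml --grid 50,200,450,1000 --out curve.csv
```

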