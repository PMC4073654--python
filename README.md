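# longswe

Sandwich-estimator marginal modelling for longitudinal and repeated-measures
data, univariate or mass-univariate (voxelwise NIfTI).

## The problem

Longitudinal studies — repeated brain scans of the same subjects, repeated
clinical measurements — produce observations that are correlated within
subject. Standard shortcuts either assume Compound Symmetry (equal variances
and equal correlations across visits: subject-dummy OLS, random-intercept
mixed models) or throw information away (per-subject summary statistics),
and full mixed-effects models need iterative, failure-prone fits at every
voxel. This package implements the non-iterative alternative: fit the
marginal model

```
y_i = X_i β + ε_i,      cov(ε_i) = V_i  (unmodelled nuisance)
```

by ordinary least squares (identity working covariance) and estimate
`cov(β̂)` with the cluster-robust sandwich

```
S = (X′X)⁻¹ [ Σ_i X_i′ V̂_i X_i ] (X′X)⁻¹
```

which is consistent whatever the true within-subject covariance. Because
nothing is iterated, the fit is fast and can never fail to converge.

Supported refinements, all aimed at small samples:

* **Homogeneous variant** — instead of the per-subject `V̂_i = e_i e_i′`,
  estimate one common covariance `V̂_0g` per group from all subjects'
  residuals at matched visit pairs (with spectral repair to positive
  semi-definiteness under missing data), and carve each subject's `V̂_i` out
  of it. Markedly more stable than the classic heterogeneous form.
* **S0–S3 residual adjustments** — the HC0–HC3 family generalised to
  clustered data: raw residuals, a global √(n/(n−p)) inflation, or leverage
  corrections e/(1−h)^½ and e/(1−h).
* **Effective degrees of freedom** — Wald tests use
  `((ν−q+1)/(νq)) (Cβ̂)′(CSC′)⁻¹(Cβ̂) ~ F(q, ν−q+1)`, with ν either the
  naive `m − p_B` or a Satterthwaite moment-matching estimate that accounts
  for the sandwich's own sampling variability (for a one-sample mean it
  returns exactly `m − 1`).
* **Compound-symmetry diagnostic** — Box's determinant likelihood-ratio test
  of equal variances/equal covariances, run on the largest usable
  complete-case subset, per voxel, with FDR or Bonferroni thresholding.
* **Monte-Carlo harness** — synthetic balanced and unbalanced cohort designs
  with compound-symmetric, decaying-correlation ("Toeplitz"), group- and
  visit-heteroscedastic covariance; empirical false/true-positive-rate
  studies against subject-dummy OLS (N-OLS) and summary-statistic OLS
  (SS-OLS) baselines.

The recommended default everywhere is the S3 homogeneous sandwich with
Satterthwaite degrees of freedom.

## Worked example

```python
import numpy as np
from longswe import SweModel, simulate as sim

design = sim.build_balanced_design(m=12, k=3)       # two groups, 3 visits
y = sim.simulate_dataset(design, sim.BALANCED_STRUCTURES["cs"], seed=9)[:, 0]
res = SweModel(design, y).fit()                     # S3-hom, Satterthwaite df
print(res.summary())
```

```
Sandwich-estimator marginal model
================================================================
subjects: 12    observations: 36    groups: 2
variant: hom    adjustment: S3    df: satterthwaite
----------------------------------------------------------------
coef                        estimate   robust SE       t       p
intercept[A]                 -0.0020      0.5860   -0.00  0.9974
visit_lin[A]                  0.0646      0.1056    0.61  0.5675
visit_quad[A]                -0.0275      0.1614   -0.17  0.8713
intercept[B]                 -0.4629      0.3474   -1.33  0.2402
visit_lin[B]                 -0.0196      0.1187   -0.17  0.8752
visit_quad[B]                 0.0678      0.1596    0.42  0.6887
================================================================
```

Each row is a marginal-model coefficient (per-group orthonormal-polynomial
visit effects here), its robust standard error from the sandwich, and a
t-test against the Satterthwaite effective df. The data were simulated under
the null with within-subject correlation 0.95, and no effect is (correctly)
significant. A group contrast:

```python
C = [0, 1, 0, 0, -1, 0]                 # difference in linear visit effect
tr = res.t_test(C)
print(float(tr.t), float(tr.nu), float(tr.p))   # 0.53, 9.87, 0.608
```

Command-line equivalents: `longswe fit` (CSV), `longswe fit-nifti`
(voxelwise maps), `longswe sim` (Monte-Carlo study from a YAML config),
`longswe cs-test` (compound-symmetry maps), `longswe efficiency`
(analytic GLS/OLS efficiency of covariate splitting).

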