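# Methods

## Model and estimators

The package fits the marginal linear model `y_i = X_i β + ε_i` for subjects
`i = 1..m` with `cov(ε_i) = V_i` left unstructured. Point estimation uses an
identity working covariance, i.e. plain OLS: `β̂ = (X′X)⁻¹X′y`. This choice
is deliberate — non-identity working covariances require iterative
estimation, can destabilise the point estimate, and the efficiency they buy
is largely recovered by design construction instead (see "Covariate
splitting" below).

The coefficient covariance is the sandwich
`S = (X′X)⁻¹ [Σ_i X_i′ V̂_i X_i] (X′X)⁻¹`, in two variants:

* **heterogeneous** (`het`): `V̂_i = e_i e_i′` from subject i's own
  residuals. Unbiasedness holds only asymptotically in m; the estimate is
  noisy in small samples.
* **homogeneous** (`hom`): a common `V̂_0g` per group g, estimated at the
  level of visit categories. The (k,k) diagonal entry is the average of
  `e_ik²` over the `m_gkk` subjects of group g observed at visit k; the
  (k,k′) entry is the uncentred correlation over subjects observed at both
  visits, rescaled by the two diagonal estimates. The normalisation is
  `1/m_gkk` with no −1 correction: small-sample bias is handled by the
  residual adjustments instead. Each subject's `V̂_i` is the sub-matrix of
  its group's `V̂_0g` at its observed visits. Missing data can make `V̂_0g`
  indefinite, so every `V̂_0g` is spectrally repaired (negative eigenvalues
  clamped to zero); the repair is idempotent and a no-op on PSD inputs, so
  it is applied unconditionally. A visit pair observed in the group but
  shared by no subject gets correlation 0 and a warning (flagged on the
  estimate) rather than an error.

**Residual adjustments.** Before either variant, residuals may be rescaled:
S0 (raw), S1 (`√(n/(n−p))`, global), S2 (`e/(1−h)^½`), S3 (`e/(1−h)`), with
h the ordinary hat-matrix diagonal per observation (scalar leverages, not
per-subject block leverages). S2/S3 are undefined at saturated observations
(h = 1) and raise, naming the offending rows. For singleton clusters S2
reproduces the textbook HC2 estimator exactly (cross-checked against an
independent implementation in the test suite). The default is S3 + hom,
which in the simulations below is the only combination that controls the
false-positive rate across all covariance structures, at the price of
slight conservatism for very small m.

## Wald inference and effective degrees of freedom

Tests of `H0: Cβ = 0` (C of numerical rank q — a declared rank inconsistent
with the numerical one is overridden with a warning) use the rescaled
statistic

    F = ((ν − q + 1)/(ν q)) (Cβ̂)′ (CSC′)⁻¹ (Cβ̂)  ~  F(q, ν − q + 1),

which for q = 1 is equivalent to `t = Cβ̂/√(CSC′) ~ t_ν` (the equivalence is
asserted to 1e-10 in the tests). ν is used as a real number (continuous F
degrees of freedom are well defined); it is clamped below at q, with a
warning, so p-values stay defined in pathological tiny designs.

Two estimators of ν:

* **naive**: `ν = m − p_B`, p_B = number of design columns constant within
  every subject.
* **Satterthwaite** (default): `CSC′` is approximated as Wishart
  `W_q(ν, CVC′/ν)` and ν chosen by moment matching. Writing
  `u_i^(r) = a_i′ e_i` with `a_i = X_i(X′X)⁻¹C_r′`, the heterogeneous
  contrast covariance is `Σ_i u_i u_i′`; under normality
  `cov(u^(r), u^(s)) = Φ^(rs) = M^(r) V M^(s)′`, where `M^(r)` maps data to
  `u^(r)` **through the residual-forming matrix I − H** and V is a
  block-diagonal plug-in covariance (hom: `V̂_0g` blocks; het:
  `e_i e_i′`). Matching the Wishart mean and total elementwise variance
  gives

      ν = [(tr T)² + ‖T‖²_F] / Σ_rs [⟨Φ^rr, Φ^ss⟩ + tr(Φ^rs Φ^rs)],
      T_rs = Σ_i Φ^(rs)_ii.

  Routing the moments through I − H is what distinguishes this estimator
  from independence-based Satterthwaite formulas: it accounts for the
  correlation that estimating β induces among residuals, and for a
  one-sample mean it yields exactly ν = m − 1 for any plug-in scale (the
  test suite verifies this closed form, the ≈r scaling of ν under r-fold
  replication of a design, and agreement within 10% with a Monte-Carlo
  moment oracle when the true covariance is plugged in). The homogeneous
  plug-in gives the more stable ν; the heterogeneous plug-in is noisier and
  biased low, which makes het + Satterthwaite conservative — matching the
  observed behaviour of the het variant in the rejection studies. Design-
  and contrast-dependent pieces (the `M^(r)`) are precomputed once; only the
  plug-in blocks change per response, keeping the voxelwise loop cheap.

Multiplicity control offers Benjamini–Hochberg FDR (default, step-up) and
Bonferroni. One-sided t inference is exposed alongside the two-sided default
for q = 1.

## Covariate splitting

Time-varying covariates (e.g. age) are split into a between-subject
component (the subject mean, optionally grand-mean centred) and a
within-subject component (deviation from the subject mean, identically zero-
sum within subject). The two components may have genuinely different
effects, and the split also removes the OLS efficiency loss: under compound
symmetry the within-centred column attains the GLS variance exactly (ratio
1.00 for any correlation and any missingness pattern — `Jw_i = 0` makes
`w_i` an eigenvector of every CS block). `relative_efficiency` computes the
analytic GLS/OLS variance ratio per column from the true per-subject
covariances; it never exceeds 1.

## Box's test of compound symmetry

CS is tested on the largest usable complete-case subset: all visit subsets
of size ≥ 2 are searched and the subset maximising
`n_complete × (#visits choose 2)` (a covariance-information proxy) is kept,
ties broken toward more subjects, then more visits. After removing the mean
structure with the analysis design matrix, the one-group common covariance
V̂0 is estimated as above and the classical determinant likelihood-ratio
statistic of equal variances/equal covariances is formed:

    χ² = −(n − c) ln(|V̂0| / |V̂0_CS|),   df = k(k+1)/2 − 2,
    c = k(k+1)²(2k−3) / [6(k−1)(k²+k−4)],

where V̂0_CS substitutes the mean diagonal and mean off-diagonal (the
restricted MLE, so the statistic is non-negative and scale invariant) and
n is the subject count minus the maximum over visits of the rank of the
design rows at that visit (m − 1 for intercept or per-visit-mean models).
The statistic is reported on the F scale (χ²/df with denominator df ∞).
The constants are not trusted blindly: the suite checks the null
false-positive rate against the binomial band at moderate m and with a
parametric-bootstrap-style small-m simulation. Voxelwise maps apply the test
per response, propagate per-voxel failures as NaN, and report the surviving
fraction after FDR/Bonferroni correction.

## Synthetic data

The generator reproduces the study conditions used to validate the method:

* **Balanced designs**: m ∈ {12, 25, 50, 100, 200} subjects (two groups of
  equal size; odd m gives the extra subject to group A, e.g. 13/12 at
  m = 25) × k ∈ {3, 5, 8} visits, per-group intercept/linear/quadratic
  orthonormal-polynomial visit effects. Visit times are 0..k−1 in visit
  units, so rate parameters are "per visit". Any orthonormal basis gives
  identical statistics (asserted in the tests); the QR-based one is the
  deterministic default.
* **Unbalanced cohort**: three groups (N/MCI/AD-like) with per-visit subject
  counts fixed exactly by the scanning table (817 subjects, 3,314 scans;
  mean scans/subject 4.16, 4.43, 3.14), baseline ages N(76.0, 5.0²),
  N(74.8, 7.4²), N(75.4, 7.5²), months 0–36 converted to years. Missingness
  is drawn per visit by seeded sampling without replacement, matching the
  marginal counts exactly; monotone dropout is not imposed (the emulated
  table itself is non-monotone). Because visits are assigned independently,
  joint completeness across visits is lower than in a real cohort with
  correlated attendance — a deliberate simplification; the complete-case
  machinery is therefore validated on its own simulations, not on cohort
  emulations. Design columns (12): per group, intercept, grand-mean-centred
  subject mean age, within-centred age, and their product. `halve_design`
  keeps ⌊m_g/2⌋ random subjects per group for nested small-sample studies.
* **Covariance**: `var(y_ik) = α_g(1 + γ t_k)`,
  `corr(y_ik, y_ik′) = ρ(1 − ψ|t_k − t_k′|)` — compound symmetry
  (ρ=0.95), "Toeplitz" linear decay (ρ=1, ψ=0.1/visit balanced,
  0.2/year cohort), group heteroscedasticity (α = 1,2[,3]), visit
  heteroscedasticity (γ = 1/visit or 2/year). The named parameter sets
  never need PSD repair (asserted); user-supplied parameters that break
  PSD are repaired with a warning, and non-positive variances raise.
  Responses are standard normals premultiplied by the lower Cholesky factor
  of the covariance restricted to observed visits (any square root is
  distributionally equivalent; Cholesky is deterministic). Non-null signal
  adds `effect_size × (t − t̄_i)` — a per-subject-centred visit effect — to
  a chosen group or to all subjects. The generator does not emulate spatial
  correlation between voxels, non-Gaussian tails, or site/scanner effects;
  passing simulations therefore speak to the estimator's statistical
  calibration under the modelled covariance families, not to robustness
  against those further features of real images.

Randomness is controlled by one master seed; realisation streams are
spawned `SeedSequence` children, so studies are reproducible and safely
parallelisable. Identical config + seed gives bit-identical output.

## Monte-Carlo harness and baselines

`run_rejection_study` measures rejection percentages (FPR at effect 0, TPR
otherwise) per method × contrast × effect size, with the normal-
approximation binomial band reported alongside (for an exact 5% test,
(4.57%, 5.43%) at 10,000 realisations; (4.04%, 5.96%) at 2,000). Method
failures within a realisation are counted, not fatal. Baselines:

* **N-OLS**: OLS with a dummy per subject plus the within-subject columns;
  classical F-test with n − rank df. Between-subject contrasts are rejected
  with an explanatory error (the dummies span them).
* **SS-OLS**: per-subject OLS slope on centred time, then a one-row-per-
  subject group model with a classical F-test; subjects with fewer than two
  distinct times are dropped with a warning.

Mixed-model baselines are out of scope; the harness accepts additional
methods as plug-in adapters. The shipped acceptance study uses 2,000
realisations per setting (the full suite and the acceptance script each run
in tens of seconds on one CPU at these sizes); the m=50/m=100, 5-visit
designs are the standard mid-size conditions for which accurate FPR control
is expected — under these the S3-hom FPR lands inside the band, while
S0-het with naive df at m=12 lands above it (both asserted).

## Numerical choices and limitations

* Full column rank is required at design construction (singular values
  relative to the largest, tolerance 1e-10); rank-deficient designs are
  rejected, never pseudo-inverted. Rows are canonicalised to
  (subject, visit) order so block indexing is deterministic.
* Estimator core is float64 throughout; NIfTI maps may be written float32.
* Voxelwise execution precomputes all design-only quantities once and
  streams voxels in batches; results are independent of batch size (the
  shared OLS fit and residuals are computed once and sliced). More than 1%
  failing voxels aborts with diagnostics; fewer propagate as NaN.
* The homogeneous variant with a *single* group is a modelling choice, not
  a default: under group-heteroscedastic variance it inherits the same
  miscalibration as CS-assuming methods.
* Known limitations: reduced power relative to correctly-specified mixed
  models at small m under CS; slight conservatism of S3-hom for m below
  ~50 (balanced) / ~200 (heavily unbalanced); no spatial regularisation,
  no permutation/bootstrap inference, no random-field cluster inference
  (FDR/Bonferroni only).
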