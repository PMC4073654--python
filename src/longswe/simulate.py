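"""Synthetic longitudinal data generation and the Monte-Carlo validation
harness.

The generator produces the study conditions used to validate the sandwich
estimator: balanced two-group designs (m subjects x k visits, per-group
orthogonal-polynomial visit effects) and an unbalanced three-group design
emulating a large observational ageing cohort (per-visit subject counts fixed
by a scanning table, group-specific baseline age distributions).  Responses
are Gaussian with within-subject covariance

    var(y_ik)            = alpha_g (1 + gamma t_k)
    corr(y_ik, y_ik')    = rho (1 - psi |t_k - t_k'|)

covering compound symmetry (psi = gamma = 0), linearly decaying "Toeplitz"
correlation (psi > 0), group-heterogeneous variance (alpha_g varying) and
visit-heterogeneous variance (gamma > 0).

The harness measures empirical false/true positive rates of the sandwich
Wald tests and of two common baselines (subject-dummy OLS and per-subject
summary-statistic OLS) over seeded realisations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import sandwich
from .design import LongitudinalDesign, fit_ols, hat_diagonals
from .inference import DofEstimate, SatterthwaiteDof, TestResult, naive_dof, wald_test
from .sandwich import psd_repair

__all__ = [
    "CovStructureParams",
    "BALANCED_STRUCTURES",
    "ADNI_STRUCTURES",
    "ADNI_VISIT_COUNTS",
    "ADNI_AGE_PARAMS",
    "SimulationSummary",
    "cov_matrix",
    "orthogonal_polynomials",
    "build_balanced_design",
    "build_adni_like_design",
    "halve_design",
    "simulate_dataset",
    "n_ols_fit",
    "ss_ols_fit",
    "run_rejection_study",
    "binomial_ci",
    "relative_efficiency",
]


@dataclass(frozen=True)
class CovStructureParams:
    """Parameters of the within-subject covariance model.

    alpha : dict group -> variance scale (or a scalar applied to all groups)
    gamma : variance slope per time unit
    rho   : correlation level
    psi   : correlation decay per time unit (>= 0)
    """

    alpha: object = 1.0
    gamma: float = 0.0
    rho: float = 0.0
    psi: float = 0.0

    def alpha_for(self, group) -> float:
        if isinstance(self.alpha, dict):
            return float(self.alpha[group])
        return float(self.alpha)


# Named parameter sets for the four covariance structures under the balanced
# (time in visit units) and cohort-like (time in years) designs.
BALANCED_STRUCTURES = {
    "cs": CovStructureParams(alpha=1.0, gamma=0.0, rho=0.95, psi=0.0),
    "toeplitz": CovStructureParams(alpha=1.0, gamma=0.0, rho=1.0, psi=0.1),
    "het_groups": CovStructureParams(alpha={"A": 1.0, "B": 2.0},
                                     gamma=0.0, rho=0.0, psi=0.0),
    "het_visits": CovStructureParams(alpha=1.0, gamma=1.0, rho=0.0, psi=0.0),
}
ADNI_STRUCTURES = {
    "cs": CovStructureParams(alpha=1.0, gamma=0.0, rho=0.95, psi=0.0),
    "toeplitz": CovStructureParams(alpha=1.0, gamma=0.0, rho=1.0, psi=0.2),
    "het_groups": CovStructureParams(alpha={"N": 1.0, "MCI": 2.0, "AD": 3.0},
                                     gamma=0.0, rho=0.0, psi=0.0),
    "het_visits": CovStructureParams(alpha=1.0, gamma=2.0, rho=0.0, psi=0.0),
}

# Per-visit subject counts (rows: months 0, 6, 12, 18, 24, 36) of the
# emulated unbalanced three-group cohort.  AD subjects are not scanned at 18
# or 36 months by protocol; month-18 is MCI-only.
ADNI_VISIT_MONTHS = (0, 6, 12, 18, 24, 36)
ADNI_VISIT_COUNTS = {
    "N": (229, 208, 196, 0, 172, 147),
    "MCI": (400, 346, 326, 286, 244, 170),
    "AD": (188, 159, 138, 0, 105, 0),
}
ADNI_AGE_PARAMS = {"N": (76.0, 5.0), "MCI": (74.8, 7.4), "AD": (75.4, 7.5)}


def cov_matrix(params: CovStructureParams, times, group=None) -> np.ndarray:
    """Within-subject covariance at the given measurement times.

    PSD is verified; a violating matrix (possible for large psi * |dt|) is
    spectrally repaired with a warning.
    """
    t = np.asarray(times, dtype=float)
    if isinstance(params.alpha, dict):
        if group is None:
            raise ValueError("group label required with per-group alpha")
        a = float(params.alpha[group])
    else:
        a = float(params.alpha)
    var = a * (1.0 + params.gamma * t)
    if np.any(var <= 0):
        raise ValueError(f"non-positive variance at times {t[var <= 0]}")
    corr = params.rho * (1.0 - params.psi * np.abs(t[:, None] - t[None, :]))
    np.fill_diagonal(corr, 1.0)
    sd = np.sqrt(var)
    V = corr * sd[:, None] * sd[None, :]
    w = np.linalg.eigvalsh(V)
    if w[0] < -1e-10 * max(w[-1], 1.0):
        warnings.warn("covariance model not PSD at these times; repaired",
                      stacklevel=2)
        V = psd_repair(V)
    return V


# ----------------------------------------------------------------------
def orthogonal_polynomials(k: int, degree: int = 2) -> np.ndarray:
    """Orthonormal polynomial basis (constant..degree) over the grid 0..k-1.

    Any orthonormal basis over the visit grid gives identical test statistics;
    this QR-based one is the deterministic default.
    """
    if degree >= k:
        raise ValueError(f"degree {degree} requires more than {k} visits")
    t = np.arange(k, dtype=float)
    V = np.vander(t, degree + 1, increasing=True)
    Q, R = np.linalg.qr(V)
    Q *= np.sign(np.diag(R))  # fix signs so the linear column increases
    return Q


def build_balanced_design(m: int, k: int, degree: int = 2,
                          basis: np.ndarray | None = None) -> LongitudinalDesign:
    """Balanced two-group design: per-group polynomial visit effects.

    Groups "A" and "B" of equal size (for odd m, A gets the extra subject —
    e.g. m=25 gives 13/12).  Columns: for each group an intercept, linear and
    quadratic (by default) orthogonal-polynomial effect of visit.  Visit times
    are t_k = 0..k-1 in visit units.
    """
    if m < 4 or k < 2:
        raise ValueError("need m >= 4 subjects and k >= 2 visits")
    P = orthogonal_polynomials(k, degree) if basis is None else np.asarray(basis)
    m_a = (m + 1) // 2
    n = m * k
    subj = np.repeat([f"s{i:04d}" for i in range(m)], k)
    grp = np.repeat(["A"] * m_a + ["B"] * (m - m_a), k)
    vis = np.tile(np.arange(k), m)
    time = np.tile(np.arange(k, dtype=float), m)
    cols, names = [], []
    for g in ("A", "B"):
        ind = (grp == g).astype(float)
        blk = np.tile(P, (m, 1)) * ind[:, None]
        cols.append(blk)
        names += [f"{nm}[{g}]" for nm in
                  ["intercept", "visit_lin", "visit_quad", "visit_cub"][: degree + 1]]
    X = np.hstack(cols)
    return LongitudinalDesign(X=X, subject_id=subj, group_id=grp,
                              visit_cat=vis, time=time,
                              column_names=tuple(names))


def balanced_contrasts(design: LongitudinalDesign) -> dict:
    """Canonical contrasts for the balanced two-group polynomial design."""
    p = design.p
    deg = p // 2 - 1
    c_lin = np.zeros(p)
    c_lin[1], c_lin[deg + 2] = 1.0, -1.0          # linear visit effect, A - B
    c_int = np.zeros(p)
    c_int[0], c_int[deg + 1] = 1.0, -1.0          # group intercept difference
    c_visit = np.zeros(p)
    c_visit[1] = c_visit[deg + 2] = 0.5           # average linear visit effect
    return {"visit_lin_diff": c_lin[None, :],
            "group_intercept_diff": c_int[None, :],
            "visit_lin_mean": c_visit[None, :]}


# ----------------------------------------------------------------------
def build_adni_like_design(counts: dict | None = None,
                           age_params: dict | None = None,
                           seed=0, rng=None) -> LongitudinalDesign:
    """Unbalanced three-group cohort design with fixed per-visit counts.

    Subject-level missingness is drawn at random (seeded) under the single
    constraint that the per-visit marginal counts match the supplied table
    exactly: for every follow-up visit, the required number of subjects is
    sampled without replacement from the group.  Monotone dropout is *not*
    imposed — the emulated cohort's table is itself non-monotone.

    Columns (12): per group, an intercept, the grand-mean-centred subject mean
    age (cross-sectional age effect), the within-subject-centred age (visit
    effect) and their product (acceleration).
    """
    counts = dict(ADNI_VISIT_COUNTS if counts is None else counts)
    age_params = dict(ADNI_AGE_PARAMS if age_params is None else age_params)
    rng = np.random.default_rng(seed) if rng is None else rng
    months = np.array(ADNI_VISIT_MONTHS, dtype=float)

    rows = []
    for g, cnts in counts.items():
        cnts = np.asarray(cnts, dtype=int)
        m_g = int(cnts[0])
        if np.any(cnts > m_g):
            raise ValueError(f"group {g}: a follow-up count exceeds the "
                             f"baseline count {m_g}")
        mu, sd = age_params[g]
        base_age = rng.normal(mu, sd, size=m_g)
        present = np.zeros((m_g, len(months)), dtype=bool)
        present[:, 0] = True
        for j in range(1, len(months)):
            if cnts[j] > 0:
                chosen = rng.choice(m_g, size=int(cnts[j]), replace=False)
                present[chosen, j] = True
        for i in range(m_g):
            for j in np.flatnonzero(present[i]):
                rows.append((f"{g}_{i:04d}", g, int(months[j]),
                             months[j] / 12.0, base_age[i] + months[j] / 12.0))
    tab = pd.DataFrame(rows, columns=["subject", "group", "visit", "time", "age"])

    # between/within split of age, per group
    subj_mean = tab.groupby("subject")["age"].transform("mean").to_numpy()
    grand_mean = tab["age"].mean()
    cross = subj_mean - grand_mean
    within = tab["age"].to_numpy() - subj_mean
    cols, names = [], []
    for g in counts:
        ind = (tab["group"] == g).to_numpy(dtype=float)
        for nm, col in (("intercept", np.ones(len(tab))), ("age_cs", cross),
                        ("visit", within), ("accel", cross * within)):
            cols.append(col * ind)
            names.append(f"{nm}[{g}]")
    X = np.column_stack(cols)
    return LongitudinalDesign(X=X, subject_id=tab["subject"].to_numpy(),
                              group_id=tab["group"].to_numpy(),
                              visit_cat=tab["visit"].to_numpy(),
                              time=tab["time"].to_numpy(),
                              column_names=tuple(names))


def halve_design(design: LongitudinalDesign, seed=0, rng=None) -> LongitudinalDesign:
    """Keep floor(m_g / 2) randomly chosen subjects per group (nested subset).

    The design matrix is rebuilt so the age columns stay centred within the
    retained subset.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    keep = []
    subj_group = design.subject_group()
    for g in design.groups:
        members = design.subjects[subj_group == g]
        keep.extend(rng.choice(members, size=len(members) // 2, replace=False))
    keep = set(keep)
    rows = np.array([s in keep for s in design.subject_id])
    # columns are kept as stored (centred in the full cohort); the subset's
    # grand mean shifts slightly, affecting only the intercept interpretation
    return LongitudinalDesign(X=design.X[rows], subject_id=design.subject_id[rows],
                              group_id=design.group_id[rows],
                              visit_cat=design.visit_cat[rows],
                              time=design.time[rows],
                              column_names=design.column_names)


# ----------------------------------------------------------------------
def simulate_dataset(design: LongitudinalDesign, params: CovStructureParams,
                     effect_size: float = 0.0, seed=0, rng=None,
                     effect_group=None, n_responses: int = 1) -> np.ndarray:
    """Draw Gaussian responses with the model covariance (plus optional signal).

    Each subject's observations are independent standard normals premultiplied
    by the lower Cholesky factor of its covariance (restricted to observed
    visits).  A non-null signal ``effect_size * (t - mean_i t)`` — a per-
    subject-centred visit effect — is added, to ``effect_group`` only if
    given, else to every subject.

    Returns an (n, n_responses) array (independent responses share the
    covariance structure).
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    n = design.n
    Y = np.empty((n, n_responses))
    subj_group = design.subject_group()
    chol_cache: dict = {}
    for si, sl in enumerate(design.subject_slices):
        g = subj_group[si]
        t = design.time[sl]
        key = (g, t.tobytes())
        L = chol_cache.get(key)
        if L is None:
            V = cov_matrix(params, t, group=g)
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                w, U = np.linalg.eigh(V)
                L = U * np.sqrt(np.clip(w, 0, None))
            chol_cache[key] = L
        z = rng.standard_normal((len(t), n_responses))
        Y[sl] = L @ z
        if effect_size != 0.0 and (effect_group is None or g == effect_group):
            Y[sl] += effect_size * (t - t.mean())[:, None]
    return Y


# ----------------------------------------------------------------------
def n_ols_fit(design: LongitudinalDesign, Y, contrast) -> TestResult:
    """Subject-dummy ("naive") OLS baseline with a classical F-test.

    The marginal-model contrast must involve within-subject columns only: the
    subject dummies span every between-subject column, so between-subject
    effects are not estimable under this baseline.
    """
    C = np.atleast_2d(np.asarray(contrast, dtype=float))
    between = design.between_subject_columns()
    if np.any(C[:, between] != 0):
        raise ValueError("contrast not estimable under N-OLS: it involves "
                         "between-subject columns (they are linear "
                         "combinations of the subject dummies)")
    within_cols = ~between
    W = design.X[:, within_cols]
    dummies = np.zeros((design.n, design.m))
    for i, sl in enumerate(design.subject_slices):
        dummies[sl, i] = 1.0
    Xn = np.hstack([W, dummies])
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    beta, _, rank, _ = np.linalg.lstsq(Xn, Y, rcond=None)
    resid = Y - Xn @ beta
    df_resid = design.n - int(rank)
    sigma2 = np.einsum("nv,nv->v", resid, resid) / df_resid
    XtX_pinv = np.linalg.pinv(Xn.T @ Xn)
    Cw = np.hstack([C[:, within_cols], np.zeros((C.shape[0], design.m))])
    mid = Cw @ XtX_pinv @ Cw.T
    q = int(np.linalg.matrix_rank(C))
    Cb = Cw @ beta
    quad = np.einsum("qv,qs,sv->v", Cb, np.linalg.inv(mid), Cb)
    fstat = quad / (q * sigma2)
    pval = stats.f.sf(fstat, q, df_resid)
    t = Cb[0] / np.sqrt(sigma2 * mid[0, 0]) if q == 1 else None
    scalar = Y.shape[1] == 1
    def _sq(x):
        return float(x[0]) if (scalar and x is not None) else x
    return TestResult(stat=_sq(fstat), df1=float(q), df2=float(df_resid),
                      p=_sq(pval), nu=float(df_resid), contrast=C,
                      t=_sq(t), p_one_sided=None)


def ss_ols_fit(design: LongitudinalDesign, Y, between_contrast=None) -> TestResult:
    """Summary-statistic OLS baseline: per-subject slope, then a group model.

    Stage 1 regresses each subject's data on an intercept and its centred
    times, extracting the slope; subjects with fewer than 2 distinct times are
    dropped with a warning.  Stage 2 is a one-row-per-subject OLS of the
    slopes on group indicators with a classical F-test.  ``between_contrast``
    is a vector over groups (sorted label order); default tests the mean
    slope across all groups.
    """
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    slopes, groups_kept = [], []
    dropped = 0
    subj_group = design.subject_group()
    for si, sl in enumerate(design.subject_slices):
        t = design.time[sl]
        if len(np.unique(t)) < 2:
            dropped += 1
            continue
        tc = t - t.mean()
        denom = tc @ tc
        slopes.append((tc @ Y[sl]) / denom)
        groups_kept.append(subj_group[si])
    if dropped:
        warnings.warn(f"{dropped} subject(s) dropped: too few observations "
                      "to estimate a slope", stacklevel=2)
    slopes = np.asarray(slopes)
    groups_kept = np.asarray(groups_kept)
    glabels = np.unique(groups_kept)
    G = (groups_kept[:, None] == glabels[None, :]).astype(float)
    if between_contrast is None:
        between_contrast = np.full(len(glabels), 1.0 / len(glabels))
    C = np.atleast_2d(np.asarray(between_contrast, dtype=float))
    beta, _, rank, _ = np.linalg.lstsq(G, slopes, rcond=None)
    resid = slopes - G @ beta
    df_resid = slopes.shape[0] - int(rank)
    with np.errstate(invalid="ignore", divide="ignore"):
        # a saturated stage-2 model leaves no error df: estimates remain
        # valid, the F-test is undefined (NaN)
        sigma2 = np.einsum("nv,nv->v", resid, resid) / df_resid
    mid = C @ np.linalg.pinv(G.T @ G) @ C.T
    q = int(np.linalg.matrix_rank(C))
    Cb = C @ beta
    quad = np.einsum("qv,qs,sv->v", Cb, np.linalg.inv(mid), Cb)
    fstat = quad / (q * sigma2)
    pval = stats.f.sf(fstat, q, df_resid)
    scalar = Y.shape[1] == 1
    def _sq(x):
        return float(x[0]) if scalar else x
    res = TestResult(stat=_sq(fstat), df1=float(q),
                     df2=float(df_resid), p=_sq(pval),
                     nu=float(df_resid), contrast=C,
                     t=None, p_one_sided=None)
    res.__dict__["stage2_estimates"] = beta
    res.__dict__["n_dropped"] = dropped
    return res


# ----------------------------------------------------------------------
def binomial_ci(p0: float, n_real: int, level: float = 0.95):
    """Normal-approximation binomial band around rate p0, in percent."""
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be a probability")
    z = stats.norm.ppf(0.5 * (1 + level))
    half = z * np.sqrt(p0 * (1 - p0) / n_real)
    return (100 * (p0 - half), 100 * (p0 + half))


@dataclass
class SimulationSummary:
    method: str
    contrast: str
    effect_size: float
    rejection_rate: float          # percent
    n_realisations: int
    ci_lo: float                   # binomial band around the nominal level, %
    ci_hi: float
    alpha: float
    seed: int
    n_failed: int = 0

    @property
    def is_fpr(self) -> bool:
        return self.effect_size == 0.0


class _SweRunner:
    """Per-design precomputation for fast repeated sandwich fits."""

    def __init__(self, design, contrast, variant, adjustment, dof_method):
        self.design = design
        self.C = np.atleast_2d(np.asarray(contrast, dtype=float))
        self.variant = variant
        self.adjustment = adjustment
        self.dof_method = dof_method
        self.pinv = np.linalg.pinv(design.X)
        self.h = hat_diagonals(design)
        if dof_method == "satterthwaite":
            self.sdof = SatterthwaiteDof(design, self.C)
        self.naive = naive_dof(design)

    def test(self, Y) -> TestResult:
        d = self.design
        beta = self.pinv @ Y
        resid = Y - d.X @ beta
        e_adj = sandwich.adjust_residuals(resid, self.h, d.n, d.p,
                                          self.adjustment)
        if self.variant == "hom":
            gc = sandwich.estimate_group_covariance(d, e_adj)
            sw = sandwich.swe_homogeneous(d, gc, contrast=self.C)
            if self.dof_method == "satterthwaite":
                nu = DofEstimate(nu=self.sdof.nu_hom(gc), method="satterthwaite")
            else:
                nu = self.naive
        else:
            sw = sandwich.swe_heterogeneous(d, e_adj, contrast=self.C)
            if self.dof_method == "satterthwaite":
                nu = DofEstimate(nu=self.sdof.nu_het(resid), method="satterthwaite")
            else:
                nu = self.naive
        return wald_test(beta, sw.S, self.C, nu, contrast_projected=True)


def run_rejection_study(design: LongitudinalDesign, params: CovStructureParams,
                        methods, contrasts: dict, effect_sizes=(0.0,),
                        n_realisations: int = 2000, alpha: float = 0.05,
                        seed: int = 0, effect_group=None) -> pd.DataFrame:
    """Monte-Carlo rejection-rate study.

    Parameters
    ----------
    methods : list of dicts, each one of
        ``{"name": ..., "kind": "swe", "variant": "hom"/"het",
        "adjustment": "S0".."S3", "dof": "satterthwaite"/"naive"}``,
        ``{"name": ..., "kind": "n_ols"}`` or ``{"name": ..., "kind": "ss_ols",
        "between_contrast": ...}``.
    contrasts : dict name -> (q, p) array (used by the "swe" and "n_ols"
        kinds; ss_ols uses its own between-group contrast).
    effect_sizes : iterable of floats; 0.0 rows are FPRs, others TPRs.

    Method failures in a realisation are recorded, not fatal.  Fully seeded:
    realisation r uses an independent child stream of ``seed``.
    """
    runners = {}
    for spec in methods:
        if spec["kind"] == "swe":
            for cname, C in contrasts.items():
                runners[(spec["name"], cname)] = _SweRunner(
                    design, C, spec["variant"], spec["adjustment"], spec["dof"])
    rej = {}
    fails = {}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_realisations)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for es in effect_sizes:
            counts = {}
            fail = {}
            for r in range(n_realisations):
                rng = np.random.default_rng(children[r])
                Y = simulate_dataset(design, params, effect_size=es, rng=rng,
                                     effect_group=effect_group)
                for spec in methods:
                    if spec["kind"] == "swe":
                        for cname in contrasts:
                            key = (spec["name"], cname)
                            try:
                                res = runners[key].test(Y)
                                p = float(np.atleast_1d(res.p)[0])
                                counts[key] = counts.get(key, 0) + (p < alpha)
                            except Exception:
                                fail[key] = fail.get(key, 0) + 1
                    elif spec["kind"] == "n_ols":
                        for cname, C in contrasts.items():
                            key = (spec["name"], cname)
                            try:
                                res = n_ols_fit(design, Y, C)
                                counts[key] = counts.get(key, 0) + (res.p < alpha)
                            except ValueError:
                                counts.setdefault(key, None)
                    elif spec["kind"] == "ss_ols":
                        key = (spec["name"], "between")
                        try:
                            res = ss_ols_fit(design, Y,
                                             spec.get("between_contrast"))
                            counts[key] = counts.get(key, 0) + (res.p < alpha)
                        except Exception:
                            fail[key] = fail.get(key, 0) + 1
            rej[es] = counts
            fails[es] = fail
    lo, hi = binomial_ci(alpha, n_realisations)
    rows = []
    for es, counts in rej.items():
        for (mname, cname), cnt in counts.items():
            if cnt is None:
                continue
            rows.append(SimulationSummary(
                method=mname, contrast=cname, effect_size=es,
                rejection_rate=100.0 * cnt / n_realisations,
                n_realisations=n_realisations, ci_lo=lo, ci_hi=hi,
                alpha=alpha, seed=seed,
                n_failed=fails[es].get((mname, cname), 0)))
    return pd.DataFrame([r.__dict__ for r in rows])


# ----------------------------------------------------------------------
def relative_efficiency(design: LongitudinalDesign, V_blocks) -> np.ndarray:
    """Per-column GLS/OLS variance ratio (analytic; <= 1 always).

    ``V_blocks`` is a list of per-subject true covariance matrices (subjects
    order).  var_OLS is the sandwich form with the true V_i; var_GLS is
    (sum X_i' V_i^-1 X_i)^-1.  The ratio diag(var_GLS)/diag(var_OLS) is the
    efficiency of the working-independence estimator for each column.
    """
    X = design.X
    bread = np.linalg.inv(X.T @ X)
    meat = np.zeros((design.p, design.p))
    info = np.zeros((design.p, design.p))
    for sl, Vi in zip(design.subject_slices, V_blocks):
        Xi = X[sl]
        meat += Xi.T @ Vi @ Xi
        info += Xi.T @ np.linalg.solve(Vi, Xi)
    var_ols = bread @ meat @ bread
    var_gls = np.linalg.inv(info)
    return np.diag(var_gls) / np.diag(var_ols)
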