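"""Wald inference on contrasts with effective degrees of freedom.

The sandwich covariance S is itself a random quantity; referring the Wald
statistic to chi^2_q ignores that variability and is liberal in small samples.
Instead the rescaled statistic

    (nu - q + 1) / (nu q) * (C b)' (C S C')^-1 (C b)  ~  F(q, nu - q + 1)

is used, where nu is an effective degrees of freedom for the covariance
estimate.  Two estimators of nu are provided:

* naive: nu = m - p_B, subjects minus the number of pure between-subject
  columns;
* Satterthwaite: C S C' is approximated by a Wishart W_q(nu, C V C'/nu) and nu
  is chosen by moment matching.  Its mean and variance are evaluated under
  normality *through the residual-forming matrix* (I - H), with the fitted
  within-subject covariances plugged in — this accounts for the correlation
  that estimating beta induces among residuals (for a one-sample mean it
  yields exactly nu = m - 1, not m).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import LongitudinalDesign
from .sandwich import GroupCovEstimate

__all__ = [
    "DofEstimate",
    "TestResult",
    "naive_dof",
    "estimate_dof",
    "SatterthwaiteDof",
    "wald_test",
    "multiplicity_control",
]


@dataclass(frozen=True)
class DofEstimate:
    """Effective degrees of freedom nu for a (contrast, response) pair."""
    nu: np.ndarray  # scalar or (V,)
    method: str


@dataclass(frozen=True)
class TestResult:
    """Wald test of H0: C beta = 0."""
    stat: np.ndarray          # F-scale statistic
    df1: float                # q
    df2: np.ndarray           # nu - q + 1
    p: np.ndarray             # upper-tail F probability (== two-sided t for q=1)
    nu: np.ndarray
    contrast: np.ndarray
    t: np.ndarray | None = None            # only for q = 1
    p_one_sided: np.ndarray | None = None  # only for q = 1, P(T > t)


# ----------------------------------------------------------------------
def naive_dof(design: LongitudinalDesign) -> DofEstimate:
    """nu = m - p_B with p_B the number of pure between-subject columns."""
    p_b = int(design.between_subject_columns().sum())
    nu = design.m - p_b
    if nu <= 0:
        raise ValueError(
            f"naive degrees of freedom non-positive: m={design.m}, p_B={p_b}")
    return DofEstimate(nu=np.asarray(float(nu)), method="naive")


class SatterthwaiteDof:
    """Moment-matching effective df, with design/contrast work precomputed.

    For contrast row r let u^(r) = (u_i^(r))_i with u_i^(r) = a_i' e_i, where
    a_i = X_i (X'X)^-1 C_r'.  Then C S C' (het) = sum_i u_i u_i', and
    cov(u^(r), u^(s)) = Phi^(rs) = M^(r) V M^(s)' with M^(r) the m x n matrix
    mapping y to u^(r) through the residual-forming matrix and V the
    block-diagonal plug-in covariance.  Matching the Wishart mean/variance
    gives

        nu = [ (tr T)^2 + ||T||_F^2 ] /
             sum_rs [ <Phi^rr, Phi^ss> + tr(Phi^rs Phi^rs) ]

    with T_rs = sum_i Phi^(rs)_ii.  This object precomputes the M^(r) once so
    that per-response evaluation costs a handful of small matrix products.
    """

    def __init__(self, design: LongitudinalDesign, contrast):
        C = np.atleast_2d(np.asarray(contrast, dtype=float))
        if C.shape[1] != design.p:
            raise ValueError(f"contrast has {C.shape[1]} columns, design p={design.p}")
        self.design = design
        self.C = C
        q, n, m = C.shape[0], design.n, design.m
        X = design.X
        XtX_inv = np.linalg.inv(X.T @ X)
        A = X @ XtX_inv @ C.T                               # (n, q)
        # G[r] is m x n with subject i's row = A[rows_i, r] on its columns
        G = np.zeros((q, m, n))
        for i, sl in enumerate(design.subject_slices):
            G[:, i, sl] = A[sl].T
        # M[r] = G[r] (I - H) = G[r] - (G[r] X) (X'X)^-1 X'
        P = XtX_inv @ X.T                                    # (p, n)
        self.M = G - np.einsum("rmp,pn->rmn", G @ X, P)      # (q, m, n)

    def _phi(self, block_cov) -> np.ndarray:
        """Phi tensor (q, q, m, m) given per-subject covariance blocks."""
        q, m, _ = self.M.shape
        phi = np.zeros((q, q, m, m))
        for sl, Vj in zip(self.design.subject_slices, block_cov):
            MV = np.einsum("rmn,nk->rmk", self.M[:, :, sl], Vj)
            phi += np.einsum("rmk,snk->rsmn", MV, self.M[:, :, sl])
        return phi

    def nu_from_blocks(self, block_cov) -> float:
        phi = self._phi(block_cov)
        q = phi.shape[0]
        T = np.einsum("rsii->rs", phi)
        num = np.trace(T) ** 2 + np.sum(T**2)
        den = 0.0
        for r in range(q):
            for s in range(q):
                den += np.sum(phi[r, r] * phi[s, s])
                den += np.trace(phi[r, s] @ phi[r, s])
        if den <= 0:
            raise ValueError("degenerate (zero) contrast covariance; "
                             "cannot estimate degrees of freedom")
        return float(num / den)

    def blocks_hom(self, group_cov: GroupCovEstimate, response: int = 0):
        d = self.design
        subj_group = d.subject_group()
        blocks = []
        for si, sl in enumerate(d.subject_slices):
            g = subj_group[si]
            lab_index = {v: j for j, v in enumerate(group_cov.visit_labels[g])}
            idx = np.array([lab_index[v] for v in d.visit_cat[sl]])
            blocks.append(group_cov.V0[g][response][np.ix_(idx, idx)])
        return blocks

    def nu_hom(self, group_cov: GroupCovEstimate) -> np.ndarray:
        nV = next(iter(group_cov.V0.values())).shape[0]
        return np.array([self.nu_from_blocks(self.blocks_hom(group_cov, v))
                         for v in range(nV)])

    def nu_het(self, residuals) -> np.ndarray:
        e = np.asarray(residuals, dtype=float)
        if e.ndim == 1:
            e = e[:, None]
        out = []
        for v in range(e.shape[1]):
            blocks = [np.outer(e[sl, v], e[sl, v])
                      for sl in self.design.subject_slices]
            out.append(self.nu_from_blocks(blocks))
        return np.array(out)


def estimate_dof(design: LongitudinalDesign, contrast,
                 group_cov: GroupCovEstimate | None = None,
                 residuals=None) -> DofEstimate:
    """Satterthwaite effective df for a contrast.

    Supply ``group_cov`` for the homogeneous variant or ``residuals`` (raw OLS
    residuals) for the heterogeneous one; the homogeneous plug-in gives the
    more precise estimate and is the default elsewhere in the package.
    """
    sw = SatterthwaiteDof(design, contrast)
    if group_cov is not None:
        nu = sw.nu_hom(group_cov)
    elif residuals is not None:
        nu = sw.nu_het(residuals)
    else:
        raise ValueError("provide group_cov (hom) or residuals (het)")
    return DofEstimate(nu=nu if nu.size > 1 else np.asarray(float(nu[0])),
                       method="satterthwaite")


# ----------------------------------------------------------------------
def wald_test(beta, S, contrast, dof: DofEstimate,
              contrast_projected: bool = False) -> TestResult:
    """Wald test of C beta = 0 with an F(q, nu - q + 1) reference.

    Parameters
    ----------
    beta : (p, V) or (p,) coefficients.
    S : (V, p, p) sandwich covariance, or (V, q, q) if ``contrast_projected``.
    contrast : (q, p) array; its rank is recomputed numerically and overrides
        the row count if smaller (with a warning).
    dof : DofEstimate (scalar or per-response nu).
    """
    C = np.atleast_2d(np.asarray(contrast, dtype=float))
    b = np.asarray(beta, dtype=float)
    if b.ndim == 1:
        b = b[:, None]
    S = np.asarray(S, dtype=float)
    if S.ndim == 2:
        S = S[None]
    q_rows = C.shape[0]
    q = int(np.linalg.matrix_rank(C))
    if q < q_rows:
        warnings.warn(f"contrast rows are rank deficient: rank {q} < {q_rows}",
                      stacklevel=2)
    Cb = C @ b                                           # (q_rows, V)
    CSC = S if contrast_projected else np.einsum("qp,vpr,sr->vqs", C, S, C)
    nV = Cb.shape[1]
    nu = np.broadcast_to(np.atleast_1d(np.asarray(dof.nu, dtype=float)), (nV,)).copy()
    clamped = nu < q
    if clamped.any():
        warnings.warn(f"effective df below contrast rank for "
                      f"{int(clamped.sum())} response(s); clamped to q={q}",
                      stacklevel=2)
        nu[clamped] = q

    quad = np.empty(nV)
    for v in range(nV):
        try:
            sol = np.linalg.solve(CSC[v], Cb[:, v])
        except np.linalg.LinAlgError:
            raise ValueError("contrast not estimable with this covariance "
                             "(singular C S C')") from None
        quad[v] = Cb[:, v] @ sol
    df2 = nu - q + 1
    fstat = df2 / (nu * q) * quad
    pval = stats.f.sf(fstat, q, df2)
    t = p1 = None
    if q == 1 and q_rows == 1:
        with np.errstate(invalid="ignore"):
            t = (Cb[0] / np.sqrt(CSC[:, 0, 0]))
        p1 = stats.t.sf(t, nu)
    out_scalar = nV == 1 and np.asarray(dof.nu).ndim == 0
    def _sq(x):
        return x[0] if (out_scalar and x is not None) else x
    return TestResult(stat=_sq(fstat), df1=float(q), df2=_sq(df2),
                      p=_sq(pval), nu=_sq(nu), contrast=C,
                      t=_sq(t), p_one_sided=_sq(p1))


def multiplicity_control(p_values, method: str = "fdr",
                         level: float = 0.05) -> np.ndarray:
    """Multiple-testing threshold mask: BH step-up FDR or Bonferroni."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    V = p.size
    if method in ("bonferroni",):
        return p <= level / V
    if method in ("fdr", "bh", "bh-fdr"):
        order = np.argsort(p, kind="stable")
        thresh = level * np.arange(1, V + 1) / V
        passed = p[order] <= thresh
        mask = np.zeros(V, dtype=bool)
        if passed.any():
            kmax = np.max(np.flatnonzero(passed))
            mask[order[: kmax + 1]] = True
        return mask
    raise ValueError(f"unknown correction method {method!r}")
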