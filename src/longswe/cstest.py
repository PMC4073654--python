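"""Box's test of Compound Symmetry, adapted to missing data.

Compound Symmetry (CS — equal variances and equal pairwise correlations
across visits) is the covariance assumption under which the naive
subject-dummy OLS and random-intercept mixed models are valid.  This module
tests it: the largest usable complete-case subset of the data is selected,
the one-group common covariance is estimated from residuals of the marginal
fit, and the classical determinant likelihood-ratio test of equal variances /
equal covariances (Box, 1950) is applied, per response (voxel).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .design import LongitudinalDesign, fit_ols
from .inference import multiplicity_control

__all__ = [
    "BoxTestResult",
    "complete_case_subset",
    "box_cs_test",
    "cs_test_map",
]


@dataclass(frozen=True)
class BoxTestResult:
    statistic: float        # F-scale: corrected chi2 statistic / df1
    df1: float
    df2: float              # inf (chi-square limit of the F form)
    p: float
    n_complete: int
    visits_used: tuple
    chi2: float             # the corrected chi-square statistic itself


# ----------------------------------------------------------------------
def complete_case_subset(design: LongitudinalDesign, data=None):
    """Select the visit subset and subjects maximising usable complete cases.

    Dropping a sparsely observed visit can retain many more subjects, so
    "largest subset with no missingness" involves a trade-off.  The rule used
    here: search all visit subsets of size >= 2 and maximise
    ``n_complete * C(#visits, 2)`` (the number of subject-level covariance
    pair observations, an information proxy), breaking ties toward more
    visits.  Deterministic.

    Returns ``(sub_design, sub_data)``; ``sub_data`` is None when ``data`` is.
    """
    visits = list(np.unique(design.visit_cat))
    k_all = len(visits)
    if k_all > 16:
        raise ValueError("complete-case search over more than 16 visit "
                         "categories is not supported")
    # subject -> set of observed visits
    observed = [set(design.visit_cat[sl]) for sl in design.subject_slices]

    best = None
    for size in range(2, k_all + 1):
        for sub in combinations(visits, size):
            sset = set(sub)
            n_c = sum(1 for o in observed if sset <= o)
            # primary: pair-information proxy; ties: more subjects, then
            # more visits (so extra sparse visits never displace subjects)
            score = (n_c * size * (size - 1) // 2, n_c, size)
            if best is None or score > best[0]:
                best = (score, sub, n_c)
    _, sub, n_c = best
    if n_c < 3:
        raise ValueError(
            f"too few complete cases: best subset has {n_c} subject(s) "
            f"complete at visits {list(sub)}")

    sset = set(sub)
    keep_subject = {s for s, o in zip(design.subjects, observed) if sset <= o}
    rows = np.array([s in keep_subject and v in sset
                     for s, v in zip(design.subject_id, design.visit_cat)])
    sub_design = LongitudinalDesign(
        X=design.X[rows],
        subject_id=design.subject_id[rows],
        group_id=design.group_id[rows],
        visit_cat=design.visit_cat[rows],
        time=design.time[rows],
        column_names=design.column_names,
    )
    sub_data = None
    if data is not None:
        data = np.asarray(data, dtype=float)
        sub_data = data[rows]
    return sub_design, sub_data


def _box_statistic(V0: np.ndarray, n_df: int):
    """Corrected chi-square statistic and df for CS, vectorised over (V,k,k)."""
    k = V0.shape[-1]
    if k < 2:
        raise ValueError("Box's CS test needs at least 2 visits")
    s2 = np.einsum("vkk->v", V0) / k                          # mean variance
    off = (V0.sum(axis=(-2, -1)) - k * s2) / (k * (k - 1))    # mean covariance
    r = off / s2
    sign, logdet = np.linalg.slogdet(V0)
    with np.errstate(invalid="ignore", divide="ignore"):
        logdet0 = (k * np.log(s2) + (k - 1) * np.log1p(-r)
                   + np.log1p((k - 1) * r))
    bad = (sign <= 0) | ~np.isfinite(logdet0)
    lnLR = logdet - logdet0
    # Box's scale correction and chi-square df (Box 1950)
    c = k * (k + 1) ** 2 * (2 * k - 3) / (6.0 * (k - 1) * (k * k + k - 4))
    df = k * (k + 1) / 2.0 - 2.0
    chi2 = -(n_df - c) * lnLR
    chi2 = np.where(bad, np.nan, np.maximum(chi2, 0.0))
    return chi2, df


def box_cs_test(sub_design: LongitudinalDesign, sub_data) -> BoxTestResult:
    """Box's CS test for a single response on a complete-case design.

    Residuals of the marginal OLS fit are formed, the common covariance V0 is
    the per-visit mean of residual cross-products (one group), and the
    determinant-based statistic -(n - c) ln(|V0| / |V0_CS|) is referred to
    chi^2 with k(k+1)/2 - 2 df; n is the subject count minus the number of
    pure between-subject design columns, and c is Box's scale correction.
    """
    y = np.asarray(sub_data, dtype=float)
    if y.ndim != 1:
        raise ValueError("box_cs_test handles one response; use cs_test_map")
    res = cs_test_map(sub_design, y[:, None], correction=None,
                      subset_already_complete=True)
    return res["tests"][0]


def cs_test_map(design: LongitudinalDesign, Y, correction="fdr",
                level: float = 0.05, subset_already_complete: bool = False):
    """Per-response Box CS test over a response matrix.

    Returns a dict with keys ``tests`` (list of BoxTestResult), ``statistic``,
    ``p`` (arrays of length V), ``mask`` (after multiplicity correction; None
    if correction is None), ``surviving_fraction``, ``n_complete`` and
    ``visits_used``.  Per-response numerical failures yield NaN entries, not
    an abort.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if subset_already_complete:
        sub, suby = design, Y
    else:
        sub, suby = complete_case_subset(design, Y)
    visits = list(np.unique(sub.visit_cat))
    k = len(visits)
    m = sub.m
    if not np.all(sub.n_i == k):
        raise ValueError("design is not complete: every subject must be "
                         "observed at every retained visit")
    if m < k + 2:
        raise ValueError(f"Box's CS test needs at least {k + 2} complete "
                         f"subjects for {k} visits; have {m}")
    _, resid = fit_ols(sub, suby)                      # (n, V)
    E = resid.reshape(m, k, -1)                        # canonical (subject, visit) order
    V0 = np.einsum("mkv,mjv->vkj", E, E) / m
    # df of the covariance estimate: subjects minus the mean parameters
    # effectively fitted per visit (rank of the design rows at that visit)
    lost = max(int(np.linalg.matrix_rank(sub.X[sub.visit_cat == v]))
               for v in visits)
    n_df = m - lost
    if n_df < 2:
        raise ValueError("not enough subjects for Box's CS test after "
                         "accounting for between-subject columns")
    chi2, df = _box_statistic(V0, n_df)
    pvals = stats.chi2.sf(chi2, df)
    fstat = chi2 / df
    tests = [BoxTestResult(statistic=float(fstat[v]), df1=float(df),
                           df2=np.inf, p=float(pvals[v]), n_complete=m,
                           visits_used=tuple(visits), chi2=float(chi2[v]))
             for v in range(V0.shape[0])]
    mask = None
    frac = None
    if correction is not None:
        finite = np.isfinite(pvals)
        mask = np.zeros(pvals.size, dtype=bool)
        if finite.any():
            mask[finite] = multiplicity_control(pvals[finite], correction, level)
        frac = float(mask.mean())
    return {"tests": tests, "statistic": fstat, "p": pvals, "mask": mask,
            "surviving_fraction": frac, "n_complete": m,
            "visits_used": tuple(visits), "n_failed": int(np.isnan(pvals).sum())}
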