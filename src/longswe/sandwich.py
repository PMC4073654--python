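"""Sandwich (robust) covariance estimators for the marginal OLS fit.

The covariance of the OLS coefficients is estimated by the sandwich form

    S = (X'X)^-1 [ sum_i X_i' Vhat_i X_i ] (X'X)^-1

where Vhat_i estimates the within-subject covariance V_i.  Two variants are
provided:

* heterogeneous ("het") — the classic per-subject estimate
  Vhat_i = e_i e_i' built from subject i's own residuals only;
* homogeneous ("hom") — a common covariance V0g is estimated per group from
  all subjects' residuals at matched visit-category pairs, and Vhat_i is the
  sub-matrix of its group's V0g at subject i's observed visits.  This pools
  information across subjects and is markedly more stable in small samples.

Small-sample residual adjustments S0-S3 (the HC0-HC3 family generalised to
clustered data) rescale the residuals before either estimate is formed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import LongitudinalDesign, hat_diagonals

__all__ = [
    "SweResult",
    "GroupCovEstimate",
    "adjust_residuals",
    "swe_heterogeneous",
    "estimate_group_covariance",
    "psd_repair",
    "swe_homogeneous",
]

ADJUSTMENTS = ("S0", "S1", "S2", "S3")


@dataclass(frozen=True)
class SweResult:
    """Coefficients plus their sandwich covariance.

    ``S`` has shape (V, p, p) (one symmetric PSD matrix per response), or
    (V, q, q) when computed contrast-wise (``contrast`` is then set).
    """

    beta: np.ndarray
    S: np.ndarray
    variant: str
    adjustment: str
    residuals_adjusted: np.ndarray
    contrast: np.ndarray | None = None


@dataclass
class GroupCovEstimate:
    """Per-group common covariance estimates V0g with bookkeeping.

    Attributes
    ----------
    groups : list of labels
    visit_labels : dict group -> array of visit-category labels (k_g of them)
    V0 : dict group -> (V, k_g, k_g) ndarray (PSD after repair)
    pair_counts : dict group -> (k_g, k_g) integer matrix m_gkk'
    correlations : dict group -> (V, k_g, k_g) ndarray of rho0gkk'
    psd_repaired : dict group -> (V,) boolean, True where repair changed V0g
    zero_pair_flagged : dict group -> bool, True if some observed-visit pair
        had no subject seen at both visits (its covariance was set to 0)
    """

    groups: list
    visit_labels: dict
    V0: dict
    pair_counts: dict
    correlations: dict
    psd_repaired: dict
    zero_pair_flagged: dict = field(default_factory=dict)

    def to_frames(self) -> dict:
        """Audit export: one tidy DataFrame per group (first response only)."""
        out = {}
        for g in self.groups:
            labels = [str(v) for v in self.visit_labels[g]]
            V = pd.DataFrame(self.V0[g][0], index=labels, columns=labels)
            m = pd.DataFrame(self.pair_counts[g], index=labels, columns=labels)
            out[g] = pd.concat({"V0": V, "pair_count": m})
        return out


# ----------------------------------------------------------------------
def adjust_residuals(residuals, h, n: int, p: int, adjustment: str):
    """Apply a small-sample residual adjustment (S0-S3).

    S0: raw residuals; S1: global sqrt(n/(n-p)) inflation; S2: rowwise
    e_j / (1-h_j)^(1/2); S3: rowwise e_j / (1-h_j), with h_j the hat-matrix
    diagonal of observation j.
    """
    if adjustment not in ADJUSTMENTS:
        raise ValueError(f"unknown adjustment {adjustment!r}; expected one of {ADJUSTMENTS}")
    e = np.asarray(residuals, dtype=float)
    if adjustment == "S0":
        return e.copy()
    if adjustment == "S1":
        return e * np.sqrt(n / (n - p))
    h = np.asarray(h, dtype=float)
    saturated = np.flatnonzero(h >= 1.0 - 1e-12)
    if saturated.size:
        raise ValueError(
            f"{adjustment} adjustment undefined: observations {saturated.tolist()} "
            f"have leverage 1 (saturated)")
    scale = 1.0 / np.sqrt(1.0 - h) if adjustment == "S2" else 1.0 / (1.0 - h)
    return e * scale[:, None] if e.ndim == 2 else e * scale


def _bread(design: LongitudinalDesign) -> np.ndarray:
    return np.linalg.inv(design.X.T @ design.X)


def swe_heterogeneous(design: LongitudinalDesign, residuals_adjusted,
                      contrast=None) -> SweResult:
    """Heterogeneous sandwich: per-subject meat Vhat_i = e_i e_i'.

    For each response, S = B [ sum_i (X_i'e_i)(X_i'e_i)' ] B with bread
    B = (X'X)^-1 — positive semi-definite by construction.  When ``contrast``
    (q x p) is given, only the q x q projection C S C' is stored.
    """
    e = np.atleast_2d(np.asarray(residuals_adjusted, dtype=float))
    if e.ndim == 1:
        e = e[:, None]
    if e.shape[0] != design.n:
        e = e.T  # tolerate (V, n)
    B = _bread(design)
    # per-subject scores g_i = X_i' e_i : (m, p, V)
    scores = np.stack([design.X[sl].T @ e[sl] for sl in design.subject_slices])
    if contrast is not None:
        C = np.atleast_2d(np.asarray(contrast, dtype=float))
        CB = C @ B                              # (q, p)
        u = np.einsum("qp,mpv->mqv", CB, scores)
        S = np.einsum("mqv,mrv->vqr", u, u)
    else:
        u = np.einsum("qp,mpv->mqv", B, scores)  # B symmetric
        S = np.einsum("mqv,mrv->vqr", u, u)
    S = 0.5 * (S + np.transpose(S, (0, 2, 1)))
    return SweResult(beta=None, S=S, variant="het", adjustment="",
                     residuals_adjusted=e,
                     contrast=None if contrast is None else np.atleast_2d(contrast))


# ----------------------------------------------------------------------
def psd_repair(V: np.ndarray) -> np.ndarray:
    """Clamp negative eigenvalues of a symmetric matrix to zero.

    Missing data can make the assembled common covariance indefinite; the
    spectral repair replaces V by sum_j max(lambda_j, 0) v_j v_j'.  Idempotent,
    and returns the input values unchanged when V is already PSD.
    """
    V = np.asarray(V, dtype=float)
    if not np.allclose(V, V.T, atol=1e-10 * max(1.0, np.abs(V).max())):
        raise ValueError("psd_repair requires a symmetric matrix")
    w, U = np.linalg.eigh(0.5 * (V + V.T))
    if w.size == 0 or w[0] >= 0:
        return V
    w = np.clip(w, 0.0, None)
    return (U * w) @ U.T


def estimate_group_covariance(design: LongitudinalDesign, residuals_adjusted,
                              repair: bool = True) -> GroupCovEstimate:
    """Estimate the per-group common covariances V0g from residuals.

    The k-th diagonal element is the mean of e_ik^2 over subjects in group g
    observed at visit k (normalised by the pair count m_gkk, with no -1 bias
    correction: that role is played by the S1-S3 residual adjustments).  The
    (k, k') off-diagonal is rho0gkk' * sqrt(V0gkk V0gk'k') where rho0gkk' is
    the uncentred correlation over the subjects observed at both visits.
    Every V0g is spectrally repaired to PSD (a no-op on complete data).
    """
    e = np.asarray(residuals_adjusted, dtype=float)
    if e.ndim == 1:
        e = e[:, None]
    nV = e.shape[1]
    subj_group = design.subject_group()

    groups = list(np.unique(design.group_id))
    visit_labels, V0, counts, corrs, repaired, zero_flag = {}, {}, {}, {}, {}, {}
    for g in groups:
        gmask = np.flatnonzero(subj_group == g)
        labels = np.unique(design.visit_cat[design.group_id == g])
        k = len(labels)
        lab_index = {v: j for j, v in enumerate(labels)}
        mg = len(gmask)
        # residual table (m_g, k, V) with NaN for unobserved visits
        E = np.full((mg, k, nV), np.nan)
        for row, si in enumerate(gmask):
            sl = design.subject_slices[si]
            for loc, v in zip(range(sl.start, sl.stop), design.visit_cat[sl]):
                E[row, lab_index[v]] = e[loc]
        obs = ~np.isnan(E[:, :, 0])                      # (m_g, k)
        m_pair = (obs[:, :, None] & obs[:, None, :]).sum(axis=0)
        if np.any(np.diag(m_pair) == 0):
            bad = labels[np.diag(m_pair) == 0]
            raise ValueError(f"group {g!r}: visit categories {bad.tolist()} "
                             "defined but never observed")
        Ez = np.where(obs[:, :, None], E, 0.0)
        sq = np.einsum("mkv,mkv->kv", Ez, Ez)            # sum e_ik^2
        diag = sq.T / np.diag(m_pair)                    # (V, k)
        # pairwise sums over I(g,k,k'):
        cross = np.einsum("mkv,mjv->vkj", Ez, Ez)        # sum e_ik e_ik'
        # sum of e_ik^2 restricted to subjects observed at both k and k'
        # sq_pair[v,k,j] = sum_{i in I(g,k,j)} e_ik^2
        sq_pair = np.einsum("mkv,mj->vkj", Ez**2, obs.astype(float))
        denom = np.sqrt(sq_pair * np.transpose(sq_pair, (0, 2, 1)))
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = cross / denom
        zero_pairs = (m_pair == 0) & ~np.eye(k, dtype=bool)
        zero_flag[g] = bool(zero_pairs.any())
        if zero_flag[g]:
            warnings.warn(
                f"group {g!r}: {int(zero_pairs.sum() // 2)} visit pair(s) share "
                "no subject; their covariance is set to 0", stacklevel=2)
        rho = np.where(np.isfinite(rho), rho, 0.0)
        np.clip(rho, -1.0, 1.0, out=rho)
        for v in range(nV):
            np.fill_diagonal(rho[v], 1.0)
        sd = np.sqrt(diag)                               # (V, k)
        V0g = rho * sd[:, :, None] * sd[:, None, :]
        rep = np.zeros(nV, dtype=bool)
        if repair:
            for v in range(nV):
                fixed = psd_repair(V0g[v])
                if fixed is not V0g[v] and not np.array_equal(fixed, V0g[v]):
                    rep[v] = True
                    V0g[v] = fixed
        visit_labels[g] = labels
        V0[g] = V0g
        counts[g] = m_pair
        corrs[g] = rho
        repaired[g] = rep
    return GroupCovEstimate(groups=groups, visit_labels=visit_labels, V0=V0,
                            pair_counts=counts, correlations=corrs,
                            psd_repaired=repaired, zero_pair_flagged=zero_flag)


def swe_homogeneous(design: LongitudinalDesign, group_cov: GroupCovEstimate,
                    contrast=None) -> SweResult:
    """Homogeneous sandwich: Vhat_i is the V0g sub-matrix at subject i's visits."""
    B = _bread(design)
    subj_group = design.subject_group()
    nV = next(iter(group_cov.V0.values())).shape[0]
    q = design.p if contrast is None else np.atleast_2d(contrast).shape[0]
    if contrast is None:
        A = design.X @ B                                  # (n, p)
    else:
        C = np.atleast_2d(np.asarray(contrast, dtype=float))
        A = design.X @ B @ C.T                            # (n, q)
    S = np.zeros((nV, q, q))
    for si, sl in enumerate(design.subject_slices):
        g = subj_group[si]
        labels = group_cov.visit_labels[g]
        lab_index = {v: j for j, v in enumerate(labels)}
        try:
            idx = np.array([lab_index[v] for v in design.visit_cat[sl]])
        except KeyError as err:
            raise ValueError(
                f"subject {design.subjects[si]!r} has visit {err.args[0]!r} "
                f"absent from group {g!r}'s covariance estimate") from None
        Vi = group_cov.V0[g][:, idx[:, None], idx[None, :]]   # (V, ni, ni)
        Ai = A[sl]                                            # (ni, q)
        S += np.einsum("aq,vab,br->vqr", Ai, Vi, Ai)
    S = 0.5 * (S + np.transpose(S, (0, 2, 1)))
    return SweResult(beta=None, S=S, variant="hom", adjustment="",
                     residuals_adjusted=None,
                     contrast=None if contrast is None else np.atleast_2d(contrast))
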