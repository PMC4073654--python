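"""Longitudinal design container and design-matrix construction.

The marginal model fitted throughout this package is ``y_i = X_i beta + eps_i``
for subjects i = 1..m, with no random effects: the within-subject covariance
V_i = cov(eps_i) is a nuisance handled by the sandwich covariance estimator,
not by the mean model.  This module owns the grand design matrix X (the n x p
stack of the X_i), the subject / group / visit-category / time structure that
every estimator needs to index blocks of it, and the between/within covariate
decomposition recommended for longitudinal covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LongitudinalDesign",
    "build_design",
    "split_covariate",
    "hat_diagonals",
    "fit_ols",
]

_RANK_RTOL = 1e-10


@dataclass(frozen=True)
class LongitudinalDesign:
    """A validated longitudinal design: X plus its grouping structure.

    Rows are canonically ordered by (subject, visit) at construction so that
    all downstream per-subject block indexing is deterministic.

    Attributes
    ----------
    X : (n, p) ndarray
        Grand design matrix, full column rank.
    subject_id, group_id, visit_cat : (n,) ndarrays
        Per-row subject label, group label and visit-category label.
    time : (n,) ndarray of float
        Time of measurement (study-time units; used by the covariance
        generators and the time-decaying correlation model, not by X).
    column_names : tuple of str
        Names of the columns of X.
    """

    X: np.ndarray
    subject_id: np.ndarray
    group_id: np.ndarray
    visit_cat: np.ndarray
    time: np.ndarray
    column_names: tuple = ()
    # derived, filled in __post_init__
    subjects: np.ndarray = field(default=None, repr=False)
    subject_slices: tuple = field(default=None, repr=False)

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        n, p = X.shape
        subj = np.asarray(self.subject_id)
        grp = np.asarray(self.group_id)
        vis = np.asarray(self.visit_cat)
        t = np.asarray(self.time, dtype=float)
        for name, arr in (("subject_id", subj), ("group_id", grp),
                          ("visit_cat", vis), ("time", t)):
            if arr.shape != (n,):
                raise ValueError(f"{name} has length {arr.shape}, expected ({n},)")
        if not np.all(np.isfinite(X)):
            raise ValueError("design matrix contains non-finite values")

        # canonical (subject, visit) order
        order = np.lexsort((vis, subj))
        if not np.array_equal(order, np.arange(n)):
            X = X[order]
            subj, grp, vis, t = subj[order], grp[order], vis[order], t[order]
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "subject_id", subj)
        object.__setattr__(self, "group_id", grp)
        object.__setattr__(self, "visit_cat", vis)
        object.__setattr__(self, "time", t)

        # invariants
        pairs = pd.MultiIndex.from_arrays([subj, vis])
        if pairs.has_duplicates:
            dup = pairs[pairs.duplicated()][0]
            raise ValueError(f"duplicated (subject, visit) pair: {dup}")
        df = pd.DataFrame({"s": subj, "g": grp})
        if (df.groupby("s", sort=False)["g"].nunique() > 1).any():
            bad = df.groupby("s", sort=False)["g"].nunique()
            bad = bad[bad > 1].index[0]
            raise ValueError(f"group varies within subject {bad!r}")

        sv = np.linalg.svd(X, compute_uv=False)
        if p >= n or sv[-1] <= _RANK_RTOL * sv[0]:
            raise ValueError(
                f"design matrix is rank deficient or saturated "
                f"(n={n}, p={p}, smallest/largest singular value "
                f"{sv[-1] / sv[0]:.2e})"
            )

        subjects, starts = np.unique(subj, return_index=True)
        # np.unique sorts; rows are sorted by subject already so starts are ordered
        starts = np.sort(starts)
        bounds = np.append(starts, n)
        slices = tuple(slice(bounds[i], bounds[i + 1]) for i in range(len(starts)))
        object.__setattr__(self, "subjects", subj[starts])
        object.__setattr__(self, "subject_slices", slices)
        if not self.column_names:
            object.__setattr__(
                self, "column_names", tuple(f"x{j}" for j in range(p)))
        elif len(self.column_names) != p:
            raise ValueError("column_names length does not match p")

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def m(self) -> int:
        return len(self.subjects)

    @property
    def n_i(self) -> np.ndarray:
        """Observations per subject, in ``subjects`` order."""
        return np.array([s.stop - s.start for s in self.subject_slices])

    @property
    def groups(self) -> np.ndarray:
        """Unique group labels (sorted)."""
        return np.unique(self.group_id)

    def subject_group(self) -> np.ndarray:
        """Group label of each subject, in ``subjects`` order."""
        return np.array([self.group_id[s.start] for s in self.subject_slices])

    def between_subject_columns(self) -> np.ndarray:
        """Boolean mask of columns constant within every subject."""
        const = np.ones(self.p, dtype=bool)
        for sl in self.subject_slices:
            block = self.X[sl]
            const &= np.ptp(block, axis=0) == 0
        return const

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.X, columns=list(self.column_names))
        out.insert(0, "time", self.time)
        out.insert(0, "visit", self.visit_cat)
        out.insert(0, "group", self.group_id)
        out.insert(0, "subject", self.subject_id)
        return out


# ----------------------------------------------------------------------
def split_covariate(values, subject_id, centre_between: bool = False):
    """Split a covariate into between- and within-subject components.

    A time-varying covariate such as age confounds two different effects: a
    cross-sectional one (carried by the subject mean) and a longitudinal one
    (carried by the deviation from the subject mean).  Entering both components
    separately avoids forcing them to share a coefficient and makes the
    within-subject column orthogonal to everything constant within subject.

    Parameters
    ----------
    values : (n,) array_like
        Covariate values, finite.
    subject_id : (n,) array_like
        Subject labels.
    centre_between : bool
        If True, subtract the grand mean from the between component.

    Returns
    -------
    between, within : (n,) ndarrays
        ``between[j]`` is the subject mean of row j's subject (grand-mean
        centred if requested); ``within = values - subject mean`` and sums to
        zero within every subject by construction.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("covariate contains non-finite values")
    s = pd.Series(v)
    means = s.groupby(np.asarray(subject_id)).transform("mean").to_numpy()
    within = v - means
    between = means.copy()
    if centre_between:
        between -= v.mean()
    if np.ptp(within) == 0 and len(v) > 1:
        warnings.warn("covariate is constant within every subject; "
                      "within component is identically zero", stacklevel=2)
    return between, within


def build_design(long_table: pd.DataFrame, model_spec=None,
                 design_columns=None) -> LongitudinalDesign:
    """Build a validated :class:`LongitudinalDesign` from a long-format table.

    Parameters
    ----------
    long_table : DataFrame
        One row per observation with columns ``subject, group, visit, time``
        plus covariates.
    model_spec : list of (name, role) or None
        Declarative covariate roles.  Each entry is ``(column, role)`` with
        role one of:

        - ``"intercept"`` — a column of ones (column name is ignored);
        - ``"group_intercept"`` — one indicator column per group;
        - ``"raw"`` — the column as-is;
        - ``"split"`` — between/within decomposition (two columns, the
          between part grand-mean centred);
        - ``"split_by_group"`` — between/within decomposition interacted
          with group indicators.

        If None, ``design_columns`` must name numeric columns used verbatim.
    design_columns : list of str, optional
        Explicit numeric design columns (used when model_spec is None).
    """
    required = {"subject", "group", "visit", "time"}
    missing = required - set(long_table.columns)
    if missing:
        raise ValueError(f"long table is missing columns {sorted(missing)}")
    tab = long_table.sort_values(["subject", "visit"], kind="stable")
    tab = tab.reset_index(drop=True)
    n = len(tab)
    subj = tab["subject"].to_numpy()
    grp = tab["group"].to_numpy()

    cols, names = [], []
    if model_spec is None:
        if not design_columns:
            raise ValueError("either model_spec or design_columns is required")
        for c in design_columns:
            cols.append(tab[c].to_numpy(dtype=float))
            names.append(c)
    else:
        glabels = np.unique(grp)
        for cname, role in model_spec:
            if role == "intercept":
                cols.append(np.ones(n))
                names.append("intercept")
            elif role == "group_intercept":
                for g in glabels:
                    cols.append((grp == g).astype(float))
                    names.append(f"intercept[{g}]")
            elif role == "raw":
                cols.append(tab[cname].to_numpy(dtype=float))
                names.append(cname)
            elif role == "split":
                b, w = split_covariate(tab[cname], subj, centre_between=True)
                cols += [b, w]
                names += [f"{cname}_between", f"{cname}_within"]
            elif role == "split_by_group":
                b, w = split_covariate(tab[cname], subj, centre_between=True)
                for g in glabels:
                    ind = (grp == g).astype(float)
                    cols += [b * ind, w * ind]
                    names += [f"{cname}_between[{g}]", f"{cname}_within[{g}]"]
            else:
                raise ValueError(f"unknown covariate role {role!r}")
    X = np.column_stack(cols)
    return LongitudinalDesign(
        X=X,
        subject_id=subj,
        group_id=grp,
        visit_cat=tab["visit"].to_numpy(),
        time=tab["time"].to_numpy(dtype=float),
        column_names=tuple(names),
    )


# ----------------------------------------------------------------------
def hat_diagonals(design: LongitudinalDesign) -> np.ndarray:
    """Diagonal of the hat matrix X (X'X)^-1 X'.

    Computed through a thin QR factorisation, so each h_j = ||Q_j.||^2 is in
    [0, 1] and sum(h) = p up to rounding.
    """
    Q, _ = np.linalg.qr(design.X)
    return np.einsum("ij,ij->i", Q, Q)


def fit_ols(design: LongitudinalDesign, Y):
    """Ordinary least squares fit, columnwise over responses.

    With an identity working covariance the marginal-model point estimate is
    plain OLS: ``beta = (X'X)^-1 X' Y``.  Robustness to the unmodelled
    within-subject correlation is delegated entirely to the sandwich
    covariance estimator.

    Parameters
    ----------
    design : LongitudinalDesign
    Y : (n,) or (n, V) array_like
        Responses; V > 1 runs the mass-univariate (e.g. voxelwise) fit.

    Returns
    -------
    beta : (p, V) ndarray
    residuals : (n, V) ndarray
    """
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    if Y.shape[0] != design.n:
        raise ValueError(f"Y has {Y.shape[0]} rows, design has {design.n}")
    beta, _, _, _ = np.linalg.lstsq(design.X, Y, rcond=None)
    resid = Y - design.X @ beta
    return beta, resid
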