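"""Model/Results objects tying design, OLS fit, sandwich covariance and
Wald inference together.

    >>> model = SweModel.from_dataframe(df, response="vol",
    ...         model_spec=[("", "group_intercept"), ("age", "split_by_group")])
    >>> res = model.fit()                       # S3 homogeneous by default
    >>> res.t_test([0, 1, 0, 0, -1, 0]).p
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import sandwich
from .design import LongitudinalDesign, build_design, fit_ols, hat_diagonals
from .inference import (DofEstimate, SatterthwaiteDof, TestResult, estimate_dof,
                        naive_dof, wald_test)

__all__ = ["SweModel", "SweResults"]


class SweModel:
    """Marginal model for longitudinal/repeated-measures data.

    Point estimation is plain OLS (identity working covariance); the
    within-subject correlation enters only through the sandwich covariance of
    the coefficient estimates, so the fit is non-iterative and cannot fail to
    converge.

    Parameters
    ----------
    design : LongitudinalDesign
    endog : (n,) or (n, V) array_like
        Response(s); V > 1 fits every column (mass-univariate mode).
    """

    def __init__(self, design: LongitudinalDesign, endog):
        self.design = design
        Y = np.asarray(endog, dtype=float)
        self._squeeze = Y.ndim == 1
        self.endog = Y[:, None] if self._squeeze else Y
        if self.endog.shape[0] != design.n:
            raise ValueError("endog rows do not match design")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str, model_spec=None,
                       design_columns=None) -> "SweModel":
        design = build_design(df, model_spec=model_spec,
                              design_columns=design_columns)
        # build_design reorders rows; realign the response identically
        tab = df.sort_values(["subject", "visit"], kind="stable")
        return cls(design, tab[response].to_numpy(dtype=float))

    def fit(self, variant: str = "hom", adjustment: str = "S3",
            dof: str = "satterthwaite") -> "SweResults":
        """Fit OLS and the requested sandwich covariance.

        variant: "hom" (per-group common covariance, recommended) or "het";
        adjustment: S0-S3 residual adjustment (S3 recommended);
        dof: "satterthwaite" or "naive".
        """
        d = self.design
        beta, resid = fit_ols(d, self.endog)
        h = hat_diagonals(d)
        e_adj = sandwich.adjust_residuals(resid, h, d.n, d.p, adjustment)
        group_cov = None
        if variant == "hom":
            group_cov = sandwich.estimate_group_covariance(d, e_adj)
            sw = sandwich.swe_homogeneous(d, group_cov)
        elif variant == "het":
            sw = sandwich.swe_heterogeneous(d, e_adj)
        else:
            raise ValueError(f"unknown variant {variant!r}")
        return SweResults(self, beta=beta, S=sw.S, residuals=resid,
                          residuals_adjusted=e_adj, variant=variant,
                          adjustment=adjustment, dof_method=dof,
                          group_cov=group_cov)


@dataclass
class SweResults:
    """Fitted coefficients, sandwich covariance and inference methods."""

    model: SweModel
    beta: np.ndarray               # (p, V)
    S: np.ndarray                  # (V, p, p)
    residuals: np.ndarray          # raw OLS residuals (n, V)
    residuals_adjusted: np.ndarray
    variant: str
    adjustment: str
    dof_method: str
    group_cov: sandwich.GroupCovEstimate | None

    @property
    def params(self) -> np.ndarray:
        return self.beta[:, 0] if self.model._squeeze else self.beta

    def cov_params(self, response: int = 0) -> np.ndarray:
        return self.S[response]

    @property
    def bse(self) -> np.ndarray:
        se = np.sqrt(np.einsum("vpp->vp", self.S)).T  # (p, V)
        return se[:, 0] if self.model._squeeze else se

    # ------------------------------------------------------------------
    def dof(self, contrast) -> DofEstimate:
        if self.dof_method == "naive":
            return naive_dof(self.model.design)
        if self.variant == "hom":
            return estimate_dof(self.model.design, contrast,
                                group_cov=self.group_cov)
        return estimate_dof(self.model.design, contrast,
                            residuals=self.residuals)

    def wald_test(self, contrast, dof: DofEstimate | None = None) -> TestResult:
        if dof is None:
            dof = self.dof(contrast)
        res = wald_test(self.beta, self.S, contrast, dof)
        return res

    def t_test(self, contrast) -> TestResult:
        C = np.atleast_2d(np.asarray(contrast, dtype=float))
        if C.shape[0] != 1:
            raise ValueError("t_test requires a rank-1 (single-row) contrast")
        return self.wald_test(C)

    def f_test(self, contrast) -> TestResult:
        return self.wald_test(contrast)

    # ------------------------------------------------------------------
    def summary(self, response: int = 0) -> str:
        d = self.model.design
        names = d.column_names
        b = self.beta[:, response]
        se = np.sqrt(np.diag(self.S[response]))
        lines = [
            "Sandwich-estimator marginal model",
            "=" * 64,
            f"subjects: {d.m}    observations: {d.n}    "
            f"groups: {len(d.groups)}",
            f"variant: {self.variant}    adjustment: {self.adjustment}    "
            f"df: {self.dof_method}",
            "-" * 64,
            f"{'coef':<24}{'estimate':>12}{'robust SE':>12}{'t':>8}{'p':>8}",
        ]
        for j, name in enumerate(names):
            c = np.zeros(d.p)
            c[j] = 1.0
            tr = self.wald_test(c[None, :])
            t = np.atleast_1d(tr.t)[response]
            p = np.atleast_1d(tr.p)[response]
            lines.append(f"{name:<24}{b[j]:>12.4f}{se[j]:>12.4f}"
                         f"{t:>8.2f}{p:>8.4f}")
        lines.append("=" * 64)
        return "\n".join(lines)

    def params_frame(self, response: int = 0) -> pd.DataFrame:
        d = self.model.design
        se = np.sqrt(np.diag(self.S[response]))
        return pd.DataFrame({"coef": list(d.column_names),
                             "estimate": self.beta[:, response],
                             "robust_se": se})
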