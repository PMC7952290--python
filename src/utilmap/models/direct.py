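"""Direct mapping: regressing EQ-5D utility on QoL-AD predictors.

Five families are provided, mirroring standard practice for modelling
utilities with a ceiling at 1:

``ols_continuous``
    OLS of utility on the composite QoL-AD score (single predictor).
``ols_categorical``
    OLS of utility on item indicator contrasts.
``tobit``
    maximum-likelihood normal regression upper-censored at 1.
``clad``
    Powell's censored least absolute deviations (iterative trimming).
``two_part``
    logistic model of being at full health plus OLS below the ceiling,
    combined as  utility = Pr + (1 - Pr) * Y.

Predictions from the OLS/CLAD/two-part families are clamped above at 1;
the Tobit predicts the censored expectation E[min(y*, 1)], which is
strictly below 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr
from scipy.special import expit

from ..design import CovariateSpec, EstimationTable
from ..exceptions import (
    ConvergenceWarning,
    DegenerateDataError,
    SingularDesignError,
)
from .base import (
    ConvergenceInfo,
    format_coef_table,
    read_json,
    save_json,
    series_from_dict,
    series_to_dict,
)
from .lad import CLAD_MAX_ITER, clad_fit, clad_objective
from .tobit import TOBIT_MAX_ITER, TobitModel, tobit_expected

DIRECT_FAMILIES = ("ols_continuous", "ols_categorical", "tobit", "clad", "two_part")

_DEFAULT_ENCODING = {
    "ols_continuous": "score",
    "ols_categorical": "categorical",
    "tobit": "categorical",
    "clad": "categorical",
    "two_part": "categorical",
}

_CEIL_EPS = 1e-12


def two_part_combine(pr_perfect, y_conditional):
    """utility = Pr(PerfectHealth) + (1 - Pr(PerfectHealth)) * Y."""
    pr = np.asarray(pr_perfect, dtype=float)
    y = np.asarray(y_conditional, dtype=float)
    return pr + (1.0 - pr) * y


def check_full_rank(X: pd.DataFrame) -> None:
    """Raise SingularDesignError naming aliased columns if X is deficient."""
    arr = X.to_numpy(dtype=float)
    if arr.shape[0] < arr.shape[1]:
        raise SingularDesignError(list(X.columns), "more parameters than rows")
    _, R, piv = qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(arr.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int((diag > tol).sum())
    if rank < arr.shape[1]:
        aliased = [X.columns[j] for j in sorted(piv[rank:])]
        raise SingularDesignError(aliased)


class DirectMapping:
    """Direct-mapping model specification bound to an estimation table.

    Parameters
    ----------
    table : EstimationTable
        Output of :func:`utilmap.design.assemble_scenario`.
    family : str
        One of :data:`DIRECT_FAMILIES`.
    encoding : str, optional
        Override the family's conventional predictor encoding.
    """

    def __init__(self, table: EstimationTable, family: str, encoding: Optional[str] = None):
        if family not in DIRECT_FAMILIES:
            raise ValueError(f"unknown direct family {family!r}")
        self.table = table
        self.family = family
        self.spec = CovariateSpec.from_table(table, encoding or _DEFAULT_ENCODING[family])
        X, ok, _ = self.spec.design_matrix(table.frame, on_error="raise")
        assert ok.all()
        check_full_rank(X)
        self.exog = X
        self.endog = table.y

    def fit(self, cluster: bool = True) -> "DirectResults":
        """Estimate the model; returns a results object.

        ``cluster=True`` requests cluster-robust standard errors grouped on
        subject (point estimates are unaffected). CLAD never receives a
        cluster adjustment and reports no standard errors.
        """
        X = self.exog.to_numpy(dtype=float)
        y = self.endog
        names = list(self.exog.columns)
        clusters = self.table.clusters if cluster else None
        fitter = getattr(self, f"_fit_{self.family}")
        return fitter(X, y, names, clusters)

    # -- family fitters ---------------------------------------------------

    def _results(self, **kw) -> "DirectResults":
        return DirectResults(
            family=self.family,
            spec=self.spec,
            n=self.table.n,
            n_excluded=self.table.n_excluded,
            scenario_label=self.table.scenario.label(),
            **kw,
        )

    def _ols_blocks(self, X, y, clusters):
        res = sm.OLS(y, X).fit()
        if clusters is not None:
            from ..evaluation import cluster_robust_covariance

            scores = X * res.resid[:, None]
            bread = np.linalg.inv(X.T @ X)
            cov = cluster_robust_covariance(scores, bread, clusters)
        else:
            cov = res.cov_HC1
        return res.params, cov, res

    def _fit_ols_continuous(self, X, y, names, clusters):
        return self._fit_ols_categorical(X, y, names, clusters)

    def _fit_ols_categorical(self, X, y, names, clusters):
        params, cov, _ = self._ols_blocks(X, y, clusters)
        return self._results(
            params=pd.Series(params, index=names),
            bse=pd.Series(np.sqrt(np.diag(cov)), index=names),
            convergence=ConvergenceInfo(True, 0),
        )

    def _fit_tobit(self, X, y, names, clusters):
        model = TobitModel(y, X, censor=1.0)
        if not model.cens.any():
            warnings.warn(
                "no observations at the ceiling; Tobit reduces to OLS",
                UserWarning, stacklevel=3,
            )
        params, converged, nit = model.fit(maxiter=TOBIT_MAX_ITER)
        H = model.hessian(params)
        try:
            bread = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            bread = np.linalg.pinv(-H)
        if clusters is not None:
            from ..evaluation import cluster_robust_covariance

            cov = cluster_robust_covariance(model.score_obs(params), bread, clusters)
        else:
            cov = bread
        beta = pd.Series(params[:-1], index=names)
        return self._results(
            params=beta,
            bse=pd.Series(np.sqrt(np.abs(np.diag(cov)))[:-1], index=names),
            scale=float(np.exp(params[-1])),
            convergence=ConvergenceInfo(converged, nit),
        )

    def _fit_clad(self, X, y, names, clusters):
        if not (y >= 1 - _CEIL_EPS).any():
            # no censoring: trimming never triggers, but run the same loop
            pass
        beta, converged, nit = clad_fit(X, y, censor=1.0, maxiter=CLAD_MAX_ITER)
        return self._results(
            params=pd.Series(beta, index=names),
            bse=None,  # Powell SEs need density estimation; not provided
            convergence=ConvergenceInfo(converged, nit),
            objective=clad_objective(beta, X, y),
        )

    def _fit_two_part(self, X, y, names, clusters):
        at_ceiling = y >= 1 - _CEIL_EPS
        if not at_ceiling.any() or at_ceiling.all():
            raise DegenerateDataError(
                "two-part model needs observations both at and below the ceiling"
            )
        from .base import column_scales

        scales = column_scales(X)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            logit_res = sm.Logit(at_ceiling.astype(float), X / scales).fit(
                method="lbfgs", maxiter=200, disp=0
            )
        logit_params = np.asarray(logit_res.params) / scales
        sep = [w for w in caught if "erfect" in str(w.message) or "onverg" in str(w.message)]
        logit_conv = logit_res.mle_retvals.get("converged", True) and not sep
        if not logit_conv:
            warnings.warn(
                "two-part logistic component hit its iteration cap or a "
                "separation problem; coefficients at the cap retained",
                ConvergenceWarning, stacklevel=3,
            )
        below = ~at_ceiling
        ols_params, ols_cov, _ = self._ols_blocks(
            X[below], y[below], clusters[below] if clusters is not None else None
        )
        p = expit(X @ logit_params)
        if clusters is not None:
            from ..evaluation import cluster_robust_covariance

            scores = X * (at_ceiling.astype(float) - p)[:, None]
            W = p * (1 - p)
            bread = np.linalg.inv((X * W[:, None]).T @ X)
            logit_cov = cluster_robust_covariance(scores, bread, clusters)
        else:
            W = p * (1 - p)
            logit_cov = np.linalg.inv((X * W[:, None]).T @ X)
        return self._results(
            params=pd.Series(ols_params, index=names),
            bse=pd.Series(np.sqrt(np.diag(ols_cov)), index=names),
            params_logit=pd.Series(logit_params, index=names),
            bse_logit=pd.Series(np.sqrt(np.diag(logit_cov)), index=names),
            convergence=ConvergenceInfo(
                bool(logit_conv), int(logit_res.mle_retvals.get("iterations", 0))
            ),
        )


@dataclass
class DirectResults:
    """Fitted direct-mapping algorithm.

    ``params`` holds the main coefficient block (for the two-part family,
    the conditional-OLS part; the logistic part sits in ``params_logit``).
    """

    family: str
    spec: CovariateSpec
    params: pd.Series
    convergence: ConvergenceInfo
    n: int
    bse: Optional[pd.Series] = None
    scale: Optional[float] = None  # tobit sigma
    params_logit: Optional[pd.Series] = None
    bse_logit: Optional[pd.Series] = None
    objective: Optional[float] = None  # clad criterion value
    n_excluded: int = 0
    scenario_label: str = ""

    kind = "direct"

    # -- prediction -------------------------------------------------------

    def predict(self, frame: pd.DataFrame, kind: str = "default",
                on_error: str = "raise") -> np.ndarray:
        """Predicted utilities for new rows.

        ``kind`` applies to the Tobit family only: ``'default'`` (alias
        ``'expected'``) uses the censored expectation E[min(y*, 1)];
        ``'clamped'`` uses min(x'b, 1). With ``on_error='mask'``,
        unencodable rows yield NaN instead of raising.
        """
        X, ok, _ = self.spec.design_matrix(frame, on_error=on_error)
        arr = X.to_numpy(dtype=float)
        out = np.full(len(frame), np.nan)
        if ok.any():
            out[ok] = self._predict_design(arr[ok], kind)
        return out

    def _predict_design(self, X: np.ndarray, kind: str) -> np.ndarray:
        cols = list(self.spec.columns)
        xb = X @ self.params.reindex(cols).to_numpy()
        if self.family == "tobit":
            if kind == "clamped":
                return np.minimum(xb, 1.0)
            return tobit_expected(xb, self.scale, censor=1.0)
        if self.family == "two_part":
            pr = expit(X @ self.params_logit.reindex(cols).to_numpy())
            return np.minimum(two_part_combine(pr, xb), 1.0)
        return np.minimum(xb, 1.0)

    # -- presentation -----------------------------------------------------

    def summary(self) -> str:
        head = [
            f"Direct mapping results — family: {self.family}",
            f"scenario: {self.scenario_label}   n = {self.n} "
            f"(excluded {self.n_excluded})",
            f"converged: {self.convergence.converged} "
            f"(iterations {self.convergence.iterations})",
        ]
        if self.scale is not None:
            head.append(f"sigma: {self.scale:.4f}")
        if self.objective is not None:
            head.append(f"censored LAD objective: {self.objective:.4f}")
        parts = ["\n".join(head)]
        if self.params_logit is not None:
            parts.append(
                format_coef_table("Part 1: Pr(perfect health), logistic",
                                  self.params_logit, self.bse_logit)
            )
            parts.append(
                format_coef_table("Part 2: OLS below the ceiling",
                                  self.params, self.bse)
            )
        else:
            parts.append(format_coef_table("Coefficients", self.params, self.bse))
        return "\n\n".join(parts)

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "family": self.family,
            "covariate_spec": self.spec.to_dict(),
            "coefficients": series_to_dict(self.params),
            "coefficients_se": series_to_dict(self.bse),
            "coefficients_logit": series_to_dict(self.params_logit),
            "coefficients_logit_se": series_to_dict(self.bse_logit),
            "scale": self.scale,
            "objective": self.objective,
            "convergence": self.convergence.to_dict(),
            "n": self.n,
            "n_excluded": self.n_excluded,
            "scenario": self.scenario_label,
        }

    def save(self, path) -> None:
        save_json(self.to_dict(), path)

    @classmethod
    def from_dict(cls, d: dict) -> "DirectResults":
        return cls(
            family=d["family"],
            spec=CovariateSpec.from_dict(d["covariate_spec"]),
            params=series_from_dict(d["coefficients"]),
            bse=series_from_dict(d.get("coefficients_se")),
            params_logit=series_from_dict(d.get("coefficients_logit")),
            bse_logit=series_from_dict(d.get("coefficients_logit_se")),
            scale=d.get("scale"),
            objective=d.get("objective"),
            convergence=ConvergenceInfo.from_dict(d["convergence"]),
            n=int(d["n"]),
            n_excluded=int(d.get("n_excluded", 0)),
            scenario_label=d.get("scenario", ""),
        )

    @classmethod
    def load(cls, path) -> "DirectResults":
        return cls.from_dict(read_json(path))


def fit_ols_direct(table: EstimationTable, continuous: bool, cluster: bool = True) -> DirectResults:
    family = "ols_continuous" if continuous else "ols_categorical"
    return DirectMapping(table, family).fit(cluster=cluster)


def fit_tobit(table: EstimationTable, cluster: bool = True) -> DirectResults:
    return DirectMapping(table, "tobit").fit(cluster=cluster)


def fit_clad(table: EstimationTable) -> DirectResults:
    return DirectMapping(table, "clad").fit(cluster=False)


def fit_two_part(table: EstimationTable, cluster: bool = True) -> DirectResults:
    return DirectMapping(table, "two_part").fit(cluster=cluster)


def predict_direct(results: DirectResults, frame: pd.DataFrame, **kw) -> np.ndarray:
    return results.predict(frame, **kw)
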