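"""Response mapping: one model per EQ-5D-5L item, then utility conversion.

Each of the five EQ-5D dimensions is modelled separately from the shared
QoL-AD design (multinomial logit, ordered logit, or OLS treated as a
rounded continuous outcome). A fitted mapper turns a predictor row into
five level-probability vectors; the default utility conversion is the exact
expectation over all 5^5 = 3,125 joint states (dimensions independent):

    E[U] = sum_s [ prod_d p_d(s_d) ] * crosswalk(s)

A modal-state conversion (per-dimension argmax, ties to the lower level,
single crosswalk lookup) is provided as the alternative reading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel

from ..design import CovariateSpec, EstimationTable
from ..exceptions import (
    ConvergenceWarning,
    DegenerateDataError,
    DistributionError,
)
from ..instruments import EQ5D_CODES
from ..value_sets import Crosswalk
from .base import ConvergenceInfo, read_json, save_json
from .direct import check_full_rank

RESPONSE_FAMILIES = ("mlogit", "ologit", "ols_categorical", "ols_continuous")

_DEFAULT_ENCODING = {
    "mlogit": "categorical",
    "ologit": "categorical",
    "ols_categorical": "categorical",
    "ols_continuous": "continuous_items",
}

N_LEVELS = 5
_SUM_TOL = 1e-10
MAX_ITER = 200


def _softmax(scores: np.ndarray) -> np.ndarray:
    scores = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(scores)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class ItemModel:
    """Fitted model for one EQ-5D dimension.

    Coefficient storage by family:

    - ``mlogit``: ``coef`` has shape (K-1, p) — one row per non-reference
      observed level (reference = lowest observed level, normally 1).
    - ``ologit``: ``coef`` has shape (1, p) (no constant) and ``cutpoints``
      holds the K-1 strictly increasing thresholds.
    - ``ols_*``: ``coef`` has shape (1, p); prediction is a one-hot
      distribution at the fitted value rounded to the nearest level with
      halves rounded toward the higher (worse) level, clamped to [1, 5].
    """

    dimension: str
    family: str
    columns: Tuple[str, ...]
    observed_levels: Tuple[int, ...]
    coef: np.ndarray
    cutpoints: Optional[np.ndarray] = None
    bse: Optional[np.ndarray] = None
    convergence: ConvergenceInfo = field(default_factory=lambda: ConvergenceInfo(True, 0))

    def __post_init__(self):
        self.coef = np.atleast_2d(np.asarray(self.coef, dtype=float))
        if self.cutpoints is not None:
            self.cutpoints = np.asarray(self.cutpoints, dtype=float)
            if not np.all(np.diff(self.cutpoints) > 0):
                raise ValueError("ologit cutpoints must be strictly increasing")

    def predict_dist(self, X: np.ndarray) -> np.ndarray:
        """Probability over the 5 levels for each row of X, shape (n, 5)."""
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        out = np.zeros((n, N_LEVELS))
        levels = list(self.observed_levels)
        if self.family == "mlogit":
            scores = np.zeros((n, len(levels)))
            scores[:, 1:] = X @ self.coef.T
            probs = _softmax(scores)
            for j, lv in enumerate(levels):
                out[:, lv - 1] = probs[:, j]
        elif self.family == "ologit":
            xb = X @ self.coef[0]
            cum = np.ones((n, len(levels)))
            for j, cut in enumerate(self.cutpoints):
                cum[:, j] = 1.0 / (1.0 + np.exp(-(cut - xb)))
            probs = np.diff(np.concatenate([np.zeros((n, 1)), cum], axis=1), axis=1)
            probs = np.clip(probs, 0.0, None)
            probs /= probs.sum(axis=1, keepdims=True)
            for j, lv in enumerate(levels):
                out[:, lv - 1] = probs[:, j]
        else:
            fitted = X @ self.coef[0]
            # half-up toward the worse (higher) level, clamped to [1, 5]
            rounded = np.floor(fitted + 0.5).astype(int)
            rounded = np.clip(rounded, 1, N_LEVELS)
            out[np.arange(n), rounded - 1] = 1.0
        return out

    def to_dict(self) -> dict:
        return {
            "dimension": self.dimension,
            "family": self.family,
            "columns": list(self.columns),
            "observed_levels": list(self.observed_levels),
            "coef": self.coef.tolist(),
            "cutpoints": None if self.cutpoints is None else self.cutpoints.tolist(),
            "bse": None if self.bse is None else np.asarray(self.bse).tolist(),
            "convergence": self.convergence.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ItemModel":
        return cls(
            dimension=d["dimension"],
            family=d["family"],
            columns=tuple(d["columns"]),
            observed_levels=tuple(int(v) for v in d["observed_levels"]),
            coef=np.asarray(d["coef"], dtype=float),
            cutpoints=None if d["cutpoints"] is None else np.asarray(d["cutpoints"]),
            bse=None if d.get("bse") is None else np.asarray(d["bse"]),
            convergence=ConvergenceInfo.from_dict(d["convergence"]),
        )


def fit_item_model(levels: np.ndarray, X: pd.DataFrame, family: str,
                   dimension: str = "item") -> ItemModel:
    """Fit one dimension's response model.

    ``levels`` are the observed EQ-5D item responses (1-5); ``X`` the shared
    design matrix including a ``const`` column. Levels never observed get
    structural-zero predicted probability (a note is logged via warning).
    """
    levels = np.asarray(levels, dtype=int)
    observed = tuple(sorted(set(levels.tolist())))
    if len(observed) < 2:
        raise DegenerateDataError(
            f"dimension {dimension!r} shows a single response level "
            f"({observed[0] if observed else 'none'}); model unidentified"
        )
    if len(observed) < N_LEVELS:
        missing = sorted(set(range(1, N_LEVELS + 1)) - set(observed))
        warnings.warn(
            f"dimension {dimension!r}: levels {missing} never observed; "
            "they receive structural-zero probability",
            UserWarning, stacklevel=2,
        )
    codes = np.searchsorted(observed, levels)
    columns = tuple(X.columns)
    arr = X.to_numpy(dtype=float)

    if family == "mlogit":
        # fit on max-abs-scaled columns (exact reparameterisation) for
        # optimiser conditioning; try Newton, fall back to L-BFGS
        from .base import column_scales

        scales = column_scales(arr)
        model = sm.MNLogit(codes, arr / scales)
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method, iters in (("newton", MAX_ITER), ("lbfgs", MAX_ITER)):
                try:
                    cand = model.fit(method=method, maxiter=iters, disp=0)
                except np.linalg.LinAlgError:
                    continue
                if np.isfinite(np.asarray(cand.params)).all():
                    res = cand
                    break
        if res is None:
            raise DegenerateDataError(
                f"dimension {dimension!r}: multinomial logit estimation failed"
            )
        conv = _convergence(res)
        coef = (np.asarray(res.params) / scales[:, None]).T  # (K-1, p)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                bse = (np.asarray(res.bse) / scales[:, None]).T
        except (ValueError, np.linalg.LinAlgError):
            bse = np.full_like(coef, np.nan)  # no curvature from the fallback
        return ItemModel(dimension, family, columns, observed, coef, None, bse, conv)

    if family == "ologit":
        from .base import column_scales

        noconst = [c for c in X.columns if c != "const"]
        arr_nc = X[noconst].to_numpy(dtype=float)
        scales = column_scales(arr_nc)
        model = OrderedModel(codes, arr_nc / scales, distr="logit")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method="lbfgs", maxiter=MAX_ITER, disp=0)
        conv = _convergence(res)
        k = len(noconst)
        beta = np.zeros(len(columns))
        bse = np.zeros(len(columns))
        for j, name in enumerate(noconst):
            beta[columns.index(name)] = res.params[j] / scales[j]
            bse[columns.index(name)] = res.bse[j] / scales[j]
        thresholds = model.transform_threshold_params(res.params)[1:-1]
        return ItemModel(dimension, family, columns, observed,
                         beta[None, :], np.asarray(thresholds), bse[None, :], conv)

    if family in ("ols_categorical", "ols_continuous"):
        res = sm.OLS(levels.astype(float), arr).fit()
        return ItemModel(dimension, family, columns, observed,
                         res.params[None, :], None, res.bse[None, :],
                         ConvergenceInfo(True, 0))

    raise ValueError(f"unknown response family {family!r}")


def _convergence(res) -> ConvergenceInfo:
    ret = getattr(res, "mle_retvals", {}) or {}
    converged = bool(ret.get("converged", True))
    iters = int(ret.get("iterations", ret.get("nit", 0)) or 0)
    if not converged:
        warnings.warn(
            "item model hit its iteration cap; last iterate retained",
            ConvergenceWarning, stacklevel=3,
        )
    return ConvergenceInfo(converged, iters)


def _validate_dists(dists: np.ndarray) -> np.ndarray:
    dists = np.asarray(dists, dtype=float)
    if dists.ndim == 2:
        dists = dists[None, :, :]
    if dists.shape[1:] != (5, N_LEVELS):
        raise DistributionError(
            f"expected five 5-level distributions, got shape {dists.shape[1:]}"
        )
    if (dists < -1e-12).any():
        raise DistributionError("negative probabilities in response distribution")
    sums = dists.sum(axis=2)
    if np.abs(sums - 1.0).max() > _SUM_TOL:
        raise DistributionError(
            f"distributions must sum to 1 within {_SUM_TOL}; worst deviation "
            f"{np.abs(sums - 1.0).max():.3e}"
        )
    return dists


def expected_utility(dists, cw: Crosswalk):
    """Exact expected crosswalk utility under independent dimensions.

    ``dists`` is either a (5, 5) array (one distribution per dimension) or a
    (n, 5, 5) stack. Enumerates all 3,125 joint states; no sampling.
    """
    arr = _validate_dists(dists)
    tensor = cw.values_tensor()
    out = np.einsum(
        "na,nb,nc,nd,ne,abcde->n",
        arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], arr[:, 4], tensor,
        optimize=True,
    )
    return float(out[0]) if np.asarray(dists).ndim == 2 else out


def modal_state_utility(dists, cw: Crosswalk):
    """Utility of the per-dimension most probable state (ties -> lower level)."""
    arr = _validate_dists(dists)
    modal = arr.argmax(axis=2)  # first maximum = lower level on ties
    tensor = cw.values_tensor()
    out = tensor[modal[:, 0], modal[:, 1], modal[:, 2], modal[:, 3], modal[:, 4]]
    return float(out[0]) if np.asarray(dists).ndim == 2 else out


class ResponseMapping:
    """Response-mapping specification: five item models, one shared design."""

    def __init__(self, table: EstimationTable, family: str,
                 encoding: Optional[str] = None):
        if family not in RESPONSE_FAMILIES:
            raise ValueError(f"unknown response family {family!r}")
        if not table.has_states:
            raise DegenerateDataError(
                "response mapping needs target EQ-5D-5L item responses; "
                "this table carries utilities only"
            )
        self.table = table
        self.family = family
        self.spec = CovariateSpec.from_table(table, encoding or _DEFAULT_ENCODING[family])
        X, ok, _ = self.spec.design_matrix(table.frame, on_error="raise")
        assert ok.all()
        check_full_rank(X)
        self.exog = X

    def fit(self) -> "ResponseResults":
        states = self.table.states()
        items = {}
        for code in EQ5D_CODES:
            items[code] = fit_item_model(
                states[code].to_numpy(), self.exog, self.family, dimension=code
            )
        return ResponseResults(
            family=self.family,
            spec=self.spec,
            item_models=items,
            n=self.table.n,
            n_excluded=self.table.n_excluded,
            scenario_label=self.table.scenario.label(),
        )


@dataclass
class ResponseResults:
    """Fitted response-mapping algorithm (five item models)."""

    family: str
    spec: CovariateSpec
    item_models: Dict[str, ItemModel]
    n: int
    n_excluded: int = 0
    scenario_label: str = ""

    kind = "response"

    @property
    def convergence(self) -> ConvergenceInfo:
        infos = [m.convergence for m in self.item_models.values()]
        return ConvergenceInfo(
            all(i.converged for i in infos),
            max((i.iterations for i in infos), default=0),
        )

    def predict_distributions(self, frame: pd.DataFrame,
                              on_error: str = "raise") -> Tuple[np.ndarray, np.ndarray]:
        """(dists, ok): dists shape (n, 5 dims, 5 levels); NaN where not ok."""
        X, ok, _ = self.spec.design_matrix(frame, on_error=on_error)
        arr = X.to_numpy(dtype=float)
        n = len(frame)
        dists = np.full((n, 5, N_LEVELS), np.nan)
        if ok.any():
            sub = arr[ok]
            for d, code in enumerate(EQ5D_CODES):
                dists[ok, d, :] = self.item_models[code].predict_dist(sub)
        return dists, ok

    def predict(self, frame: pd.DataFrame, crosswalk: Crosswalk,
                method: str = "expected", on_error: str = "raise") -> np.ndarray:
        """Predicted utilities; ``method`` is 'expected' or 'modal'."""
        dists, ok = self.predict_distributions(frame, on_error=on_error)
        out = np.full(len(frame), np.nan)
        if ok.any():
            fn = expected_utility if method == "expected" else modal_state_utility
            out[ok] = fn(dists[ok], crosswalk)
        return out

    def summary(self) -> str:
        lines = [
            f"Response mapping results — family: {self.family}",
            f"scenario: {self.scenario_label}   n = {self.n} "
            f"(excluded {self.n_excluded})",
        ]
        for code, m in self.item_models.items():
            lines.append(
                f"  {code}: observed levels {list(m.observed_levels)}, "
                f"converged={m.convergence.converged} "
                f"(iterations {m.convergence.iterations})"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "family": self.family,
            "covariate_spec": self.spec.to_dict(),
            "items": {code: m.to_dict() for code, m in self.item_models.items()},
            "n": self.n,
            "n_excluded": self.n_excluded,
            "scenario": self.scenario_label,
        }

    def save(self, path) -> None:
        save_json(self.to_dict(), path)

    @classmethod
    def from_dict(cls, d: dict) -> "ResponseResults":
        return cls(
            family=d["family"],
            spec=CovariateSpec.from_dict(d["covariate_spec"]),
            item_models={c: ItemModel.from_dict(v) for c, v in d["items"].items()},
            n=int(d["n"]),
            n_excluded=int(d.get("n_excluded", 0)),
            scenario_label=d.get("scenario", ""),
        )

    @classmethod
    def load(cls, path) -> "ResponseResults":
        return cls.from_dict(read_json(path))


def fit_response_mapper(table: EstimationTable, family: str,
                        encoding: Optional[str] = None) -> ResponseResults:
    return ResponseMapping(table, family, encoding=encoding).fit()


def predict_item_distribution(model: ItemModel, X) -> np.ndarray:
    return model.predict_dist(np.atleast_2d(np.asarray(X, dtype=float)))
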