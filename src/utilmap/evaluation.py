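"""Model-performance metrics, calibration summaries and the comparison table.

`evaluate` reports the criteria conventional in utility-mapping studies:
RMSE and MAE of predicted against observed utilities, the share of
predictions within 0.1 utility points of the observation (boundary counted
as accurate), the predicted range, and per-quartile calibration rows
(observed-utility quartiles; median/IQR/10th-90th centiles of the
predictions falling in each).

`cluster_robust_covariance` is the sandwich estimator with score
contributions summed within clusters and a G/(G-1) small-sample factor —
the longitudinal data cluster repeated visits within subject, which affects
standard errors but never point estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .exceptions import DegenerateClusterError
from .value_sets import Crosswalk

ACCURACY_BAND = 0.1


@dataclass
class EvaluationReport:
    """Prediction-accuracy summary for one fitted mapping algorithm."""

    rmse: float
    mae: float
    accuracy_within_0_1: float  # percentage of |error| <= 0.1
    min_predicted: float
    max_predicted: float
    n: int
    quartile_rows: List[dict] = field(default_factory=list)
    label: str = ""

    def to_row(self) -> dict:
        return {
            "model": self.label,
            "rmse": self.rmse,
            "mae": self.mae,
            "min_predicted": self.min_predicted,
            "max_predicted": self.max_predicted,
            "accuracy_within_0.1_pct": self.accuracy_within_0_1,
            "n": self.n,
        }

    def quartile_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.quartile_rows)


def evaluate(predicted, observed, label: str = "") -> EvaluationReport:
    """Compare predicted with observed utilities.

    Quartiles are formed on the observed utilities (type-7 sample quantiles,
    boundary ties assigned to the lower quartile); each row summarises the
    predictions for observations in that quartile.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError(
            f"length mismatch: {predicted.shape} predictions vs "
            f"{observed.shape} observations"
        )
    if predicted.size == 0:
        raise ValueError("cannot evaluate on empty inputs")
    err = predicted - observed
    rmse = float(np.sqrt(np.mean(err ** 2)))
    mae = float(np.mean(np.abs(err)))
    accuracy = float(100.0 * np.mean(np.abs(err) <= ACCURACY_BAND))

    cuts = np.quantile(observed, [0.25, 0.5, 0.75])  # numpy default = type 7
    # searchsorted side='left': an observation equal to a boundary goes to
    # the lower quartile
    which = np.searchsorted(cuts, observed, side="left")
    rows = []
    for q in range(4):
        mask = which == q
        if not mask.any():
            rows.append({"quartile": q + 1, "n": 0})
            continue
        p = predicted[mask]
        rows.append(
            {
                "quartile": q + 1,
                "n": int(mask.sum()),
                "observed_mean": float(np.mean(observed[mask])),
                "predicted_median": float(np.median(p)),
                "predicted_p25": float(np.quantile(p, 0.25)),
                "predicted_p75": float(np.quantile(p, 0.75)),
                "predicted_p10": float(np.quantile(p, 0.10)),
                "predicted_p90": float(np.quantile(p, 0.90)),
            }
        )
    return EvaluationReport(
        rmse=rmse,
        mae=mae,
        accuracy_within_0_1=accuracy,
        min_predicted=float(predicted.min()),
        max_predicted=float(predicted.max()),
        n=int(predicted.size),
        quartile_rows=rows,
        label=label,
    )


def compare_models(
    fits: Dict[str, object],
    frame: pd.DataFrame,
    observed,
    crosswalk: Optional[Crosswalk] = None,
    labels: Optional[Dict[str, str]] = None,
) -> pd.DataFrame:
    """One evaluation row per fitted mapping algorithm.

    ``fits`` maps a family key to a fitted results object (direct or
    response); response results need ``crosswalk``. Rows keep the insertion
    order of ``fits`` (pass an ordered mapping for the conventional table
    layout); the lowest RMSE and MAE are flagged in ``best_rmse`` /
    ``best_mae`` columns.
    """
    observed = np.asarray(observed, dtype=float)
    rows = []
    for key, res in fits.items():
        if getattr(res, "kind", None) == "response":
            if crosswalk is None:
                raise ValueError("response-mapping results need a crosswalk")
            pred = res.predict(frame, crosswalk)
        else:
            pred = res.predict(frame)
        label = (labels or {}).get(key, key)
        rows.append(evaluate(pred, observed, label=label).to_row())
    table = pd.DataFrame(rows)
    table["best_rmse"] = table["rmse"] == table["rmse"].min()
    table["best_mae"] = table["mae"] == table["mae"].min()
    return table


def cluster_robust_covariance(score_obs, bread, cluster_ids) -> np.ndarray:
    """Sandwich covariance with within-cluster score aggregation.

    Parameters
    ----------
    score_obs : (n, p) array
        Per-observation score (estimating-equation) contributions, e.g.
        ``x_i * e_i`` for least squares.
    bread : (p, p) array
        The bread of the sandwich: inverse negative Hessian (MLE) or
        ``(X'X)^{-1}`` (least squares).
    cluster_ids : length-n array
        Cluster membership; with every observation its own cluster this is
        the HC-type heteroskedasticity-robust estimator (times n/(n-1)).

    Returns
    -------
    (p, p) covariance matrix, scaled by the small-sample factor G/(G-1).
    """
    scores = np.asarray(score_obs, dtype=float)
    bread = np.asarray(bread, dtype=float)
    ids = np.asarray(cluster_ids)
    if scores.ndim != 2 or len(ids) != scores.shape[0]:
        raise ValueError("score_obs must be (n, p) with one cluster id per row")
    _, inverse = np.unique(ids, return_inverse=True)
    G = int(inverse.max()) + 1
    if G < 2:
        raise DegenerateClusterError(
            f"cluster-robust covariance needs at least 2 clusters, got {G}"
        )
    p = scores.shape[1]
    summed = np.zeros((G, p))
    np.add.at(summed, inverse, scores)
    meat = summed.T @ summed
    return (G / (G - 1.0)) * bread @ meat @ bread
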