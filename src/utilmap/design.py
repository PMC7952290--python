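"""Scenario assembly and design-matrix encoding.

A mapping *scenario* fixes which rater's QoL-AD supplies the predictors,
which rater's EQ-5D supplies the target, whether item 7 enters, and whether
age and sex are included. :func:`assemble_scenario` applies complete-case
filtering (rows must have every required QoL-AD item and the target
utility) and produces an :class:`EstimationTable`.

Predictors enter models through a serialisable :class:`CovariateSpec` in one
of three encodings:

``score``
    the standardised composite QoL-AD score as a single continuous column;
``categorical``
    each item as indicator contrasts with level 1 (poor) as reference;
``continuous_items``
    each item as a continuous 1-4 score.

Age (continuous, uncentred) and a male indicator (female reference) are
appended when the scenario includes them. Levels never observed at fit time
are dropped from the design with a warning, and prediction on a row showing
such a level raises rather than silently mapping to the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .exceptions import EmptyScenarioError, PredictionError
from .instruments import EQ5D_CODES, ITEM_MARRIAGE, N_ITEMS, score_qolad

ENCODINGS = ("score", "categorical", "continuous_items")


@dataclass(frozen=True)
class Scenario:
    """Rater pairing and covariate switches for one mapping exercise."""

    predictor_rater: str = "self"
    target_rater: str = "self"
    include_item7: bool = False
    include_age_sex: bool = True

    def __post_init__(self):
        for name in ("predictor_rater", "target_rater"):
            if getattr(self, name) not in ("self", "proxy"):
                raise ValueError(f"{name} must be 'self' or 'proxy'")

    def label(self) -> str:
        return (
            f"{self.predictor_rater}->{self.target_rater}"
            f"{'+item7' if self.include_item7 else ''}"
            f"{'+agesex' if self.include_age_sex else ''}"
        )


def scenario_items(include_item7: bool) -> Tuple[int, ...]:
    return tuple(
        i for i in range(1, N_ITEMS + 1) if include_item7 or i != ITEM_MARRIAGE
    )


@dataclass
class EstimationTable:
    """Complete-case rows for one scenario, ready for model fitting.

    ``frame`` columns: subject_id, q1..q13 (float, NaN where excluded),
    score, age, male, y (target utility) and mo/sc/ua/pd/ad (target 5L
    levels; NaN when the target was supplied as a bare utility).
    """

    frame: pd.DataFrame
    scenario: Scenario
    n_total: int
    n_excluded: int

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def y(self) -> np.ndarray:
        return self.frame["y"].to_numpy(dtype=float)

    @property
    def clusters(self) -> np.ndarray:
        return self.frame["subject_id"].to_numpy()

    @property
    def has_states(self) -> bool:
        return bool(self.frame[list(EQ5D_CODES)].notna().all(axis=None))

    def states(self) -> pd.DataFrame:
        """Target EQ-5D-5L levels (one column per dimension code)."""
        return self.frame[list(EQ5D_CODES)].astype(int)


def assemble_scenario(observations, scenario: Scenario) -> EstimationTable:
    """Complete-case estimation table for a scenario.

    A row is included when the predictor rater's QoL-AD has every required
    item, the target rater's utility is present, and (if requested) age and
    sex are present. Exclusion counts are retained on the result.
    """
    observations = list(observations)
    if not observations:
        raise EmptyScenarioError("no observations supplied")
    items = scenario_items(scenario.include_item7)
    rows = []
    for obs in observations:
        rec = obs.qolad(scenario.predictor_rater)
        y = obs.utility(scenario.target_rater)
        if rec is None or y is None:
            continue
        if any(rec.items[i - 1] is None for i in items):
            continue
        if scenario.include_age_sex and (obs.age is None or obs.sex is None):
            continue
        row = {
            "subject_id": obs.subject_id,
            "visit": obs.visit,
            "age": obs.age,
            "male": 1.0 if obs.sex == "male" else 0.0 if obs.sex == "female" else np.nan,
            "y": float(y),
        }
        for i in range(1, N_ITEMS + 1):
            v = rec.items[i - 1]
            row[f"q{i}"] = np.nan if v is None else float(v)
        row["score"] = score_qolad(rec, include_item7=scenario.include_item7)
        state = obs.eq5d(scenario.target_rater)
        for j, code in enumerate(EQ5D_CODES):
            row[code] = (
                float(state.levels[j])
                if state is not None and state.version == "5L"
                else np.nan
            )
        rows.append(row)
    if not rows:
        raise EmptyScenarioError(
            f"zero complete cases for scenario {scenario.label()}"
        )
    frame = pd.DataFrame(rows).reset_index(drop=True)
    return EstimationTable(
        frame=frame,
        scenario=scenario,
        n_total=len(observations),
        n_excluded=len(observations) - len(frame),
    )


@dataclass(frozen=True)
class CovariateSpec:
    """Serialised design encoding; owns fit-time and predict-time encoding."""

    encoding: str
    items: Tuple[int, ...]
    include_age_sex: bool
    include_item7: bool
    #: categorical only — per item, the non-reference levels kept as columns
    item_levels: Dict[int, Tuple[int, ...]] = field(default_factory=dict)
    #: categorical only — per item, every level observed at fit time
    observed_levels: Dict[int, Tuple[int, ...]] = field(default_factory=dict)

    @property
    def columns(self) -> Tuple[str, ...]:
        cols = ["const"]
        if self.encoding == "score":
            cols.append("score")
        elif self.encoding == "continuous_items":
            cols.extend(f"q{i}" for i in self.items)
        else:
            for i in self.items:
                cols.extend(f"q{i}_{lv}" for lv in self.item_levels.get(i, ()))
        if self.include_age_sex:
            cols.extend(["age", "male"])
        return tuple(cols)

    @classmethod
    def from_table(cls, table: EstimationTable, encoding: str) -> "CovariateSpec":
        """Determine the encoding (incl. observed levels) from fit data."""
        if encoding not in ENCODINGS:
            raise ValueError(f"encoding must be one of {ENCODINGS}")
        scenario = table.scenario
        items = scenario_items(scenario.include_item7)
        item_levels: Dict[int, Tuple[int, ...]] = {}
        observed: Dict[int, Tuple[int, ...]] = {}
        if encoding == "categorical":
            dropped = []
            for i in items:
                seen = sorted(set(table.frame[f"q{i}"].astype(int)))
                observed[i] = tuple(seen)
                keep = tuple(lv for lv in (2, 3, 4) if lv in seen)
                item_levels[i] = keep
                dropped.extend(f"q{i}_{lv}" for lv in (2, 3, 4) if lv not in seen)
            if dropped:
                warnings.warn(
                    "levels never observed in the estimation data were "
                    f"dropped from the design: {dropped}",
                    UserWarning,
                    stacklevel=2,
                )
        return cls(
            encoding=encoding,
            items=items,
            include_age_sex=scenario.include_age_sex,
            include_item7=scenario.include_item7,
            item_levels=item_levels,
            observed_levels=observed,
        )

    # -- encoding ---------------------------------------------------------

    def design_matrix(
        self, frame: pd.DataFrame, on_error: str = "raise"
    ) -> Tuple[pd.DataFrame, np.ndarray, pd.Series]:
        """Encode rows under this specification.

        Returns ``(X, ok, reasons)``: the design matrix (rows that could not
        be encoded are filled with NaN), a boolean mask of encodable rows,
        and a per-row reason string (empty where ok). With
        ``on_error='raise'`` any problem raises :class:`PredictionError`.
        """
        frame = normalise_predictors(frame)
        n = len(frame)
        reasons = pd.Series([""] * n, index=frame.index, dtype=object)

        def flag(mask, reason):
            fresh = mask & (reasons == "")
            reasons[fresh] = reason

        data = {"const": np.ones(n)}
        if self.encoding == "score":
            if "score" in frame.columns:
                score = pd.to_numeric(frame["score"], errors="coerce")
            else:
                score = _score_from_items(frame, self.include_item7)
            flag(score.isna(), "missing QoL-AD items for composite score")
            data["score"] = score.to_numpy(dtype=float)
        elif self.encoding == "continuous_items":
            for i in self.items:
                col = pd.to_numeric(frame.get(f"q{i}"), errors="coerce")
                flag(col.isna(), f"missing QoL-AD item {i}")
                data[f"q{i}"] = col.to_numpy(dtype=float)
        else:
            for i in self.items:
                col = pd.to_numeric(frame.get(f"q{i}"), errors="coerce")
                flag(col.isna(), f"missing QoL-AD item {i}")
                seen = self.observed_levels.get(i, (1, 2, 3, 4))
                unseen = col.notna() & ~col.isin(seen)
                flag(unseen, f"item {i} level not observed at fit time")
                col = col.where(~unseen)
                for lv in self.item_levels.get(i, ()):
                    data[f"q{i}_{lv}"] = (col == lv).astype(float).to_numpy()
        if self.include_age_sex:
            age = pd.to_numeric(frame.get("age"), errors="coerce")
            flag(age.isna(), "missing age")
            data["age"] = age.to_numpy(dtype=float)
            male = frame.get("male")
            if male is None and "sex" in frame.columns:
                sexes = frame["sex"].astype(str).str.strip().str.lower()
                male = sexes.map({"male": 1.0, "female": 0.0})
            male = pd.to_numeric(male, errors="coerce")
            flag(male.isna(), "missing sex")
            data["male"] = male.to_numpy(dtype=float)

        X = pd.DataFrame(data, index=frame.index)[list(self.columns)]
        ok = (reasons == "").to_numpy()
        X[~ok] = np.nan
        if on_error == "raise" and not ok.all():
            bad = reasons[~ok]
            raise PredictionError(
                f"{len(bad)} rows cannot be encoded; first problem "
                f"(row {bad.index[0]}): {bad.iloc[0]}"
            )
        return X, ok, reasons

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "encoding": self.encoding,
            "items": list(self.items),
            "include_age_sex": self.include_age_sex,
            "include_item7": self.include_item7,
            "item_levels": {str(k): list(v) for k, v in self.item_levels.items()},
            "observed_levels": {
                str(k): list(v) for k, v in self.observed_levels.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateSpec":
        return cls(
            encoding=d["encoding"],
            items=tuple(d["items"]),
            include_age_sex=d["include_age_sex"],
            include_item7=d["include_item7"],
            item_levels={int(k): tuple(v) for k, v in d["item_levels"].items()},
            observed_levels={
                int(k): tuple(v) for k, v in d["observed_levels"].items()
            },
        )


def _score_from_items(frame: pd.DataFrame, include_item7: bool) -> pd.Series:
    items = scenario_items(include_item7)
    cols = {}
    for i in items:
        cols[i] = pd.to_numeric(frame.get(f"q{i}"), errors="coerce")
    block = pd.DataFrame(cols)
    raw = block.sum(axis=1)
    ok = block.notna().all(axis=1)
    if include_item7:
        score = raw.astype(float)
    else:
        score = 13.0 + (raw - 12.0) * (39.0 / 36.0)
    return score.where(ok)


def normalise_predictors(frame: pd.DataFrame, rater: Optional[str] = None) -> pd.DataFrame:
    """Map column-dictionary names onto canonical predictor names.

    ``{rater}_qolad_i`` -> ``qi`` (for the requested rater, or whichever
    single rater's block is present), keeping subject_id/age/sex/male as-is.
    Frames already in canonical form pass through unchanged.
    """
    cols = set(frame.columns)
    if any(c.startswith("q") and c[1:].isdigit() for c in cols):
        return frame
    if rater is None:
        for cand in ("self", "proxy"):
            if f"{cand}_qolad_1" in cols:
                rater = cand
                break
    rename = {}
    if rater is not None:
        for i in range(1, N_ITEMS + 1):
            src = f"{rater}_qolad_{i}"
            if src in cols:
                rename[src] = f"q{i}"
    out = frame.rename(columns=rename).copy()
    if rename:
        for i in range(1, N_ITEMS + 1):
            col = out.get(f"q{i}")
            if col is not None and col.dtype == object:
                from .instruments import encode_response
                def enc(v):
                    if v is None or (isinstance(v, float) and pd.isna(v)):
                        return np.nan
                    if isinstance(v, str) and not v.strip():
                        return np.nan
                    try:
                        return float(encode_response(v))
                    except Exception:
                        return np.nan
                out[f"q{i}"] = col.map(enc)
    return out
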