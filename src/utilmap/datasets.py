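"""Per-observation records and CSV input/output.

Column dictionary (one row per subject-visit; missing values are empty
cells):

========================  ===================================================
column                    meaning
========================  ===================================================
subject_id                opaque subject identifier (clustering unit)
visit                     integer visit index (0 = baseline)
age                       age of the person with dementia, years
sex                       ``female`` / ``male``
{r}_qolad_1..13           QoL-AD responses for rater ``r`` in {self, proxy};
                          labels (poor/fair/good/excellent) or levels 1-4
{r}_eq5d5l_{d}            EQ-5D-5L level 1-5, dimension ``d`` in
                          {mo, sc, ua, pd, ad}
{r}_eq5d3l_{d}            EQ-5D-3L level 1-3 (validation-style data)
{r}_utility               observed utility; if absent it is derived from the
                          5L state (crosswalk) or 3L state (tariff)
========================  ===================================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional

import pandas as pd

from .exceptions import FormatError
from .instruments import (
    EQ5D_CODES,
    N_ITEMS,
    Eq5dState,
    QolAdRecord,
    encode_response,
)
from .value_sets import Crosswalk, Tariff3L, crosswalk_utility, utility_3l

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Observation:
    """One subject-visit with both raters' questionnaires where available."""

    subject_id: str
    visit: int
    age: Optional[float] = None
    sex: Optional[str] = None
    qolad_self: Optional[QolAdRecord] = None
    qolad_proxy: Optional[QolAdRecord] = None
    eq5d_self: Optional[Eq5dState] = None
    eq5d_proxy: Optional[Eq5dState] = None
    utility_self: Optional[float] = None
    utility_proxy: Optional[float] = None

    def __post_init__(self):
        for name in ("utility_self", "utility_proxy"):
            u = getattr(self, name)
            if u is not None and u > 1 + 1e-12:
                raise ValueError(f"{name} exceeds 1: {u}")

    def qolad(self, rater: str) -> Optional[QolAdRecord]:
        return self.qolad_self if rater == "self" else self.qolad_proxy

    def eq5d(self, rater: str) -> Optional[Eq5dState]:
        return self.eq5d_self if rater == "self" else self.eq5d_proxy

    def utility(self, rater: str) -> Optional[float]:
        return self.utility_self if rater == "self" else self.utility_proxy


def _parse_ordinal(value, top: int):
    """Parse an ordinal cell; returns (level or None, parse_failed flag)."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None, False
    if isinstance(value, str) and not value.strip():
        return None, False
    try:
        if top == 4:
            return encode_response(value), False
        level = int(float(value))
        if 1 <= level <= top:
            return level, False
        return None, True
    except (ValueError, TypeError):
        return None, True


def _qolad_columns(rater: str):
    return [f"{rater}_qolad_{i}" for i in range(1, N_ITEMS + 1)]


def read_dataset(
    path,
    crosswalk: Optional[Crosswalk] = None,
    tariff: Optional[Tariff3L] = None,
) -> List[Observation]:
    """Read observations from CSV per the module column dictionary.

    Utilities absent from the file are derived from the 5L state via
    ``crosswalk`` or, failing that, from the 3L state via ``tariff`` when
    those objects are supplied. Unparseable ordinal cells become missing;
    their count is logged.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "sex": str})
    if "subject_id" not in df.columns:
        raise FormatError("dataset is missing mandatory column 'subject_id'")
    needed = [c for c in _qolad_columns("self") if c != "self_qolad_7"]
    needed_proxy = [c for c in _qolad_columns("proxy") if c != "proxy_qolad_7"]
    if not (
        set(needed).issubset(df.columns) or set(needed_proxy).issubset(df.columns)
    ):
        raise FormatError(
            "dataset must contain the 12 non-item-7 QoL-AD columns for at "
            "least one rater (self_qolad_* or proxy_qolad_*)"
        )

    observations = []
    n_unparseable = 0
    for idx, row in df.iterrows():
        subject_id = row["subject_id"]
        visit = int(row["visit"]) if "visit" in df.columns and pd.notna(row.get("visit")) else 0
        age = None
        if "age" in df.columns and pd.notna(row.get("age")):
            age = float(row["age"])
        sex = None
        if "sex" in df.columns and isinstance(row.get("sex"), str) and row["sex"].strip():
            sex = row["sex"].strip().lower()

        kwargs = {}
        for rater in ("self", "proxy"):
            cols = _qolad_columns(rater)
            if set(c for c in cols if not c.endswith("_7")).issubset(df.columns):
                items = []
                for col in cols:
                    level, failed = _parse_ordinal(row.get(col), top=4)
                    n_unparseable += failed
                    items.append(level)
                if any(v is not None for v in items):
                    kwargs[f"qolad_{rater}"] = QolAdRecord(
                        subject_id=subject_id, visit=visit, rater=rater,
                        items=tuple(items), age=age, sex=sex,
                    )
            for version, top in (("5l", 5), ("3l", 3)):
                cols5 = [f"{rater}_eq5d{version}_{d}" for d in EQ5D_CODES]
                if set(cols5).issubset(df.columns):
                    levels = []
                    for col in cols5:
                        level, failed = _parse_ordinal(row.get(col), top=top)
                        n_unparseable += failed
                        levels.append(level)
                    if all(v is not None for v in levels):
                        kwargs[f"eq5d_{rater}"] = Eq5dState(
                            version.upper(), tuple(levels)
                        )

            utility = None
            ucol = f"{rater}_utility"
            if ucol in df.columns and pd.notna(row.get(ucol)):
                utility = float(row[ucol])
            else:
                state = kwargs.get(f"eq5d_{rater}")
                if state is not None:
                    if state.version == "5L" and crosswalk is not None:
                        utility = crosswalk_utility(state, crosswalk)
                    elif state.version == "3L" and tariff is not None:
                        utility = utility_3l(state, tariff)
            if utility is not None:
                kwargs[f"utility_{rater}"] = utility

        observations.append(
            Observation(subject_id=subject_id, visit=visit, age=age, sex=sex, **kwargs)
        )
    if n_unparseable:
        logger.warning("read_dataset: %d unparseable ordinal cells set to missing",
                       n_unparseable)
    return observations


def to_frame(observations) -> pd.DataFrame:
    """Observations -> DataFrame in the column-dictionary layout."""
    rows = []
    for obs in observations:
        row = {
            "subject_id": obs.subject_id,
            "visit": obs.visit,
            "age": obs.age,
            "sex": obs.sex,
        }
        for rater in ("self", "proxy"):
            rec = obs.qolad(rater)
            for i in range(1, N_ITEMS + 1):
                row[f"{rater}_qolad_{i}"] = rec.items[i - 1] if rec else None
            state = obs.eq5d(rater)
            for j, code in enumerate(EQ5D_CODES):
                key = f"{rater}_eq5d5l_{code}" if state and state.version == "5L" \
                    else f"{rater}_eq5d3l_{code}"
                row[key] = state.levels[j] if state else None
            row[f"{rater}_utility"] = obs.utility(rater)
        rows.append(row)
    frame = pd.DataFrame(rows)
    # keep a stable column order: ids, demographics, then rater blocks
    lead = ["subject_id", "visit", "age", "sex"]
    rest = [c for c in frame.columns if c not in lead]
    return frame[lead + rest]


def write_dataset(observations, path) -> None:
    """Write observations to CSV (empty cells for missing values)."""
    to_frame(observations).to_csv(path, index=False)
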