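"""EQ-5D value sets: 3L additive tariffs and 5L->3L crosswalk tables.

A 3L value set (tariff) attaches a societal utility to each of the 243
three-level health states by subtracting decrements from full health (1):
a constant for any dysfunction, a per-dimension per-level decrement, and an
extra term if any dimension is at level 3. A crosswalk maps each of the
3,125 five-level states to a 3L-valued utility, so 5L data can be valued
with a 3L tariff.

The UK (Dolan) 3L tariff ships with the package. No published 5L->3L
crosswalk table ships; :func:`synthetic_uk_crosswalk` constructs a synthetic
stand-in with the same structure (see its docstring), and any externally
obtained table can be loaded from CSV with :func:`load_crosswalk`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Mapping

import numpy as np
import pandas as pd

from .exceptions import CrosswalkIntegrityError, FormatError, StateError
from .instruments import EQ5D_CODES, Eq5dState

__all__ = [
    "Tariff3L",
    "Crosswalk",
    "utility_3l",
    "crosswalk_utility",
    "load_value_set",
    "load_crosswalk",
    "uk_tariff",
    "synthetic_uk_crosswalk",
]


@dataclass(frozen=True)
class Tariff3L:
    """Additive EQ-5D-3L tariff.

    utility(state) = 1 - constant*1{any level > 1}
                       - sum_d decrement(d, level_d)
                       - n3 * 1{any level == 3}
    """

    constant: float
    decrements: Mapping  # (dimension code, level in {2,3}) -> decrement >= 0
    n3: float
    label: str = "unnamed"

    def __post_init__(self):
        dec = dict(self.decrements)
        for (code, level), value in dec.items():
            if code not in EQ5D_CODES:
                raise FormatError(f"unknown dimension code {code!r} in tariff")
            if level not in (2, 3):
                raise FormatError(f"tariff decrement level must be 2 or 3, got {level!r}")
            if value < 0:
                raise FormatError(f"negative decrement for ({code}, {level}): {value}")
        missing = [
            (c, l) for c in EQ5D_CODES for l in (2, 3) if (c, l) not in dec
        ]
        if missing:
            raise FormatError(f"tariff is missing decrements for {missing}")
        if self.constant < 0 or self.n3 < 0:
            raise FormatError("tariff constant and N3 term must be non-negative")
        object.__setattr__(self, "decrements", dec)

    def utility(self, state) -> float:
        return utility_3l(state, self)

    def values_tensor(self) -> np.ndarray:
        """Utilities of all 243 3L states as a (3,3,3,3,3) array."""
        out = np.empty((3,) * 5)
        for levels in itertools.product((1, 2, 3), repeat=5):
            out[tuple(l - 1 for l in levels)] = utility_3l(levels, self)
        return out


def utility_3l(state, tariff: Tariff3L) -> float:
    """Utility of a 3L health state under an additive tariff.

    ``state`` may be an :class:`Eq5dState` (version 3L) or a plain sequence
    of five levels in {1, 2, 3}.
    """
    if isinstance(state, Eq5dState):
        if state.version != "3L":
            raise StateError(f"expected a 3L state, got version {state.version}")
        levels = state.levels
    else:
        levels = tuple(state)
        Eq5dState("3L", levels)  # validates
    u = 1.0
    if any(lv > 1 for lv in levels):
        u -= tariff.constant
    for code, lv in zip(EQ5D_CODES, levels):
        if lv > 1:
            u -= tariff.decrements[(code, lv)]
    if any(lv == 3 for lv in levels):
        u -= tariff.n3
    return u


def _state_key(levels) -> str:
    return "".join(str(lv) for lv in levels)


@dataclass(frozen=True)
class Crosswalk:
    """A complete 5L -> utility lookup table (3,125 states)."""

    table: Dict[str, float]
    label: str = "unnamed"

    def __post_init__(self):
        table = dict(self.table)
        expected = {_state_key(s) for s in itertools.product(range(1, 6), repeat=5)}
        keys = set(table)
        if keys != expected:
            missing = sorted(expected - keys)[:5]
            extra = sorted(keys - expected)[:5]
            raise CrosswalkIntegrityError(
                f"crosswalk must cover exactly the 3125 5L states; "
                f"missing e.g. {missing}, unexpected e.g. {extra}"
            )
        bad = {k: v for k, v in table.items() if not np.isfinite(v) or v > 1 + 1e-12}
        if bad:
            raise CrosswalkIntegrityError(
                f"crosswalk utilities must be finite and <= 1; offending: "
                f"{dict(itertools.islice(bad.items(), 5))}"
            )
        object.__setattr__(self, "table", table)

    def utility(self, state) -> float:
        return crosswalk_utility(state, self)

    @property
    def min_utility(self) -> float:
        return min(self.table.values())

    @property
    def max_utility(self) -> float:
        return max(self.table.values())

    def values_tensor(self) -> np.ndarray:
        """Utilities of all 3,125 5L states as a (5,5,5,5,5) array.

        Axis d indexes dimension d's level (0-based), in instrument order.
        """
        out = np.empty((5,) * 5)
        for levels in itertools.product(range(1, 6), repeat=5):
            out[tuple(l - 1 for l in levels)] = self.table[_state_key(levels)]
        return out


def crosswalk_utility(state, cw: Crosswalk) -> float:
    """Exact crosswalk table lookup for a 5L state."""
    if isinstance(state, Eq5dState):
        if state.version != "5L":
            raise StateError(f"expected a 5L state, got version {state.version}")
        levels = state.levels
    else:
        levels = tuple(state)
        Eq5dState("5L", levels)  # validates
    key = _state_key(levels)
    try:
        return cw.table[key]
    except KeyError:  # unreachable for a validated Crosswalk
        raise CrosswalkIntegrityError(f"state {key} absent from crosswalk") from None


# ---------------------------------------------------------------------------
# CSV schemas
#
# tariff:    term,dimension,level,decrement
#            rows: one 'constant', one 'n3', and ten 'decrement' rows
# crosswalk: state,utility  with 5-character state strings, 3125 rows
# ---------------------------------------------------------------------------

def load_value_set(path) -> Tariff3L:
    """Load a 3L tariff from its CSV schema (term,dimension,level,decrement)."""
    df = pd.read_csv(path, dtype={"term": str, "dimension": str}, keep_default_na=False)
    required = {"term", "dimension", "level", "decrement"}
    if not required.issubset(df.columns):
        raise FormatError(f"tariff file must have columns {sorted(required)}")
    constant = n3 = None
    decrements = {}
    problems = []
    for idx, row in df.iterrows():
        term = row["term"].strip().lower()
        try:
            value = float(row["decrement"])
        except (TypeError, ValueError):
            problems.append(f"row {idx}: non-numeric decrement {row['decrement']!r}")
            continue
        if term == "constant":
            constant = value
        elif term == "n3":
            n3 = value
        elif term == "decrement":
            code = row["dimension"].strip().lower()
            try:
                level = int(row["level"])
            except (TypeError, ValueError):
                problems.append(f"row {idx}: bad level {row['level']!r}")
                continue
            decrements[(code, level)] = value
        else:
            problems.append(f"row {idx}: unknown term {term!r}")
    if constant is None or n3 is None:
        problems.append("missing 'constant' or 'n3' row")
    if problems:
        raise FormatError("invalid tariff file: " + "; ".join(problems))
    label = str(path)
    return Tariff3L(constant=constant, decrements=decrements, n3=n3, label=label)


def load_crosswalk(path) -> Crosswalk:
    """Load a 5L->3L crosswalk from its CSV schema (state,utility)."""
    df = pd.read_csv(path, dtype={"state": str}, float_precision="round_trip")
    if not {"state", "utility"}.issubset(df.columns):
        raise CrosswalkIntegrityError("crosswalk file must have columns state,utility")
    if len(df) != 5 ** 5:
        raise CrosswalkIntegrityError(
            f"crosswalk must have exactly {5 ** 5} rows, found {len(df)}"
        )
    dup = df["state"][df["state"].duplicated()]
    if len(dup):
        raise CrosswalkIntegrityError(f"duplicate states: {sorted(set(dup))[:5]}")
    utilities = pd.to_numeric(df["utility"], errors="coerce")
    bad = df.loc[utilities.isna(), "state"]
    if len(bad):
        raise CrosswalkIntegrityError(f"non-numeric utilities for states {list(bad)[:5]}")
    return Crosswalk(
        table=dict(zip(df["state"], utilities.astype(float))), label=str(path)
    )


def uk_tariff() -> Tariff3L:
    """The published UK (Dolan) EQ-5D-3L tariff, shipped with the package."""
    with resources.files("utilmap.data").joinpath("uk_tariff_3l.csv").open("rb") as fh:
        return _tariff_from_buffer(fh)


def _tariff_from_buffer(fh) -> Tariff3L:
    tariff = load_value_set(fh)
    return Tariff3L(
        constant=tariff.constant,
        decrements=tariff.decrements,
        n3=tariff.n3,
        label="UK-Dolan",
    )


# Per-dimension interpolation weights P(3L level | 5L level) used by the
# synthetic crosswalk: 5L levels sit at positions 1, 1.5, 2, 2.5, 3 on the
# 3L severity grid, with half-levels split evenly between the neighbours.
_INTERP_5L_TO_3L = np.array(
    [
        [1.0, 0.0, 0.0],
        [0.5, 0.5, 0.0],
        [0.0, 1.0, 0.0],
        [0.0, 0.5, 0.5],
        [0.0, 0.0, 1.0],
    ]
)


def synthetic_uk_crosswalk(tariff: Tariff3L | None = None) -> Crosswalk:
    """A synthetic 5L->3L crosswalk built on the UK 3L tariff.

    This is a constructed stand-in, not the published crosswalk table: each
    5L level is spread probabilistically onto the two nearest 3L levels
    (levels 1/3/5 map exactly to 3L 1/2/3; levels 2/4 split 50:50 between
    their neighbours, independently across dimensions) and the utility of a
    5L state is the expected UK-tariff utility of the induced 3L-state
    distribution. Full health maps to 1 exactly and the value is monotone
    non-increasing in every dimension.
    """
    if tariff is None:
        tariff = uk_tariff()
    values3 = tariff.values_tensor()  # (3,)*5
    # Contract each axis of the 3L value tensor with the per-level weights:
    # result[a,b,c,d,e] = E[U_3L | 5L state (a,b,c,d,e)].
    w = _INTERP_5L_TO_3L
    values5 = values3
    for axis in range(5):
        values5 = np.tensordot(w, values5, axes=([1], [axis]))
        values5 = np.moveaxis(values5, 0, axis)
    values5 = np.round(values5, 6)  # table values carry 6 decimals
    table = {
        _state_key(levels): float(values5[tuple(l - 1 for l in levels)])
        for levels in itertools.product(range(1, 6), repeat=5)
    }
    return Crosswalk(table=table, label="UK-synthetic-interpolated")


def write_crosswalk(cw: Crosswalk, path) -> None:
    """Write a crosswalk in its CSV schema (state,utility)."""
    states = sorted(cw.table)
    pd.DataFrame(
        {"state": states, "utility": [repr(cw.table[s]) for s in states]}
    ).to_csv(path, index=False)
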