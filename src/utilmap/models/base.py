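"""Shared results machinery: convergence records and JSON serialisation."""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConvergenceInfo:
    converged: bool
    iterations: int
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
            "message": self.message,
        }

    @classmethod
    def from_dict(cls, d) -> "ConvergenceInfo":
        return cls(bool(d["converged"]), int(d["iterations"]), d.get("message", ""))


def series_to_dict(s: Optional[pd.Series]) -> Optional[dict]:
    if s is None:
        return None
    return {str(k): float(v) for k, v in s.items()}


def series_from_dict(d, name=None) -> Optional[pd.Series]:
    if d is None:
        return None
    return pd.Series({k: float(v) for k, v in d.items()}, name=name, dtype=float)


def save_json(document: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(document, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def column_scales(X: np.ndarray) -> np.ndarray:
    """Max-abs scale per column (1 for all-zero columns).

    Likelihood fits run on X / scales and coefficients are divided by the
    scales afterwards — an exact reparameterisation that keeps indicator
    and age columns on comparable magnitudes for the optimisers.
    """
    scales = np.abs(np.asarray(X, dtype=float)).max(axis=0)
    scales[scales == 0] = 1.0
    return scales


def format_coef_table(title: str, params: pd.Series, bse: Optional[pd.Series]) -> str:
    lines = [title, "-" * len(title)]
    width = max((len(str(k)) for k in params.index), default=4) + 2
    header = f"{'term':<{width}}{'coef':>12}"
    if bse is not None:
        header += f"{'std err':>12}"
    lines.append(header)
    for name, value in params.items():
        row = f"{name:<{width}}{value:>12.4f}"
        if bse is not None:
            se = bse.get(name, np.nan)
            row += f"{se:>12.4f}"
        lines.append(row)
    return "\n".join(lines)
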