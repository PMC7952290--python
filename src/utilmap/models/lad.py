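"""Least absolute deviations and Powell's censored LAD (CLAD).

The LAD subproblem min_b sum_i |y_i - x_i b| is solved exactly as a linear
program (residuals split into positive and negative parts, HiGHS solver),
which gives reproducible tie handling. CLAD handles an upper censoring
point c by Powell's iterative trimming: fit LAD on the current subsample,
then keep only observations whose fitted value lies strictly below c, until
the kept set stabilises or the iteration cap is reached.
"""

from __future__ import annotations

import warnings
from typing import Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from ..exceptions import ConvergenceWarning, DegenerateDataError

CLAD_MAX_ITER = 400


def lad_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact median (LAD) regression via linear programming.

    Minimises sum_i |y_i - x_i b| over b. Returns the coefficient vector.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    # variables: [b (p, free), u (n, >=0), v (n, >=0)];  Xb + u - v = y
    c = np.concatenate([np.zeros(p), np.ones(2 * n)])
    A_eq = sparse.hstack(
        [sparse.csr_matrix(X), sparse.eye(n, format="csr"), -sparse.eye(n, format="csr")]
    )
    bounds = [(None, None)] * p + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"LAD linear program failed: {res.message}")
    return res.x[:p]


def clad_fit(
    X: np.ndarray,
    y: np.ndarray,
    censor: float = 1.0,
    maxiter: int = CLAD_MAX_ITER,
) -> Tuple[np.ndarray, bool, int]:
    """Powell's censored LAD by iterative trimming.

    Returns ``(beta, converged, iterations)``. On hitting the iteration cap
    the last iterate is returned with ``converged=False`` and a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    keep = np.ones(n, dtype=bool)
    beta = None
    for iteration in range(1, maxiter + 1):
        if not keep.any():
            raise DegenerateDataError(
                "CLAD trimming removed every observation; the linear "
                "predictor sits at or above the censoring point everywhere"
            )
        beta = lad_fit(X[keep], y[keep])
        new_keep = X @ beta < censor
        if np.array_equal(new_keep, keep):
            return beta, True, iteration
        keep = new_keep
    warnings.warn(
        f"CLAD did not stabilise within {maxiter} iterations; "
        "returning the last iterate",
        ConvergenceWarning,
        stacklevel=2,
    )
    return beta, False, maxiter


def clad_objective(beta: np.ndarray, X: np.ndarray, y: np.ndarray, censor: float = 1.0) -> float:
    """The censored LAD criterion sum_i |y_i - min(x_i b, censor)|."""
    fitted = np.minimum(np.asarray(X, dtype=float) @ beta, censor)
    return float(np.sum(np.abs(np.asarray(y, dtype=float) - fitted)))
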