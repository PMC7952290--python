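"""Synthetic paired QoL-AD / EQ-5D data with known ground truth.

The generator emulates the structure a QoL-AD -> EQ-5D mapping study relies
on: repeated visits clustered within subjects, 13 four-level QoL-AD items
driven by a shared latent health factor, EQ-5D-5L responses drawn from
known multinomial-logit models given the realised QoL-AD composite score
(plus age and sex), utilities obtained through a crosswalk (hence a ceiling
at 1), proxy ratings systematically lower than self ratings, and extra
missingness on QoL-AD item 7.

Because the EQ-5D items are drawn conditionally on the realised QoL-AD
score — an additive function of the items — the multinomial-logit response
mapper is correctly specified for these data and parameter-recovery tests
are well-posed. A ``misspecified=True`` switch draws the EQ-5D items from
the latent factor instead, so that no fitted mapper is exactly correct.

All randomness flows from one ``numpy.random.default_rng(seed)`` stream in
a fixed documented order (subjects, visit effects, self items, proxy items,
self EQ-5D, proxy EQ-5D, item-7 missingness), so a fixed seed reproduces
the dataset byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr

from .datasets import Observation
from .exceptions import DistributionError
from .instruments import EQ5D_CODES, N_ITEMS, Eq5dState, QolAdRecord
from .value_sets import Crosswalk, synthetic_uk_crosswalk

#: QoL-AD item thresholds on the standard-normal item-latent scale,
#: yielding level probabilities (.10, .30, .40, .20) for an average self
#: rating — per-item mean 2.7, hence a composite near 35 with SD near 6.
DEFAULT_THRESHOLDS = (-1.7, -0.34, 1.13)

#: Ground-truth multinomial-logit blocks for the EQ-5D items, on the
#: standardised scales z = (score - 35)/6, a = (age - 78)/8, male in {0,1}.
#: One entry per non-reference level 2..5; worse levels fall away from
#: full health faster as the QoL-AD score drops.
DEFAULT_ETA = {
    "intercept": (-0.1, -0.8, -1.8, -3.0),
    "z": (-0.41, -0.63, -0.85, -1.08),
    "age": (0.10, 0.15, 0.20, 0.25),
    "male": (-0.10, -0.10, -0.10, -0.10),
}
#: Per-dimension prevalence shifts added to every non-reference intercept.
DIMENSION_SHIFT = {"mo": 0.0, "sc": -0.45, "ua": 0.10, "pd": 0.45, "ad": 0.20}


@dataclass(frozen=True)
class SimConfig:
    """Study-design and ground-truth parameters for the generator.

    Defaults emulate the estimation cohorts typical of dementia mapping
    studies: ~450 subjects at three visits, age 78 (SD 8), 55% female,
    composite self-rated QoL-AD near 35 (SD 6) with proxy ratings about 5
    points lower, Spearman correlation near 0.5 between composite score and
    utility, around 13% extra missingness on item 7, and roughly a fifth of
    observations at the utility ceiling.
    """

    n_subjects: int = 450
    visits_per_subject: int = 3
    latent_between_sd: float = 0.8
    latent_within_sd: float = 0.6
    item_noise_sd: float = 0.9
    qolad_thresholds: Tuple[float, float, float] = DEFAULT_THRESHOLDS
    proxy_shift: float = -0.55
    ceiling_target: float = 0.20
    item7_missing_rate: float = 0.13
    age_mean: float = 78.0
    age_sd: float = 8.0
    female_fraction: float = 0.55
    misspecified: bool = False
    seed: int = 0

    def __post_init__(self):
        if min(self.latent_between_sd, self.latent_within_sd, self.item_noise_sd) <= 0:
            raise ValueError("latent and item noise SDs must be positive")
        if not 0 <= self.item7_missing_rate <= 1:
            raise ValueError("item7_missing_rate must lie in [0, 1]")
        if not 0 < self.ceiling_target < 1:
            raise ValueError("ceiling_target must lie in (0, 1)")
        if tuple(sorted(self.qolad_thresholds)) != tuple(self.qolad_thresholds):
            raise ValueError("qolad_thresholds must be increasing")

    def to_dict(self) -> dict:
        return asdict(self)


def _standardised_score(items12_sum: np.ndarray) -> np.ndarray:
    return 13.0 + (items12_sum - 12.0) * (39.0 / 36.0)


def _draw_items(rng, h_std: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Threshold h + item noise into 13 four-level items, (n, 13)."""
    n = len(h_std)
    noise = rng.normal(0.0, cfg.item_noise_sd, size=(n, N_ITEMS))
    total_sd = np.sqrt(
        cfg.latent_between_sd ** 2 + cfg.latent_within_sd ** 2 + cfg.item_noise_sd ** 2
    )
    latent = (h_std[:, None] + noise) / total_sd
    t = np.asarray(cfg.qolad_thresholds)
    return 1 + (latent[:, :, None] > t[None, None, :]).sum(axis=2)


def _eta_matrix(z, age_std, male, delta: float) -> np.ndarray:
    """Linear predictors for levels 2..5, shape (n, 4)."""
    out = np.empty((len(z), 4))
    for j in range(4):
        out[:, j] = (
            DEFAULT_ETA["intercept"][j]
            + delta
            + DEFAULT_ETA["z"][j] * z
            + DEFAULT_ETA["age"][j] * age_std
            + DEFAULT_ETA["male"][j] * male
        )
    return out


def _level_probs(eta: np.ndarray, shift: float) -> np.ndarray:
    """(n, 5) level probabilities from non-reference linear predictors."""
    scores = np.concatenate([np.zeros((len(eta), 1)), eta + shift], axis=1)
    scores -= scores.max(axis=1, keepdims=True)
    e = np.exp(scores)
    return e / e.sum(axis=1, keepdims=True)


def _calibrate_delta(z, age_std, male, target: float) -> float:
    """Intercept shift putting the expected full-health fraction at target."""

    def ceiling(delta):
        p1 = np.ones(len(z))
        for code in EQ5D_CODES:
            probs = _level_probs(_eta_matrix(z, age_std, male, delta),
                                 DIMENSION_SHIFT[code])
            p1 *= probs[:, 0]
        return p1.mean() - target

    return brentq(ceiling, -12.0, 12.0, xtol=1e-10)


def truth_design_params(cfg: SimConfig, delta: Dict[str, float]) -> Dict[str, dict]:
    """Ground-truth mlogit coefficients on the fitted design scale.

    Returns, per dimension and non-reference level, coefficients for the
    columns (const, score, age, male) — i.e. the standardised-scale truth
    re-expressed for a design using the raw composite score and uncentred
    age, so recovery tests can compare like with like.
    """
    out = {}
    for code in EQ5D_CODES:
        per_level = {}
        for j, level in enumerate((2, 3, 4, 5)):
            a = DEFAULT_ETA["intercept"][j] + DIMENSION_SHIFT[code] + delta[code]
            bz = DEFAULT_ETA["z"][j]
            ba = DEFAULT_ETA["age"][j]
            bm = DEFAULT_ETA["male"][j]
            per_level[level] = {
                "const": a - bz * 35.0 / 6.0 - ba * 78.0 / 8.0,
                "score": bz / 6.0,
                "age": ba / 8.0,
                "male": bm,
            }
        out[code] = per_level
    return out


def simulate_dataset(
    config: SimConfig, crosswalk: Optional[Crosswalk] = None
) -> Tuple[List[Observation], dict]:
    """Generate paired QoL-AD / EQ-5D observations plus the ground truth.

    Returns ``(observations, truth)`` where ``truth`` records the full
    parameterisation actually used (including the ceiling-calibration
    intercept shift and the design-scale mlogit coefficients).
    """
    cfg = config
    if crosswalk is None:
        crosswalk = synthetic_uk_crosswalk()
    rng = np.random.default_rng(cfg.seed)
    n_sub, visits = cfg.n_subjects, cfg.visits_per_subject
    n = n_sub * visits

    # subjects
    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, size=n_sub), 40.0, 100.0)
    female = rng.random(n_sub) < cfg.female_fraction
    b = rng.normal(0.0, cfg.latent_between_sd, size=n_sub)
    # visit effects
    w = rng.normal(0.0, cfg.latent_within_sd, size=(n_sub, visits))
    h = (b[:, None] + w).ravel()  # subject-major, visit-minor

    subject_idx = np.repeat(np.arange(n_sub), visits)
    age_obs = age[subject_idx]
    male_obs = (~female[subject_idx]).astype(float)

    items_self = _draw_items(rng, h, cfg)
    items_proxy = _draw_items(rng, h + cfg.proxy_shift, cfg)

    age_std = (age_obs - 78.0) / 8.0
    total_sd = np.sqrt(
        cfg.latent_between_sd ** 2 + cfg.latent_within_sd ** 2 + cfg.item_noise_sd ** 2
    )

    truth = {"config": cfg.to_dict(), "delta": {}, "mlogit": {}}
    states = {}
    delta = None
    for rater, items in (("self", items_self), ("proxy", items_proxy)):
        mask12 = np.ones(N_ITEMS, dtype=bool)
        mask12[6] = False  # item 7 excluded from the driving score
        score = _standardised_score(items[:, mask12].sum(axis=1))
        if cfg.misspecified:
            z = h / total_sd if rater == "self" else (h + cfg.proxy_shift) / total_sd
        else:
            z = (score - 35.0) / 6.0
        if delta is None:
            # one shared response process: the ceiling is calibrated on the
            # self-rated scenario; proxies, scoring lower, land below it
            delta = _calibrate_delta(z, age_std, male_obs, cfg.ceiling_target)
        levels = np.empty((n, 5), dtype=int)
        for d, code in enumerate(EQ5D_CODES):
            probs = _level_probs(_eta_matrix(z, age_std, male_obs, delta),
                                 DIMENSION_SHIFT[code])
            u = rng.random(n)
            levels[:, d] = 1 + (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        states[rater] = levels
        truth["delta"][rater] = {code: float(delta) for code in EQ5D_CODES}
        truth["mlogit"][rater] = truth_design_params(
            cfg, {code: delta for code in EQ5D_CODES}
        )

    miss7_self = rng.random(n) < cfg.item7_missing_rate
    miss7_proxy = rng.random(n) < cfg.item7_missing_rate

    tensor = crosswalk.values_tensor()
    observations = []
    for i in range(n):
        sid = f"S{subject_idx[i] + 1:04d}"
        visit = i % visits
        sex = "female" if female[subject_idx[i]] else "male"
        recs = {}
        for rater, items, miss7 in (
            ("self", items_self, miss7_self),
            ("proxy", items_proxy, miss7_proxy),
        ):
            vals = [int(v) for v in items[i]]
            if miss7[i]:
                vals[6] = None
            recs[rater] = QolAdRecord(
                subject_id=sid, visit=visit, rater=rater, items=tuple(vals),
                age=float(age_obs[i]), sex=sex,
            )
        st_self = Eq5dState("5L", tuple(int(v) for v in states["self"][i]))
        st_proxy = Eq5dState("5L", tuple(int(v) for v in states["proxy"][i]))
        observations.append(
            Observation(
                subject_id=sid,
                visit=visit,
                age=float(age_obs[i]),
                sex=sex,
                qolad_self=recs["self"],
                qolad_proxy=recs["proxy"],
                eq5d_self=st_self,
                eq5d_proxy=st_proxy,
                utility_self=float(tensor[tuple(l - 1 for l in st_self.levels)]),
                utility_proxy=float(tensor[tuple(l - 1 for l in st_proxy.levels)]),
            )
        )
    return observations, truth


def simulate_from_model(results, frame: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Draw EQ-5D-5L item responses from a fitted response mapper.

    ``results`` is a :class:`~utilmap.models.response.ResponseResults` (or
    anything exposing ``predict_distributions``); ``frame`` supplies the
    predictor rows. Returns a DataFrame with one level column per dimension
    code. Rows that cannot be encoded raise.
    """
    rng = np.random.default_rng(seed)
    dists, ok = results.predict_distributions(frame, on_error="raise")
    n = dists.shape[0]
    out = {}
    for d, code in enumerate(EQ5D_CODES):
        p = dists[:, d, :]
        if (p < -1e-12).any():
            raise DistributionError("negative probabilities from model")
        u = rng.random(n)
        out[code] = 1 + (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return pd.DataFrame(out, index=frame.index)
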