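"""Item-level response models and distribution-to-utility conversion."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import utilmap as um
from utilmap.exceptions import DegenerateDataError, DistributionError
from utilmap.models.response import (
    ItemModel,
    ResponseMapping,
    expected_utility,
    fit_item_model,
    modal_state_utility,
)


def _design(rng, n, p=3):
    X = pd.DataFrame({"const": np.ones(n)})
    for j in range(p):
        X[f"x{j}"] = rng.normal(size=n)
    return X


def _random_dists(rng, n=1):
    d = rng.random((n, 5, 5)) + 1e-3
    return d / d.sum(axis=2, keepdims=True)


class TestFitItemModel:
    def test_two_level_mlogit_collapses_to_binary_logit(self, rng):
        n = 800
        X = _design(rng, n, p=2)
        eta = 0.3 - 0.8 * X["x0"] + 0.5 * X["x1"]
        levels = 1 + (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            item = fit_item_model(levels, X, "mlogit", dimension="mo")
        logit = sm.Logit(levels - 1, X.to_numpy(float)).fit(disp=0)
        assert np.abs(item.coef[0] - logit.params).max() < 1e-6

    def test_mlogit_parameter_recovery(self, rng):
        n = 5000
        X = _design(rng, n, p=3)
        truth = np.array(
            [
                [-0.5, 0.8, -0.3, 0.2],
                [-1.0, -0.4, 0.6, 0.0],
                [-1.5, 0.3, 0.3, -0.5],
            ]
        )  # levels 2..4 vs reference 1
        scores = np.concatenate(
            [np.zeros((n, 1)), X.to_numpy(float) @ truth.T], axis=1
        )
        p = np.exp(scores - scores.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        u = rng.random(n)
        levels = 1 + (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            item = fit_item_model(levels, X, "mlogit", dimension="sc")
        z = (item.coef - truth) / item.bse
        assert np.abs(z).max() < 3.0

    def test_ologit_cutpoints_strictly_increasing(self, rng):
        n = 600
        X = _design(rng, n, p=2)
        eta = X["x0"].to_numpy()
        u = np.random.default_rng(5).logistic(size=n)
        levels = np.digitize(eta + u, [-2, -0.5, 0.5, 2]) + 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            item = fit_item_model(levels, X, "ologit", dimension="ua")
        assert (np.diff(item.cutpoints) > 0).all()

    def test_degenerate_single_level(self, rng):
        X = _design(rng, 50)
        with pytest.raises(DegenerateDataError, match="pd"):
            fit_item_model(np.ones(50, dtype=int), X, "mlogit", dimension="pd")

    def test_unobserved_levels_get_structural_zero(self, rng):
        n = 400
        X = _design(rng, n, p=1)
        levels = 1 + (rng.random(n) < 0.5).astype(int)  # only levels 1, 2
        with pytest.warns(UserWarning, match="never observed"):
            item = fit_item_model(levels, X, "mlogit", dimension="ad")
        dist = item.predict_dist(X.to_numpy(float)[:10])
        assert (dist[:, 2:] == 0).all()
        assert np.allclose(dist.sum(axis=1), 1.0)


class TestPredictDistribution:
    def test_mlogit_zero_coefficients_uniform(self):
        item = ItemModel(
            dimension="mo", family="mlogit", columns=("const",),
            observed_levels=(1, 2, 3, 4, 5), coef=np.zeros((4, 1)),
        )
        dist = item.predict_dist(np.ones((3, 1)))
        assert np.allclose(dist, 0.2)

    @pytest.mark.parametrize(
        "fitted,expected_level",
        [(3.5, 4), (2.49, 2), (2.5, 3), (0.2, 1), (6.3, 5), (4.5, 5)],
    )
    def test_ols_rounding_half_toward_worse(self, fitted, expected_level):
        item = ItemModel(
            dimension="sc", family="ols_categorical", columns=("const",),
            observed_levels=(1, 2, 3, 4, 5), coef=np.array([[fitted]]),
        )
        dist = item.predict_dist(np.ones((1, 1)))
        assert dist[0, expected_level - 1] == 1.0
        assert dist.sum() == 1.0

    def test_ologit_matches_statsmodels_predict(self, rng):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        n = 500
        X = _design(rng, n, p=2)
        u = rng.logistic(size=n)
        levels = np.digitize(X["x0"] + 0.5 * X["x1"] + u, [-2, -0.5, 0.5, 2]) + 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            item = fit_item_model(levels, X, "ologit", dimension="mo")
            # independent route: statsmodels' own fit and predict
            noconst = X[["x0", "x1"]].to_numpy(float)
            sm_res = OrderedModel(
                np.searchsorted(sorted(set(levels)), levels), noconst, distr="logit"
            ).fit(method="lbfgs", maxiter=200, disp=0)
        rows = rng.choice(n, size=20, replace=False)
        ours = item.predict_dist(X.to_numpy(float)[rows])
        theirs = sm_res.predict(noconst[rows])
        observed = sorted(set(levels))
        for j, lv in enumerate(observed):
            assert np.allclose(ours[:, lv - 1], theirs[:, j], atol=1e-5)

    def test_cutpoint_ordering_enforced(self):
        with pytest.raises(ValueError, match="increasing"):
            ItemModel(
                dimension="mo", family="ologit", columns=("const", "x"),
                observed_levels=(1, 2, 3), coef=np.zeros((1, 2)),
                cutpoints=np.array([0.5, 0.1]),
            )


class TestUtilityConversion:
    def test_degenerate_full_health(self, uk_crosswalk):
        dists = np.zeros((5, 5))
        dists[:, 0] = 1.0
        assert expected_utility(dists, uk_crosswalk) == pytest.approx(1.0)
        assert modal_state_utility(dists, uk_crosswalk) == pytest.approx(1.0)

    def test_linearity_in_one_dimension(self, toy_crosswalk):
        dists = np.zeros((5, 5))
        dists[:, 0] = 1.0
        dists[0] = [0.5, 0, 0, 0, 0.5]
        expected = 0.5 * toy_crosswalk.table["11111"] + 0.5 * toy_crosswalk.table["51111"]
        assert expected_utility(dists, toy_crosswalk) == pytest.approx(expected)

    def test_enumeration_matches_monte_carlo(self, toy_crosswalk, uk_crosswalk, rng):
        dists = _random_dists(rng)[0]
        for cw in (toy_crosswalk, uk_crosswalk):
            exact = expected_utility(dists, cw)
            n_draws = 1_000_000
            draws = np.empty((n_draws, 5), dtype=int)
            for d in range(5):
                draws[:, d] = rng.choice(5, size=n_draws, p=dists[d])
            tensor = cw.values_tensor()
            sampled = tensor[draws[:, 0], draws[:, 1], draws[:, 2], draws[:, 3], draws[:, 4]]
            mc, se = sampled.mean(), sampled.std() / np.sqrt(n_draws)
            assert exact == pytest.approx(mc, abs=3 * se)

    def test_expected_within_crosswalk_bounds(self, uk_crosswalk, rng):
        dists = _random_dists(rng, n=50)
        values = expected_utility(dists, uk_crosswalk)
        assert (values >= uk_crosswalk.min_utility - 1e-12).all()
        assert (values <= uk_crosswalk.max_utility + 1e-12).all()

    def test_modal_tie_goes_to_lower_level(self, toy_crosswalk):
        dists = np.zeros((5, 5))
        dists[:, 0] = 1.0
        dists[0] = [0.4, 0.4, 0.2, 0, 0]
        assert modal_state_utility(dists, toy_crosswalk) == pytest.approx(
            toy_crosswalk.table["11111"]
        )

    def test_modal_equals_expected_for_degenerate(self, uk_crosswalk, rng):
        for _ in range(10):
            dists = np.zeros((5, 5))
            for d in range(5):
                dists[d, rng.integers(0, 5)] = 1.0
            assert modal_state_utility(dists, uk_crosswalk) == expected_utility(
                dists, uk_crosswalk
            )

    def test_modal_vs_expected_comparison_harness(self, uk_crosswalk, rng):
        dists = _random_dists(rng, n=100)
        gap = modal_state_utility(dists, uk_crosswalk) - expected_utility(
            dists, uk_crosswalk
        )
        span = uk_crosswalk.max_utility - uk_crosswalk.min_utility
        assert np.abs(gap).max() <= span

    def test_invalid_distributions_rejected(self, uk_crosswalk):
        bad = np.zeros((5, 5))
        bad[:, 0] = 0.9  # sums to 0.9
        with pytest.raises(DistributionError):
            expected_utility(bad, uk_crosswalk)
        neg = np.zeros((5, 5))
        neg[:, 0] = 1.5
        neg[:, 1] = -0.5
        with pytest.raises(DistributionError):
            expected_utility(neg, uk_crosswalk)


class TestResponseMapping:
    def test_fit_names_degenerate_dimension(self, table_small):
        frame = table_small.frame.copy()
        frame["ua"] = 1.0
        from utilmap.design import EstimationTable

        broken = EstimationTable(
            frame=frame, scenario=table_small.scenario,
            n_total=table_small.n_total, n_excluded=table_small.n_excluded,
        )
        with pytest.raises(DegenerateDataError, match="ua"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ResponseMapping(broken, "mlogit").fit()

    def test_requires_item_level_targets(self, table_small):
        frame = table_small.frame.copy()
        for code in ("mo", "sc", "ua", "pd", "ad"):
            frame[code] = np.nan
        from utilmap.design import EstimationTable

        bare = EstimationTable(
            frame=frame, scenario=table_small.scenario,
            n_total=table_small.n_total, n_excluded=table_small.n_excluded,
        )
        with pytest.raises(DegenerateDataError):
            ResponseMapping(bare, "mlogit")

    @pytest.mark.parametrize("family", ["mlogit", "ologit", "ols_categorical",
                                        "ols_continuous"])
    def test_serialisation_round_trip_bitwise(self, tmp_path, table_small,
                                              uk_crosswalk, family):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = um.fit_response_mapper(table_small, family)
        path = tmp_path / f"{family}.json"
        res.save(path)
        back = um.load_model(path)
        p1 = res.predict(table_small.frame, uk_crosswalk)
        p2 = back.predict(table_small.frame, uk_crosswalk)
        assert (p1 == p2).all()

    def test_continuous_family_uses_items_as_scores(self, table_small):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = um.fit_response_mapper(table_small, "ols_continuous")
        assert "q1" in res.spec.columns
        assert not any(c.startswith("q1_") for c in res.spec.columns)

    def test_row_permutation_invariance(self, table_small, uk_crosswalk):
        from utilmap.design import EstimationTable

        perm = np.random.default_rng(4).permutation(table_small.n)
        shuffled = EstimationTable(
            frame=table_small.frame.iloc[perm].reset_index(drop=True),
            scenario=table_small.scenario,
            n_total=table_small.n_total, n_excluded=table_small.n_excluded,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = um.fit_response_mapper(table_small, "ols_categorical")
            r2 = um.fit_response_mapper(shuffled, "ols_categorical")
        p1 = r1.predict(table_small.frame, uk_crosswalk)
        p2 = r2.predict(table_small.frame, uk_crosswalk)
        assert np.allclose(p1, p2, atol=1e-10)

    def test_distributions_sum_to_one(self, table_small):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = um.fit_response_mapper(table_small, "mlogit")
        dists, ok = res.predict_distributions(table_small.frame)
        assert ok.all()
        assert np.allclose(dists.sum(axis=2), 1.0, atol=1e-10)
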