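"""Direct-mapping estimators: OLS, Tobit, CLAD and the two-part model."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

import utilmap as um
from utilmap.design import Scenario, assemble_scenario
from utilmap.exceptions import DegenerateDataError, SingularDesignError
from utilmap.models.direct import DirectMapping, check_full_rank, two_part_combine
from utilmap.models.lad import clad_fit, clad_objective, lad_fit
from utilmap.models.tobit import TobitModel, tobit_expected


def _table_from_xy(rng, x, y, clusters=None):
    """Wrap a 1-predictor problem as an estimation table via the score slot."""
    n = len(y)
    frame = pd.DataFrame(
        {
            "subject_id": clusters if clusters is not None else [f"s{i}" for i in range(n)],
            "visit": 0,
            "age": 75.0,
            "male": 0.0,
            "score": x,
            "y": y,
        }
    )
    for i in range(1, 14):
        frame[f"q{i}"] = 2.0
    for code in ("mo", "sc", "ua", "pd", "ad"):
        frame[code] = np.nan
    from utilmap.design import EstimationTable

    return EstimationTable(
        frame=frame,
        scenario=Scenario("self", "self", False, False),
        n_total=n,
        n_excluded=0,
    )


class TestOlsDirect:
    def test_noise_free_line_recovered_exactly(self, rng):
        x = rng.uniform(13, 52, size=50)
        y = 0.01 * x + 0.1
        table = _table_from_xy(rng, x, y)
        res = um.fit_ols_direct(table, continuous=True, cluster=False)
        assert res.params["score"] == pytest.approx(0.01, abs=1e-12)
        assert res.params["const"] == pytest.approx(0.1, abs=1e-10)

    def test_known_coefficients_recovered_within_3_se(self, sim_small):
        observations, _ = sim_small
        table = um.assemble_scenario(
            observations, um.Scenario("self", "self", False, True)
        )
        rng = np.random.default_rng(11)
        spec_model = DirectMapping(table, "ols_categorical")
        X = spec_model.exog.to_numpy(float)
        beta0 = rng.normal(0, 0.05, size=X.shape[1])
        beta0[0] = 0.7
        y = X @ beta0 + rng.normal(0, 0.1, size=len(X))
        table.frame["y"] = y
        res = DirectMapping(table, "ols_categorical").fit(cluster=False)
        z = (res.params.to_numpy() - beta0) / res.bse.to_numpy()
        assert np.abs(z).max() < 3.0

    def test_prediction_clamped_at_one(self, rng):
        x = rng.uniform(13, 52, 30)
        y = np.clip(0.02 * x + 0.2, None, 1.0)
        table = _table_from_xy(rng, x, y)
        res = um.fit_ols_direct(table, continuous=True, cluster=False)
        high = table.frame.copy()
        high["score"] = 52.0
        assert res.predict(high).max() <= 1.0

    def test_rank_deficient_design_names_aliased_columns(self):
        X = pd.DataFrame(
            {"const": np.ones(10), "a": np.arange(10.0), "b": 2 * np.arange(10.0)}
        )
        with pytest.raises(SingularDesignError) as err:
            check_full_rank(X)
        assert "b" in err.value.aliased or "a" in err.value.aliased

    def test_row_permutation_invariance(self, table_small):
        res1 = DirectMapping(table_small, "ols_categorical").fit(cluster=False)
        shuffled = table_small
        perm = np.random.default_rng(3).permutation(table_small.n)
        from utilmap.design import EstimationTable

        shuffled = EstimationTable(
            frame=table_small.frame.iloc[perm].reset_index(drop=True),
            scenario=table_small.scenario,
            n_total=table_small.n_total,
            n_excluded=table_small.n_excluded,
        )
        res2 = DirectMapping(shuffled, "ols_categorical").fit(cluster=False)
        assert np.allclose(res1.params.to_numpy(), res2.params.to_numpy(), atol=1e-10)


class TestTobit:
    def test_censored_expectation_matches_monte_carlo(self, rng):
        mu, sigma = 0.8, 0.2
        draws = np.minimum(rng.normal(mu, sigma, size=1_000_000), 1.0)
        mc, se = draws.mean(), draws.std() / 1000.0
        assert tobit_expected(mu, sigma) == pytest.approx(mc, abs=3 * se)

    def test_prediction_strictly_below_one(self):
        # mu up to one sigma-scaled reach past the ceiling; far beyond that
        # the shortfall drops under float resolution
        mus = np.linspace(-1, 2, 31)
        assert (tobit_expected(mus, 0.15) < 1.0).all()
        assert (tobit_expected(mus, 2.0) < 1.0).all()

    def test_equals_ols_without_censoring(self, rng):
        x = rng.uniform(13, 52, size=400)
        y = 0.01 * x + rng.normal(0, 0.05, size=400)  # never reaches 1
        assert y.max() < 1.0
        table = _table_from_xy(rng, x, y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tob = DirectMapping(table, "tobit", encoding="score").fit(cluster=False)
        ols = um.fit_ols_direct(table, continuous=True, cluster=False)
        rel = np.abs(tob.params.to_numpy() - ols.params.to_numpy()) / np.maximum(
            np.abs(ols.params.to_numpy()), 1e-8
        )
        assert rel.max() < 1e-4

    def test_parameter_recovery_with_censoring(self, rng):
        n = 5000
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        beta0 = np.array([0.7, 0.4, -0.2])
        sigma0 = 0.3
        ystar = beta0[0] + beta0[1] * x1 + beta0[2] * x2 + rng.normal(0, sigma0, n)
        y = np.minimum(ystar, 1.0)
        frac = (ystar >= 1).mean()
        assert 0.15 < frac < 0.4
        X = np.column_stack([np.ones(n), x1, x2])
        model = TobitModel(y, X)
        params, converged, _ = model.fit()
        assert converged
        cov = np.linalg.inv(-model.hessian(params))
        se = np.sqrt(np.diag(cov))[:3]
        assert np.abs(params[:3] - beta0).max() < (3 * se).max()
        assert np.exp(params[3]) == pytest.approx(sigma0, rel=0.1)

    def test_loglike_at_optimum_beats_null(self, rng):
        n = 300
        x = rng.normal(size=n)
        y = np.minimum(0.6 + 0.3 * x + rng.normal(0, 0.25, n), 1.0)
        X = np.column_stack([np.ones(n), x])
        model = TobitModel(y, X)
        params, _, _ = model.fit()
        null = np.array([0.0, 0.0, 0.0])  # beta = 0, log sigma = 0
        assert model.loglike(params) >= model.loglike(null)

    def test_all_censored_rejected(self):
        X = np.ones((5, 1))
        with pytest.raises(DegenerateDataError):
            TobitModel(np.ones(5), X)

    def test_fitted_results_predict_below_one(self, table_small):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = um.fit_tobit(table_small, cluster=False)
        pred = res.predict(table_small.frame)
        assert (pred < 1.0).all()
        clamped = res.predict(table_small.frame, kind="clamped")
        assert clamped.max() <= 1.0


class TestClad:
    def test_without_censoring_equals_plain_lad(self, rng):
        n = 60
        x = rng.uniform(-1, 1, n)
        y = 0.1 + 0.2 * x + rng.normal(0, 0.05, n)  # stays far below 1
        X = np.column_stack([np.ones(n), x])
        beta_lad = lad_fit(X, y)
        beta_clad, converged, iters = clad_fit(X, y)
        assert converged and iters == 1
        assert np.allclose(beta_lad, beta_clad, atol=1e-10)

    def test_tiny_instance_beats_grid_oracle(self):
        X = np.column_stack([np.ones(8), np.arange(8.0)])
        y = np.array([0.2, 0.3, 0.5, 0.6, 0.8, 1.0, 1.0, 1.0])
        beta, converged, _ = clad_fit(X, y)
        assert converged
        value = clad_objective(beta, X, y)
        b0 = np.linspace(-1, 1, 401)
        b1 = np.linspace(-0.5, 0.5, 401)
        B0, B1 = np.meshgrid(b0, b1)
        fitted = np.minimum(B0[..., None] + B1[..., None] * X[:, 1], 1.0)
        grid_best = np.abs(y - fitted).sum(axis=-1).min()
        assert value <= grid_best + 1e-9

    def test_iteration_cap_respected(self, table_small):
        res = um.fit_clad(table_small)
        assert res.convergence.iterations <= 400
        assert res.bse is None

    def test_degenerate_when_everything_trimmed(self):
        X = np.ones((6, 1))
        y = np.full(6, 1.0)
        y[0] = 0.99  # LAD intercept = median = 1 -> everything trimmed
        with pytest.raises(DegenerateDataError):
            clad_fit(X, y)


class TestTwoPart:
    @given(
        pr=st.floats(0, 1, allow_nan=False),
        y=st.floats(-0.5, 1.0, allow_nan=False),
    )
    def test_combination_formula_identity(self, pr, y):
        assert two_part_combine(pr, y) == pytest.approx(pr + (1 - pr) * y, abs=1e-15)

    def test_formula_endpoints(self):
        assert two_part_combine(1.0, -0.3) == 1.0
        assert two_part_combine(0.5, 0.6) == pytest.approx(0.8)
        assert two_part_combine(0.0, 0.6) == pytest.approx(0.6)

    def test_parameter_recovery(self, rng):
        n = 5000
        x = rng.uniform(-1, 1, n)
        X = np.column_stack([np.ones(n), x])
        gamma0 = np.array([-0.5, 1.2])  # logistic block
        beta0 = np.array([0.45, 0.25])  # conditional block
        p = 1 / (1 + np.exp(-(X @ gamma0)))
        ceiling = rng.random(n) < p
        y = np.where(ceiling, 1.0, X @ beta0 + rng.normal(0, 0.08, n))
        assert y[~ceiling].max() < 1.0
        table = _table_from_xy(rng, x, y)
        res = DirectMapping(table, "two_part", encoding="score").fit(cluster=False)
        zl = (res.params_logit.to_numpy() - gamma0) / res.bse_logit.to_numpy()
        zo = (res.params.to_numpy() - beta0) / res.bse.to_numpy()
        assert np.abs(zl).max() < 3.0
        assert np.abs(zo).max() < 3.0

    def test_needs_both_sides_of_ceiling(self, rng):
        x = rng.uniform(-1, 1, 50)
        table = _table_from_xy(rng, x, np.full(50, 0.5))
        with pytest.raises(DegenerateDataError):
            DirectMapping(table, "two_part", encoding="score").fit(cluster=False)

    def test_prediction_between_y_and_one(self, table_small):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = um.fit_two_part(table_small, cluster=False)
        pred = res.predict(table_small.frame)
        assert pred.max() <= 1.0
        # convex combination with the ceiling: prediction >= conditional part
        X, _, _ = res.spec.design_matrix(table_small.frame)
        cond = np.minimum(X.to_numpy(float) @ res.params.to_numpy(), 1.0)
        assert (pred >= cond - 1e-12).all()


class TestSerialisation:
    @pytest.mark.parametrize("family", ["ols_continuous", "ols_categorical",
                                        "tobit", "clad", "two_part"])
    def test_round_trip_preserves_predictions(self, tmp_path, table_small, family):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = DirectMapping(table_small, family).fit(
                cluster=(family != "clad")
            )
        path = tmp_path / f"{family}.json"
        res.save(path)
        back = um.load_model(path)
        p1 = res.predict(table_small.frame)
        p2 = back.predict(table_small.frame)
        assert (p1 == p2).all()  # bit-for-bit
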