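import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from survbench.influence import (
    DEFAULT_INTERVAL_EDGES_DAYS,
    DiscreteTimeSurvModel,
    aggregate_influences,
    fit_discrete_time_model,
    influence_ranking,
    predict_survival,
    select_l2,
    standardize,
)
from survbench.simulate import SyntheticConfig, generate_feature_cohort


def toy_model(hazards, beta=(), names=None):
    hazards = np.asarray(hazards, float)
    beta = np.asarray(beta, float)
    edges = np.arange(hazards.size + 1, dtype=float) * 100.0
    return DiscreteTimeSurvModel(
        interval_edges=edges,
        alpha=logit(hazards),
        beta=beta,
        l2_strength=0.0,
        feature_names=names or tuple(f"x{j}" for j in range(beta.size)),
        log_likelihood=0.0,
        n_iter=0,
        converged=True,
    )


class TestStandardize:
    def test_direct_formula(self):
        fm = standardize(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(fm.values[:, 0], [-1.22474487, 0.0, 1.22474487])
        assert fm.train_means[0] == 2.0

    def test_training_columns_centered_unit_scale(self, rng):
        raw = rng.normal(5, 3, (200, 4))
        fm = standardize(raw)
        assert np.allclose(fm.values.mean(axis=0), 0.0, atol=1e-8)
        assert np.allclose(fm.values.std(axis=0), 1.0, atol=1e-8)

    def test_missing_imputed_to_exact_zero(self, rng):
        raw = rng.normal(size=(50, 2))
        raw[3, 0] = np.nan
        fm = standardize(raw)
        assert fm.values[3, 0] == 0.0

    def test_all_missing_column_becomes_zeros(self, rng):
        raw = rng.normal(size=(20, 2))
        raw[:, 1] = np.nan
        fm = standardize(raw)
        assert (fm.values[:, 1] == 0.0).all()
        assert len(fm.feature_names) == 2

    def test_zero_variance_dropped_with_warning(self, rng):
        raw = np.column_stack([rng.normal(size=30), np.full(30, 7.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            fm = standardize(raw, feature_names=["a", "const"])
        assert fm.feature_names == ("a",)
        assert fm.dropped == ("const",)

    def test_held_out_split_keeps_training_stats(self, rng):
        train = rng.normal(0, 1, (100, 1))
        test = rng.normal(2, 1, (100, 1))
        fm_train = standardize(train)
        fm_test = standardize(
            test, feature_names=["x0"],
            train_means=fm_train.train_means, train_sds=fm_train.train_sds,
        )
        # oracle: direct recompute with held-out stats
        expected = (test - fm_train.train_means) / fm_train.train_sds
        assert np.allclose(fm_test.values, expected)
        assert abs(fm_test.values.mean()) > 0.5  # no re-centering on test


class TestFit:
    def test_zero_covariates_match_life_table(self):
        # K = 2 intervals of 100 days; hand life table:
        # interval 1: deaths at 50, 80 (2 death terms); the patient censored
        # at 60 contributes nothing (partial interval); those at 150 and 250
        # fully survive it (2 survival terms) -> h1 = 2/4
        # interval 2: death at 150 (1 death term); follow-up to 250 runs past
        # the last edge and fully survives it (1 survival term) -> h2 = 1/2
        time = np.array([50.0, 80.0, 60.0, 150.0, 250.0])
        event = np.array([True, True, False, True, False])
        edges = np.array([0.0, 100.0, 200.0])
        model = fit_discrete_time_model(np.empty((5, 0)), time, event, edges)
        h = model.hazards(np.empty((1, 0)))[0]
        assert h[0] == pytest.approx(1 / 2, abs=1e-6)
        assert h[1] == pytest.approx(1 / 2, abs=1e-6)

    def test_zero_covariates_interior_hazards_exact(self, rng):
        time = rng.uniform(1, 300, 400)
        event = rng.random(400) < 0.5
        edges = np.array([0.0, 100.0, 200.0, 300.0])
        model = fit_discrete_time_model(np.empty((400, 0)), time, event, edges)
        h = model.hazards(np.empty((1, 0)))[0]
        # analytic life-table: deaths / at-risk per interval, where the
        # at-risk set excludes patients censored within an earlier or the
        # current interval (they contribute nothing to the current one)
        for k in range(3):
            lo, hi = edges[k], edges[k + 1]
            at_risk = (time > lo) & ((time >= hi) | event)
            deaths = event & (time > lo) & (time <= hi)
            assert h[k] == pytest.approx(deaths.sum() / at_risk.sum(), abs=1e-6)

    def test_duplication_invariance_at_zero_penalty(self, rng):
        X = rng.normal(size=(80, 2))
        time = rng.uniform(1, 1500, 80)
        event = rng.random(80) < 0.6
        m1 = fit_discrete_time_model(X, time, event)
        m2 = fit_discrete_time_model(
            np.vstack([X, X]), np.tile(time, 2), np.tile(event, 2)
        )
        assert np.allclose(m1.beta, m2.beta, atol=1e-5)
        assert np.allclose(m1.alpha, m2.alpha, atol=1e-5)

    def test_recovers_known_signal(self):
        cfg = SyntheticConfig(n_patients=2000, seed=5)
        fc = generate_feature_cohort(cfg)
        fm = standardize(fc.features)
        model = fit_discrete_time_model(fm, fc.time, fc.event, l2_strength=1.0)
        nonzero = np.flatnonzero(fc.true_beta)
        # fitted beta largest (in magnitude) exactly on the true signals,
        # with matching signs
        top = set(np.argsort(-np.abs(model.beta))[: nonzero.size])
        assert top == set(nonzero)
        assert np.all(np.sign(model.beta[nonzero]) == np.sign(fc.true_beta[nonzero]))

    def test_penalty_shrinks_coefficients(self, rng):
        cfg = SyntheticConfig(n_patients=500, seed=9)
        fc = generate_feature_cohort(cfg)
        fm = standardize(fc.features)
        loose = fit_discrete_time_model(fm, fc.time, fc.event, l2_strength=0.0)
        tight = fit_discrete_time_model(fm, fc.time, fc.event, l2_strength=100.0)
        assert np.linalg.norm(tight.beta) < np.linalg.norm(loose.beta)

    def test_requires_events_and_valid_edges(self):
        with pytest.raises(ValueError, match="event"):
            fit_discrete_time_model(np.empty((2, 0)), [1.0, 2.0], [False, False])
        with pytest.raises(ValueError, match="edges"):
            fit_discrete_time_model(
                np.empty((2, 0)), [1.0, 2.0], [True, True],
                interval_edges=np.array([10.0, 5.0]),
            )


class TestSelectL2:
    def test_single_value_grid(self, rng):
        cfg = SyntheticConfig(n_patients=200, seed=2)
        fc = generate_feature_cohort(cfg)
        assert select_l2(standardize(fc.features), fc.time, fc.event, grid=[3.0]) == 3.0

    def test_pure_noise_prefers_heavy_penalty(self):
        wins = 0
        for seed in range(7):
            cfg = SyntheticConfig(
                n_patients=300, n_features=8, n_nonzero=0, seed=seed
            )
            fc = generate_feature_cohort(cfg)
            chosen = select_l2(
                standardize(fc.features), fc.time, fc.event,
                grid=[0.01, 100.0], n_folds=3, seed=seed,
            )
            wins += chosen == 100.0
        assert wins >= 5

    def test_strong_signal_prefers_light_penalty(self):
        wins = 0
        for seed in range(7):
            cfg = SyntheticConfig(
                n_patients=600, n_features=5, n_nonzero=3,
                coefficient_scale=1.0, seed=seed,
            )
            fc = generate_feature_cohort(cfg)
            chosen = select_l2(
                standardize(fc.features), fc.time, fc.event,
                grid=[0.01, 1000.0], n_folds=3, seed=seed,
            )
            wins += chosen == 0.01
        assert wins >= 5


class TestPredictSurvival:
    def test_closed_form_values(self):
        model = toy_model([0.1, 0.2])
        assert predict_survival(model, np.empty(0), 0.0) == 1.0
        assert predict_survival(model, np.empty(0), 100.0) == pytest.approx(0.9)
        assert predict_survival(model, np.empty(0), 200.0) == pytest.approx(0.72)

    def test_log_linear_interpolation_inside_interval(self):
        model = toy_model([0.1, 0.2])
        s = predict_survival(model, np.empty(0), 150.0)
        assert s == pytest.approx(np.exp((np.log(0.9) + np.log(0.72)) / 2))

    def test_monotone_in_time(self, rng):
        model = toy_model(rng.uniform(0.05, 0.3, 5), beta=[0.4, -0.2])
        x = rng.normal(size=2)
        ts = np.linspace(0, 500, 60)
        vals = [predict_survival(model, x, t) for t in ts]
        assert (np.diff(vals) <= 1e-12).all()

    def test_beyond_horizon_errors(self):
        model = toy_model([0.1, 0.2])
        with pytest.raises(ValueError, match="horizon"):
            predict_survival(model, np.empty(0), 201.0)

    def test_protective_feature_never_lowers_survival(self):
        model = toy_model([0.1, 0.2, 0.15], beta=[0.8])
        for t in [50.0, 150.0, 300.0]:
            s = [predict_survival(model, np.array([x]), t) for x in (-1.0, 0.0, 2.0)]
            assert s[0] <= s[1] <= s[2]


class TestInfluence:
    def test_arithmetic_example(self):
        model = toy_model([0.1], beta=[2.0, -1.0], names=("f1", "f2"))
        r = influence_ranking(model, np.array([0.5, 1.0]), k=1)
        assert r.positive == (("f1", 1.0),)
        assert r.negative == (("f2", -1.0),)

    def test_all_zero_patient_is_uninformative(self):
        model = toy_model([0.1], beta=[2.0, -1.0])
        r = influence_ranking(model, np.zeros(2), k=2)
        assert r.uninformative
        assert r.positive == () and r.negative == ()

    def test_matches_brute_force(self, rng):
        p = 15
        model = toy_model([0.1, 0.2], beta=rng.normal(size=p))
        x = rng.normal(size=p)
        r = influence_ranking(model, x, k=5)
        infl = model.beta * x
        expected_pos = sorted(
            [(f"x{j}", infl[j]) for j in range(p) if infl[j] > 0],
            key=lambda t: -t[1],
        )[:5]
        assert [n for n, _ in r.positive] == [n for n, _ in expected_pos]
        assert r.positive[0][1] == pytest.approx(max(infl))
        assert r.negative[0][1] == pytest.approx(min(infl))

    def test_k_exceeding_features_truncates_with_warning(self):
        model = toy_model([0.1], beta=[1.0, 2.0])
        with pytest.warns(UserWarning, match="truncating"):
            r = influence_ranking(model, np.array([1.0, 1.0]), k=9)
        assert len(r.positive) == 2

    def test_ties_broken_by_feature_index(self):
        model = toy_model([0.1], beta=[1.0, 1.0, 1.0])
        r = influence_ranking(model, np.ones(3), k=2)
        assert [n for n, _ in r.positive] == ["x0", "x1"]

    def test_aggregate_identical_patients(self):
        model = toy_model([0.1], beta=[2.0, -1.0], names=("up", "down"))
        rankings = [influence_ranking(model, np.array([1.0, 1.0]), k=1)] * 100
        agg = aggregate_influences(rankings)
        pos = agg[(agg["direction"] == "positive") & (agg["feature"] == "up")]
        assert pos.iloc[0]["n_patients"] == 100

    def test_dominant_feature_tops_aggregation(self, rng):
        beta = np.array([3.0, 0.2, 0.1, -0.1])
        model = toy_model([0.1, 0.2], beta=beta)
        X = rng.normal(size=(150, 4))
        rankings = [influence_ranking(model, X[i], k=1) for i in range(150)]
        agg = aggregate_influences(rankings)
        pos = agg[agg["direction"] == "positive"]
        assert pos.iloc[0]["feature"] == "x0"
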