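import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from survbench.discrimination import (
    age_tertile_groups,
    auc_confidence_interval,
    concordance_confidence_interval,
    harrell_c,
    roc_auc,
    subgroup_auc,
)

from conftest import brute_force_auc, brute_force_cindex, make_cohort


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([1, 2, 3, 4], [False, False, True, True])
        assert r.auc == 1.0

    def test_all_tied_scores(self):
        r = roc_auc([5, 5, 5, 5], [False, True, False, True])
        assert r.auc == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            roc_auc([1, 2], [True, True])

    def test_curve_geometry_and_area(self, rng):
        scores = rng.integers(0, 10, 60).astype(float)  # heavy ties
        labels = rng.random(60) < 0.4
        r = roc_auc(scores, labels)
        pts = r.roc_points
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)
        assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()
        assert r.auc == pytest.approx(np.trapezoid(pts[:, 1], pts[:, 0]), abs=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_pair_enumeration_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        scores = rng.integers(0, 4, n).astype(float)
        labels = np.zeros(n, bool)
        labels[rng.choice(n, max(1, n // 2), replace=False)] = True
        if labels.all():
            labels[0] = False
        r = roc_auc(scores, labels)
        assert r.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 2**16))
    def test_invariant_under_monotone_transform_and_antisymmetric(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30)
        labels = np.concatenate([np.ones(10, bool), np.zeros(20, bool)])
        base = roc_auc(scores, labels).auc
        assert roc_auc(np.exp(scores), labels).auc == pytest.approx(base, abs=1e-12)
        assert roc_auc(3 * scores + 7, labels).auc == pytest.approx(base, abs=1e-12)
        assert roc_auc(-scores, labels).auc == pytest.approx(1 - base, abs=1e-12)


class TestAucCI:
    def test_bootstrap_deterministic_under_seed(self, rng):
        scores = rng.normal(size=80)
        labels = rng.random(80) < 0.4
        a = auc_confidence_interval(scores, labels, n_boot=300, seed=11)
        b = auc_confidence_interval(scores, labels, n_boot=300, seed=11)
        assert a == b
        c = auc_confidence_interval(scores, labels, n_boot=300, seed=12)
        assert a != c

    def test_small_n_boot_rejected(self, rng):
        with pytest.raises(ValueError, match="n_boot"):
            auc_confidence_interval([1, 2, 3], [True, False, True], n_boot=50)

    def test_analytic_coverage_near_nominal(self):
        # binormal truth: cases N(mu, 1) vs controls N(0, 1), AUC = Phi(mu/sqrt 2)
        mu = 1.0
        truth = norm.cdf(mu / np.sqrt(2))
        rng = np.random.default_rng(7)
        n_reps, covered = 300, 0
        for _ in range(n_reps):
            cases = rng.normal(mu, 1, 60)
            ctrls = rng.normal(0, 1, 90)
            scores = np.concatenate([cases, ctrls])
            labels = np.concatenate([np.ones(60, bool), np.zeros(90, bool)])
            lo, hi = auc_confidence_interval(scores, labels, method="analytic")
            covered += lo <= truth <= hi
        assert 0.90 <= covered / n_reps <= 0.99


class TestHarrellC:
    def test_perfect_ranking_no_censoring(self, rng):
        time = rng.uniform(1, 100, 20)
        res = harrell_c(-time, time, np.ones(20, bool))
        assert res.c_index == 1.0

    def test_hand_enumerated_censored_example(self):
        time = np.array([2.0, 4.0, 4.0, 6.0, 9.0])
        event = np.array([True, True, False, False, True])
        scores = np.array([9.0, 5.0, 5.0, 2.0, 2.0])
        oracle, n_comp = brute_force_cindex(scores, time, event)
        res = harrell_c(scores, time, event)
        assert res.c_index == pytest.approx(oracle, abs=1e-12)
        assert res.n_comparable_pairs == n_comp

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pair_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(5, 12))
        time = rng.integers(1, 8, n).astype(float)  # force tied times
        event = rng.random(n) < 0.6
        if not event.any():
            event[0] = True
        scores = rng.integers(0, 5, n).astype(float)
        oracle, n_comp = brute_force_cindex(scores, time, event)
        if n_comp == 0:
            with pytest.raises(ValueError):
                harrell_c(scores, time, event)
            return
        res = harrell_c(scores, time, event)
        assert res.c_index == pytest.approx(oracle, abs=1e-12)
        assert res.n_comparable_pairs == n_comp
        assert res.n_comparable_pairs >= res.n_tied_score_pairs

    def test_agrees_with_scikit_survival(self, rng):
        sksurv = pytest.importorskip("sksurv.metrics")
        time = rng.uniform(1, 100, 150)
        event = rng.random(150) < 0.6
        scores = rng.normal(size=150) + 0.02 * (100 - time)
        res = harrell_c(scores, time, event)
        ref = sksurv.concordance_index_censored(event, time, scores)
        assert res.c_index == pytest.approx(ref[0], abs=1e-12)

    def test_no_events_errors(self):
        with pytest.raises(ValueError, match="comparable"):
            harrell_c([1.0, 2.0], [3.0, 4.0], [False, False])

    def test_reduces_to_auc_for_binary_outcome(self, rng):
        # survival data carrying only binary information: all deaths at one
        # time, all survivors censored later
        scores = rng.integers(0, 6, 40).astype(float)
        event = rng.random(40) < 0.4
        if not event.any():
            event[0] = True
        time = np.where(event, 1.0, 2.0)
        res = harrell_c(scores, time, event)
        assert res.c_index == pytest.approx(roc_auc(scores, event).auc, abs=1e-12)

    def test_bootstrap_ci_brackets_estimate(self, rng):
        time = rng.uniform(1, 100, 120)
        event = rng.random(120) < 0.5
        scores = -time + rng.normal(0, 30, 120)
        res = harrell_c(scores, time, event)
        lo, hi = concordance_confidence_interval(scores, time, event, n_boot=200, seed=0)
        assert lo <= res.c_index <= hi


class TestSubgroups:
    def test_age_tertiles_near_equal(self, rng):
        ages = rng.integers(22, 99, 1283).astype(float)
        groups, labels = age_tertile_groups(ages)
        sizes = groups.value_counts()
        assert sizes.max() - sizes.min() <= ages.size * 0.05  # ties permitting
        assert len(labels) == 3

    def test_degenerate_group_reported_not_estimable(self, rng):
        n = 60
        df = make_cohort(
            rng.uniform(400, 500, n), np.zeros(n, bool),
            sex=["Female"] * (n // 2) + ["Male"] * (n // 2),
        )
        # give some females deaths so that group is estimable; males stay
        # all-controls
        df.loc[: n // 4 - 1, "followup_days"] = 100.0
        df.loc[: n // 4 - 1, "event"] = True
        table = subgroup_auc(df, 365.0, "sex", n_boot=150)
        male = table[table["group"] == "Male"].iloc[0]
        assert np.isnan(male["eolci_score_auc"])
        female = table[table["group"] == "Female"].iloc[0]
        assert not np.isnan(female["eolci_score_auc"])

    def test_unknown_grouping_errors(self, small_cohort):
        with pytest.raises(ValueError, match="grouping"):
            subgroup_auc(small_cohort, 365.0, "zodiac")
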