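import math

import numpy as np
import pandas as pd
import pytest

from stromasig import (
    SurvivalTable,
    categorize_by_quantile,
    cox_fit,
    generate_cutpoint_study,
    km_estimate,
    logrank_test,
    maxstat_cutpoint,
)
from stromasig.survcut import CoxScreenResult
from tests.conftest import make_survival


def random_survival(rng, n, tie_rounding=None):
    time = rng.exponential(10, n)
    if tie_rounding is not None:
        time = np.maximum(np.round(time, tie_rounding), 0.1)
    event = rng.integers(0, 2, n)
    if event.sum() == 0:
        event[0] = 1
    return make_survival(time, event)


def brute_force_maxstat(score, surv, minprop=0.1):
    """Definitional search: every admissible midpoint cutpoint evaluated
    with the log-rank test; ties broken toward the smallest cutpoint."""
    s = score.to_numpy()
    n = len(s)
    m = math.ceil(minprop * n)
    values = np.sort(np.unique(s))
    best_stat, best_cut = -np.inf, None
    for i in range(len(values) - 1):
        cut = (values[i] + values[i + 1]) / 2.0
        low = s <= cut
        k = int(low.sum())
        if k < m or n - k < m:
            continue
        groups = pd.Series(np.where(low, "a", "b"), index=score.index)
        try:
            lr = logrank_test(surv, groups)
        except ValueError:
            continue
        if abs(lr.z) > best_stat:
            best_stat, best_cut = abs(lr.z), cut
    return best_stat, best_cut


class TestKaplanMeier:
    def test_no_censoring_product_limit(self):
        surv = make_survival([1.0, 2.0, 3.0], [1, 1, 1])
        km = km_estimate(surv)
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0], atol=1e-15)
        assert km.median == 2.0

    def test_all_censored_survival_stays_one(self):
        km = km_estimate(make_survival([1.0, 2.0, 3.0], [0, 0, 0]))
        assert km.survival_at(100.0) == 1.0
        assert np.isnan(km.median)

    def test_hand_product_limit_with_censoring(self, toy_survival):
        km = km_estimate(toy_survival)
        np.testing.assert_allclose(km.event_times, [1.0, 3.0, 4.0])
        np.testing.assert_allclose(km.survival, [0.75, 0.375, 0.0], atol=1e-12)
        # S(3) = 3/4 * 1/2 = 0.375 <= 0.5 -> median 3
        assert km.median == 3.0

    def test_no_censoring_equals_empirical_survival(self, rng):
        time = rng.exponential(5, 40)
        surv = make_survival(time, np.ones(40, dtype=int))
        km = km_estimate(surv)
        for t, s in zip(km.event_times, km.survival):
            assert s == pytest.approx((time > t).mean(), abs=1e-12)

    def test_matches_lifelines_curve_and_median(self, rng):
        from lifelines import KaplanMeierFitter

        surv = random_survival(rng, 80, tie_rounding=0)
        km = km_estimate(surv)
        kmf = KaplanMeierFitter().fit(surv.time, surv.event)
        ref = kmf.survival_function_at_times(km.event_times).to_numpy()
        np.testing.assert_allclose(km.survival, ref, atol=1e-12)
        assert km.median == pytest.approx(kmf.median_survival_time_)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            make_survival([-1.0, 2.0], [1, 1])

    def test_median_ci_brackets_median(self, rng):
        surv = random_survival(rng, 200)
        km = km_estimate(surv)
        lo, hi = km.median_ci
        if not np.isnan(lo) and not np.isnan(hi):
            assert lo <= km.median <= hi


class TestLogRank:
    def test_interleaved_identical_groups_give_zero(self):
        time = [1.0, 1.0, 2.0, 2.0, 3.0, 3.0]
        event = [1, 1, 1, 1, 0, 0]
        surv = make_survival(time, event)
        groups = pd.Series(["a", "b"] * 3, index=surv.sample_ids)
        res = logrank_test(surv, groups)
        assert abs(res.U) < 1e-12
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_by_two_table(self):
        # g1 events at 1,2; g2 events at 3,4 -> U=7/6, V=17/36 (hand O-E table)
        surv = make_survival([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        groups = pd.Series(["g1", "g1", "g2", "g2"], index=surv.sample_ids)
        res = logrank_test(surv, groups)
        assert res.U == pytest.approx(7 / 6, abs=1e-12)
        assert res.V == pytest.approx(17 / 36, abs=1e-12)
        assert res.chi2 == pytest.approx((7 / 6) ** 2 / (17 / 36), abs=1e-12)

    def test_matches_lifelines_on_random_data(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        for _ in range(25):
            surv = random_survival(rng, int(rng.integers(10, 80)), tie_rounding=0)
            grp = rng.integers(0, 2, surv.n)
            if len(np.unique(grp)) < 2:
                grp[:2] = [0, 1]
            groups = pd.Series(np.where(grp == 0, "a", "b"), index=surv.sample_ids)
            mine = logrank_test(surv, groups)
            t, e = surv.time.to_numpy(), surv.event.to_numpy()
            ref = ll_logrank(t[grp == 0], t[grp == 1], e[grp == 0], e[grp == 1])
            assert mine.chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
            assert mine.p == pytest.approx(ref.p_value, abs=1e-8)

    def test_z_squared_is_chi2_and_label_swap_negates_u(self, rng):
        surv = random_survival(rng, 50)
        groups = pd.Series(
            np.where(rng.integers(0, 2, 50) == 0, "a", "b"), index=surv.sample_ids
        )
        res = logrank_test(surv, groups)
        assert res.z**2 == pytest.approx(res.chi2, rel=1e-12)
        flipped = groups.map({"a": "b2", "b": "a2"})  # swaps which label sorts first
        res2 = logrank_test(surv, flipped)
        assert res2.U == pytest.approx(-res.U, abs=1e-10)
        assert res2.chi2 == pytest.approx(res.chi2, rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        surv = make_survival([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="two groups"):
            logrank_test(surv, pd.Series(["a", "a"], index=surv.sample_ids))
        censored = make_survival([1.0, 2.0], [0, 0])
        with pytest.raises(ValueError, match="events"):
            logrank_test(censored, pd.Series(["a", "b"], index=censored.sample_ids))


class TestMaxstat:
    def test_matches_brute_force_enumeration(self, rng):
        checked = 0
        while checked < 25:
            n = int(rng.integers(20, 60))
            surv = random_survival(rng, n, tie_rounding=0)
            score = pd.Series(
                np.round(rng.normal(size=n), 1), index=surv.sample_ids
            )  # rounded -> score ties exercise the distinct-value logic
            try:
                res = maxstat_cutpoint(score, surv, n_perm=5, seed=0)
            except ValueError:
                continue
            ref_stat, ref_cut = brute_force_maxstat(score, surv)
            assert res.max_stat == pytest.approx(ref_stat, abs=1e-12)
            assert res.cutpoint == pytest.approx(ref_cut, abs=1e-12)
            checked += 1

    def test_max_dominates_median_split(self, rng):
        surv = random_survival(rng, 60)
        score = pd.Series(rng.normal(size=60), index=surv.sample_ids)
        res = maxstat_cutpoint(score, surv, n_perm=5, seed=0)
        labels, _thr = categorize_by_quantile(score, q=0.5)
        median_z = abs(logrank_test(surv, labels).z)
        assert res.max_stat >= median_z - 1e-12

    def test_groups_consistent_with_cutpoint_and_minprop(self, rng):
        surv = random_survival(rng, 100)
        score = pd.Series(rng.normal(size=100), index=surv.sample_ids)
        res = maxstat_cutpoint(score, surv, minprop=0.2, n_perm=5, seed=0)
        high = res.groups == "high"
        assert ((score > res.cutpoint) == high).all()
        assert min(high.sum(), (~high).sum()) >= math.ceil(0.2 * 100)

    def test_permutation_p_is_seeded_and_in_range(self, rng):
        score, surv, _t = generate_cutpoint_study(n=80, hazard_ratio=3.0, seed=5)
        r1 = maxstat_cutpoint(score, surv, n_perm=100, seed=42)
        r2 = maxstat_cutpoint(score, surv, n_perm=100, seed=42)
        assert r1.p_perm == r2.p_perm
        assert 1 / 101 <= r1.p_perm <= 1.0
        assert r1.p_perm < 0.05  # strong planted effect

    def test_recovers_planted_step(self):
        hits = 0
        for seed in range(10):
            score, surv, truth = generate_cutpoint_study(n=250, hazard_ratio=2.5, seed=seed)
            res = maxstat_cutpoint(score, surv, n_perm=20, seed=seed)
            q_hat = (score <= res.cutpoint).mean()
            if abs(q_hat - truth.planted_cutpoint_quantile) <= 0.10:
                hits += 1
        assert hits >= 8

    def test_no_admissible_candidate_errors(self):
        surv = make_survival([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        const = pd.Series([1.0] * 4, index=surv.sample_ids)
        with pytest.raises(ValueError, match="candidate"):
            maxstat_cutpoint(const, surv, n_perm=5, seed=0)


class TestQuantileCategorization:
    def test_exact_tertile_on_distinct_scores(self):
        score = pd.Series(np.arange(1.0, 10.0), index=[f"s{i}" for i in range(9)])
        labels, thr = categorize_by_quantile(score, q=2 / 3)
        assert (labels == "high").sum() == 3
        assert thr == pytest.approx(np.quantile(np.arange(1.0, 10.0), 2 / 3))

    def test_upper_tertile_split_fractions(self, rng):
        score = pd.Series(rng.normal(size=900), index=[f"s{i}" for i in range(900)])
        labels, _ = categorize_by_quantile(score, q=2 / 3)
        assert (labels == "high").mean() == pytest.approx(1 / 3, abs=0.01)

    def test_ties_at_threshold_fall_low(self):
        score = pd.Series([1.0, 2.0, 2.0, 2.0, 2.0, 5.0], index=[f"s{i}" for i in range(6)])
        labels, thr = categorize_by_quantile(score, q=2 / 3)
        assert thr == pytest.approx(2.0)
        assert (labels == "high").sum() == 1  # only the strictly-greater sample
        # high fraction <= 1 - q + tie mass
        assert (labels == "high").mean() <= 1 - 2 / 3 + (score == thr).mean() + 1e-12

    def test_constant_scores_rejected(self):
        score = pd.Series([3.0, 3.0, 3.0], index=["a", "b", "c"])
        with pytest.raises(ValueError, match="constant"):
            categorize_by_quantile(score)

    def test_interface_matches_maxstat_downstream(self, rng):
        """Quantile and maxstat splits feed identical label machinery."""
        score, surv, _ = generate_cutpoint_study(n=60, hazard_ratio=2.0, seed=3)
        for labels in (
            categorize_by_quantile(score)[0],
            maxstat_cutpoint(score, surv, n_perm=5, seed=0).groups,
        ):
            res = logrank_test(surv, labels)
            assert np.isfinite(res.chi2)


def _breslow_score_test(time, event, x):
    """Independent derivation: partial-likelihood score U(0) and information
    I(0) with Breslow tie handling for a single covariate."""
    order = np.argsort(time)
    time, event, x = time[order], event[order], x[order]
    U = I = 0.0
    for i in np.nonzero(event == 1)[0]:
        risk = time >= time[i]
        xbar = x[risk].mean()
        U += x[i] - xbar
        I += np.mean((x[risk] - xbar) ** 2)
    return U, I


class TestCox:
    def test_score_test_at_zero_equals_logrank_without_ties(self, rng):
        # dual route: partial-likelihood algebra vs hypergeometric counting
        n = 60
        time = rng.exponential(10, n)  # continuous -> no ties
        event = rng.integers(0, 2, n)
        event[0] = 1
        x = rng.integers(0, 2, n).astype(float)
        x[:2] = [0, 1]
        surv = make_survival(time, event)
        groups = pd.Series(np.where(x == 0, "a", "b"), index=surv.sample_ids)
        lr = logrank_test(surv, groups)
        U, I = _breslow_score_test(time, event, x)
        assert lr.chi2 == pytest.approx(U * U / I, abs=1e-6)

    def test_binary_covariate_recovers_true_hazard_ratio(self, rng):
        n = 800
        x = rng.integers(0, 2, n)
        hazard = 0.05 * np.exp(np.log(2.0) * x)
        t_event = rng.exponential(1 / hazard)
        censor = rng.uniform(0, 60, n)
        surv = make_survival(np.minimum(t_event, censor), (t_event <= censor).astype(int))
        res = cox_fit(surv, pd.DataFrame({"x": x.astype(float)}, index=surv.sample_ids))
        hr = res.summary.loc["x", "hazard_ratio"]
        assert 1.6 < hr < 2.5
        assert res.summary.loc["x", "ci_lower"] < hr < res.summary.loc["x", "ci_upper"]

    def test_univariate_screen_selects_informative_covariate(self, rng):
        n = 400
        x = rng.integers(0, 2, n)
        noise = rng.normal(size=n)
        hazard = 0.05 * np.exp(1.0 * x)
        t_event = rng.exponential(1 / hazard)
        censor = rng.uniform(0, 60, n)
        surv = make_survival(np.minimum(t_event, censor), (t_event <= censor).astype(int))
        res = cox_fit(
            surv,
            pd.DataFrame({"x": x.astype(float), "noise": noise}, index=surv.sample_ids),
            mode="univariate_screen",
        )
        assert isinstance(res, CoxScreenResult)
        assert "x" in res.selected and "noise" not in res.selected
        assert res.final is not None and "x" in res.final.summary.index

    def test_categorical_covariate_one_hot_reference(self, rng):
        n = 90
        stage = rng.choice(["I", "II", "III"], size=n)
        surv = make_survival(rng.exponential(10, n), np.ones(n, dtype=int))
        res = cox_fit(surv, pd.DataFrame({"stage": stage}, index=surv.sample_ids))
        assert list(res.summary.index) == ["stage[II]", "stage[III]"]

    def test_degenerate_designs_rejected(self, rng):
        n = 40
        surv = make_survival(rng.exponential(10, n), np.ones(n, dtype=int))
        x = rng.normal(size=n)
        with pytest.raises(ValueError, match="zero-variance"):
            cox_fit(surv, pd.DataFrame({"c": np.ones(n)}, index=surv.sample_ids))
        with pytest.raises(ValueError, match="collinear"):
            cox_fit(surv, pd.DataFrame({"a": x, "b": 2 * x}, index=surv.sample_ids))
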