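import numpy as np
import pytest

from bloodhof.survival import (
    SurvivalRecord,
    calibration_table,
    concordance_index,
    event_by_horizon,
    fit_cox_ph,
    km_estimate,
    net_benefit_curve,
)


def rec(times, events):
    return [SurvivalRecord(f"p{i}", float(t), int(e)) for i, (t, e) in enumerate(zip(times, events))]


def brute_c_index(scores, times, events):
    """O(n^2) explicit pair enumeration (the independent oracle)."""
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            comparable = (times[i] < times[j] and events[i] == 1) or (
                times[i] == times[j] and events[i] == 1 and events[j] == 0
            )
            if not comparable:
                continue
            den += 1
            if scores[i] > scores[j]:
                num += 1
            elif scores[i] == scores[j]:
                num += 0.5
    return num / den


def random_instance(rng, n):
    times = rng.exponential(100, n).round(1) + 1
    events = rng.integers(0, 2, n)
    scores = rng.choice([0.1, 0.5, 0.9, 1.3], n)  # score ties on purpose
    if events.sum() == 0:
        events[0] = 1
    return scores, times, events


class TestKaplanMeier:
    def test_no_censoring_matches_empirical_survival(self):
        km = km_estimate(rec([1, 2, 3, 4], [1, 1, 1, 1]))
        np.testing.assert_allclose(km.survival, [0.75, 0.5, 0.25, 0.0])

    def test_hand_product_limit_with_censoring(self):
        # death at 1 (3 at risk), censor at 2, death at 3 (1 at risk)
        km = km_estimate(rec([1, 2, 3], [1, 0, 1]))
        assert km.at(1) == pytest.approx(2 / 3)
        assert km.at(2.5) == pytest.approx(2 / 3)
        assert km.at(3) == pytest.approx(0.0)

    def test_hand_product_limit_censor_before_second_death(self):
        # death at 1 (4 at risk), censor at 2, death at 3 (2 at risk)
        km = km_estimate(rec([1, 2, 3, 5], [1, 0, 1, 0]))
        assert km.at(1) == pytest.approx(3 / 4)
        assert km.at(3) == pytest.approx(3 / 8)

    def test_all_censored_is_flat_one(self):
        km = km_estimate(rec([5, 10], [0, 0]))
        assert km.at(0) == 1.0 and km.at(100) == 1.0

    def test_monotone_nonincreasing_step_function(self):
        rng = np.random.default_rng(0)
        km = km_estimate(rec(rng.exponential(50, 200) + 1, rng.integers(0, 2, 200)))
        assert km.at(0) == 1.0
        assert (np.diff(km.survival) <= 1e-12).all()

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(1)
        times = rng.exponential(50, 300).round() + 1
        events = rng.integers(0, 2, 300)
        km = km_estimate(rec(times, events))
        kmf = lifelines.KaplanMeierFitter().fit(times, events)
        for t in [10, 50, 120, 300]:
            assert km.at(t) == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-10
            )


class TestConcordance:
    def test_perfectly_ordered_scores(self):
        records = rec([1, 2, 3, 4], [1, 1, 1, 1])
        assert concordance_index([4, 3, 2, 1], records) == 1.0
        assert concordance_index([1, 2, 3, 4], records) == 0.0

    def test_three_subject_hand_case(self):
        records = rec([1, 2, 3], [1, 1, 0])
        assert concordance_index([0.5, 0.9, 0.1], records) == pytest.approx(2 / 3)

    def test_matches_brute_force_on_200_random_censored_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            scores, times, events = random_instance(rng, int(rng.integers(5, 100)))
            records = rec(times, events)
            assert concordance_index(scores, records) == pytest.approx(
                brute_c_index(scores, times, events), abs=1e-14
            )

    def test_complement_symmetry_without_ties(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(50, 80) + 1
        events = rng.integers(0, 2, 80)
        events[0] = 1
        scores = rng.normal(size=80)  # continuous: no ties
        records = rec(times, events)
        c = concordance_index(scores, records)
        assert c + concordance_index(-scores, records) == pytest.approx(1.0, abs=1e-12)

    def test_no_comparable_pairs_is_an_error(self):
        with pytest.raises(ValueError, match="comparable"):
            concordance_index([1, 2], rec([5, 5], [1, 1]))


class TestCoxFit:
    def test_tiny_dataset_matches_grid_search_oracle(self):
        records = rec([1, 2, 3, 4], [1, 1, 1, 0])
        x = np.array([[1.0], [0.0], [1.0], [0.0]])
        fit = fit_cox_ph(x, records)

        def breslow_ll(beta):
            # explicit prefix-risk-set computation, descending time
            order = np.argsort([-r.time for r in records])
            eta = (x[:, 0] * beta)[order]
            ev = np.array([r.event for r in records])[order]
            ll, cum = 0.0, 0.0
            for i in range(len(records)):
                cum += np.exp(eta[i])
                if ev[i] == 1:
                    ll += eta[i] - np.log(cum)
            return ll

        grid = np.linspace(fit.coefficients[0] - 2, fit.coefficients[0] + 2, 40001)
        lls = np.array([breslow_ll(b) for b in grid])
        assert fit.log_partial_likelihood == pytest.approx(lls.max(), abs=1e-4)
        assert abs(grid[lls.argmax()] - fit.coefficients[0]) < 1e-3

    def test_recovers_binary_log_hazard_ratio(self):
        rng = np.random.default_rng(7)
        n = 500
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / np.exp(np.log(2) * x))
        c = rng.exponential(2.0, n)
        records = rec(np.minimum(t, c) + 1e-6, (t <= c).astype(int))
        fit = fit_cox_ph(x[:, None], records)
        assert abs(fit.coefficients[0] - np.log(2)) < 3 * fit.standard_errors[0]

    def test_null_covariate_near_zero(self):
        rng = np.random.default_rng(8)
        n = 500
        x = rng.normal(size=n)
        records = rec(rng.exponential(1.0, n) + 1e-6, np.ones(n, dtype=int))
        fit = fit_cox_ph(x[:, None], records)
        assert abs(fit.coefficients[0]) < 3 * fit.standard_errors[0]

    def test_likelihood_trace_non_decreasing(self):
        rng = np.random.default_rng(9)
        n = 200
        x = rng.normal(size=(n, 2))
        lp = x @ np.array([0.5, -0.8])
        t = rng.exponential(1.0 / np.exp(lp))
        records = rec(t + 1e-6, np.ones(n, dtype=int))
        fit = fit_cox_ph(x, records)
        assert (np.diff(fit.ll_trace) >= -1e-9).all()
        assert fit.converged

    def test_matches_breslow_reference_implementation(self):
        sksurv = pytest.importorskip("sksurv.linear_model")
        rng = np.random.default_rng(10)
        n = 300
        x = rng.normal(size=(n, 2))
        lp = x @ np.array([0.7, -0.3])
        t = np.round(rng.exponential(100 / np.exp(lp))) + 1  # ties via rounding
        c = rng.uniform(20, 400, n)
        times, events = np.minimum(t, c), (t <= c).astype(int)
        fit = fit_cox_ph(x, rec(times, events))
        y = np.array(
            [(bool(e), float(tt)) for e, tt in zip(events, times)],
            dtype=[("event", "?"), ("time", "<f8")],
        )
        ref = sksurv.CoxPHSurvivalAnalysis(ties="breslow").fit(x, y)
        np.testing.assert_allclose(fit.coefficients, ref.coef_, atol=1e-5)


class TestNetBenefit:
    def test_treat_all_closed_form(self):
        y = np.array([1] * 3 + [0] * 7)
        table = net_benefit_curve(np.full(10, 0.9), y, [0.2])
        assert table["treat_all"].iloc[0] == pytest.approx(0.3 - 0.7 * 0.25)
        # a model that treats everyone equals the treat-all line
        assert table["net_benefit"].iloc[0] == pytest.approx(table["treat_all"].iloc[0])

    def test_treat_none_is_zero_and_perfect_model_hits_prevalence(self):
        y = np.array([1] * 3 + [0] * 7)
        probs = y.astype(float)
        table = net_benefit_curve(probs, y, [0.1, 0.5, 0.9])
        assert (table["treat_none"] == 0).all()
        np.testing.assert_allclose(table["net_benefit"], 0.3)

    def test_treat_all_is_linear_in_odds_with_slope_one_minus_prevalence(self):
        y = np.array([1] * 4 + [0] * 6)
        pts = np.array([0.1, 0.2, 0.3, 0.4])
        table = net_benefit_curve(np.full(10, 1.0), y, pts)
        odds = pts / (1 - pts)
        slopes = np.diff(table["treat_all"]) / np.diff(odds)
        np.testing.assert_allclose(slopes, -(1 - 0.4), atol=1e-12)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            net_benefit_curve([0.5], [1], [])

    def test_event_by_horizon_complete_case(self):
        outcome, usable = event_by_horizon(rec([100, 400, 200, 500], [1, 0, 0, 1]), 365)
        assert list(outcome) == [1, 0, 0, 0]
        assert list(usable) == [True, True, False, True]


class TestCalibration:
    def test_constant_predictions_collapse_to_overall_km(self):
        records = rec([100, 200, 300, 400, 500, 600], [1, 1, 0, 1, 0, 1])
        table = calibration_table(np.full(6, 0.7), records, horizon=365, n_bins=3)
        assert len(table) == 1
        overall = km_estimate(records).at(365)
        assert table["observed_km"].iloc[0] == pytest.approx(overall)

    def test_two_quantile_bins_of_five(self):
        records = rec(np.arange(1, 11) * 50, [1] * 10)
        preds = np.linspace(0.1, 0.9, 10)
        table = calibration_table(preds, records, horizon=250, n_bins=2)
        assert list(table["n"]) == [5, 5]

    def test_well_calibrated_predictions_agree_with_km(self):
        rng = np.random.default_rng(12)
        n = 4000
        scale = rng.choice([200.0, 600.0], n)
        t = rng.exponential(scale)
        c = rng.uniform(100, 1500, n)
        records = rec(np.minimum(t, c) + 1e-6, (t <= c).astype(int))
        horizon = 365.0
        preds = np.exp(-horizon / scale)  # the true survival probabilities
        table = calibration_table(preds, records, horizon, n_bins=2)
        assert np.abs(table["mean_predicted"] - table["observed_km"]).max() < 0.03
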