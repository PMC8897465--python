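"""Waiting-time extraction, survival estimation, and mixed-Gamma fitting."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from mitobook.memory import (
    ActivationRecord,
    MemoryFit,
    WaitingTimeSet,
    cumulative_activation,
    estimate_states,
    extract_waiting_times,
    fit_survival,
    kaplan_meier,
    memory_score,
    simulate_chain,
    survival_model,
)


def rec(nid, t_act, t_end=100.0, movie="m1", state="unknown"):
    return ActivationRecord(nid, movie, state, t_act, t_end)


class TestExtraction:
    def test_pooled_t0_is_first_activation(self):
        records = [rec("a", 5.0), rec("b", 7.0), rec("c", 9.0)]
        wts = extract_waiting_times(records)["unknown"]
        assert wts.T0 == 5.0
        np.testing.assert_array_equal(np.sort(wts.observed), [0.0, 2.0, 4.0])

    def test_per_movie_mode_shifts_each_movie(self):
        records = [rec("a", 5.0, movie="m1"), rec("b", 9.0, movie="m1"),
                   rec("c", 20.0, movie="m2"), rec("d", 26.0, movie="m2")]
        wts = extract_waiting_times(records, t0_mode="per_movie")["unknown"]
        np.testing.assert_array_equal(np.sort(wts.observed), [0, 0, 4, 6])

    def test_censored_entry_carries_remaining_time(self):
        records = [rec("a", 5.0), rec("b", None, t_end=30.0)]
        wts = extract_waiting_times(records)["unknown"]
        np.testing.assert_array_equal(wts.censored, [25.0])

    def test_split_by_mother_state(self):
        records = [rec("a", 5.0, state="active"), rec("b", 8.0, state="inactive")]
        wts = extract_waiting_times(records)
        assert set(wts) == {"active", "inactive"}

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError):
            extract_waiting_times([rec("a", None)])


class TestKaplanMeier:
    def test_uncensored_empirical_survival(self):
        wts = WaitingTimeSet(0.0, observed=np.array([1.0, 2.0, 3.0]),
                             censored=np.array([]))
        c = kaplan_meier(wts)
        s_at = lambda t: c.S[np.searchsorted(c.times, t, side="right") - 1]
        assert s_at(0.5) == pytest.approx(1.0)
        assert s_at(1.5) == pytest.approx(2 / 3)
        assert s_at(2.5) == pytest.approx(1 / 3)
        assert s_at(3.5) == pytest.approx(0.0)

    def test_matches_independent_product_limit_oracle(self):
        rng = np.random.default_rng(4)
        obs = rng.exponential(10.0, 60)
        cens = rng.exponential(15.0, 25)
        c = kaplan_meier(WaitingTimeSet(0.0, obs, cens))
        # hand-coded product-limit estimator
        durations = np.concatenate([obs, cens])
        events = np.concatenate([np.ones(60), np.zeros(25)])
        order = np.argsort(durations)
        s, at_risk = 1.0, len(durations)
        oracle = {}
        for d, e in zip(durations[order], events[order]):
            if e:
                s *= (at_risk - 1) / at_risk
            oracle[d] = s
            at_risk -= 1
        for t, s_hat in oracle.items():
            i = np.searchsorted(c.times, t, side="right") - 1
            assert c.S[i] == pytest.approx(s_hat, abs=1e-10)

    def test_survival_is_monotone_and_starts_at_one(self):
        rng = np.random.default_rng(5)
        c = kaplan_meier(
            WaitingTimeSet(0.0, rng.gamma(2, 30, 100), rng.uniform(0, 90, 40))
        )
        assert c.S[0] == pytest.approx(1.0)
        assert np.all(np.diff(c.S) <= 1e-12)


class TestSurvivalModel:
    def test_normalization_at_zero(self):
        s = survival_model(np.array([0.0]), np.array([0.2, 0.3, 0.5]), 50.0)
        assert s[0] == pytest.approx(1.0)

    def test_exponential_half_life(self):
        tau = 80.0
        s = survival_model(np.array([tau * math.log(2)]),
                           np.array([1.0, 0.0, 0.0]), tau)
        assert s[0] == pytest.approx(0.5)

    def test_mean_is_a_times_b_by_quadrature(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            p = rng.dirichlet([1, 1, 1])
            tau = rng.uniform(10, 300)
            val, _ = quad(
                lambda t: survival_model(np.array([t]), p, tau)[0],
                0, 200 * tau, limit=300,
            )
            a = p @ [1, 2, 3]
            assert val == pytest.approx(a * tau, rel=1e-4)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            survival_model(np.array([1.0]), np.array([0.5, 0.2, 0.2]), 10.0)


class TestFitSurvival:
    @staticmethod
    def dense_curve(p, tau):
        from mitobook.memory import SurvivalCurve

        t = np.linspace(1.0, 12 * tau, 400)
        S = survival_model(t, p, tau)
        return SurvivalCurve(times=t, S=S, n_at_risk=np.full(t.size, 400),
                             is_event=np.ones(t.size, bool))

    def test_self_consistency_on_model_curve(self):
        p, tau = np.array([0.3, 0.4, 0.3]), 100.0
        fit = fit_survival(self.dense_curve(p, tau))
        np.testing.assert_allclose(fit.p, p, atol=0.02)
        assert fit.tau == pytest.approx(tau, rel=0.02)
        assert fit.b == fit.tau

    def test_recovery_from_simulated_events(self):
        recs = simulate_chain(np.array([0.3, 0.4, 0.3]), 100.0, 10_000, seed=1)
        Tr = np.array([r.t_activation for r in recs])
        fit = fit_survival(kaplan_meier(WaitingTimeSet(0.0, Tr, np.array([]))))
        assert fit.a == pytest.approx(2.0, rel=0.10)
        assert fit.b == pytest.approx(100.0, rel=0.10)

    def test_exponential_limit(self):
        # at the simplex corner p = (1,0,0) sampled KM noise can only push
        # a upward (the mixture absorbs correlated fluctuations), so the
        # limit is checked on the exact exponential survival curve
        fit = fit_survival(self.dense_curve(np.array([1.0, 0.0, 0.0]), 50.0))
        assert 0.95 <= fit.a <= 1.1
        assert fit.tau == pytest.approx(50.0, rel=0.02)

    def test_too_few_events_rejected(self):
        from mitobook.memory import SurvivalCurve

        c = SurvivalCurve(times=np.array([1.0, 2.0]), S=np.array([0.5, 0.0]),
                          n_at_risk=np.array([2, 1]),
                          is_event=np.array([True, True]))
        with pytest.raises(Exception):
            fit_survival(c)


class TestEstimateStates:
    def test_gamma_three_sample(self):
        rng = np.random.default_rng(7)
        a_mv, N, Nr = estimate_states(rng.gamma(3.0, 100.0, 100_000))
        assert a_mv == pytest.approx(3.0, rel=0.05)
        assert Nr == 4

    def test_exponential_sample(self):
        rng = np.random.default_rng(8)
        _, _, Nr = estimate_states(rng.standard_exponential(100_000) * 50)
        assert Nr == 2

    def test_constant_shift_inflates_estimate(self):
        rng = np.random.default_rng(9)
        x = rng.gamma(2.0, 50.0, 50_000)
        a0, _, _ = estimate_states(x)
        a1, _, _ = estimate_states(x + 200.0)
        assert a1 > 2 * a0  # shifted mean, same variance

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            estimate_states(np.full(10, 3.0))


class TestSimulateChain:
    def test_exponential_mean(self):
        recs = simulate_chain(np.array([1.0, 0.0, 0.0]), 80.0, 10_000, seed=3)
        Tr = np.array([r.t_activation for r in recs])
        assert Tr.mean() == pytest.approx(80.0, rel=0.03)

    def test_survival_agrees_with_closed_form(self):
        p, tau = np.array([0.3, 0.4, 0.3]), 100.0
        recs = simulate_chain(p, tau, 10_000, seed=4)
        Tr = np.sort([r.t_activation for r in recs])
        emp = 1.0 - np.arange(1, Tr.size + 1) / Tr.size
        sup = np.max(np.abs(emp - survival_model(Tr, p, tau)))
        assert sup < 0.02

    def test_seed_determinism(self):
        a = simulate_chain(np.array([0.5, 0.5, 0.0]), 10.0, 100, seed=5)
        b = simulate_chain(np.array([0.5, 0.5, 0.0]), 10.0, 100, seed=5)
        assert [r.t_activation for r in a] == [r.t_activation for r in b]

    def test_censoring_at_movie_end(self):
        recs = simulate_chain(np.array([0.0, 0.0, 1.0]), 100.0, 500,
                              T0=10.0, t_end=150.0, seed=6)
        censored = [r for r in recs if not r.observed]
        assert censored  # Gamma(3,100) routinely exceeds 140 s
        assert all(r.t_end == 150.0 for r in recs)
        assert all(r.t_activation >= 10.0 for r in recs if r.observed)


class TestScore:
    def test_identical_fits_score_one(self):
        f = MemoryFit(np.array([0.3, 0.4, 0.3]), 100.0, 0.0)
        assert memory_score(f, f) == (1.0, 1.0)

    def test_doubled_lifetime_doubles_both_scores(self):
        fa = MemoryFit(np.array([0.3, 0.4, 0.3]), 100.0, 0.0)
        fi = MemoryFit(np.array([0.3, 0.4, 0.3]), 200.0, 0.0)
        s_ab, s_b = memory_score(fi, fa)
        assert s_ab == pytest.approx(2.0)
        assert s_b == pytest.approx(2.0)


class TestCumulativeActivation:
    def test_t50_is_median_activation(self):
        records = [rec(str(i), t) for i, t in enumerate([2.0, 4.0, 6.0, 8.0])]
        _, _, t50 = cumulative_activation(records)
        assert t50 == 4.0

    def test_single_nucleus(self):
        _, _, t50 = cumulative_activation([rec("a", 7.0)])
        assert t50 == 7.0

    def test_curve_nondecreasing_and_ends_at_one(self):
        rng = np.random.default_rng(10)
        records = [rec(str(i), float(t), t_end=1e4)
                   for i, t in enumerate(rng.gamma(2, 30, 50))]
        _, curve, _ = cumulative_activation(records)
        assert np.all(np.diff(curve) >= 0)
        assert curve[-1] == pytest.approx(1.0)
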