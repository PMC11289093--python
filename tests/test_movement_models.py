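import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from qflytrack.movement_models import (CrwModel, HmmModel, RwModel,
                                       StateParams, fit_crw, fit_hmm, fit_rw,
                                       gamma_from_mean_sd, hmm_loglik,
                                       mean_sd_from_gamma, simulate_path,
                                       viterbi_states)
from qflytrack.track_io import StepSeries, derive_steps


class TestGammaParameterization:
    @pytest.mark.parametrize("mean,sd,shape,rate", [
        (0.8, 0.3, 7.1111111111, 8.8888888889),
        (4.0, 3.0, 1.7777777778, 0.4444444444),
        (1.0, 1.0, 1.0, 1.0),
    ])
    def test_moment_equations(self, mean, sd, shape, rate):
        a, r = gamma_from_mean_sd(mean, sd)
        assert a == pytest.approx(shape, abs=1e-9)
        assert r == pytest.approx(rate, abs=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0.01, 50), st.floats(0.01, 20))
    def test_round_trip(self, mean, sd):
        assert mean_sd_from_gamma(*gamma_from_mean_sd(mean, sd)) == \
            pytest.approx((mean, sd), rel=1e-10)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            gamma_from_mean_sd(0.0, 1.0)


def _series_from(model, n, seed):
    path, states = simulate_path(model, n, seed=seed)
    return derive_steps(path, 0.0), states


class TestSimulatePath:
    def test_rw_turning_angles_uniform(self):
        s, _ = _series_from(RwModel(1.0, 0.5), 3000, seed=1)
        # K-S against the uniform distribution on (-pi, pi]
        d, p = stats.kstest(s.turning_angles, "uniform",
                           args=(-np.pi, 2 * np.pi))
        assert p > 0.01

    def test_degenerate_crw_is_straight(self):
        m = CrwModel(1.0, 1e-9, 0.0, math.inf)
        s, _ = _series_from(m, 50, seed=2)
        np.testing.assert_allclose(s.turning_angles, 0.0, atol=1e-6)
        np.testing.assert_allclose(s.lengths, 1.0, atol=1e-5)

    def test_hmm_state_occupancy_matches_stationary(self, ref_hmm):
        _, states = simulate_path(ref_hmm, 100_000, seed=3)
        assert np.mean(states) == pytest.approx(0.5, abs=0.02)

    def test_positions_accumulate(self):
        path, _ = simulate_path(RwModel(2.0, 1.0), 10, seed=4)
        s = derive_steps(path, 0.0)
        np.testing.assert_allclose(s.positions(), path.xy(), atol=1e-9)


def _brute_force_loglik(model, series):
    """Exhaustive sum over all state sequences (oracle for small n)."""
    lengths = series.lengths
    turns = np.concatenate([[np.nan], series.turning_angles])
    n = len(lengths)
    delta = model.start_distribution()
    total = 0.0
    for seq in itertools.product(range(model.n_states), repeat=n):
        p = delta[seq[0]]
        for t in range(1, n):
            p *= model.transition[seq[t - 1], seq[t]]
        for t, k in enumerate(seq):
            sp = model.states[k]
            shape, rate = sp.gamma_params()
            p *= stats.gamma.pdf(lengths[t], shape, scale=1 / rate)
            if not np.isnan(turns[t]):
                p *= stats.vonmises.pdf(turns[t], sp.turn_kappa, loc=sp.turn_mean)
        total += p
    return math.log(total)


def _random_hmm(rng):
    st1 = StateParams(rng.uniform(0.5, 1.5), rng.uniform(0.2, 0.6),
                      rng.uniform(-1, 1), rng.uniform(0, 2))
    st2 = StateParams(rng.uniform(2, 6), rng.uniform(1, 4),
                      rng.uniform(-1, 1), rng.uniform(0, 2))
    a, b = rng.uniform(0.1, 0.9, 2)
    return HmmModel([st1, st2], np.array([[a, 1 - a], [1 - b, b]]))


class TestHmmLoglik:
    def test_forward_equals_enumeration(self, ref_hmm):
        rng = np.random.default_rng(10)
        for trial in range(4):
            model = _random_hmm(rng)
            series, _ = _series_from(ref_hmm, 8, seed=100 + trial)
            ll = hmm_loglik(model, [series])
            assert ll == pytest.approx(_brute_force_loglik(model, series),
                                       abs=1e-10)

    def test_identical_states_reduce_to_crw(self, small_hmm_series):
        sp = StateParams(2.0, 1.5, 0.1, 0.7)
        model = HmmModel([sp, sp], np.array([[0.6, 0.4], [0.3, 0.7]]))
        ll = hmm_loglik(model, small_hmm_series)
        shape, rate = sp.gamma_params()
        oracle = 0.0
        for s in small_hmm_series:
            oracle += stats.gamma.logpdf(s.lengths, shape, scale=1 / rate).sum()
            oracle += stats.vonmises.logpdf(s.turning_angles, sp.turn_kappa,
                                            loc=sp.turn_mean).sum()
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_empty_path_contributes_nothing(self, ref_hmm, small_hmm_series):
        empty = StepSeries(np.empty(0), np.empty(0), np.empty(0), empty=True)
        assert hmm_loglik(ref_hmm, small_hmm_series + [empty]) == \
            pytest.approx(hmm_loglik(ref_hmm, small_hmm_series), abs=1e-12)

    def test_zero_length_step_errors(self, ref_hmm):
        bad = StepSeries(np.array([0.0, 1.0]), np.array([0.0, 0.1]),
                         np.array([0.1]))
        with pytest.raises(ValueError, match="min_step"):
            hmm_loglik(ref_hmm, [bad])


class TestFitHmm:
    def test_refit_from_fitted_model_is_fixed_point(self, small_hmm_series):
        r1 = fit_hmm(small_hmm_series, n_starts=5, seed=1)
        r2 = fit_hmm(small_hmm_series, n_starts=1, init=r1.model)
        assert r2.loglik == pytest.approx(r1.loglik, abs=1e-6)

    def test_more_starts_never_hurt(self, small_hmm_series):
        r1 = fit_hmm(small_hmm_series, n_starts=1, seed=3)
        r5 = fit_hmm(small_hmm_series, n_starts=5, seed=3)
        assert r5.loglik >= r1.loglik - 1e-9

    def test_states_sorted_by_step_mean(self, hmm_series):
        r = fit_hmm(hmm_series[:10], n_starts=5, seed=4)
        means = [s.step_mean for s in r.model.states]
        assert means == sorted(means)

    def test_aic_identity_and_param_count(self, hmm_series):
        r = fit_hmm(hmm_series[:10], n_starts=3, seed=5)
        assert r.n_params == 10
        assert r.aic == pytest.approx(-2 * r.loglik + 2 * r.n_params, abs=0)

    def test_stationary_initial_distribution(self, hmm_series):
        r = fit_hmm(hmm_series[:10], n_starts=3, seed=6)
        d = r.model.start_distribution()
        np.testing.assert_allclose(d @ r.model.transition, d, atol=1e-10)


class TestFitRwCrw:
    def test_crw_beats_rw_on_crw_data(self):
        m = CrwModel(2.0, 1.5, 0.0, 0.7)
        series = [_series_from(m, 500, seed=s)[0] for s in range(4)]
        assert fit_crw(series).aic < fit_rw(series).aic

    def test_rw_data_gives_near_zero_kappa(self):
        series = [_series_from(RwModel(2.0, 1.5), 1000, seed=s)[0]
                  for s in (7, 8)]
        assert fit_crw(series).model.turn_kappa < 0.1

    def test_param_counts_and_aic_differences(self, small_hmm_series):
        rw, crw = fit_rw(small_hmm_series), fit_crw(small_hmm_series)
        hmm = fit_hmm(small_hmm_series, n_starts=3, seed=9)
        assert (rw.n_params, crw.n_params, hmm.n_params) == (2, 4, 10)
        d_aic = crw.aic - rw.aic
        d_ll = crw.loglik - rw.loglik
        assert d_aic == pytest.approx(-2 * d_ll + 2 * (4 - 2), abs=1e-9)

    def test_gamma_ml_recovers_moments(self):
        rng = np.random.default_rng(12)
        shape, rate = gamma_from_mean_sd(3.0, 2.0)
        lengths = rng.gamma(shape, 1 / rate, 5000)
        s = StepSeries(lengths, np.zeros(5000), np.zeros(4999))
        m = fit_crw([s]).model
        assert m.step_mean == pytest.approx(3.0, abs=0.15)
        assert m.step_sd == pytest.approx(2.0, abs=0.15)

    def test_degenerate_equal_lengths_error(self):
        s = StepSeries(np.ones(20), np.zeros(20), np.zeros(19))
        with pytest.raises(ValueError, match="degenerate"):
            fit_rw([s])


def _brute_force_viterbi(model, series):
    lengths = series.lengths
    turns = np.concatenate([[np.nan], series.turning_angles])
    n = len(lengths)
    delta = model.start_distribution()
    best, best_seq = -math.inf, None
    for seq in itertools.product(range(model.n_states), repeat=n):
        lp = math.log(delta[seq[0]])
        for t in range(1, n):
            lp += math.log(model.transition[seq[t - 1], seq[t]])
        for t, k in enumerate(seq):
            sp = model.states[k]
            shape, rate = sp.gamma_params()
            lp += stats.gamma.logpdf(lengths[t], shape, scale=1 / rate)
            if not np.isnan(turns[t]):
                lp += stats.vonmises.logpdf(turns[t], sp.turn_kappa,
                                            loc=sp.turn_mean)
        if lp > best + 1e-12:
            best, best_seq = lp, seq
    return np.array(best_seq)


class TestViterbi:
    def test_identical_states_tie_break_low_index(self, small_hmm_series):
        sp = StateParams(2.0, 1.5, 0.0, 0.5)
        model = HmmModel([sp, sp], np.array([[0.5, 0.5], [0.5, 0.5]]))
        states = viterbi_states(model, small_hmm_series[0])
        assert np.all(states == 0)

    def test_recovers_generating_states_when_separated(self, ref_hmm):
        hits = total = 0
        for seed in range(5):
            path, truth = simulate_path(ref_hmm, 200, seed=200 + seed)
            decoded = viterbi_states(ref_hmm, derive_steps(path, 0.0))
            hits += int(np.sum(decoded == truth))
            total += len(truth)
        assert hits / total > 0.8

    def test_matches_exhaustive_argmax(self, ref_hmm):
        rng = np.random.default_rng(30)
        for trial in range(3):
            model = _random_hmm(rng)
            series, _ = _series_from(ref_hmm, 8, seed=300 + trial)
            np.testing.assert_array_equal(
                viterbi_states(model, series),
                _brute_force_viterbi(model, series))


def test_simulated_gamma_moments_clt():
    """Sample mean/SD of simulated step lengths converge to (mu, sigma)."""
    m = RwModel(4.0, 3.0)
    s, _ = _series_from(m, 20_000, seed=40)
    n = s.lengths.size
    assert np.mean(s.lengths) == pytest.approx(4.0, abs=4 * 3.0 / math.sqrt(n))
    assert np.std(s.lengths) == pytest.approx(3.0, abs=0.15)


def test_transition_matrix_validation():
    sp = StateParams(1.0, 0.5)
    with pytest.raises(ValueError, match="sum to 1"):
        HmmModel([sp, sp], np.array([[0.9, 0.2], [0.2, 0.8]]))
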