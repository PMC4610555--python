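import itertools
import json

import numpy as np
import pytest

from gaitphase.hmm import (
    HmmParams,
    baum_welch,
    build_left_right_A,
    fixed_lag_viterbi,
    forward_backward,
    path_logjoint,
    sample,
    uniform_pi,
    viterbi,
)


def _toy_params(n=2, mu=None, sigma=1.0, dur=10.0):
    mu = np.asarray(mu if mu is not None else np.arange(n) * 10.0, dtype=float)
    return HmmParams(
        A=build_left_right_A(n, np.full(n, dur)),
        pi=uniform_pi(n),
        w=np.ones((n, 1)),
        mu=mu[:, None],
        sigma=np.full((n, 1), sigma),
    )


class TestConstruction:
    def test_single_state_matrix(self):
        np.testing.assert_array_equal(build_left_right_A(1, [5.0]), [[1.0]])

    def test_two_state_cyclic_from_durations(self):
        A = build_left_right_A(2, [10.0, 10.0])
        np.testing.assert_allclose(A, [[0.9, 0.1], [0.1, 0.9]])

    def test_rows_stochastic_and_structure(self):
        A = build_left_right_A(6, [3, 6, 10, 7, 5, 20])
        np.testing.assert_allclose(A.sum(axis=1), 1.0)
        allowed = np.zeros((6, 6), dtype=bool)
        for i in range(6):
            allowed[i, i] = allowed[i, (i + 1) % 6] = True
        assert np.all(A[~allowed] == 0.0)

    def test_non_cyclic_last_state_absorbs(self):
        A = build_left_right_A(3, [5, 5, 5], cyclic=False)
        assert A[2, 0] == 0.0 and A[2, 2] == 1.0

    def test_duration_below_one_sample_rejected(self):
        with pytest.raises(ValueError):
            build_left_right_A(2, [0.5, 10.0])

    def test_uniform_pi(self):
        np.testing.assert_allclose(uniform_pi(2), [0.5, 0.5])
        pi6 = uniform_pi(6)
        np.testing.assert_allclose(pi6, 1.0 / 6.0)
        assert pi6.sum() == pytest.approx(1.0)


class TestParamsValidation:
    def test_rejects_non_stochastic_rows(self):
        with pytest.raises(ValueError):
            HmmParams(A=[[0.5, 0.4], [0.1, 0.9]], pi=[0.5, 0.5],
                      w=np.ones((2, 1)), mu=np.zeros((2, 1)),
                      sigma=np.ones((2, 1)))

    def test_rejects_zero_sigma(self):
        with pytest.raises(ValueError):
            _toy_params(sigma=0.0)

    def test_json_round_trip(self, tmp_path):
        p = _toy_params(4, mu=[0, 5, 10, 15])
        path = tmp_path / "model.json"
        p.save(path, classifier="test", fs_hz=50.0)
        q, meta = HmmParams.load(path)
        np.testing.assert_allclose(q.A, p.A)
        np.testing.assert_allclose(q.mu, p.mu)
        assert meta["fs_hz"] == 50.0


class TestViterbi:
    def test_single_state(self):
        p = _toy_params(1, mu=[0.0])
        res = viterbi(p, np.random.default_rng(0).normal(size=20))
        assert np.all(res.states == 0)

    def test_matches_exhaustive_enumeration(self):
        p = HmmParams(
            A=[[0.7, 0.3], [0.4, 0.6]], pi=[0.6, 0.4],
            w=np.ones((2, 1)), mu=np.array([[0.0], [2.0]]),
            sigma=np.array([[1.0], [1.5]]),
        )
        rng = np.random.default_rng(42)
        obs = rng.normal(1.0, 1.5, size=8)
        best_path, best_ll = None, -np.inf
        for states in itertools.product((0, 1), repeat=8):
            ll = path_logjoint(p, obs, np.array(states))
            if ll > best_ll:
                best_ll, best_path = ll, states
        res = viterbi(p, obs)
        np.testing.assert_array_equal(res.states, best_path)
        assert path_logjoint(p, obs, res.states) == pytest.approx(best_ll)

    def test_recovers_noise_free_state_script(self):
        p = _toy_params(3, mu=[0.0, 100.0, 200.0], sigma=1.0, dur=10.0)
        script = np.repeat([0, 1, 2, 0, 1, 2], 10)
        obs = p.mu[script, 0]
        res = viterbi(p, obs)
        np.testing.assert_array_equal(res.states, script)

    def test_gamma_rows_sum_to_one(self):
        p = _toy_params(4, mu=[0, 5, 10, 15])
        res = viterbi(p, np.random.default_rng(1).normal(5, 5, size=100))
        np.testing.assert_allclose(res.gamma.sum(axis=1), 1.0, atol=1e-8)

    def test_extreme_observations_never_nan(self):
        p = _toy_params(2, mu=[0.0, 10.0], sigma=0.1)
        res = viterbi(p, np.array([1e6, -1e6, 0.0, 10.0]))
        assert np.all(np.isfinite(res.gamma))
        assert np.isfinite(res.loglik)

    def test_path_beats_random_paths(self):
        p = _toy_params(3, mu=[0, 10, 20], sigma=3.0)
        rng = np.random.default_rng(5)
        obs = rng.normal(10, 8, size=12)
        res = viterbi(p, obs)
        best = path_logjoint(p, obs, res.states)
        for _ in range(1000):
            rand = rng.integers(0, 3, size=12)
            assert path_logjoint(p, obs, rand) <= best + 1e-9

    def test_agrees_with_hmmlearn(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        p = _toy_params(3, mu=[0.0, 50.0, 100.0], sigma=8.0)
        rng = np.random.default_rng(3)
        _, obs = sample(p, 300, rng)
        ref = hmmlearn.GaussianHMM(n_components=3, covariance_type="diag",
                                   init_params="")
        ref.startprob_ = p.pi
        ref.transmat_ = p.A
        ref.means_ = p.mu
        ref.covars_ = p.sigma**2
        X = obs[:, None]
        res = viterbi(p, obs)
        np.testing.assert_array_equal(res.states, ref.predict(X))
        assert res.loglik == pytest.approx(ref.score(X), rel=1e-8)


class TestFixedLagViterbi:
    def test_lag_geq_length_equals_offline(self):
        p = _toy_params(3, mu=[0, 20, 40], sigma=5.0)
        _, obs = sample(p, 80, np.random.default_rng(2))
        off = viterbi(p, obs)
        on = fixed_lag_viterbi(p, obs, lag_samples=len(obs))
        np.testing.assert_array_equal(on.states, off.states)

    def test_small_lag_high_agreement_when_separated(self):
        p = _toy_params(4, mu=[0, 100, 200, 300], sigma=5.0, dur=20.0)
        _, obs = sample(p, 1000, np.random.default_rng(9))
        off = viterbi(p, obs)
        on = fixed_lag_viterbi(p, obs, lag_samples=5)
        agreement = np.mean(on.states == off.states)
        assert agreement >= 0.99

    def test_zero_lag_rejected(self):
        p = _toy_params(2)
        with pytest.raises(ValueError):
            fixed_lag_viterbi(p, np.zeros(10), 0)


class TestBaumWelch:
    def test_zero_iterations_returns_init(self):
        p = _toy_params(2)
        out, trace = baum_welch(p, [np.array([0.0, 1.0, 10.0, 9.0])],
                                max_iter=0)
        np.testing.assert_array_equal(out.A, p.A)
        np.testing.assert_array_equal(out.mu, p.mu)
        assert trace == []

    def test_loglik_nondecreasing(self):
        p = _toy_params(3, mu=[0, 8, 16], sigma=4.0)
        _, obs = sample(p, 400, np.random.default_rng(13))
        # deliberately perturbed start
        init = _toy_params(3, mu=[2, 6, 18], sigma=6.0)
        _, trace = baum_welch(init, [obs], max_iter=25)
        diffs = np.diff(trace)
        assert np.all(diffs >= -1e-8)

    def test_invariants_hold_after_training(self):
        p = _toy_params(4, mu=[0, 10, 20, 30], sigma=3.0)
        _, obs = sample(p, 500, np.random.default_rng(4))
        out, _ = baum_welch(p, [obs], max_iter=15)
        out.validate()
        # structural zeros preserved
        assert np.all(out.A[p.A == 0] == 0.0)

    def test_recovers_means_within_5pct(self):
        true = _toy_params(4, mu=[10.0, 110.0, 210.0, 310.0], sigma=12.0,
                           dur=15.0)
        _, obs = sample(true, 5000, np.random.default_rng(21))
        init = _toy_params(4, mu=[0.0, 90.0, 230.0, 290.0], sigma=25.0,
                           dur=15.0)
        out, _ = baum_welch(init, [obs], max_iter=60)
        # align states by nearest true mean
        order = np.argsort(out.mu[:, 0])
        est = out.mu[order, 0]
        np.testing.assert_allclose(est, true.mu[:, 0], rtol=0.05)

    def test_multiple_sequences_accepted(self):
        p = _toy_params(2, mu=[0, 30], sigma=5.0)
        rng = np.random.default_rng(8)
        seqs = [sample(p, 200, rng)[1] for _ in range(3)]
        out, trace = baum_welch(p, seqs, max_iter=5)
        assert len(trace) <= 5
        out.validate()

    def test_rejects_empty_and_nan(self):
        p = _toy_params(2)
        with pytest.raises(ValueError):
            baum_welch(p, [], max_iter=1)
        with pytest.raises(ValueError):
            baum_welch(p, [np.array([0.0, np.nan, 1.0])], max_iter=1)
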