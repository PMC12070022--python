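"""Covariate-transition HMM: likelihood, posteriors, EM, Viterbi, BIC."""

import numpy as np
import pytest

from socialhmm.hmm import (
    HMMParameters,
    ModelError,
    N_HOURS,
    ObservationSequence,
    bic,
    em_fit,
    emission_logprob,
    forward_backward,
    forward_loglik,
    hour_onehot,
    n_free_parameters,
    transition_probs,
    viterbi,
)
from socialhmm.simulate import simulate_sequences

from conftest import enum_best_path, enum_gamma, enum_loglik, random_instance


def simple_params(N=2, C=2, beta=None, pi=None, phi=None, covariate="hour_onehot24"):
    P = N_HOURS if covariate == "hour_onehot24" else 1
    b = np.zeros((N, N, P)) if beta is None else beta
    return HMMParameters(
        pi=np.full(N, 1.0 / N) if pi is None else np.asarray(pi, float),
        phi=np.full((N, C), 0.5) if phi is None else np.asarray(phi, float),
        beta=b,
        covariate=covariate,
    )


class TestTransitionProbs:
    def test_zero_beta_is_uniform(self):
        A = transition_probs(simple_params(), hour_onehot(7))
        assert np.allclose(A, 0.5)

    def test_softmax_arithmetic(self):
        beta = np.zeros((2, 2, N_HOURS))
        beta[0, 1, 7] = 1.0
        A = transition_probs(simple_params(beta=beta), hour_onehot(7))
        assert A[0] == pytest.approx([1 / (1 + np.e), np.e / (1 + np.e)], abs=1e-12)
        # other hours unaffected
        A6 = transition_probs(simple_params(beta=beta), hour_onehot(6))
        assert np.allclose(A6, 0.5)

    def test_rows_stochastic_for_random_beta(self, rng):
        for _ in range(10):
            params, _ = random_instance(rng)
            A = params.transition_matrices()
            assert np.allclose(A.sum(axis=2), 1.0, atol=1e-12)

    def test_malformed_onehot_rejected(self):
        with pytest.raises(ModelError):
            transition_probs(simple_params(), np.ones(N_HOURS))

    def test_zero_beta_constant_over_hours(self, rng):
        # homogeneous collapse: every hour shares one matrix
        params, _ = random_instance(rng, N=2)
        params.beta[:] = 0.0
        A = params.transition_matrices()
        assert np.allclose(A, A[0])


class TestEmissionLogprob:
    def test_all_missing_is_zero(self):
        p = simple_params(C=5)
        lp = emission_logprob(p, np.full(5, np.nan))
        assert np.allclose(lp, 0.0)

    def test_half_probabilities(self):
        p = simple_params(C=5, phi=np.full((2, 5), 0.5))
        lp = emission_logprob(p, np.array([1, 0, 1, 1, 0], float))
        assert np.allclose(lp, 5 * np.log(0.5))

    def test_direct_product(self):
        p = simple_params(C=2, phi=np.array([[0.9, 0.2], [0.5, 0.5]]))
        lp = emission_logprob(p, np.array([1.0, 0.0]))
        assert lp[0] == pytest.approx(np.log(0.9 * 0.8))

    def test_degenerate_phi_gives_minus_inf(self):
        p = simple_params(C=1, phi=np.array([[0.0], [1.0]]))
        lp = emission_logprob(p, np.array([1.0]))
        assert lp[0] == -np.inf and lp[1] == 0.0


class TestForward:
    def test_t1_closed_form(self, rng):
        params, seq = random_instance(rng, T=1, p_missing=0.0)
        expected = np.log(
            np.sum(params.pi * np.exp(emission_logprob(params, seq.x[0])))
        )
        assert forward_loglik(params, seq) == pytest.approx(expected, abs=1e-12)

    def test_all_missing_gives_zero(self, rng):
        params, seq = random_instance(rng, T=6)
        seq.x[:] = np.nan
        assert forward_loglik(params, seq) == pytest.approx(0.0, abs=1e-12)

    def test_matches_enumeration(self, rng):
        for _ in range(40):
            params, seq = random_instance(rng)
            assert forward_loglik(params, seq) == pytest.approx(
                enum_loglik(params, seq), abs=1e-10
            )

    def test_dimension_mismatch_errors(self, rng):
        params, seq = random_instance(rng, C=3)
        bad = ObservationSequence("b", seq.x[:, :2], seq.hour_of_day)
        with pytest.raises(ModelError):
            forward_loglik(params, bad)

    def test_masking_equals_marginalization(self, rng):
        # dropping one observation reproduces the enumerated marginal exactly
        for _ in range(10):
            params, seq = random_instance(rng, T=5, p_missing=0.0)
            seq.x[2, 1] = np.nan
            assert forward_loglik(params, seq) == pytest.approx(
                enum_loglik(params, seq), abs=1e-10
            )

    def test_hmmlearn_cross_check(self):
        # homogeneous model, complete data: map 5 Bernoulli channels onto a
        # 32-symbol categorical HMM and compare log-likelihoods
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(3)
        C = 5
        phi = rng.uniform(0.1, 0.9, (2, C))
        beta = np.zeros((2, 2, 1))
        beta[:, 1, 0] = rng.normal(0, 1, 2)
        params = simple_params(C=C, beta=beta, pi=[0.3, 0.7], phi=phi, covariate="none")
        x = rng.integers(0, 2, (200, C)).astype(float)
        seq = ObservationSequence("h", x, np.arange(200) % 24)
        codes = (x * (2 ** np.arange(C))).sum(axis=1).astype(int)
        emission = np.ones((2, 2**C))
        for s in range(2**C):
            bits = [(s >> c) & 1 for c in range(C)]
            for n in range(2):
                emission[n, s] = np.prod(
                    [phi[n, c] if b else 1 - phi[n, c] for c, b in enumerate(bits)]
                )
        m = hmmlearn.CategoricalHMM(n_components=2, init_params="")
        m.startprob_ = params.pi
        m.transmat_ = params.transition_matrices()[0]
        m.emissionprob_ = emission
        assert forward_loglik(params, seq) == pytest.approx(
            m.score(codes.reshape(-1, 1)), abs=1e-8
        )


class TestForwardBackward:
    def test_gamma_normalized_and_xi_consistent(self, rng):
        params, seq = random_instance(rng, T=8)
        gamma, xi = forward_backward(params, seq)
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(xi.sum(axis=2), gamma[:-1], atol=1e-9)
        assert np.allclose(xi.sum(axis=1), gamma[1:], atol=1e-9)

    def test_matches_enumeration(self, rng):
        for _ in range(20):
            params, seq = random_instance(rng, T=3)
            gamma, _ = forward_backward(params, seq)
            assert np.allclose(gamma, enum_gamma(params, seq), atol=1e-10)

    def test_uninformative_model_uniform_posterior(self):
        p = simple_params(N=3, C=2, phi=np.full((3, 2), 0.5),
                          pi=np.full(3, 1 / 3))
        seq = ObservationSequence("u", np.array([[1., 0.]] * 5), np.arange(5))
        gamma, _ = forward_backward(p, seq)
        assert np.allclose(gamma, 1 / 3, atol=1e-12)


class TestViterbi:
    def test_forced_self_transition(self):
        beta = np.zeros((2, 2, N_HOURS))
        beta[0, 1, :] = -20.0  # leaving state 1 is essentially impossible
        p = simple_params(beta=beta, pi=[1.0, 0.0])
        seq = ObservationSequence("v", np.full((30, 2), np.nan), np.arange(30) % 24)
        path = viterbi(p, seq)
        assert (path.states == 1).all()
        assert path.missing_mask.all()

    def test_attains_enumerated_maximum(self, rng):
        for _ in range(25):
            params, seq = random_instance(rng)
            path = viterbi(params, seq)
            _, best = enum_best_path(params, seq)
            got = _path_prob(params, seq, path.states - 1)
            assert got == pytest.approx(best, rel=1e-9)

    def test_symmetric_ties_break_to_state_one(self):
        p = simple_params(N=2, C=2)
        seq = ObservationSequence("t", np.array([[1.0, 0.0]] * 6), np.arange(6))
        assert (viterbi(p, seq).states == 1).all()

    def test_beats_random_paths(self, rng):
        params, seq = random_instance(rng, T=8)
        vit_p = _path_prob(params, seq, viterbi(params, seq).states - 1)
        N = params.n_states
        for _ in range(1000):
            rnd = rng.integers(0, N, seq.T)
            assert _path_prob(params, seq, rnd) <= vit_p * (1 + 1e-12)


def _path_prob(params, seq, states0):
    A = params.transition_matrices()
    hidx = seq.hour_of_day if params.covariate == "hour_onehot24" else np.zeros(seq.T, int)
    pr = params.pi[states0[0]] * np.exp(emission_logprob(params, seq.x[0])[states0[0]])
    for t in range(1, seq.T):
        pr *= A[hidx[t], states0[t - 1], states0[t]]
        pr *= np.exp(emission_logprob(params, seq.x[t])[states0[t]])
    return pr


class TestEMFit:
    def test_single_state_closed_form(self, rng):
        x = rng.integers(0, 2, (80, 3)).astype(float)
        x[rng.random((80, 3)) < 0.2] = np.nan
        seq = ObservationSequence("s", x, np.arange(80) % 24)
        fit = em_fit([seq], n_states=1, n_restarts=1, seed=0)
        means = np.nanmean(x, axis=0)
        assert np.allclose(fit.params.phi[0], means, atol=1e-10)
        obs = ~np.isnan(x)
        expected_ll = np.nansum(
            np.where(obs, x * np.log(means) + (1 - x) * np.log(1 - means), 0.0)
        )
        assert fit.loglik == pytest.approx(expected_ll, abs=1e-8)

    def test_loglik_nondecreasing(self, two_state_params):
        seqs, _ = simulate_sequences(two_state_params, 8, 150, seed=4)
        fit = em_fit(seqs, 2, n_restarts=3, seed=9, max_iter=100)
        assert (np.diff(fit.loglik_trace) >= -1e-8).all()

    def test_handles_missing_blocks(self, two_state_params):
        seqs, _ = simulate_sequences(two_state_params, 6, 200, seed=5)
        for s in seqs:
            s.x[40:80] = np.nan
        fit = em_fit(seqs, 2, n_restarts=2, seed=1, max_iter=60)
        assert np.isfinite(fit.loglik)
        assert fit.n_obs_used == 6 * 160

    def test_all_missing_errors(self):
        seq = ObservationSequence("m", np.full((10, 2), np.nan), np.arange(10))
        with pytest.raises(ModelError):
            em_fit([seq], 2)

    def test_invalid_state_count_errors(self):
        seq = ObservationSequence("m", np.zeros((10, 2)), np.arange(10))
        with pytest.raises(ModelError):
            em_fit([seq], 0)

    def test_label_permutation_symmetry(self, two_state_params):
        # starting EM from a model and from its state-swapped twin must give
        # the same likelihood
        seqs, _ = simulate_sequences(two_state_params, 5, 120, seed=6)
        p = two_state_params
        swapped_beta = p.beta[np.ix_([1, 0], [1, 0])]
        swapped_beta = swapped_beta - swapped_beta[:, 0:1, :]
        swapped = HMMParameters(
            pi=p.pi[[1, 0]], phi=p.phi[[1, 0]], beta=swapped_beta,
            covariate=p.covariate, channels=p.channels,
        )
        f1 = em_fit(seqs, 2, init_params=p, max_iter=40, order_channel=None)
        f2 = em_fit(seqs, 2, init_params=swapped, max_iter=40, order_channel=None)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)

    def test_canonical_state_order(self, two_state_params):
        seqs, _ = simulate_sequences(two_state_params, 10, 300, seed=7)
        fit = em_fit(seqs, 2, n_restarts=3, seed=2)
        # state 1 must be the low-phone-usage (inactive) state
        assert fit.params.phi[0, -1] < fit.params.phi[1, -1]


class TestModelSelection:
    @pytest.mark.parametrize(
        "N,C,P,expected", [(2, 5, 24, 59), (3, 5, 24, 161), (2, 5, 1, 13)]
    )
    def test_free_parameter_count(self, N, C, P, expected):
        params = HMMParameters(
            pi=np.full(N, 1 / N),
            phi=np.full((N, C), 0.5),
            beta=np.zeros((N, N, P)),
            covariate="hour_onehot24" if P == 24 else "none",
        )
        assert n_free_parameters(params) == expected

    def test_bic_arithmetic(self):
        params = HMMParameters(
            pi=np.full(2, 0.5), phi=np.full((2, 5), 0.5),
            beta=np.zeros((2, 2, 24)),
        )
        from socialhmm.hmm import FitResult

        fit = FitResult(params, -1000.0, np.array([-1000.0]), True, 1, 10000)
        assert bic(fit) == pytest.approx(2000 + 59 * np.log(10000))
        # larger k at identical fit -> larger BIC
        params3 = HMMParameters(
            pi=np.full(3, 1 / 3), phi=np.full((3, 5), 0.5),
            beta=np.zeros((3, 3, 24)),
        )
        fit3 = FitResult(params3, -1000.0, np.array([-1000.0]), True, 1, 10000)
        assert bic(fit3) > bic(fit)

    def test_two_state_data_prefers_two_states(self, two_state_params):
        seqs, _ = simulate_sequences(two_state_params, 30, 300, seed=8)
        f1 = em_fit(seqs, 1, n_restarts=1, seed=0)
        f2 = em_fit(seqs, 2, n_restarts=3, seed=0)
        assert f2.bic < f1.bic
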