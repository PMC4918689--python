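"""Product-HMM core: indexing, initialization, likelihood, EM, decoding."""

import itertools
import logging

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm

from phmmdfc import (VARIANCE_FLOOR, EmissionParams, ProductHMMModel,
                     baum_welch_fit, generate_observations, index_to_substates,
                     init_parameters, label_to_substates, log_likelihood,
                     log_likelihood_backward, state_bits, state_label,
                     substates_to_index, viterbi_decode)
from phmmdfc.experiments import transition_recovery
from phmmdfc.synthetic import make_phmm


# ---------------------------------------------------------------------------
# Joint-state indexing


class TestStateIndexing:
    @given(k=st.integers(1, 8))
    def test_index_substate_label_round_trip_all_states(self, k):
        names = [f"n{i}" for i in range(k)]
        for idx in range(2 ** k):
            sub = index_to_substates(idx, k)
            assert set(sub) <= {-1, 1}
            assert substates_to_index(sub) == idx
            assert substates_to_index(label_to_substates(
                state_label(idx, names))) == idx

    def test_channel_zero_is_most_significant_bit(self):
        # K=3: index 4 = bit pattern 100 -> channel 0 correlated only
        np.testing.assert_array_equal(index_to_substates(4, 3), [1, -1, -1])
        assert state_label(4, ["DMN", "LFPN", "RFPN"]) == "DMN-lfpn-rfpn"

    def test_bits_table_consistent_with_scalar_expansion(self):
        bits = state_bits(4)
        for idx in range(16):
            np.testing.assert_array_equal(2 * bits[idx] - 1,
                                          index_to_substates(idx, 4))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            index_to_substates(8, 3)
        with pytest.raises(ValueError):
            substates_to_index(np.array([1, 0, -1]))
        with pytest.raises(ValueError):
            label_to_substates("Dmn-lfpn")


# ---------------------------------------------------------------------------
# Initialization


class TestInitParameters:
    def test_study_scale_initialization_k6(self, rng):
        obs = rng.uniform(-1, 1, size=(6, 103))
        model = init_parameters(obs)
        assert model.n_states == 64
        np.testing.assert_allclose(model.startprob, 1.0 / 64)
        off = model.transmat[~np.eye(64, dtype=bool)]
        np.testing.assert_allclose(off, 1.0 / 65)
        np.testing.assert_allclose(np.diag(model.transmat), 2.0 / 65)
        np.testing.assert_allclose(model.transmat.sum(axis=1), 1.0, atol=1e-12)

    @given(k=st.integers(1, 7))
    def test_initial_transition_rows_sum_to_one_for_any_k(self, k):
        rng = np.random.default_rng(3)
        model = init_parameters(rng.uniform(-1, 1, size=(k, 50)))
        np.testing.assert_allclose(model.transmat.sum(axis=1), 1.0, atol=1e-12)
        assert abs(model.startprob.sum() - 1.0) < 1e-12

    def test_sign_split_moments_match_hand_computation(self):
        obs = np.array([[-0.4, -0.2, 0.1, 0.5]])
        model = init_parameters(obs)
        mu, sd = model.emissions.means[0], model.emissions.stds[0]
        assert mu[1] == pytest.approx(0.3)
        assert mu[0] == pytest.approx(-0.3)
        # ddof=1 sample stds of (0.1, 0.5) and (-0.4, -0.2)
        assert sd[1] == pytest.approx(np.sqrt((0.2 ** 2 + 0.2 ** 2) / 1))
        assert sd[0] == pytest.approx(np.sqrt((0.1 ** 2 + 0.1 ** 2) / 1))

    def test_missing_sign_falls_back_to_grand_moments(self, caplog):
        obs = np.array([[0.2, 0.4, 0.6, 0.8]])  # no negative samples
        with caplog.at_level(logging.WARNING):
            model = init_parameters(obs)
        assert "no negative samples" in caplog.text
        grand_mu, grand_sd = obs[0].mean(), obs[0].std(ddof=1)
        assert model.emissions.means[0, 0] == pytest.approx(grand_mu - grand_sd)
        assert model.emissions.stds[0, 0] == pytest.approx(grand_sd)

    def test_variance_floor_applied(self):
        obs = np.array([[0.5, 0.5 + 1e-9, -0.5, -0.5 - 1e-9]])
        model = init_parameters(obs)
        assert (model.emissions.stds >= VARIANCE_FLOOR).all()


# ---------------------------------------------------------------------------
# Likelihood


def brute_force_log_likelihood(model, obs):
    """Exhaustive sum over all joint-state paths (independent oracle)."""
    m, t = model.n_states, obs.shape[1]
    mu, sd = model.joint_means(), model.joint_stds()
    total = 0.0
    for path in itertools.product(range(m), repeat=t):
        p = model.startprob[path[0]]
        for a, b in zip(path[:-1], path[1:]):
            p *= model.transmat[a, b]
        for step, state in enumerate(path):
            p *= np.prod(norm.pdf(obs[:, step], loc=mu[state], scale=sd[state]))
        total += p
    return np.log(total)


class TestLogLikelihood:
    def test_single_step_closed_form(self, k2_model, rng):
        obs = rng.uniform(-1, 1, size=(2, 1))
        mu, sd = k2_model.joint_means(), k2_model.joint_stds()
        direct = np.log(sum(
            k2_model.startprob[i] * np.prod(norm.pdf(obs[:, 0], mu[i], sd[i]))
            for i in range(4)))
        assert log_likelihood(k2_model, obs) == pytest.approx(direct, abs=1e-10)

    def test_matches_exhaustive_path_enumeration(self, k2_model, rng):
        obs = rng.uniform(-1, 1, size=(2, 3))
        assert log_likelihood(k2_model, obs) == pytest.approx(
            brute_force_log_likelihood(k2_model, obs), abs=1e-8)

    def test_identical_emissions_marginalize_transitions(self, rng):
        # same Gaussian for both sub-states on each channel: paths marginalize
        em = EmissionParams(means=[[0.1, 0.1], [0.2, 0.2]],
                            stds=[[0.3, 0.3], [0.4, 0.4]])
        obs = rng.uniform(-1, 1, size=(2, 6))
        direct = norm.logpdf(obs[0], 0.1, 0.3).sum() + \
            norm.logpdf(obs[1], 0.2, 0.4).sum()
        for stay in (0.25, 0.9):
            model = make_phmm(2, 0.5, -0.5, 0.1, stay)
            model = ProductHMMModel(k=2, startprob=model.startprob,
                                    transmat=model.transmat, emissions=em)
            assert log_likelihood(model, obs) == pytest.approx(direct, abs=1e-8)

    def test_forward_and_backward_recursions_agree(self, k2_model, rng):
        obs = rng.uniform(-1, 1, size=(2, 40))
        fwd = log_likelihood(k2_model, obs)
        bwd = log_likelihood_backward(k2_model, obs)
        assert fwd == pytest.approx(bwd, abs=1e-8)

    def test_non_finite_observation_rejected(self, k2_model):
        obs = np.array([[0.1, np.nan], [0.2, 0.3]])
        with pytest.raises(ValueError, match="non-finite"):
            log_likelihood(k2_model, obs)

    def test_channel_count_mismatch_rejected(self, k2_model, rng):
        with pytest.raises(ValueError, match="channel count"):
            log_likelihood(k2_model, rng.uniform(-1, 1, size=(3, 5)))


@pytest.mark.parametrize("t_len", [5, 40])
def test_likelihood_and_viterbi_match_hmmlearn(k2_model, rng, t_len):
    """Independent cross-check: the product HMM equals a diagonal-covariance
    Gaussian HMM on the joint 2^K space."""
    hmmlearn = pytest.importorskip("hmmlearn.hmm")
    obs = rng.uniform(-1, 1, size=(2, t_len))
    ref = hmmlearn.GaussianHMM(n_components=4, covariance_type="diag",
                               init_params="")
    ref.startprob_ = k2_model.startprob
    ref.transmat_ = k2_model.transmat
    ref.means_ = k2_model.joint_means()
    ref.covars_ = k2_model.joint_stds() ** 2
    assert log_likelihood(k2_model, obs) == pytest.approx(
        ref.score(obs.T), abs=1e-8)
    ref_logprob, ref_path = ref.decode(obs.T)
    seq = viterbi_decode(k2_model, obs)
    np.testing.assert_array_equal(seq.joint, ref_path)
    assert seq.log_prob == pytest.approx(ref_logprob, abs=1e-8)


# ---------------------------------------------------------------------------
# Viterbi


class TestViterbi:
    def test_single_step_argmax(self, k2_model, rng):
        obs = rng.uniform(-1, 1, size=(2, 1))
        mu, sd = k2_model.joint_means(), k2_model.joint_stds()
        scores = [k2_model.startprob[i] *
                  np.prod(norm.pdf(obs[:, 0], mu[i], sd[i])) for i in range(4)]
        assert viterbi_decode(k2_model, obs).joint[0] == int(np.argmax(scores))

    def test_matches_exhaustive_enumeration(self, k2_model, rng):
        obs = rng.uniform(-1, 1, size=(2, 4))
        mu, sd = k2_model.joint_means(), k2_model.joint_stds()
        best, best_lp = None, -np.inf
        for path in itertools.product(range(4), repeat=4):
            lp = np.log(k2_model.startprob[path[0]])
            for a, b in zip(path[:-1], path[1:]):
                lp += np.log(k2_model.transmat[a, b])
            for step, state in enumerate(path):
                lp += norm.logpdf(obs[:, step], mu[state], sd[state]).sum()
            if lp > best_lp:
                best, best_lp = path, lp
        seq = viterbi_decode(k2_model, obs)
        np.testing.assert_array_equal(seq.joint, best)
        assert seq.log_prob == pytest.approx(best_lp, abs=1e-8)

    def test_path_log_prob_bounded_by_total_likelihood(self, k2_model, rng):
        obs = rng.uniform(-1, 1, size=(2, 30))
        assert viterbi_decode(k2_model, obs).log_prob <= \
            log_likelihood(k2_model, obs) + 1e-10

    def test_per_channel_expansion_matches_joint(self, k2_model, rng):
        obs = rng.uniform(-1, 1, size=(2, 10))
        seq = viterbi_decode(k2_model, obs)
        for t, idx in enumerate(seq.joint):
            np.testing.assert_array_equal(seq.per_channel[:, t],
                                          index_to_substates(int(idx), 2))


# ---------------------------------------------------------------------------
# Learning


class TestBaumWelch:
    def test_loglik_trace_nondecreasing_and_rows_stochastic(self, rng):
        obs = rng.uniform(-1, 1, size=(3, 80))
        res = baum_welch_fit(init_parameters(obs), obs, max_iter=40)
        diffs = np.diff(res.log_likelihoods)
        assert (diffs >= -1e-8).all()
        np.testing.assert_allclose(res.model.transmat.sum(axis=1), 1.0,
                                   atol=1e-10)
        assert res.model.startprob.sum() == pytest.approx(1.0, abs=1e-10)
        assert (res.model.transmat >= 0).all()

    def test_recovers_diagonal_dominant_transitions(self):
        assert transition_recovery(master_seed=2024) <= 0.05

    def test_nonconvergence_returns_flagged_best_model(self, rng):
        obs = rng.uniform(-1, 1, size=(2, 60))
        res = baum_welch_fit(init_parameters(obs), obs, max_iter=2, tol=1e-12)
        assert not res.converged
        assert isinstance(res.model, ProductHMMModel)

    def test_emissions_never_reestimated(self, rng):
        obs = rng.uniform(-1, 1, size=(2, 60))
        model0 = init_parameters(obs)
        res = baum_welch_fit(model0, obs, max_iter=20)
        np.testing.assert_array_equal(res.model.emissions.means,
                                      model0.emissions.means)
        np.testing.assert_array_equal(res.model.emissions.stds,
                                      model0.emissions.stds)


# ---------------------------------------------------------------------------
# Generation


class TestGenerateObservations:
    @pytest.mark.parametrize("t_gen", [150, 300])
    def test_generated_shapes(self, k2_model, t_gen):
        obs, seq = generate_observations(k2_model, t_gen, seed=5)
        assert obs.shape == (2, t_gen)
        assert len(seq) == t_gen

    def test_seeded_determinism(self, k2_model):
        a = generate_observations(k2_model, 80, seed=9)
        b = generate_observations(k2_model, 80, seed=9)
        c = generate_observations(k2_model, 80, seed=10)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1].joint, b[1].joint)
        assert not np.array_equal(a[0], c[0])

    def test_hidden_path_transition_frequencies_approach_transmat(self, k2_model):
        _, seq = generate_observations(k2_model, 50_000, seed=11)
        counts = np.zeros((4, 4))
        np.add.at(counts, (seq.joint[:-1], seq.joint[1:]), 1)
        freq = counts / counts.sum(axis=1, keepdims=True)
        assert np.max(np.abs(freq - k2_model.transmat)) < 0.02

    def test_decoding_recovers_well_separated_states(self):
        # emission separation 6 sigma, loopback 0.85
        from phmmdfc.experiments import decoding_accuracy

        assert decoding_accuracy(master_seed=77) >= 0.95
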