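"""Unit tests for motif models: PCM->PWM conversion, window scoring,
information content, TFFM posteriors and the detailed decomposition."""

import itertools
import warnings

import numpy as np
import pytest

from varbind.models import (
    BackgroundDistribution,
    ModelError,
    PositionCountMatrix,
    build_detailed_from_first_order,
    encode_sequence,
    information_content,
    pcm_to_pwm,
    sequence_likelihood,
    tffm_posterior_scores,
)
from varbind.synth import make_tffm

from oracles import brute_likelihood, brute_posterior


class TestPcmToPwm:
    def test_uniform_counts_uniform_bg_zero_weights(self, uniform_bg):
        pcm = PositionCountMatrix(np.full((4, 3), 25.0))
        pwm = pcm_to_pwm(pcm, uniform_bg, pseudocount_scale=0.0)
        assert np.allclose(pwm.weights, 0.0)
        assert pwm.min_score == pwm.max_score == 0.0

    def test_single_column_with_pseudocount(self, uniform_bg):
        pcm = PositionCountMatrix(np.array([[8.0], [0.0], [0.0], [0.0]]))
        pwm = pcm_to_pwm(pcm, uniform_bg, pseudocount_scale=1.0)
        assert pwm.weights[0, 0] == pytest.approx(np.log2((8.25 / 9) / 0.25))
        assert pwm.weights[1, 0] == pytest.approx(np.log2((0.25 / 9) / 0.25))

    def test_pseudocount_free_limit(self, uniform_bg):
        counts = np.array([[3.0, 1.0], [2.0, 1.0], [4.0, 1.0], [1.0, 7.0]])
        pcm = PositionCountMatrix(counts)
        pwm = pcm_to_pwm(pcm, uniform_bg, pseudocount_scale=0.0)
        expected = np.log2((counts / counts.sum(axis=0)) / 0.25)
        assert np.allclose(pwm.weights, expected)

    def test_default_pseudocount_is_sqrt_column_total(self, uniform_bg):
        counts = np.array([[9.0], [3.0], [2.0], [2.0]])  # N = 16, k = 4
        pwm = pcm_to_pwm(PositionCountMatrix(counts), uniform_bg)
        expected = np.log2(((counts + 4 * 0.25) / 20.0) / 0.25)
        assert np.allclose(pwm.weights, expected)

    def test_all_zero_column_is_degenerate(self, uniform_bg):
        counts = np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ModelError, match="degenerate motif column"):
            pcm_to_pwm(PositionCountMatrix(counts), uniform_bg, 1.0)

    def test_zero_background_rejected(self):
        with pytest.raises(ModelError):
            BackgroundDistribution(np.array([0.5, 0.5, 0.0, 0.0]))


class TestPwmWindowScore:
    def test_consensus_scores_one_anticonsensus_zero(self, toy_pwm):
        assert toy_pwm.window_score(toy_pwm.consensus()) == 1.0
        assert toy_pwm.window_score(toy_pwm.anti_consensus()) == 0.0

    def test_all_windows_in_unit_interval(self, toy_pwm):
        L = toy_pwm.length
        for win in itertools.product("ACGT", repeat=L):
            assert 0.0 <= toy_pwm.window_score("".join(win)) <= 1.0

    def test_wrong_length_rejected(self, toy_pwm):
        with pytest.raises(ModelError):
            toy_pwm.window_score("ACG")

    def test_constant_model_returns_half(self, uniform_bg):
        pcm = PositionCountMatrix(np.full((4, 2), 10.0))
        pwm = pcm_to_pwm(pcm, uniform_bg, pseudocount_scale=0.0)
        assert pwm.max_score == pwm.min_score
        assert pwm.window_score("AC") == 0.5

    def test_n_scores_background_expectation(self, toy_pwm):
        # with uniform background the N contribution is the column mean weight
        win = "N" + toy_pwm.consensus()[1:]
        raw = toy_pwm.weights[:, 0].mean() + sum(
            toy_pwm.weights.max(axis=0)[1:])
        expected = (raw - toy_pwm.min_score) / (toy_pwm.max_score - toy_pwm.min_score)
        assert toy_pwm.window_score(win) == pytest.approx(expected)

    def test_vectorized_scores_match_scalar(self, toy_pwm):
        seq = "ACGTACGTTTGACA"
        codes = encode_sequence(seq)
        starts = np.arange(len(seq) - toy_pwm.length + 1)
        batch = toy_pwm.window_scores(codes, starts)
        singles = [toy_pwm.window_score(seq[s:s + toy_pwm.length]) for s in starts]
        assert np.allclose(batch, singles)


class TestInformationContent:
    def test_extremes_and_mixture(self):
        counts = np.array([
            [5.0, 20.0, 3.0],
            [5.0, 0.0, 1.0],
            [5.0, 0.0, 0.0],
            [5.0, 0.0, 0.0],
        ])
        ic = information_content(PositionCountMatrix(counts), 0.0)
        assert ic[0] == pytest.approx(0.0)
        assert ic[1] == pytest.approx(2.0)
        assert ic[2] == pytest.approx(
            2 + 0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))

    def test_bounds_hold_for_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            counts = rng.gamma(1.0, 10.0, size=(4, 5))
            ic = information_content(PositionCountMatrix(counts), 0.5)
            assert np.all(ic >= 0.0) and np.all(ic <= 2.0)


class TestTffmPosteriors:
    @pytest.mark.parametrize("trial", range(12))
    def test_matches_brute_force_path_enumeration(self, trial):
        rng = np.random.default_rng(100 + trial)
        L = int(rng.integers(1, 4))
        p_self = float(rng.uniform(0.6, 0.95))
        m = make_tffm(int(rng.integers(2**31)), L,
                      float(rng.uniform(0, 1)),
                      self_transition=p_self,
                      motif_entry=float(rng.uniform(0.01, 1.0 - p_self)))
        seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(L, 9))))
        got = tffm_posterior_scores(m, seq)
        want = brute_posterior(m, seq)
        assert np.allclose(got, want, atol=1e-9)

    def test_zero_entry_means_zero_posteriors(self, toy_tffm):
        m = make_tffm(3, 2, 0.5, motif_entry=0.0)
        post = tffm_posterior_scores(m, "ACGTAC")
        assert np.all(post == 0.0)

    def test_all_n_sequence_stays_in_unit_interval(self, toy_tffm):
        post = tffm_posterior_scores(toy_tffm, "NNNNNN")
        assert post.size == 6
        assert np.all((post >= 0.0) & (post <= 1.0))

    def test_short_sequence_warns_and_returns_empty(self, toy_tffm):
        with pytest.warns(UserWarning, match="shorter than the motif"):
            post = tffm_posterior_scores(toy_tffm, "A")
        assert post.size == 0

    def test_posteriors_are_probabilities(self, toy_tffm):
        post = tffm_posterior_scores(toy_tffm, "CACACATTGGC")
        assert np.all((post >= 0.0) & (post <= 1.0))

    def test_window_score_equals_local_posterior(self, toy_tffm):
        seq = "ACGTACGTGGCATGCAT"
        codes = encode_sequence(seq)
        starts = np.arange(1, len(seq) - toy_tffm.length + 1)
        ws = toy_tffm.window_scores(codes, starts)
        for s, w in zip(starts, ws):
            local = seq[s - 1:s + toy_tffm.length]
            assert tffm_posterior_scores(toy_tffm, local)[-1] == pytest.approx(
                w, abs=1e-12)


class TestDetailedDecomposition:
    def test_single_position_model_all_trimers(self):
        m = make_tffm(42, 1, 0.8, self_transition=0.8, motif_entry=0.2)
        d = build_detailed_from_first_order(m)
        assert d.transition.shape == (8, 8)
        for trimer in itertools.product("ACGT", repeat=3):
            s = "".join(trimer)
            assert sequence_likelihood(d, s) == pytest.approx(
                sequence_likelihood(m, s), abs=1e-9)

    def test_uniform_model_gives_uniform_blocks(self):
        mc = np.full((2, 4, 4), 0.25)
        m = make_tffm(0, 2, 0.0)
        m.motif_conditional = mc
        m.background_conditional = np.full((4, 4), 0.25)
        d = build_detailed_from_first_order(m)
        assert np.allclose(d.transition[4:8, 8:12], 0.25)

    def test_likelihoods_preserved_on_random_sequences(self):
        rng = np.random.default_rng(11)
        m = make_tffm(5, 3, 0.6, self_transition=0.85, motif_entry=0.1)
        d = build_detailed_from_first_order(m)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(3, 7))))
            assert sequence_likelihood(d, seq) == pytest.approx(
                sequence_likelihood(m, seq), abs=1e-9)

    def test_first_order_likelihood_matches_path_enumeration(self):
        m = make_tffm(9, 2, 0.4, self_transition=0.9, motif_entry=0.1)
        for seq in ("ACGTA", "TTTT", "CACAG"):
            assert sequence_likelihood(m, seq) == pytest.approx(
                brute_likelihood(m, seq), abs=1e-12)

    def test_detailed_window_scores_match_source(self, toy_tffm):
        d = build_detailed_from_first_order(toy_tffm)
        seq = "GGCACATTCACAGG"
        codes = encode_sequence(seq)
        starts = np.arange(len(seq) - toy_tffm.length + 1)
        assert np.allclose(d.window_scores(codes, starts),
                           toy_tffm.window_scores(codes, starts), atol=1e-12)


class TestValidation:
    def test_nonstochastic_rows_rejected(self):
        with pytest.raises(ModelError):
            make_tffm(0, 2, 0.0).__class__(
                background_emission=np.full(4, 0.25),
                background_conditional=np.full((4, 4), 0.2),
                motif_conditional=np.full((2, 4, 4), 0.25),
                background_self_transition=0.9, motif_entry=0.05)

    def test_transition_budget_enforced(self):
        with pytest.raises(ModelError):
            make_tffm(0, 2, 0.0, self_transition=0.9, motif_entry=0.2)

    def test_negative_counts_rejected(self):
        with pytest.raises(ModelError):
            PositionCountMatrix(np.array([[1.0], [-1.0], [1.0], [1.0]]))
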