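"""Single-read CTC decoding against brute-force path enumeration."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pairdecode as pd
from pairdecode.decoding import ENUMERATION_GUARD_T
from conftest import make_profile
from oracles import (best_path, log_forward, modal_sequence,
                     sequence_mass_table)


class TestCollapse:
    @pytest.mark.parametrize("path,expected", [
        ([4, 4, 4], ""),
        ([0, 4, 0], "AA"),
        ([0, 0, 1, 1, 4, 1], "ACC"),
        ([2, 2, 2], "G"),
        ([], ""),
    ])
    def test_standard_collapse(self, path, expected):
        assert pd.collapse_path(path) == expected

    def test_drop_blanks_only_variant(self):
        assert pd.collapse_path([0, 0, 4, 1], merge_repeats=False) == "AAC"


class TestForwardProbability:
    def test_single_frame(self):
        p = pd.ProbabilityProfile("x", np.array([[0.6, 0.1, 0.1, 0.1, 0.1]]))
        assert math.exp(pd.forward_probability(p, "")) == pytest.approx(0.1)
        assert math.exp(pd.forward_probability(p, "A")) == pytest.approx(0.6)

    def test_two_uniform_frames_empty(self):
        p = pd.ProbabilityProfile("x", np.full((2, 5), 0.2))
        assert math.exp(pd.forward_probability(p, "")) == pytest.approx(0.04)

    def test_unreachable_sequence(self):
        p = pd.ProbabilityProfile("x", np.full((2, 5), 0.2))
        assert pd.forward_probability(p, "ACG") == -math.inf
        # repeat needs a separating blank: "AA" needs >= 3 frames
        assert pd.forward_probability(p, "AA") == -math.inf

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_path_enumeration(self, seed):
        p = make_profile(seed, 4)
        table = sequence_mass_table(p.probabilities)
        for seq, prob in table.items():
            got = pd.forward_probability(p, seq)
            assert got == pytest.approx(math.log(prob), abs=1e-9)

    @pytest.mark.parametrize("T", [4, 5, 6])
    def test_normalization(self, T):
        """Sum of P(seq) over all sequences of length <= T is exactly 1."""
        p = make_profile(100 + T, T)
        total = 0.0
        for L in range(T + 1):
            for combo in itertools.product("ACGT", repeat=L):
                total += math.exp(pd.forward_probability(p, "".join(combo)))
        assert total == pytest.approx(1.0, abs=1e-9)


class TestViterbi:
    def test_one_hot_path(self):
        p = pd.ProbabilityProfile("x", np.eye(5)[[0, 0, 4, 1]])
        res = pd.viterbi_decode(p)
        assert res.sequence.bases == "AC"
        assert res.log_prob == 0.0
        assert pd.collapse_path(res.path) == "AC"

    def test_tie_breaks_by_alphabet(self):
        p = pd.ProbabilityProfile("x", np.array([[0.3, 0.3, 0.2, 0.1, 0.1]]))
        assert pd.viterbi_decode(p).sequence.bases == "A"

    @pytest.mark.parametrize("seed", [5, 6])
    def test_matches_exhaustive_best_path(self, seed):
        p = make_profile(seed, 6)
        res = pd.viterbi_decode(p)
        oracle_lp, _ = best_path(p.probabilities)
        assert res.log_prob == pytest.approx(oracle_lp, abs=1e-9)

    def test_path_score_at_most_sequence_score(self):
        for seed in range(5):
            p = make_profile(200 + seed, 5)
            res = pd.viterbi_decode(p)
            assert res.log_prob <= pd.forward_probability(
                p, res.sequence.bases) + 1e-12


class TestBeamSearch:
    def test_one_hot_equals_viterbi(self):
        p = pd.ProbabilityProfile("x", np.eye(5)[[2, 4, 1, 1]])
        assert (pd.beam_search_decode(p, 4).sequence.bases
                == pd.viterbi_decode(p).sequence.bases)

    def test_rejects_bad_width(self):
        p = make_profile(0, 3)
        with pytest.raises(ValueError, match="beam_width"):
            pd.beam_search_decode(p, 0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_wide_beam_equals_exhaustive_argmax(self, seed):
        p = make_profile(300 + seed, 5)
        res = pd.beam_search_decode(p, 4096)
        assert res.sequence.bases == modal_sequence(p.probabilities)

    @pytest.mark.parametrize("seed", [7, 8, 9])
    def test_exhaustive_width_dominates_sweep(self, seed):
        """An exhaustive beam returns the global argmax, so its score bounds
        the score of every narrower beam's call.  (Scores of intermediate
        widths need not increase monotonically: pruned beam sets are not
        nested.)"""
        p = make_profile(seed, 5)
        scores = [pd.beam_search_decode(p, w).log_prob
                  for w in (1, 2, 4, 8, 16, 4096)]
        assert all(scores[-1] >= s - 1e-12 for s in scores)
        assert scores[-1] == pytest.approx(pd.enumerate_decode(p).log_prob,
                                           abs=1e-9)

    def test_reported_score_is_forward_probability(self):
        p = make_profile(42, 10)
        res = pd.beam_search_decode(p, 8)
        assert res.log_prob == pytest.approx(
            pd.forward_probability(p, res.sequence.bases), abs=1e-12)


class TestEnumerateDecode:
    def test_guard_refuses_large_T(self):
        p = make_profile(0, ENUMERATION_GUARD_T + 1)
        with pytest.raises(ValueError, match="guard"):
            pd.enumerate_decode(p)

    def test_hand_computed_two_frames(self):
        # P("A") = 0.4*0.6 + 0.6*0.4 + 0.4*0.4 = 0.64 > P("") = 0.36
        mat = np.array([[0.4, 0, 0, 0, 0.6], [0.4, 0, 0, 0, 0.6]])
        res = pd.enumerate_decode(pd.ProbabilityProfile("x", mat))
        assert res.sequence.bases == "A"
        assert math.exp(res.log_prob) == pytest.approx(0.64)

    def test_one_hot_agrees_with_other_decoders(self):
        p = pd.ProbabilityProfile("x", np.eye(5)[[3, 4, 0]])
        assert (pd.enumerate_decode(p).sequence.bases
                == pd.viterbi_decode(p).sequence.bases
                == pd.beam_search_decode(p, 16).sequence.bases == "TA")

    def test_beats_every_enumerated_competitor(self):
        p = make_profile(17, 4)
        res = pd.enumerate_decode(p)
        for seq, prob in sequence_mass_table(p.probabilities).items():
            assert res.log_prob >= math.log(prob) - 1e-9 if prob > 0 else True


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.integers(1, 6))
def test_forward_dominates_any_single_path(seed, T):
    """P(collapse(path)) >= product of the path's frame probabilities:
    the sequence mass sums over all paths, including that one."""
    rng = np.random.default_rng(seed)
    mat = rng.dirichlet(np.ones(5), size=T)
    p = pd.ProbabilityProfile("x", mat)
    path = rng.integers(0, 5, size=T)
    path_lp = float(np.log(mat[np.arange(T), path]).sum())
    seq = pd.collapse_path(path)
    assert pd.forward_probability(p, seq) >= path_lp - 1e-9
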