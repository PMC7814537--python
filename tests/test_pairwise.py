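"""Banded alignment, signal maps and envelope construction."""

import numpy as np
import pytest
from Bio import Align

import pairdecode as pd
from pairdecode.pairwise import build_envelope, envelope_area, path_to_signal_map


def unbanded_aligner(params: pd.AlignParams) -> Align.PairwiseAligner:
    """Biopython global aligner with the same linear-gap scoring scheme:
    the independent unbanded Needleman-Wunsch oracle."""
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = params.match
    al.mismatch_score = params.mismatch
    al.open_gap_score = params.gap
    al.extend_gap_score = params.gap
    return al


class TestBandedAlign:
    def test_identical_sequences(self):
        aln = pd.banded_global_align("ACGT", "ACGT")
        assert aln.score == 8.0 and aln.matches == 4
        assert aln.columns == [(0, 0), (1, 1), (2, 2), (3, 3)]

    def test_single_deletion(self):
        aln = pd.banded_global_align("ACGT", "AGT")
        assert aln.score == 4.0  # 3 matches * 2 - one gap * 2
        assert sum(1 for i, j in aln.columns if j is None) == 1

    def test_matches_unbanded_oracle(self):
        params = pd.AlignParams(band_half_width=50)
        oracle = unbanded_aligner(params)
        rng = np.random.default_rng(9)
        bases = np.array(list("ACGT"))
        for _ in range(100):
            a = "".join(bases[rng.integers(0, 4, rng.integers(20, 41))])
            b = "".join(bases[rng.integers(0, 4, rng.integers(20, 41))])
            aln = pd.banded_global_align(a, b, params)
            assert aln.score == pytest.approx(oracle.score(a, b))

    def test_narrow_band_raises_not_wrong(self):
        with pytest.raises(pd.BandInfeasibleError):
            pd.banded_global_align("AC", "ACGTACGTACGTACGT",
                                   pd.AlignParams(band_half_width=1))

    def test_empty_sequences(self):
        aln = pd.banded_global_align("", "ACG")
        assert aln.score == -6.0 and len(aln.columns) == 3
        assert pd.banded_global_align("", "").columns == []

    def test_rejects_degenerate_params(self):
        with pytest.raises(ValueError):
            pd.AlignParams(match=1, mismatch=1)
        with pytest.raises(ValueError):
            pd.AlignParams(gap=0.5)


class TestSignalMap:
    def test_trailing_blanks_attach_backward(self):
        m = path_to_signal_map([0, 4, 1, 4])
        assert m.intervals.tolist() == [[0, 2], [2, 4]]

    def test_leading_blanks_attach_forward(self):
        m = path_to_signal_map([4, 4, 0])
        assert m.intervals.tolist() == [[0, 3]]

    def test_all_blank_path_gives_empty_map(self):
        assert len(path_to_signal_map([4, 4, 4])) == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_intervals_tile_frames(self, seed):
        rng = np.random.default_rng(seed)
        path = rng.integers(0, 5, size=40)
        m = path_to_signal_map(path)
        if len(m):
            assert m.intervals[0, 0] == 0 and m.intervals[-1, 1] == 40
            assert np.array_equal(m.intervals[1:, 0], m.intervals[:-1, 1])
            n_bases = len(pd.collapse_path(path))
            assert len(m) == n_bases


def _identity_setup(T=12, n_bases=3):
    path = [0, 0, 4, 1, 1, 4, 2, 2, 4, 3, 3, 4][:T]
    m = path_to_signal_map(path)
    cols = [(i, i) for i in range(len(m))]
    guide = pd.GuideAlignment(cols, float(2 * len(cols)), len(cols))
    return m, guide


class TestEnvelope:
    def test_identity_guide_zero_padding_is_diagonal_rectangles(self):
        m, guide = _identity_setup()
        env = build_envelope(m, m, guide, padding=0)
        for (s, e) in m.intervals:
            for t1 in range(s, e):
                lo, hi = env.lo[t1], env.hi[t1]
                assert lo <= s and hi >= e

    def test_padding_dilates_monotonically(self):
        m, guide = _identity_setup()
        env0 = build_envelope(m, m, guide, padding=0)
        env5 = build_envelope(m, m, guide, padding=5)
        assert np.all(env5.lo <= env0.lo) and np.all(env5.hi >= env0.hi)

    def test_empty_guide_with_bases_is_error(self):
        m, _ = _identity_setup()
        with pytest.raises(ValueError, match="empty guide"):
            build_envelope(m, m, pd.GuideAlignment([], 0.0), padding=0)

    def test_invariants_enforced_by_constructor(self):
        with pytest.raises(ValueError):  # lo not below hi
            pd.AlignmentEnvelope(np.array([0, 2]), np.array([2, 2]), 2)
        with pytest.raises(ValueError):  # corner (0, 0) uncovered
            pd.AlignmentEnvelope(np.array([1, 1]), np.array([2, 2]), 2)

    def test_full_and_single_band_areas(self):
        full = pd.AlignmentEnvelope.full(7, 11)
        assert envelope_area(full) == 77
        band = pd.AlignmentEnvelope(np.arange(5), np.arange(1, 6), 5)
        assert envelope_area(band) == 5

    def test_transpose_is_involution_and_preserves_cells(self):
        env = pd.AlignmentEnvelope(np.array([0, 0, 2, 3]),
                                   np.array([2, 3, 5, 6]), 6)
        tr = env.transpose()
        back = tr.transpose()
        assert np.array_equal(back.lo, env.lo) and np.array_equal(back.hi, env.hi)
        for t1 in range(env.t1_size):
            for t2 in range(env.t2_size):
                assert env.contains(t1, t2) == tr.contains(t2, t1)

    def test_true_coalignment_covered_on_clean_simulation(self):
        """With clean (event-free) reads, the guide envelope at padding 10
        contains at least 99% of the known true co-alignment path."""
        for k in range(3):
            truth = pd.random_dna(120, 500 + k)
            kw = dict(seq_length=120, base_dropout_rate=0.0,
                      base_miscall_rate=0.0)
            r1, r2 = pd.simulate_pair(truth,
                                      pd.SimulationConfig(seed=700 + k, **kw),
                                      pd.SimulationConfig(seed=900 + k, **kw))
            v1 = pd.viterbi_decode(r1.profile)
            v2 = pd.viterbi_decode(r2.profile)
            guide = pd.banded_global_align(v1.sequence, v2.sequence)
            env = build_envelope(path_to_signal_map(v1.path),
                                 path_to_signal_map(v2.path), guide, padding=10)
            cells = pd.true_coalignment(r1, r2)
            frac = np.mean([env.contains(t1, t2) for t1, t2 in cells])
            assert frac >= 0.99

    def test_envelope_area_fraction_small_at_scale(self):
        """At ~9 frames/base and 2000+ frames, the envelope covers well
        under a quarter of the full DP matrix."""
        truth = pd.random_dna(230, 42)
        r1, r2 = pd.simulate_pair(truth,
                                  pd.SimulationConfig(seq_length=230, seed=1),
                                  pd.SimulationConfig(seq_length=230, seed=2))
        v1 = pd.viterbi_decode(r1.profile)
        v2 = pd.viterbi_decode(r2.profile)
        guide = pd.banded_global_align(v1.sequence, v2.sequence)
        env = build_envelope(path_to_signal_map(v1.path),
                             path_to_signal_map(v2.path), guide, padding=10)
        assert r1.profile.T >= 2000
        ratio = envelope_area(env) / (r1.profile.T * r2.profile.T)
        assert ratio < 0.25
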