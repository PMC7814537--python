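"""Pair consensus decoding: banded 2D beam search over two CTC profiles.

When two reads y1, y2 derive from the same molecule (a 1D2 template /
complement pair), the consensus sequence is the one maximizing
P(l|y1) * P(l|y2) -- under a flat prior over sequences and independence of
the reads, the modal sequence of the joint posterior.  The search couples
two CTC prefix recursions: each beam entry is a sequence prefix carrying
forward masses for *both* reads, and a prefix's score is the sum of its two
per-read log masses.

Frames of read 1 are consumed in order (t1 sweeps 0..T1-1); read-2 masses
are maintained as vectors over the alignment envelope's admissible frame
range at the current t1, so memory and time per step are bounded by
beam_width x the envelope's row width rather than T2.  Read-2 vectors grow
lazily through a parent-pointer chain as the envelope window slides upward;
with a full envelope the recursion is exact, which is what makes brute-force
oracle comparison possible at tiny frame counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._kernels import blank_run_scan, prefix_scan
from .decoding import (NEG_INF, DecodeResult, _lse2, beam_search_decode,
                       forward_probability, viterbi_decode)
from .pairwise import (AlignmentEnvelope, AlignParams, BandInfeasibleError,
                       DEFAULT_PADDING, banded_global_align, build_envelope,
                       path_to_signal_map)
from .profiles import BLANK, DnaSequence, ProbabilityProfile, reverse_complement_profile

_BASES = "ACGT"


class LowIdentityGuideError(RuntimeError):
    """The preliminary basecalls align too poorly to trust an envelope."""


@dataclass
class PairDecodeResult:
    """Consensus sequence with its combined and per-read log scores.

    ``log_prob_1`` / ``log_prob_2`` are the per-read prefix-forward masses of
    the returned sequence under the (possibly banded) recursion; with a full
    envelope they equal the exact per-read forward probabilities.
    """

    sequence: DnaSequence
    log_prob_combined: float
    log_prob_1: float
    log_prob_2: float

    def __post_init__(self) -> None:
        total = self.log_prob_1 + self.log_prob_2
        if (self.log_prob_combined != total
                and not abs(self.log_prob_combined - total) <= 1e-9):
            raise ValueError("combined log-probability must equal the sum of "
                             "the per-read components")
        if self.log_prob_1 > 1e-9 or self.log_prob_2 > 1e-9:
            raise ValueError("per-read log-probabilities must be <= 0")


class _PrefixNode:
    """Read-2 forward masses of one prefix over a growing frame window.

    ``b``/``nb`` cover frames ``[lo, hi)``.  The root node is the empty
    prefix (pure blank mass).  Growth recurses through ``parent`` because
    the forward update at frame t2 needs the parent prefix's masses at
    t2 - 1; parents are therefore always at least as grown as children.
    """

    __slots__ = ("parent", "char", "is_repeat", "lo", "hi", "b", "nb")

    def __init__(self, parent, char: int, is_repeat: bool, lo: int):
        self.parent = parent
        self.char = char
        self.is_repeat = is_repeat
        self.lo = lo
        self.hi = lo
        self.b = np.empty(0)
        self.nb = np.empty(0)

    def mass_at(self, t2: int) -> float:
        """Total (blank + non-blank) log mass after consuming frames 0..t2."""
        if t2 < self.lo or t2 >= self.hi:
            return NEG_INF
        k = t2 - self.lo
        return _lse2(float(self.b[k]), float(self.nb[k]))


_EMPTY = np.empty(0)


def _grow(node: _PrefixNode, new_hi: int, lp2_cols) -> None:
    """Extend ``node``'s window up to frame ``new_hi`` (exclusive)."""
    chain = []
    cur = node
    while cur is not None and cur.hi < new_hi:
        chain.append(cur)
        cur = cur.parent
    for nd in reversed(chain):
        start, stop = nd.hi, new_hi
        if nd.parent is None:  # root: empty prefix
            b_prev = float(nd.b[-1]) if nd.b.size else 0.0
            seg = blank_run_scan(lp2_cols[BLANK], start, stop, b_prev)
            nd.b = np.concatenate([nd.b, seg])
            nd.nb = np.concatenate([nd.nb, np.full(stop - start, NEG_INF)])
        else:
            par = nd.parent
            if nd.b.size:
                ob, onb = float(nd.b[-1]), float(nd.nb[-1])
            else:
                ob = onb = NEG_INF
            seg_b, seg_nb = prefix_scan(
                lp2_cols[nd.char], lp2_cols[BLANK],
                par.b if par.b.size else _EMPTY,
                par.nb if par.nb.size else _EMPTY,
                par.lo, par.parent is None, nd.is_repeat,
                start, stop, ob, onb)
            nd.b = np.concatenate([nd.b, seg_b])
            nd.nb = np.concatenate([nd.nb, seg_nb])
        nd.hi = new_hi


def pair_beam_search(p1: ProbabilityProfile, p2: ProbabilityProfile,
                     env: AlignmentEnvelope,
                     beam_width: int = 25) -> PairDecodeResult:
    """Find the consensus sequence of two profiles by banded 2D beam search.

    Returns the complete prefix maximizing
    ``log P(l|y1) + log P(l|y2)`` among the surviving beams.  Deterministic:
    ties break by score, then shorter sequence, then lexicographic order.
    With a full envelope and a beam wide enough to hold every distinct
    prefix, the result is the exact joint argmax.
    """
    if beam_width < 1:
        raise ValueError(f"beam_width must be >= 1, got {beam_width}")
    T1, T2 = p1.T, p2.T
    if env.t1_size != T1 or env.t2_size != T2:
        raise ValueError(
            f"envelope shape ({env.t1_size}, {env.t2_size}) does not match "
            f"profiles ({T1}, {T2})")
    lp1 = p1.log_probabilities
    lp2 = p2.log_probabilities
    lp2_cols = [np.ascontiguousarray(lp2[:, c]) for c in range(5)]
    # running best-path mass of read 2: a prefix-independent baseline that
    # makes masses at different t2 comparable when pruning over a window
    baseline2 = np.cumsum(lp2.max(axis=1))

    root = _PrefixNode(None, -1, False, 0)
    # prefix -> [blank mass, non-blank mass (read 1), read-2 node]
    beams: dict[str, list] = {"": [0.0, NEG_INF, root]}

    for t1 in range(T1):
        hi = int(env.hi[t1])
        lo = int(env.lo[t1])
        lpt = lp1[t1]
        lp_blank = float(lpt[BLANK])
        candidates: dict[str, list] = {}
        for prefix, (b1, nb1, node) in beams.items():
            tot = _lse2(b1, nb1)
            ent = candidates.get(prefix)
            if ent is None:
                ent = candidates[prefix] = [NEG_INF, NEG_INF, node]
            else:
                ent[2] = node  # the established node wins over a fresh child
            ent[0] = _lse2(ent[0], lp_blank + tot)
            if prefix:
                last = _BASES.index(prefix[-1])
                ent[1] = _lse2(ent[1], float(lpt[last]) + nb1)
            else:
                last = -1
            for c in range(4):
                contrib = float(lpt[c]) + (b1 if c == last else tot)
                if contrib == NEG_INF:
                    continue
                child = prefix + _BASES[c]
                ent2 = candidates.get(child)
                if ent2 is None:
                    candidates[child] = [
                        NEG_INF, contrib,
                        _PrefixNode(node, c, c == last, lo)]
                else:
                    ent2[1] = _lse2(ent2[1], contrib)
        scored = []
        for prefix, ent in candidates.items():
            node = ent[2]
            _grow(node, hi, lp2_cols)
            # pruning score: read-1 mass at t1 plus the best
            # baseline-normalized read-2 mass in the admissible window (the
            # two reads need not have consumed the same number of frames
            # mid-sweep, so raw masses at different t2 are not comparable)
            k0 = lo - node.lo
            seg = np.logaddexp(node.b[k0:hi - node.lo],
                               node.nb[k0:hi - node.lo])
            best2 = float((seg - baseline2[lo:hi]).max()) if seg.size else NEG_INF
            score = _lse2(ent[0], ent[1]) + best2
            scored.append((score, prefix, ent))
        scored.sort(key=lambda item: (-item[0], len(item[1]), item[1]))
        beams = {prefix: ent for _, prefix, ent in scored[:beam_width]}

    best_score, best_prefix, best_ent = NEG_INF, "", None
    for prefix, (b1, nb1, node) in beams.items():
        lp_1 = _lse2(b1, nb1)
        lp_2 = node.mass_at(T2 - 1)
        score = lp_1 + lp_2
        if (best_ent is None
                or score > best_score
                or (score == best_score
                    and (len(prefix), prefix) < (len(best_prefix), best_prefix))):
            best_score, best_prefix = score, prefix
            best_ent = (lp_1, lp_2)
    seq = DnaSequence(f"{p1.read_id}+{p2.read_id}", best_prefix)
    return PairDecodeResult(seq, best_ent[0] + best_ent[1],
                            best_ent[0], best_ent[1])


def pair_decode_pipeline(p1: ProbabilityProfile, p2: ProbabilityProfile,
                         params: AlignParams | None = None,
                         padding: int = DEFAULT_PADDING,
                         beam_width: int = 25,
                         complement_strand_2: bool = False,
                         guide_identity_floor: float = 0.3,
                         full_envelope_cell_limit: int = 4_000_000
                         ) -> PairDecodeResult:
    """Full consensus pipeline: Viterbi basecalls -> guide alignment ->
    envelope -> banded 2D beam search.

    With ``complement_strand_2`` the second profile is reverse-complemented
    first, so a 1D2 complement-strand read is decoded on the template
    strand's coordinates.  A guide alignment with identity below
    ``guide_identity_floor`` (likely not a true pair) falls back to the full
    envelope when the T1 x T2 matrix is small enough
    (``full_envelope_cell_limit`` cells), and raises otherwise.
    """
    if params is None:
        params = AlignParams()
    if complement_strand_2:
        p2 = reverse_complement_profile(p2)
    v1 = viterbi_decode(p1)
    v2 = viterbi_decode(p2)
    if len(v1.sequence) == 0 or len(v2.sequence) == 0:
        # a read whose preliminary basecall is empty carries no sequence
        # evidence; the consensus degenerates to the other read's own call
        return _degenerate_single(p1, p2, v1, v2, beam_width)
    env = _envelope_from_basecalls(p1, p2, v1, v2, params, padding,
                                   guide_identity_floor, full_envelope_cell_limit)
    return pair_beam_search(p1, p2, env, beam_width)


def _degenerate_single(p1, p2, v1: DecodeResult, v2: DecodeResult,
                       beam_width: int) -> PairDecodeResult:
    informative = p1 if len(v1.sequence) > 0 else p2
    warnings.warn(
        "one read's preliminary basecall is empty; returning the other "
        "read's single-read call as the consensus", RuntimeWarning,
        stacklevel=3)
    single = beam_search_decode(informative, beam_width)
    seq = DnaSequence(f"{p1.read_id}+{p2.read_id}", single.sequence.bases)
    lp1 = forward_probability(p1, seq.bases)
    lp2 = forward_probability(p2, seq.bases)
    return PairDecodeResult(seq, lp1 + lp2, lp1, lp2)


def _envelope_from_basecalls(p1, p2, v1: DecodeResult, v2: DecodeResult,
                             params: AlignParams, padding: int,
                             identity_floor: float,
                             cell_limit: int) -> AlignmentEnvelope:
    map1 = path_to_signal_map(v1.path)
    map2 = path_to_signal_map(v2.path)
    if len(map1) == 0 or len(map2) == 0:
        # an all-blank preliminary basecall carries no anchor information
        return AlignmentEnvelope.full(p1.T, p2.T)
    try:
        guide = banded_global_align(v1.sequence, v2.sequence, params)
    except BandInfeasibleError:
        wide = AlignParams(params.match, params.mismatch, params.gap,
                           max(len(v1.sequence), len(v2.sequence)))
        guide = banded_global_align(v1.sequence, v2.sequence, wide)
    if guide.identity < identity_floor:
        if p1.T * p2.T <= cell_limit:
            warnings.warn(
                f"guide alignment identity {guide.identity:.3f} below "
                f"{identity_floor}; falling back to the full envelope",
                RuntimeWarning, stacklevel=2)
            return AlignmentEnvelope.full(p1.T, p2.T)
        raise LowIdentityGuideError(
            f"guide alignment identity {guide.identity:.3f} is below "
            f"{identity_floor} and the {p1.T} x {p2.T} full matrix exceeds "
            f"the fallback limit; the reads are unlikely to be a true pair")
    return build_envelope(map1, map2, guide, padding)
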