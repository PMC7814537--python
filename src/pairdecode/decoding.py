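"""Single-read CTC decoding: collapse, forward probability, Viterbi, beam search.

A CTC profile defines a distribution P(l | y) over basecalled sequences l:
the probability of l is the sum, over every frame-by-frame label path that
*collapses* to l, of the product of per-frame symbol probabilities.  Collapse
is the standard CTC rule: merge runs of identical non-blank labels, then drop
blanks (so a repeat base requires an intervening blank frame).

Finding the modal sequence of P(l | y) exactly requires enumerating all
sequences, which is intractable beyond toy sizes; ``enumerate_decode`` does
it anyway for tiny frame counts (the testing oracle), while ``viterbi_decode``
(best single path) and ``beam_search_decode`` (prefix beam search) are the
practical decoders.

All arithmetic is in natural-log space with ``-inf`` for log(0).

Tie-breaking is deterministic everywhere: alphabet order A < C < G < T <
blank, then shorter sequence first, then lexicographic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .profiles import ALPHABET, BLANK, DnaSequence, ProbabilityProfile, encode_bases

NEG_INF = -math.inf

_BASES = "ACGT"


def _lse2(a: float, b: float) -> float:
    """log(exp(a) + exp(b)) for scalars, tolerant of -inf."""
    if a == NEG_INF:
        return b
    if b == NEG_INF:
        return a
    if a < b:
        a, b = b, a
    return a + math.log1p(math.exp(b - a))


@dataclass
class DecodeResult:
    """A decoded sequence with its log-probability score.

    ``path`` is the winning frame-by-frame label path for Viterbi decoding
    and ``None`` for the other decoders (which score whole sequences, not
    paths).
    """

    sequence: DnaSequence
    log_prob: float
    path: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.log_prob > 1e-9:
            raise ValueError(f"log_prob must be <= 0, got {self.log_prob}")
        if self.path is not None:
            collapsed = collapse_path(self.path)
            if collapsed != self.sequence.bases:
                raise ValueError(
                    f"path collapses to {collapsed!r}, not {self.sequence.bases!r}")


def collapse_path(path, merge_repeats: bool = True) -> str:
    """Collapse a label path to its DNA string.

    Standard CTC collapse merges consecutive identical non-blank labels and
    removes blanks; with ``merge_repeats=False`` only blanks are removed
    (the non-default variant used by some models).
    """
    out = []
    prev = BLANK
    for lab in path:
        lab = int(lab)
        if lab != BLANK and (not merge_repeats or lab != prev):
            out.append(ALPHABET[lab])
        prev = lab
    return "".join(out)


def forward_probability(p: ProbabilityProfile, seq) -> float:
    """Exact log P(seq | profile): sum over all label paths collapsing to seq.

    Standard CTC forward recursion over the blank-interleaved expanded label
    sequence.  Returns ``-inf`` when no path can produce ``seq`` (e.g. the
    expanded sequence is longer than the number of frames allows).
    """
    bases = seq.bases if isinstance(seq, DnaSequence) else seq
    idx = encode_bases(bases)
    lp = p.log_probabilities
    T, L = p.T, len(idx)
    if L == 0:
        return float(lp[:, BLANK].sum())
    S = 2 * L + 1
    ext = np.full(S, BLANK, dtype=np.int64)
    ext[1::2] = idx
    # the skip transition (s-2 -> s) is legal only into a base differing
    # from the previous base (otherwise a blank is mandatory)
    can_skip = np.zeros(S, dtype=bool)
    can_skip[3::2] = idx[1:] != idx[:-1]

    alpha = np.full(S, NEG_INF)
    alpha[0] = lp[0, BLANK]
    alpha[1] = lp[0, idx[0]]
    prev1 = np.empty(S)
    prev2 = np.empty(S)
    with np.errstate(invalid="ignore"):
        for t in range(1, T):
            prev1[0] = NEG_INF
            prev1[1:] = alpha[:-1]
            prev2[:2] = NEG_INF
            prev2[2:] = alpha[:-2]
            prev2[~can_skip] = NEG_INF
            alpha = np.logaddexp(np.logaddexp(alpha, prev1), prev2) + lp[t, ext]
    return float(np.logaddexp(alpha[-1], alpha[-2]))


def viterbi_decode(p: ProbabilityProfile) -> DecodeResult:
    """Best single label path, collapsed.

    Frames are independent given the profile (no transition model), so the
    best path is the per-frame argmax; ties go to the lower symbol index,
    i.e. alphabet order A < C < G < T < blank.
    """
    labels = np.argmax(p.probabilities, axis=1)
    log_prob = float(p.log_probabilities[np.arange(p.T), labels].sum())
    seq = collapse_path(labels)
    return DecodeResult(DnaSequence(p.read_id, seq), log_prob, labels)


def _prefix_beam_step(beams: dict, lpt: np.ndarray, beam_width: int) -> dict:
    """One frame of CTC prefix beam search over (blank, non-blank) masses."""
    candidates: dict[str, list[float]] = {}
    lp_blank = float(lpt[BLANK])
    for prefix, (b, nb) in beams.items():
        tot = _lse2(b, nb)
        ent = candidates.get(prefix)
        if ent is None:
            ent = candidates[prefix] = [NEG_INF, NEG_INF]
        # stay: emit blank, or re-emit the final base (extends its run)
        ent[0] = _lse2(ent[0], lp_blank + tot)
        if prefix:
            last = _BASES.index(prefix[-1])
            ent[1] = _lse2(ent[1], float(lpt[last]) + nb)
        else:
            last = -1
        # extend by each base
        for c in range(4):
            contrib = float(lpt[c]) + (b if c == last else tot)
            if contrib == NEG_INF:
                continue
            child = prefix + _BASES[c]
            ent2 = candidates.get(child)
            if ent2 is None:
                candidates[child] = [NEG_INF, contrib]
            else:
                ent2[1] = _lse2(ent2[1], contrib)
    if len(candidates) <= beam_width:
        return candidates
    ranked = sorted(candidates.items(),
                    key=lambda kv: (-_lse2(kv[1][0], kv[1][1]), len(kv[0]), kv[0]))
    return dict(ranked[:beam_width])


def beam_search_decode(p: ProbabilityProfile, beam_width: int = 25) -> DecodeResult:
    """CTC prefix beam search.

    Each beam entry is a sequence prefix carrying separate blank-ending and
    non-blank-ending forward masses, updated frame by frame; the top
    ``beam_width`` prefixes by total mass survive each frame.  The reported
    log-probability is the exact forward probability of the returned
    sequence.  Deterministic: ties break shorter-first then lexicographic.
    """
    if beam_width < 1:
        raise ValueError(f"beam_width must be >= 1, got {beam_width}")
    lp = p.log_probabilities
    beams: dict[str, list[float]] = {"": [0.0, NEG_INF]}
    for t in range(p.T):
        beams = _prefix_beam_step(beams, lp[t], beam_width)
    best = min(beams.items(),
               key=lambda kv: (-_lse2(kv[1][0], kv[1][1]), len(kv[0]), kv[0]))
    seq = best[0]
    return DecodeResult(DnaSequence(p.read_id, seq), forward_probability(p, seq))


ENUMERATION_GUARD_T = 8
"""``enumerate_decode`` refuses profiles with more frames than this: the
search space grows as 4^T."""


def enumerate_decode(p: ProbabilityProfile, max_len: int | None = None) -> DecodeResult:
    """Exact modal sequence by exhaustive search (testing oracle).

    Evaluates ``forward_probability`` for every sequence of length up to
    ``min(max_len, T)`` and returns the argmax.  Intractable in general,
    hence guarded to ``T <= 8`` frames.
    """
    if p.T > ENUMERATION_GUARD_T:
        raise ValueError(
            f"enumerate_decode guard: T={p.T} exceeds the {ENUMERATION_GUARD_T}-frame "
            f"enumeration limit")
    limit = p.T if max_len is None else min(max_len, p.T)
    best_seq, best_score = "", forward_probability(p, "")
    for length in range(1, limit + 1):
        for combo in itertools.product(_BASES, repeat=length):
            seq = "".join(combo)
            score = forward_probability(p, seq)
            if score > best_score:  # ascending length + lexicographic order
                best_seq, best_score = seq, score
    return DecodeResult(DnaSequence(p.read_id, best_seq), best_score)
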