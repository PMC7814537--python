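"""Independent brute-force oracles used by the test suite.

Everything here works directly on raw T x 5 probability matrices by
enumerating label paths, sharing no code with the package's recursions.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

_SYMBOLS = "ACGT-"
_BLANK = 4


def collapse(path) -> str:
    """Reference CTC collapse: merge runs of identical non-blank labels,
    drop blanks."""
    out = []
    prev = _BLANK
    for lab in path:
        if lab != _BLANK and lab != prev:
            out.append(_SYMBOLS[lab])
        prev = lab
    return "".join(out)


def sequence_mass_table(mat: np.ndarray) -> dict[str, float]:
    """P(sequence) for every sequence, by enumerating all 5^T label paths."""
    T = mat.shape[0]
    table: dict[str, float] = {}
    for path in itertools.product(range(5), repeat=T):
        prob = 1.0
        for t, lab in enumerate(path):
            prob *= mat[t, lab]
        seq = collapse(path)
        table[seq] = table.get(seq, 0.0) + prob
    return table


def log_forward(mat: np.ndarray, seq: str) -> float:
    """log P(seq) by path enumeration (-inf when unreachable)."""
    prob = sequence_mass_table(mat).get(seq, 0.0)
    return math.log(prob) if prob > 0 else -math.inf


def best_path(mat: np.ndarray) -> tuple[float, tuple]:
    """The single most probable label path (max product) and its log-prob."""
    best = (-math.inf, ())
    T = mat.shape[0]
    for path in itertools.product(range(5), repeat=T):
        lp = 0.0
        for t, lab in enumerate(path):
            p = mat[t, lab]
            lp += math.log(p) if p > 0 else -math.inf
        if lp > best[0]:
            best = (lp, path)
    return best


def _argmax_with_ties(table: dict[str, float]) -> str:
    """Highest mass; ties broken shorter-first then lexicographic."""
    return min(table, key=lambda s: (-table[s], len(s), s))


def modal_sequence(mat: np.ndarray) -> str:
    """Exact argmax of P(sequence) by path enumeration."""
    return _argmax_with_ties(sequence_mass_table(mat))


def modal_pair_sequence(mat1: np.ndarray, mat2: np.ndarray) -> tuple[str, float]:
    """Exact argmax of P(seq | read1) * P(seq | read2) and its log score."""
    t1 = sequence_mass_table(mat1)
    t2 = sequence_mass_table(mat2)
    joint = {s: t1[s] * t2[s] for s in t1.keys() & t2.keys()
             if t1[s] > 0 and t2[s] > 0}
    s = _argmax_with_ties(joint)
    return s, math.log(joint[s])


def random_profile_matrix(rng: np.random.Generator, T: int) -> np.ndarray:
    """A random row-stochastic T x 5 matrix."""
    return rng.dirichlet(np.ones(5), size=T)
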