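"""Banded global alignment, sequence-to-signal maps, and alignment envelopes.

Nanopore reads vary in length over orders of magnitude, so a naive global
alignment matrix can be infeasibly large; the aligner here is a
Needleman-Wunsch restricted to a fixed-width band around the length-rescaled
diagonal (cell (i, j) is admissible iff ``|j - i*|b|/|a|| <= band_half_width``).

A Viterbi label path explicitly maps each decoded base to a frame interval
(`path_to_signal_map`).  Aligning the two Viterbi basecalls gives a
nucleotide-level correspondence between the reads, and through the two
signal maps a correspondence between their frames; padded and made monotone,
that correspondence is the *alignment envelope* that bands the 2D pair
beam search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .profiles import BLANK, DnaSequence, encode_bases


class BandInfeasibleError(ValueError):
    """The diagonal band cannot connect the DP origin to the terminus."""


@dataclass
class AlignParams:
    """Scoring and banding parameters for global alignment (linear gaps)."""

    match: float = 2.0
    mismatch: float = -1.0
    gap: float = -2.0
    band_half_width: int = 100

    def __post_init__(self) -> None:
        if not self.match > self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if not self.gap < 0:
            raise ValueError("gap score must be negative")
        if self.band_half_width < 1:
            raise ValueError("band_half_width must be a positive integer")


@dataclass
class GuideAlignment:
    """A global alignment of two sequences: ordered columns of index pairs.

    Each column is ``(i, j)``, ``(i, None)`` (gap in b) or ``(None, j)``
    (gap in a); indices are strictly increasing.
    """

    columns: list
    score: float
    matches: int = 0

    def __post_init__(self) -> None:
        prev_i = prev_j = -1
        for i, j in self.columns:
            if i is None and j is None:
                raise ValueError("alignment column cannot be (gap, gap)")
            if i is not None:
                if i <= prev_i:
                    raise ValueError("alignment i-indices must strictly increase")
                prev_i = i
            if j is not None:
                if j <= prev_j:
                    raise ValueError("alignment j-indices must strictly increase")
                prev_j = j

    @property
    def identity(self) -> float:
        """Match columns divided by total alignment columns (0 if empty)."""
        return self.matches / len(self.columns) if self.columns else 0.0


def _band_limits(m: int, n: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    i = np.arange(m + 1)
    center = i * (n / m) if m > 0 else np.zeros(m + 1)
    jlo = np.maximum(0, np.ceil(center - w)).astype(np.int64)
    jhi = np.minimum(n, np.floor(center + w)).astype(np.int64)
    return jlo, jhi


def banded_global_align(a, b, params: AlignParams | None = None) -> GuideAlignment:
    """Optimal global alignment restricted to a fixed diagonal band.

    The band follows the length-rescaled diagonal so unequal-length sequences
    stay alignable; whenever the unbanded optimum lies inside the band the
    result equals full Needleman-Wunsch.  Raises ``BandInfeasibleError``
    (never a silent wrong answer) when consecutive band rows disconnect.
    """
    if params is None:
        params = AlignParams()
    sa = a.bases if isinstance(a, DnaSequence) else a
    sb = b.bases if isinstance(b, DnaSequence) else b
    ea, eb = encode_bases(sa), encode_bases(sb)
    m, n = len(ea), len(eb)
    if m == 0:
        return GuideAlignment([(None, j) for j in range(n)], n * params.gap, 0)
    if n == 0:
        return GuideAlignment([(i, None) for i in range(m)], m * params.gap, 0)
    jlo, jhi = _band_limits(m, n, params.band_half_width)
    gaps = np.flatnonzero(jlo[1:] > jhi[:-1] + 1)
    if gaps.size:
        i = int(gaps[0]) + 1
        raise BandInfeasibleError(
            f"band_half_width={params.band_half_width} too narrow for lengths "
            f"({m}, {n}): rows {i - 1} and {i} of the DP band do not connect")
    M, ptr = _kernels.banded_nw_fill(
        ea, eb, float(params.match), float(params.mismatch), float(params.gap),
        jlo, jhi)
    if not np.isfinite(M[m, n]):
        raise BandInfeasibleError(
            f"band_half_width={params.band_half_width} leaves the DP terminus "
            f"unreachable for lengths ({m}, {n})")
    columns: list = []
    matches = 0
    i, j = m, n
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 1:
            i -= 1
            j -= 1
            columns.append((i, j))
            if ea[i] == eb[j]:
                matches += 1
        elif p == 2:
            i -= 1
            columns.append((i, None))
        elif p == 3:
            j -= 1
            columns.append((None, j))
        else:  # pragma: no cover - guarded by the finiteness check above
            raise BandInfeasibleError("traceback fell out of the band")
    columns.reverse()
    return GuideAlignment(columns, float(M[m, n]), matches)


@dataclass
class SequenceToSignalMap:
    """Per-base half-open frame intervals ``[start_i, end_i)`` of a decoded
    sequence, tiling ``[0, T)`` when at least one base exists."""

    intervals: np.ndarray  # shape (n_bases, 2)
    t_size: int

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=np.int64).reshape(-1, 2)
        self.intervals = iv
        if iv.size:
            if np.any(iv[:, 0] >= iv[:, 1]):
                raise ValueError("signal-map intervals must be non-empty")
            if np.any(iv[1:, 0] < iv[:-1, 1]):
                raise ValueError("signal-map intervals must be sorted and disjoint")
            if iv[0, 0] < 0 or iv[-1, 1] > self.t_size:
                raise ValueError("signal-map intervals must lie within [0, T)")

    def __len__(self) -> int:
        return self.intervals.shape[0]


def path_to_signal_map(path) -> SequenceToSignalMap:
    """Extract per-base frame intervals from a Viterbi label path.

    Base i spans from its first emitting frame to the frame before base
    i+1's first emitting frame: trailing blanks attach to the preceding
    base, leading blanks to base 0, so the intervals tile [0, T) exactly
    whenever the path contains at least one non-blank label.
    """
    labels = np.asarray(path, dtype=np.int64)
    T = labels.size
    starts = []
    prev = BLANK
    for t, lab in enumerate(labels):
        if lab != BLANK and lab != prev:
            starts.append(t)
        prev = int(lab)
    if not starts:
        return SequenceToSignalMap(np.empty((0, 2), dtype=np.int64), T)
    bounds = [0] + starts[1:] + [T]
    iv = np.column_stack([bounds[:-1], bounds[1:]])
    return SequenceToSignalMap(iv, T)


@dataclass
class AlignmentEnvelope:
    """Monotone per-frame band: for each frame t1 of read 1, the admissible
    half-open frame range ``[lo(t1), hi(t1))`` of read 2.

    ``lo`` and ``hi`` are non-decreasing staircases covering the (0, 0) and
    (T1-1, T2-1) corners, so a co-alignment path can always enter and leave.
    """

    lo: np.ndarray
    hi: np.ndarray
    t2_size: int

    def __post_init__(self) -> None:
        lo = np.asarray(self.lo, dtype=np.int64)
        hi = np.asarray(self.hi, dtype=np.int64)
        if lo.shape != hi.shape or lo.ndim != 1 or lo.size < 1:
            raise ValueError("envelope lo/hi must be equal-length 1-D arrays")
        if np.any(lo < 0) or np.any(hi > self.t2_size) or np.any(lo >= hi):
            raise ValueError("envelope requires 0 <= lo(t1) < hi(t1) <= T2")
        if np.any(np.diff(lo) < 0) or np.any(np.diff(hi) < 0):
            raise ValueError("envelope lo and hi must be non-decreasing")
        if lo[0] != 0 or hi[-1] != self.t2_size:
            raise ValueError("envelope must cover (0, 0) and (T1-1, T2-1)")
        self.lo, self.hi = lo, hi

    @property
    def t1_size(self) -> int:
        return self.lo.size

    @classmethod
    def full(cls, t1_size: int, t2_size: int) -> "AlignmentEnvelope":
        """The unconstrained envelope: every (t1, t2) cell admissible."""
        return cls(np.zeros(t1_size, dtype=np.int64),
                   np.full(t1_size, t2_size, dtype=np.int64), t2_size)

    def contains(self, t1: int, t2: int) -> bool:
        return bool(self.lo[t1] <= t2 < self.hi[t1])

    def area(self) -> int:
        return int(np.sum(self.hi - self.lo))

    def transpose(self) -> "AlignmentEnvelope":
        """The same admissible cell set indexed by frames of read 2."""
        t2 = np.arange(self.t2_size)
        lo_t = np.searchsorted(self.hi, t2, side="right")
        hi_t = np.searchsorted(self.lo, t2, side="right")
        return AlignmentEnvelope(lo_t, hi_t, self.t1_size)


DEFAULT_PADDING = 150
"""Default envelope dilation in frames (~16 bases of slack at 9 frames/base)."""


def build_envelope(map1: SequenceToSignalMap, map2: SequenceToSignalMap,
                   guide: GuideAlignment,
                   padding: int = DEFAULT_PADDING) -> AlignmentEnvelope:
    """Turn a guide alignment of two basecalls into a signal-space envelope.

    Each aligned column (i, j) contributes the rectangle
    ``map1[i] x map2[j]``; gap columns extend the previous rectangle along
    the gapped read's axis.  Bounds are then dilated by ``padding`` frames,
    clipped, forced to cover the corners, and repaired to a monotone
    staircase (hi by running max, lo by running min from the end).
    """
    if padding < 0:
        raise ValueError("padding must be non-negative")
    T1, T2 = map1.t_size, map2.t_size
    if len(map1) == 0 or len(map2) == 0:
        return AlignmentEnvelope.full(T1, T2)
    if not guide.columns:
        raise ValueError("cannot band: empty guide alignment for non-empty reads")
    lo = np.full(T1, T2, dtype=np.int64)
    hi = np.zeros(T1, dtype=np.int64)
    rows = (0, 1)  # origin cell until the first aligned base on each axis
    cols = (0, 1)
    for i, j in guide.columns:
        if i is not None:
            rows = tuple(map1.intervals[i])
        if j is not None:
            cols = tuple(map2.intervals[j])
        r0, r1 = rows
        lo[r0:r1] = np.minimum(lo[r0:r1], cols[0])
        hi[r0:r1] = np.maximum(hi[r0:r1], cols[1])
    untouched = lo > hi  # frames of read 1 never visited (cannot happen when
    lo[untouched] = 0    # the maps tile [0, T); kept as a safety net)
    hi[untouched] = T2
    lo = np.maximum(lo - padding, 0)
    hi = np.minimum(hi + padding, T2)
    lo = np.minimum(lo, T2 - 1)
    hi = np.maximum(hi, lo + 1)
    lo[0] = 0
    hi[-1] = T2
    hi = np.maximum.accumulate(hi)
    lo = np.minimum.accumulate(lo[::-1])[::-1]
    return AlignmentEnvelope(lo, hi, T2)


def envelope_area(env: AlignmentEnvelope) -> int:
    """Number of admissible DP cells, sum over t1 of hi(t1) - lo(t1)."""
    return env.area()
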