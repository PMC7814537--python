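"""Data model and I/O for CTC probability profiles and DNA sequences.

A CTC basecaller consumes a current trace and emits, for every signal frame,
a softmax distribution over the four bases plus a *blank* gap symbol.  That
``T x 5`` row-stochastic matrix -- the probability profile -- is the substrate
every decoder in this package consumes.  Profiles are stored on disk in
probability space and converted to natural-log space internally, with
``-inf`` as the log(0) sentinel.

Canonical column order is ``(A, C, G, T, blank)``; files may declare another
order (``# alphabet=...`` header, or an explicit ``column_order`` argument)
and are permuted into canonical order on load.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT-"
"""Canonical symbol order: the four bases then the CTC blank."""

BLANK = 4
"""Column index of the blank symbol."""

N_SYMBOLS = 5

ROW_SUM_TOL = 1e-6
"""Rows whose sum is within this tolerance of 1 are renormalized; beyond it
the profile is rejected."""

_COMPLEMENT_COLS = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, blank fixed
_RC_TABLE = str.maketrans("ACGT", "TGCA")

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


class ProfileError(ValueError):
    """Base class for profile I/O and validation failures."""


class ProfileParseError(ProfileError):
    """A profile file could not be parsed as a T x 5 numeric matrix."""


class ProfileValidationError(ProfileError):
    """A parsed matrix violates the probability-profile invariants."""


def revcomp(bases: str) -> str:
    """Reverse-complement a DNA string."""
    return bases.translate(_RC_TABLE)[::-1]


def encode_bases(bases: str) -> np.ndarray:
    """Map a DNA string to an int array over the canonical alphabet."""
    try:
        return np.fromiter((_BASE_INDEX[b] for b in bases), dtype=np.int64,
                           count=len(bases))
    except KeyError as exc:
        raise ValueError(f"non-ACGT character {exc} in sequence") from None


@dataclass
class DnaSequence:
    """A named DNA sequence over {A, C, G, T} (possibly empty)."""

    seq_id: str
    bases: str

    def __post_init__(self) -> None:
        bad = set(self.bases) - set("ACGT")
        if bad:
            raise ValueError(
                f"sequence {self.seq_id!r} contains non-ACGT characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self, seq_id: str | None = None) -> "DnaSequence":
        return DnaSequence(seq_id if seq_id is not None else self.seq_id,
                           revcomp(self.bases))


@dataclass
class ProbabilityProfile:
    """Per-frame softmax output ``P(symbol | frame)`` of a CTC basecaller.

    ``probabilities`` has shape ``(T, 5)`` with columns in canonical
    ``(A, C, G, T, blank)`` order; every row is a probability distribution.
    """

    read_id: str
    probabilities: np.ndarray
    _log: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        mat = np.asarray(self.probabilities, dtype=np.float64)
        if mat.ndim != 2 or mat.shape[1] != N_SYMBOLS:
            raise ProfileValidationError(
                f"profile {self.read_id!r}: expected a T x {N_SYMBOLS} matrix, "
                f"got shape {mat.shape}")
        if mat.shape[0] < 1:
            raise ProfileValidationError(
                f"profile {self.read_id!r}: needs at least one frame")
        neg = np.argwhere(mat < 0)
        if neg.size:
            r, c = neg[0]
            raise ProfileValidationError(
                f"profile {self.read_id!r}: negative entry at row {r}, column {c}")
        sums = mat.sum(axis=1)
        off = np.abs(sums - 1.0)
        bad = int(np.argmax(off))
        if off[bad] > ROW_SUM_TOL:
            raise ProfileValidationError(
                f"profile {self.read_id!r}: row {bad} sums to {sums[bad]:.9g}, "
                f"outside 1 +/- {ROW_SUM_TOL}")
        mat = mat / sums[:, None]
        self.probabilities = mat

    @classmethod
    def _from_validated(cls, read_id: str, mat: np.ndarray) -> "ProbabilityProfile":
        """Wrap a matrix known to satisfy the invariants without
        renormalizing (renormalization is not bit-stable under repetition)."""
        obj = cls.__new__(cls)
        obj.read_id = read_id
        obj.probabilities = mat
        obj._log = None
        return obj

    @property
    def T(self) -> int:
        """Number of signal frames."""
        return self.probabilities.shape[0]

    @property
    def log_probabilities(self) -> np.ndarray:
        """Natural-log probabilities; exact zeros become ``-inf``."""
        if self._log is None:
            with np.errstate(divide="ignore"):
                self._log = np.log(self.probabilities)
        return self._log


def reverse_complement_profile(p: ProbabilityProfile,
                               read_id: str | None = None) -> ProbabilityProfile:
    """Place a profile on the opposite strand's coordinate system.

    Reverses frame order and swaps the A<->T and C<->G columns; the blank
    column is unchanged.  Applying the operation twice returns the original
    profile, and for any sequence ``s``,
    ``forward_probability(rc(p), revcomp(s)) == forward_probability(p, s)``.
    """
    mat = np.ascontiguousarray(p.probabilities[::-1, _COMPLEMENT_COLS])
    return ProbabilityProfile._from_validated(
        read_id if read_id is not None else p.read_id, mat)


def _validate_column_order(order: str) -> np.ndarray:
    if sorted(order) != sorted(ALPHABET):
        raise ProfileParseError(
            f"column order {order!r} is not a permutation of {ALPHABET!r}")
    return np.array([order.index(c) for c in ALPHABET])


def _infer_format(path: str | os.PathLike) -> str:
    ext = os.path.splitext(os.fspath(path))[1].lower()
    return "npy" if ext == ".npy" else "csv"


def read_profile(path: str | os.PathLike, format: str | None = None,
                 column_order: str | None = None,
                 read_id: str | None = None) -> ProbabilityProfile:
    """Load a probability profile from CSV or npy binary.

    CSV files may carry a ``# alphabet=ACGT-`` header declaring the column
    order; ``column_order`` overrides any declaration (and is the only way to
    declare a non-canonical order for the binary format).
    """
    fmt = format or _infer_format(path)
    declared: str | None = None
    if fmt == "csv":
        rows: list[list[float]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "alphabet=" in line:
                        declared = line.split("alphabet=", 1)[1].strip()
                    continue
                fields = line.split(",")
                if len(fields) != N_SYMBOLS:
                    raise ProfileParseError(
                        f"{path}: row at line {lineno} has {len(fields)} fields, "
                        f"expected {N_SYMBOLS}")
                try:
                    rows.append([float(x) for x in fields])
                except ValueError:
                    raise ProfileParseError(
                        f"{path}: row at line {lineno} is not numeric") from None
        if not rows:
            raise ProfileParseError(f"{path}: no data rows found")
        mat = np.array(rows, dtype=np.float64)
    elif fmt == "npy":
        try:
            mat = np.load(path, allow_pickle=False)
        except Exception as exc:
            raise ProfileParseError(f"{path}: cannot read npy file: {exc}") from exc
        mat = np.asarray(mat, dtype=np.float64)
        if mat.ndim != 2 or mat.shape[1] != N_SYMBOLS:
            raise ProfileParseError(
                f"{path}: expected a T x {N_SYMBOLS} array, got shape {mat.shape}")
    else:
        raise ValueError(f"unknown profile format {fmt!r}")

    order = column_order or declared
    if order is not None and order != ALPHABET:
        mat = mat[:, _validate_column_order(order)]
    if read_id is None:
        read_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return ProbabilityProfile(read_id, mat)


def write_profile(p: ProbabilityProfile, path: str | os.PathLike,
                  format: str | None = None) -> None:
    """Write a profile to CSV (with alphabet header) or npy binary."""
    fmt = format or _infer_format(path)
    if fmt == "csv":
        with open(path, "w") as fh:
            fh.write(f"# alphabet={ALPHABET}\n")
            for row in p.probabilities:
                fh.write(",".join(f"{x:.17g}" for x in row) + "\n")
    elif fmt == "npy":
        np.save(path, p.probabilities)
    else:
        raise ValueError(f"unknown profile format {fmt!r}")


def write_fasta(results, path: str | os.PathLike) -> None:
    """Write decode results (or bare sequences) as 80-column multi-FASTA.

    Each record's description carries the decoder's log-probability when the
    item exposes one (``logprob=`` comment field).
    """
    records = []
    for item in results:
        if isinstance(item, DnaSequence):
            seq, desc = item, ""
        else:  # DecodeResult-like: .sequence and .log_prob
            seq = item.sequence
            desc = f"logprob={item.log_prob:.6f}"
        records.append(SeqRecord(Seq(seq.bases), id=seq.seq_id, description=desc))
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=80).write_file(records)


def read_fasta(path: str | os.PathLike) -> list[DnaSequence]:
    """Read a multi-FASTA file into uppercase DNA sequences."""
    return [DnaSequence(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(os.fspath(path), "fasta")]
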