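"""Read-accuracy evaluation: identity = matches / alignment length.

A decoded sequence is globally aligned to its reference (the simulation
truth, or any known sequence) and scored as the number of match columns
divided by the total number of alignment columns -- counting every column,
including end gaps, which is the strict convention.  The batch summary's
headline statistic is the median.

For users with real data and externally produced alignments, PAF records
can be ingested directly instead of re-aligning.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

from .pairwise import AlignParams, BandInfeasibleError, banded_global_align
from .profiles import DnaSequence


@dataclass
class AccuracyReport:
    """Identity of one query against one reference."""

    matches: int
    alignment_length: int
    identity: float
    read_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must lie in [0, 1]")


@dataclass
class BatchSummary:
    """Order statistics of a batch of identities."""

    n: int
    median: float
    q1: float
    q3: float


def compute_identity(ref, query, params: AlignParams | None = None,
                     read_id: str | None = None) -> AccuracyReport:
    """Globally align ``query`` to ``ref`` and report matches / columns.

    The band is widened automatically to feasibility, so the result never
    depends on an accidental band truncation.  Empty inputs are an error:
    identity is undefined without columns.
    """
    sref = ref.bases if isinstance(ref, DnaSequence) else ref
    squery = query.bases if isinstance(query, DnaSequence) else query
    if not sref or not squery:
        raise ValueError("identity is undefined for empty sequences")
    if params is None:
        params = AlignParams(band_half_width=max(len(sref), len(squery)))
    try:
        aln = banded_global_align(sref, squery, params)
    except BandInfeasibleError:
        wide = AlignParams(params.match, params.mismatch, params.gap,
                           max(len(sref), len(squery)))
        aln = banded_global_align(sref, squery, wide)
    if read_id is None:
        read_id = query.seq_id if isinstance(query, DnaSequence) else ""
    return AccuracyReport(aln.matches, len(aln.columns),
                          aln.matches / len(aln.columns), read_id)


def summarize_batch(reports) -> BatchSummary:
    """Median and quartiles of a batch of accuracy reports (or raw floats)."""
    values = sorted(r.identity if isinstance(r, AccuracyReport) else float(r)
                    for r in reports)
    if not values:
        raise ValueError("cannot summarize an empty batch")
    q = statistics.quantiles(values, n=4, method="inclusive") if len(values) > 1 \
        else [values[0]] * 3
    return BatchSummary(len(values), statistics.median(values), q[0], q[2])


def identities_from_paf(path) -> list[AccuracyReport]:
    """Ingest minimap-style PAF records: matches (col 10) over alignment
    block length (col 11)."""
    out = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                continue
            matches = int(fields[9])
            block = int(fields[10])
            if block > 0:
                out.append(AccuracyReport(matches, block, matches / block,
                                          fields[0]))
    return out
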