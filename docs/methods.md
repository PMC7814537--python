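# Methods

## The problem

A CTC-trained nanopore basecaller maps a current trace to a *probability
profile*: for each of `T` signal frames, a softmax distribution over
`{A, C, G, T, blank}`. The profile defines a distribution `P(l | y)` over
basecalled sequences `l`: the probability of `l` is the sum, over every
frame-by-frame label path that collapses to `l`, of the product of per-frame
probabilities. Collapse is the standard CTC rule — merge runs of identical
non-blank labels, then delete blanks — so a repeated base requires an
intervening blank frame. (A drop-blanks-only collapse variant is available
in `collapse_path` but is not used by the decoders.)

With the 1D² protocol a duplex's template strand is followed through the
pore by its complement, giving two reads `y1, y2` of the same sequence on
opposite strands. Under a flat prior over sequences and independent reads,
the consensus problem is to find the `l` maximizing
`P(l|y1) · P(l|y2)`. This package implements that pair decoding, plus the
single-read decoders, the banded aligner and alignment envelope that make
it tractable, an identity evaluator, and a simulator that generates
ground-truthed profiles so everything can be tested without real reads or a
trained network.

## Single-read decoding

* `forward_probability` is the exact CTC forward recursion over the
  blank-interleaved expanded sequence, entirely in natural-log space with
  `-inf` as the log(0) sentinel and log-sum-exp combining.
* `viterbi_decode` returns the best single label path. The profiles carry
  no transition model — frames are independent given the network output —
  so the best path is the per-frame argmax (ties to the lower symbol index,
  i.e. alphabet order `A < C < G < T < blank`), collapsed.
* `beam_search_decode` is CTC prefix beam search: each surviving prefix
  carries separate blank-ending and non-blank-ending forward masses,
  updated frame by frame; the top `beam_width` prefixes by total mass
  survive each frame. Pruning is purely by rank — no probability threshold
  — so an exhaustive width reduces to exact search. The reported score is
  the exact forward probability of the returned sequence, recomputed.
  Note that the *returned score is not monotone in `beam_width`* in
  general: pruned beam sets are not nested, so a wider beam can
  occasionally return a slightly worse sequence. What is guaranteed, and
  tested, is that a beam wide enough to hold every distinct prefix equals
  the exhaustive argmax.
* `enumerate_decode` is the intractable exact search, implemented for
  testing and guarded to `T <= 8` frames.

Tie-breaking is uniform everywhere: score, then shorter sequence, then
lexicographic order.

## Guide alignment and the envelope

Because reads vary in length over orders of magnitude, the preliminary
nucleotide-level alignment uses Needleman–Wunsch restricted to a fixed
diagonal band. The band follows the *length-rescaled* diagonal — cell
`(i, j)` is admissible iff `|j − i·|b|/|a|| ≤ band_half_width` — so
unequal-length reads remain alignable. Defaults: match 2, mismatch −1,
linear gap −2, band half-width 100 bases. Scores are deliberately simple
(no affine gaps) so the banded result can be checked exactly against an
unbanded reference aligner. An infeasible band (rows of the band
disconnect) raises an explicit error rather than returning a silently
truncated alignment; the consensus pipeline responds by widening the band
to the longer sequence length.

A Viterbi label path explicitly maps each decoded base to a half-open frame
interval: a base spans from its first emitting frame to the frame before
the next base's first emitting frame, so trailing blanks attach to the
preceding base, leading blanks to base 0, and the intervals tile `[0, T)`.
Any consistent tiling convention works here because envelope padding
absorbs boundary error.

`build_envelope` combines the two signal maps through the guide alignment:
every aligned base pair `(i, j)` contributes the rectangle
`map1[i] × map2[j]`, gap columns extend the previous rectangle along the
gapped read's axis, and the union is dilated by `padding` frames, clipped,
forced to cover the `(0,0)` and `(T1−1, T2−1)` corners, and repaired to a
monotone staircase (upper bound by running max, lower bound by running min
from the end). The envelope is stored as one `[lo, hi)` interval per frame
of read 1 — `O(T1)` storage matching the monotone structure of time-warped
co-alignment. Default padding is 150 frames (~16 bases at 9 frames/base);
the envelope-coverage and banding-losslessness tests run at padding 10 to
exercise the tight regime.

## Pair beam search

The consensus search couples two prefix recursions. Frames of read 1 are
consumed in order; each beam entry is a sequence prefix carrying

* scalar read-1 masses at the current `t1`, updated exactly as in the 1D
  prefix search, and
* vector read-2 masses over the envelope's admissible frame window at
  `t1`, advanced by the same prefix recursion along the `t2` axis.

A prefix's read-2 update at frame `t2` needs its parent prefix's masses at
`t2 − 1`, so beam entries keep a parent pointer and windows grow lazily up
the chain as the envelope slides. With a full envelope the recursion is
exact, which is what makes the brute-force oracle comparisons possible;
with a real envelope, mass below the window floor is truncated — that
truncation *is* the banding approximation, and the losslessness test
verifies it does not change the output when the envelope covers the true
co-alignment.

Mid-sweep, the two reads have not consumed comparable amounts of evidence
(read 2's window typically runs ahead of `t1` by the padding), so raw
masses at different `t2` cannot be compared directly. The pruning score is
therefore `mass1(t1) + max over the window of (mass2(t2) − baseline(t2))`,
where the baseline is read 2's running best-path mass (cumulative max
per-frame log-probability). The baseline is prefix-independent, so it
cancels within any fixed `t2` and merely aligns the scales across `t2`;
without it, wide windows systematically favour prefixes that explain only
a short prefix of read 2. Final selection ignores the heuristic entirely:
after the last frame the winner is the prefix maximizing the sum of the two
fully-consumed masses, and the reported per-read components are exactly
those masses.

The full pipeline reverse-complements profile 2 when it is a
complement-strand read (frame order reversed, A↔T and C↔G columns swapped)
so everything downstream is orientation-free, then: Viterbi on each
profile, guide alignment, signal maps, envelope, pair beam search. A guide
alignment with identity below 0.3 is treated as evidence the reads are not
a true pair: the pipeline warns and falls back to the full envelope when
`T1 × T2` is small enough to afford it, and refuses otherwise. A read whose
preliminary basecall is empty carries no sequence evidence, and the
consensus degenerates (with a warning) to the other read's single-read
call.

## The simulator

The generator emulates the softmax output of a trained basecaller, not pore
physics. DNA translocates at ~450 bases/s and is sampled at 4 kHz, so each
base occupies ~9 frames on average; per-base dwell is drawn from a shifted
negative binomial (minimum 1 frame) with mean `frames_per_base_mean`
(default 9) and shape `frames_per_base_dispersion` (default 3, allowing
overdispersion a geometric dwell cannot express). Each base emits a
contiguous run of base-dominant frames followed by blank-dominant frames
(expected blank fraction 0.6 of all frames); blanks are never interleaved
within a base's run because an interior blank would split the run under
merge-repeats collapse and make the truth unreachable, and a separating
blank is always placed between consecutive identical bases for the same
reason. These are simulator conventions, not biological claims.

Noise acts at two scales, and the distinction matters:

* **Frame-level** Dirichlet jitter around the frame's dominant symbol
  (concentration 10 on the dominant symbol, symmetric pseudo-count 0.1).
  The small pseudo-count keeps stray mass rare and spiky, the way a
  confident softmax behaves. Frame noise alone, at any level, produces a
  *systematic* insertion bias that is shared by both reads of a pair —
  the joint posterior keeps the spurious bases, so consensus decoding
  cannot beat single reads under pure frame noise. That regime is
  measurably miscalibrated (decoded reads are consistently longer than
  the truth) and unlike real basecaller output.
* **Base-level events**, independent between the two reads of a pair:
  with probability `base_dropout_rate` (default 0.08) a base's emission
  centre hedges towards blank (75% of the centre mass), creating deletion
  errors; with probability `base_miscall_rate` (default 0.08) it hedges
  towards a uniformly chosen wrong base (60%), creating substitutions.
  Events are soft — the way a real softmax hedges at genuinely ambiguous
  signal — so a single-read decoder usually calls them wrong while the
  paired read's clean evidence lets the consensus recover the truth.

The default noise level was chosen so that single-read beam decoding of
default simulations lands near the high-80s% median identity reported for
small recurrent basecallers on real 1D reads; under those conditions the
pair consensus median lands near the mid-90s%. The simulator does not
model k-mer-dependent current levels, homopolymer-specific error,
correlated inter-read artefacts, or raw signal, so passing tests
demonstrate the correctness and the qualitative behaviour of the decoding
machinery — not performance on real flowcell data.

Every simulated read carries its truth, its true label path and the
base-to-frame map derived from it, and `true_coalignment` exposes the known
monotone `(t1, t2)` path of a pair, used to verify envelope coverage.

## Numerical and scale choices

* All decoder arithmetic is log-domain with `-inf` sentinels; no scaling
  factors. Profile rows whose sums are within `1e-6` of 1 are renormalized
  on load, anything worse is rejected with the offending row named.
* Oracle tests enumerate all `5^T` label paths at `T ≤ 5-6` and all
  sequences up to length `T`; acceptance-level experiments use 200
  simulated pairs of 70-base molecules (~630 frames per read), sizes at
  which the whole suite completes on one CPU in minutes while the
  statistics (medians over ≥200 values) are stable.
* The banded aligner's traceback prefers diagonal, then up (gap in the
  second sequence), then left on score ties, making alignments — and hence
  identity values — deterministic.
* Identity is matches over total alignment columns of a *global*
  alignment, end gaps included: the strict convention. The evaluator
  auto-widens its band to feasibility so identity never depends on band
  truncation.

## Known limitations

* Pair decoding only (`N = 2`); multi-read consensus would need additional
  search heuristics.
* The envelope truncates read-2 mass below its floor; pathological
  envelopes that exclude the true co-alignment give degraded (though
  explicitly banded, never silently unbanded) results.
* The pruning heuristic is exact only in the full-envelope limit;
  beam search carries the usual non-monotonicity in beam width.
* The simulator's noise is stationary and sequence-independent.
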