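"""Verify the decoders against exhaustive search on a tiny profile.

At five frames the space of candidate sequences is small enough to
enumerate, so the exact modal sequence is computable.  A wide-beam prefix
search must find the same sequence, and the sum of P(sequence) over all
candidates must be exactly 1 (CTC defines a proper distribution).
"""

import itertools
import math

import numpy as np

import pairdecode as pd

rng = np.random.default_rng(2)
profile = pd.ProbabilityProfile("tiny", rng.dirichlet(np.ones(5), size=5))

exact = pd.enumerate_decode(profile)
beam = pd.beam_search_decode(profile, beam_width=4096)
print(f"exhaustive argmax: {exact.sequence.bases!r} "
      f"(log-probability {exact.log_prob:.4f})")
print(f"wide-beam search : {beam.sequence.bases!r} "
      f"(log-probability {beam.log_prob:.4f})")
print(f"agree: {exact.sequence.bases == beam.sequence.bases}")

total = sum(math.exp(pd.forward_probability(profile, "".join(c)))
            for L in range(6) for c in itertools.product("ACGT", repeat=L))
print(f"sum of P(sequence) over all candidates: {total:.12f}")
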