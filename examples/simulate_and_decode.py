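"""Simulate one nanopore-style probability profile and decode it.

Generates a 60-base molecule, emulates the softmax output a CTC basecaller
would produce for it (~9 frames per base), then decodes with Viterbi
(best single label path) and prefix beam search (approximate modal
sequence), scoring both against the known truth.
"""

import pairdecode as pd

truth = pd.random_dna(60, seed_or_rng=7)
cfg = pd.SimulationConfig(seq_length=60, seed=1)
read = pd.simulate_read(truth, cfg)
print(f"truth ({len(truth)} bases): {truth.bases}")
print(f"profile: {read.profile.T} frames "
      f"({read.profile.T / len(truth):.1f} frames/base)")

for name, result in [("viterbi", pd.viterbi_decode(read.profile)),
                     ("beam-25", pd.beam_search_decode(read.profile, 25))]:
    ident = pd.compute_identity(truth, result.sequence).identity
    print(f"{name}: {result.sequence.bases}")
    print(f"  log-probability {result.log_prob:.2f}, identity {ident:.3f}")

# The log-probability is log P(sequence | profile); identity is matches over
# global-alignment columns against the truth. Beam search typically edges
# out Viterbi because it sums over label paths instead of taking one.
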