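"""Shared fixtures: random profiles and the one heavyweight simulation batch."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import pairdecode as pd
from oracles import random_profile_matrix

PAIR_BATCH_SIZE = 200
PAIR_BATCH_LENGTH = 70


def make_profile(seed: int, T: int, read_id: str = "p") -> pd.ProbabilityProfile:
    rng = np.random.default_rng(seed)
    return pd.ProbabilityProfile(read_id, random_profile_matrix(rng, T))


@dataclasses.dataclass
class PairBatchResult:
    """Identity of every single-read call, better-of-pair call, and pair
    consensus over the simulated 1D2 batch at default (moderate) noise."""

    single: list[float]
    better_single: list[float]
    consensus: list[float]


@pytest.fixture(scope="session")
def pair_improvement_batch() -> PairBatchResult:
    """Decode a batch of simulated 1D2 pairs at the generator's default
    noise with both the single-read and the pair-consensus decoders.

    Session-scoped: this is the suite's one expensive simulation.
    """
    singles, better, cons = [], [], []
    for k in range(PAIR_BATCH_SIZE):
        truth = pd.random_dna(PAIR_BATCH_LENGTH, 10_000 + k)
        cfg1 = pd.SimulationConfig(seq_length=PAIR_BATCH_LENGTH, seed=20_000 + k)
        cfg2 = pd.SimulationConfig(seq_length=PAIR_BATCH_LENGTH, seed=50_000 + k)
        r1, r2 = pd.simulate_pair(truth, cfg1, cfg2)
        ids = []
        for r in (r1, r2):
            call = pd.beam_search_decode(r.profile, 25)
            ident = (pd.compute_identity(truth, call.sequence).identity
                     if len(call.sequence) else 0.0)
            ids.append(ident)
            singles.append(ident)
        better.append(max(ids))
        res = pd.pair_decode_pipeline(r1.profile, r2.profile)
        cons.append(pd.compute_identity(truth, res.sequence).identity
                    if len(res.sequence) else 0.0)
    return PairBatchResult(singles, better, cons)
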