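"""Synthetic CTC profile simulator with ground truth.

Emulates what a trained nanopore basecaller's softmax head produces, without
any network: DNA moves through the pore at ~450 bases/s while the current is
sampled at 4 kHz, so each base occupies ~9 signal frames on average.  The
simulator draws a per-base dwell from a shifted negative binomial (minimum
1 frame, configurable mean and overdispersion), emits a contiguous run of
base-dominant frames followed by optional blank-dominant frames, and draws
each frame's softmax row from a Dirichlet concentrated on the frame's
dominant symbol.

Noise acts at two scales.  Frame-level Dirichlet jitter (the
``emission_concentration`` knob) blurs individual rows.  Base-level *events*
corrupt a whole base's emission centre independently in each read: with
``base_dropout_rate`` the centre hedges towards blank (the event was partly
missed, creating deletion errors) and with ``base_miscall_rate`` towards a
uniformly chosen wrong base (substitution errors).  Events are *soft* --
the corrupt symbol receives most but not all of the centre mass -- the way
a real softmax hedges at a genuinely ambiguous stretch of signal; a
single-read decoder usually calls them wrong, while the paired read's clean
evidence lets consensus decoding recover the truth.  Event noise is what
makes the two reads of a pair disagree independently, and the true label
path always remains the uncorrupted one.

Blanks within a dwell are trailing (never interleaved with the base's own
frames): an interior blank would split the run under merge-repeats CTC
collapse and make the truth unreachable.  For the same reason a blank frame
is always guaranteed between consecutive identical bases.  These are
simulator conventions, not claims about pore physics.

Everything is reproducible from the config seed, and every simulated read
carries its true sequence, label path and base-to-frame map, so decoders can
be scored against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .decoding import collapse_path
from .pairwise import SequenceToSignalMap, path_to_signal_map
from .profiles import BLANK, DnaSequence, ProbabilityProfile, encode_bases, revcomp

DEFAULT_FRAMES_PER_BASE = 9.0
"""Mean dwell in frames: 4000 Hz sampling / ~450 bases/s translocation."""

DEFAULT_EMISSION_CONCENTRATION = 10.0
"""Dirichlet concentration added to the dominant symbol of each frame."""

DEFAULT_BASE_DROPOUT_RATE = 0.08
"""Per-base probability that a base's emission frames hedge towards blank
(the signal event was partly missed), creating deletion errors."""

DEFAULT_BASE_MISCALL_RATE = 0.08
"""Per-base probability that the emission frames hedge towards a uniformly
chosen wrong base, creating substitution errors."""

_DIRICHLET_SPREAD = 0.1   # symmetric pseudo-count shared by all five symbols
_DROPOUT_BLANK_WEIGHT = 0.75   # centre mass moved to blank in a dropout event
_MISCALL_WRONG_WEIGHT = 0.6    # centre mass moved to the wrong base in a miscall


@dataclass
class SimulationConfig:
    """Knobs of the synthetic profile generator.

    ``frames_per_base_mean`` is the mean dwell (default 9 frames);
    ``frames_per_base_dispersion`` is the negative-binomial shape r
    (variance = m + m^2/r on the shifted part, smaller r = burstier);
    ``emission_concentration`` controls softmax sharpness (higher = cleaner);
    ``blank_fraction`` is the expected fraction of frames that are
    blank-dominant; ``base_dropout_rate`` / ``base_miscall_rate`` are the
    per-base event-noise rates (deletion and substitution pressure);
    ``noiseless`` disables all noise and emits exact one-hot rows.
    """

    seq_length: int = 500
    frames_per_base_mean: float = DEFAULT_FRAMES_PER_BASE
    frames_per_base_dispersion: float = 3.0
    emission_concentration: float = DEFAULT_EMISSION_CONCENTRATION
    blank_fraction: float = 0.6
    base_dropout_rate: float = DEFAULT_BASE_DROPOUT_RATE
    base_miscall_rate: float = DEFAULT_BASE_MISCALL_RATE
    noiseless: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frames_per_base_mean < 1:
            raise ValueError("frames_per_base_mean must be >= 1")
        if self.emission_concentration <= 0:
            raise ValueError("emission_concentration must be positive")
        if not 0 <= self.blank_fraction < 1:
            raise ValueError("blank_fraction must be in [0, 1)")
        if self.frames_per_base_dispersion <= 0:
            raise ValueError("frames_per_base_dispersion must be positive")
        if not (0 <= self.base_dropout_rate < 1 and 0 <= self.base_miscall_rate < 1
                and self.base_dropout_rate + self.base_miscall_rate < 1):
            raise ValueError("event rates must lie in [0, 1) and sum below 1")
        mu = self.frames_per_base_mean
        if mu > 1 and self.blank_fraction * mu / (mu - 1) > 1:
            raise ValueError("blank_fraction too large for this mean dwell")


@dataclass
class SimulatedRead:
    """A ground-truthed synthetic read: profile plus the truth that made it."""

    truth: DnaSequence
    profile: ProbabilityProfile
    true_path: np.ndarray
    true_map: SequenceToSignalMap

    def __post_init__(self) -> None:
        if collapse_path(self.true_path) != self.truth.bases:
            raise ValueError("true_path does not collapse to the truth sequence")


def random_dna(length: int, seed_or_rng) -> DnaSequence:
    """A uniform random DNA sequence (convenience for experiments)."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    bases = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
    return DnaSequence(f"random_{length}", bases)


def _draw_dwells(n: int, cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    mu = cfg.frames_per_base_mean - 1.0
    if mu <= 0:
        return np.ones(n, dtype=np.int64)
    r = cfg.frames_per_base_dispersion
    extra = rng.negative_binomial(r, r / (r + mu), size=n)
    return 1 + extra.astype(np.int64)


def simulate_read(truth: DnaSequence, cfg: SimulationConfig,
                  read_id: str | None = None) -> SimulatedRead:
    """Generate one synthetic profile for ``truth`` under ``cfg``.

    Fully reproducible from ``cfg.seed``: two calls with the same arguments
    return bit-identical profiles.
    """
    if len(truth) == 0:
        raise ValueError("truth sequence must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    idx = encode_bases(truth.bases)
    n = idx.size
    dwells = _draw_dwells(n, cfg, rng)
    mu = cfg.frames_per_base_mean
    blank_rate = cfg.blank_fraction * mu / (mu - 1) if mu > 1 else 0.0

    labels: list[int] = []       # the true path (what the molecule did)
    targets: list[np.ndarray] = []  # per-frame emission centre distribution
    one_hot = np.eye(5)
    for i in range(n):
        d = int(dwells[i])
        n_blank = int(rng.binomial(d - 1, blank_rate)) if d > 1 else 0
        repeat_next = i + 1 < n and idx[i + 1] == idx[i]
        if repeat_next and n_blank == 0:
            if d == 1:
                d += 1  # make room for the mandatory separating blank
            n_blank = 1
        base = int(idx[i])
        q = one_hot[base]
        if not cfg.noiseless:
            u = rng.random()
            if u < cfg.base_dropout_rate:
                # missed event: frames hedge towards blank, deletion-prone
                q = _DROPOUT_BLANK_WEIGHT * one_hot[BLANK] + \
                    (1 - _DROPOUT_BLANK_WEIGHT) * one_hot[base]
            elif u < cfg.base_dropout_rate + cfg.base_miscall_rate:
                # ambiguous event: frames hedge towards a wrong base
                wrong = int((base + 1 + rng.integers(3)) % 4)
                q = _MISCALL_WRONG_WEIGHT * one_hot[wrong] + \
                    (1 - _MISCALL_WRONG_WEIGHT) * one_hot[base]
        labels.extend([base] * (d - n_blank))
        targets.extend([q] * (d - n_blank))
        labels.extend([BLANK] * n_blank)
        targets.extend([one_hot[BLANK]] * n_blank)
    path = np.array(labels, dtype=np.int64)
    T = path.size

    if cfg.noiseless:
        mat = np.zeros((T, 5))
        mat[np.arange(T), path] = 1.0
    else:
        alpha = _DIRICHLET_SPREAD + cfg.emission_concentration * np.array(targets)
        # Dirichlet draw via normalized gammas (vectorized over frames)
        g = rng.gamma(alpha)
        mat = g / g.sum(axis=1, keepdims=True)

    if read_id is None:
        read_id = f"sim_{truth.seq_id}_{cfg.seed}"
    profile = ProbabilityProfile(read_id, mat)
    return SimulatedRead(truth, profile, path, path_to_signal_map(path))


def simulate_pair(truth: DnaSequence, cfg1: SimulationConfig,
                  cfg2: SimulationConfig,
                  as_complement: bool = False
                  ) -> tuple[SimulatedRead, SimulatedRead]:
    """Two independent reads of the same molecule (a synthetic 1D2 pair).

    With ``as_complement`` the second read is generated from the
    reverse-complement of ``truth`` and its profile stored in complement
    orientation, exercising the pipeline's complement-strand handling.
    """
    read1 = simulate_read(truth, cfg1, read_id=f"{truth.seq_id}_template")
    if as_complement:
        truth2 = DnaSequence(f"{truth.seq_id}_rc", revcomp(truth.bases))
        read2 = simulate_read(truth2, cfg2, read_id=f"{truth.seq_id}_complement")
    else:
        read2 = simulate_read(truth, cfg2, read_id=f"{truth.seq_id}_template2")
    return read1, read2


def true_coalignment(read1: SimulatedRead, read2: SimulatedRead) -> np.ndarray:
    """The known (t1, t2) co-alignment path of a co-oriented simulated pair.

    Within each base's rectangle map1[i] x map2[i] the path steps
    diagonally, saturating the shorter axis; the result is a monotone cell
    path from (0, 0) to (T1-1, T2-1) usable to test envelope coverage.
    Both reads must share the same truth orientation.
    """
    if read1.truth.bases != read2.truth.bases:
        raise ValueError("true_coalignment requires co-oriented reads of the "
                         "same truth")
    cells = []
    for (s1, e1), (s2, e2) in zip(read1.true_map.intervals,
                                  read2.true_map.intervals):
        h, w = e1 - s1, e2 - s2
        for step in range(max(h, w)):
            cells.append((s1 + min(step, h - 1), s2 + min(step, w - 1)))
    return np.array(cells, dtype=np.int64)


def moderate_noise_config(seed: int, seq_length: int = 70) -> SimulationConfig:
    """The package's reference 'moderate noise' condition: default dwell and
    emission parameters, varying only the seed and length."""
    return SimulationConfig(seq_length=seq_length, seed=seed)
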