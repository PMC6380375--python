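"""Probabilistic-oddball auditory streams and the concurrent visual tasks.

The auditory paradigm is a tone stream whose frequencies are drawn from a
Gaussian distribution in base-2 log-frequency (an "octave" scale) centred at
``centre_freq``.  Eighty percent of tones are *contextual* draws from that
distribution; ten percent are *mean probes* pinned to the distribution centre
and ten percent are *oddball probes* pinned two octaves above it.  Only the
probes enter the ERP contrasts, so the two probe types are physically
identical across the narrow- and broad-variance conditions — what differs is
the statistical context they appear in.

The visual side is either an incidental detection task (experiment 1, not
modelled beyond timing) or an N-back working-memory stream (experiment 2)
that manipulates cognitive load.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ParadigmConfig",
    "ToneEvent",
    "ToneSequence",
    "NBackStream",
    "build_tone_sequence",
    "freq_octave_transform",
    "octave_to_freq",
    "nback_targets",
    "build_nback_stream",
    "block_schedule",
    "events_table",
]

Role = Literal["contextual", "mean_probe", "oddball_probe"]

#: Consonant alphabet for the N-back letters (vowels excluded to discourage
#: chunking into pronounceable strings).
NBACK_ALPHABET = "BCDFGHJKLMNPQRSTVWXZ"

#: Probes never occupy the first slots of a block, so each probe has a local
#: statistical context to be compared against.
PROBE_FREE_LEAD_SLOTS = 5


def freq_octave_transform(frequency: float, reference: float) -> float:
    """Frequency ratio expressed in octaves: ``log2(frequency / reference)``."""
    if frequency <= 0 or reference <= 0:
        raise ValueError(
            f"frequencies must be positive, got {frequency=}, {reference=}"
        )
    return float(np.log2(frequency / reference))


def octave_to_freq(octaves: float, reference: float) -> float:
    """Inverse of :func:`freq_octave_transform`."""
    if reference <= 0:
        raise ValueError(f"reference must be positive, got {reference}")
    return float(reference * 2.0**octaves)


@dataclass(frozen=True)
class ParadigmConfig:
    """Parameters of one tone-stream block.

    Parameters
    ----------
    centre_freq
        Centre of the contextual log-frequency distribution, Hz.
    sigma_octaves
        Standard deviation of the contextual distribution in octaves;
        0.50 for the narrow-variance condition, 1.50 for broad.
    probe_rate
        Fraction of tones per probe type (mean and oddball each).
    oddball_offset
        Oddball-probe position above the centre, in octaves.
    tone_duration, ramp
        Tone length and rise/fall ramp, ms (metadata only; no audio is
        rendered).
    soa
        Stimulus-onset asynchrony between successive tones, ms.
    block_duration
        Block length in seconds; must be a whole number of SOA slots.
    """

    centre_freq: float = 500.0
    sigma_octaves: float = 0.50
    probe_rate: float = 0.10
    oddball_offset: float = 2.0
    tone_duration: float = 50.0
    ramp: float = 10.0
    soa: float = 500.0
    block_duration: float = 780.0
    n_blocks: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_octaves <= 0:
            raise ValueError(f"sigma_octaves must be > 0, got {self.sigma_octaves}")
        if not 0 < self.probe_rate < 0.5:
            raise ValueError(
                f"need 2*probe_rate < 1 so contextual tones remain, got {self.probe_rate}"
            )
        if self.soa < self.tone_duration:
            raise ValueError("soa must be at least tone_duration")
        n_slots = self.block_duration * 1000.0 / self.soa
        if abs(n_slots - round(n_slots)) > 1e-9:
            raise ValueError(
                f"block_duration {self.block_duration} s is not a whole number of "
                f"{self.soa} ms slots"
            )

    @property
    def slots_per_block(self) -> int:
        return round(self.block_duration * 1000.0 / self.soa)

    @property
    def oddball_freq(self) -> float:
        return octave_to_freq(self.oddball_offset, self.centre_freq)

    @classmethod
    def from_yaml(cls, path) -> "ParadigmConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh)


@dataclass(frozen=True)
class ToneEvent:
    onset: float  # ms from block start
    frequency: float  # Hz
    role: Role
    variance_condition: str = "narrow"
    load_condition: str = "none"
    block_id: int = 0


@dataclass
class ToneSequence:
    """Ordered tone events of one block, with the config that produced them."""

    events: list[ToneEvent]
    config: ParadigmConfig

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def roles(self) -> np.ndarray:
        return np.array([e.role for e in self.events])

    def frequencies(self) -> np.ndarray:
        return np.array([e.frequency for e in self.events])

    def onsets(self) -> np.ndarray:
        return np.array([e.onset for e in self.events])


@dataclass
class NBackStream:
    letters: list[str]
    onsets: np.ndarray  # ms
    target_flags: np.ndarray  # bool
    n_level: int
    display_duration: float = 400.0
    isi: float = 1000.0


def _place_probes(n_tones: int, n_probes_total: int, rng: np.random.Generator) -> np.ndarray:
    """Choose probe slots: none in the first ``PROBE_FREE_LEAD_SLOTS`` and no
    two probes in consecutive slots (each probe keeps a contextual neighbour)."""
    candidates = np.arange(PROBE_FREE_LEAD_SLOTS, n_tones)
    if n_probes_total > (len(candidates) + 1) // 2:
        raise ValueError("cannot place probes without adjacent pairs: too dense")
    for _ in range(1000):
        pick = np.sort(rng.choice(candidates, size=n_probes_total, replace=False))
        if n_probes_total < 2 or np.all(np.diff(pick) >= 2):
            return pick
    # Rejection sampling failing 1000 times means the density is borderline;
    # fall back to a deterministic thinning of a stride-2 lattice.
    lattice = candidates[::2]
    return np.sort(rng.choice(lattice, size=n_probes_total, replace=False))


def build_tone_sequence(
    config: ParadigmConfig,
    n_tones: int | None = None,
    seed: int | None = None,
    variance_condition: str | None = None,
    load_condition: str = "none",
    block_id: int = 0,
) -> ToneSequence:
    """Generate one block's tone stream.

    Exactly ``round(n_tones * probe_rate)`` mean probes and the same number of
    oddball probes are embedded pseudo-randomly; the remaining slots carry
    contextual tones whose base-2 log frequencies are i.i.d. Gaussian around
    the centre with s.d. ``sigma_octaves``.  Deterministic in (config, seed).
    """
    if n_tones is None:
        n_tones = config.slots_per_block
    if seed is None:
        seed = config.seed
    n_probe = n_tones * config.probe_rate
    if abs(n_probe - round(n_probe)) > 1e-9:
        raise ValueError(
            f"n_tones * probe_rate = {n_probe} is not an integer; choose n_tones "
            f"so each probe type gets a whole count"
        )
    n_probe = round(n_probe)
    if variance_condition is None:
        variance_condition = "narrow" if config.sigma_octaves <= 1.0 else "broad"

    rng = np.random.default_rng(seed)
    probe_slots = _place_probes(n_tones, 2 * n_probe, rng)
    # Interleave probe identities randomly over the chosen slots.
    identity = np.array(["mean_probe"] * n_probe + ["oddball_probe"] * n_probe)
    rng.shuffle(identity)

    roles = np.full(n_tones, "contextual", dtype=object)
    roles[probe_slots] = identity

    freqs = np.empty(n_tones)
    n_ctx = n_tones - 2 * n_probe
    ctx_octaves = rng.normal(0.0, config.sigma_octaves, size=n_ctx)
    freqs[roles == "contextual"] = config.centre_freq * 2.0**ctx_octaves
    freqs[roles == "mean_probe"] = config.centre_freq
    freqs[roles == "oddball_probe"] = config.oddball_freq

    events = [
        ToneEvent(
            onset=i * config.soa,
            frequency=float(freqs[i]),
            role=str(roles[i]),
            variance_condition=variance_condition,
            load_condition=load_condition,
            block_id=block_id,
        )
        for i in range(n_tones)
    ]
    return ToneSequence(events=events, config=config)


def nback_targets(letters: Sequence[str], n_level: int) -> np.ndarray:
    """Target flags for a letter sequence: ``letters[i] == letters[i - n]``;
    the first ``n_level`` letters can never be targets."""
    flags = np.zeros(len(letters), dtype=bool)
    for i in range(n_level, len(letters)):
        flags[i] = letters[i] == letters[i - n_level]
    return flags


def build_nback_stream(
    n_level: int,
    n_letters: int,
    target_fraction: float = 0.25,
    seed: int = 0,
) -> NBackStream:
    """Generate an N-back letter stream.

    Letters appear for 400 ms with a 1,000 ms inter-stimulus interval plus a
    uniform 0-500 ms jitter, so consecutive onsets are 1,400-1,900 ms apart.
    ``target_flags[i]`` is True iff ``letters[i] == letters[i - n_level]``.
    """
    if n_level not in (1, 2):
        raise ValueError(f"n_level must be 1 or 2, got {n_level}")
    if n_letters <= n_level:
        raise ValueError(f"need n_letters > n_level, got {n_letters} <= {n_level}")
    if not 0 < target_fraction < 1:
        raise ValueError(f"target_fraction must be in (0, 1), got {target_fraction}")

    rng = np.random.default_rng(seed)
    letters: list[str] = []
    for i in range(n_letters):
        if i >= n_level and rng.random() < target_fraction:
            letters.append(letters[i - n_level])
        else:
            # Draw a non-target letter: avoid accidentally matching i - n_level.
            forbidden = letters[i - n_level] if i >= n_level else None
            pool = [c for c in NBACK_ALPHABET if c != forbidden]
            letters.append(pool[rng.integers(len(pool))])

    flags = nback_targets(letters, n_level)

    jitter = rng.uniform(0.0, 500.0, size=n_letters)
    gaps = 400.0 + 1000.0 + jitter[:-1]
    onsets = np.concatenate([[0.0], np.cumsum(gaps)])
    return NBackStream(
        letters=letters, onsets=onsets, target_flags=flags, n_level=n_level
    )


def _child_seed(master: int, *indices: int) -> int:
    """Fixed seed-splitting rule: hash the master seed with the index path."""
    ss = np.random.SeedSequence(master, spawn_key=tuple(indices))
    return int(ss.generate_state(1)[0] % (2**31))


def block_schedule(
    experiment: int, seed: int = 0, base_config: ParadigmConfig | None = None
) -> list[tuple[ToneSequence, NBackStream | None]]:
    """Full block list for one simulated participant.

    Experiment 1: two 780 s blocks (narrow, broad), order counterbalanced by
    seed parity, no working-memory stream.  Experiment 2: sixteen 210 s
    blocks, four per (variance x load) cell, in a deterministic Latin-square
    order rotated by the seed.
    """
    if experiment not in (1, 2):
        raise ValueError(f"experiment must be 1 or 2, got {experiment}")
    if base_config is None:
        base_config = ParadigmConfig()

    sigma = {"narrow": 0.50, "broad": 1.50}
    out: list[tuple[ToneSequence, NBackStream | None]] = []

    if experiment == 1:
        order = ["narrow", "broad"] if seed % 2 == 0 else ["broad", "narrow"]
        for b, var in enumerate(order):
            cfg = replace(
                base_config, sigma_octaves=sigma[var], block_duration=780.0, seed=seed
            )
            seq = build_tone_sequence(
                cfg, seed=_child_seed(seed, 1, b), variance_condition=var, block_id=b
            )
            out.append((seq, None))
        return out

    cells = [
        (var, load) for var in ("narrow", "broad") for load in ("low", "high")
    ]
    # Latin-square rotation of the 4 cells, repeated over 4 rounds, keyed to seed.
    order = []
    for rnd in range(4):
        rot = (seed + rnd) % 4
        order.extend(cells[rot:] + cells[:rot])
    for b, (var, load) in enumerate(order):
        cfg = replace(
            base_config, sigma_octaves=sigma[var], block_duration=210.0, seed=seed
        )
        seq = build_tone_sequence(
            cfg,
            seed=_child_seed(seed, 2, b),
            variance_condition=var,
            load_condition=load,
            block_id=b,
        )
        n_level = 1 if load == "low" else 2
        # Enough letters to outlast the 210 s block at the minimum 1,400 ms gap.
        n_letters = int(np.ceil(210_000 / 1400)) + 1
        nback = build_nback_stream(n_level, n_letters, seed=_child_seed(seed, 3, b))
        out.append((seq, nback))
    return out


def events_table(sequences: Sequence[ToneSequence]) -> pd.DataFrame:
    """Flatten tone sequences to a BIDS-events-like table (onset in seconds)."""
    rows = []
    for seq in sequences:
        for e in seq.events:
            rows.append(
                {
                    "onset": e.onset / 1000.0,
                    "duration": seq.config.tone_duration / 1000.0,
                    "trial_type": e.role,
                    "frequency": e.frequency,
                    "block": e.block_id,
                    "variance": e.variance_condition,
                    "load": e.load_condition,
                }
            )
    return pd.DataFrame(rows)
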