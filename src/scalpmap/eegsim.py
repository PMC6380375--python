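"""Forward simulation of multichannel evoked EEG for the oddball paradigm.

The generative model is deliberately simple: each evoked component is a
Gaussian-windowed pulse in time with a fixed scalp topography (a smooth
radial falloff on the electrode sphere — no leadfield), scaled per trial by
condition-dependent gains, and summed with channel-correlated pink (1/f)
noise plus independent white sensor noise.  An MMN-like component carries
the effects of interest: its amplitude on oddball-probe trials is offset by
a surprise gain, further modulated by the variance context and, optionally,
by working-memory load.

Continuous recordings are written as 24-bit BDF (the native BioSemi format)
alongside a BIDS-like events TSV and an SFP electrode file, and read back
through MNE-Python.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .paradigm import ToneSequence

__all__ = [
    "Montage",
    "ErpTemplate",
    "EffectSpec",
    "ContinuousRecording",
    "load_montage",
    "default_templates",
    "component_waveform",
    "epoch_time_axis",
    "pink_noise",
    "noise_epochs",
    "simulate_epoch",
    "simulate_epochs",
    "simulate_recording",
    "write_recording",
    "read_recording",
]

FS = 1024.0  # Hz, acquisition rate
#: Epoch support at the acquisition rate: 128 samples (125 ms) before the
#: event and 512 samples (500 ms) after.  This margin is what lets polyphase
#: 25/128 resampling land exactly on the 5 ms output grid (see preproc).
EPOCH_PRE = 128
EPOCH_POST = 512
EPOCH_LEN = EPOCH_PRE + EPOCH_POST


def epoch_time_axis(fs: float = FS) -> np.ndarray:
    """Time axis in ms for a simulated epoch (event at t = 0)."""
    return (np.arange(EPOCH_LEN) - EPOCH_PRE) / fs * 1000.0


# ---------------------------------------------------------------------------
# Montage

@dataclass
class Montage:
    """64-channel 10-10 electrode set with unit-sphere positions."""

    labels: list[str]
    positions: np.ndarray  # (64, 3), unit norm

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            dupes = {l for l in self.labels if self.labels.count(l) > 1}
            raise ValueError(f"duplicate channel labels: {sorted(dupes)}")
        if len(self.labels) != 64:
            raise ValueError(f"expected 64 channels, got {len(self.labels)}")
        if "FCz" not in self.labels:
            raise ValueError("montage must include FCz")
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("positions must lie on the unit sphere")

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def write_sfp(self, path) -> None:
        with open(path, "w") as fh:
            for lab, (x, y, z) in zip(self.labels, self.positions):
                fh.write(f"{lab}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")


def _fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    # Algebraic least-squares sphere fit: |p|^2 = 2 c.p + (r^2 - |c|^2).
    A = np.hstack([2 * points, np.ones((len(points), 1))])
    b = (points**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    centre = sol[:3]
    radius = float(np.sqrt(sol[3] + centre @ centre))
    return centre, radius


def load_montage(coordinates_file=None) -> Montage:
    """Load the electrode montage.

    With no argument, builds the standard BioSemi 64-channel 10-10 montage
    from MNE's template positions.  Otherwise parses an SFP file
    (``label x y z`` per line).  Positions are re-centred on a best-fit
    sphere and normalised to unit radius.
    """
    import mne

    if coordinates_file is None:
        std = mne.channels.make_standard_montage("biosemi64")
        pos_map = std.get_positions()["ch_pos"]
        labels = list(std.ch_names)
        pos = np.array([pos_map[l] for l in labels])
    else:
        with open(coordinates_file) as fh:
            raw_labels = [
                line.split()[0]
                for line in fh
                if line.strip() and not line.startswith("#")
            ]
        if len(raw_labels) != len(set(raw_labels)):
            dupes = {l for l in raw_labels if raw_labels.count(l) > 1}
            raise ValueError(
                f"duplicate electrode labels in {coordinates_file}: {sorted(dupes)}"
            )
        custom = mne.channels.read_custom_montage(coordinates_file)
        pos_map = custom.get_positions()["ch_pos"]
        labels = list(custom.ch_names)
        pos = np.array([pos_map[l] for l in labels])

    centre, _ = _fit_sphere(pos)
    pos = pos - centre
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return Montage(labels=labels, positions=pos)


# ---------------------------------------------------------------------------
# Evoked components

@dataclass
class ErpTemplate:
    """One evoked component: a Gaussian pulse in time with a fixed topography.

    ``width`` is the full width at half maximum of the pulse in ms;
    ``topography`` holds one weight per montage channel with maximum
    magnitude 1 at the component's reference channel.
    """

    name: str
    peak_latency: float  # ms
    width: float  # ms, FWHM
    peak_amplitude: float  # microvolts at the reference channel
    topography: np.ndarray  # (n_channels,), max |w| == 1

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"width must be > 0, got {self.width}")
        m = np.max(np.abs(self.topography))
        if not np.isclose(m, 1.0):
            raise ValueError(f"topography max magnitude must be 1, got {m}")


def radial_topography(
    montage: Montage, centre_labels: tuple[str, ...] = ("Fz", "Cz"), width_rad: float = 0.9
) -> np.ndarray:
    """Smooth radial-falloff weights around the mean direction of some
    electrodes (fronto-central by default), normalised to max 1."""
    centre = montage.positions[[montage.index(l) for l in centre_labels]].mean(axis=0)
    centre /= np.linalg.norm(centre)
    angles = np.arccos(np.clip(montage.positions @ centre, -1.0, 1.0))
    w = np.exp(-((angles / width_rad) ** 2))
    return w / np.max(np.abs(w))


def default_templates(montage: Montage) -> list[ErpTemplate]:
    """Default three-component evoked response.

    A P1-like obligatory response, an MMN/N1-like fronto-central negativity
    (the carrier of the surprise effects) and a later P2, with latencies in
    the 75-250 ms range where auditory mismatch effects live.
    """
    fc = radial_topography(montage, ("Fz", "Cz"))
    cz = radial_topography(montage, ("Cz",))
    return [
        ErpTemplate("p1", 70.0, 80.0, 2.5, fc),
        ErpTemplate("mmn", 125.0, 60.0, -2.5, fc),
        ErpTemplate("p2", 230.0, 90.0, 1.5, cz),
    ]


def component_waveform(template: ErpTemplate, time_axis: np.ndarray) -> np.ndarray:
    """Gaussian-windowed pulse: unit peak at the nominal latency times the
    template's peak amplitude."""
    t = np.asarray(time_axis, dtype=float)
    if t.ndim != 1 or (len(t) > 1 and np.any(np.diff(t) <= 0)):
        raise ValueError("time_axis must be 1-D and strictly increasing")
    sigma = template.width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return template.peak_amplitude * np.exp(
        -0.5 * ((t - template.peak_latency) / sigma) ** 2
    )


# ---------------------------------------------------------------------------
# Effects and noise

@dataclass
class EffectSpec:
    """Condition-dependent gains and the noise model.

    The MMN-like template's peak amplitude is offset, on oddball-probe
    trials only, by ``surprise_gain``, plus ``variance_gain`` in the
    narrow-variance context and ``load_gain`` under high working-memory
    load.  Negative gains make oddball responses more negative, the usual
    MMN polarity.  ``base_gain`` multiplies every template (1 = nominal).
    """

    base_gain: float = 1.0
    surprise_gain: float = -2.0  # microvolts, odd vs mean
    variance_gain: float = -1.0  # extra surprise in the narrow context
    load_gain: float = 0.0  # extra surprise under high load
    effect_template: str = "mmn"
    pink_exponent: float = 1.0
    pink_rms: float = 7.0  # microvolts per channel
    white_rms: float = 2.0  # microvolts per channel
    artifact_rate: float = 0.0
    n_noise_sources: int = 8  # shared sources making the pink noise spatially correlated

    def __post_init__(self) -> None:
        for g in (self.base_gain, self.surprise_gain, self.variance_gain, self.load_gain):
            if not np.isfinite(g):
                raise ValueError("gains must be finite")
        if self.pink_rms < 0 or self.white_rms < 0:
            raise ValueError("noise RMS must be >= 0")
        if not 0 <= self.artifact_rate < 1:
            raise ValueError(f"artifact_rate must be in [0, 1), got {self.artifact_rate}")

    def template_gain(self, template_name: str, role: str, variance: str, load: str) -> float:
        """Peak-amplitude offset (microvolts) added to a template in a condition."""
        if role not in ("contextual", "mean_probe", "oddball_probe"):
            raise ValueError(f"unknown role {role!r}")
        if variance not in ("narrow", "broad"):
            raise ValueError(f"unknown variance condition {variance!r}")
        if load not in ("none", "low", "high"):
            raise ValueError(f"unknown load condition {load!r}")
        if template_name != self.effect_template or role != "oddball_probe":
            return 0.0
        g = self.surprise_gain
        if variance == "narrow":
            g += self.variance_gain
        if load == "high":
            g += self.load_gain
        return g

    @classmethod
    def from_yaml(cls, path) -> "EffectSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def pink_noise(
    n_samples: int,
    n_series: int,
    rng: np.random.Generator,
    exponent: float = 1.0,
    fs: float = FS,
) -> np.ndarray:
    """(n_series, n_samples) of 1/f^exponent noise with unit RMS per series.

    Spectral shaping of white Gaussian noise; the DC bin is zeroed so each
    series is mean-free in expectation.
    """
    white = rng.standard_normal((n_series, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0
    shaped = np.fft.irfft(spec * shaping, n=n_samples, axis=-1)
    rms = np.sqrt(np.mean(shaped**2, axis=-1, keepdims=True))
    return shaped / rms


def _mixing_matrix(n_channels: int, n_sources: int, montage: Montage, rng) -> np.ndarray:
    """Spatially smooth source-to-channel mixing with unit row power."""
    dirs = rng.standard_normal((n_sources, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    angles = np.arccos(np.clip(montage.positions @ dirs.T, -1, 1))  # (ch, src)
    mix = np.exp(-((angles / 1.0) ** 2)) * rng.choice([-1, 1], size=(1, n_sources))
    mix /= np.sqrt((mix**2).sum(axis=1, keepdims=True))
    return mix


def _channel_noise(
    n_samples: int, montage: Montage, effects: EffectSpec, rng, fs: float = FS
) -> np.ndarray:
    """(channels, samples) correlated pink + independent white noise, microvolts."""
    nch = len(montage.labels)
    out = np.zeros((nch, n_samples))
    if effects.pink_rms > 0:
        sources = pink_noise(n_samples, effects.n_noise_sources, rng, effects.pink_exponent, fs)
        mix = _mixing_matrix(nch, effects.n_noise_sources, montage, rng)
        out += effects.pink_rms * (mix @ sources)
    if effects.white_rms > 0:
        out += effects.white_rms * rng.standard_normal((nch, n_samples))
    return out


def noise_epochs(
    n_trials: int,
    n_samples: int,
    montage: Montage,
    effects: EffectSpec,
    rng: np.random.Generator,
    fs: float = FS,
) -> np.ndarray:
    """(trials, channels, samples) of pure noise drawn from the epoch noise model."""
    flat = _channel_noise(n_trials * n_samples, montage, effects, rng, fs)
    return (
        flat.reshape(len(montage.labels), n_trials, n_samples).transpose(1, 0, 2).copy()
    )


def _evoked_epoch(
    templates: list[ErpTemplate],
    effects: EffectSpec,
    role: str,
    variance: str,
    load: str,
    time_axis: np.ndarray,
) -> np.ndarray:
    """Noise-free (channels, time) evoked response for one condition."""
    nch = len(templates[0].topography)
    epoch = np.zeros((nch, len(time_axis)))
    for tpl in templates:
        gain = effects.base_gain * tpl.peak_amplitude + effects.template_gain(
            tpl.name, role, variance, load
        )
        if gain == 0.0:
            continue
        wave = component_waveform(
            ErpTemplate(tpl.name, tpl.peak_latency, tpl.width, 1.0, tpl.topography),
            time_axis,
        )
        epoch += gain * tpl.topography[:, None] * wave[None, :]
    return epoch


def _artifact(
    shape: tuple[int, int], time_axis: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """A >100 microvolt slow excursion on a random channel subset."""
    nch, nt = shape
    amp = rng.uniform(150.0, 400.0) * rng.choice([-1.0, 1.0])
    centre = rng.uniform(time_axis[0], time_axis[-1])
    bump = np.exp(-0.5 * ((time_axis - centre) / 50.0) ** 2)
    ch = rng.integers(nch)
    weights = np.zeros(nch)
    weights[ch] = 1.0
    weights[max(0, ch - 2) : ch + 3] = np.maximum(weights[max(0, ch - 2) : ch + 3], 0.5)
    weights[ch] = 1.0
    return amp * weights[:, None] * bump[None, :]


def simulate_epoch(
    templates: list[ErpTemplate],
    effects: EffectSpec,
    condition: dict,
    seed: int,
    montage: Montage,
    fs: float = FS,
) -> np.ndarray:
    """One (channels, time) epoch at 1,024 Hz: evoked response + noise.

    ``condition`` needs keys ``role``, ``variance`` and (optionally) ``load``.
    Deterministic in seed.
    """
    rng = np.random.default_rng(seed)
    t = epoch_time_axis(fs)
    epoch = _evoked_epoch(
        templates,
        effects,
        condition["role"],
        condition["variance"],
        condition.get("load", "none"),
        t,
    )
    epoch = epoch + _channel_noise(len(t), montage, effects, rng, fs)
    if effects.artifact_rate > 0 and rng.random() < effects.artifact_rate:
        epoch = epoch + _artifact(epoch.shape, t, rng)
    return epoch


def simulate_epochs(
    templates: list[ErpTemplate],
    effects: EffectSpec,
    conditions: list[dict],
    seed: int,
    montage: Montage,
    fs: float = FS,
) -> np.ndarray:
    """(trials, channels, time) stack of epochs, one per condition dict.

    Noise is drawn in one vectorised pass, which is what makes the
    group-study simulations tractable; trial i of a call equals
    ``simulate_epoch`` only in distribution, not sample-for-sample.
    """
    rng = np.random.default_rng(seed)
    t = epoch_time_axis(fs)
    data = noise_epochs(len(conditions), len(t), montage, effects, rng, fs)
    cache: dict[tuple, np.ndarray] = {}
    for i, cond in enumerate(conditions):
        key = (cond["role"], cond["variance"], cond.get("load", "none"))
        if key not in cache:
            cache[key] = _evoked_epoch(templates, effects, *key, t)
        data[i] += cache[key]
        if effects.artifact_rate > 0 and rng.random() < effects.artifact_rate:
            data[i] += _artifact(data[i].shape, t, rng)
    return data


# ---------------------------------------------------------------------------
# Continuous recordings

@dataclass
class ContinuousRecording:
    """Continuous multichannel voltage trace with its event list."""

    data: np.ndarray  # (channels, samples), microvolts
    fs: float
    events: pd.DataFrame  # columns: sample, onset (s), trial_type, frequency, variance, load, block
    montage: Montage
    seed: int = 0

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs


def simulate_recording(
    sequence: ToneSequence,
    templates: list[ErpTemplate],
    effects: EffectSpec,
    montage: Montage,
    seed: int,
    fs: float = FS,
) -> ContinuousRecording:
    """Continuous block recording: background noise + evoked response at
    every tone onset, with ``artifact_rate`` of trials contaminated by a
    >100 microvolt excursion."""
    if len(sequence) == 0:
        raise ValueError("tone sequence is empty")
    rng = np.random.default_rng(seed)
    onsets_ms = sequence.onsets()
    event_samples = np.round(onsets_ms / 1000.0 * fs).astype(int)
    if len(event_samples) > 1 and np.min(np.diff(event_samples)) < EPOCH_POST:
        raise ValueError("events closer than the evoked-response support would overlap")

    # Recording length = number of tone slots times the SOA (the block length).
    soa_ms = sequence.config.soa
    n_samples = int(round(len(sequence) * soa_ms / 1000.0 * fs))
    data = _channel_noise(n_samples, montage, effects, rng, fs)

    t_post = np.arange(EPOCH_POST) / fs * 1000.0  # evoked support, 0..500 ms
    t_epoch = epoch_time_axis(fs)
    cache: dict[tuple, np.ndarray] = {}
    rows = []
    for ev, s in zip(sequence.events, event_samples):
        key = (ev.role, ev.variance_condition, ev.load_condition)
        if key not in cache:
            cache[key] = _evoked_epoch(templates, effects, *key, t_post)
        hi = min(s + EPOCH_POST, n_samples)
        data[:, s:hi] += cache[key][:, : hi - s]
        if effects.artifact_rate > 0 and rng.random() < effects.artifact_rate:
            art = _artifact((data.shape[0], len(t_epoch)), t_epoch, rng)
            lo = s - EPOCH_PRE
            a0, a1 = max(-lo, 0), EPOCH_LEN - max(lo + EPOCH_LEN - n_samples, 0)
            data[:, max(lo, 0) : lo + a1] += art[:, a0:a1]
        rows.append(
            {
                "sample": int(s),
                "onset": ev.onset / 1000.0,
                "trial_type": ev.role,
                "frequency": ev.frequency,
                "variance": ev.variance_condition,
                "load": ev.load_condition,
                "block": ev.block_id,
            }
        )
    return ContinuousRecording(
        data=data, fs=fs, events=pd.DataFrame(rows), montage=montage, seed=seed
    )


# ---------------------------------------------------------------------------
# BDF + sidecar I/O

# Symmetric digital range: decoding gain (phys range / dig range) is then the
# exact inverse of the encoding scale and the offset vanishes.
_DIG_MAX = 2**23 - 1
_DIG_MIN = -(2**23 - 1)


def _bdf_paths(path: str | os.PathLike) -> tuple[str, str, str, str]:
    base = str(path)
    if base.endswith(".bdf"):
        base = base[:-4]
    return base + ".bdf", base + "_events.tsv", base + ".sfp", base + ".json"


def write_recording(rec: ContinuousRecording, path) -> str:
    """Write a recording as 24-bit BDF + events TSV + SFP montage + sidecar.

    Voltages are quantised to the 24-bit digital range over a symmetric
    physical range just covering the data, so the round-trip error is below
    one quantisation step.  Returns the BDF path.
    """
    bdf_path, ev_path, sfp_path, meta_path = _bdf_paths(path)
    nch, n_samples = rec.data.shape
    spr = int(round(rec.fs))  # one-second data records
    n_records = int(np.ceil(n_samples / spr))
    padded = np.zeros((nch, n_records * spr))
    padded[:, :n_samples] = rec.data

    # Physical range fields are 8 ASCII chars; one decimal place always fits.
    phys_max = np.ceil(max(1.0, float(np.max(np.abs(rec.data))) * 1.01) * 10) / 10
    scale = _DIG_MAX / phys_max
    digital = np.clip(np.round(padded * scale), _DIG_MIN, _DIG_MAX).astype(np.int32)

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii")[:n]
        return b + b" " * (n - len(b))

    with open(bdf_path, "wb") as fh:
        fh.write(b"\xffBIOSEMI")
        fh.write(pad("simulated subject", 80))
        fh.write(pad("scalpmap synthetic recording", 80))
        fh.write(pad("01.01.00", 8))
        fh.write(pad("00.00.00", 8))
        fh.write(pad(str(256 * (nch + 1)), 8))
        fh.write(pad("24BIT", 44))
        fh.write(pad(str(n_records), 8))
        fh.write(pad("1", 8))
        fh.write(pad(str(nch), 4))
        for lab in rec.montage.labels:
            fh.write(pad(lab, 16))
        for _ in range(nch):
            fh.write(pad("Active electrode", 80))
        for _ in range(nch):
            fh.write(pad("uV", 8))
        for _ in range(nch):
            fh.write(pad(f"{-phys_max:.1f}", 8))
        for _ in range(nch):
            fh.write(pad(f"{phys_max:.1f}", 8))
        for _ in range(nch):
            fh.write(pad(str(_DIG_MIN), 8))
        for _ in range(nch):
            fh.write(pad(str(_DIG_MAX), 8))
        for _ in range(nch):
            fh.write(pad("HP:DC LP:none", 80))
        for _ in range(nch):
            fh.write(pad(str(spr), 8))
        for _ in range(nch):
            fh.write(pad("", 32))
        # Records: channel-blocked 24-bit little-endian two's complement.
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            u = block.astype(np.int64) & 0xFFFFFF
            raw = np.empty((nch, spr, 3), dtype=np.uint8)
            raw[..., 0] = u & 0xFF
            raw[..., 1] = (u >> 8) & 0xFF
            raw[..., 2] = (u >> 16) & 0xFF
            fh.write(raw.tobytes())

    rec.events.to_csv(ev_path, sep="\t", index=False)
    rec.montage.write_sfp(sfp_path)
    with open(meta_path, "w") as fh:
        json.dump({"n_samples": n_samples, "fs": rec.fs, "seed": rec.seed}, fh)
    return bdf_path


def _check_bdf_intact(bdf_path: str) -> None:
    size = os.path.getsize(bdf_path)
    if size < 256:
        raise IOError(f"{bdf_path}: truncated BDF (no full header)")
    with open(bdf_path, "rb") as fh:
        header = fh.read(256)
    try:
        n_records = int(header[236:244].decode("ascii").strip())
        nch = int(header[252:256].decode("ascii").strip())
        header_bytes = int(header[184:192].decode("ascii").strip())
    except ValueError as err:
        raise IOError(f"{bdf_path}: corrupt BDF header") from err
    with open(bdf_path, "rb") as fh:
        fh.seek(256 + 216 * nch)
        spr_field = fh.read(8 * nch)
    try:
        spr = int(spr_field[:8].decode("ascii").strip())
    except ValueError as err:
        raise IOError(f"{bdf_path}: corrupt BDF signal header") from err
    expected = header_bytes + n_records * nch * spr * 3
    if size != expected:
        raise IOError(
            f"{bdf_path}: corrupt or truncated BDF ({size} bytes, expected {expected})"
        )


def read_recording(path) -> ContinuousRecording:
    """Read a recording written by :func:`write_recording`."""
    import mne

    bdf_path, ev_path, sfp_path, meta_path = _bdf_paths(path)
    _check_bdf_intact(bdf_path)
    raw = mne.io.read_raw_bdf(bdf_path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # Volts -> microvolts
    with open(meta_path) as fh:
        meta = json.load(fh)
    data = data[:, : meta["n_samples"]]
    events = pd.read_csv(ev_path, sep="\t")
    montage = load_montage(sfp_path)
    order = [raw.ch_names.index(l) for l in montage.labels]
    return ContinuousRecording(
        data=data[order],
        fs=float(raw.info["sfreq"]),
        events=events,
        montage=montage,
        seed=int(meta["seed"]),
    )
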