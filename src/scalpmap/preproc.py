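"""Preprocessing chain: continuous recording -> clean baseline-corrected epochs.

The chain runs in a fixed order — epoch, downsample to 200 Hz, band-pass
0.50-40 Hz, artifact thresholding at 100 microvolts, baseline correction
over -100..0 ms — and the config validator refuses any re-ordering.  The
default output grid is 101 samples spanning -100..+400 ms in 5 ms steps.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import h5py
import numpy as np
import pandas as pd
from scipy import signal

from .eegsim import ContinuousRecording

__all__ = [
    "PreprocConfig",
    "EpochSet",
    "epoch_continuous",
    "resample_epochs",
    "bandpass_filter",
    "reject_artifacts",
    "baseline_correct",
    "preprocess",
    "write_epochs",
    "read_epochs",
]

#: Canonical stage order; PreprocConfig refuses permutations of it.
STAGES = ("epoch", "resample", "filter", "reject", "baseline")

#: Epoching margin (ms before window start / after window end) used by the
#: full chain so that filtering and polyphase resampling transients fall
#: outside the reported window.  25 ms pre keeps the -125 ms margin start on
#: an exact 1,024 Hz sample AND on the 5 ms output grid of the -100 ms
#: window start; the window is cropped back after filtering.
MARGIN_PRE_MS = 25.0
MARGIN_POST_MS = 99.0


@dataclass(frozen=True)
class PreprocConfig:
    epoch_window: tuple[float, float] = (-100.0, 400.0)  # ms
    target_rate: float = 200.0  # Hz
    band: tuple[float, float] = (0.50, 40.0)  # Hz
    artifact_threshold: float = 100.0  # microvolts
    baseline_window: tuple[float, float] = (-100.0, 0.0)  # ms
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        lo, hi = self.epoch_window
        if not lo < 0 < hi:
            raise ValueError(f"epoch window must straddle 0, got {self.epoch_window}")
        f_lo, f_hi = self.band
        if not 0 < f_lo < f_hi < self.target_rate / 2:
            raise ValueError(
                f"band {self.band} invalid for target rate {self.target_rate}"
            )
        if self.artifact_threshold <= 0:
            raise ValueError("artifact threshold must be > 0")
        if tuple(self.stages) != STAGES:
            raise ValueError(
                f"preprocessing stages must run in the order {STAGES}, got {self.stages}"
            )


@dataclass
class EpochSet:
    """Trials x channels x time voltage data with trial metadata.

    ``rejected`` marks trials excluded from averaging; their voltages are
    kept untouched so rejection is non-destructive.
    """

    data: np.ndarray  # (trials, channels, samples), microvolts
    fs: float
    time: np.ndarray  # ms, per sample
    channels: list[str]
    trials: pd.DataFrame  # per-trial metadata incl. trial_type/variance/load
    rejected: np.ndarray  # (trials,) bool
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.data.shape[0]
        if len(self.trials) != n or len(self.rejected) != n:
            raise ValueError("trial metadata/rejection mask length mismatch")
        if self.data.shape[2] != len(self.time):
            raise ValueError("time axis length mismatch")

    @property
    def n_retained(self) -> int:
        return int((~self.rejected).sum())

    def copy_with(self, **kw) -> "EpochSet":
        base = dict(
            data=self.data,
            fs=self.fs,
            time=self.time,
            channels=self.channels,
            trials=self.trials,
            rejected=self.rejected,
            log=list(self.log),
        )
        base.update(kw)
        return EpochSet(**base)


def epoch_continuous(
    rec: ContinuousRecording, window: tuple[float, float]
) -> EpochSet:
    """Cut one epoch per event at the acquisition rate.

    Epoch sample 0 sits at ``event_sample + round(window[0] * fs / 1000)``;
    the end sample is included.  Events without full window support are
    dropped (counted in the log).
    """
    w0, w1 = window
    start = round(w0 * rec.fs / 1000.0)
    stop = round(w1 * rec.fs / 1000.0)  # inclusive
    n_samp = stop - start + 1
    time = (np.arange(n_samp) + start) / rec.fs * 1000.0

    keep_rows, slabs = [], []
    n_total = rec.data.shape[1]
    for _, row in rec.events.iterrows():
        s = int(row["sample"])
        if s + start < 0 or s + stop >= n_total:
            continue
        keep_rows.append(row)
        slabs.append(rec.data[:, s + start : s + stop + 1])
    n_dropped = len(rec.events) - len(keep_rows)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} events without full epoch support")
    if not keep_rows:
        raise ValueError("no events with full epoch support")
    data = np.stack(slabs)
    trials = pd.DataFrame(keep_rows).reset_index(drop=True)
    log = [f"epoch: {len(keep_rows)} epochs cut, {n_dropped} dropped at edges"]
    return EpochSet(
        data=data,
        fs=rec.fs,
        time=time,
        channels=list(rec.montage.labels),
        trials=trials,
        rejected=np.zeros(len(keep_rows), dtype=bool),
        log=log,
    )


def _snap_to_grid(time: np.ndarray, step_ms: float) -> np.ndarray:
    """Snap a resampled time axis onto the nominal output grid when the
    residual offset (from non-integer sample alignment of the source grid)
    is below half a source sample."""
    t0 = time[0]
    snapped0 = np.round(t0 / step_ms) * step_ms
    if abs(snapped0 - t0) < step_ms / 2:
        return snapped0 + np.arange(len(time)) * step_ms
    return time


def resample_epochs(epochs: EpochSet, target: float) -> EpochSet:
    """Anti-aliased polyphase resampling (25/128 for 1,024 -> 200 Hz)."""
    if target > epochs.fs:
        raise ValueError(f"target {target} Hz above source rate {epochs.fs}")
    if target == epochs.fs:
        return epochs
    frac = Fraction(target / epochs.fs).limit_denominator(10_000)
    up, down = frac.numerator, frac.denominator
    out = signal.resample_poly(epochs.data, up, down, axis=2)
    step = 1000.0 / target
    time = _snap_to_grid(epochs.time[0] + np.arange(out.shape[2]) * step, step)
    log = epochs.log + [f"resample: {epochs.fs:g} -> {target:g} Hz ({up}/{down})"]
    return epochs.copy_with(data=out, fs=float(target), time=time, log=log)


#: Reflect padding per epoch edge before zero-phase filtering.
FILTER_PAD = 100


def bandpass_filter(epochs: EpochSet, band: tuple[float, float]) -> EpochSet:
    """Two zero-phase order-2 Butterworth passes: high-pass then low-pass.

    Each pass runs forward and backward (squaring the magnitude response),
    with symmetric-reflect padding to tame edge transients on short epochs.
    """
    lo, hi = band
    nyq = epochs.fs / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band {band} invalid at fs {epochs.fs} (Nyquist {nyq})")
    padlen = min(FILTER_PAD, epochs.data.shape[2] - 1)
    out = epochs.data
    for btype, edge in (("highpass", lo), ("lowpass", hi)):
        sos = signal.butter(2, edge, btype=btype, fs=epochs.fs, output="sos")
        out = signal.sosfiltfilt(sos, out, axis=2, padtype="even", padlen=padlen)
    log = epochs.log + [f"filter: zero-phase Butterworth HP {lo:g} Hz, LP {hi:g} Hz"]
    return epochs.copy_with(data=out, log=log)


def reject_artifacts(epochs: EpochSet, threshold: float) -> EpochSet:
    """Flag trials whose absolute voltage strictly exceeds the threshold on
    any channel/sample.  Retained voltages are untouched."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    bad = np.abs(epochs.data).max(axis=(1, 2)) > threshold
    rejected = epochs.rejected | bad
    log = epochs.log + [
        f"reject: {int(bad.sum())} trials exceed {threshold:g} microvolts "
        f"({int(rejected.sum())} rejected total)"
    ]
    return epochs.copy_with(rejected=rejected, log=log)


def baseline_correct(epochs: EpochSet, window: tuple[float, float]) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    w0, w1 = window
    sel = (epochs.time >= w0) & (epochs.time <= w1)
    if not sel.any():
        raise ValueError(f"baseline window {window} contains no samples")
    if w0 < epochs.time[0] - 1e-9 or w1 > epochs.time[-1] + 1e-9:
        raise ValueError(f"baseline window {window} outside epoch")
    base = epochs.data[:, :, sel].mean(axis=2, keepdims=True)
    log = epochs.log + [f"baseline: mean over {w0:g}..{w1:g} ms subtracted"]
    return epochs.copy_with(data=epochs.data - base, log=log)


def _crop(epochs: EpochSet, window: tuple[float, float]) -> EpochSet:
    sel = (epochs.time >= window[0] - 1e-9) & (epochs.time <= window[1] + 1e-9)
    return epochs.copy_with(data=epochs.data[:, :, sel], time=epochs.time[sel])


def preprocess(rec: ContinuousRecording, config: PreprocConfig | None = None) -> EpochSet:
    """Full chain in the canonical order; see module docstring."""
    if config is None:
        config = PreprocConfig()
    margin_window = (
        config.epoch_window[0] - MARGIN_PRE_MS,
        config.epoch_window[1] + MARGIN_POST_MS,
    )
    epochs = epoch_continuous(rec, margin_window)
    epochs = resample_epochs(epochs, config.target_rate)
    epochs = bandpass_filter(epochs, config.band)
    epochs = _crop(epochs, config.epoch_window)
    epochs = reject_artifacts(epochs, config.artifact_threshold)
    epochs = baseline_correct(epochs, config.baseline_window)
    return epochs


def preprocess_epochs(epochs: EpochSet, config: PreprocConfig | None = None) -> EpochSet:
    """The same chain starting from already-cut wide epochs (the epoch-level
    simulation route): resample -> filter -> crop -> reject -> baseline."""
    if config is None:
        config = PreprocConfig()
    epochs = resample_epochs(epochs, config.target_rate)
    epochs = bandpass_filter(epochs, config.band)
    epochs = _crop(epochs, config.epoch_window)
    epochs = reject_artifacts(epochs, config.artifact_threshold)
    epochs = baseline_correct(epochs, config.baseline_window)
    return epochs


# ---------------------------------------------------------------------------
# HDF5 container

def write_epochs(epochs: EpochSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip", compression_opts=1)
        f.create_dataset("time", data=epochs.time)
        f.create_dataset("rejected", data=epochs.rejected)
        f.attrs["fs"] = epochs.fs
        f.attrs["channels"] = json.dumps(epochs.channels)
        f.attrs["trials"] = epochs.trials.to_json(orient="records")
        f.attrs["log"] = json.dumps(epochs.log)


def read_epochs(path) -> EpochSet:
    from io import StringIO

    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            time=f["time"][()],
            channels=json.loads(f.attrs["channels"]),
            trials=pd.read_json(StringIO(f.attrs["trials"]), orient="records"),
            rejected=f["rejected"][()].astype(bool),
            log=json.loads(f.attrs["log"]),
        )
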