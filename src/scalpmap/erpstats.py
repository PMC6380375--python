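"""Single-channel ERP statistics.

Condition averaging, the unbiased zero-crossing rule for picking the
analysis time window, fully-crossed within-subject ANOVAs on window-mean
amplitudes, paired t-tests, one-sample effect size and the matching
noncentral-t power/sample-size calculation.

All factors here have two levels, so every ANOVA effect reduces to a
one-sample t-test of a per-subject contrast value and ``F = t**2`` with
df = (1, n - 1); that identity is also what the tests assert.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import stats

from .preproc import EpochSet

__all__ = [
    "Erp",
    "TimeWindow",
    "AnovaResult",
    "average_erp",
    "grand_mean_erp",
    "select_time_window",
    "window_mean_amplitude",
    "contrast_weights",
    "rm_anova",
    "paired_t",
    "cohen_d",
    "power_one_sample_t",
    "required_sample_size",
]


@dataclass
class Erp:
    """Channels x time average over the retained trials of one condition."""

    data: np.ndarray  # (channels, samples), microvolts
    time: np.ndarray  # ms
    channels: list[str]
    fs: float
    condition: str
    n_trials: int

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channels.index(label)]


@dataclass(frozen=True)
class TimeWindow:
    start: float  # ms
    end: float  # ms

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end}]")


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df: tuple[int, int]
    p: float


def _condition_mask(trials: pd.DataFrame, condition: dict | str) -> np.ndarray:
    if isinstance(condition, str):
        return (trials["trial_type"] == condition).to_numpy()
    mask = np.ones(len(trials), dtype=bool)
    for col, val in condition.items():
        mask &= (trials[col] == val).to_numpy()
    return mask


def average_erp(epochs: EpochSet, condition: dict | str) -> Erp:
    """Arithmetic mean over retained trials matching a condition.

    ``condition`` is either a trial_type string or a dict of metadata-column
    constraints, e.g. ``{"trial_type": "oddball_probe", "variance": "narrow"}``.
    """
    mask = _condition_mask(epochs.trials, condition) & ~epochs.rejected
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"no retained trials for condition {condition!r}")
    return Erp(
        data=epochs.data[mask].mean(axis=0),
        time=epochs.time,
        channels=list(epochs.channels),
        fs=epochs.fs,
        condition=str(condition),
        n_trials=n,
    )


def grand_mean_erp(erps: list[Erp]) -> Erp:
    """Unweighted mean across condition ERPs (and, stacked across subjects,
    across participants) — the all-condition average that the window
    selection rule operates on."""
    if not erps:
        raise ValueError("no ERPs to average")
    data = np.mean([e.data for e in erps], axis=0)
    ref = erps[0]
    return Erp(
        data=data,
        time=ref.time,
        channels=ref.channels,
        fs=ref.fs,
        condition="grand_mean",
        n_trials=sum(e.n_trials for e in erps),
    )


def select_time_window(grand_mean: Erp, channel: str = "FCz") -> TimeWindow:
    """Window of interest = span between the first two post-onset zero
    crossings of the all-condition grand mean.

    A crossing is a strict sign change between consecutive samples,
    timestamped at the earlier sample; a sample that is exactly zero counts
    as one crossing at its own time.  Only crossings strictly after
    stimulus onset qualify.  Because the input is the mean over ALL
    conditions, the choice is orthogonal to any condition contrast.
    """
    wave = grand_mean.channel(channel)
    time = grand_mean.time
    post = time >= 0
    w, t = wave[post], time[post]
    crossings: list[float] = []
    i = 0
    while i < len(w) - 1 and len(crossings) < 2:
        if w[i] == 0.0:
            if t[i] > 0:
                crossings.append(float(t[i]))
            i += 1
            continue
        if np.sign(w[i]) != np.sign(w[i + 1]) and w[i + 1] != 0.0 and t[i] > 0:
            crossings.append(float(t[i]))
        i += 1
    if len(w) and w[-1] == 0.0 and t[-1] > 0 and len(crossings) < 2:
        crossings.append(float(t[-1]))
    if len(crossings) < 2:
        raise ValueError(
            f"grand mean at {channel} crosses zero {len(crossings)} time(s) after "
            "onset; need two crossings to define a window"
        )
    return TimeWindow(start=crossings[0], end=crossings[1])


def window_mean_amplitude(erp: Erp, channel: str, window: TimeWindow) -> float:
    """Mean voltage over samples with start <= t <= end at one channel."""
    sel = (erp.time >= window.start) & (erp.time <= window.end)
    if not sel.any():
        raise ValueError(f"window {window} contains no samples")
    return float(erp.channel(channel)[sel].mean())


# ---------------------------------------------------------------------------
# Within-subject inference

def contrast_weights(factors: list[str], effect: str) -> pd.DataFrame:
    """+/-1/n coding of a main effect or interaction over the crossed cells.

    Cells are the full crossing of the 2-level factors, each factor's levels
    coded +1 (first level) / -1 (second level); an interaction's cell code
    is the product of its factors' codes, scaled so the contrast value is a
    difference of cell-mean averages (weights sum to zero, positive half
    sums to one).
    """
    levels = {
        "surprise": ["oddball_probe", "mean_probe"],
        "variance": ["narrow", "broad"],
        "load": ["low", "high"],
    }
    for f in factors:
        if f not in levels:
            raise ValueError(f"unknown factor {f!r}")
    names = effect.split(":")
    if any(n not in factors for n in names):
        raise ValueError(f"effect {effect!r} not within factors {factors}")
    rows = []
    for combo in product(*(levels[f] for f in factors)):
        cell = dict(zip(factors, combo))
        code = 1.0
        for n in names:
            code *= 1.0 if cell[n] == levels[n][0] else -1.0
        rows.append({**cell, "weight": code})
    df = pd.DataFrame(rows)
    df["weight"] /= (len(df) / 2.0)
    return df


def _cell_key(cell: dict, factors: list[str]) -> tuple:
    return tuple(cell[f] for f in factors)


def rm_anova(cell_means: pd.DataFrame, factors: list[str]) -> list[AnovaResult]:
    """Within-subject ANOVA over fully-crossed 2-level factors.

    ``cell_means`` needs one row per subject x cell with columns ``subject``,
    ``amplitude`` and one column per factor.  Every effect is tested as a
    one-sample t of the per-subject contrast value, reported as
    F = t^2 with df = (1, n - 1).
    """
    subjects = sorted(cell_means["subject"].unique())
    if len(subjects) < 3:
        raise ValueError(f"need >= 3 subjects, got {len(subjects)}")
    n_cells = 2 ** len(factors)
    pivot = cell_means.set_index(["subject"] + factors)["amplitude"]
    results = []
    effects = [
        ":".join(c)
        for r in range(1, len(factors) + 1)
        for c in combinations(factors, r)
    ]
    for effect in effects:
        w = contrast_weights(factors, effect)
        contrasts = np.empty(len(subjects))
        for i, subj in enumerate(subjects):
            vals = []
            for _, row in w.iterrows():
                key = (subj,) + _cell_key(row, factors)
                try:
                    vals.append(row["weight"] * pivot.loc[key])
                except KeyError:
                    raise ValueError(
                        f"subject {subj!r} missing cell {dict(row[factors])}"
                    ) from None
            contrasts[i] = np.sum(vals)
        sd = contrasts.std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero-variance contrast for effect {effect!r}")
        n = len(subjects)
        t = contrasts.mean() / (sd / np.sqrt(n))
        F = t * t
        p = float(stats.f.sf(F, 1, n - 1))
        results.append(AnovaResult(effect=effect, F=float(F), df=(1, n - 1), p=p))
    if len(subjects) * n_cells != len(cell_means):
        raise ValueError("cell_means does not contain exactly one row per subject x cell")
    return results


def paired_t(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, int, float]:
    """Classical paired t-test; returns (t, df, two-sided p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-D arrays with n >= 2")
    d = a - b
    if d.std(ddof=1) == 0:
        if np.allclose(d, 0):
            return 0.0, len(d) - 1, 1.0
        raise ValueError("zero-variance differences: t undefined")
    t, p = stats.ttest_rel(a, b)
    return float(t), len(a) - 1, float(p)


def cohen_d(contrast_values: np.ndarray) -> float:
    """One-sample Cohen's d: mean / sample standard deviation (ddof = 1)."""
    x = np.asarray(contrast_values, dtype=float)
    if len(x) < 2:
        raise ValueError("need n >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation: d undefined")
    return float(x.mean() / sd)


def power_one_sample_t(d: float, n: int, alpha: float) -> float:
    """Power of the two-sided one-sample t-test at effect size d."""
    df = n - 1
    if df < 1:
        return 0.0
    tcrit = stats.t.isf(alpha / 2.0, df)
    nc = d * np.sqrt(n)
    main = stats.nct.sf(tcrit, df, nc)
    # Far-tail term is <= ~1e-16 whenever d > 0; scipy's nct.cdf can return
    # NaN there, in which case it is dropped.
    other = stats.nct.cdf(-tcrit, df, nc)
    if not np.isfinite(other):
        other = 0.0
    return float(main + other)


def required_sample_size(
    d: float, alpha: float, power: float, n_max: int = 100_000
) -> int:
    """Smallest n whose two-sided one-sample noncentral-t power meets the
    target."""
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    if d <= 0:
        raise ValueError("d must be > 0")
    for n in range(2, n_max + 1):
        if power_one_sample_t(d, n, alpha) >= power:
            return n
    raise ValueError(f"power {power} not reachable with n <= {n_max}")
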