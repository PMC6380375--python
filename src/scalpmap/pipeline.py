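"""Study-scale simulation drivers: simulated experiments end to end.

These helpers run the generative model through the analysis chain at the
group level — simulate per-trial epochs for every subject and condition
cell, preprocess them, average, convert to spatiotemporal volumes and
collect FCz window amplitudes — plus reduced-fidelity shortcuts used by the
calibration studies (type-I error and model-recovery simulations), which
draw condition-average data directly from the same noise model instead of
averaging thousands of individual trials.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import bayesmap, eegsim, erpstats, preproc, stmap
from .eegsim import EffectSpec, ErpTemplate, Montage

__all__ = [
    "StudyResult",
    "exp_cells",
    "cell_name",
    "standard_contrast",
    "simulate_subject_epochs",
    "run_group_study",
    "null_anova_rejection_rate",
    "simulate_noise_erp",
    "simulate_null_contrast_volumes",
    "simulate_cell_volumes",
]

#: Between-subject multiplicative jitter (s.d.) on the effect gains.
SUBJECT_GAIN_JITTER = 0.1


def exp_cells(design: str) -> list[tuple[str, str, str]]:
    """(role, variance, load) cells of a design: 'exp1' (2x2) or 'exp2' (2x2x2)."""
    roles = ("oddball_probe", "mean_probe")
    variances = ("narrow", "broad")
    if design == "exp1":
        return [(r, v, "none") for r in roles for v in variances]
    if design == "exp2":
        return [(r, v, l) for r in roles for v in variances for l in ("low", "high")]
    raise ValueError(f"unknown design {design!r}")


def cell_name(cell: tuple[str, str, str]) -> str:
    role, var, load = cell
    short = "odd" if role == "oddball_probe" else "mean"
    return f"{short}_{var}" if load == "none" else f"{short}_{var}_{load}"


def standard_contrast(name: str, design: str) -> stmap.ContrastSpec:
    """Canonical contrasts over the design cells, as cell-mean differences."""
    cells = exp_cells(design)
    weights: dict[str, float] = {}
    for cell in cells:
        role, var, load = cell
        s = 1.0 if role == "oddball_probe" else -1.0
        v = 1.0 if var == "narrow" else -1.0
        l = 1.0 if load == "high" else -1.0
        if name == "surprise":
            w = s
        elif name == "surprise_x_variance":
            w = s * v
        elif name == "surprise_x_load":
            if design != "exp2":
                raise ValueError("surprise_x_load needs the 2x2x2 design")
            w = s * l
        else:
            raise ValueError(f"unknown contrast {name!r}")
        weights[cell_name(cell)] = w / (len(cells) / 2.0)
    return stmap.ContrastSpec(name=name, weights=weights)


def _subject_effects(effects: EffectSpec, rng: np.random.Generator) -> EffectSpec:
    scale = max(0.0, 1.0 + SUBJECT_GAIN_JITTER * rng.standard_normal())
    return replace(
        effects,
        surprise_gain=effects.surprise_gain * scale,
        variance_gain=effects.variance_gain * scale,
        load_gain=effects.load_gain * scale,
    )


def simulate_subject_epochs(
    cells: list[tuple[str, str, str]],
    n_trials_per_cell: int,
    templates: list[ErpTemplate],
    effects: EffectSpec,
    montage: Montage,
    seed: int,
    config: preproc.PreprocConfig | None = None,
) -> preproc.EpochSet:
    """Simulate and preprocess one subject's trial epochs over the cells."""
    conditions = [
        {"role": r, "variance": v, "load": l}
        for (r, v, l) in cells
        for _ in range(n_trials_per_cell)
    ]
    data = eegsim.simulate_epochs(templates, effects, conditions, seed, montage)
    trials = pd.DataFrame(
        {
            "trial_type": [c["role"] for c in conditions],
            "variance": [c["variance"] for c in conditions],
            "load": [c["load"] for c in conditions],
        }
    )
    wide = preproc.EpochSet(
        data=data,
        fs=eegsim.FS,
        time=eegsim.epoch_time_axis(),
        channels=list(montage.labels),
        trials=trials,
        rejected=np.zeros(len(conditions), dtype=bool),
    )
    return preproc.preprocess_epochs(wide, config)


@dataclass
class StudyResult:
    """Everything downstream inference consumes from one simulated study."""

    design: str
    cells: list[tuple[str, str, str]]
    cell_volumes: list[dict[str, stmap.StVolume]]  # per subject, keyed by cell_name
    cell_amplitudes: pd.DataFrame  # subject, surprise, variance, load, amplitude
    window: erpstats.TimeWindow
    grid: stmap.ScalpGrid
    montage: Montage

    def contrast_volumes(self, contrast: stmap.ContrastSpec) -> list[stmap.StVolume]:
        return [stmap.subject_contrast(v, contrast) for v in self.cell_volumes]

    def bayes_cell_volumes(self) -> list[dict[tuple[str, str, str], stmap.StVolume]]:
        return [
            {cell: vols[cell_name(cell)] for cell in self.cells}
            for vols in self.cell_volumes
        ]


def run_group_study(
    design: str,
    n_subjects: int,
    n_trials_per_cell: int,
    effects: EffectSpec | None = None,
    templates: list[ErpTemplate] | None = None,
    montage: Montage | None = None,
    seed: int = 0,
    smooth: bool = True,
    channel: str = "FCz",
) -> StudyResult:
    """Simulate a full group study and run it through the analysis chain.

    Per subject: trial epochs for every cell -> preprocessing -> condition
    ERPs -> smoothed spatiotemporal volumes and FCz window amplitudes.  The
    analysis window is the zero-crossing window of the grand mean across
    subjects and conditions, selected before any contrast is formed.
    """
    if montage is None:
        montage = eegsim.load_montage()
    if templates is None:
        templates = eegsim.default_templates(montage)
    if effects is None:
        effects = EffectSpec()
    cells = exp_cells(design)
    grid = stmap.project_montage(montage)
    root = np.random.SeedSequence(seed)
    subj_seeds = root.generate_state(n_subjects) % (2**31)
    jitter_rng = np.random.default_rng(root.spawn(1)[0])

    all_erps: list[list[erpstats.Erp]] = []
    cell_volumes: list[dict[str, stmap.StVolume]] = []
    for s in range(n_subjects):
        eff_s = _subject_effects(effects, jitter_rng)
        epochs = simulate_subject_epochs(
            cells, n_trials_per_cell, templates, eff_s, montage, int(subj_seeds[s])
        )
        erps = [
            erpstats.average_erp(
                epochs, {"trial_type": r, "variance": v, "load": l}
            )
            for (r, v, l) in cells
        ]
        all_erps.append(erps)
        vols = {}
        for cell, erp in zip(cells, erps):
            vol = stmap.build_volume(erp, grid)
            vol.subject = f"sub-{s:02d}"
            if smooth:
                vol = stmap.smooth_volume(vol)
            vols[cell_name(cell)] = vol
        cell_volumes.append(vols)

    grand = erpstats.grand_mean_erp([e for erps in all_erps for e in erps])
    window = erpstats.select_time_window(grand, channel)

    rows = []
    for s, erps in enumerate(all_erps):
        for cell, erp in zip(cells, erps):
            rows.append(
                {
                    "subject": s,
                    "surprise": cell[0],
                    "variance": cell[1],
                    "load": cell[2],
                    "amplitude": erpstats.window_mean_amplitude(erp, channel, window),
                }
            )
    return StudyResult(
        design=design,
        cells=cells,
        cell_volumes=cell_volumes,
        cell_amplitudes=pd.DataFrame(rows),
        window=window,
        grid=grid,
        montage=montage,
    )


# ---------------------------------------------------------------------------
# Reduced-fidelity calibration shortcuts

def _window_noise_amplitudes(
    n: int,
    rng: np.random.Generator,
    effects: EffectSpec,
    n_samples: int = 101,
    fs: float = 200.0,
    window: tuple[int, int] = (40, 51),
) -> np.ndarray:
    """n window-mean amplitudes of single-channel trial noise (pink + white)."""
    pink = eegsim.pink_noise(n_samples * n, 1, rng, effects.pink_exponent, fs)
    traces = effects.pink_rms * pink.reshape(n, n_samples)
    traces += effects.white_rms * rng.standard_normal((n, n_samples))
    return traces[:, window[0] : window[1]].mean(axis=1)


def null_anova_rejection_rate(
    n_experiments: int,
    n_subjects: int,
    n_trials_per_cell: int,
    seed: int,
    alpha: float = 0.05,
    effects: EffectSpec | None = None,
    design: str = "exp1",
) -> pd.DataFrame:
    """Type-I error of the FCz window ANOVA under the no-effect null.

    Each simulated experiment draws trial noise at the reference channel
    from the generative noise model, averages it into subject x cell window
    amplitudes and runs the within-subject ANOVA.  Returns the rejection
    rate per effect over the experiments.
    """
    if effects is None:
        effects = EffectSpec()
    cells = exp_cells(design)
    factors = ["surprise", "variance"] + (["load"] if design == "exp2" else [])
    rng = np.random.default_rng(seed)
    counts: dict[str, int] = {}
    for _ in range(n_experiments):
        rows = []
        for s in range(n_subjects):
            for cell in cells:
                amps = _window_noise_amplitudes(n_trials_per_cell, rng, effects)
                rows.append(
                    {
                        "subject": s,
                        "surprise": cell[0],
                        "variance": cell[1],
                        "load": cell[2],
                        "amplitude": amps.mean(),
                    }
                )
        for res in erpstats.rm_anova(pd.DataFrame(rows), factors):
            counts.setdefault(res.effect, 0)
            counts[res.effect] += int(res.p < alpha)
    return pd.DataFrame(
        [
            {"effect": e, "rejection_rate": c / n_experiments, "n_experiments": n_experiments}
            for e, c in counts.items()
        ]
    )


def simulate_noise_erp(
    montage: Montage,
    effects: EffectSpec,
    rng: np.random.Generator,
    n_trials: int = 1,
    n_samples: int = 101,
    fs: float = 200.0,
) -> erpstats.Erp:
    """Condition-average of pure noise: one channel-noise draw scaled by
    1/sqrt(n_trials), standing for the average of n_trials noise epochs."""
    data = eegsim._channel_noise(n_samples, montage, effects, rng, fs) / np.sqrt(n_trials)
    time = -100.0 + 5.0 * np.arange(n_samples)
    return erpstats.Erp(
        data=data, time=time, channels=list(montage.labels), fs=fs,
        condition="noise", n_trials=n_trials,
    )


def simulate_null_contrast_volumes(
    n_subjects: int,
    grid: stmap.ScalpGrid,
    montage: Montage,
    effects: EffectSpec,
    rng: np.random.Generator,
    n_trials: int = 100,
    smooth: bool = True,
) -> list[stmap.StVolume]:
    """Subject contrast volumes under the null: smoothed noise-only averages."""
    out = []
    for _ in range(n_subjects):
        erp = simulate_noise_erp(montage, effects, rng, n_trials)
        vol = stmap.build_volume(erp, grid)
        if smooth:
            vol = stmap.smooth_volume(vol)
        out.append(vol)
    return out


def simulate_cell_volumes(
    design: str,
    n_subjects: int,
    grid: stmap.ScalpGrid,
    montage: Montage,
    templates: list[ErpTemplate],
    effects: EffectSpec,
    rng: np.random.Generator,
    n_trials: int = 100,
    smooth: bool = True,
) -> list[dict[tuple[str, str, str], stmap.StVolume]]:
    """Per-subject condition-average volumes drawn directly at the average
    level: deterministic evoked response per cell plus averaged noise.

    The reduced-fidelity counterpart of :func:`run_group_study` (no trial
    loop, no preprocessing) used by the model-comparison calibrations.
    """
    cells = exp_cells(design)
    time = -100.0 + 5.0 * np.arange(101)
    out = []
    for s in range(n_subjects):
        eff_s = _subject_effects(effects, rng)
        vols = {}
        for cell in cells:
            evoked = eegsim._evoked_epoch(templates, eff_s, *cell, time)
            noise = eegsim._channel_noise(len(time), montage, effects, rng, 200.0)
            erp = erpstats.Erp(
                data=evoked + noise / np.sqrt(n_trials),
                time=time,
                channels=list(montage.labels),
                fs=200.0,
                condition=cell_name(cell),
                n_trials=n_trials,
            )
            vol = stmap.build_volume(erp, grid)
            vol.subject = f"sub-{s:02d}"
            if smooth:
                vol = stmap.smooth_volume(vol)
            vols[cell] = vol
        out.append(vols)
    return out
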