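# scalpmap

A simulation and analysis pipeline for probabilistic-oddball EEG experiments
on auditory statistical learning.

In these experiments a listener hears a stream of pure tones whose
frequencies are drawn from a Gaussian distribution in log-frequency
(centre 500 Hz, s.d. σ = 0.50 octaves in the *narrow* condition or 1.50
octaves in the *broad* condition, one tone every 500 ms). Ten percent of
tones are *mean probes* pinned to 500 Hz and ten percent are *oddball
probes* pinned two octaves above (2000 Hz). Because the probes are
physically identical across conditions, any difference in the evoked
response to oddball vs. mean probes (the *surprise* effect, an MMN-like
fronto-central negativity at ~100–250 ms), and any modulation of that
difference by the contextual variance (the *surprise × variance*
interaction), is a signature of the brain having learned the statistical
structure of the stream. A concurrent visual N-back task (1-back vs.
2-back) adds a *cognitive load* factor.

`scalpmap` provides every stage needed to study the statistics of this
design without human data:

| module | what it does |
| --- | --- |
| `scalpmap.paradigm` | tone-stream and N-back stream generation (exact probe proportions, pseudo-random placement, block schedules) |
| `scalpmap.eegsim` | forward simulation of 64-channel, 1,024 Hz recordings: Gaussian-pulse evoked components with fixed scalp topographies, condition-dependent gains, channel-correlated 1/f + white noise, artifact trials; 24-bit BDF + events TSV + SFP I/O |
| `scalpmap.preproc` | epoch (−100…400 ms) → downsample to 200 Hz → zero-phase Butterworth 0.50–40 Hz → reject \|v\| > 100 µV → baseline-correct (−100…0 ms) |
| `scalpmap.erpstats` | condition ERPs, the orthogonal zero-crossing window rule, within-subject ANOVA (every 2-level effect as F = t², df = (1, n−1)), paired t, Cohen's d, noncentral-t power/sample-size |
| `scalpmap.stmap` | 32×32×101 scalp×time volumes (azimuthal projection, barycentric interpolation, 8 mm × 8 mm × 20 ms FWHM smoothing), group one-sample t-maps, sign-flip max-statistic permutation FWE (peak and cluster-mass), small-volume correction with an orthogonality audit |
| `scalpmap.bayesmap` | voxelwise BIC model comparison: a Null model (surprise + surprise×variance regressors) vs. a Load×Surprise model (plus the surprise×load regressor), posterior probability maps under uniform model priors |
| `scalpmap.pipeline` | group-study drivers: simulate n subjects end to end, plus reduced-fidelity calibration shortcuts |

## The statistics at the core

For subject *s* and condition cell *c*, the window-mean amplitude
*y<sub>sc</sub>* at channel FCz enters a fully-crossed within-subject
ANOVA; each 2-level effect is tested through its per-subject contrast
*ℓ<sub>s</sub> = Σ<sub>c</sub> w<sub>c</sub> y<sub>sc</sub>* as a one-sample
t, reported as F = t² with df = (1, n−1). The analysis window is the span
between the first two post-onset zero crossings of the grand-mean ERP over
*all* conditions, which keeps its choice orthogonal to every contrast.

For whole-scalp inference each condition ERP is interpolated into a
32×32×101 scalp×time volume, contrast volumes are formed per subject, and
the group one-sample t-map *t(v) = ȳ(v) / (s(v)/√n)* is assessed with
sign-flip permutations: the maximum-|t| null distribution gives peak-level
family-wise-error p-values and the maximum cluster-mass null (clusters by
6-connectivity above a p < 0.001 two-sided forming threshold) gives
cluster-level ones.

Model comparison uses the BIC approximation to the log model evidence at
every voxel, ln *p(y|m)* ≈ −½(n ln(RSS/n) + k ln n), from OLS fits with
per-subject intercepts, converted to posterior probabilities under uniform
model priors.

## Worked example

Simulate a 10-subject study of the 2×2 (surprise × variance) design with 80
probe trials per cell and the default planted gains (surprise −2 µV,
surprise×variance −1 µV on the MMN-like component), then test both routes:

```python
from scalpmap import erpstats, pipeline, stmap

study = pipeline.run_group_study("exp1", n_subjects=10, n_trials_per_cell=80, seed=0)
print(f"analysis window: {study.window.start:g}-{study.window.end:g} ms")
for r in erpstats.rm_anova(study.cell_amplitudes, ["surprise", "variance"]):
    print(f"{r.effect:>20}: F({r.df[0]},{r.df[1]}) = {r.F:6.2f}, p = {r.p:.2e}")

contrast = pipeline.standard_contrast("surprise", "exp1")
volumes = study.contrast_volumes(contrast)
tmap, clusters = stmap.permutation_fwe(volumes, stmap.PermScheme(n_permutations=500, seed=1))
print(clusters.head(3).round(4).to_string(index=False))
```

prints

```
analysis window: 90-180 ms
            surprise: F(1,9) =  82.08, p = 8.09e-06
            variance: F(1,9) =  16.47, p = 2.85e-03
   surprise:variance: F(1,9) =  22.04, p = 1.13e-03
 cluster   peak_t  peak_x  peak_y  peak_time_ms  extent  p_fwe_peak  p_fwe_cluster
       1 -12.7939      15      18         135.0    1988      0.0080         0.0080
       2  -5.6514       9      12         215.0      17      0.3533         0.3892
```

The zero-crossing rule lands on a 90–180 ms window bracketing the planted
MMN-like negativity; the ANOVA recovers the surprise main effect and the
surprise×variance interaction; and the permutation map localises the
surprise effect to a fronto-central cluster (pixel (15, 18) is the
projected FCz location, and the planted component peaks at 125 ms) with a
negative peak t — odd minus mean is a negativity — at peak- and
cluster-level FWE p = 0.008, while the runner-up noise cluster stays far
from significance.

A command-line interface mirrors the file-based workflow
(`scalpmap stimgen | simulate | preproc | erpstats | stmap | bayesmap`);
run `scalpmap --help` for details.

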