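# Methods

This note documents the generative model behind `scalpmap`'s simulations,
the analysis conventions, the parameters that matter (with defaults and
reasons), and what the validation suite does and does not establish.

## Stimulus paradigm

A block is a regular train of 50 ms pure tones, one per 500 ms slot
(stimulus-onset asynchrony). Tone roles per block are fixed exactly at the
design proportions: `round(n·0.10)` mean probes (500 Hz), the same number
of oddball probes (2000 Hz = two octaves above the centre), and the
remainder contextual tones with i.i.d. base-2 log frequencies
N(0, σ²) around the 500 Hz centre, σ = 0.50 octaves (narrow) or 1.50
(broad). "Pseudo-random" probe placement is made concrete with two
constraints the source design leaves open: no probe in the first five
slots of a block, and no two probes in adjacent slots, so every probe is
preceded by local context. Contextual tones may fall arbitrarily close to
probe frequencies — probes are meant to be indistinguishable from
contextual draws, so no exclusion zone is applied.

Block schedules: experiment 1 is two 780 s blocks (1,560 slots each;
narrow/broad order counterbalanced by seed parity); experiment 2 is
sixteen 210 s blocks (420 slots), four per variance × load cell, ordered by
a seed-rotated Latin square. The N-back letter stream uses a 20-consonant
alphabet, 400 ms display, 1,000 ms inter-stimulus interval plus uniform
0–500 ms jitter, and a 25 % target rate; alphabet and target rate are
config-exposed assumptions (the design specifies neither). All randomness
derives from one master seed through fixed `SeedSequence` splitting, so
every artefact is a pure function of (config, seed).

## Forward model of the evoked EEG

Each trial's evoked response is a sum of components; each component is a
Gaussian pulse in time (parameterised by peak latency, FWHM and peak
amplitude in µV) times a fixed topography over the 64 electrodes. No
head-model or leadfield is simulated: topographies are radial-falloff
weights `exp(-(θ/0.9)²)` of the angular distance θ to a centre direction on
the unit electrode sphere, normalised to 1 at the nearest electrode.
Defaults (chosen to echo the component structure of auditory evoked
responses and the early fronto-central latencies at which mismatch effects
are reported):

| component | peak | FWHM | amplitude | topography centre |
| --- | --- | --- | --- | --- |
| p1 | 70 ms | 80 ms | +2.5 µV | Fz–Cz midpoint |
| mmn | 125 ms | 60 ms | −2.5 µV | Fz–Cz midpoint (max at FCz) |
| p2 | 230 ms | 90 ms | +1.5 µV | Cz |

The `mmn` component carries the condition effects: on oddball-probe trials
its peak amplitude is offset by the surprise gain (default −2.0 µV), plus
the variance-interaction gain in the narrow context (−1.0 µV) and the load
gain under high load (0 by default; set negative to plant a load ×
surprise interaction). The p1 pulse is deliberately broad and early so the
all-condition grand mean rises clearly away from zero soon after onset —
otherwise the zero-crossing window rule (below) can latch onto
noise wiggles in the flat pre-p1 segment.

Noise is channel-correlated pink noise plus independent white sensor
noise: eight shared 1/f sources (exponent 1.0) mixed to channels through
spatially smooth random weights, at 7 µV RMS per channel, plus 2 µV RMS
white noise. This puts the single-trial surprise effect at an SNR of
roughly 0.3 at FCz — calibrated so that detection at the published study
scale (19 subjects, ~150 probe trials per cell) is comfortable while a
single subject's single trial is far below threshold, the regime these
paradigms live in. Between-subject variability is a multiplicative jitter
(s.d. 0.1) on the effect gains. Artifact trials (optional rate) receive a
150–400 µV slow Gaussian excursion on a small channel neighbourhood, sized
to survive the band-pass and trip the 100 µV rejection threshold.

Continuous recordings place the evoked response at every tone onset over a
continuous noise background; recording length equals slots × SOA. Files
are written as 24-bit BDF with a symmetric digital range (so the decoding
gain is the exact inverse of the encoding scale; round-trip error is below
half a quantisation step), read back through MNE-Python, with events as a
TSV table and the montage as SFP. The default montage is MNE's standard
64-channel BioSemi 10-10 set, re-centred by an algebraic sphere fit and
normalised to the unit sphere. The amplifier's analog band pass
(0.16–100 Hz) is not modelled.

## Preprocessing

The chain runs in a fixed order — epoch, downsample, filter, reject,
baseline — and the config validator refuses re-orderings. Conventions:

* **Epoching.** Window edges in ms are converted to sample offsets by
  rounding at 1,024 Hz, end sample included. The full chain epochs with a
  25 ms pre / 99 ms post margin so filter and resampler transients fall
  outside the reported −100…400 ms window (the margin start, −125 ms, is
  both an exact 1,024 Hz sample and on the 5 ms output grid).
* **Resampling.** Polyphase 25/128 (1,024 → 200 Hz) with the scipy Kaiser
  anti-aliasing design. The output axis is snapped onto the nominal 5 ms
  grid when the residual offset is below half a source sample; the final
  window is 101 samples, −100…400 ms inclusive.
* **Filtering.** "Band-pass 0.50–40 Hz" is implemented as two separate
  zero-phase passes — an order-2 Butterworth high-pass at 0.50 Hz, then an
  order-2 low-pass at 40 Hz — each run forward and backward (squared
  magnitude response) with 100-sample symmetric-reflect padding per edge.
* **Artifact rejection.** A trial is flagged when any channel sample
  strictly exceeds 100 µV in absolute value (a sample at exactly 100 µV is
  retained). Absolute, not peak-to-peak, thresholding is used; flagged
  trials keep their voltages and are only excluded from averaging.
* **Baseline.** Per trial and channel, the mean over −100…0 ms is
  subtracted.

## Single-channel statistics

The analysis window is the span between the first two zero crossings,
strictly after stimulus onset, of the grand-mean ERP at FCz averaged over
all conditions *and* participants (participant-level averaging is an
assumption; the selection is orthogonal to every condition contrast and a
label-permutation test asserts it). A crossing is a strict sign change
between consecutive samples, timestamped at the earlier sample; an exactly
zero sample counts once at its own time. Fewer than two crossings is an
error, not a fallback.

All ANOVA factors are 2-level, so each effect is the one-sample t of a
per-subject contrast (weights ±1/(cells/2), i.e. differences of cell-mean
averages), reported as F = t² with df = (1, n−1); sphericity machinery is
moot. p-values are two-sided throughout. Cohen's d is the one-sample
mean/s.d. of subject contrast values. `required_sample_size` finds the
smallest n whose two-sided one-sample noncentral-t power reaches the
target; scipy's far-tail `nct.cdf` NaNs are treated as zero (the term is
≤ 1e−16 there). Note that at (d = 1.06, α = 10⁻⁴) this two-sided
calculation gives n = 28 and 35 for 80 % and 95 % power; published figures
derived from such settings depend on tool conventions (notably sidedness)
that are rarely stated, and no particular pair of values is asserted.

## Spatiotemporal maps

Electrodes are projected azimuthal-equidistantly (vertex to grid centre,
polar angle to planar radius) onto a 32×32 grid, scaled so the outermost
ring spans a 28-pixel disc; taking that disc as 180 mm of scalp gives
6.43 mm per pixel, which converts the 8 mm spatial FWHM to 1.24 pixels
(the grid-to-millimetre correspondence is a recorded assumption). Frames
are linear barycentric interpolations on the Delaunay triangulation of the
projected electrodes; the mask is the convex hull plus the one-pixel rind
needed so every electrode's rounded pixel is inside, filled by
nearest-electrode values. One frame per 5 ms bin stacks into a 32×32×101
volume; smoothing is separable Gaussian at 8 mm × 8 mm × 20 ms FWHM,
renormalised by the smoothed mask so constants are preserved at edges.

Group inference is a voxelwise one-sample t across subject contrast
volumes (zero-variance voxels get ±∞ sentinels and a flag). Family-wise
error is controlled by sign-flip permutation — not random-field theory,
whose smoothness estimation on these 2D+time volumes is under-specified —
with the identity flip included, so the smallest attainable p is
1/(n_permutations + 1): peak-level p from the max-|t| null, cluster-level
p from the max cluster-mass null at a two-sided p < 0.001 forming
threshold, clusters by 6-connectivity in (x, y, t). Requesting more
permutations than the 2ⁿ unique flips enumerates them all with a warning;
below 100 permutations a granularity warning fires. Small-volume
correction restricts the same machinery to a mask and refuses masks whose
source contrast is not orthogonal (weight inner product ≠ 0) to the tested
one.

## Bayesian model maps

Two group-level models are compared at every voxel over the stacked
subject × cell data of the 2×2×2 design: Null (surprise and
surprise×variance effect codes) and Load×Surprise (those plus
surprise×load). Both include per-subject intercepts; the balanced design
makes all effect columns mutually orthogonal. Log evidence is the BIC
approximation −½(n ln(RSS/n) + k ln n) from a single stacked OLS fit (a
fixed-effects group scheme; random-effects model frequencies are out of
scope), and posteriors assume uniform model priors with max-subtraction
against overflow. Voxels that every model fits essentially perfectly
(RSS < 10⁻¹²) carry no comparative information and are forced to uniform
posteriors. The per-time-bin summary reports the fraction of masked voxels
where each model's posterior exceeds 0.5; the overall winner needs a mean
posterior above 0.5, otherwise none is declared.

## Validation scales and what passing shows

The calibration studies in the test suite run at reduced scales chosen to
keep the full suite in the minutes range: type-I error of the FCz ANOVA
over 500 null experiments (8 subjects, 20 trials per cell, trial noise
drawn from the generative noise model at the reference channel); null
permutation FWE over 200 experiments (8 subjects, 300 permutations,
noise-only condition averages); planted-effect recovery in one full
19-subject, 150-trials-per-cell study (the published scale); Bayesian
self-consistency over 50 runs of 8 subjects with condition averages drawn
directly at the average level (deterministic evoked response + noise/√n)
rather than by averaging simulated trials. The trial-level and
average-level routes share the same evoked and noise model; the shortcut
skips preprocessing, which the full-chain tests cover separately.

Passing these tests shows the pipeline is statistically calibrated and
recovers what the generator plants *under the generator's assumptions*:
Gaussian component pulses, fixed topographies, stationary 1/f + white
noise, no eye or muscle artifacts beyond threshold-tripping excursions, no
bad channels, no inter-subject latency or topography variability. Real
recordings violate all of these to some degree, so results here bound what
the analysis can do on clean data rather than certify performance on human
EEG.

## Known limitations

* No source-space modelling anywhere; topographies are phenomenological.
* The BDF writer supports the subset of the format this pipeline produces
  (one data record per second, identical rate on all channels, no status
  channel or annotations).
* `simulate_epochs` draws noise in one vectorised pass, so a trial in a
  batch does not reproduce `simulate_epoch` sample-for-sample at the same
  seed (distributions are identical).
* Between-subject variability is a single gain scale; latency and
  topography jitter are not modelled, which makes group localisation
  slightly sharper than it would be on real data.
* Random-field-theory FWE, ICA/EOG correction, bad-channel interpolation,
  re-referencing and audio rendering are out of scope.
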