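# Methods

## Model

The simulator is a four-sheet firing-rate network of the
gain-control/adaptation/laterally-connected (GCAL) family. Sheets live in a
common visual coordinate frame; a sheet of density *d* and half-extent *r*
holds a (2*rd*)² grid of units at spacing 1/*d*. V1 spans a unit square at
density 48; the LGN On/Off sheets (density 24) are enlarged by the LGN→V1
connection radius and the retina (density 24) by the retina→LGN kernel radius,
so no feedforward field is ever truncated. Lateral fields are truncated at the
V1 edge and renormalized per unit.

One stimulus presentation (one *iteration*, nominal duration 1.0 ≈ 250 ms in
20 steps of δt = 0.05 ≈ 12.5 ms) proceeds:

1. **Retina.** The luminance image χ ∈ [0, 1] is sampled on the retina grid.
2. **LGN.** Each channel computes a linear difference-of-Gaussians drive
   (center and surround lobes each of unit volume, so uniform input gives
   exactly zero; the Off kernel is the negated On kernel), scales it by γ_L,
   half-rectifies, and divides by `k + γ_S · pool`, where `pool` is a Gaussian
   spatial average (σ_pool, truncated, edge-renormalized) of the channel's own
   rectified drive. Output is clipped to [0, 1]. This divisive normalization
   is the contrast gain control: response ratios across contrasts are
   compressed relative to the γ_S = 0 (linear) case.
3. **V1 settling.** The afferent drive γ_A Σ ψ·η (per-unit connection fields
   jointly normalized over both channels) is computed once and held fixed.
   The first V1 response is afferent-only; then 17 recurrent steps (the
   t+0.15…t+0.95 window) apply narrow lateral excitation and wide lateral
   inhibition: η ← f(aff + γ_E Σ ψ_E η − γ_I Σ ψ_I η), with
   f(x) = clip(x − θ, 0, 1) a piecewise-linear output function with per-unit
   adaptive threshold θ (a smooth logistic option exists behind
   `output_fn="logistic"` but is not the default). Updates are synchronous.
4. **Learning.** Every plastic projection (afferent, lateral inhibitory;
   lateral excitatory only when its rate is raised from the default 0) takes
   one Hebbian step with the final settled activity:
   w ← w + α·pre·post, then each target unit's weight vector (jointly across
   On/Off for the afferent projection) is renormalized to unit sum. Per-unit
   weight sums are therefore exactly 1 after every iteration.
5. **Homeostasis.** ȳ ← (1−β)·η + β·ȳ and θ ← θ + λ(ȳ − μ), driving each
   unit's long-run mean activity toward the target μ.

### Parameters

All tunables live in `gcalsim.config` and are pure scalars, so perturbation
experiments are reversible dotted-path overrides. The architectural constants
(sheet densities 24/24/48, DoG kernel radius 0.375, afferent radius 0.27083,
lateral excitatory/inhibitory radii 0.104/0.22917, settle window of 17 steps,
the 10,000 + 10,000-iteration protocol, afferent learning rate 0.01 with 0.03
as its "tripled" value, excitatory learning rate 0 with 0.01/0.2 as raised
values) follow the published model class this package reimplements. The
remaining scalars are not published at full precision; they were calibrated
once against the model class's documented baseline behavior — peak spatial
frequency sensitivity roughly midway between the 1.5 and 6 cycles/image test
stimuli; mean V1 activation to the 80%-contrast gratings near 0.03 (low SF)
and 0.14 (medium SF) with maxima near 0.5–0.6; a smooth orientation map whose
activation-weighted tuning histogram peaks at π/2 with near-zero excess
kurtosis — and then frozen:

| parameter | value | role |
|---|---|---|
| DoG σ_c / σ_s | 0.030 / 0.120 | LGN passband (peak ≈ 3.2 c/img) |
| γ_L, k | 2.33, 0.11 | LGN gain and saturation constant |
| γ_S, σ_pool (radius) | 5.0, 0.15 (0.25) | gain-control strength and pool width |
| γ_A, γ_E, γ_I | 1.5, 1.7, 1.4 | afferent / lateral gains |
| lateral σ_E / σ_I | 0.020 / 0.075 | initial lateral Gaussian widths |
| α_A, α_E, α_I | 0.01, 0.0, 0.3 | Hebbian rates (per connection field) |
| μ, λ, β, θ₀ | 0.019, 0.01, 0.991, 0.15 | homeostasis |
| blob σ_minor, aspect | 0.0442, 4.67 | training stimuli |

Two conventions matter when comparing with other implementations. First,
σ values here are standard deviations; implementations that state "sizes"
typically mean 2σ. Second, learning rates are per connection field: the
per-connection Hebbian step is α·`LEARNING_RATE_UNIT`/P with P the field size
and `LEARNING_RATE_UNIT` = 10, which makes rates independent of sheet density
and sets the development timescale so that mature maps emerge within ~10⁴
iterations at the baseline rates. Rate *ratios* (e.g. the tripled afferent
rate) are unaffected.

The gain-control pool width deserves a note: with σ_pool = 0.15 the pool
tracks the wide stripes of the 1.5 c/img grating (suppressing it divisively)
but averages across the fine stripes of the 6 c/img grating, which is the
mechanism behind the strong low-SF/medium-SF asymmetry of the baseline model
(mean activation ≈ 0.027 vs ≈ 0.16 at 80% contrast).

## Synthetic stimuli

Training images are pairs of elongated Gaussian blobs, positions uniform over
the retina bounds, orientations uniform over [0, π), summed and capped at
luminance 1. Test images are sinusoidal gratings
I = 0.5 + (c/2)·sin(2πf·u + φ) with contrast c defined as the fraction of the
[0, 1] range. These two families emulate, respectively, generic oriented
visual experience during development and the psychophysical grating batteries
used to measure contrast sensitivity. What they do *not* emulate: natural
image statistics (broadband spectra, occlusion, correlations across scales),
luminance noise, temporal structure, and eye movements. Passing tests
therefore show that the *mechanisms* behave as described under controlled
drive, not that the model quantitatively predicts responses to natural
stimuli.

## Measurement

Measurement never mutates state (learning and homeostasis are simply not on
the read-out path). The contrast battery is 2 spatial frequencies × 5
contrasts of vertical gratings; mean/max/std activation is taken over **all**
V1 units. The orientation map battery is 8 orientations × 8 phases at 80%
contrast; per unit, responses are aggregated over phases by maximum and the
preference/selectivity computed by vector summation with doubled angles. The
tuning histogram weights each responsive unit's preference by its activation
to the medium-SF 80% grating, in 36 bins of 5°; excess kurtosis (Fisher,
normal ⇒ 0) is computed on the activation-weighted sample of angles treated
as plain linear values. Bimodality is a declared heuristic — two local maxima
of at least 25% of the histogram peak whose separating trough falls below 80%
of the lower one — always reported next to the raw histogram so it cannot
silently gate a result.

## Perturbation protocols

Perturbations scale or set single resolved-config scalars between phases and
are logged with iteration stamps; nothing else changes, so applying and
inverting a perturbation restores the prior state exactly. The registry
contains the unmodified control (10,000 + 10,000 iterations), the chronic
best fit (γ_I × 0.90 and α_A × 3 after the first 10,000), the first-episode
best fit (retina→LGN and LGN→V1 strengths × 0.85), its 1,000-iteration acute
variant, the alternative models B–G, parameter-class sweeps (lateral
excitation/inhibition, homeostatic rate, excitatory learning rate, gain
control, afferent strength), and the sequential protocol: pretrain → FES
perturbation for 1,000 iterations → restore both afferent strengths to
baseline (keeping all learned weights, thresholds and traces) → chronic
perturbation for the remaining 9,000. Protocols sharing a seed share the
pretraining phase bit-exactly (a cached baseline state is forked), so
perturbation effects are isolated from stimulus-stream differences.

## Numerical choices

* Recurrent settling uses synchronous updates and a fixed 17-step window; the
  settled pattern changes by < 10⁻³ per unit over the final step in the
  trained model.
* The settle and Hebbian inner loops are numba-compiled (with numpy
  fallbacks); the lateral sums scatter from active units only, exploiting the
  sparsity of settled activity. Compiled loops use fastmath, so V1 settling
  validates its inputs and re-checks its output for finiteness, re-running a
  plain numpy settler to locate the failing step when something is wrong.
* Retina→LGN filtering and gain-control pooling use precomputed-FFT
  correlation; the retina is sized so the valid-mode output lands exactly on
  the LGN grid.
* Degenerate Hebbian normalization (a zero weight sum) keeps the previous
  weights and warns; it cannot occur from valid states (sums start at 1 and
  updates are nonnegative).
* Snapshots (HDF5) store config, weights, thresholds, traces, iteration and
  RNG state, and round-trip bit-exactly; one `numpy` PCG64 generator per run
  drives everything.

## Problem sizes

The acceptance script runs the full study conditions: full sheet geometry,
10,000 development + 10,000 perturbed iterations per protocol (1,000 + 9,000
for the sequential protocol), about ten minutes on one CPU. The test suite
uses the same full sheet geometry — the 6 c/img grating aliases on coarser
LGN grids, so densities are never reduced — with shortened 2,500 + 2,500
phases over five fixed seeds; the perturbation signatures are already
expressed at that horizon.

## Known limitations

* **Orientation selectivity is weaker than the published model's.** Mature
  maps here have median vector-sum selectivity ≈ 0.17 (best units ≈ 1.0, with
  clean oriented ON/OFF receptive fields), versus the sharp maps of the
  original implementation. Three documented consequences are accepted and
  left failing in the acceptance tests rather than papered over: median
  selectivity does not triple from its (noise-floor) untrained value;
  preferred orientations of the weakly selective subpopulation drift by more
  than the published < 10% fraction; and the chronic perturbation broadens
  tuning through elevated excess kurtosis but does not reproduce the
  published bimodal flank structure of the tuning histogram. Every
  calibration that sharpened selectivity broke one of the printed activation
  anchors, which were given priority.
* A single receptive-field size: peak SF sensitivity varies little across
  units, so absolute activation levels at the two test frequencies reflect
  the shared passband rather than a population of scales.
* One model run per seed; no trial-to-trial response noise. Stochasticity
  enters only through initial weights and the stimulus stream.
* The LGN stage abstracts the whole retino-geniculate cascade; separate
  excitatory/inhibitory populations, multiple cortical layers, direction
  selectivity and ocular dominance are out of scope.
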