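# Methods

This note documents the model behind `vsdikit`'s simulator, the conventions
of its quantification pipeline, the calibration of the defaults, and what the
synthetic studies do and do not demonstrate about real recordings.

## The forward model

**Signal components.** A Schaffer-collateral stimulus evokes two population
signals in the CA1 sheet: a fast glutamatergic depolarization and, after a
~5 ms synaptic delay, a slow GABA_A-mediated hyperpolarization (fIPSP). Both
are modelled as unit-peak difference-of-exponential transients,

    K(t) = (e^{-t/τ_decay} − e^{-t/τ_rise}) / peak,   t > 0,

with defaults τ_rise/τ_decay = 2/8 ms for the depolarization (total duration
~30 ms) and 15/70 ms for the hyperpolarization (duration above 5% of peak
~210 ms, in the observed 200–250 ms range). Only durations are constrained by
the phenomenology; the two-exponential shape is a modelling choice.

**Space.** Amplitude is uniform within each dorso-ventral layer band and
decays as `exp(−dist/λ)` along the proximo-distal axis, with distance in
multiples of the mean pixel side from the electrode column. λ = 180 µm places
the signal at the noise floor by ~500 µm, consistent with detectability up to
~300–400 µm and an indistinguishable-from-background distal region at
~531 µm. Margin (non-hippocampal) pixels carry no signal. Per-layer
hyperpolarization amplitudes default to 1.0 (pyramidal layer), 0.55 (oriens
and proximal radiatum) and 0.45 (distal radiatum): perisomatic inhibition
dominates, other layers are comparable and lower.

**Stimulus strength.** All amplitudes scale with a logistic input–output
factor `1/(1+exp(−(U−v50)/k))`, v50 = 7.5 V, k = 2 V, which exceeds 0.95 at
15 V and is flat between 15 and 20 V (the recording intensity).

**Transduction and noise.** Fluorescence is linear in voltage with inverted
sign, `F = F₀(1 − g·V)`; g = 0.0055 per voltage unit, F₀ = 8000 counts. Each
acquisition averages 15 sweeps (5 s apart, hence a 70 s acquisition window);
noise is additive Gaussian, homoscedastic, independent across pixels, frames
and sweeps (SD 104 counts per sweep). `sweep_noise="averaged"` draws the
sweep mean directly from its exact sampling distribution
(SD 104/√15) in one pass; the default `"per_sweep"` literally averages
fifteen draws. The two are identical in distribution; studies use the
single-pass form for speed. No bleaching, drift, or optical blurring is
modelled.

**Pharmacology.** Conditions are multiplicative switches: TTX zeroes both
components; PTX zeroes the hyperpolarization and scales the depolarization
by 2.5 (the disinhibition seen without ionotropic blockade, AUC ~3 → ~7.5);
CGP55845 changes nothing; CDP scales the hyperpolarization by 1.28
(5.7 → 7.3). fIPSP experiments are run with the ionotropic blockade
(`depol_scale = 0`) as an always-active *context* condition, while the drug
under test carries the protocol window — onset immediately after the last
baseline acquisition (an acquisition at exactly the onset timestamp is still
pre-drug), offset 10 minutes later.

**Plasticity.** DHPG-type conditions carry a per-layer potentiation
`(peak, half-life)`: the hyperpolarization amplitude is multiplied by
`1 + peak` while the drug is present and decays as
`1 + peak·2^{−(τ−offset)/half-life}` during washout. Defaults: proximal
radiatum +60% with 45 min half-life (largest and most persistent), pyramidal
layer and distal radiatum +30% / 12 min, oriens +15% / 12 min. mGlu5 or IP3
blockade before DHPG removes the potentiation entirely; mGlu5 blockade after
DHPG leaves it intact (induction vs maintenance). Magnitudes are free
calibration; the layer ordering and the induction logic are the constrained
part.

**Protocol.** Six baseline acquisitions at 0–20 min (4-min spacing), drug
from 20 to 30 min, thirteen washout acquisitions at 30–78 min. Acquisition
noise seeds are spawned deterministically from the configuration seed, so a
protocol is a pure function of (geometry, config, condition).

## Quantification conventions

- **ΔF·F⁻¹**: per-pixel baseline F₀ is the mean over all pre-stimulus frames
  (the window is configurable); the canonical sign is
  depolarization-positive, `s = −(F−F₀)/F₀`. With noise off this inverts the
  transduction exactly (`s = g·V` to ~1e-14).
- **Smoothing**: k×k mean filter, k ∈ {3, 5}, frame by frame. Edge pixels
  average over their in-grid neighbors only (shrinking window) rather than
  zero padding, so boundary pixels are not attenuated; the vendor software's
  edge rule is unknown, and this is a documented potential deviation.
  Repeated smoothing requires an explicit override.
- **ROIs**: one ROI per layer band (distal radiatum constructed by
  translating proximal radiatum ventrally), their union (whole CA1), n equal
  adjacent column blocks P/M/D starting at the electrode (width 6 px by
  default, back-computed from the printed 106/318/531 µm centers), and
  1×8-px measurement lines at the middle row of each parent — lower-middle
  row on ties, anchored at the electrode-side boundary for layers, centered
  on the columns for P/M/D (a centered line may overhang a 6-px parent by
  one column per side; it must stay on the grid). Background ROIs are
  translated copies of the signal ROI packed greedily into the margin,
  row-major, kept one pixel off the grid border because border pixels behave
  differently under the shrinking-window filter.
- **AUC**: hyperpolarization window = 200 ms starting at the first frame at
  or after stimulus + 5 ms (ceil rounding: 3 frames at 2.2 ms);
  depolarization window = 30 ms starting exactly one frame before the
  stimulus. The integral is taken over the piecewise-linear interpolant of
  the trace; *rectified* mode integrates |interpolant| exactly by splitting
  segments at zero crossings, *signed* mode integrates −trace (hyper) or
  +trace (depol). Rectified is the default because measured background AUCs
  are clearly positive, which only a folded integral produces from zero-mean
  noise. Units are %·ms.
- **Time courses**: baseline = mean AUC of the last four pre-drug
  acquisitions; washout = first acquisition alone ("time zero") then three
  bins of four, each at the mean timestamp of its members; all points as
  100·AUC/baseline.

## Estimator choice for amplitude recovery

The rectified AUC has a positive noise-floor bias: for a trace with signal
s(t) and noise SD ς, `E∫|s+n| ≥ ∫|s|`, with the excess largest where
|s| ≲ ς. Percent-of-baseline changes computed from rectified AUCs are
therefore attenuated toward 100%. The signed integral is unbiased under
zero-mean noise, so parameter-recovery analyses (and the
`potentiation_timecourses` helper) default to signed mode, while
pharmacology panels mirror the published rectified convention. A second,
real attenuation affects layer-resolved recovery: 3×3 smoothing mixes a
potentiated band with its unpotentiated neighbors, so a +50% amplitude step
in an 8-row band reads ~+45% at the ROI level even without noise. At default
noise, twelve slices recover the step at its first post-drug point to within
a few percent-of-baseline units.

## Calibration of defaults

Defaults were set analytically from the published anchor values before any
acceptance run: gain and layer amplitudes so the noise-free whole-CA1
rectified hyperpolarization AUC is ≈ 8 %·ms; the depolarization amplitude so
the 30-ms depolarization AUC is ≈ 3 %·ms (≈ 7.5 under PTX); the noise SD so
the background AUC is ≈ 25% of the whole-CA1 signal (published backgrounds
are 20–30% of baselines); F₀ = 8000 counts so 16-bit TIFF quantization
(±0.5 count) is negligible against the sweep-averaged noise (≈ 27 counts).
These anchors are calibration targets, not oracles — measured values move
with noise realizations and smoothing.

## Problem sizes

The default field of view is 66×76 pixels (CA1 = 32 rows × 24 columns,
four 8-row bands; the margin hosts three whole-CA1-shaped background ROIs).
Multi-slice studies use 12 slices; distinct slices differ only by their
noise seed (no biological variability in amplitudes — the panel statistics
are therefore noise-limited, which is the conservative case for the t
tests). The Monte-Carlo type-I calibration runs 1000 replicates of
7-vs-7-slice comparisons on a reduced 20×16-px grid with 128 frames,
chosen so the full pipeline — render, ΔF·F⁻¹, smoothing, trace, AUC, t
test — runs inside every replicate.

## What the synthetic studies do and do not show

Passing studies demonstrate that the pipeline's conventions are internally
consistent and that it recovers known ground truth under the stated noise
model. They do not validate the biology: real recordings have correlated
noise (shot noise scales with brightness, slow drifts, bleaching),
non-rectangular anatomy, staining gradients, trial-to-trial response
variability and slice-to-slice amplitude differences, none of which are
modelled. The simulator's amplitudes are in arbitrary voltage units tied to
the AUC calibration because absolute camera and voltage scales are not
published. Statistical wrappers delegate to scipy/statsmodels/pingouin; the
repeated-measures ANOVA applies no sphericity correction, and the mixed
treatment×time design reports the between-treatment effect as its primary
statistic.

## Degenerate inputs and numerical notes

Zero-variance samples in `compare` return explicit degenerate results
(statistic 0/p = 1 for identical samples, p = 0 flag for a constant nonzero
shift) instead of NaN; all-constant ANOVA groups return a flagged undefined
F. Empty ROIs, non-positive F₀, saturating gain·V ≥ 1, windows that leave
the recording, and protocols with the wrong acquisition counts raise typed
errors. AUC windows that start between samples are handled by interpolating
the trace at the window edges, so the integral is exact for the interpolant.
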