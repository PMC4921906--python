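# vsdikit

Simulation and quantification of voltage-sensitive-dye imaging (VSDI) of
GABAergic network activity in hippocampal CA1.

## Why

Extracellular electrodes cannot resolve where inhibition happens. VSDI can:
with a dye such as Di-4-ANEPPS, whose emission falls when the membrane
depolarizes, a stimulated hippocampal slice yields movies in which a
Schaffer-collateral shock appears as a fast (~30 ms) depolarizing transient
and — once ionotropic glutamatergic transmission is blocked — a slow
(200–250 ms) GABA_A-mediated hyperpolarization, a *field inhibitory
postsynaptic potential* (fIPSP). Quantifying that signal per anatomical layer
and per distance from the electrode, across a drug protocol, is a pipeline
with many small conventions (ΔF·F⁻¹ baseline, smoothing, ROI construction,
AUC windows, percent-of-baseline binning). `vsdikit` implements that pipeline
and pairs it with a forward simulator that produces frame stacks with known
ground truth, so every stage can be validated end to end.

## The model and the measurements

The simulator is phenomenological. The voltage at frame time *t*, row *r*,
column *c* is

    V(t,r,c) = io(U) · [ d·A_D·D(t) − h(ℓ)·A_H(ℓ)·pot(ℓ,τ)·H(t−t_on) ] · S(c)

where `D`, `H` are unit-peak difference-of-exponential transients (rise/decay
2/8 ms and 15/70 ms), `A_D`, `A_H(ℓ)` amplitudes per layer ℓ (largest in the
pyramidal layer), `S(c) = exp(−dist(c)/λ)` the decay along the proximo-distal
axis (λ = 180 µm), `io(U)` a logistic input–output factor that plateaus by
15–20 V, and `d`, `h(ℓ)`, `pot(ℓ,τ)` pharmacological multipliers (TTX, PTX,
CGP55845, CDP, DHPG ± antagonists) resolved at protocol time τ. The dye maps
voltage to counts as `F = F₀(1 − g·V)` plus Gaussian noise, averaged over 15
sweeps 5 s apart (a ~70 s acquisition).

The analysis side computes `s = −(F − F₀)/F₀` (depolarization-positive),
3×3 or 5×5 spatial smoothing with shrinking windows at edges, ROI traces in
percent, and windowed AUCs in %·ms: 200 ms starting ~5 ms after the stimulus
for hyperpolarization, 30 ms starting one frame before it for depolarization.
Drug experiments (6 baseline + 13 washout acquisitions, 4 min apart, 10 min
application) are normalized to the mean of the last four baseline AUCs and
binned 1 + 4 + 4 + 4 over washout.

## Worked example

```python
import vsdikit as vk

geometry = vk.default_geometry()            # 66 x 76 px of 33.3 x 37.5 um
print(geometry.pixel_side_mean)             # 35.4
print(vk.axis_center_distance_um(2, 6, 35.4))  # 531.0 (distal axis block)

cfg = vk.SimConfig()                        # calibrated defaults
stack = vk.simulate_acquisition(geometry, cfg, "ionotropic_block", seed=1)
dff = vk.smooth_spatial(vk.compute_dff(stack), 3)
rois = vk.layer_rois(geometry)
res = vk.auc(vk.extract_trace(dff, rois["whole_CA1"]), mode="hyper")
print(round(res.value, 2))                  # 6.72  (%.ms, one slice)

bgs = vk.background_rois(rois["whole_CA1"], geometry, n=3)
print(round(vk.background_auc(dff, bgs), 2))  # 1.59
```

The whole-CA1 rectified hyperpolarization AUC of a single simulated slice is
~7–8 %·ms against a background (same ROI translated outside the hippocampus,
mean of three copies) of ~1.5–2 %·ms — the noise floor is roughly a quarter
of the signal. A TTX acquisition collapses onto that floor; CDP raises the
signal by ~28%.

A full study — simulate every condition, quantify, test — is one call
(`vk.run_study(vk.RunConfig(), outdir)`) or one command:

```
vsdikit run-study --seed 1 --out study_out
```

## Layout

- `vsdikit.geometry` / `vsdikit.synthgen` — field-of-view model and forward
  simulator (conditions, protocol, sweep averaging).
- `vsdikit.preprocess` — ΔF·F⁻¹, spatial smoothing, ROI masking.
- `vsdikit.roi` — layer / axis / line / background ROI constructions, JSON
  serialization.
- `vsdikit.quantify` — traces, windowed AUCs, input–output curves,
  percent-of-baseline time courses, AUC distribution shares.
- `vsdikit.stats` — t tests and ANOVA wrappers with a uniform result schema.
- `vsdikit.io` / `vsdikit.study` / `vsdikit.cli` — TIFF+JSON formats, study
  orchestration, command-line interface.

See `docs/methods.md` for the modelling choices, calibration and limitations.
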