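"""Forward simulator of stimulus-evoked VSDI acquisitions.

The model is deliberately phenomenological (no conductances, no spiking):
a Schaffer-collateral shock evokes, in every CA1 layer, a fast depolarizing
transient (~30 ms) and, after a short synaptic delay, a slow GABA_A
hyperpolarization (~200-250 ms) whose amplitude is largest in the pyramidal
layer. Both components decay exponentially with distance from the stimulating
electrode along the proximo-distal axis and scale with stimulus strength
through a logistic input-output curve that plateaus by 15-20 V.

The dye transduction is linear and sign-inverting: depolarization *reduces*
Di-4-ANEPPS fluorescence. Each acquisition is the average of ``n_sweeps``
identical sweeps contaminated by independent Gaussian photon/readout noise.

Pharmacology enters as multiplicative switches on the two components plus an
optional layer-specific potentiation factor (mGlu5/IP3-dependent plasticity)
that decays exponentially in protocol time after drug washout begins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, ProtocolError, SaturationError
from .geometry import LAYER_LABELS, GeometryModel

__all__ = [
    "SimConfig",
    "Condition",
    "CONDITIONS",
    "get_condition",
    "compose",
    "io_scale",
    "unit_peak_kinetic",
    "voltage_field",
    "render_acquisition",
    "simulate_acquisition",
    "Protocol",
    "simulate_protocol",
    "FrameStack",
    "AcquisitionSeries",
]

#: Default peak hyperpolarization per layer (arbitrary voltage units).
#: Largest in the pyramidal layer, comparable lower values elsewhere.
DEFAULT_HYPER_AMP = {
    "str_oriens": 0.55,
    "pyr_layer": 1.0,
    "radt_prox": 0.55,
    "radt_dist": 0.45,
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the spatiotemporal voltage model and the acquisition.

    Amplitudes are in arbitrary voltage units; ``gain`` converts them to
    fractional fluorescence change. Defaults are calibrated so that the
    noise-free whole-CA1 rectified hyperpolarization AUC is ~8 %.ms, the
    30-ms depolarization AUC ~3 %.ms, and the background AUC ~25% of the
    whole-CA1 signal (see docs/methods.md).
    """

    depol_amp: float = 2.0
    depol_rise_ms: float = 2.0
    depol_decay_ms: float = 8.0
    hyper_amp_by_layer: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HYPER_AMP)
    )
    hyper_onset_ms: float = 5.0
    hyper_rise_ms: float = 15.0
    hyper_decay_ms: float = 70.0
    spatial_decay_len_um: float = 180.0
    gain: float = 0.0055
    f0: float = 8000.0
    noise_sd: float = 104.0
    n_sweeps: int = 15
    sweep_interval_s: float = 5.0
    n_frames: int = 256
    dt_ms: float = 2.2
    stim_frame: int = 20
    stim_voltage: float = 20.0
    io_v50: float = 7.5
    io_slope: float = 2.0
    sweep_noise: str = "per_sweep"  # or "averaged": draw the sweep mean directly
    seed: int = 0

    def __post_init__(self) -> None:
        nonneg = {
            "depol_amp": self.depol_amp,
            "depol_rise_ms": self.depol_rise_ms,
            "depol_decay_ms": self.depol_decay_ms,
            "hyper_onset_ms": self.hyper_onset_ms,
            "hyper_rise_ms": self.hyper_rise_ms,
            "hyper_decay_ms": self.hyper_decay_ms,
            "noise_sd": self.noise_sd,
            "stim_voltage": self.stim_voltage,
        }
        for name, value in nonneg.items():
            if value < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {value}")
        for layer, amp in self.hyper_amp_by_layer.items():
            if amp < 0:
                raise ConfigurationError(f"hyper_amp_by_layer[{layer!r}] must be >= 0")
        if self.gain <= 0 or self.f0 <= 0:
            raise ConfigurationError("gain and f0 must be > 0")
        if self.dt_ms <= 0:
            raise ConfigurationError("dt_ms must be > 0")
        if self.spatial_decay_len_um <= 0:
            raise ConfigurationError("spatial_decay_len_um must be > 0")
        if self.io_slope <= 0:
            raise ConfigurationError("io_slope must be > 0")
        if self.n_sweeps < 1 or self.n_frames < 2:
            raise ConfigurationError("n_sweeps >= 1 and n_frames >= 2 required")
        if not (0 <= self.stim_frame < self.n_frames):
            raise ConfigurationError("stim_frame must lie within the recording")
        if self.sweep_noise not in ("per_sweep", "averaged"):
            raise ConfigurationError("sweep_noise must be 'per_sweep' or 'averaged'")


@dataclass(frozen=True)
class Condition:
    """A pharmacological condition as multiplicative parameter switches.

    ``depol_scale`` multiplies the depolarization amplitude,
    ``hyper_scale_by_layer`` the hyperpolarization per layer (missing layers
    default to 1). ``potentiation_by_layer`` maps a layer to
    ``(peak fractional increase, decay half-life in minutes)`` for
    plasticity-inducing conditions: the hyperpolarization amplitude is
    multiplied by ``1 + peak`` while the drug is present and by
    ``1 + peak * 2**(-(t - offset)/half_life)`` during washout.

    ``onset_min``/``offset_min`` place the drug within the protocol; when
    ``onset_min`` is None the condition is active at all times (single
    steady-state acquisitions).
    """

    name: str
    depol_scale: float = 1.0
    hyper_scale_by_layer: Mapping[str, float] = field(default_factory=dict)
    potentiation_by_layer: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    onset_min: float | None = None
    offset_min: float | None = None

    def potentiation_factor(self, layer: str, time_min: float) -> float:
        if layer not in self.potentiation_by_layer:
            return 1.0
        if self.onset_min is not None and time_min <= self.onset_min:
            return 1.0
        peak, half_life = self.potentiation_by_layer[layer]
        if half_life <= 0:
            raise ConfigurationError("potentiation half-life must be > 0")
        if self.offset_min is None or time_min < self.offset_min:
            return 1.0 + peak
        return 1.0 + peak * 2.0 ** (-(time_min - self.offset_min) / half_life)

    def resolve(self, time_min: float, layers: Sequence[str]) -> tuple[float, dict[str, float]]:
        """Effective (depol multiplier, per-layer hyper multiplier) at a protocol time.

        ``onset_min`` is the moment application begins: an acquisition taken
        at exactly that timestamp is still pre-drug.
        """
        active = self.onset_min is None or time_min > self.onset_min
        if not active:
            return 1.0, {layer: 1.0 for layer in layers}
        hyper = {}
        for layer in layers:
            hyper[layer] = self.hyper_scale_by_layer.get(layer, 1.0) * self.potentiation_factor(
                layer, time_min
            )
        return self.depol_scale, hyper


def _dhpg_potentiation() -> dict[str, tuple[float, float]]:
    # Largest and most persistent in proximal radiatum; weakest in oriens.
    return {
        "radt_prox": (0.60, 45.0),
        "pyr_layer": (0.30, 12.0),
        "radt_dist": (0.30, 12.0),
        "str_oriens": (0.15, 12.0),
    }


#: Registry of named conditions. Conditions targeting the hyperpolarization
#: are defined per drug; the experimental fIPSP context (continuous NBQX+APV)
#: is obtained with ``compose(CONDITIONS["ionotropic_block"], <drug>)``.
CONDITIONS: dict[str, Condition] = {
    "drug_free": Condition("drug_free"),
    "ionotropic_block": Condition("ionotropic_block", depol_scale=0.0),
    "TTX": Condition("TTX", depol_scale=0.0, hyper_scale_by_layer={l: 0.0 for l in LAYER_LABELS}),
    "PTX": Condition("PTX", depol_scale=2.5, hyper_scale_by_layer={l: 0.0 for l in LAYER_LABELS}),
    "CGP": Condition("CGP"),
    "CDP": Condition("CDP", hyper_scale_by_layer={l: 1.28 for l in LAYER_LABELS}),
    "DHPG": Condition("DHPG", potentiation_by_layer=_dhpg_potentiation()),
    # mGlu1 blockade does not touch the potentiation.
    "DHPG+LY": Condition("DHPG+LY", potentiation_by_layer=_dhpg_potentiation()),
    # mGlu5 blockade before DHPG prevents induction...
    "DHPG+MPEP_before": Condition("DHPG+MPEP_before"),
    # ...but after DHPG the plasticity is already expressed.
    "DHPG+MPEP_after": Condition("DHPG+MPEP_after", potentiation_by_layer=_dhpg_potentiation()),
    # IP3-receptor blockade (2-APB / Xestospongin C) also prevents induction.
    "DHPG+IP3_block": Condition("DHPG+IP3_block"),
}


def get_condition(condition: "Condition | str") -> Condition:
    if isinstance(condition, Condition):
        return condition
    try:
        return CONDITIONS[condition]
    except KeyError:
        raise ConfigurationError(
            f"unknown condition {condition!r}; known: {sorted(CONDITIONS)}"
        ) from None


def compose(*conditions: "Condition | str", name: str | None = None) -> Condition:
    """Combine conditions multiplicatively (co-applied drugs)."""
    conds = [get_condition(c) for c in conditions]
    if not conds:
        raise ConfigurationError("compose requires at least one condition")
    depol = 1.0
    hyper: dict[str, float] = {}
    pot: dict[str, tuple[float, float]] = {}
    onset = None
    offset = None
    for c in conds:
        depol *= c.depol_scale
        for layer, s in c.hyper_scale_by_layer.items():
            hyper[layer] = hyper.get(layer, 1.0) * s
        pot.update(c.potentiation_by_layer)
        onset = c.onset_min if c.onset_min is not None else onset
        offset = c.offset_min if c.offset_min is not None else offset
    return Condition(
        name=name or "+".join(c.name for c in conds),
        depol_scale=depol,
        hyper_scale_by_layer=hyper,
        potentiation_by_layer=pot,
        onset_min=onset,
        offset_min=offset,
    )


# ---------------------------------------------------------------------------
# model primitives
# ---------------------------------------------------------------------------


def io_scale(stim_voltage: float, io_v50: float = 7.5, io_slope: float = 2.0) -> float:
    """Logistic input-output scaling of response amplitude, in [0, 1].

    Monotone nondecreasing in voltage; with the defaults the curve exceeds
    0.95 by 15 V and is effectively flat between 15 and 20 V.
    """
    if stim_voltage < 0:
        raise ConfigurationError("stimulation voltage must be >= 0")
    if io_slope <= 0:
        raise ConfigurationError("io_slope must be > 0")
    return 1.0 / (1.0 + math.exp(-(stim_voltage - io_v50) / io_slope))


def unit_peak_kinetic(t_ms: np.ndarray, rise_ms: float, decay_ms: float) -> np.ndarray:
    """Difference-of-exponentials transient normalized to unit peak.

    Zero for t <= 0. For ``rise == decay`` the limit (alpha function) is used.
    """
    if rise_ms <= 0 or decay_ms <= 0:
        raise ConfigurationError("kinetic constants must be > 0")
    t = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    if math.isclose(rise_ms, decay_ms):
        tau = decay_ms
        out[pos] = (tp / tau) * np.exp(1.0 - tp / tau)
        return out
    if rise_ms > decay_ms:
        rise_ms, decay_ms = decay_ms, rise_ms
    raw = np.exp(-tp / decay_ms) - np.exp(-tp / rise_ms)
    t_peak = math.log(decay_ms / rise_ms) * rise_ms * decay_ms / (decay_ms - rise_ms)
    peak = math.exp(-t_peak / decay_ms) - math.exp(-t_peak / rise_ms)
    out[pos] = raw / peak
    return out


def _as_condition_list(condition) -> "list[Condition]":
    if isinstance(condition, (list, tuple)):
        return [get_condition(c) for c in condition]
    return [get_condition(condition)]


def voltage_field(
    geometry: GeometryModel,
    cfg: SimConfig,
    condition,
    acquisition_time_min: float = 0.0,
) -> np.ndarray:
    """Ground-truth voltage V(t, r, c) for one acquisition.

    ``V = io * [depol_scale * D(t) - hyper_scale(layer) * pot(layer, time) *
    H(t - onset)] * S(c)`` with D, H unit-peak transients carrying the
    configured amplitudes, ``S(c) = exp(-dist/length_const)`` along the
    proximo-distal axis, and V = 0 on margin pixels and before the stimulus.
    Depolarization-positive sign convention.

    ``condition`` may be a single condition (or name) or a sequence of
    co-applied conditions, each resolved at the acquisition time with its own
    drug window; their multipliers combine multiplicatively. This is how a
    windowed drug is simulated on top of an always-present blocker cocktail.
    """
    conds = _as_condition_list(condition)
    layers = list(geometry.layer_bands)
    for cond in conds:
        for layer in cond.hyper_scale_by_layer:
            if layer not in layers:
                raise ConfigurationError(f"condition scales unknown layer {layer!r}")
        for layer in cond.potentiation_by_layer:
            if layer not in layers:
                raise ConfigurationError(f"condition potentiates unknown layer {layer!r}")
    for layer in layers:
        if layer not in cfg.hyper_amp_by_layer:
            raise ConfigurationError(f"no hyperpolarization amplitude for layer {layer!r}")

    depol_scale = 1.0
    hyper_scale = {layer: 1.0 for layer in layers}
    for cond in conds:
        d, h = cond.resolve(acquisition_time_min, layers)
        depol_scale *= d
        for layer in layers:
            hyper_scale[layer] *= h[layer]
    io = io_scale(cfg.stim_voltage, cfg.io_v50, cfg.io_slope)

    t = (np.arange(cfg.n_frames) - cfg.stim_frame) * cfg.dt_ms
    d_t = cfg.depol_amp * depol_scale * unit_peak_kinetic(t, cfg.depol_rise_ms, cfg.depol_decay_ms)
    h_t = unit_peak_kinetic(t - cfg.hyper_onset_ms, cfg.hyper_rise_ms, cfg.hyper_decay_ms)

    cols = np.arange(geometry.n_cols)
    s_c = np.exp(-geometry.col_distance_um(cols) / cfg.spatial_decay_len_um)

    depol_map = np.zeros(geometry.shape)
    hyper_map = np.zeros(geometry.shape)
    c0, c1 = geometry.ca1_cols
    for layer, (r0, r1) in geometry.layer_bands.items():
        depol_map[r0:r1, c0:c1] = 1.0
        hyper_map[r0:r1, c0:c1] = cfg.hyper_amp_by_layer[layer] * hyper_scale[layer]
    depol_map *= s_c[None, :]
    hyper_map *= s_c[None, :]

    v = io * (d_t[:, None, None] * depol_map[None] - h_t[:, None, None] * hyper_map[None])
    return v


@dataclass(eq=False)
class FrameStack:
    """A sweep-averaged fluorescence movie with acquisition metadata."""

    data: np.ndarray  # frames x rows x cols, counts
    dt_ms: float
    stim_frame: int
    geometry: GeometryModel | None = None
    acquisition_time_min: float = 0.0
    condition: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ConfigurationError("frame stack must be frames x rows x cols")
        if not np.all(np.isfinite(self.data)):
            raise ConfigurationError("frame stack contains non-finite values")
        if self.dt_ms <= 0:
            raise ConfigurationError("dt_ms must be > 0")
        if self.geometry is not None and self.data.shape[1:] != self.geometry.shape:
            raise ConfigurationError("frame stack shape inconsistent with geometry")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_ms


def render_acquisition(
    voltage: np.ndarray,
    cfg: SimConfig,
    seed: "int | np.random.SeedSequence | None" = None,
    geometry: GeometryModel | None = None,
    acquisition_time_min: float = 0.0,
    condition: str = "",
) -> FrameStack:
    """Transduce a voltage field into a sweep-averaged fluorescence stack.

    Per sweep, ``F = f0 * (1 - gain * V) + noise`` with independent Gaussian
    noise of SD ``noise_sd``; the returned stack is the mean over
    ``n_sweeps`` sweeps. With ``cfg.sweep_noise == "averaged"`` the sweep mean
    is drawn in one pass from its exact sampling distribution
    (SD ``noise_sd / sqrt(n_sweeps)``). Deterministic given the seed.
    """
    v = np.asarray(voltage, dtype=float)
    if cfg.gain * np.max(np.abs(v)) >= 1.0:
        raise SaturationError("gain * |V| >= 1: fluorescence would saturate to zero")
    signal = cfg.f0 * (1.0 - cfg.gain * v)
    if cfg.noise_sd == 0:
        data = signal.copy()
    else:
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        if cfg.sweep_noise == "per_sweep":
            acc = np.zeros_like(signal)
            for _ in range(cfg.n_sweeps):
                acc += rng.normal(0.0, cfg.noise_sd, size=signal.shape)
            data = signal + acc / cfg.n_sweeps
        else:
            data = signal + rng.normal(
                0.0, cfg.noise_sd / math.sqrt(cfg.n_sweeps), size=signal.shape
            )
    return FrameStack(
        data=data,
        dt_ms=cfg.dt_ms,
        stim_frame=cfg.stim_frame,
        geometry=geometry,
        acquisition_time_min=acquisition_time_min,
        condition=condition,
    )


def simulate_acquisition(
    geometry: GeometryModel,
    cfg: SimConfig,
    condition,
    acquisition_time_min: float = 0.0,
    seed: "int | np.random.SeedSequence | None" = None,
) -> FrameStack:
    """One acquisition: voltage field + dye transduction + sweep noise."""
    conds = _as_condition_list(condition)
    v = voltage_field(geometry, cfg, conds, acquisition_time_min)
    return render_acquisition(
        v, cfg, seed=seed, geometry=geometry,
        acquisition_time_min=acquisition_time_min,
        condition="+".join(c.name for c in conds),
    )


# ---------------------------------------------------------------------------
# protocol
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Protocol:
    """Acquisition schedule of a drug experiment.

    Six baseline acquisitions 4 minutes apart, a 10-minute drug application,
    then thirteen washout acquisitions 4 minutes apart starting at the end of
    the application.
    """

    n_baseline: int = 6
    drug_duration_min: float = 10.0
    n_washout: int = 13
    interval_min: float = 4.0

    def __post_init__(self) -> None:
        if min(self.n_baseline, self.n_washout) < 1 or min(
            self.drug_duration_min, self.interval_min
        ) <= 0:
            raise ProtocolError("protocol fields must be positive")

    @property
    def drug_onset_min(self) -> float:
        return (self.n_baseline - 1) * self.interval_min

    @property
    def drug_offset_min(self) -> float:
        return self.drug_onset_min + self.drug_duration_min

    def acquisition_times(self) -> list[float]:
        baseline = [i * self.interval_min for i in range(self.n_baseline)]
        washout = [self.drug_offset_min + i * self.interval_min for i in range(self.n_washout)]
        return baseline + washout


@dataclass(eq=False)
class AcquisitionSeries:
    """Ordered acquisitions of one simulated slice experiment.

    ``condition`` is the windowed drug under test; ``context`` an optional
    always-present condition (e.g. the ionotropic blocker cocktail).
    """

    stacks: list[FrameStack]
    protocol: Protocol
    condition: Condition
    geometry: GeometryModel
    cfg: SimConfig
    context: Condition | None = None

    def __post_init__(self) -> None:
        times = [s.acquisition_time_min for s in self.stacks]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ProtocolError("acquisition timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.stacks)

    def __iter__(self):
        return iter(self.stacks)

    @property
    def acquisition_duration_s(self) -> float:
        """Span of the sweep window of one acquisition (15 sweeps @ 5 s -> 70 s)."""
        return (self.cfg.n_sweeps - 1) * self.cfg.sweep_interval_s


def simulate_protocol(
    geometry: GeometryModel,
    cfg: SimConfig,
    condition: "Condition | str",
    protocol: Protocol | None = None,
    context: "Condition | str | None" = None,
) -> AcquisitionSeries:
    """Simulate a full baseline / drug / washout experiment.

    The condition's drug window defaults to the protocol's (application right
    after the last baseline acquisition, washout acquisitions starting at the
    end of the application). ``context`` is an optional condition present
    throughout the whole experiment (e.g. ``"ionotropic_block"`` for fIPSP
    recordings). Per-acquisition noise seeds are spawned deterministically
    from ``cfg.seed``.
    """
    proto = protocol or Protocol()
    cond = get_condition(condition)
    onset = cond.onset_min if cond.onset_min is not None else proto.drug_onset_min
    offset = cond.offset_min if cond.offset_min is not None else onset + proto.drug_duration_min
    cond = replace(cond, onset_min=onset, offset_min=offset)
    ctx = get_condition(context) if context is not None else None
    conds = ([ctx] if ctx is not None else []) + [cond]
    name = "+".join(c.name for c in conds)

    times = proto.acquisition_times()
    children = np.random.SeedSequence(cfg.seed).spawn(len(times))
    stacks = []
    prev: tuple | None = None
    v = None
    for t, child in zip(times, children):
        layers = list(geometry.layer_bands)
        parts = [c.resolve(t, layers) for c in conds]
        key = tuple((d, tuple(sorted(h.items()))) for d, h in parts)
        if key != prev:  # potentiation varies across washout; reuse otherwise
            v = voltage_field(geometry, cfg, conds, t)
            prev = key
        stacks.append(
            render_acquisition(
                v, cfg, seed=child, geometry=geometry,
                acquisition_time_min=t, condition=name,
            )
        )
    return AcquisitionSeries(stacks=stacks, protocol=proto, condition=cond,
                             geometry=geometry, cfg=cfg, context=ctx)
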