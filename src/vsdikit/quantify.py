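"""ROI traces, windowed AUCs, input-output curves and drug time courses.

The response magnitude is the area under the ROI trace in a fixed window:

* hyperpolarization: 200 ms starting at the first frame at or after
  (stimulus time + 5 ms), the approximate latency of the inhibitory signal;
* depolarization: 30 ms starting one frame before the stimulus.

Both a rectified integral (|trace|, robust to the sign convention and always
non-negative like the published background values) and a signed integral
(-trace for hyperpolarization, +trace for depolarization; unbiased under
zero-mean noise) are available. Integrals are taken over the piecewise-linear
interpolant of the trace; the rectified mode splits segments at zero
crossings, so it equals the exact integral of |interpolant|.

Drug time courses follow the binning of the acquisition protocol: baseline is
the mean AUC of the last four pre-drug acquisitions, the first washout
acquisition stands alone as time zero, and the remaining twelve are averaged
in three consecutive bins of four; every point is expressed as a percentage
of baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, ProtocolError, UsageError
from .preprocess import DFFStack, compute_dff, smooth_spatial
from .roi import ROI, ROISet
from .synthgen import AcquisitionSeries

HYPER_WINDOW_DELAY_MS = 5.0
HYPER_WINDOW_LENGTH_MS = 200.0
DEPOL_WINDOW_LENGTH_MS = 30.0


@dataclass(eq=False)
class Trace:
    """Per-frame mean dF/F over a ROI, in percent (depolarization-positive)."""

    values: np.ndarray
    dt_ms: float
    stim_frame: int
    roi_label: str = ""
    acquisition_time_min: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise UsageError("trace values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise DataError("trace contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.values.size

    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_ms


@dataclass(frozen=True)
class AUCResult:
    """Windowed area under a ROI trace, in %.ms."""

    roi_label: str
    window: tuple[float, float]  # (start after stimulus in ms, length in ms)
    mode: str
    value: float
    rectified: bool = True
    acquisition_time_min: float = 0.0


@dataclass(eq=False)
class TimeCourse:
    """Percent-of-baseline AUC series of one ROI across a drug protocol."""

    roi_label: str
    mode: str
    rectified: bool
    baseline_auc: float
    points: list[tuple[float, float]]  # (time_min, percent of baseline)
    per_acquisition: list[tuple[float, float]] = field(default_factory=list)
    binning: str = ""


def extract_trace(dff: DFFStack, roi: ROI) -> Trace:
    """Unweighted ROI mean per frame, scaled to percent."""
    mask = np.asarray(roi.mask, dtype=bool)
    if mask.shape != dff.data.shape[1:]:
        raise UsageError("ROI mask shape does not match the stack grid")
    if not mask.any():
        raise UsageError("empty ROI")
    values = dff.data[:, mask].mean(axis=1) * 100.0
    return Trace(
        values=values,
        dt_ms=dff.dt_ms,
        stim_frame=dff.stim_frame,
        roi_label=roi.label,
        acquisition_time_min=dff.acquisition_time_min,
    )


def _piecewise_linear_integral(
    times: np.ndarray, values: np.ndarray, t0: float, t1: float, rectified: bool
) -> float:
    """Integral over [t0, t1] of the linear interpolant (or its absolute value)."""
    if t0 < times[0] - 1e-9 or t1 > times[-1] + 1e-9:
        raise ConfigurationError("integration window exceeds the recording")
    inside = (times > t0) & (times < t1)
    knots = np.concatenate(([t0], times[inside], [t1]))
    vals = np.interp(knots, times, values)
    a, b = knots[:-1], knots[1:]
    va, vb = vals[:-1], vals[1:]
    widths = b - a
    if not rectified:
        return float(np.sum(0.5 * (va + vb) * widths))
    total = 0.0
    crossing = (va * vb) < 0
    same = ~crossing
    total += float(np.sum(0.5 * (np.abs(va[same]) + np.abs(vb[same])) * widths[same]))
    if crossing.any():
        wa, wb = va[crossing], vb[crossing]
        w = widths[crossing]
        tc = wa / (wa - wb) * w  # distance from segment start to the zero crossing
        total += float(np.sum(0.5 * (np.abs(wa) * tc + np.abs(wb) * (w - tc))))
    return total


def default_window(trace: Trace, mode: str) -> tuple[float, float]:
    """(start after stimulus in ms, length in ms) for a quantification mode.

    The hyperpolarization window starts at the first *frame* at or after the
    nominal 5-ms latency; the depolarization window starts exactly one frame
    before the stimulus.
    """
    t_stim = trace.stim_frame * trace.dt_ms
    if mode == "hyper":
        start_frame = math.ceil((t_stim + HYPER_WINDOW_DELAY_MS) / trace.dt_ms - 1e-9)
        return start_frame * trace.dt_ms - t_stim, HYPER_WINDOW_LENGTH_MS
    if mode == "depol":
        if trace.stim_frame < 1:
            raise ConfigurationError("no frame before the stimulus")
        return -trace.dt_ms, DEPOL_WINDOW_LENGTH_MS
    raise ConfigurationError("mode must be 'hyper' or 'depol'")


def auc(
    trace: Trace,
    mode: str = "hyper",
    rectified: bool = True,
    window: tuple[float, float] | None = None,
) -> AUCResult:
    """Windowed AUC of a ROI trace, in %.ms.

    ``window`` overrides the default as (start after stimulus in ms, length in
    ms). Rectified mode integrates |trace|; signed mode integrates -trace for
    hyperpolarization and +trace for depolarization.
    """
    if mode not in ("hyper", "depol"):
        raise ConfigurationError("mode must be 'hyper' or 'depol'")
    if window is None:
        window = default_window(trace, mode)
    start_ms, length_ms = float(window[0]), float(window[1])
    if length_ms <= 0:
        raise ConfigurationError("window length must be > 0")
    t_stim = trace.stim_frame * trace.dt_ms
    t0 = t_stim + start_ms
    t1 = t0 + length_ms
    times = trace.times_ms()
    if t0 < -1e-9 or t1 > times[-1] + 1e-9:
        raise ConfigurationError("AUC window exceeds the recording")
    values = trace.values if mode == "depol" else -trace.values
    value = _piecewise_linear_integral(times, values, t0, t1, rectified)
    return AUCResult(
        roi_label=trace.roi_label,
        window=(start_ms, length_ms),
        mode=mode,
        value=value,
        rectified=rectified,
        acquisition_time_min=trace.acquisition_time_min,
    )


def background_auc(
    dff: DFFStack,
    backgrounds: "ROISet | Sequence[ROI]",
    mode: str = "hyper",
    rectified: bool = True,
    window: tuple[float, float] | None = None,
) -> float:
    """Mean AUC over the background ROIs (same window and mode as the signal)."""
    rois = list(backgrounds)
    if not rois:
        raise UsageError("at least one background ROI is required")
    values = [
        auc(extract_trace(dff, r), mode=mode, rectified=rectified, window=window).value
        for r in rois
    ]
    return float(np.mean(values))


def io_curve(
    items: Iterable[tuple[float, DFFStack]],
    roi: ROI,
    mode: str = "hyper",
    rectified: bool = True,
) -> pd.DataFrame:
    """AUC as a function of stimulation voltage, on one ROI and window."""
    rows = []
    shapes = set()
    for voltage, dff in items:
        shapes.add(dff.data.shape[1:])
        rows.append(
            {
                "voltage": float(voltage),
                "auc": auc(extract_trace(dff, roi), mode=mode, rectified=rectified).value,
            }
        )
    if len(shapes) > 1:
        raise UsageError("acquisitions have mismatched grids")
    if len(rows) < 2 or not any(r["voltage"] == 0 for r in rows):
        raise UsageError("an input-output curve needs >= 2 voltages including 0")
    return pd.DataFrame(rows).sort_values("voltage").reset_index(drop=True)


def timecourse(
    series: AcquisitionSeries,
    roi: ROI,
    mode: str = "hyper",
    rectified: bool = True,
    smooth: int = 3,
    f0_frames: tuple[int, int] | None = None,
    allow_nonstandard: bool = False,
) -> TimeCourse:
    """Percent-of-baseline AUC time course of one ROI across a drug protocol.

    Baseline is the mean AUC of the last four baseline acquisitions; the first
    washout acquisition is reported alone (time zero) and the remaining twelve
    in three bins of four, each at the mean timestamp of its members.
    """
    proto = series.protocol
    n_baseline, n_washout = proto.n_baseline, proto.n_washout
    if not allow_nonstandard:
        if (n_baseline, n_washout) != (6, 13) or len(series) != 19:
            raise ProtocolError(
                "expected 6 baseline + 13 washout acquisitions; pass "
                "allow_nonstandard=True for other protocols"
            )
    if len(series) != n_baseline + n_washout:
        raise ProtocolError("series length does not match its protocol")
    if n_baseline < 4:
        raise ProtocolError("baseline averaging needs at least 4 baseline acquisitions")

    per_acq: list[tuple[float, float]] = []
    for stack in series:
        dff = compute_dff(stack, f0_frames=f0_frames)
        if smooth:
            dff = smooth_spatial(dff, smooth)
        res = auc(extract_trace(dff, roi), mode=mode, rectified=rectified)
        per_acq.append((stack.acquisition_time_min, res.value))

    baseline_vals = [v for _, v in per_acq[n_baseline - 4:n_baseline]]
    baseline = float(np.mean(baseline_vals))
    if baseline == 0:
        raise DataError("baseline AUC is zero; cannot normalize")

    washout = per_acq[n_baseline:]
    points: list[tuple[float, float]] = []
    t0, v0 = washout[0]
    points.append((t0, 100.0 * v0 / baseline))
    rest = washout[1:]
    for i in range(0, len(rest) - len(rest) % 4, 4):
        chunk = rest[i:i + 4]
        t = float(np.mean([t for t, _ in chunk]))
        v = float(np.mean([v for _, v in chunk]))
        points.append((t, 100.0 * v / baseline))
    return TimeCourse(
        roi_label=roi.label,
        mode=mode,
        rectified=rectified,
        baseline_auc=baseline,
        points=points,
        per_acquisition=per_acq,
        binning="baseline: mean of last 4 pre-drug; washout: first alone, then bins of 4",
    )


def distribution_summary(aucs: Mapping[str, float]) -> dict[str, float]:
    """Each region's share of the total AUC, in percent (sums to 100)."""
    if len(aucs) < 2:
        raise UsageError("distribution summary needs at least two regions")
    values = {k: float(v) for k, v in aucs.items()}
    total = sum(values.values())
    if total <= 0:
        raise DataError("total AUC is not positive; shares are undefined")
    return {k: 100.0 * v / total for k, v in values.items()}
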