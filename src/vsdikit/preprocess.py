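"""Raw fluorescence to smoothed fractional-change (dF/F) stacks.

The basic VSDI signal is the fractional change in fluorescence relative to a
pre-stimulus baseline. Because Di-4-ANEPPS emission *decreases* on
depolarization, the canonical sign convention here flips the raw change so
that depolarization is positive and hyperpolarization negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DataError, UsageError
from .geometry import GeometryModel
from .synthgen import FrameStack


@dataclass(eq=False)
class DFFStack:
    """Fractional fluorescence change per pixel and frame.

    ``data`` is dimensionless, depolarization-positive (unless built with
    ``depolarization_positive=False``). ``smoothing_applied`` is 0, 3 or 5.
    """

    data: np.ndarray
    dt_ms: float
    stim_frame: int
    f0_map: np.ndarray
    smoothing_applied: int = 0
    geometry: GeometryModel | None = None
    acquisition_time_min: float = 0.0
    condition: str = ""

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_ms


def compute_dff(
    stack: FrameStack,
    f0_frames: tuple[int, int] | None = None,
    depolarization_positive: bool = True,
) -> DFFStack:
    """Fractional change relative to the per-pixel pre-stimulus mean.

    ``s = -(F - F0) / F0`` so that a fluorescence decrease (depolarization)
    comes out positive. ``f0_frames`` is a half-open frame interval that must
    end at or before the stimulus frame; default is all pre-stimulus frames.
    """
    if f0_frames is None:
        f0_frames = (0, stack.stim_frame)
    a, b = int(f0_frames[0]), int(f0_frames[1])
    if not (0 <= a < b <= stack.n_frames):
        raise ConfigurationError(f"invalid F0 window ({a}, {b})")
    if b > stack.stim_frame:
        raise ConfigurationError("F0 window must end at or before the stimulus frame")
    f0 = stack.data[a:b].mean(axis=0)
    if np.any(f0 <= 0):
        raise DataError("non-positive baseline fluorescence in the F0 window")
    dff = (f0[None] - stack.data) / f0[None]
    if not depolarization_positive:
        dff = -dff
    return DFFStack(
        data=dff,
        dt_ms=stack.dt_ms,
        stim_frame=stack.stim_frame,
        f0_map=f0,
        smoothing_applied=0,
        geometry=stack.geometry,
        acquisition_time_min=stack.acquisition_time_min,
        condition=stack.condition,
    )


def smooth_spatial(dff: DFFStack, k: int, force: bool = False) -> DFFStack:
    """k x k spatial mean filter, frame by frame.

    Edge pixels are averaged over their in-grid neighbors only (shrinking
    window), so ROI-boundary pixels are not attenuated toward zero. Repeating
    the smoothing requires ``force=True``.
    """
    if k not in (3, 5):
        raise ConfigurationError("smoothing kernel must be 3 or 5")
    if dff.smoothing_applied and not force:
        raise UsageError(
            "stack already smoothed; pass force=True to smooth again"
        )
    kernel = np.ones((1, k, k))
    sums = ndimage.correlate(dff.data, kernel, mode="constant", cval=0.0)
    counts = ndimage.correlate(
        np.ones(dff.data.shape[1:]), np.ones((k, k)), mode="constant", cval=0.0
    )
    out = sums / counts[None]
    return DFFStack(
        data=out,
        dt_ms=dff.dt_ms,
        stim_frame=dff.stim_frame,
        f0_map=dff.f0_map,
        smoothing_applied=k,
        geometry=dff.geometry,
        acquisition_time_min=dff.acquisition_time_min,
        condition=dff.condition,
    )


def mask_outside(dff: DFFStack, roi) -> DFFStack:
    """Zero all values outside the ROI (used to isolate CA1 in maps)."""
    mask = np.asarray(roi.mask, dtype=bool)
    if mask.shape != dff.data.shape[1:]:
        raise ConfigurationError("ROI mask shape does not match the stack grid")
    if not mask.any():
        raise UsageError("empty ROI")
    return DFFStack(
        data=dff.data * mask[None],
        dt_ms=dff.dt_ms,
        stim_frame=dff.stim_frame,
        f0_map=dff.f0_map,
        smoothing_applied=dff.smoothing_applied,
        geometry=dff.geometry,
        acquisition_time_min=dff.acquisition_time_min,
        condition=dff.condition,
    )
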