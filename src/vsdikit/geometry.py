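"""Pixel-grid geometry of a CA1 field of view.

The camera sees a rectangular grid of pixels. A contiguous block of rows
(ordered dorso-ventrally: stratum oriens, pyramidal layer, proximal and distal
stratum radiatum) intersected with a column interval forms the CA1 region; the
distal radiatum band also stands in for stratum lacunosum-moleculare, as the
pixel size does not allow a finer subdivision. Everything outside that
rectangle is non-hippocampal margin (cortex / thalamus in a sagittal slice)
and is where background ROIs live. The stimulating electrode sits at the
proximal column edge of CA1; distances along the proximo-distal axis are
measured in multiples of the mean pixel side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, GeometryError

#: Dorso-ventral layer labels, in anatomical order.
LAYER_LABELS = ("str_oriens", "pyr_layer", "radt_prox", "radt_dist")


@dataclass(frozen=True, eq=False)
class GeometryModel:
    """Validated map of the imaging grid onto CA1 anatomy.

    Attributes
    ----------
    n_rows, n_cols : int
        Grid size in pixels.
    pixel_h, pixel_v : float
        Physical pixel size in micrometers (horizontal and vertical).
    pixel_side_mean : float
        Mean of ``pixel_h`` and ``pixel_v``; the side of the "square pixel"
        used for distances along the proximo-distal axis.
    electrode_col : int
        Column of the stimulating electrode (proximal edge of CA1).
    layer_bands : dict[str, tuple[int, int]]
        Ordered map layer label -> half-open row interval, dorso-ventral.
    ca1_cols : tuple[int, int]
        Half-open column interval of the CA1 region.
    margin_mask : numpy.ndarray of bool
        True on non-hippocampal pixels (complement of the CA1 rectangle).
    """

    n_rows: int
    n_cols: int
    pixel_h: float
    pixel_v: float
    electrode_col: int
    layer_bands: Mapping[str, tuple[int, int]]
    ca1_cols: tuple[int, int]
    margin_mask: np.ndarray
    pixel_side_mean: float

    # -- masks -------------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def band_mask(self, label: str) -> np.ndarray:
        """Boolean mask of one layer band intersected with the CA1 columns."""
        if label not in self.layer_bands:
            raise ConfigurationError(f"unknown layer label {label!r}")
        r0, r1 = self.layer_bands[label]
        c0, c1 = self.ca1_cols
        mask = np.zeros(self.shape, dtype=bool)
        mask[r0:r1, c0:c1] = True
        return mask

    def ca1_mask(self) -> np.ndarray:
        """Boolean mask of the whole CA1 rectangle (union of the bands)."""
        mask = np.zeros(self.shape, dtype=bool)
        for label in self.layer_bands:
            mask |= self.band_mask(label)
        return mask

    def layer_of_row(self) -> list[str | None]:
        """Layer label per row (None outside the bands)."""
        out: list[str | None] = [None] * self.n_rows
        for label, (r0, r1) in self.layer_bands.items():
            for r in range(r0, r1):
                out[r] = label
        return out

    def col_distance_um(self, cols) -> np.ndarray:
        """Distance of pixel column(s) from the electrode, in micrometers."""
        return np.abs(np.asarray(cols, dtype=float) - self.electrode_col) * self.pixel_side_mean

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "pixel_h": self.pixel_h,
            "pixel_v": self.pixel_v,
            "electrode_col": self.electrode_col,
            "layer_bands": {k: list(v) for k, v in self.layer_bands.items()},
            "ca1_cols": list(self.ca1_cols),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeometryModel":
        return build_geometry(
            n_rows=d["n_rows"],
            n_cols=d["n_cols"],
            pixel_h=d["pixel_h"],
            pixel_v=d["pixel_v"],
            electrode_col=d["electrode_col"],
            layer_band_spec={k: tuple(v) for k, v in d["layer_bands"].items()},
            ca1_cols=tuple(d["ca1_cols"]),
        )


def build_geometry(
    n_rows: int,
    n_cols: int,
    pixel_h: float,
    pixel_v: float,
    electrode_col: int,
    layer_band_spec: Mapping[str, Sequence[int]],
    ca1_cols: tuple[int, int] | None = None,
    margin_rows: int | None = None,
) -> GeometryModel:
    """Validate and assemble a :class:`GeometryModel`.

    Parameters
    ----------
    layer_band_spec
        Ordered mapping of layer label to a half-open ``(row_start, row_stop)``
        interval. Bands must be disjoint, contiguous and dorso-ventrally
        ordered (each band starts where the previous one stops).
    ca1_cols
        Half-open column interval of CA1. Defaults to
        ``(electrode_col, n_cols)``.
    margin_rows
        Optional check: the first band must start at exactly this row,
        reserving ``margin_rows`` rows of margin above CA1.
    """
    if n_rows <= 0 or n_cols <= 0:
        raise ConfigurationError("grid dimensions must be positive")
    if pixel_h <= 0 or pixel_v <= 0:
        raise ConfigurationError("pixel sizes must be positive")
    if not (0 <= electrode_col < n_cols):
        raise ConfigurationError(
            f"electrode column {electrode_col} outside grid of {n_cols} columns"
        )
    if not layer_band_spec:
        raise ConfigurationError("at least one layer band is required")

    bands: dict[str, tuple[int, int]] = {}
    prev_stop: int | None = None
    for label, interval in layer_band_spec.items():
        r0, r1 = int(interval[0]), int(interval[1])
        if not (0 <= r0 < r1 <= n_rows):
            raise GeometryError(f"band {label!r} interval ({r0}, {r1}) outside the grid")
        if prev_stop is not None:
            if r0 < prev_stop:
                raise GeometryError(f"band {label!r} overlaps the previous band")
            if r0 != prev_stop:
                raise GeometryError(
                    f"band {label!r} is not contiguous with the previous band"
                )
        bands[label] = (r0, r1)
        prev_stop = r1
    first_start = next(iter(bands.values()))[0]
    if margin_rows is not None and first_start != margin_rows:
        raise GeometryError(
            f"bands start at row {first_start}, expected margin of {margin_rows} rows"
        )

    if ca1_cols is None:
        ca1_cols = (electrode_col, n_cols)
    c0, c1 = int(ca1_cols[0]), int(ca1_cols[1])
    if not (0 <= c0 < c1 <= n_cols):
        raise GeometryError(f"CA1 column interval ({c0}, {c1}) outside the grid")
    if not (c0 <= electrode_col < c1):
        raise ConfigurationError("electrode column must lie within the CA1 columns")

    margin = np.ones((n_rows, n_cols), dtype=bool)
    margin[first_start:prev_stop, c0:c1] = False

    return GeometryModel(
        n_rows=n_rows,
        n_cols=n_cols,
        pixel_h=float(pixel_h),
        pixel_v=float(pixel_v),
        electrode_col=int(electrode_col),
        layer_bands=bands,
        ca1_cols=(c0, c1),
        margin_mask=margin,
        pixel_side_mean=(float(pixel_h) + float(pixel_v)) / 2.0,
    )


def default_geometry() -> GeometryModel:
    """Default field of view used throughout the synthetic studies.

    66 x 76 pixels of 33.3 x 37.5 um. The CA1 rectangle occupies rows 34-65
    and columns 4-27 (four 8-row dorso-ventral bands, 24 columns starting at
    the electrode). The margin is large enough to host three translated
    copies of a whole-CA1 ROI away from the grid border, which the
    background rule requires.
    """
    band_h = 8
    r0 = 34
    bands = {label: (r0 + i * band_h, r0 + (i + 1) * band_h) for i, label in enumerate(LAYER_LABELS)}
    return build_geometry(
        n_rows=66,
        n_cols=76,
        pixel_h=33.3,
        pixel_v=37.5,
        electrode_col=4,
        layer_band_spec=bands,
        ca1_cols=(4, 28),
    )
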