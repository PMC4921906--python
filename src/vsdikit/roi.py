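"""The ROI system: layers, proximo-distal regions, measurement lines, backgrounds.

All constructions are deterministic functions of the geometry:

* one ROI per dorso-ventral layer band (distal radiatum obtained by
  translating proximal radiatum ventrally to the adjacent position) plus
  their union (whole CA1);
* ``n`` equal adjacent column blocks P / M / D starting at the electrode;
* 1 x 8 pixel measurement lines placed at the middle row of a parent ROI —
  anchored at the electrode-side boundary for layer ROIs, centered on the
  parent's columns for P/M/D;
* background ROIs: translated copies of a signal ROI packed greedily into the
  non-hippocampal margin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .errors import GeometryError, UsageError
from .geometry import GeometryModel

ROLES = ("signal", "background", "line")
AXIS_LABELS = ("P", "M", "D")


def _rle_encode(mask: np.ndarray) -> list[int]:
    """Run lengths of the flattened mask, alternating 0-runs and 1-runs,
    starting with the length of the initial 0-run (possibly 0)."""
    flat = np.asarray(mask, dtype=bool).ravel()
    runs: list[int] = []
    current = False
    count = 0
    for v in flat:
        if v == current:
            count += 1
        else:
            runs.append(count)
            current = v
            count = 1
    runs.append(count)
    return runs


def _rle_decode(runs: list[int], shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos = 0
    value = False
    for run in runs:
        if value:
            flat[pos:pos + run] = True
        pos += run
        value = not value
    if pos != flat.size:
        raise UsageError("run-length data does not match the grid size")
    return flat.reshape(shape)


@dataclass(eq=False)
class ROI:
    """A labelled pixel mask with a role and an anatomical tag."""

    label: str
    role: str
    mask: np.ndarray
    tag: str = ""
    provenance: str = "drawn"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise UsageError("ROI mask must be 2-D")
        if not self.mask.any():
            raise UsageError(f"ROI {self.label!r} is empty")
        if self.role not in ROLES:
            raise UsageError(f"ROI role must be one of {ROLES}")
        if self.role == "line":
            rows, cols = np.nonzero(self.mask)
            one_row = len(set(rows.tolist())) == 1
            one_col = len(set(cols.tolist())) == 1
            if self.mask.sum() != 8 or not (one_row or one_col):
                raise UsageError("line ROIs must be exactly 1 pixel wide and 8 long")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def bbox(self) -> tuple[int, int, int, int]:
        rows, cols = np.nonzero(self.mask)
        return int(rows.min()), int(rows.max()) + 1, int(cols.min()), int(cols.max()) + 1

    def translated(self, dr: int, dc: int, label: str | None = None) -> "ROI":
        """Copy of the ROI shifted by (dr, dc) pixels; must stay on the grid."""
        r0, r1, c0, c1 = self.bbox()
        nr, nc = self.mask.shape
        if not (0 <= r0 + dr and r1 + dr <= nr and 0 <= c0 + dc and c1 + dc <= nc):
            raise GeometryError(f"translating ROI {self.label!r} leaves the grid")
        mask = np.zeros_like(self.mask)
        rows, cols = np.nonzero(self.mask)
        mask[rows + dr, cols + dc] = True
        return ROI(
            label=label or self.label,
            role=self.role,
            mask=mask,
            tag=self.tag,
            provenance=f"translated-from {self.label}",
        )

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "role": self.role,
            "tag": self.tag,
            "provenance": self.provenance,
            "shape": list(self.mask.shape),
            "rle": _rle_encode(self.mask),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ROI":
        mask = _rle_decode(list(d["rle"]), tuple(d["shape"]))
        return cls(label=d["label"], role=d["role"], mask=mask,
                   tag=d.get("tag", ""), provenance=d.get("provenance", "drawn"))


@dataclass(eq=False)
class ROISet:
    """Ordered collection of ROIs on one grid, with unique labels."""

    rois: list[ROI] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [r.label for r in self.rois]
        if len(set(labels)) != len(labels):
            raise UsageError("ROI labels must be unique")
        shapes = {r.mask.shape for r in self.rois}
        if len(shapes) > 1:
            raise UsageError("all ROIs in a set must share the grid shape")

    def __iter__(self) -> Iterator[ROI]:
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)

    def __getitem__(self, label: str) -> ROI:
        for r in self.rois:
            if r.label == label:
                return r
        raise KeyError(label)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.rois]

    def add(self, roi: ROI) -> None:
        if roi.label in self.labels:
            raise UsageError(f"duplicate ROI label {roi.label!r}")
        self.rois.append(roi)

    def to_json(self, path=None) -> str:
        payload = json.dumps({"rois": [r.to_dict() for r in self.rois]}, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "ROISet":
        if hasattr(source, "read"):
            d = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                d = json.loads(text)
            else:
                with open(text) as fh:
                    d = json.load(fh)
        return cls(rois=[ROI.from_dict(r) for r in d["rois"]])


# ---------------------------------------------------------------------------
# constructions
# ---------------------------------------------------------------------------


def layer_rois(geometry: GeometryModel) -> ROISet:
    """One signal ROI per dorso-ventral layer plus their union (whole CA1).

    Distal radiatum is constructed by translating proximal radiatum ventrally
    to the adjacent position, mirroring how the ROIs were drawn.
    """
    labels = list(geometry.layer_bands)
    if len(labels) < 4:
        raise GeometryError("geometry must define all four layer bands")
    rois = ROISet()
    prox = None
    for label in labels:
        if label == "radt_dist" and prox is not None:
            r0, r1 = geometry.layer_bands["radt_prox"]
            roi = prox.translated(r1 - r0, 0, label="radt_dist")
            roi.label = "radt_dist"
            roi.tag = "radt_dist"
            expected = geometry.band_mask("radt_dist")
            if not np.array_equal(roi.mask, expected):
                raise GeometryError(
                    "translated radt_prox does not coincide with the radt_dist band"
                )
            rois.add(roi)
            continue
        roi = ROI(label=label, role="signal", mask=geometry.band_mask(label), tag=label)
        if label == "radt_prox":
            prox = roi
        rois.add(roi)
    union = np.zeros(geometry.shape, dtype=bool)
    for r in rois:
        union |= r.mask
    rois.add(ROI(label="whole_CA1", role="signal", mask=union, tag="whole_CA1",
                 provenance="union of layer ROIs"))
    return rois


def axis_rois(geometry: GeometryModel, width_px: int = 6, n: int = 3) -> ROISet:
    """n equal adjacent column blocks along the proximo-distal axis.

    The first block (P) starts at the electrode column; each spans the whole
    CA1 dorso-ventral extent. The center of the k-th block lies at
    ``(k - 1/2) * width_px * pixel_side_mean`` micrometers from the electrode.
    """
    if width_px < 1 or n < 1:
        raise GeometryError("width_px and n must be >= 1")
    c0 = geometry.electrode_col
    if c0 + n * width_px > geometry.ca1_cols[1]:
        raise GeometryError(
            f"{n} blocks of {width_px} columns do not fit distal to the electrode"
        )
    bands = list(geometry.layer_bands.values())
    r0, r1 = bands[0][0], bands[-1][1]
    rois = ROISet()
    for k in range(n):
        label = AXIS_LABELS[k] if k < len(AXIS_LABELS) else f"D{k - 1}"
        mask = np.zeros(geometry.shape, dtype=bool)
        mask[r0:r1, c0 + k * width_px:c0 + (k + 1) * width_px] = True
        provenance = "drawn" if k == 0 else f"translated-from {rois.labels[0]}"
        rois.add(ROI(label=label, role="signal", mask=mask, tag=label,
                     provenance=provenance))
    return rois


def axis_center_distance_um(k: int, width_px: int, pixel_side_mean: float) -> float:
    """Distance of the k-th (0-based) axis block center from the electrode."""
    return (k + 0.5) * width_px * pixel_side_mean


def line_roi(parent: ROI, geometry: GeometryModel, axis: str) -> ROI:
    """1 x 8 pixel measurement line at the middle row of a parent ROI.

    ``axis="dorso_ventral"`` (layer parents): the line starts at the parent
    boundary nearest the electrode and runs distally. ``axis="proximo_distal"``
    (P/M/D parents): the line is centered on the parent's column span and may
    overhang into adjacent columns, but must stay on the grid. Ties in the
    middle row go to the lower-middle row.
    """
    if axis not in ("dorso_ventral", "proximo_distal"):
        raise UsageError("axis must be 'dorso_ventral' or 'proximo_distal'")
    rows = np.unique(np.nonzero(parent.mask)[0])
    cols = np.unique(np.nonzero(parent.mask)[1])
    mid_row = int(rows[(len(rows) - 1) // 2])
    if axis == "dorso_ventral":
        if len(cols) < 8:
            raise GeometryError("parent ROI is shorter than 8 pixels along the line")
        if abs(int(cols.min()) - geometry.electrode_col) <= abs(
            int(cols.max()) - geometry.electrode_col
        ):
            start = int(cols.min())
        else:
            start = int(cols.max()) - 7
    else:
        width = int(cols.max()) - int(cols.min()) + 1
        start = int(cols.min()) + (width - 8) // 2
    if start < 0 or start + 8 > geometry.n_cols:
        raise GeometryError("8-pixel line does not fit on the grid")
    mask = np.zeros(geometry.shape, dtype=bool)
    mask[mid_row, start:start + 8] = True
    return ROI(
        label=f"line_{parent.label}",
        role="line",
        mask=mask,
        tag=parent.tag or parent.label,
        provenance=f"line in {parent.label}",
    )


def background_rois(signal_roi: ROI, geometry: GeometryModel, n: int = 3,
                    border_px: int = 1) -> ROISet:
    """n disjoint translated copies of a signal ROI inside the margin.

    Placement is deterministic: candidate top-left positions are scanned in
    row-major order and accepted greedily when the translated mask lies
    entirely in the non-hippocampal margin and does not overlap a previously
    placed copy. Copies are kept ``border_px`` pixels away from the grid
    border (background ROIs sit in tissue interior, and edge pixels behave
    differently under the shrinking-window smoothing).
    """
    if n < 1:
        raise UsageError("n must be >= 1")
    r0, r1, c0, c1 = signal_roi.bbox()
    pattern = signal_roi.mask[r0:r1, c0:c1]
    h, w = pattern.shape
    margin = geometry.margin_mask
    used = np.zeros(geometry.shape, dtype=bool)
    placed: list[ROI] = []
    for rr in range(border_px, geometry.n_rows - h + 1 - border_px):
        for cc in range(border_px, geometry.n_cols - w + 1 - border_px):
            window_margin = margin[rr:rr + h, cc:cc + w]
            window_used = used[rr:rr + h, cc:cc + w]
            if np.all(window_margin[pattern]) and not np.any(window_used[pattern]):
                mask = np.zeros(geometry.shape, dtype=bool)
                mask[rr:rr + h, cc:cc + w] = pattern
                used |= mask
                placed.append(
                    ROI(
                        label=f"{signal_roi.label}_bg{len(placed) + 1}",
                        role="background",
                        mask=mask,
                        tag=signal_roi.tag,
                        provenance=f"translated-from {signal_roi.label}",
                    )
                )
                if len(placed) == n:
                    return ROISet(rois=placed)
    raise GeometryError(
        f"margin cannot host {n} disjoint copies of ROI {signal_roi.label!r}"
    )
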