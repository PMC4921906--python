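"""End-to-end synthetic studies and the one-command study runner.

The helpers here reproduce, on simulated slices, the figure-level procedures
of the analysis: the pharmacological characterization of the hyperpolarizing
signal (TTX / PTX / CDP against background), its spatial distribution along
the dorso-ventral and proximo-distal axes (8-pixel measurement lines), the
drug time courses (percent of baseline), and a Monte-Carlo type-I-error
calibration of the group comparison.

All helpers are deterministic functions of their seed: per-slice and
per-acquisition seeds are spawned from a single integer.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .geometry import GeometryModel, build_geometry, default_geometry
from .preprocess import compute_dff, smooth_spatial
from .quantify import auc, background_auc, extract_trace, timecourse
from .roi import ROISet, axis_rois, background_rois, layer_rois, line_roi
from .stats import compare
from .synthgen import (
    CONDITIONS,
    Condition,
    SimConfig,
    compose,
    get_condition,
    simulate_acquisition,
    simulate_protocol,
    voltage_field,
    render_acquisition,
)

logger = logging.getLogger("vsdikit")

#: fIPSP recording context: ionotropic glutamatergic transmission blocked.
FIPSP_BASELINE = CONDITIONS["ionotropic_block"]


def study_config(**overrides) -> SimConfig:
    """Default simulator configuration for multi-slice studies.

    Identical to :class:`SimConfig` defaults except that sweep noise is drawn
    from the exact sampling distribution of the sweep mean in a single pass,
    which keeps 12-slice studies fast without changing the statistics.
    """
    overrides.setdefault("sweep_noise", "averaged")
    return SimConfig(**overrides)


def _analyze(stack, smooth: int = 3):
    dff = compute_dff(stack)
    if smooth:
        dff = smooth_spatial(dff, smooth)
    return dff


def _slice_seeds(seeds: Sequence[int] | None, n_slices: int) -> list[int]:
    if seeds is None:
        return list(range(1, n_slices + 1))
    seeds = list(seeds)
    if len(seeds) != n_slices:
        raise ConfigurationError("seeds length must equal n_slices")
    return seeds


def inhibition_panel(
    n_slices: int = 12,
    seeds: Sequence[int] | None = None,
    geometry: GeometryModel | None = None,
    cfg: SimConfig | None = None,
    smooth: int = 3,
    rectified: bool = True,
) -> pd.DataFrame:
    """Whole-CA1 fIPSP AUC under baseline / TTX / PTX / CDP, with backgrounds.

    Every drug condition is recorded in the fIPSP context (continuous
    ionotropic blockade). Returns one row per (slice, condition) with the
    whole-CA1 AUC and the mean AUC of three whole-CA1-shaped background ROIs
    measured on the same acquisition.
    """
    geometry = geometry or default_geometry()
    cfg = cfg or study_config()
    seeds = _slice_seeds(seeds, n_slices)
    whole = layer_rois(geometry)["whole_CA1"]
    bgs = background_rois(whole, geometry, n=3)
    conditions = {
        "baseline": FIPSP_BASELINE,
        "TTX": compose("ionotropic_block", "TTX", name="TTX"),
        "PTX": compose("ionotropic_block", "PTX", name="PTX"),
        "CDP": compose("ionotropic_block", "CDP", name="CDP"),
    }
    rows = []
    for s, seed in enumerate(seeds):
        children = np.random.SeedSequence(seed).spawn(len(conditions))
        for (name, cond), child in zip(conditions.items(), children):
            stack = simulate_acquisition(geometry, replace(cfg, seed=seed), cond, seed=child)
            dff = _analyze(stack, smooth)
            rows.append({
                "slice": s,
                "condition": name,
                "auc": auc(extract_trace(dff, whole), mode="hyper", rectified=rectified).value,
                "background": background_auc(dff, bgs, mode="hyper", rectified=rectified),
            })
    return pd.DataFrame(rows)


def spatial_panel(
    n_slices: int = 12,
    seeds: Sequence[int] | None = None,
    geometry: GeometryModel | None = None,
    cfg: SimConfig | None = None,
    smooth: int = 3,
    rectified: bool = True,
    axis_width_px: int = 6,
) -> pd.DataFrame:
    """Line-ROI AUCs along the dorso-ventral and proximo-distal axes.

    One fIPSP-context acquisition per slice; 8-pixel measurement lines in each
    layer ROI and in each P/M/D block, plus the mean of three line-shaped
    background ROIs. Returns one row per (slice, roi).
    """
    geometry = geometry or default_geometry()
    cfg = cfg or study_config()
    seeds = _slice_seeds(seeds, n_slices)
    layers = layer_rois(geometry)
    layer_lines = [
        line_roi(layers[label], geometry, "dorso_ventral") for label in geometry.layer_bands
    ]
    axis_lines = [
        line_roi(r, geometry, "proximo_distal") for r in axis_rois(geometry, width_px=axis_width_px)
    ]
    bgs = background_rois(layer_lines[0], geometry, n=3)
    rows = []
    for s, seed in enumerate(seeds):
        stack = simulate_acquisition(geometry, replace(cfg, seed=seed), FIPSP_BASELINE, seed=seed)
        dff = _analyze(stack, smooth)
        for roi_obj, kind in (
            [(r, "layer_line") for r in layer_lines] + [(r, "axis_line") for r in axis_lines]
        ):
            rows.append({
                "slice": s,
                "roi": roi_obj.tag,
                "kind": kind,
                "auc": auc(extract_trace(dff, roi_obj), mode="hyper", rectified=rectified).value,
            })
        rows.append({
            "slice": s,
            "roi": "background",
            "kind": "background",
            "auc": background_auc(dff, bgs, mode="hyper", rectified=rectified),
        })
    return pd.DataFrame(rows)


def potentiation_timecourses(
    condition: "Condition | str",
    rois: Mapping[str, object],
    n_slices: int = 12,
    seeds: Sequence[int] | None = None,
    geometry: GeometryModel | None = None,
    cfg: SimConfig | None = None,
    smooth: int = 3,
    rectified: bool = False,
) -> pd.DataFrame:
    """Percent-of-baseline time courses across simulated slices.

    The condition is applied in the fIPSP context (ionotropic blockade).
    Signed AUC is the default estimator here: it is unbiased under zero-mean
    noise and therefore recovers amplitude changes on the percent scale.
    Returns one row per (slice, roi, time point).
    """
    geometry = geometry or default_geometry()
    cfg = cfg or study_config()
    seeds = _slice_seeds(seeds, n_slices)
    cond = get_condition(condition)
    rows = []
    for s, seed in enumerate(seeds):
        series = simulate_protocol(geometry, replace(cfg, seed=seed), cond,
                                   context=FIPSP_BASELINE)
        for label, roi_obj in rois.items():
            tc = timecourse(series, roi_obj, mode="hyper", rectified=rectified, smooth=smooth)
            for k, (t, pct) in enumerate(tc.points):
                rows.append({
                    "slice": s, "roi": label, "point": k,
                    "time_min": t, "percent": pct,
                    "baseline_auc": tc.baseline_auc,
                })
    return pd.DataFrame(rows)


def step_potentiation_condition(peak: float = 0.5, layer: str = "radt_prox",
                                half_life_min: float = 1e6) -> Condition:
    """A known-truth plasticity condition: one layer potentiated by ``peak``.

    The default half-life is effectively infinite so every washout point sees
    the full factor ``1 + peak``.
    """
    return Condition(
        name=f"step_{layer}_{peak:+.0%}",
        potentiation_by_layer={layer: (peak, half_life_min)},
    )


# ---------------------------------------------------------------------------
# Monte-Carlo calibration
# ---------------------------------------------------------------------------


def small_geometry() -> GeometryModel:
    """Scaled-down grid (20 x 16 px) for Monte-Carlo calibration runs."""
    bands = {label: (8 + 3 * i, 11 + 3 * i) for i, label in
             enumerate(("str_oriens", "pyr_layer", "radt_prox", "radt_dist"))}
    return build_geometry(20, 16, 33.3, 37.5, electrode_col=2,
                          layer_band_spec=bands, ca1_cols=(2, 14))


def small_config(**overrides) -> SimConfig:
    overrides.setdefault("n_frames", 128)
    overrides.setdefault("stim_frame", 8)
    return study_config(**overrides)


def null_calibration(
    n_reps: int = 1000,
    n_per_group: int = 7,
    seed: int = 0,
    alpha: float = 0.05,
    smooth: int = 3,
    rectified: bool = True,
) -> float:
    """Type-I error rate of the two-group comparison under the null.

    Both groups are fIPSP-context slices with identical ground truth; each
    replicate runs the full pipeline (render, dF/F, smoothing, ROI trace,
    AUC) on every slice and an unpaired t test between the groups. Returns
    the fraction of replicates rejecting at ``alpha``.
    """
    geometry = small_geometry()
    cfg = small_config()
    whole = layer_rois(geometry)["whole_CA1"]
    v = voltage_field(geometry, cfg, FIPSP_BASELINE)
    children = np.random.SeedSequence(seed).spawn(n_reps * 2 * n_per_group)
    it = iter(children)

    def one_auc(child):
        stack = render_acquisition(v, cfg, seed=child, geometry=geometry)
        dff = _analyze(stack, smooth)
        return auc(extract_trace(dff, whole), mode="hyper", rectified=rectified).value

    rejections = 0
    for _ in range(n_reps):
        a = [one_auc(next(it)) for _ in range(n_per_group)]
        b = [one_auc(next(it)) for _ in range(n_per_group)]
        if compare(a, b, paired=False).p_value < alpha:
            rejections += 1
    return rejections / n_reps


# ---------------------------------------------------------------------------
# one-command study
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of a full synthetic study (round-trips through YAML)."""

    geometry: GeometryModel = field(default_factory=default_geometry)
    sim: SimConfig = field(default_factory=study_config)
    conditions: list[str] = field(default_factory=lambda: ["drug_free", "DHPG"])
    smooth: int = 3
    mode: str = "hyper"
    rectified: bool = True
    seed: int = 0
    write_stacks: bool = False

    def to_dict(self) -> dict:
        return {
            "geometry": self.geometry.to_dict(),
            "sim": dataclasses.asdict(self.sim),
            "conditions": list(self.conditions),
            "smooth": self.smooth,
            "mode": self.mode,
            "rectified": self.rectified,
            "seed": self.seed,
            "write_stacks": self.write_stacks,
        }

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        if "geometry" in kwargs and isinstance(kwargs["geometry"], dict):
            kwargs["geometry"] = GeometryModel.from_dict(kwargs["geometry"])
        if "sim" in kwargs and isinstance(kwargs["sim"], dict):
            sim = dict(kwargs["sim"])
            if "hyper_amp_by_layer" in sim:
                sim["hyper_amp_by_layer"] = dict(sim["hyper_amp_by_layer"])
            kwargs["sim"] = SimConfig(**sim)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        text = str(source)
        if "\n" not in text and Path(text).exists():
            text = Path(text).read_text()
        return cls.from_dict(yaml.safe_load(text))


def run_study(config: RunConfig, outdir) -> dict:
    """Simulate, quantify and compare every configured condition.

    Writes (all regenerable from config + seed): the geometry and ROI JSON,
    per-acquisition AUC table (CSV), percent-of-baseline time courses (CSV),
    paired baseline-vs-washout test results (JSON), optionally the raw TIFF
    series, and a plain-text summary. Returns the output paths.
    """
    from . import io as vio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geometry, cfg = config.geometry, config.sim

    logger.info("run_study: %d conditions, seed=%d", len(config.conditions), config.seed)
    (outdir / "config.yaml").write_text(config.to_yaml())
    (outdir / "geometry.json").write_text(json.dumps(geometry.to_dict(), indent=1))

    rois = layer_rois(geometry)
    ROISet(rois=list(rois)).to_json(outdir / "rois.json")

    auc_rows, tc_rows, tests = [], [], []
    for idx, name in enumerate(config.conditions):
        cond_seed = (config.seed + 7919 * (idx + 1)) % (2 ** 31)
        series = simulate_protocol(geometry, replace(cfg, seed=cond_seed),
                                   get_condition(name), context=FIPSP_BASELINE)
        logger.info("condition %s: %d acquisitions (seed %d)", name, len(series), cond_seed)
        if config.write_stacks:
            vio.save_series(series, outdir / f"series_{name}")
        whole_aucs = []
        for i, stack in enumerate(series):
            dff = _analyze(stack, config.smooth)
            for roi_obj in rois:
                res = auc(extract_trace(dff, roi_obj), mode=config.mode,
                          rectified=config.rectified)
                auc_rows.append({
                    "condition": name, "acquisition": i,
                    "time_min": stack.acquisition_time_min,
                    "roi": roi_obj.label, "mode": config.mode,
                    "rectified": config.rectified, "auc": res.value,
                })
                if roi_obj.label == "whole_CA1":
                    whole_aucs.append(res.value)
        for roi_obj in rois:
            tc = timecourse(series, roi_obj, mode=config.mode,
                            rectified=config.rectified, smooth=config.smooth)
            for t, pct in tc.points:
                tc_rows.append({"condition": name, "roi": roi_obj.label,
                                "time_min": t, "percent": pct,
                                "baseline_auc": tc.baseline_auc})
        nb = series.protocol.n_baseline
        result = compare(whole_aucs[nb:nb + 4], whole_aucs[nb - 4:nb], paired=True,
                         name=f"{name}: washout (first 4) vs baseline (last 4), whole CA1",
                         labels=["washout", "baseline"])
        tests.append(result.to_dict())

    paths = {
        "aucs": outdir / "aucs.csv",
        "timecourses": outdir / "timecourses.csv",
        "tests": outdir / "tests.json",
        "summary": outdir / "summary.txt",
    }
    pd.DataFrame(auc_rows).to_csv(paths["aucs"], index=False)
    pd.DataFrame(tc_rows).to_csv(paths["timecourses"], index=False)
    paths["tests"].write_text(json.dumps(tests, indent=1))

    lines = [f"vsdikit study (schema {vio.SCHEMA_VERSION}), seed {config.seed}",
             f"conditions: {', '.join(config.conditions)}"]
    for t in tests:
        lines.append(
            f"  {t['name']}: t={t['statistic']}, p={t['p_value']}, "
            f"significant={t['significant']}"
        )
    paths["summary"].write_text("\n".join(lines) + "\n")
    return {k: str(v) for k, v in paths.items()}
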