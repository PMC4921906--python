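import math
from dataclasses import replace

import numpy as np
import pytest

import vsdikit as vk
from vsdikit.errors import ConfigurationError, DataError, ProtocolError, UsageError
from vsdikit.quantify import _piecewise_linear_integral


def _trace(values, dt_ms=2.2, stim_frame=20):
    return vk.Trace(values=np.asarray(values, float), dt_ms=dt_ms, stim_frame=stim_frame,
                    roi_label="test")


def riemann_oracle(times, values, t0, t1, rectified, step=0.01):
    """Independent fine-grid Riemann sum over the linear interpolant."""
    grid = np.arange(t0, t1, step) + step / 2
    y = np.interp(grid, times, values)
    if rectified:
        y = np.abs(y)
    return float(y.sum() * step)


class TestExtractTrace:
    def test_zero_stack_zero_trace(self):
        dff = vk.DFFStack(data=np.zeros((6, 4, 4)), dt_ms=1.0, stim_frame=2,
                          f0_map=np.ones((4, 4)))
        roi = vk.ROI("all", "signal", np.ones((4, 4), dtype=bool))
        assert np.all(vk.extract_trace(dff, roi).values == 0)

    def test_single_pixel_roi_in_percent(self, rng):
        data = rng.normal(size=(6, 4, 4))
        dff = vk.DFFStack(data=data, dt_ms=1.0, stim_frame=2, f0_map=np.ones((4, 4)))
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 2] = True
        tr = vk.extract_trace(dff, vk.ROI("px", "signal", mask))
        assert np.allclose(tr.values, data[:, 1, 2] * 100)

    def test_two_pixel_mean(self):
        data = np.zeros((3, 2, 2))
        data[1, 0, 0], data[1, 0, 1] = 0.02, 0.04
        dff = vk.DFFStack(data=data, dt_ms=1.0, stim_frame=2, f0_map=np.ones((2, 2)))
        mask = np.zeros((2, 2), dtype=bool)
        mask[0, :] = True
        tr = vk.extract_trace(dff, vk.ROI("pair", "signal", mask))
        assert tr.values[1] == pytest.approx(0.03 * 100)


class TestAUC:
    def test_zero_trace(self):
        res = vk.auc(_trace(np.zeros(256)), mode="hyper")
        assert res.value == 0.0

    def test_window_start_rounding_to_frames(self):
        """5 ms after the stimulus lands on the 3rd frame at 2.2 ms."""
        tr = _trace(np.zeros(256))
        start, length = vk.default_window(tr, "hyper")
        assert start == pytest.approx(3 * 2.2)
        assert length == 200.0
        d_start, d_length = vk.default_window(tr, "depol")
        assert d_start == pytest.approx(-2.2)
        assert d_length == 30.0

    def test_triangular_pulse_closed_form(self):
        """A triangle of peak 0.1% and 100 ms base inside the window
        integrates to 5.0 %.ms."""
        tr = _trace(np.zeros(256))
        t = tr.times_ms()
        t_stim = 20 * 2.2
        apex, half = t_stim + 70.0, 50.0
        tri = np.clip(1 - np.abs(t - apex) / half, 0, None) * 0.1
        res = vk.auc(_trace(-tri), mode="hyper", rectified=False)
        assert res.value == pytest.approx(0.5 * 100.0 * 0.1, rel=1e-3)

    def test_matches_riemann_oracle_on_random_piecewise_linear(self, rng):
        tr0 = _trace(np.zeros(256))
        times = tr0.times_ms()
        t_stim = 20 * 2.2
        for _ in range(50):
            values = rng.normal(scale=0.05, size=256)
            for mode, rectified in (("hyper", True), ("hyper", False), ("depol", True)):
                tr = _trace(values)
                res = vk.auc(tr, mode=mode, rectified=rectified)
                t0 = t_stim + res.window[0]
                w = values if mode == "depol" else -values
                oracle = riemann_oracle(times, w, t0, t0 + res.window[1], rectified)
                # normalize by the rectified magnitude so the signed mode is
                # not judged against a near-zero denominator
                scale = riemann_oracle(times, w, t0, t0 + res.window[1], True)
                assert abs(res.value - oracle) / scale < 1e-3

    def test_signed_linear_rectified_homogeneous(self, rng):
        values = rng.normal(scale=0.05, size=256)
        a = vk.auc(_trace(values), rectified=False).value
        b = vk.auc(_trace(3 * values), rectified=False).value
        assert b == pytest.approx(3 * a, rel=1e-12)
        ra = vk.auc(_trace(values), rectified=True).value
        rb = vk.auc(_trace(2.5 * values), rectified=True).value
        assert rb == pytest.approx(2.5 * ra, rel=1e-12)
        assert ra >= 0

    def test_window_exceeding_recording_rejected(self):
        with pytest.raises(ConfigurationError):
            vk.auc(_trace(np.zeros(60)), mode="hyper")  # 60 frames < 5+200 ms

    def test_integral_helper_splits_zero_crossings(self):
        # v(t) = t - 1 on [0, 2]: |v| integrates to 1, signed to 0
        t = np.array([0.0, 2.0])
        v = np.array([-1.0, 1.0])
        assert _piecewise_linear_integral(t, v, 0, 2, rectified=True) == pytest.approx(1.0)
        assert _piecewise_linear_integral(t, v, 0, 2, rectified=False) == pytest.approx(0.0)


class TestBackgroundAUC:
    def test_noise_free_zero(self, tiny_geometry, quiet_cfg):
        stack = vk.simulate_acquisition(tiny_geometry, quiet_cfg, "drug_free")
        dff = vk.smooth_spatial(vk.compute_dff(stack), 3)
        line = vk.line_roi(vk.layer_rois(tiny_geometry)["pyr_layer"],
                           tiny_geometry, "dorso_ventral")
        bgs = vk.background_rois(line, tiny_geometry, n=3)
        assert vk.background_auc(dff, bgs) == 0.0

    def test_identical_backgrounds_mean_equals_single(self, tiny_geometry, tiny_cfg):
        stack = vk.simulate_acquisition(tiny_geometry, tiny_cfg, "drug_free", seed=11)
        dff = vk.compute_dff(stack)
        line = vk.line_roi(vk.layer_rois(tiny_geometry)["pyr_layer"],
                           tiny_geometry, "dorso_ventral")
        bg = vk.background_rois(line, tiny_geometry, n=1)
        single = vk.auc(vk.extract_trace(dff, bg.rois[0])).value
        assert vk.background_auc(dff, bg) == pytest.approx(single)

    def test_noise_gives_positive_rectified_small_signed(self, tiny_geometry, tiny_cfg):
        """Rectified background is strictly positive (folded noise) while the
        signed integral stays near zero and below the rectified one."""
        line = vk.line_roi(vk.layer_rois(tiny_geometry)["pyr_layer"],
                           tiny_geometry, "dorso_ventral")
        bgs = vk.background_rois(line, tiny_geometry, n=3)
        rect, signed = [], []
        for seed in range(10):
            stack = vk.simulate_acquisition(tiny_geometry, tiny_cfg, "drug_free",
                                            seed=seed)
            dff = vk.smooth_spatial(vk.compute_dff(stack), 3)
            rect.append(vk.background_auc(dff, bgs, rectified=True))
            signed.append(vk.background_auc(dff, bgs, rectified=False))
        assert min(rect) > 0
        assert abs(np.mean(signed)) < np.mean(rect)


class TestIOCurve:
    def test_flat_zero_for_zero_stacks(self, tiny_geometry):
        roi = vk.layer_rois(tiny_geometry)["whole_CA1"]
        dff = vk.DFFStack(data=np.zeros((128, *tiny_geometry.shape)), dt_ms=2.2,
                          stim_frame=8, f0_map=np.ones(tiny_geometry.shape))
        table = vk.io_curve([(0.0, dff), (10.0, dff), (20.0, dff)], roi)
        assert np.all(table["auc"] == 0)

    def test_proportional_to_io_scale_when_noise_free(self, tiny_geometry, quiet_cfg):
        roi = vk.layer_rois(tiny_geometry)["whole_CA1"]
        items = []
        for v in [0.0, 5.0, 10.0, 15.0, 20.0]:
            cfg_v = replace(quiet_cfg, stim_voltage=v)
            stack = vk.simulate_acquisition(tiny_geometry, cfg_v, "ionotropic_block")
            items.append((v, vk.smooth_spatial(vk.compute_dff(stack), 3)))
        table = vk.io_curve(items, roi)
        scales = np.array([vk.io_scale(v) for v in table["voltage"]])
        ratio = table["auc"].to_numpy() / scales
        assert np.allclose(ratio, ratio[-1], rtol=1e-9)
        assert np.all(np.diff(table["auc"]) >= 0)
        assert abs(table["auc"].iloc[-1] - table["auc"].iloc[-2]) < 0.10 * table["auc"].iloc[-1]

    def test_requires_zero_voltage(self, tiny_geometry):
        roi = vk.layer_rois(tiny_geometry)["whole_CA1"]
        dff = vk.DFFStack(data=np.zeros((128, *tiny_geometry.shape)), dt_ms=2.2,
                          stim_frame=8, f0_map=np.ones(tiny_geometry.shape))
        with pytest.raises(UsageError):
            vk.io_curve([(5.0, dff), (10.0, dff)], roi)


class TestTimecourse:
    def test_drug_free_noise_free_exactly_100(self, tiny_geometry, quiet_cfg):
        series = vk.simulate_protocol(tiny_geometry, quiet_cfg, "drug_free")
        tc = vk.timecourse(series, vk.layer_rois(tiny_geometry)["whole_CA1"],
                           rectified=False)
        assert [p for _, p in tc.points] == pytest.approx([100.0] * 4)

    def test_binning_one_plus_three_points(self, tiny_geometry, quiet_cfg):
        series = vk.simulate_protocol(tiny_geometry, quiet_cfg, "drug_free")
        tc = vk.timecourse(series, vk.layer_rois(tiny_geometry)["whole_CA1"])
        assert len(tc.points) == 4
        assert tc.points[0][0] == 30.0  # first washout acquisition alone
        assert [t for t, _ in tc.points[1:]] == pytest.approx([40.0, 56.0, 72.0])

    def test_baseline_from_last_four(self, tiny_geometry, quiet_cfg):
        series = vk.simulate_protocol(tiny_geometry, quiet_cfg, "drug_free")
        tc = vk.timecourse(series, vk.layer_rois(tiny_geometry)["whole_CA1"])
        vals = [v for _, v in tc.per_acquisition[2:6]]
        assert tc.baseline_auc == pytest.approx(np.mean(vals))

    def test_global_amplitude_step_reads_150_percent(self, tiny_geometry, quiet_cfg):
        """A uniform 1.5x step in hyperpolarization amplitude at drug onset
        appears as 150% of baseline at every post-drug point (signed AUC,
        noise-free)."""
        step = vk.Condition("step_all",
                            hyper_scale_by_layer={l: 1.5 for l in vk.LAYER_LABELS})
        series = vk.simulate_protocol(tiny_geometry, quiet_cfg, step,
                                      context="ionotropic_block")
        tc = vk.timecourse(series, vk.layer_rois(tiny_geometry)["whole_CA1"],
                           rectified=False)
        assert [p for _, p in tc.points] == pytest.approx([150.0] * 4, rel=1e-9)

    def test_wrong_protocol_rejected(self, tiny_geometry, quiet_cfg):
        proto = vk.Protocol(n_baseline=5, n_washout=9)
        series = vk.simulate_protocol(tiny_geometry, quiet_cfg, "drug_free", proto)
        roi = vk.layer_rois(tiny_geometry)["whole_CA1"]
        with pytest.raises(ProtocolError):
            vk.timecourse(series, roi)
        tc = vk.timecourse(series, roi, allow_nonstandard=True)
        assert len(tc.points) == 3  # first alone + two full bins of four


class TestDistributionSummary:
    def test_equal_shares(self):
        shares = vk.distribution_summary({"a": 2.0, "b": 2.0, "c": 2.0, "d": 2.0})
        assert list(shares.values()) == pytest.approx([25.0] * 4)

    def test_arithmetic(self):
        shares = vk.distribution_summary({"a": 4, "b": 2, "c": 1, "d": 1})
        assert shares == pytest.approx({"a": 50.0, "b": 25.0, "c": 12.5, "d": 12.5})
        assert sum(shares.values()) == pytest.approx(100.0)

    def test_zero_total_rejected(self):
        with pytest.raises(DataError):
            vk.distribution_summary({"a": 0.0, "b": 0.0})
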