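import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats as sps

import vsdikit as vk
from vsdikit.errors import ConfigurationError, SaturationError


class TestIOScale:
    def test_zero_voltage_near_floor(self):
        # closed form: 1 / (1 + exp(7.5 / 2))
        assert vk.io_scale(0.0) == pytest.approx(1 / (1 + math.exp(7.5 / 2)))
        assert vk.io_scale(0.0) == pytest.approx(0.023, abs=1e-3)

    def test_midpoint(self):
        assert vk.io_scale(7.5) == 0.5

    def test_plateau_between_15_and_20_volts(self):
        s15, s20 = vk.io_scale(15.0), vk.io_scale(20.0)
        assert s15 >= 0.95 and s20 >= 0.95
        assert abs(s20 - s15) < 0.03

    def test_monotone_in_voltage(self):
        volts = np.linspace(0, 25, 60)
        vals = [vk.io_scale(v) for v in volts]
        assert np.all(np.diff(vals) >= 0)

    def test_negative_voltage_rejected(self):
        with pytest.raises(ConfigurationError):
            vk.io_scale(-1.0)


class TestKinetics:
    def test_unit_peak_and_causality(self):
        t = np.linspace(-20, 600, 4000)
        for rise, decay in [(2, 8), (15, 70), (5, 5)]:
            k = vk.unit_peak_kinetic(t, rise, decay)
            assert k.max() == pytest.approx(1.0, abs=1e-4)
            assert np.all(k[t <= 0] == 0)

    def test_depol_brief_and_hyper_persistent(self, tiny_geometry, quiet_cfg):
        """Depolarization decays below 10% of peak within 35 ms of its peak
        while the hyperpolarization is still above 10% at 150 ms."""
        cfg = quiet_cfg
        t = np.arange(0, 400, 0.01)
        d = vk.unit_peak_kinetic(t, cfg.depol_rise_ms, cfg.depol_decay_ms)
        h = vk.unit_peak_kinetic(t, cfg.hyper_rise_ms, cfg.hyper_decay_ms)
        t_peak = t[np.argmax(d)]
        assert d[t >= t_peak + 35.0][0] < 0.10
        assert h[np.searchsorted(t, 150.0)] > 0.10
        # total hyper duration (above 5% of peak) in the 200-250 ms range
        above = t[h > 0.05]
        assert 200.0 <= above[-1] - above[0] + 0.01 <= 260.0


class TestVoltageField:
    def test_ttx_silences_everything(self, tiny_geometry, quiet_cfg):
        v = vk.voltage_field(tiny_geometry, quiet_cfg, "TTX")
        assert np.all(v == 0)

    def test_ionotropic_block_pure_hyperpolarization(self, tiny_geometry, quiet_cfg):
        v = vk.voltage_field(tiny_geometry, quiet_cfg, "ionotropic_block")
        band = tiny_geometry.band_mask("pyr_layer")
        at_electrode = v[:, band[:, tiny_geometry.electrode_col], tiny_geometry.electrode_col]
        expected = -quiet_cfg.hyper_amp_by_layer["pyr_layer"] * vk.io_scale(
            quiet_cfg.stim_voltage, quiet_cfg.io_v50, quiet_cfg.io_slope
        )
        # peak within one frame of the kinetic peak; never positive
        assert at_electrode.min() == pytest.approx(expected, rel=1e-3)
        assert np.all(v <= 0)

    def test_margin_and_prestimulus_silent(self, tiny_geometry, quiet_cfg):
        v = vk.voltage_field(tiny_geometry, quiet_cfg, "drug_free")
        assert np.all(v[:, tiny_geometry.margin_mask] == 0)
        assert np.all(v[: quiet_cfg.stim_frame + 1] == 0)

    def test_spatial_decay_exact_exponential(self, tiny_geometry, quiet_cfg):
        v = vk.voltage_field(tiny_geometry, quiet_cfg, "ionotropic_block")
        r = tiny_geometry.layer_bands["pyr_layer"][0]
        c0 = tiny_geometry.electrode_col
        ref = v[:, r, c0].min()
        for c in range(c0 + 1, tiny_geometry.ca1_cols[1]):
            d = tiny_geometry.col_distance_um(c)
            expected = ref * math.exp(-d / quiet_cfg.spatial_decay_len_um)
            assert v[:, r, c].min() == pytest.approx(expected, rel=1e-12)

    def test_unknown_condition_and_layer_rejected(self, tiny_geometry, quiet_cfg):
        with pytest.raises(ConfigurationError):
            vk.voltage_field(tiny_geometry, quiet_cfg, "nonexistent_drug")
        bad = vk.Condition("bad", hyper_scale_by_layer={"not_a_layer": 2.0})
        with pytest.raises(ConfigurationError):
            vk.voltage_field(tiny_geometry, quiet_cfg, bad)


class TestConditions:
    def test_registry_invariants(self):
        ttx, ptx, block = (vk.CONDITIONS[k] for k in ("TTX", "PTX", "ionotropic_block"))
        assert ttx.depol_scale == 0 and all(v == 0 for v in ttx.hyper_scale_by_layer.values())
        assert ptx.depol_scale > 1 and all(v == 0 for v in ptx.hyper_scale_by_layer.values())
        assert block.depol_scale == 0 and not block.hyper_scale_by_layer

    def test_dhpg_potentiation_ordering(self):
        pot = vk.CONDITIONS["DHPG"].potentiation_by_layer
        peaks = {k: v[0] for k, v in pot.items()}
        lives = {k: v[1] for k, v in pot.items()}
        assert peaks["radt_prox"] == max(peaks.values())
        assert lives["radt_prox"] == max(lives.values())
        assert peaks["str_oriens"] == min(peaks.values())

    def test_compose_multiplies_scales(self):
        c = vk.compose("ionotropic_block", "PTX")
        assert c.depol_scale == 0.0
        assert all(v == 0 for v in c.hyper_scale_by_layer.values())

    def test_potentiation_clock(self):
        cond = replace(vk.CONDITIONS["DHPG"], onset_min=20.0, offset_min=30.0)
        peak, half = cond.potentiation_by_layer["radt_prox"]
        assert cond.potentiation_factor("radt_prox", 20.0) == 1.0  # still pre-drug
        assert cond.potentiation_factor("radt_prox", 25.0) == 1.0 + peak
        assert cond.potentiation_factor("radt_prox", 30.0) == 1.0 + peak
        assert cond.potentiation_factor("radt_prox", 30.0 + half) == pytest.approx(
            1.0 + peak / 2
        )


class TestRenderAcquisition:
    def test_zero_field_zero_noise_gives_f0(self, tiny_geometry, quiet_cfg):
        v = np.zeros((quiet_cfg.n_frames,) + tiny_geometry.shape)
        stack = vk.render_acquisition(v, quiet_cfg, geometry=tiny_geometry)
        assert np.all(stack.data == quiet_cfg.f0)

    def test_transduction_sign(self, tiny_geometry, quiet_cfg):
        v = np.zeros((quiet_cfg.n_frames,) + tiny_geometry.shape)
        v[5, 0, 0] = 1.0   # depolarized
        v[6, 0, 0] = -1.0  # hyperpolarized
        stack = vk.render_acquisition(v, quiet_cfg, geometry=tiny_geometry)
        assert stack.data[5, 0, 0] < quiet_cfg.f0 < stack.data[6, 0, 0]

    def test_transduction_monotone_and_linear(self, tiny_geometry, quiet_cfg):
        shape = (quiet_cfg.n_frames,) + tiny_geometry.shape
        v1, v2 = np.full(shape, -0.5), np.full(shape, -1.0)
        f1 = vk.render_acquisition(v1, quiet_cfg).data
        f2 = vk.render_acquisition(v2, quiet_cfg).data
        assert np.all(f2 >= f1)  # more hyperpolarized -> brighter
        dev1, dev2 = f1 - quiet_cfg.f0, f2 - quiet_cfg.f0
        assert np.allclose(dev2, 2 * dev1, rtol=1e-12)

    def test_saturation_rejected(self, tiny_geometry, quiet_cfg):
        v = np.full((quiet_cfg.n_frames,) + tiny_geometry.shape, 1.0 / quiet_cfg.gain)
        with pytest.raises(SaturationError):
            vk.render_acquisition(v, quiet_cfg)

    @pytest.mark.parametrize("mode", ["per_sweep", "averaged"])
    def test_sweep_averaging_reduces_noise(self, tiny_geometry, mode):
        cfg = vk.SimConfig(n_frames=256, stim_frame=8, noise_sd=10.0, n_sweeps=15,
                           sweep_noise=mode)
        v = np.zeros((cfg.n_frames,) + tiny_geometry.shape)
        stack = vk.render_acquisition(v, cfg, seed=7)
        sd = stack.data[:, 0, 0].std(ddof=1)
        assert sd == pytest.approx(10.0 / math.sqrt(15), rel=0.15)

    def test_deterministic_given_seed(self, tiny_geometry, tiny_cfg):
        v = vk.voltage_field(tiny_geometry, tiny_cfg, "drug_free")
        a = vk.render_acquisition(v, tiny_cfg, seed=42).data
        b = vk.render_acquisition(v, tiny_cfg, seed=42).data
        c = vk.render_acquisition(v, tiny_cfg, seed=43).data
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_ttx_pixels_match_margin_pixels(self, tiny_geometry, tiny_cfg):
        """Under TTX, CA1 pixels carry pure noise indistinguishable from the
        margin (two-sample test at alpha = 0.01)."""
        stack = vk.simulate_acquisition(tiny_geometry, tiny_cfg, "TTX", seed=5)
        ca1 = stack.data[:, tiny_geometry.ca1_mask()].ravel()
        margin = stack.data[:, tiny_geometry.margin_mask].ravel()
        p = sps.ttest_ind(ca1, margin).pvalue
        assert p > 0.01


class TestProtocol:
    def test_sweep_window_duration_70_s(self, tiny_geometry, quiet_cfg):
        series = vk.simulate_protocol(tiny_geometry, quiet_cfg, "drug_free")
        assert series.acquisition_duration_s == pytest.approx(70.0)

    def test_schedule_6_plus_13_at_4_min(self, tiny_geometry, quiet_cfg):
        series = vk.simulate_protocol(tiny_geometry, quiet_cfg, "drug_free")
        times = [s.acquisition_time_min for s in series]
        assert len(times) == 19
        assert times[:6] == [0, 4, 8, 12, 16, 20]
        assert np.allclose(np.diff(times[6:]), 4.0)
        assert times[6] == series.protocol.drug_offset_min

    def test_drug_free_identical_ground_truth(self, tiny_geometry, quiet_cfg):
        series = vk.simulate_protocol(tiny_geometry, quiet_cfg, "drug_free")
        ref = series.stacks[0].data
        for stack in series:
            assert np.array_equal(stack.data, ref)

    def test_dhpg_potentiates_radt_prox_most_at_first_washout(
        self, tiny_geometry, quiet_cfg
    ):
        base = vk.simulate_protocol(tiny_geometry, quiet_cfg, "drug_free",
                                    context="ionotropic_block")
        dhpg = vk.simulate_protocol(tiny_geometry, quiet_cfg, "DHPG",
                                    context="ionotropic_block")
        i = 6  # first washout acquisition

        def amp(series, layer):
            # hyperpolarization raises fluorescence above f0
            band = tiny_geometry.band_mask(layer)
            return (series.stacks[i].data[:, band] - quiet_cfg.f0).max()

        excess = {
            layer: amp(dhpg, layer) / amp(base, layer) - 1.0
            for layer in ("radt_prox", "pyr_layer")
        }
        assert excess["radt_prox"] > excess["pyr_layer"] > 0
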