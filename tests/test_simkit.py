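"""Simulator statistics against its own analytic oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gpfcs as g
from gpfcs.simkit import (
    CHANNEL_STEP_NM,
    analytic_channel_gp,
    default_channel_centers,
    lambda_max_for_gp,
)

from conftest import make_config


class TestConfigValidation:
    def test_gp_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="gp_true"):
            make_config(gp_true=1.5)

    @pytest.mark.parametrize("field", ["d_true", "brightness", "k_off", "bleach_rate"])
    def test_negative_rates_rejected(self, field):
        with pytest.raises(ValueError, match=field):
            make_config(**{field: -1.0})

    def test_too_few_bins_rejected(self):
        cfg = make_config(duration=5e-6, bin_width=1e-6)
        with pytest.raises(ValueError, match="10"):
            g.simulate_trace(cfg)

    def test_step_constraint_names_bin_width(self):
        # one 1-ms bin moves a molecule far beyond omega0/10 at D = 5
        cfg = make_config(d_true=5.0, bin_width=1e-3, duration=1.0)
        with pytest.raises(ValueError, match="bin_width"):
            g.simulate_trace(cfg)


class TestTraceStatistics:
    def test_seed_determinism(self):
        cfg = make_config(duration=0.2, bin_width=1e-5, seed=3)
        a, b = g.simulate_trace(cfg), g.simulate_trace(cfg)
        assert np.array_equal(a.counts_blue, b.counts_blue)
        assert np.array_equal(a.counts_red, b.counts_red)

    def test_seed_determinism_with_events(self):
        cfg = make_config(
            duration=0.3, bin_width=1e-4, d_true=1.0, k_off=50.0, bleach_rate=5.0, seed=3
        )
        a, b = g.simulate_trace(cfg), g.simulate_trace(cfg)
        assert np.array_equal(a.counts_blue, b.counts_blue)

    def test_zero_brightness_gives_empty_trace(self):
        cfg = make_config(brightness=0.0, duration=0.1, bin_width=1e-5)
        tr = g.simulate_trace(cfg)
        assert tr.counts_blue.sum() == 0 and tr.counts_red.sum() == 0

    @pytest.mark.parametrize("gp_true", [-0.5, 0.0, 0.66])
    def test_channel_split_matches_gp(self, gp_true):
        """Blue-photon fraction is (1 + GP) / 2 within binomial error."""
        cfg = make_config(gp_true=gp_true, duration=0.5, bin_width=1e-5, seed=11)
        tr = g.simulate_trace(cfg)
        nb, total = tr.counts_blue.sum(), tr.counts_blue.sum() + tr.counts_red.sum()
        p = (1.0 + gp_true) / 2.0
        se = np.sqrt(p * (1 - p) / total)
        assert abs(nb / total - p) < 4 * se

    def test_mean_count_rate_matches_analytic(self):
        """Detected rate = c * B * pi * omega0^2 / 2 within 3 SE.

        The SE is estimated from the trace itself by blocking (the noise
        is dominated by slow occupancy fluctuations, not shot noise).
        """
        cfg = make_config(duration=4.0, bin_width=1e-5, d_true=5.0, seed=21)
        tr = g.simulate_trace(cfg)
        blocks = (tr.counts_blue + tr.counts_red).reshape(16, -1).mean(axis=1)
        rate = blocks.mean() / cfg.bin_width / 1e3
        se = blocks.std(ddof=1) / np.sqrt(16) / cfg.bin_width / 1e3
        assert abs(rate - g.expected_count_rate_khz(cfg)) < 3 * se

    def test_permanent_dye_bleaches_exchangeable_does_not(self):
        common = dict(duration=2.0, bin_width=1e-4, d_true=1.0, seed=5)
        perm = g.simulate_trace(make_config(bleach_rate=20.0, **common))
        exch = g.simulate_trace(make_config(bleach_rate=20.0, k_off=50.0, **common))
        t = (np.arange(10) + 0.5) * 0.2

        def log_slope(tr):
            blocks = (tr.counts_blue + tr.counts_red).reshape(10, -1).mean(axis=1)
            return np.polyfit(t, np.log(blocks), 1)[0]

        assert log_slope(perm) < -0.1
        assert abs(log_slope(exch)) < 0.15


class TestSpectralOracles:
    @settings(max_examples=25, deadline=None)
    @given(
        gp=st.floats(-0.85, 0.85),
        sigma=st.floats(18.0, 45.0),
    )
    def test_lambda_max_inverts_gp(self, gp, sigma):
        lam = lambda_max_for_gp(gp, sigma)
        assert analytic_channel_gp(lam, sigma) == pytest.approx(gp, abs=1e-9)

    def test_red_shift_decreases_gp(self):
        centers = default_channel_centers()
        gps = [analytic_channel_gp(lam, 30.0, centers) for lam in (580.0, 600.0, 620.0)]
        assert gps[0] > gps[1] > gps[2]


class TestVesicleStack:
    def two_phase_config(self, **kw):
        defaults = dict(
            phases=[
                g.VesiclePhase(0.0, np.pi, 200.0, lambda_max=575.0),
                g.VesiclePhase(np.pi, 2 * np.pi, 200.0, lambda_max=610.0),
            ],
            seed=2,
        )
        defaults.update(kw)
        return g.VesicleImageConfig(**defaults)

    def test_empty_scene_is_all_zero(self):
        cfg = g.VesicleImageConfig(
            phases=[g.VesiclePhase(0.0, 2 * np.pi, 0.0, lambda_max=600.0)],
            background=0.0,
        )
        assert g.simulate_vesicle_stack(cfg).pixels.sum() == 0

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError, match="amplitude"):
            g.VesiclePhase(0.0, 2 * np.pi, -1.0, lambda_max=600.0)

    def test_sectors_must_partition_circle(self):
        with pytest.raises(ValueError, match="partition"):
            g.VesicleImageConfig(
                phases=[
                    g.VesiclePhase(0.0, 2.0, 10.0, lambda_max=600.0),
                    g.VesiclePhase(3.0, 2 * np.pi, 10.0, lambda_max=600.0),
                ]
            )

    def test_determinism_and_channel_count(self):
        cfg = self.two_phase_config()
        a, b = g.simulate_vesicle_stack(cfg), g.simulate_vesicle_stack(cfg)
        assert np.array_equal(a.pixels, b.pixels)
        assert a.n_channels == 32
        assert a.channel_centers[1] - a.channel_centers[0] == pytest.approx(CHANNEL_STEP_NM)


class TestTimelapse:
    def test_permanent_membrane_decays_geometrically(self):
        frames = g.simulate_timelapse(
            "permanent", 3, 0.1, seed=4, membrane_intensity=400.0
        )
        mem = g.timelapse_masks()["membrane"]
        vals = np.array([f.total_intensity[mem].mean() for f in frames])
        ratios = vals / vals[0]
        assert np.allclose(ratios, [1.0, 0.9, 0.81], atol=0.03)

    def test_exchangeable_membrane_is_stationary(self):
        frames = g.simulate_timelapse("exchangeable", 12, 0.2, seed=4)
        mem = g.timelapse_masks()["membrane"]
        vals = np.array([f.total_intensity[mem].mean() for f in frames])
        assert np.all(np.abs(vals / vals[0] - 1.0) < 0.05)

    def test_zero_internalization_keeps_ratio_flat(self):
        frames = g.simulate_timelapse("exchangeable", 8, 0.0, 0.0, seed=4)
        masks = g.timelapse_masks()
        ratio = np.array(
            [
                f.total_intensity[masks["cytosol"]].mean()
                / f.total_intensity[masks["membrane"]].mean()
                for f in frames
            ]
        )
        assert ratio.std() < 0.2 * ratio.mean() + 0.01

    def test_frame_count_validation(self):
        with pytest.raises(ValueError, match="frames"):
            g.simulate_timelapse("permanent", 1, 0.1)
        with pytest.raises(ValueError, match="bleach_per_frame"):
            g.simulate_timelapse("permanent", 3, 1.5)
        with pytest.raises(ValueError, match="dye_kind"):
            g.simulate_timelapse("sticky", 3, 0.1)
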