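"""GP imaging: ratiometric math, masks, thresholds, and the spectral
generator's analytic oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gpfcs as g
from gpfcs import (
    ChannelStack,
    VesicleImageConfig,
    VesiclePhase,
    analytic_sector_gp,
    delta_gp,
    experiment_mean_gp,
    gp_from_spectral,
    gp_from_two_channel,
    mean_spectrum,
    sector_masks,
    simulate_vesicle_stack,
)
from gpfcs.simkit import default_channel_centers


def banded(ordered, disordered):
    return ChannelStack(
        np.stack([ordered, disordered], axis=2).astype(float),
        kind="banded",
        band_edges=[(580, 630), (650, 700)],
    )


def spectral(pixels):
    return ChannelStack(pixels, kind="spectral", channel_centers=default_channel_centers())


@pytest.fixture(scope="module")
def two_phase():
    # background-free so the noiseless channel-integral oracle applies
    cfg = VesicleImageConfig(
        phases=[
            VesiclePhase(0.0, np.pi, 300.0, lambda_max=575.0),
            VesiclePhase(np.pi, 2 * np.pi, 300.0, lambda_max=610.0),
        ],
        background=0.0,
        seed=5,
    )
    return cfg, simulate_vesicle_stack(cfg)


class TestSpectralGP:
    def test_balanced_and_one_sided_pixels(self):
        px = np.zeros((1, 2, 32))
        px[0, 0, [1, 8]] = 50.0  # channels nearest 575 and 640 nm
        px[0, 1, 1] = 80.0  # blue only
        img = gp_from_spectral(spectral(px), threshold=10.0)
        assert img.gp[0, 0] == pytest.approx(0.0)
        assert img.gp[0, 1] == pytest.approx(1.0)

    def test_wavelengths_validated(self):
        px = np.ones((2, 2, 32))
        with pytest.raises(ValueError, match="outside channel range"):
            gp_from_spectral(spectral(px), lambda_b=400.0)
        with pytest.raises(ValueError, match="lambda_b"):
            gp_from_spectral(spectral(px), lambda_b=650.0, lambda_r=600.0)

    def test_all_masked_is_flagged_not_raised(self):
        img = gp_from_spectral(spectral(np.ones((4, 4, 32))), threshold=1e9)
        assert img.n_valid == 0 and np.isnan(img.mean_gp)

    def test_threshold_monotonicity(self, two_phase):
        _, stack = two_phase
        masks = [
            gp_from_spectral(stack, threshold=t).mask for t in (20.0, 40.0, 80.0)
        ]
        assert np.all(masks[1] <= masks[0]) and np.all(masks[2] <= masks[1])

    def test_sector_gp_matches_analytic_oracle(self, two_phase):
        """Per-sector mean GP equals the noiseless channel-integral GP
        within Poisson error of the sector mean."""
        cfg, stack = two_phase
        # crest-level threshold: compare where per-pixel counting error of
        # the intensity ratio is small
        img = gp_from_spectral(stack, threshold=500.0)
        for phase, mask in zip(cfg.phases, sector_masks(cfg)):
            sel = mask & img.mask
            vals = img.gp[sel]
            se = vals.std() / np.sqrt(vals.size)
            expected = analytic_sector_gp(phase, cfg)
            assert vals.mean() == pytest.approx(expected, abs=max(4 * se, 0.02))

    def test_lo_ld_delta_gp_positive(self, two_phase):
        """A ~35 nm red shift between phases gives Lo GP > Ld GP."""
        cfg, stack = two_phase
        img = gp_from_spectral(stack)
        lo, ld = sector_masks(cfg)
        assert delta_gp(img, lo, ld) > 0

    def test_gp_values_bounded(self, two_phase):
        _, stack = two_phase
        img = gp_from_spectral(stack)
        assert np.all(np.abs(img.gp[img.mask]) <= 1.0)


class TestTwoChannelGP:
    def test_uniform_image_fully_valid_constant_gp(self):
        img = gp_from_two_channel(banded(np.full((8, 8), 30.0), np.full((8, 8), 10.0)))
        assert img.n_valid == 64
        assert np.allclose(img.gp, 0.5)

    def test_equal_bands_give_zero_mean_gp(self):
        img = gp_from_two_channel(banded(np.full((4, 4), 9.0), np.full((4, 4), 9.0)))
        assert img.mean_gp == pytest.approx(0.0)

    def test_region_gp_recovered_from_poisson_counts(self, rng):
        """Ordered-rich (GP 0.5) and disordered (GP -0.2) regions recover
        their ground truth within Poisson tolerance."""
        amp, n = 400.0, 24
        gp_map = np.where(np.arange(n)[:, None] < n // 2, 0.5, -0.2)
        ordered = rng.poisson(amp * (1 + gp_map) / 2)
        disordered = rng.poisson(amp * (1 - gp_map) / 2)
        img = gp_from_two_channel(banded(ordered, disordered), 0.25)
        top = img.gp[: n // 2][img.mask[: n // 2]]
        bottom = img.gp[n // 2 :][img.mask[n // 2 :]]
        assert top.mean() == pytest.approx(0.5, abs=4 * top.std() / np.sqrt(top.size))
        assert bottom.mean() == pytest.approx(
            -0.2, abs=4 * bottom.std() / np.sqrt(bottom.size)
        )

    @settings(max_examples=20, deadline=None)
    @given(scale=st.floats(0.1, 20.0))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(3)
        o = rng.poisson(50.0, (6, 6)).astype(float)
        d = rng.poisson(30.0, (6, 6)).astype(float)
        a = gp_from_two_channel(banded(o, d), 0.3)
        b = gp_from_two_channel(banded(o * scale, d * scale), 0.3)
        assert np.array_equal(a.mask, b.mask)
        np.testing.assert_allclose(
            a.gp[a.mask], b.gp[b.mask], rtol=1e-12, atol=1e-12
        )

    def test_threshold_fraction_validated(self):
        img = banded(np.ones((2, 2)), np.ones((2, 2)))
        with pytest.raises(ValueError, match="threshold_fraction"):
            gp_from_two_channel(img, 1.5)


class TestDeltaGP:
    def test_identical_masks_give_zero_and_swap_flips_sign(self, two_phase):
        cfg, stack = two_phase
        img = gp_from_spectral(stack)
        lo, ld = sector_masks(cfg)
        assert delta_gp(img, lo, lo) == 0.0
        assert delta_gp(img, lo, ld) == -delta_gp(img, ld, lo)

    def test_empty_mask_named_in_error(self, two_phase):
        _, stack = two_phase
        img = gp_from_spectral(stack)
        empty = np.zeros(img.gp.shape, bool)
        with pytest.raises(ValueError, match="mask_b"):
            delta_gp(img, img.mask, empty)


class TestMeanSpectrum:
    def test_delta_spectrum_argmax(self):
        px = np.zeros((2, 2, 32))
        px[:, :, 5] = 9.0
        spec, peak = mean_spectrum(spectral(px), np.ones((2, 2), bool))
        assert peak == default_channel_centers()[5]

    def test_gaussian_peak_located_within_one_channel(self, two_phase):
        cfg, stack = two_phase
        _, ld_mask = sector_masks(cfg)
        bright = stack.total_intensity > 100
        _, peak = mean_spectrum(stack, ld_mask & bright)
        assert abs(peak - 610.0) <= cfg.channel_step

    def test_single_pixel_mask_returns_its_values(self):
        px = np.arange(32.0).reshape(1, 1, 32)
        mask = np.ones((1, 1), bool)
        spec, _ = mean_spectrum(spectral(px), mask)
        np.testing.assert_array_equal(spec, px[0, 0])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mean_spectrum(spectral(np.ones((2, 2, 32))), np.zeros((2, 2), bool))


class TestAggregation:
    def test_experiment_mean_is_mean_of_image_means(self):
        imgs = [
            gp_from_two_channel(banded(np.full((3, 3), a), np.full((3, 3), b)))
            for a, b in [(30.0, 10.0), (10.0, 30.0)]
        ]
        assert experiment_mean_gp(imgs) == pytest.approx(0.0)

    def test_red_shift_strictly_decreases_mean_gp(self):
        means = []
        for lam in (580.0, 600.0, 620.0):
            cfg = VesicleImageConfig(
                phases=[VesiclePhase(0.0, 2 * np.pi, 300.0, lambda_max=lam)], seed=8
            )
            img = gp_from_spectral(simulate_vesicle_stack(cfg))
            means.append(img.mean_gp)
        assert means[0] > means[1] > means[2]
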