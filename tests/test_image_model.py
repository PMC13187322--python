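import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memtopo import (
    FrameStack,
    PipelineConfig,
    UncertainValue,
    average_channels,
    gaussian_blur,
    propagate_difference,
    propagate_ratio,
    read_stack,
    subtract_background,
    write_stack,
)


def make_stack(n_frames=2, n_channels=2, size=16, roles=None):
    rng = np.random.default_rng(0)
    data = rng.uniform(0, 10, size=(n_frames, n_channels, size, size))
    roles = roles or {0: "membrane_reference", 1: "receptor"}
    return FrameStack(data=data, channel_roles=roles)


class TestFrameStack:
    def test_requires_four_axes(self):
        with pytest.raises(ValueError, match="frame, channel"):
            FrameStack(np.zeros((4, 4)), {0: "receptor"})

    def test_rejects_negative_and_nonfinite(self):
        with pytest.raises(ValueError, match="negative"):
            FrameStack(np.full((1, 1, 4, 4), -1.0), {0: "receptor"})
        bad = np.zeros((1, 1, 4, 4))
        bad[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            FrameStack(bad, {0: "receptor"})

    def test_role_index_out_of_range(self):
        with pytest.raises(ValueError, match="channel 5"):
            FrameStack(np.zeros((1, 3, 4, 4)), {5: "receptor"})

    def test_duplicate_roles_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            FrameStack(np.zeros((1, 2, 4, 4)), {0: "receptor", 1: "receptor"})

    def test_channel_lookup(self):
        s = make_stack()
        assert s.channel_index("receptor") == 1
        assert s.channel("receptor", 0).shape == (16, 16)
        with pytest.raises(KeyError):
            s.channel_index("target")


class TestReadStack:
    def test_multiframe_multichannel_roundtrip(self, tmp_path):
        roles = {0: "receptor", 1: "protein", 2: "target"}
        stack = make_stack(n_frames=30, n_channels=3, roles=roles)
        path = tmp_path / "stack.tiff"
        write_stack(path, stack)
        back = read_stack(path, roles)
        assert back.data.shape == (30, 3, 16, 16)
        np.testing.assert_allclose(back.data, stack.data, rtol=1e-6)

    def test_single_plane_gets_degenerate_axes(self, tmp_path):
        import tifffile

        path = tmp_path / "plane.tiff"
        tifffile.imwrite(path, np.ones((8, 8), dtype=np.float32))
        back = read_stack(path, {0: "receptor"})
        assert back.data.shape == (1, 1, 8, 8)

    def test_declared_role_out_of_range_errors(self, tmp_path):
        path = tmp_path / "s.tiff"
        write_stack(path, make_stack(n_frames=2, n_channels=3,
                                     roles={0: "receptor", 1: "protein", 2: "target"}))
        with pytest.raises(ValueError):
            read_stack(path, {0: "receptor", 1: "protein", 5: "target"})

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_stack("/nonexistent/stack.tiff", {0: "receptor"})

    def test_channel_count_mismatch(self, tmp_path):
        path = tmp_path / "s.tiff"
        write_stack(path, make_stack(n_frames=2, n_channels=2))
        with pytest.raises(ValueError, match="channel"):
            read_stack(path, {0: "receptor"})


class TestSubtractBackground:
    def test_constant_image_removed(self):
        out = subtract_background(np.full((64, 64), 7.5), 50)
        np.testing.assert_allclose(out, 0.0)

    def test_single_bright_pixel_retained(self):
        # oracle: the true rolling ball on the same toy agrees
        from skimage.restoration import rolling_ball

        img = np.zeros((101, 101))
        img[50, 50] = 100.0
        out = subtract_background(img, 50)
        assert abs(out[50, 50] - 100.0) <= 1.0
        oracle = img - rolling_ball(img, radius=50)
        assert abs(oracle[50, 50] - 100.0) <= 1.0

    def test_shape_preserved_and_nonnegative(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 50, (40, 60))
        out = subtract_background(img, 20)
        assert out.shape == img.shape
        assert np.all(out >= 0)

    def test_idempotent_on_flat_residual(self):
        img = np.full((64, 64), 3.0)
        once = subtract_background(img, 50)
        twice = subtract_background(once, 50)
        assert np.max(np.abs(twice - once)) <= 1e-6 * max(img.max(), 1)

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            subtract_background(np.zeros((8, 8)), 0)

    def test_ball_kernel_also_available(self):
        img = np.full((32, 32), 5.0)
        np.testing.assert_allclose(subtract_background(img, 5, kernel="ball"), 0.0)

    def test_default_radius_50_matches_config(self):
        assert PipelineConfig().pre_rolling_ball_radius_px == 50


class TestGaussianBlur:
    def test_sigma_zero_identity(self):
        img = np.random.default_rng(0).uniform(0, 1, (16, 16))
        np.testing.assert_array_equal(gaussian_blur(img, 0), img)

    def test_delta_impulse_matches_explicit_kernel(self):
        # oracle: analytic normalised Gaussian kernel
        sigma = 2.0
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        out = gaussian_blur(img, sigma)
        assert abs(out.sum() - 1.0) <= 1e-6
        yy, xx = np.mgrid[-20:21, -20:21]
        kernel = np.exp(-(yy**2 + xx**2) / (2 * sigma**2))
        kernel /= kernel.sum()
        np.testing.assert_allclose(out, kernel, atol=1e-4)

    def test_negative_sigma_errors(self):
        with pytest.raises(ValueError):
            gaussian_blur(np.zeros((4, 4)), -1.0)

    def test_defaults_cover_both_published_sigmas(self):
        cfg = PipelineConfig()
        assert cfg.pre_blur_sigma_px == 1.0
        assert cfg.seg_blur_sigma_px == 2.0


class TestAverageChannels:
    def test_mean_of_constant_channels(self):
        data = np.stack([np.full((1, 8, 8), 2.0), np.full((1, 8, 8), 4.0)], axis=1)
        s = FrameStack(data, {0: "membrane_reference", 1: "receptor"})
        np.testing.assert_allclose(
            average_channels(s, ["membrane_reference", "receptor"], 0), 3.0
        )

    def test_single_role_verbatim(self):
        s = make_stack()
        np.testing.assert_array_equal(
            average_channels(s, ["receptor"], 1), s.channel("receptor", 1)
        )

    def test_empty_roles_error(self):
        with pytest.raises(ValueError):
            average_channels(make_stack(), [], 0)

    def test_unknown_role_error(self):
        with pytest.raises(KeyError):
            average_channels(make_stack(), ["target"], 0)


class TestPropagation:
    def test_difference_worked_example(self):
        out = propagate_difference(UncertainValue(1.8, 0.3), UncertainValue(1.2, 0.4))
        assert out.value == pytest.approx(0.6)
        assert out.sem == pytest.approx(0.5)  # sqrt(0.09 + 0.16)

    def test_ratio_unit_denominator(self):
        out = propagate_ratio(UncertainValue(3.2, 0.7), UncertainValue(1.0, 0.0))
        assert (out.value, out.sem) == (pytest.approx(3.2), pytest.approx(0.7))

    def test_ratio_equal_exact(self):
        out = propagate_ratio(UncertainValue(2.0, 0.0), UncertainValue(2.0, 0.0))
        assert (out.value, out.sem) == (1.0, 0.0)

    def test_ratio_zero_numerator_convention(self):
        out = propagate_ratio(UncertainValue(0.0, 0.5), UncertainValue(2.0, 0.1))
        assert out.value == 0.0
        assert out.sem == pytest.approx(0.25)

    def test_ratio_zero_denominator_errors(self):
        with pytest.raises(ZeroDivisionError):
            propagate_ratio(UncertainValue(1.0, 0.1), UncertainValue(0.0, 0.1))

    def test_negative_sem_rejected(self):
        with pytest.raises(ValueError):
            UncertainValue(1.0, -0.1)

    def test_monte_carlo_oracle(self):
        # 1e5 Gaussian draws; sems agree within 3% relative
        rng = np.random.default_rng(12345)
        a = rng.normal(1.8, 0.3, 100_000)
        b = rng.normal(1.2, 0.4, 100_000)
        diff = propagate_difference(UncertainValue(1.8, 0.3), UncertainValue(1.2, 0.4))
        assert abs((a - b).std() - diff.sem) / diff.sem <= 0.03
        # ratio: first-order propagation is exact only for small relative
        # errors, so check it at 5% level errors
        c = rng.normal(1.8, 0.09, 100_000)
        d = rng.normal(1.2, 0.06, 100_000)
        ratio = propagate_ratio(UncertainValue(1.8, 0.09), UncertainValue(1.2, 0.06))
        assert abs((c / d).std() - ratio.sem) / ratio.sem <= 0.03

    @settings(max_examples=50, deadline=None)
    @given(
        av=st.floats(-5, 5), asem=st.floats(0, 2),
        bv=st.floats(-5, 5), bsem=st.floats(0, 2),
    )
    def test_difference_properties(self, av, asem, bv, bsem):
        out = propagate_difference(UncertainValue(av, asem), UncertainValue(bv, bsem))
        assert out.value == pytest.approx(av - bv)
        assert out.sem >= max(asem, bsem) - 1e-12
        assert out.sem**2 == pytest.approx(asem**2 + bsem**2)


class TestPipelineConfig:
    def test_defaults_match_published_parameters(self):
        cfg = PipelineConfig()
        assert cfg.body_dilate_px == 9
        assert cfg.neighbourhood_dilate_px == 35
        assert cfg.cluster_threshold == 2.0
        assert (cfg.cluster_area_min_px, cfg.cluster_area_max_px) == (5, 100)

    def test_validation(self):
        with pytest.raises(ValueError):
            PipelineConfig(cluster_area_min_px=10, cluster_area_max_px=5)
        with pytest.raises(ValueError):
            PipelineConfig(cluster_threshold=0.0)
        with pytest.raises(ValueError):
            PipelineConfig(membrane_threshold_method="fixed")

    def test_yaml_json_roundtrip(self, tmp_path):
        cfg = PipelineConfig(holes_radius_px=60, caax_reference_enrichment=UncertainValue(1.1, 0.05))
        for name in ("cfg.yaml", "cfg.json"):
            p = tmp_path / name
            cfg.save(p)
            back = PipelineConfig.from_file(p)
            assert back == cfg
            assert back.config_hash() == cfg.config_hash()
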