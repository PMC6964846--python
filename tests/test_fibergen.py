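"""Fiber-image simulator: sampling, rendering, finalization, references."""

import numpy as np
import pytest
from scipy.stats import kstest

from fiberorient.fibergen import (
    FiberSpec,
    SimulationConfig,
    _rasterize_fiber,
    finalize_image,
    reference_parameters,
    render_fibers,
    sample_vonmises,
    simulate,
)
from fiberorient.model_fitting import VonMisesParams


class TestSampleVonMises:
    def test_support(self):
        angles = sample_vonmises(5000, VonMisesParams(80.0, 3.0), seed=0)
        assert np.all((angles >= 0.0) & (angles < 180.0))

    def test_isotropic_limit_is_uniform(self):
        angles = sample_vonmises(10000, VonMisesParams(0.0, 0.0), seed=1)
        stat = kstest(angles / 180.0, "uniform")
        assert stat.pvalue > 0.01

    def test_concentrated_samples_center_on_mean(self):
        angles = sample_vonmises(10000, VonMisesParams(45.0, 5.0), seed=2)
        t2 = np.deg2rad(angles) * 2.0
        mean = np.degrees(0.5 * np.arctan2(np.sin(t2).sum(), np.cos(t2).sum()))
        assert abs(mean - 45.0) < 1.0

    def test_seed_reproducible(self):
        a = sample_vonmises(100, VonMisesParams(10.0, 1.0), seed=7)
        b = sample_vonmises(100, VonMisesParams(10.0, 1.0), seed=7)
        assert np.array_equal(a, b)


class TestRenderFibers:
    def test_single_fiber_area(self):
        """A width-5, AR-15 fiber covers w^2 * AR = 375 px^2 of area; the
        rasterized coverage sum matches and the solidly covered pixel count
        is within rasterization slack."""
        config = SimulationConfig(width=5.0, aspect_ratio=15.0, k=1.0, seed=0)
        canvas = np.zeros(config.size)
        _rasterize_fiber(canvas, FiberSpec(angle=0.0, width=5.0, length=75.0,
                                           center=(256.0, 256.0)))
        assert canvas.sum() == pytest.approx(375.0, rel=0.01)
        assert abs(np.count_nonzero(canvas >= 0.5) - 375) <= 37

    def test_overlap_adds(self):
        fiber = FiberSpec(angle=30.0, width=3.0, length=60.0, center=(64.0, 64.0))
        once = np.zeros((128, 128))
        _rasterize_fiber(once, fiber)
        twice = np.zeros((128, 128))
        _rasterize_fiber(twice, fiber)
        _rasterize_fiber(twice, fiber)
        assert np.allclose(twice, 2.0 * once)

    def test_no_fibers_gives_blank_canvas(self):
        config = SimulationConfig(k=1.0)
        canvas, fibers = render_fibers(config, np.array([]), np.random.default_rng(0))
        assert canvas.sum() == 0.0 and fibers == []

    def test_fibers_fit_inside_image(self):
        config = SimulationConfig(width=10.0, aspect_ratio=45.0, k=0.05, seed=3)
        rng = np.random.default_rng(3)
        canvas, fibers = render_fibers(config, np.linspace(0, 179, 20), rng)
        border = np.concatenate([canvas[0], canvas[-1], canvas[:, 0], canvas[:, -1]])
        assert border.max() < 1e-9

    def test_oversized_fiber_rejected(self):
        config = SimulationConfig(size=(64, 64), width=5.0, aspect_ratio=15.0, k=1.0)
        with pytest.raises(ValueError):
            render_fibers(config, np.array([0.0]), np.random.default_rng(0))


class TestFinalizeImage:
    def test_output_max_is_full_16bit(self, rng):
        raw = np.zeros((64, 64))
        raw[30:34, 10:50] = 1.0
        img = finalize_image(raw, 0.0, np.random.default_rng(0))
        assert img.values.max() == 65535.0
        assert np.array_equal(img.sigma, np.sqrt(img.values))

    def test_zero_noise_is_deterministic_blur(self):
        raw = np.zeros((64, 64))
        raw[30:34, 10:50] = 1.0
        a = finalize_image(raw, 0.0, np.random.default_rng(0))
        b = finalize_image(raw, 0.0, np.random.default_rng(99))
        assert np.array_equal(a.values, b.values)

    def test_blank_canvas_rejected(self):
        with pytest.raises(ValueError):
            finalize_image(np.zeros((32, 32)), 0.0, np.random.default_rng(0))

    def test_speckle_background_bounded_by_half_max(self):
        """With noise factor 1 the speckle is bounded by half the canvas
        maximum, so blank-background regions stay below ~half the final
        maximum after blurring and rescaling."""
        raw = np.zeros((128, 128))
        raw[40:48, 20:100] = 2.0  # a thick bright fiber band
        img = finalize_image(raw, 1.0, np.random.default_rng(5))
        background = img.values[80:, :]
        assert background.max() <= 0.55 * 65535


class TestReferences:
    def _specs(self, angles, length=75.0):
        return [FiberSpec(angle=a, width=5.0, length=length, center=(0, 0))
                for a in angles]

    def test_identical_angles_give_exact_mean(self):
        ref = reference_parameters(self._specs([30.0] * 20))
        assert ref.theta_bar_ref == pytest.approx(30.0)
        assert np.isinf(ref.k_ref)

    def test_k_recovered_from_sampled_angles(self):
        errs = []
        for seed in range(20):
            angles = sample_vonmises(200, VonMisesParams(20.0, 2.0), seed=seed)
            ref = reference_parameters(self._specs(angles))
            errs.append(abs(ref.k_ref - 2.0) / 2.0)
        assert np.median(errs) < 0.10

    def test_b_ref_monotone_in_k(self):
        medians = []
        for k in (0.5, 1.0, 2.0, 5.0):
            vals = []
            for seed in range(8):
                angles = sample_vonmises(300, VonMisesParams(0.0, k), seed=seed)
                vals.append(reference_parameters(self._specs(angles)).b_ref)
            medians.append(np.median(vals))
        assert medians == sorted(medians)


class TestSimulate:
    def test_seed_determinism(self):
        config = SimulationConfig(size=(128, 128), width=3.0, aspect_ratio=15.0,
                                  k=1.0, noise_factor=0.5, seed=13)
        a = simulate(config)
        b = simulate(config)
        assert np.array_equal(a.image.values, b.image.values)
        assert [f.center for f in a.fibers] == [f.center for f in b.fibers]

    def test_parameter_ranges_enforced(self):
        with pytest.raises(ValueError):
            SimulationConfig(width=0.5)
        with pytest.raises(ValueError):
            SimulationConfig(aspect_ratio=10.0)
        with pytest.raises(ValueError):
            SimulationConfig(k=6.0)
        with pytest.raises(ValueError):
            SimulationConfig(noise_factor=1.5)

    def test_fiber_count_follows_coverage(self):
        config = SimulationConfig(size=(128, 128), width=2.0, aspect_ratio=15.0,
                                  k=1.0, coverage_target=0.3)
        assert config.n_fibers == int(np.ceil(0.3 * 128 * 128 / (2.0 * 30.0)))

    def test_bundle_ground_truth_consistency(self, small_fiber_bundle):
        bundle = small_fiber_bundle
        assert len(bundle.fibers) == bundle.config.n_fibers
        assert bundle.image.values.max() == 65535.0
        assert np.isfinite(bundle.reference.b_ref)
        assert -90.0 <= bundle.reference.theta_bar_ref < 90.0


def test_pipeline_recovers_orientation_of_aligned_bundle(aligned_bundle_512):
    """End to end: a clean k = 5 bundle analyzed at the default operating
    point yields the reference mean orientation within 2 degrees."""
    from fiberorient import analyze_image
    from fiberorient.evaluation import circular_error_deg

    result = analyze_image(aligned_bundle_512.image)
    err = circular_error_deg(result.fit.theta_bar,
                             aligned_bundle_512.reference.theta_bar_ref)
    assert err <= 2.0
    assert result.fit.r_squared > 0.99
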