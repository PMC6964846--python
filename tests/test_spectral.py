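"""DFT and uncertainty-propagation correctness against independent oracles."""

import numpy as np
import pytest

from fiberorient.spectral import (
    IntensityImage,
    forward_dft,
    poisson_uncertainty,
    power_spectrum,
    spectrum_uncertainty,
)


def brute_force_spectrum(values, sigma):
    """Literal double-loop evaluation of the DFT and its propagated
    uncertainties; the oracle against which the FFT-based path is checked."""
    nx, ny = values.shape
    re = np.zeros((nx, ny))
    im = np.zeros((nx, ny))
    var_re = np.zeros((nx, ny))
    var_im = np.zeros((nx, ny))
    cov = np.zeros((nx, ny))
    for u in range(nx):
        for v in range(ny):
            for x in range(nx):
                for y in range(ny):
                    phi = 2.0 * np.pi * (u * x / nx + v * y / ny)
                    c, s = np.cos(phi), np.sin(phi)
                    re[u, v] += values[x, y] * c
                    im[u, v] -= values[x, y] * s
                    var_re[u, v] += sigma[x, y] ** 2 * c * c
                    var_im[u, v] += sigma[x, y] ** 2 * s * s
                    cov[u, v] += sigma[x, y] ** 2 * (-s) * c
    return re, im, np.sqrt(var_re), np.sqrt(var_im), cov


class TestPoissonUncertainty:
    def test_sqrt_of_counts(self):
        assert np.array_equal(poisson_uncertainty(np.full((3, 3), 4.0)),
                              np.full((3, 3), 2.0))
        assert poisson_uncertainty(np.array([[0.0]]))[0, 0] == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            poisson_uncertainty(np.array([[-1.0]]))

    def test_matches_poisson_replicate_spread(self):
        rng = np.random.default_rng(0)
        lam = rng.uniform(0, 65535, size=16)
        draws = rng.poisson(lam, size=(20000, 16))
        emp = draws.std(axis=0, ddof=1)
        assert np.allclose(emp, np.sqrt(lam), rtol=0.05)


class TestForwardDFT:
    def test_constant_image_is_dc_only(self):
        spec = forward_dft(IntensityImage.from_counts(np.full((6, 4), 3.0)))
        assert spec.re[0, 0] == pytest.approx(6 * 4 * 3.0)
        rest = np.abs(spec.re + 1j * spec.im)
        rest[0, 0] = 0.0
        assert np.all(rest < 1e-9)

    def test_delta_image_has_flat_magnitude(self):
        values = np.zeros((5, 7))
        values[0, 0] = 2.0
        spec = forward_dft(IntensityImage.from_counts(values))
        mag = np.hypot(spec.re, spec.im)
        assert np.allclose(mag, 2.0)

    def test_matches_brute_force(self, random_image_8x8):
        spec = forward_dft(random_image_8x8)
        re, im, *_ = brute_force_spectrum(
            random_image_8x8.values, random_image_8x8.sigma)
        assert np.allclose(spec.re, re, rtol=1e-9, atol=1e-6)
        assert np.allclose(spec.im, im, rtol=1e-9, atol=1e-6)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            forward_dft(np.empty((0, 0)))

    def test_parseval(self, random_image_8x8):
        spec = forward_dft(random_image_8x8)
        p = spec.re**2 + spec.im**2
        lhs = p.sum()
        rhs = random_image_8x8.values.size * (random_image_8x8.values**2).sum()
        assert lhs == pytest.approx(rhs, rel=1e-10)


class TestSpectrumUncertainty:
    def test_dc_bin_closed_form(self):
        sigma = 1.7
        img = IntensityImage(values=np.full((4, 6), 5.0),
                             sigma=np.full((4, 6), sigma))
        spec = spectrum_uncertainty(img)
        assert spec.d_re[0, 0] == pytest.approx(sigma * np.sqrt(24))
        assert spec.d_im[0, 0] == pytest.approx(0.0, abs=1e-9)
        assert spec.cov[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force(self, random_image_8x8):
        spec = spectrum_uncertainty(random_image_8x8)
        _, _, d_re, d_im, cov = brute_force_spectrum(
            random_image_8x8.values, random_image_8x8.sigma)
        assert np.allclose(spec.d_re, d_re, rtol=1e-9, atol=1e-6)
        assert np.allclose(spec.d_im, d_im, rtol=1e-9, atol=1e-6)
        assert np.allclose(spec.cov, cov, rtol=1e-9, atol=1e-6)

    def test_linearity_in_sigma(self, random_image_8x8):
        base = spectrum_uncertainty(random_image_8x8)
        scaled = spectrum_uncertainty(
            IntensityImage(values=random_image_8x8.values,
                           sigma=3.0 * random_image_8x8.sigma))
        assert np.allclose(scaled.d_re, 3.0 * base.d_re)
        assert np.allclose(scaled.d_im, 3.0 * base.d_im)
        assert np.allclose(scaled.cov, 9.0 * base.cov)

    def test_empirical_covariance(self):
        """MC replicates reproduce the propagated Re-Im covariance per bin."""
        rng = np.random.default_rng(1)
        shape = (4, 5)  # odd extent so the doubled frequencies are distinct
        values = rng.uniform(10, 100, shape)
        img = IntensityImage.from_counts(values)
        spec = spectrum_uncertainty(img)
        n = 100000
        res = np.empty((n,) + shape)
        ims = np.empty((n,) + shape)
        for i in range(n):
            f = np.fft.fft2(values + rng.normal(size=shape) * img.sigma)
            res[i], ims[i] = f.real, f.imag
        emp_cov = ((res - res.mean(0)) * (ims - ims.mean(0))).mean(0)
        scale = np.abs(spec.cov).max()
        assert scale > 0
        assert np.allclose(emp_cov, spec.cov, atol=0.05 * scale)


class TestPowerSpectrum:
    def test_constant_image_dc_values(self):
        sigma = 2.0
        c, nx, ny = 5.0, 4, 4
        img = IntensityImage(values=np.full((nx, ny), c),
                             sigma=np.full((nx, ny), sigma))
        ps = power_spectrum(spectrum_uncertainty(img))
        dc = ps.center
        assert ps.p[dc] == pytest.approx((nx * ny * c) ** 2)
        assert ps.dp[dc] == pytest.approx(2 * nx * ny * c * sigma * np.sqrt(nx * ny))

    def test_zero_bin_zero_uncertainty(self):
        img = IntensityImage(values=np.zeros((4, 4)), sigma=np.zeros((4, 4)))
        ps = power_spectrum(spectrum_uncertainty(img))
        assert np.all(ps.p == 0) and np.all(ps.dp == 0)

    def test_centering_convention(self, random_image_8x8):
        ps = power_spectrum(spectrum_uncertainty(random_image_8x8))
        spec = forward_dft(random_image_8x8)
        assert ps.p[ps.center] == pytest.approx(spec.re[0, 0] ** 2)

    def test_requires_uncertainty(self, random_image_8x8):
        with pytest.raises(ValueError):
            power_spectrum(forward_dft(random_image_8x8))


def test_parseval_on_fiber_image(small_fiber_bundle):
    img = small_fiber_bundle.image
    ps = power_spectrum(spectrum_uncertainty(img))
    assert ps.p.sum() == pytest.approx(
        img.values.size * (img.values**2).sum(), rel=1e-10)
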