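"""Discrete Fourier transform of an intensity image with first-order
propagation of per-pixel uncertainty into the power spectrum.

The uncertainty model treats each pixel intensity :math:`I(x, y)` as an
independent random variable with standard deviation :math:`\\Delta I(x, y)`
(by default the Poisson photon-counting value :math:`\\sqrt{I}`).  Because the
real and imaginary parts of the DFT are linear combinations of the same pixel
values, they are correlated, and the covariance between them must be carried
along to propagate the uncertainty into the power spectrum
:math:`P = \\Re^2 + \\Im^2`.

All transforms are unnormalized (no :math:`1/XY` factor), so Parseval's
identity reads ``p.sum() == X * Y * (values**2).sum()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "IntensityImage",
    "SpectrumField",
    "PowerSpectrum",
    "poisson_uncertainty",
    "forward_dft",
    "spectrum_uncertainty",
    "power_spectrum",
]


def poisson_uncertainty(values: np.ndarray) -> np.ndarray:
    """Photon-counting (Poisson) uncertainty ``sqrt(I)`` per pixel.

    Parameters
    ----------
    values
        Non-negative intensity grid (counts).

    Returns
    -------
    ndarray
        Elementwise square root of the intensities.  This is the default
        per-pixel uncertainty when no explicit uncertainty image is supplied.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("Poisson uncertainty requires non-negative intensities")
    return np.sqrt(values)


@dataclass
class IntensityImage:
    """2D non-negative intensity field with per-pixel uncertainty.

    Attributes
    ----------
    values
        Intensity grid (counts, dimensionless), shape (rows, cols).
    sigma
        Per-pixel standard deviation, same shape and units as ``values``.
    bit_depth
        Nominal maximum representable intensity (65535 for 16-bit data).
    """

    values: np.ndarray
    sigma: np.ndarray
    bit_depth: int = 65535

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("image must be a non-empty 2D array")
        if self.values.shape != self.sigma.shape:
            raise ValueError(
                f"values shape {self.values.shape} != sigma shape {self.sigma.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("intensities must be non-negative")
        if np.any(self.sigma < 0):
            raise ValueError("uncertainties must be non-negative")

    @classmethod
    def from_counts(cls, values: np.ndarray, bit_depth: int = 65535) -> "IntensityImage":
        """Build an image whose sigma is the Poisson uncertainty ``sqrt(I)``."""
        values = np.asarray(values, dtype=float)
        return cls(values=values, sigma=poisson_uncertainty(values), bit_depth=bit_depth)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class SpectrumField:
    """Complex DFT of an image together with per-bin uncertainties.

    ``re``/``im`` are the real and imaginary parts of the unnormalized DFT in
    standard FFT ordering (DC at index ``(0, 0)``).  ``d_re``/``d_im`` are
    their standard deviations and ``cov`` is the covariance between the real
    and imaginary part at the same bin; ``cov`` may be of either sign.
    """

    re: np.ndarray
    im: np.ndarray
    d_re: np.ndarray | None = None
    d_im: np.ndarray | None = None
    cov: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.re.shape

    @property
    def has_uncertainty(self) -> bool:
        return self.d_re is not None and self.d_im is not None and self.cov is not None


@dataclass
class PowerSpectrum:
    """Centered power spectrum ``P = |F|^2`` with its uncertainty ``dp``.

    When ``centered`` is true (the only state produced by this module) the DC
    bin sits at index ``(rows // 2, cols // 2)``, i.e. the numpy ``fftshift``
    convention.
    """

    p: np.ndarray
    dp: np.ndarray
    centered: bool = True
    n_clamped: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.p.shape

    @property
    def center(self) -> tuple[int, int]:
        return (self.p.shape[0] // 2, self.p.shape[1] // 2)


def forward_dft(image: IntensityImage | np.ndarray) -> SpectrumField:
    """Unnormalized 2D DFT of the image (uncertainty fields left unset).

    The transform is ``F(u, v) = sum_xy I(x, y) exp(-2 pi i (ux/X + vy/Y))``
    with no ``1/XY`` scaling.
    """
    values = image.values if isinstance(image, IntensityImage) else np.asarray(image, float)
    if values.ndim != 2 or values.size == 0:
        raise ValueError("image must be a non-empty 2D array")
    f = np.fft.fft2(values)
    return SpectrumField(re=f.real, im=f.imag)


def spectrum_uncertainty(image: IntensityImage) -> SpectrumField:
    """DFT of an image with full first-order uncertainty propagation.

    With ``phi = 2 pi (ux/X + vy/Y)`` the propagated quantities are

    - ``d_re^2 = sum sigma^2 cos^2(phi)``
    - ``d_im^2 = sum sigma^2 sin^2(phi)``
    - ``cov    = Cov(Re, Im) = -sum sigma^2 sin(phi) cos(phi)``

    (the minus sign follows from ``Im = -sum I sin(phi)``).  All three are
    evaluated in closed form from the DFT of ``sigma^2`` at doubled
    frequencies, using ``cos^2 = (1 + cos 2phi)/2`` etc., which is exactly
    equivalent to the double sum but runs at FFT cost.
    """
    base = forward_dft(image)
    var = image.sigma**2
    nrows, ncols = var.shape
    g = np.fft.fft2(var)
    # G2[u, v] = G[(2u) mod X, (2v) mod Y] = sum var * exp(-i 2 phi)
    ui = (2 * np.arange(nrows)) % nrows
    vi = (2 * np.arange(ncols)) % ncols
    g2 = g[np.ix_(ui, vi)]
    s0 = var.sum()
    d_re = np.sqrt(np.clip((s0 + g2.real) / 2.0, 0.0, None))
    d_im = np.sqrt(np.clip((s0 - g2.real) / 2.0, 0.0, None))
    # sum var*sin(2phi) = -Im(G2)  =>  Cov = -(1/2) sum var*sin(2phi) = Im(G2)/2
    cov = g2.imag / 2.0
    return SpectrumField(re=base.re, im=base.im, d_re=d_re, d_im=d_im, cov=cov)


def power_spectrum(spec: SpectrumField) -> PowerSpectrum:
    """Centered power spectrum with first-order uncertainty.

    ``P = Re^2 + Im^2`` and, by the delta method,

    ``dp = 2 sqrt(Re^2 d_re^2 + Im^2 d_im^2 + 2 Re Im cov)``.

    The radicand can go slightly negative when the covariance term dominates
    within numerical noise; such bins are clamped to zero and counted in
    ``n_clamped``.
    """
    if not spec.has_uncertainty:
        raise ValueError("SpectrumField carries no uncertainty fields; "
                         "use spectrum_uncertainty() to build it")
    p = spec.re**2 + spec.im**2
    radicand = (
        spec.re**2 * spec.d_re**2
        + spec.im**2 * spec.d_im**2
        + 2.0 * spec.re * spec.im * spec.cov
    )
    n_clamped = int(np.count_nonzero(radicand < 0))
    if n_clamped:
        logger.debug("power_spectrum: clamped %d negative radicand bins", n_clamped)
    dp = 2.0 * np.sqrt(np.clip(radicand, 0.0, None))
    return PowerSpectrum(
        p=np.fft.fftshift(p),
        dp=np.fft.fftshift(dp),
        centered=True,
        n_clamped=n_clamped,
    )
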