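"""Monte-Carlo generator of greyscale fiber-network test images.

Images emulate second-harmonic-generation-like recordings of fibrous tissue:
straight fibers of a given width and aspect ratio, orientations drawn from a
semi-circular von Mises distribution, rendered additively (overlaps sum),
blurred with a sigma-2-pixel Gaussian to soften edges, contaminated with
uniform speckle noise, and scaled to the full 16-bit range.  Ground truth —
the exact list of drawn fibers and reference orientation parameters fitted to
the sampled angles — is carried alongside the image.

Fibers are added until the cumulative pre-overlap fiber area reaches
``coverage_target`` of the image area, so visual density is comparable across
fiber geometries; the count is therefore a deterministic function of the
configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .angular import CumulativeDistribution
from .model_fitting import (
    SigmoidFit,
    VonMisesParams,
    fit_cdf_sigmoid,
    fit_vonmises_pdf,
    vonmises_pdf,
    wrap_half_circle,
)
from .spectral import IntensityImage

__all__ = [
    "FiberSpec",
    "SimulationConfig",
    "ReferenceParams",
    "FiberImageBundle",
    "sample_vonmises",
    "render_fibers",
    "finalize_image",
    "reference_distribution",
    "reference_parameters",
    "simulate",
]


@dataclass
class FiberSpec:
    """One rendered fiber: orientation (degrees, [-90, 90)), geometry in
    pixels, and subpixel center position ``(cx, cy)`` (x = column axis)."""

    angle: float
    width: float
    length: float
    center: tuple[float, float]


@dataclass
class SimulationConfig:
    """Parameters of one simulated fiber image.

    ``width`` in pixels (1-10), ``aspect_ratio`` = length / width (15-45),
    ``k`` the von Mises concentration (0.01-5), ``theta_bar`` the mean fiber
    orientation in degrees, ``noise_factor`` in [0, 1] scaling additive
    speckle up to half the image maximum, ``coverage_target`` the summed
    pre-overlap fiber area as a fraction of the image area.  ``seed`` fixes
    all randomness.
    """

    size: tuple[int, int] = (512, 512)
    width: float = 5.0
    aspect_ratio: float = 30.0
    k: float = 1.0
    theta_bar: float = 0.0
    noise_factor: float = 0.0
    coverage_target: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1.0 <= self.width <= 10.0):
            raise ValueError("fiber width must lie in [1, 10] pixels")
        if not (15.0 <= self.aspect_ratio <= 45.0):
            raise ValueError("aspect ratio must lie in [15, 45]")
        if not (0.01 <= self.k <= 5.0):
            raise ValueError("dispersion k must lie in [0.01, 5]")
        if not (0.0 <= self.noise_factor <= 1.0):
            raise ValueError("noise factor must lie in [0, 1]")
        if self.coverage_target <= 0:
            raise ValueError("coverage target must be positive")
        self.theta_bar = float(wrap_half_circle(self.theta_bar))

    @property
    def length(self) -> float:
        return self.width * self.aspect_ratio

    @property
    def n_fibers(self) -> int:
        area = self.size[0] * self.size[1]
        return max(2, math.ceil(self.coverage_target * area / (self.width * self.length)))


@dataclass
class ReferenceParams:
    """Ground-truth orientation parameters fitted to the sampled fiber angles."""

    theta_bar_ref: float
    b_ref: float
    k_ref: float
    r2_vonmises: float = float("nan")
    r2_sigmoid: float = float("nan")


@dataclass
class FiberImageBundle:
    """Simulated image plus its full ground truth."""

    image: IntensityImage
    fibers: list[FiberSpec]
    reference: ReferenceParams
    config: SimulationConfig


def sample_vonmises(
    n: int,
    params: VonMisesParams,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Rejection-sample ``n`` fiber angles (degrees, [0, 180)).

    Proposals are uniform over the half circle; the envelope is the density
    value at the mode, so acceptance is exact for every ``k >= 0``.
    """
    if n < 1:
        raise ValueError("need n >= 1 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mode = params.theta_bar % 180.0
    peak = float(vonmises_pdf(mode, params.theta_bar, params.k))
    out = np.empty(0)
    while out.size < n:
        m = max(64, int(1.5 * (n - out.size)))
        theta = rng.uniform(0.0, 180.0, size=m)
        u = rng.uniform(0.0, 1.0, size=m)
        accept = u * peak < vonmises_pdf(theta, params.theta_bar, params.k)
        out = np.concatenate([out, theta[accept]])
    return out[:n]


def _half_extents(width: float, length: float, angle_deg: float) -> tuple[float, float]:
    t = math.radians(angle_deg)
    hx = (length * abs(math.cos(t)) + width * abs(math.sin(t))) / 2.0
    hy = (length * abs(math.sin(t)) + width * abs(math.cos(t))) / 2.0
    return hx, hy


def _rasterize_fiber(
    canvas: np.ndarray, fiber: FiberSpec
) -> None:
    """Add one anti-aliased rotated rectangle to the canvas in place.

    Pixel coverage is approximated separably: the signed distances along the
    fiber axis and perpendicular to it are turned into clipped linear edge
    ramps, whose product approximates the overlapped area of the unit pixel.
    """
    nrows, ncols = canvas.shape
    cx, cy = fiber.center
    hx, hy = _half_extents(fiber.width, fiber.length, fiber.angle)
    x0 = max(0, int(math.floor(cx - hx - 1)))
    x1 = min(ncols - 1, int(math.ceil(cx + hx + 1)))
    y0 = max(0, int(math.floor(cy - hy - 1)))
    y1 = min(nrows - 1, int(math.ceil(cy + hy + 1)))
    if x1 < x0 or y1 < y0:
        return
    xs = np.arange(x0, x1 + 1) - cx
    ys = np.arange(y0, y1 + 1) - cy
    xg, yg = np.meshgrid(xs, ys)
    t = math.radians(fiber.angle)
    d_par = xg * math.cos(t) + yg * math.sin(t)
    d_perp = -xg * math.sin(t) + yg * math.cos(t)
    cov_par = np.clip(fiber.length / 2.0 - np.abs(d_par) + 0.5, 0.0, 1.0)
    cov_perp = np.clip(fiber.width / 2.0 - np.abs(d_perp) + 0.5, 0.0, 1.0)
    canvas[y0 : y1 + 1, x0 : x1 + 1] += cov_par * cov_perp


def render_fibers(
    config: SimulationConfig,
    angles: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[FiberSpec]]:
    """Draw one unit-intensity fiber per angle, additively accumulated.

    Centers are sampled uniformly over the positions where the rotated
    rectangle fits fully inside the image; a configuration whose fiber cannot
    fit at any orientation is rejected.
    """
    nrows, ncols = config.size
    canvas = np.zeros((nrows, ncols))
    fibers: list[FiberSpec] = []
    w, length = config.width, config.length
    for ang in np.atleast_1d(np.asarray(angles, dtype=float)):
        ang = float(wrap_half_circle(ang))
        hx, hy = _half_extents(w, length, ang)
        if 2 * hx > ncols - 1 or 2 * hy > nrows - 1:
            raise ValueError(
                f"fiber {length:.0f}x{w:.0f} at {ang:.1f} deg does not fit in "
                f"a {ncols}x{nrows} image"
            )
        cx = rng.uniform(hx, ncols - 1 - hx)
        cy = rng.uniform(hy, nrows - 1 - hy)
        fiber = FiberSpec(angle=ang, width=w, length=length, center=(cx, cy))
        _rasterize_fiber(canvas, fiber)
        fibers.append(fiber)
    return canvas, fibers


def finalize_image(
    raw: np.ndarray,
    noise_factor: float,
    rng: np.random.Generator,
    bit_depth: int = 65535,
) -> IntensityImage:
    """Add speckle, blur, and scale a raw fiber canvas to 16-bit counts.

    Per-pixel speckle noise drawn uniformly from ``[0, noise_factor * max / 2]``
    (``max`` being the canvas maximum, so ``noise_factor = 1`` allows noise up
    to half the maximum intensity) is added to the raw canvas, the result is
    smoothed with a Gaussian kernel of standard deviation 2 pixels, and
    intensities are rescaled so the maximum equals ``bit_depth`` and rounded
    to integer counts.  The per-pixel uncertainty is the Poisson value
    ``sqrt(I)``.

    The speckle enters *before* the smoothing step: the blur stands for the
    optical/integration response of the acquisition, so noise — like signal —
    passes through it.  This keeps the simulated noise spectrally compatible
    with the photon-counting uncertainty model downstream; injecting
    broadband noise of this amplitude after the blur would give it a white
    Fourier floor whose true variance vastly exceeds the Poisson level, an
    image no counting detector produces.
    """
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise ValueError("raw canvas must be non-negative")
    peak = float(raw.max())
    if peak <= 0:
        raise ValueError("all-zero canvas cannot be scaled to 16-bit range")
    if noise_factor > 0:
        raw = raw + rng.uniform(0.0, noise_factor * peak / 2.0, size=raw.shape)
    blurred = gaussian_filter(raw, sigma=2.0)
    values = np.rint(blurred * (bit_depth / blurred.max()))
    return IntensityImage.from_counts(values, bit_depth=bit_depth)


def reference_distribution(
    fibers: list[FiberSpec], n_bins: int = 180
) -> tuple[np.ndarray, np.ndarray]:
    """Length-weighted, unit-sum 1-degree histogram of ground-truth angles.

    Each fiber contributes its length to the bin of its orientation — the
    same construction used when manually traced fibers serve as reference.
    With a single geometry per image this equals the plain angle histogram.
    """
    angles = wrap_half_circle([f.angle for f in fibers])
    lengths = np.array([f.length for f in fibers])
    hist, edges = np.histogram(
        angles, bins=n_bins, range=(-90.0, 90.0), weights=lengths
    )
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = hist.sum()
    return centers, hist / total if total > 0 else hist


def reference_parameters(
    fibers: list[FiberSpec], n_bins: int = 180
) -> ReferenceParams:
    """Fit reference orientation parameters to the sampled fiber angles.

    ``theta_bar_ref`` and ``k_ref`` come from a von Mises fit to the binned
    frequency distribution; ``b_ref`` from the circularized-sigmoid fit to
    its cumulative form.  Fitting the *sampled* angles (rather than using the
    configured distribution parameters) absorbs the Monte-Carlo sampling
    error of the finite fiber set into the reference.
    """
    if len(fibers) < 2:
        raise ValueError("need at least 2 fibers for reference parameters")
    theta, freq = reference_distribution(fibers, n_bins)
    if np.count_nonzero(freq) == 1:
        # perfectly aligned bundle: mean orientation is exact, the
        # dispersion fits are undefined (infinitely concentrated)
        angles = wrap_half_circle([f.angle for f in fibers])
        return ReferenceParams(
            theta_bar_ref=float(np.mean(angles)),
            b_ref=float("inf"),
            k_ref=float("inf"),
        )
    vm, r2_vm = fit_vonmises_pdf((theta, freq), n_bins=n_bins)
    cd = CumulativeDistribution(theta=theta, c=np.cumsum(freq), dc=0.0)
    sf = fit_cdf_sigmoid(cd)
    if not sf.converged:
        raise RuntimeError(f"reference sigmoid fit failed: {sf.message}")
    return ReferenceParams(
        theta_bar_ref=vm.theta_bar,
        b_ref=sf.b,
        k_ref=vm.k,
        r2_vonmises=r2_vm,
        r2_sigmoid=sf.r_squared,
    )


def simulate(config: SimulationConfig) -> FiberImageBundle:
    """Generate one fiber image bundle; fully determined by the config."""
    rng = np.random.default_rng(config.seed)
    angles = sample_vonmises(
        config.n_fibers,
        VonMisesParams(theta_bar=config.theta_bar, k=config.k),
        seed=rng,
    )
    raw, fibers = render_fibers(config, angles, rng)
    image = finalize_image(raw, config.noise_factor, rng)
    reference = reference_parameters(fibers)
    return FiberImageBundle(image=image, fibers=fibers, reference=reference, config=config)
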