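"""Angular orientation distribution from a filtered power spectrum.

Each spectrum bin contributes its intensity to the 1-degree orientation wedge
(or wedges) its pixel area overlaps, weighted by the overlapped area fraction,
so the total weight over all wedges equals the pixel count ``X * Y``.  Wedge
sums are then amplified by ``N_wedge ** alpha`` — the count of mask-kept bins
whose center falls in the wedge raised to the anisotropy exponent — and
normalized to a unit-sum distribution ``I(theta)``.

Angles are fiber orientations in degrees in ``[-90, 90)``: a fiber oriented at
``theta`` in the image produces spectral energy along the perpendicular
direction, so wedge angles computed in Fourier coordinates are rotated by 90
degrees before binning.  Convention: 0 degrees is the image x-axis (columns),
positive angles rotate toward the y-axis (rows).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .adaptive_filter import FilteredSpectrum

logger = logging.getLogger(__name__)

__all__ = [
    "AngularDistribution",
    "CumulativeDistribution",
    "WedgeWeights",
    "angular_wedge_weights",
    "angular_intensity",
    "cumulative",
]


@dataclass
class AngularDistribution:
    """Normalized 1-degree-binned orientation intensities with uncertainties."""

    theta: np.ndarray          # bin centers, degrees in [-90, 90)
    intensity: np.ndarray      # I(theta) >= 0, sums to 1 when any bin nonzero
    d_intensity: np.ndarray    # propagated uncertainty, same normalization
    n_per_bin: np.ndarray      # kept-bin count N per wedge (integer)
    alpha: float


@dataclass
class CumulativeDistribution:
    """Running sum ``C(theta)`` of a normalized angular distribution.

    The uncertainty ``dc`` is a single constant — the maximum of the
    quadrature-accumulated uncertainty over all angles — because the starting
    angle of the summation is arbitrary and ``dc`` must not depend on it.
    """

    theta: np.ndarray
    c: np.ndarray
    dc: float


@dataclass
class WedgeWeights:
    """Precomputed pixel-to-wedge area weights for one spectrum shape.

    ``w`` is a sparse ``(n_bins, n_pixels)`` matrix of area fractions,
    ``w_sq`` its elementwise square (for quadrature uncertainty sums), and
    ``pixel_bin`` maps each pixel to the wedge containing its center.
    """

    shape: tuple[int, int]
    n_bins: int
    theta: np.ndarray
    w: sp.csr_matrix
    w_sq: sp.csr_matrix
    pixel_bin: np.ndarray


_WEIGHT_CACHE: dict[tuple[tuple[int, int], int, int], WedgeWeights] = {}


def _fiber_angle_deg(dy: np.ndarray, dx: np.ndarray) -> np.ndarray:
    """Fiber orientation (degrees, [-90, 90)) of a centered spectrum offset."""
    phi = np.degrees(np.arctan2(dy, dx))  # Fourier-domain angle
    return (phi + 90.0 + 90.0) % 180.0 - 90.0


def angular_wedge_weights(
    shape: tuple[int, int], n_bins: int = 180, subsamples: int = 5
) -> WedgeWeights:
    """Distribute each spectrum pixel's unit area over the orientation wedges.

    Area fractions are obtained by ``subsamples x subsamples`` uniform
    subpixel sampling: each subsample carries ``1 / subsamples**2`` of the
    pixel area into the wedge containing its angle.  This enforces the total
    weight ``sum(w) == X * Y`` exactly by construction, and the subsampling
    error is far below the 1-degree bin width everywhere except immediately
    next to the (always centrally cut) DC bin.

    Results are cached per ``(shape, n_bins, subsamples)``.
    """
    key = (tuple(shape), int(n_bins), int(subsamples))
    hit = _WEIGHT_CACHE.get(key)
    if hit is not None:
        return hit

    nrows, ncols = shape
    cy, cx = nrows // 2, ncols // 2
    bin_width = 180.0 / n_bins
    yy, xx = np.meshgrid(
        np.arange(nrows) - cy, np.arange(ncols) - cx, indexing="ij"
    )
    offsets = (np.arange(subsamples) + 0.5) / subsamples - 0.5
    npix = nrows * ncols
    frac = 1.0 / (subsamples * subsamples)

    # Collapse the subsample hits of each pixel into per-bin counts with one
    # run-length pass: each pixel's hits, laid out contiguously and sorted
    # within the pixel, form runs of identical bin indices.
    n_sub = subsamples * subsamples
    hits = np.empty((npix, n_sub), dtype=np.int16)
    col = 0
    for oy in offsets:
        for ox in offsets:
            theta = _fiber_angle_deg((yy + oy).ravel(), (xx + ox).ravel())
            b = np.floor((theta + 90.0) / bin_width).astype(np.int16)
            np.clip(b, 0, n_bins - 1, out=b)
            hits[:, col] = b
            col += 1
    hits.sort(axis=1)
    flat = hits.ravel()
    starts_mask = np.ones(flat.size, dtype=bool)
    starts_mask[1:] = flat[1:] != flat[:-1]
    starts_mask[::n_sub] = True  # runs never span pixel boundaries
    starts = np.flatnonzero(starts_mask)
    counts = np.diff(np.append(starts, flat.size))
    rows = flat[starts].astype(np.int32)
    cols = (starts // n_sub).astype(np.int32)
    w = sp.csr_matrix((counts * frac, (rows, cols)), shape=(n_bins, npix))

    center_theta = _fiber_angle_deg(yy.ravel(), xx.ravel())
    pixel_bin = np.floor((center_theta + 90.0) / bin_width).astype(np.int64)
    np.clip(pixel_bin, 0, n_bins - 1, out=pixel_bin)

    theta_centers = -90.0 + (np.arange(n_bins) + 0.5) * bin_width
    ww = WedgeWeights(
        shape=(nrows, ncols),
        n_bins=n_bins,
        theta=theta_centers,
        w=w,
        w_sq=w.multiply(w).tocsr(),
        pixel_bin=pixel_bin,
    )
    _WEIGHT_CACHE[key] = ww
    return ww


def angular_intensity(
    fs: FilteredSpectrum,
    weights: WedgeWeights,
    alpha: float,
) -> AngularDistribution:
    """Anisotropy-weighted, normalized angular intensity distribution.

    Per wedge, the raw area-weighted sum ``S = sum(P' * w)`` and the
    quadrature uncertainty ``sqrt(sum((P' * w)^2))`` are both multiplied by
    ``N ** alpha`` (``N`` = number of kept bins whose center falls in the
    wedge; wedges with ``N == 0`` contribute zero), then jointly rescaled so
    that the intensities sum to one.  ``alpha = 0`` recovers the plain area
    sum and ``alpha = -1`` the per-wedge mean.
    """
    if fs.p_filtered.shape != weights.shape:
        raise ValueError("weights were built for a different spectrum shape")
    pflat = fs.p_filtered.ravel()
    raw = weights.w @ pflat
    raw_unc = np.sqrt(weights.w_sq @ (pflat * pflat))
    n_per_bin = np.bincount(
        weights.pixel_bin[fs.keep_mask.ravel()], minlength=weights.n_bins
    )
    amp = np.zeros(weights.n_bins)
    nz = n_per_bin > 0
    amp[nz] = n_per_bin[nz].astype(float) ** alpha
    intensity = amp * raw
    d_intensity = amp * raw_unc
    total = intensity.sum()
    if total > 0:
        intensity = intensity / total
        d_intensity = d_intensity / total
    else:
        logger.warning("angular_intensity: all-zero distribution (empty mask?)")
    return AngularDistribution(
        theta=weights.theta,
        intensity=intensity,
        d_intensity=d_intensity,
        n_per_bin=n_per_bin,
        alpha=float(alpha),
    )


def cumulative(ad: AngularDistribution) -> CumulativeDistribution:
    """Cumulative form of a normalized angular distribution.

    ``C`` runs from the first bin at -90 degrees and reaches exactly 1 at the
    last bin.  The constant uncertainty is the maximum over angles of the
    quadrature sum of the per-bin uncertainties.
    """
    c = np.cumsum(ad.intensity)
    if c[-1] > 0:
        c = c / c[-1]
    dc = float(np.sqrt(np.max(np.cumsum(ad.d_intensity**2))))
    return CumulativeDistribution(theta=ad.theta, c=c, dc=dc)
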