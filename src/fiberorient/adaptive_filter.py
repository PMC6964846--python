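"""Adaptive anisotropic masking of the power spectrum by relative uncertainty.

A spectrum bin is kept only if its relative uncertainty ``dp / p`` does not
exceed ``delta_cut`` and it lies at least ``r_min`` pixels from the centered
DC bin.  Because directional fiber energy concentrates in high-signal streaks
while noise dominates elsewhere, this single relative-uncertainty criterion
yields a filter that adapts to the anisotropy of each image without any
assumption about fiber geometry.  The central exclusion removes the
non-directional low-frequency bins whose huge intensities would otherwise
distort the angular distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .spectral import PowerSpectrum

logger = logging.getLogger(__name__)

__all__ = ["FilteredSpectrum", "relative_uncertainty_map", "adaptive_mask"]

#: Operating point: maximum relative uncertainty of a kept bin (2.1%).
DEFAULT_DELTA_CUT = 0.021
#: Operating point: central cut-off radius in pixels.
DEFAULT_R_MIN = 3.0


@dataclass
class FilteredSpectrum:
    """Masked power spectrum: ``p_filtered = p * keep_mask``."""

    p_filtered: np.ndarray
    keep_mask: np.ndarray
    delta_cut: float
    r_min: float
    n_kept: int


def relative_uncertainty_map(ps: PowerSpectrum) -> np.ndarray:
    """Per-bin relative uncertainty ``dp / p``; bins with ``p == 0`` become inf."""
    if not ps.centered:
        raise ValueError("power spectrum must be centered")
    delta = np.full(ps.shape, np.inf)
    np.divide(ps.dp, ps.p, out=delta, where=ps.p > 0)
    return delta


def _radius_grid(shape: tuple[int, int]) -> np.ndarray:
    cy, cx = shape[0] // 2, shape[1] // 2
    dy = np.arange(shape[0])[:, None] - cy
    dx = np.arange(shape[1])[None, :] - cx
    return np.hypot(dy, dx)


def mask_from_delta(
    delta: np.ndarray, delta_cut: float, r_min: float
) -> np.ndarray:
    """Boolean keep-mask from a precomputed relative-uncertainty map."""
    return (delta <= delta_cut) & (_radius_grid(delta.shape) >= r_min)


def adaptive_mask(
    ps: PowerSpectrum,
    delta_cut: float = DEFAULT_DELTA_CUT,
    r_min: float = DEFAULT_R_MIN,
) -> FilteredSpectrum:
    """Build the adaptive keep-mask and apply it to the power spectrum.

    Parameters
    ----------
    ps
        Centered power spectrum with uncertainties.
    delta_cut
        Maximum relative uncertainty of a kept bin, as a fraction
        (default 0.021, i.e. 2.1%).
    r_min
        Bins strictly closer than this many pixels to the centered DC bin are
        always dropped (default 3).

    An empty mask is legal (a warning is logged); downstream the angular
    distribution then comes out all-zero rather than crashing.
    """
    if delta_cut <= 0:
        raise ValueError("delta_cut must be positive")
    if r_min < 0:
        raise ValueError("r_min must be non-negative")
    delta = relative_uncertainty_map(ps)
    keep = mask_from_delta(delta, delta_cut, r_min)
    n_kept = int(np.count_nonzero(keep))
    if n_kept == 0:
        logger.warning(
            "adaptive_mask: no spectrum bins satisfy delta <= %.4g with r >= %g",
            delta_cut, r_min,
        )
    return FilteredSpectrum(
        p_filtered=np.where(keep, ps.p, 0.0),
        keep_mask=keep,
        delta_cut=float(delta_cut),
        r_min=float(r_min),
        n_kept=n_kept,
    )
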