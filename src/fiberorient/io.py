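"""Reading and writing images, distributions, and fit results.

Greyscale 8/16-bit TIFF and PNG images are supported.  Integer intensities
are preserved exactly on a write/read round trip; unless a companion
uncertainty image is supplied, the per-pixel uncertainty defaults to the
Poisson value ``sqrt(I)``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .angular import AngularDistribution, CumulativeDistribution
from .fibergen import FiberSpec
from .model_fitting import SigmoidFit
from .spectral import IntensityImage, poisson_uncertainty

__all__ = [
    "read_image",
    "write_image",
    "distribution_to_csv",
    "fit_to_json",
    "fibers_to_csv",
]

SCHEMA_TAG = "fiberorient/1"


def _read_array(path: Path) -> np.ndarray:
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        return np.asarray(tifffile.imread(path))
    import imageio.v3 as iio

    return np.asarray(iio.imread(path))


def read_image(
    path: str | Path,
    sigma_path: str | Path | None = None,
    allow_rgb: bool = False,
) -> IntensityImage:
    """Load a greyscale TIFF/PNG as an :class:`IntensityImage`.

    Integer pixel values are kept exactly (no rescaling).  RGB input is
    rejected unless ``allow_rgb`` is set, in which case channels are averaged.
    """
    path = Path(path)
    arr = _read_array(path)
    if arr.dtype.kind not in "ui":
        raise ValueError(f"{path}: unsupported dtype {arr.dtype}; need 8/16-bit integer")
    bit_depth = 255 if arr.dtype.itemsize == 1 else 65535
    if arr.ndim == 3:
        if not allow_rgb:
            raise ValueError(
                f"{path} is not greyscale; pass allow_rgb=True to average channels"
            )
        arr = arr.mean(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2D greyscale image, got shape {arr.shape}")
    values = np.asarray(arr, dtype=float)
    if sigma_path is not None:
        sigma = _read_array(Path(sigma_path)).astype(float)
    else:
        sigma = poisson_uncertainty(values)
    return IntensityImage(values=values, sigma=sigma, bit_depth=bit_depth)


def write_image(path: str | Path, image: IntensityImage | np.ndarray) -> None:
    """Write an intensity image as 16-bit (TIFF) or 8/16-bit (PNG)."""
    path = Path(path)
    values = image.values if isinstance(image, IntensityImage) else np.asarray(image)
    arr = np.rint(values).astype(np.uint16)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr)


def distribution_to_csv(
    path: str | Path,
    ad: AngularDistribution,
    cd: CumulativeDistribution | None = None,
) -> None:
    """Export an angular distribution (and optionally its CDF) as CSV."""
    frame = pd.DataFrame(
        {
            "theta_deg": ad.theta,
            "intensity": ad.intensity,
            "d_intensity": ad.d_intensity,
        }
    )
    if cd is not None:
        frame["cumulative"] = cd.c
    frame.to_csv(path, index=False)


def fit_to_json(path: str | Path, fit: SigmoidFit, extra: dict | None = None) -> None:
    """Export a sigmoid fit as JSON (schema-tagged)."""
    payload = {
        "schema": SCHEMA_TAG,
        "theta_bar_deg": fit.theta_bar,
        "b_per_deg": fit.b,
        "r_squared": fit.r_squared,
        "ci95": {"b": fit.ci_b, "theta_bar_deg": fit.ci_theta},
        "converged": fit.converged,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))


def fibers_to_csv(path: str | Path, fibers: list[FiberSpec]) -> None:
    """Export a ground-truth fiber list as CSV."""
    pd.DataFrame(
        {
            "angle_deg": [f.angle for f in fibers],
            "width_px": [f.width for f in fibers],
            "length_px": [f.length for f in fibers],
            "cx": [f.center[0] for f in fibers],
            "cy": [f.center[1] for f in fibers],
        }
    ).to_csv(path, index=False)
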