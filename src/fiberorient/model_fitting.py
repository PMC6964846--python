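"""Parametric orientation models and their least-squares fits.

Two dispersion parameterizations are used side by side, as is customary for
fiber-orientation analysis:

* the semi-circular (pi-periodic) von Mises density with mean ``theta_bar``
  and concentration ``k``, fitted to the binned angular frequency
  distribution, and
* a circularized sigmoid with slope ``b`` (per degree) and center
  ``theta_bar``, fitted to the cumulative orientation distribution
  ``C(theta)``.

No closed-form conversion between ``b`` and ``k`` is assumed; each carries
its own reference value in validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import expit, i0e

from .angular import AngularDistribution, CumulativeDistribution

__all__ = [
    "VonMisesParams",
    "SigmoidFit",
    "vonmises_pdf",
    "sigmoid_circular",
    "fit_cdf_sigmoid",
    "fit_vonmises_pdf",
]


def wrap_half_circle(theta_deg):
    """Wrap angles (degrees) into the half-open interval [-90, 90)."""
    return (np.asarray(theta_deg, dtype=float) + 90.0) % 180.0 - 90.0


@dataclass
class VonMisesParams:
    """Mean orientation (degrees, [-90, 90)) and concentration of the
    semi-circular von Mises model; ``k = 0`` is the isotropic limit."""

    theta_bar: float
    k: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("concentration k must be non-negative")
        self.theta_bar = float(wrap_half_circle(self.theta_bar))


@dataclass
class SigmoidFit:
    """Circularized-sigmoid CDF fit result.

    ``b`` is the slope in 1/degree, ``theta_bar`` the center in degrees in
    [-90, 90), ``ci_b``/``ci_theta`` 95% confidence half-widths derived from
    the parameter covariance with the constant CDF uncertainty as observation
    sigma.
    """

    b: float
    theta_bar: float
    r_squared: float
    ci_b: float = float("nan")
    ci_theta: float = float("nan")
    converged: bool = True
    message: str = ""


def vonmises_pdf(theta_deg, theta_bar_deg: float, k: float):
    """Semi-circular von Mises density, per radian over a half circle.

    ``P(theta) = exp(k cos(2 (theta - theta_bar))) / (pi I0(k))`` with the
    modified Bessel function ``I0``; evaluated stably via the exponentially
    scaled ``i0e`` so large ``k`` does not overflow.  Integrates to 1 over
    any 180-degree window.
    """
    if k < 0:
        raise ValueError("concentration k must be non-negative")
    t = np.deg2rad(np.asarray(theta_deg, dtype=float) - theta_bar_deg)
    return np.exp(k * (np.cos(2.0 * t) - 1.0)) / (np.pi * i0e(k))


def sigmoid_circular(theta_deg, b: float, theta_bar_deg: float):
    """Circularized sigmoid model for the cumulative orientation distribution.

    The base logistic ``S(theta) = 1 / (1 + exp(-b (theta - theta_bar)))`` is
    augmented by its neighbours one period (180 degrees) away, minus constant
    offsets, so that the semicircularity condition
    ``C(theta) = C(theta - 180) + 1`` holds:

    ``S_circ(t) = S(t) + S(t+180) - S(180) + S(t-180) - S(-180)``.
    """
    t = np.asarray(theta_deg, dtype=float)

    def s(x):
        return expit(b * (x - theta_bar_deg))

    return s(t) + s(t + 180.0) - s(180.0) + s(t - 180.0) - s(-180.0)


def _circular_mean_deg(theta_deg: np.ndarray, weights: np.ndarray) -> float:
    """Axial (180-degree periodic) weighted circular mean, degrees [-90, 90)."""
    t2 = np.deg2rad(theta_deg) * 2.0
    c = float(np.sum(weights * np.cos(t2)))
    s = float(np.sum(weights * np.sin(t2)))
    if c == 0.0 and s == 0.0:
        return 0.0
    return float(wrap_half_circle(np.degrees(0.5 * np.arctan2(s, c))))


def fit_cdf_sigmoid(cd: CumulativeDistribution) -> SigmoidFit:
    """Nonlinear least-squares fit of the circularized sigmoid to ``C(theta)``.

    The circularization terms assume the step of the CDF lies in the interior
    of the angular window, so the distribution is first cyclically
    re-registered: the axis is rolled so the circular-mean angle maps to 0,
    the fit is performed there, and the fitted center is mapped back.  The
    constant CDF uncertainty ``dc`` (when positive) scales the parameter
    covariance from which the 95% confidence half-widths derive.

    Non-convergence is reported through ``converged``/``message`` on the
    returned fit rather than raised.
    """
    theta = np.asarray(cd.theta, dtype=float)
    c = np.asarray(cd.c, dtype=float)
    n = theta.size
    intensity = np.diff(c, prepend=0.0)
    bin_width = 180.0 / n

    mu = _circular_mean_deg(theta, np.clip(intensity, 0.0, None))
    shift_bins = int(np.round(mu / bin_width))
    intensity_rolled = np.roll(intensity, -shift_bins)
    c_rolled = np.cumsum(intensity_rolled)
    if c_rolled[-1] > 0:
        c_rolled = c_rolled / c_rolled[-1]

    sigma = None
    if np.isfinite(cd.dc) and cd.dc > 0:
        sigma = np.full(n, cd.dc)
    p0 = (0.05, 0.0)
    try:
        popt, pcov = curve_fit(
            sigmoid_circular,
            theta,
            c_rolled,
            p0=p0,
            sigma=sigma,
            absolute_sigma=sigma is not None,
            bounds=((1e-8, -95.0), (np.inf, 95.0)),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - diagnostics
        return SigmoidFit(
            b=float("nan"), theta_bar=float("nan"), r_squared=float("nan"),
            converged=False, message=str(exc),
        )
    b_fit, tb_fit = popt
    resid = c_rolled - sigmoid_circular(theta, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((c_rolled - c_rolled.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    return SigmoidFit(
        b=float(b_fit),
        theta_bar=float(wrap_half_circle(tb_fit + shift_bins * bin_width)),
        r_squared=r2,
        ci_b=float(1.96 * perr[0]),
        ci_theta=float(1.96 * perr[1]),
    )


def _as_binned_distribution(data, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalize the accepted input forms to (bin centers, unit-sum freqs)."""
    if isinstance(data, AngularDistribution):
        return np.asarray(data.theta, float), np.asarray(data.intensity, float)
    if isinstance(data, tuple) and len(data) == 2:
        theta, freq = (np.asarray(a, dtype=float) for a in data)
        total = freq.sum()
        return theta, freq / total if total > 0 else freq
    angles = wrap_half_circle(np.asarray(data, dtype=float).ravel())
    if angles.size < 10:
        raise ValueError("need at least 10 angle observations to fit")
    hist, edges = np.histogram(angles, bins=n_bins, range=(-90.0, 90.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, hist / hist.sum()


def fit_vonmises_pdf(
    data, n_bins: int = 180
) -> tuple[VonMisesParams, float]:
    """Least-squares von Mises fit to a (binned) orientation distribution.

    ``data`` may be raw angles in degrees (binned here into 1-degree bins),
    a ``(theta, frequency)`` pair, or an ``AngularDistribution``.  The model
    fitted to the unit-sum bin frequencies is the density times the angular
    bin width in radians.  Returns the parameters and the coefficient of
    determination of the fit.
    """
    theta, freq = _as_binned_distribution(data, n_bins)
    if np.count_nonzero(freq) < 2:
        raise ValueError("degenerate distribution: fewer than 2 occupied bins")
    bin_rad = np.deg2rad(theta[1] - theta[0])

    def model(t, tb, k):
        return vonmises_pdf(t, tb, abs(k)) * bin_rad

    mu0 = _circular_mean_deg(theta, freq)
    try:
        popt, _ = curve_fit(model, theta, freq, p0=(mu0, 1.0), maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"von Mises fit failed to converge: {exc}") from exc
    tb, k = float(wrap_half_circle(popt[0])), float(abs(popt[1]))
    resid = freq - model(theta, *popt)
    ss_tot = float(np.sum((freq - freq.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    return VonMisesParams(theta_bar=tb, k=k), r2
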