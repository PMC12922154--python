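"""Circular descriptive statistics and the von Mises kernel.

All public functions take and return angles in **degrees** (the unit saccade
direction is exported in by eye trackers); internally everything runs in
radians.  Densities are always expressed **per radian**, so a circular-uniform
density is 1/(2*pi) regardless of the angular unit of the grid.

The von Mises distribution vM(mu, kappa) is the circular analogue of the
normal distribution: kappa >= 0 is a concentration (inverse-dispersion)
parameter, kappa = 0 is the circular uniform.  Its pdf is

    f(theta) = exp(kappa * cos(theta - mu)) / (2*pi * I0(kappa)),

with I0 the modified Bessel function of order zero.  For numerical stability
at large kappa the implementation uses the exponentially scaled Bessel
function:  f = exp(kappa*(cos(d) - 1)) / (2*pi * i0e(kappa)), which never
overflows (i0e(k) = I0(k)*exp(-k)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

__all__ = [
    "VonMisesParams",
    "CircularSummary",
    "circular_mean",
    "von_mises_pdf",
    "estimate_kappa",
    "smoothing_concentration",
    "mean_resultant_of_kappa",
    "circular_distance_deg",
]

#: Resultant lengths this close to zero leave the mean direction undefined.
_UNDEFINED_MEAN_TOL = 1e-12

#: Cap on the concentration returned by :func:`estimate_kappa` as R -> 1.
KAPPA_MAX = 1e6


@dataclass(frozen=True)
class VonMisesParams:
    """Mean direction (degrees, [0, 360)) and concentration of a von Mises law."""

    mu_deg: float
    kappa: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu_deg):
            raise ValueError("mu_deg must be finite")
        if not (np.isfinite(self.kappa) and self.kappa >= 0):
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")
        mu = float(self.mu_deg) % 360.0
        object.__setattr__(self, "mu_deg", 0.0 if mu >= 360.0 else mu)


@dataclass(frozen=True)
class CircularSummary:
    """Circular mean direction, mean resultant length and sample size.

    ``mean_deg`` is ``None`` when the resultant length is numerically zero
    (e.g. antipodal data): the mean direction is then undefined and is never
    silently reported as 0 degrees.
    """

    mean_deg: float | None
    resultant_length: float
    n: int

    @property
    def mean_defined(self) -> bool:
        return self.mean_deg is not None


def _as_radians(angles_deg) -> np.ndarray:
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValueError("empty angle sample")
    if not np.all(np.isfinite(a)):
        raise ValueError("angles must be finite")
    return np.deg2rad(a)


def circular_mean(angles_deg) -> CircularSummary:
    """Mean direction and resultant length of a sample of angles (degrees).

    The circular mean is the argument of the mean unit vector
    ``(1/n) * sum_i exp(i*theta_i)``; its modulus is the mean resultant
    length R in [0, 1].  The arithmetic mean is invalid on the circle
    (e.g. mean of 350 and 10 degrees is 0, not 180).
    """
    rad = _as_radians(angles_deg)
    c = np.mean(np.cos(rad))
    s = np.mean(np.sin(rad))
    r = float(min(np.hypot(c, s), 1.0))
    if r < _UNDEFINED_MEAN_TOL:
        return CircularSummary(mean_deg=None, resultant_length=r, n=rad.size)
    mean = float(np.rad2deg(np.arctan2(s, c)) % 360.0)
    if mean >= 360.0:  # -eps % 360 can round up to exactly 360.0
        mean = 0.0
    return CircularSummary(mean_deg=mean, resultant_length=r, n=rad.size)


def von_mises_pdf(theta_deg, params: VonMisesParams) -> np.ndarray | float:
    """von Mises density per radian, evaluated at angles given in degrees.

    Periodic with period 360 deg; kappa = 0 gives the uniform 1/(2*pi).
    Stable for arbitrarily large kappa via the scaled Bessel function.
    """
    theta = np.deg2rad(np.asarray(theta_deg, dtype=float))
    mu = np.deg2rad(params.mu_deg)
    delta = np.cos(theta - mu) - 1.0  # in [-2, 0]: exp never overflows
    out = np.exp(params.kappa * delta) / (2.0 * np.pi * special.i0e(params.kappa))
    return out if out.ndim else float(out)


def mean_resultant_of_kappa(kappa) -> np.ndarray | float:
    """A(kappa) = I1(kappa)/I0(kappa), the population resultant length of vM(., kappa)."""
    k = np.asarray(kappa, dtype=float)
    out = np.where(k > 0, special.i1e(k) / special.i0e(k), 0.0)
    return out if out.ndim else float(out)


def _kappa_seed(r: float) -> float:
    # Standard small/large-R series approximations to A^{-1}(R) (Fisher 1993).
    if r < 0.53:
        return 2.0 * r + r**3 + (5.0 / 6.0) * r**5
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    return 1.0 / (r**3 - 4.0 * r**2 + 3.0 * r)


def estimate_kappa(resultant_length: float, n: int | None = None) -> float:
    """Invert A(kappa) = I1(kappa)/I0(kappa) = R by bracketed root finding.

    Parameters
    ----------
    resultant_length
        Mean resultant length R in [0, 1].
    n
        Sample size; accepted for interface symmetry with the textbook
        bias-corrected variants, unused by the plain inversion.

    Returns
    -------
    float
        kappa >= 0 solving A(kappa) = R to 1e-10, 0 for R = 0 and capped at
        ``KAPPA_MAX`` as R -> 1.
    """
    r = float(resultant_length)
    if not (0.0 <= r <= 1.0):
        raise ValueError(f"resultant_length must lie in [0, 1], got {r}")
    if r == 0.0:
        return 0.0
    if r == 1.0:
        return KAPPA_MAX
    seed = _kappa_seed(r)
    if not np.isfinite(seed) or seed >= KAPPA_MAX:
        return KAPPA_MAX
    lo, hi = 0.0, max(2.0 * seed, 1.0)
    while mean_resultant_of_kappa(hi) < r:
        hi *= 2.0
        if hi >= KAPPA_MAX:
            return KAPPA_MAX
    return float(
        optimize.brentq(lambda k: mean_resultant_of_kappa(k) - r, lo, hi, xtol=1e-10)
    )


def smoothing_concentration(angles_deg, override: float | None = None) -> float:
    """Plug-in concentration nu for von Mises kernel density estimation.

    Taylor-type rule assuming an underlying vM(mu, kappa) reference density:

        nu = [ 3 * n * kappa^2 * I2(2*kappa) / (4 * sqrt(pi) * I0(kappa)^2) ]^(2/5)

    with kappa estimated from the sample resultant length.  nu plays the role
    of an *inverse* bandwidth: it grows like n^(2/5), so kernels sharpen with
    more data, and tends to 0 (maximal smoothing) for near-uniform samples.

    ``override``, when given, is returned verbatim (must be >= 0): the rule is
    a default, not a mandate, and reproducible analyses should pin nu in
    their configuration.
    """
    if override is not None:
        if not (np.isfinite(override) and override >= 0):
            raise ValueError("concentration override must be >= 0")
        return float(override)
    a = np.asarray(angles_deg, dtype=float)
    if a.size < 2:
        raise ValueError(
            "smoothing_concentration needs n >= 2; pass an explicit concentration"
        )
    kappa = estimate_kappa(circular_mean(a).resultant_length)
    if kappa == 0.0:
        return 0.0
    n = a.size
    # I2(2k)/I0(k)^2 via scaled Bessels: ive(2,2k)e^{2k} / (i0e(k)e^{k})^2.
    ratio = special.ive(2, 2.0 * kappa) / special.i0e(kappa) ** 2
    num = 3.0 * n * kappa**2 * ratio
    den = 4.0 * np.sqrt(np.pi)
    return float((num / den) ** 0.4)


def circular_distance_deg(a_deg, b_deg) -> np.ndarray | float:
    """Shortest angular distance |a - b| on the circle, in degrees (0..180)."""
    d = np.abs(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)) % 360.0
    out = np.where(d > 180.0, 360.0 - d, d)
    return out if out.ndim else float(out)
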