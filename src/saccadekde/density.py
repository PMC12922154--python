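"""Kernel density estimators for saccade direction and amplitude.

The two estimators that matter scientifically:

* :func:`kde_direction` - 1-D circular KDE of saccade direction with a von
  Mises kernel of concentration ``nu``: the kernel wraps around the circle,
  so 0 and 360 degrees are the same direction and the estimate is smooth
  across the boundary.
* :func:`kde_joint_mixed` - 2-D product-kernel KDE over (direction,
  amplitude): von Mises in the angular coordinate, Gaussian (reflected at
  r = 0 so no probability mass leaks to negative amplitudes) in the radial
  coordinate, evaluated on a polar grid and normalized with the polar area
  element r*dr*dtheta so the density integrates to one over the plane.

Both have deliberately naive Gaussian baselines (:func:`kde_direction_gaussian`,
:func:`kde_joint_gaussian`) that treat direction as a *linear* variable with
no wrap-around.  These reproduce the boundary artifact of legacy analyses -
density leaking off the 0/360 edge - and exist to be compared against, not
used.  Histogram utilities cover the older binned representations, including
the bin-center polyline whose false impression of continuity motivates KDE in
the first place.

All direction densities are per **radian**; 2-D densities are per
(radian x amplitude-unit).  Direct summation over samples is the definition
of the estimators and is used verbatim (no FFT approximation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .circular import VonMisesParams, von_mises_pdf
from .io import AmplitudeUnit, SaccadeTable, ValidationError

__all__ = [
    "KernelKind",
    "Normalization",
    "DirectionDensity",
    "JointDensityGrid",
    "HistogramResult",
    "kde_direction",
    "kde_direction_gaussian",
    "kde_joint_mixed",
    "kde_joint_gaussian",
    "histogram_direction",
    "bin_center_polyline",
    "classify_orientation",
    "orientation_frequencies",
    "amplitude_bandwidth",
    "joint_bandwidths",
    "save_direction_density",
    "load_direction_density",
    "save_joint_grid",
    "load_joint_grid",
]


class KernelKind(str, Enum):
    VON_MISES = "von_mises"
    GAUSSIAN_LINEAR = "gaussian_linear"


class Normalization(str, Enum):
    #: density * r * dr * dtheta sums to 1 (joint density over the plane)
    POLAR_AREA = "polar_area"
    #: raw product-kernel values, density * dr * dtheta sums to ~1
    COORDINATE_AREA = "coordinate_area"


# default grid resolution: 1 deg angular step, 200 radial steps, r_max at
# 1.05x the largest observed amplitude
DEFAULT_THETA_STEP_DEG = 1.0
DEFAULT_R_STEPS = 200
DEFAULT_R_MAX_FACTOR = 1.05


def _theta_grid(step_deg: float) -> np.ndarray:
    if step_deg <= 0:
        raise ValidationError("grid step must be positive")
    n = 360.0 / step_deg
    if abs(n - round(n)) > 1e-9:
        raise ValidationError(f"360 must be divisible by the grid step, got {step_deg}")
    return np.arange(round(n)) * step_deg


@dataclass(frozen=True)
class DirectionDensity:
    """1-D circular density on a uniform angular grid covering [0, 360)."""

    theta_grid_deg: np.ndarray
    values: np.ndarray  # density per radian
    kernel: KernelKind
    concentration_or_bandwidth: float
    n_samples: int

    @property
    def step_deg(self) -> float:
        return float(self.theta_grid_deg[1] - self.theta_grid_deg[0])

    def mode_deg(self) -> float:
        """Grid angle of the density maximum."""
        return float(self.theta_grid_deg[int(np.argmax(self.values))])

    def integral(self) -> float:
        """Riemann integral over one period (the grid is periodic-uniform)."""
        return float(np.sum(self.values) * np.deg2rad(self.step_deg))


@dataclass(frozen=True)
class JointDensityGrid:
    """2-D density over (direction, amplitude) on a polar grid.

    ``values[j, k]`` is the density at angle ``theta_grid_deg[j]`` and
    amplitude ``r_grid[k]``.  Under :attr:`Normalization.POLAR_AREA` the
    polar Riemann sum ``sum(values * r) * dr * dtheta`` equals 1.
    """

    theta_grid_deg: np.ndarray
    r_grid: np.ndarray
    r_unit: AmplitudeUnit
    values: np.ndarray
    normalization: Normalization
    kernels: tuple[KernelKind, KernelKind]
    bandwidths: tuple[float, float]  # (angular nu or h_theta, radial h)
    n_samples: int
    meta: dict = field(default_factory=dict)

    @property
    def dtheta_rad(self) -> float:
        return float(np.deg2rad(self.theta_grid_deg[1] - self.theta_grid_deg[0]))

    @property
    def dr(self) -> float:
        return float(self.r_grid[1] - self.r_grid[0])

    def polar_mass(self) -> float:
        """Riemann sum of density * r * dr * dtheta over the grid."""
        return float(np.sum(self.values * self.r_grid[None, :]) * self.dr * self.dtheta_rad)

    def mode(self) -> tuple[float, float]:
        """(theta_deg, r) of the grid cell with the largest density."""
        j, k = np.unravel_index(int(np.argmax(self.values)), self.values.shape)
        return float(self.theta_grid_deg[j]), float(self.r_grid[k])


@dataclass(frozen=True)
class HistogramResult:
    bin_edges_deg: np.ndarray
    counts: np.ndarray  # integers (absolute) or fractions summing to 1 (relative)
    mode: str  # "absolute" | "relative"
    layout: str = "polar"  # presentation hint only

    def bin_centers_deg(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_deg[:-1] + self.bin_edges_deg[1:])


# ---------------------------------------------------------------------------
# 1-D direction estimators
# ---------------------------------------------------------------------------


def kde_direction(angles_deg, nu: float, grid_step_deg: float = DEFAULT_THETA_STEP_DEG) -> DirectionDensity:
    """von Mises KDE of saccade direction.

    f(theta) = (1/n) * sum_i vM(theta; theta_i, nu), per radian, by direct
    summation on a uniform grid over [0, 360).  nu = 0 degenerates to the
    circular uniform density.
    """
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size == 0:
        raise ValidationError("kde_direction: empty sample")
    if nu < 0:
        raise ValidationError("concentration nu must be >= 0")
    grid = _theta_grid(grid_step_deg)
    # kernel matrix (grid x samples) via the stable scaled-Bessel pdf
    diff = grid[:, None] - angles[None, :]
    vals = von_mises_pdf(diff, VonMisesParams(mu_deg=0.0, kappa=nu))
    vals = np.asarray(vals).mean(axis=1)
    return DirectionDensity(
        theta_grid_deg=grid,
        values=vals,
        kernel=KernelKind.VON_MISES,
        concentration_or_bandwidth=float(nu),
        n_samples=angles.size,
    )


def _gaussian_linear_kernel(grid_deg: np.ndarray, angles_deg: np.ndarray, h_deg: float) -> np.ndarray:
    """(grid x samples) matrix of linear normal kernels, per radian, no wrap."""
    g = np.deg2rad(grid_deg)[:, None]
    a = np.deg2rad(angles_deg)[None, :]
    h = np.deg2rad(h_deg)
    z = (g - a) / h
    return np.exp(-0.5 * z**2) / (h * np.sqrt(2.0 * np.pi))


def kde_direction_gaussian(
    angles_deg, bandwidth_deg: float, grid_step_deg: float = DEFAULT_THETA_STEP_DEG
) -> DirectionDensity:
    """Gaussian-kernel direction estimate treating angle as a *linear* variable.

    No wrap-around is applied: mass placed by samples near 360 does not
    reach the grid near 0 and vice versa.  This is the legacy baseline whose
    circular-boundary artifact the von Mises estimator removes; it is kept
    solely for comparison.
    """
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size == 0:
        raise ValidationError("kde_direction_gaussian: empty sample")
    if bandwidth_deg <= 0:
        raise ValidationError("bandwidth must be > 0")
    grid = _theta_grid(grid_step_deg)
    vals = _gaussian_linear_kernel(grid, angles, bandwidth_deg).mean(axis=1)
    return DirectionDensity(
        theta_grid_deg=grid,
        values=vals,
        kernel=KernelKind.GAUSSIAN_LINEAR,
        concentration_or_bandwidth=float(bandwidth_deg),
        n_samples=angles.size,
    )


# ---------------------------------------------------------------------------
# 2-D joint estimators
# ---------------------------------------------------------------------------


def amplitude_bandwidth(amplitudes) -> float:
    """Silverman's rule-of-thumb bandwidth for the radial Gaussian kernel:
    h = 0.9 * min(sd, IQR/1.34) * n^(-1/5), floored at a small positive value
    for degenerate (constant) samples."""
    r = np.asarray(amplitudes, dtype=float)
    if r.size == 0:
        raise ValidationError("amplitude_bandwidth: empty sample")
    sd = float(np.std(r, ddof=1)) if r.size > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(r, [75, 25])))
    spread = min(x for x in (sd, iqr / 1.34) if x > 0) if (sd > 0 or iqr > 0) else 0.0
    if spread == 0.0:
        spread = max(abs(float(np.mean(r))), 1.0) * 1e-3
    return 0.9 * spread * r.size ** (-0.2)


def joint_bandwidths(table: SaccadeTable) -> tuple[float, float]:
    """Default (nu, h) for the bivariate product-kernel estimator.

    The 1-D rules (:func:`saccadekde.circular.smoothing_concentration`,
    :func:`amplitude_bandwidth`) target the univariate MISE rate, bandwidth
    ~ n^(-1/5).  For a d = 2 product kernel the optimal per-axis rate is
    n^(-1/(d+4)) = n^(-1/6), so the 1-D choices are rescaled to that rate:
    the angular concentration (an inverse squared bandwidth) by n^(-1/15)
    and the radial bandwidth by n^(1/30).  Without this adjustment the joint
    estimate is systematically under-smoothed and its mode is noisy.
    """
    from .circular import smoothing_concentration

    n = len(table)
    if n < 2:
        raise ValidationError("joint_bandwidths needs n >= 2; pass explicit bandwidths")
    nu = smoothing_concentration(table.directions_deg) * n ** (-1.0 / 15.0)
    h = amplitude_bandwidth(table.amplitudes) * n ** (1.0 / 30.0)
    return nu, h


def _reflected_gaussian(r_grid: np.ndarray, r_i: np.ndarray, h: float) -> np.ndarray:
    """(samples x r_grid) reflected Gaussian kernel: G(r; ri, h) + G(r; -ri, h).

    Reflection at r = 0 keeps each kernel's mass on [0, inf) without the
    renormalization bias truncation would introduce near zero."""
    z1 = (r_grid[None, :] - r_i[:, None]) / h
    z2 = (r_grid[None, :] + r_i[:, None]) / h
    norm = 1.0 / (h * np.sqrt(2.0 * np.pi))
    return norm * (np.exp(-0.5 * z1**2) + np.exp(-0.5 * z2**2))


def _r_grid(table: SaccadeTable, r_max: float | None, r_steps: int):
    amps = table.amplitudes
    if r_max is None:
        r_max = DEFAULT_R_MAX_FACTOR * float(np.max(amps))
    if r_max <= 0:
        raise ValidationError("r_max must be positive")
    if r_steps < 2:
        raise ValidationError("r_steps must be >= 2")
    meta = {}
    p99 = float(np.percentile(amps, 99))
    if r_max < p99:
        meta["truncation_warning"] = (
            f"r_max={r_max:g} truncates the amplitude distribution "
            f"(99th percentile {p99:g})"
        )
    return np.linspace(0.0, float(r_max), int(r_steps)), meta


def _joint_product(
    table: SaccadeTable,
    angular_kernel: np.ndarray,  # (theta_grid x samples)
    h_r: float,
    theta_grid: np.ndarray,
    r_grid: np.ndarray,
    normalization: Normalization,
) -> np.ndarray:
    radial = _reflected_gaussian(r_grid, table.amplitudes, h_r)  # (samples x r)
    vals = angular_kernel @ radial / len(table)
    if normalization is Normalization.POLAR_AREA:
        dr = r_grid[1] - r_grid[0]
        dtheta = np.deg2rad(theta_grid[1] - theta_grid[0])
        mass = np.sum(vals * r_grid[None, :]) * dr * dtheta
        if mass <= 0:
            raise ValidationError("joint density has zero polar mass on this grid")
        vals = vals / mass
    return vals


def kde_joint_mixed(
    table: SaccadeTable,
    nu: float,
    h: float,
    theta_step_deg: float = DEFAULT_THETA_STEP_DEG,
    r_max: float | None = None,
    r_steps: int = DEFAULT_R_STEPS,
    normalization: Normalization = Normalization.POLAR_AREA,
) -> JointDensityGrid:
    """Mixed von Mises (direction) x Gaussian (amplitude) joint KDE.

    f(theta, r) = (1/n) * sum_i vM(theta; theta_i, nu) * G_refl(r; r_i, h),
    evaluated on a uniform polar grid; under the default polar-area
    normalization the grid is rescaled so sum f * r * dr * dtheta = 1.
    """
    if len(table) == 0:
        raise ValidationError("kde_joint_mixed: empty table")
    if nu < 0:
        raise ValidationError("concentration nu must be >= 0")
    if h <= 0:
        raise ValidationError("amplitude bandwidth h must be > 0")
    theta_grid = _theta_grid(theta_step_deg)
    r_grid, meta = _r_grid(table, r_max, r_steps)
    diff = theta_grid[:, None] - table.directions_deg[None, :]
    angular = np.asarray(von_mises_pdf(diff, VonMisesParams(mu_deg=0.0, kappa=nu)))
    vals = _joint_product(table, angular, h, theta_grid, r_grid, normalization)
    return JointDensityGrid(
        theta_grid_deg=theta_grid,
        r_grid=r_grid,
        r_unit=table.unit,
        values=vals,
        normalization=normalization,
        kernels=(KernelKind.VON_MISES, KernelKind.GAUSSIAN_LINEAR),
        bandwidths=(float(nu), float(h)),
        n_samples=len(table),
        meta=meta,
    )


def kde_joint_gaussian(
    table: SaccadeTable,
    h_theta_deg: float,
    h_r: float,
    theta_step_deg: float = DEFAULT_THETA_STEP_DEG,
    r_max: float | None = None,
    r_steps: int = DEFAULT_R_STEPS,
    normalization: Normalization = Normalization.POLAR_AREA,
) -> JointDensityGrid:
    """Gaussian-only joint KDE: linear no-wrap Gaussian on direction too.

    Same product structure, grid and normalization as :func:`kde_joint_mixed`;
    only the directional kernel differs.  Baseline for comparison.
    """
    if len(table) == 0:
        raise ValidationError("kde_joint_gaussian: empty table")
    if h_theta_deg <= 0 or h_r <= 0:
        raise ValidationError("bandwidths must be > 0")
    theta_grid = _theta_grid(theta_step_deg)
    r_grid, meta = _r_grid(table, r_max, r_steps)
    angular = _gaussian_linear_kernel(theta_grid, table.directions_deg, h_theta_deg)
    vals = _joint_product(table, angular, h_r, theta_grid, r_grid, normalization)
    return JointDensityGrid(
        theta_grid_deg=theta_grid,
        r_grid=r_grid,
        r_unit=table.unit,
        values=vals,
        normalization=normalization,
        kernels=(KernelKind.GAUSSIAN_LINEAR, KernelKind.GAUSSIAN_LINEAR),
        bandwidths=(float(h_theta_deg), float(h_r)),
        n_samples=len(table),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Histogram baselines
# ---------------------------------------------------------------------------


def histogram_direction(angles_deg, n_bins: int, mode: str = "absolute") -> HistogramResult:
    """Direction histogram on uniform half-open bins partitioning [0, 360)."""
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    if mode not in ("absolute", "relative"):
        raise ValidationError(f"mode must be 'absolute' or 'relative', got {mode!r}")
    angles = np.asarray(angles_deg, dtype=float) % 360.0
    if angles.size == 0 and mode == "relative":
        raise ValidationError("relative histogram of an empty sample is undefined")
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    idx = np.minimum((angles // (360.0 / n_bins)).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    if mode == "relative":
        counts = counts / angles.size
    return HistogramResult(bin_edges_deg=edges, counts=counts, mode=mode)


def bin_center_polyline(hist: HistogramResult) -> list[tuple[float, float]]:
    """Legacy bin-center polyline, closed around the circle.

    Connecting bin centers by straight lines suggests knowledge of values
    between bins that the data do not contain; this constructor exists to
    reproduce and illustrate that legacy display, and its output is flagged
    accordingly downstream (the plot functions label it "legacy").
    """
    if hist.counts.size == 0:
        raise ValidationError("empty histogram")
    centers = hist.bin_centers_deg()
    verts = [(float(c), float(v)) for c, v in zip(centers, hist.counts)]
    # close the loop: first vertex repeated one full turn later
    verts.append((float(centers[0]) + 360.0, float(hist.counts[0])))
    return verts


# ---------------------------------------------------------------------------
# Orientation classes
# ---------------------------------------------------------------------------


def classify_orientation(direction_deg: float) -> str:
    """Classify a direction as 'horizontal' or 'vertical'.

    Horizontal is the pair of 90-degree wedges centred on the horizontal
    axis: [315, 360) u [0, 45) u [135, 225); everything else (the wedges
    centred on 90 and 270) is vertical.  The wedges are half-open at the
    45-degree diagonals, so every angle belongs to exactly one class.
    """
    d = float(direction_deg) % 360.0
    if d < 45.0 or d >= 315.0 or (135.0 <= d < 225.0):
        return "horizontal"
    return "vertical"


def orientation_frequencies(angles_deg) -> dict[str, float]:
    """Relative frequency of horizontal vs. vertical saccades (sums to 1)."""
    a = np.asarray(angles_deg, dtype=float) % 360.0
    if a.size == 0:
        raise ValidationError("empty sample")
    horiz = np.mean((a < 45.0) | (a >= 315.0) | ((a >= 135.0) & (a < 225.0)))
    return {"horizontal": float(horiz), "vertical": float(1.0 - horiz)}


# ---------------------------------------------------------------------------
# Grid serialization (CSV + JSON sidecar)
# ---------------------------------------------------------------------------


def save_direction_density(density: DirectionDensity, csv_path, meta_path=None) -> None:
    pd.DataFrame(
        {"theta_deg": density.theta_grid_deg, "density": density.values}
    ).to_csv(csv_path, index=False, float_format="%.17g")
    if meta_path is not None:
        meta = {
            "kernel": density.kernel.value,
            "concentration_or_bandwidth": density.concentration_or_bandwidth,
            "n_samples": density.n_samples,
            "grid_step_deg": density.step_deg,
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=2)


def load_direction_density(csv_path, meta_path) -> DirectionDensity:
    df = pd.read_csv(csv_path, float_precision="round_trip")
    with open(meta_path) as fh:
        meta = json.load(fh)
    return DirectionDensity(
        theta_grid_deg=df["theta_deg"].to_numpy(),
        values=df["density"].to_numpy(),
        kernel=KernelKind(meta["kernel"]),
        concentration_or_bandwidth=meta["concentration_or_bandwidth"],
        n_samples=meta["n_samples"],
    )


def save_joint_grid(grid: JointDensityGrid, csv_path, meta_path=None) -> None:
    """Long-format CSV (theta_deg, r, density) plus a JSON metadata sidecar."""
    tt, rr = np.meshgrid(grid.theta_grid_deg, grid.r_grid, indexing="ij")
    pd.DataFrame(
        {"theta_deg": tt.ravel(), "r": rr.ravel(), "density": grid.values.ravel()}
    ).to_csv(csv_path, index=False, float_format="%.17g")
    if meta_path is not None:
        meta = {
            "r_unit": grid.r_unit.value,
            "normalization": grid.normalization.value,
            "kernels": [k.value for k in grid.kernels],
            "bandwidths": list(grid.bandwidths),
            "n_samples": grid.n_samples,
            "n_theta": int(grid.theta_grid_deg.size),
            "n_r": int(grid.r_grid.size),
            **grid.meta,
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=2)


def load_joint_grid(csv_path, meta_path) -> JointDensityGrid:
    df = pd.read_csv(csv_path, float_precision="round_trip")
    with open(meta_path) as fh:
        meta = json.load(fh)
    n_theta, n_r = meta["n_theta"], meta["n_r"]
    theta = df["theta_deg"].to_numpy().reshape(n_theta, n_r)[:, 0]
    r = df["r"].to_numpy().reshape(n_theta, n_r)[0, :]
    return JointDensityGrid(
        theta_grid_deg=theta,
        r_grid=r,
        r_unit=AmplitudeUnit(meta["r_unit"]),
        values=df["density"].to_numpy().reshape(n_theta, n_r),
        normalization=Normalization(meta["normalization"]),
        kernels=tuple(KernelKind(k) for k in meta["kernels"]),
        bandwidths=tuple(meta["bandwidths"]),
        n_samples=meta["n_samples"],
        meta={k: v for k, v in meta.items() if k == "truncation_warning"},
    )
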