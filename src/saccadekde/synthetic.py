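"""Seeded synthetic saccade generator.

Emulates the statistical structure of AOI-filtered saccade data from a
two-alternative graph-selection task: directions follow a mixture of von
Mises components, amplitudes a Gamma law (right-skewed and strictly
positive, as observed amplitude distributions are).  Two presets ship with
the package:

* ``correct_like`` - the gaze pattern of successful solvers: mostly
  horizontal back-and-forth comparison saccades (tight von Mises components
  at 0 and 180 degrees), a small vertical component, and short-to-medium
  amplitudes.
* ``incorrect_like`` - diffuse, weakly oriented scanning (one nearly flat
  von Mises component) with longer amplitudes, the signature of exploratory
  search.

The preset parameters are package conventions engineered to reproduce those
qualitative contrasts; they are synthetic stand-ins, not estimates fitted to
any empirical dataset.

Reproducibility: one :class:`numpy.random.Generator` per generated table,
consumed in a fixed documented order (per saccade: component index,
direction, amplitude redraws until the displacement fits on screen, start
point coordinates), so identical (scenario, n, seed) always yields the
identical table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .circular import (
    VonMisesParams,
    circular_distance_deg,
    smoothing_concentration,
    von_mises_pdf,
)
from .density import kde_direction
from .io import AmplitudeUnit, SaccadeRecord, SaccadeTable, ScreenGeometry

__all__ = [
    "MixtureComponent",
    "GroupScenario",
    "sample_von_mises",
    "generate_group",
    "recovery_experiment",
    "CORRECT_LIKE",
    "INCORRECT_LIKE",
    "SCENARIOS",
]


@dataclass(frozen=True)
class MixtureComponent:
    """One mixture component: direction law and Gamma amplitude law (px)."""

    weight: float
    direction: VonMisesParams
    amplitude_shape: float
    amplitude_scale: float

    def __post_init__(self) -> None:
        if not (0.0 < self.weight <= 1.0):
            raise ValueError(f"weight must lie in (0, 1], got {self.weight}")
        if self.amplitude_shape <= 0 or self.amplitude_scale <= 0:
            raise ValueError("gamma shape and scale must be positive")


@dataclass(frozen=True)
class GroupScenario:
    name: str
    components: tuple[MixtureComponent, ...]
    n_default: int = 1000
    geometry: ScreenGeometry = field(
        default_factory=lambda: ScreenGeometry(
            width_px=1920, height_px=1080, ppd_override=39.04
        )
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        if not self.components:
            raise ValueError("scenario needs at least one component")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"component weights must sum to 1, got {total}")


CORRECT_LIKE = GroupScenario(
    name="correct_like",
    components=(
        MixtureComponent(0.45, VonMisesParams(0.0, 12.0), 4.0, 25.0),
        MixtureComponent(0.45, VonMisesParams(180.0, 12.0), 4.0, 25.0),
        MixtureComponent(0.10, VonMisesParams(90.0, 4.0), 4.0, 25.0),
    ),
)

INCORRECT_LIKE = GroupScenario(
    name="incorrect_like",
    components=(MixtureComponent(1.0, VonMisesParams(90.0, 0.5), 4.0, 60.0),),
)

SCENARIOS: dict[str, GroupScenario] = {
    CORRECT_LIKE.name: CORRECT_LIKE,
    INCORRECT_LIKE.name: INCORRECT_LIKE,
}


def sample_von_mises(params: VonMisesParams, n: int, seed) -> np.ndarray:
    """Draw ``n`` directions (degrees, [0, 360)) from vM(mu, kappa).

    Uses the Best-Fisher wrapped-Cauchy rejection sampler (as implemented by
    :meth:`numpy.random.Generator.vonmises`) for kappa > 0 and the circular
    uniform for kappa = 0.  ``seed`` may be an int or a Generator; an int
    always reproduces the same sequence.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if params.kappa == 0.0:
        return rng.uniform(0.0, 360.0, size=n)
    draws = rng.vonmises(np.deg2rad(params.mu_deg), params.kappa, size=n)
    return np.rad2deg(draws) % 360.0


def _draw_feasible_amplitude(
    rng: np.random.Generator,
    comp: MixtureComponent,
    direction_deg: float,
    geometry: ScreenGeometry,
) -> tuple[float, float, float]:
    """Draw a Gamma amplitude whose on-screen displacement fits the screen.

    Returns (amplitude, dx, dy) in screen coordinates (y down).  Redraws
    until |dx| < width and |dy| < height, so a start point always exists;
    the redraw consumes the same stream, keeping generation deterministic.
    """
    theta = math.radians(direction_deg)
    for _ in range(1000):
        amp = float(rng.gamma(comp.amplitude_shape, comp.amplitude_scale))
        if amp == 0.0:
            continue
        dx = amp * math.cos(theta)
        dy = -amp * math.sin(theta)  # screen y runs downward
        if abs(dx) < geometry.width_px and abs(dy) < geometry.height_px:
            return amp, dx, dy
    raise RuntimeError("could not draw an on-screen amplitude (scale far exceeds screen)")


def generate_group(scenario: GroupScenario, n: int | None = None, seed: int = 0) -> SaccadeTable:
    """Generate a saccade table for one scenario.

    Per saccade: a component is chosen by weight, the direction drawn from
    its von Mises law, the amplitude from its Gamma law (px), and endpoints
    synthesized by placing a uniform-random start point such that the whole
    displacement stays on screen.  Records carry ``group = scenario.name``.
    """
    n = scenario.n_default if n is None else int(n)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    geom = scenario.geometry
    cum_w = np.cumsum([c.weight for c in scenario.components])
    records = []
    for _ in range(n):
        ci = int(np.searchsorted(cum_w, rng.random(), side="right"))
        ci = min(ci, len(scenario.components) - 1)
        comp = scenario.components[ci]
        direction = float(sample_von_mises(comp.direction, 1, rng)[0])
        amp, dx, dy = _draw_feasible_amplitude(rng, comp, direction, geom)
        # feasible start interval so that end = start + (dx, dy) stays on screen
        sx = rng.uniform(max(0.0, -dx), min(geom.width_px, geom.width_px - dx))
        sy = rng.uniform(max(0.0, -dy), min(geom.height_px, geom.height_px - dy))
        records.append(
            SaccadeRecord(
                direction_deg=direction,
                amplitude_value=amp,
                amplitude_unit=AmplitudeUnit.PX,
                start_xy=(sx, sy),
                end_xy=(sx + dx, sy + dy),
                group=scenario.name,
            )
        )
    return SaccadeTable(
        records=tuple(records), geometry=geom, source=f"synthetic:{scenario.name}"
    )


def recovery_experiment(
    true_params: VonMisesParams,
    n: int,
    seed: int,
    grid_step_deg: float = 1.0,
    nu: float | None = None,
) -> dict:
    """Sample from a von Mises law, fit the direction KDE, measure recovery.

    Returns the circular distance between the KDE mode and the true mean
    direction (``mode_error_deg``) and the Riemann integral of the absolute
    density error (``integrated_abs_error``).  For kappa = 0 the reference is
    the circular uniform 1/(2*pi) and the mode error is reported as NaN (a
    uniform law has no mode).
    """
    if n < 10:
        raise ValueError("recovery_experiment needs n >= 10")
    angles = sample_von_mises(true_params, n, seed)
    nu_used = smoothing_concentration(angles, override=nu)
    est = kde_direction(angles, nu=nu_used, grid_step_deg=grid_step_deg)
    f_true = np.asarray(von_mises_pdf(est.theta_grid_deg, true_params))
    iae = float(np.sum(np.abs(est.values - f_true)) * np.deg2rad(est.step_deg))
    mode_error = (
        float("nan")
        if true_params.kappa == 0.0
        else circular_distance_deg(est.mode_deg(), true_params.mu_deg)
    )
    return {
        "mode_error_deg": mode_error,
        "integrated_abs_error": iae,
        "nu": nu_used,
        "n": n,
    }
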