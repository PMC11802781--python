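"""Time-resolved spread of somatically labelled protein into spines.

Reproduces the photoactivation paradigm: the dendrite sits at its protein
steady state; from t = 0 every protein supplied by the soma is labelled,
and the labelled subpopulation spreads through the shaft and exchanges
with spines while the *total* pool stays stationary. Because the total
occupancies are constant, the labelled dynamics are linear and
time-invariant:

``dp_l/dt = D_p p_l'' - lambda_p p_l - k_in(x) p_l + nu_p s_l``
``ds_l/dt = k_in(x) p_l - (nu_p + lambda_p) s_l``

with ``k_in(x) = u_p (1 - s_tot(x)/(rho eta_p))`` frozen at its
steady-state value. The soma acts as a well-mixed, fully labelled
reservoir from t = 0 on: the labelled shaft density at x = 0 is clamped
to its steady value (and the unlabelled remainder to zero), which encodes
both the instantaneous labelling of the somatic pool and the labelled
somatic synthesis. The spatial operator is the same conservative
finite-volume stencil as the steady-state solver, so the steady profile is
an exact fixed point of the stepping scheme. Time stepping: implicit
(backward Euler) shaft update with the spine exchange coupled explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .errors import ConfigurationError, NumericalError
from .params import DendriteGeometry, SpeciesParams, spine_capacity_density
from .steady_state import Scenario, SpatialProfile, solve_steady

DEFAULT_SPINE_POSITIONS = (25.0, 50.0, 75.0, 105.0)


@dataclass(frozen=True)
class LabelingTimeSeries:
    """Labelled spine occupancy vs time at selected spine positions."""

    times: np.ndarray            # s
    spine_positions: np.ndarray  # um
    labelled: np.ndarray         # (n_times, n_spines) labelled copies/spine
    total: np.ndarray            # (n_spines,) steady total copies/spine
    normalised: np.ndarray | None = None

    @property
    def labelled_fraction(self) -> np.ndarray:
        return self.labelled / self.total[None, :]


def _banded(lower, diag, upper):
    n = len(diag)
    ab = np.zeros((3, n))
    ab[0, 1:] = upper[:-1]
    ab[1] = diag
    ab[2, :-1] = lower[1:]
    return ab


def _shaft_operator(species: SpeciesParams, geom: DendriteGeometry, k_in):
    """Tridiagonal FV operator: diffusion - lambda_p - k_in(x)."""
    n = geom.n_nodes
    dx = geom.grid_dx
    a_int = species.D_p / (dx * dx)
    a_end = 2.0 * a_int
    lower = np.zeros(n)
    upper = np.zeros(n)
    diag = np.empty(n)
    lower[1:-1] = a_int
    upper[1:-1] = a_int
    upper[0] = a_end
    lower[-1] = a_end
    diag[0] = -a_end
    diag[-1] = -a_end
    diag[1:-1] = -2.0 * a_int
    diag -= species.lambda_p + k_in
    return lower, diag, upper


def simulate_labeling(
    species: SpeciesParams,
    geom: DendriteGeometry,
    spine_positions=DEFAULT_SPINE_POSITIONS,
    t_end: float = 8 * 3600.0,
    dt: float = 10.0,
    steady: SpatialProfile | None = None,
    labelled_boundary: bool = True,
    p0: np.ndarray | None = None,
    s0: np.ndarray | None = None,
    save_every: int = 6,
) -> LabelingTimeSeries:
    """Evolve the labelled subpopulation on top of the steady state.

    By default the labelled pools start empty and the soma is a fully
    labelled reservoir from t = 0 on (continuous photoactivation at the
    soma: the labelled shaft density at x = 0 equals its steady value).
    ``labelled_boundary=False`` with explicit initial pools instead
    follows the unlabelled remainder, whose somatic boundary value is
    zero (used for conservation checks). Occupancies are recorded every
    ``save_every`` steps at the requested spine positions (copies per
    spine).
    """
    if steady is None:
        steady = solve_steady(species, geom, Scenario.somatic())
    x = steady.x
    E = spine_capacity_density(species, geom)
    k_in = species.u_p * (1.0 - steady.p_spine / E)
    cexit = species.nu_p + species.lambda_p

    max_rate = max(float(np.max(k_in)), cexit)
    if dt * max_rate > 1.0:
        raise ConfigurationError(
            f"time step dt={dt} s too large for the spine exchange rates "
            f"(max rate {max_rate:.2e}/s); choose dt <= {1.0 / max_rate:.1f} s"
        )

    positions = np.asarray(spine_positions, dtype=float)
    if np.any(positions < 0) or np.any(positions > geom.L):
        raise ConfigurationError("spine positions outside the dendrite")
    idx = np.array([int(round(pos / geom.grid_dx)) for pos in positions])

    n = len(x)
    p_l = np.zeros(n) if p0 is None else np.asarray(p0, dtype=float).copy()
    s_l = np.zeros(n) if s0 is None else np.asarray(s0, dtype=float).copy()

    boundary_value = steady.p[0] if labelled_boundary else 0.0
    p_l[0] = boundary_value

    lower, diag, upper = _shaft_operator(species, geom, k_in)
    # backward Euler: (I - dt*Lop) p_new = p_old + dt*nu*s_old, with the
    # somatic node held at the reservoir value (Dirichlet row)
    bl = -dt * lower
    bd = 1.0 - dt * diag
    bu = -dt * upper
    bd[0], bu[0] = 1.0, 0.0
    ab = _banded(bl, bd, bu)

    n_steps = int(round(t_end / dt))
    times = [0.0]
    records = [s_l[idx] / geom.rho]
    for step in range(1, n_steps + 1):
        rhs = p_l + dt * species.nu_p * s_l
        rhs[0] = boundary_value
        p_l = solve_banded((1, 1), ab, rhs)
        s_l = (s_l + dt * k_in * p_l) / (1.0 + dt * cexit)
        if step % save_every == 0 or step == n_steps:
            times.append(step * dt)
            records.append(s_l[idx] / geom.rho)

    labelled = np.asarray(records)
    if np.min(labelled) < -1e-9 * np.max(np.abs(labelled)):
        raise NumericalError("negative labelled occupancy", {"min": labelled.min()})
    total = steady.p_spine[idx] / geom.rho
    series = LabelingTimeSeries(
        times=np.asarray(times),
        spine_positions=positions,
        labelled=labelled,
        total=total,
    )
    return series


def normalise_to_proximal(
    series: LabelingTimeSeries, mode: str = "matched_time"
) -> LabelingTimeSeries:
    """Divide every trace by the proximal-most spine's trace.

    ``matched_time`` divides at matched times (0/0 at t = 0 defined as 0);
    ``terminal`` divides by the proximal trace's final value.
    """
    order = np.argsort(series.spine_positions)
    prox = series.labelled[:, order[0]]
    if mode == "matched_time":
        denom = np.where(prox > 0, prox, np.inf)[:, None]
        normalised = series.labelled / denom
    elif mode == "terminal":
        if prox[-1] <= 0:
            raise ConfigurationError("proximal trace never rises above zero")
        normalised = series.labelled / prox[-1]
    else:
        raise ConfigurationError(f"unknown normalisation mode {mode!r}")
    return LabelingTimeSeries(
        times=series.times,
        spine_positions=series.spine_positions,
        labelled=series.labelled,
        total=series.total,
        normalised=normalised,
    )


def saturation_time(
    times,
    trace,
    asymptote: float,
    level: float = 0.95,
) -> float | None:
    """First time a monotone rising trace exceeds ``level * asymptote``.

    The asymptote is the analytic fixed point of the labelling dynamics
    (the steady total occupancy), not the last sample. Returns the
    linearly interpolated crossing time, or None if the level is not
    reached within the simulated window.
    """
    if not 0 < level < 1:
        raise ConfigurationError(f"level must lie in (0, 1), got {level}")
    if not asymptote > 0:
        raise ConfigurationError("asymptote must be > 0")
    times = np.asarray(times, dtype=float)
    trace = np.asarray(trace, dtype=float)
    target = level * asymptote
    above = trace >= target
    if not above.any():
        return None
    k = int(np.argmax(above))
    if k == 0:
        return float(times[0])
    t0, t1 = times[k - 1], times[k]
    y0, y1 = trace[k - 1], trace[k]
    if y1 == y0:
        return float(t1)
    return float(t0 + (target - y0) * (t1 - t0) / (y1 - y0))
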