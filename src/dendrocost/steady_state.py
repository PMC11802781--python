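"""Steady-state mRNA/protein/spine distributions along a closed dendrite.

The dendrite is the segment [0, L] with the soma at x = 0 and a sealed tip
at x = L. At dynamical equilibrium the dendritic mRNA density obeys a
diffusion-decay equation with the ensemble diffusion constant ``D_eff``
(motor transport folded in), giving the classic
``cosh((L-x)/ell_m)/cosh(L/ell_m)`` shape with ``ell_m = sqrt(D_eff/
lambda_m)``. The shaft protein density is sourced by local translation
``tau*m(x)`` and by the somatic synthesis exported through x = 0, loses
protein to degradation and to spines, and must fill every spine to at least
the fraction ``phi`` of its capacity. The overall amplitude (total mRNA of
the species) is the unknown fixed by that filling constraint.

Localisation scenarios: ``somatic`` keeps all mRNA in the soma (no
dendritic mRNA, protein reaches spines by diffusion only); ``dendritic``
keeps a share ``r_soma`` of mRNA in the soma and distributes the rest along
the dendrite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .errors import ConfigurationError, NumericalError
from .params import (
    DendriteGeometry,
    SpeciesParams,
    distal_shaft_density,
    spine_capacity_density,
)
from .transport import cached_effective_diffusion, normalised_cosh_profile

__all__ = [
    "Scenario", "SpatialProfile", "spine_occupancy", "mrna_profile_shape",
    "solve_protein_bvp", "solve_steady", "total_counts",
]


@dataclass(frozen=True)
class Scenario:
    """mRNA localisation scenario: all-somatic, or dendritic with share r_soma."""

    kind: str
    r_soma: float = 1.0

    def __post_init__(self):
        if self.kind not in ("somatic", "dendritic"):
            raise ConfigurationError(f"unknown scenario kind {self.kind!r}")
        if self.kind == "dendritic" and not 0.0 < self.r_soma < 1.0:
            raise ConfigurationError(
                f"dendritic scenario needs 0 < r_soma < 1, got {self.r_soma}"
            )

    @classmethod
    def somatic(cls) -> "Scenario":
        return cls("somatic", 1.0)

    @classmethod
    def dendritic(cls, r_soma: float) -> "Scenario":
        return cls("dendritic", r_soma)

    def label(self) -> str:
        if self.kind == "somatic":
            return "somatic"
        return f"dendritic(r_soma={self.r_soma:g})"


@dataclass(frozen=True)
class SpatialProfile:
    """Steady-state spatial distributions plus somatic pools."""

    x: np.ndarray
    m: np.ndarray
    p: np.ndarray
    p_spine: np.ndarray
    m_soma: float
    p_soma: float
    r_soma: float
    scenario: Scenario
    diagnostics: dict = field(default_factory=dict, compare=False)

    @property
    def m_dendrite(self) -> float:
        return float(np.trapezoid(self.m, self.x))

    @property
    def m_total(self) -> float:
        return self.m_soma + self.m_dendrite


def spine_occupancy(
    p: np.ndarray | float, species: SpeciesParams, geom: DendriteGeometry
) -> np.ndarray | float:
    """Quasi-steady spine protein density for a given shaft density.

    Exact equilibrium of the spine balance:
    ``s = u_p p E / (u_p p + (nu_p + lambda_p) E)`` with ``E = rho*eta_p``;
    saturates below the capacity density E.
    """
    E = spine_capacity_density(species, geom)
    cexit = species.nu_p + species.lambda_p
    p = np.asarray(p, dtype=float) if np.ndim(p) else float(p)
    return species.u_p * p * E / (species.u_p * p + cexit * E)


def mrna_profile_shape(
    x: np.ndarray, L: float, D_eff: float, lambda_m: float, v_bias: float = 0.0
) -> np.ndarray:
    """Unit-amplitude dendritic mRNA shape (m(0) = 1), sealed tip at L.

    Without drift this is ``cosh((L-x)/ell)/cosh(L/ell)``. With a net
    anterograde drift the advection term ``-v_bias * dm/dx`` shifts the
    exponents of the two-mode solution.
    """
    ell = np.sqrt(D_eff / lambda_m)
    if v_bias == 0.0:
        return normalised_cosh_profile(x, L, ell)
    disc = np.sqrt(v_bias * v_bias + 4.0 * D_eff * lambda_m)
    r1 = (v_bias + disc) / (2.0 * D_eff)   # growing mode
    r2 = (v_bias - disc) / (2.0 * D_eff)   # decaying mode
    # m = c1 e^{r1 x} + c2 e^{r2 x} with m'(L) = 0; with c2 = 1 this gives
    # c1 = -(r2/r1) e^{(r2-r1)L}. All exponents below stay <= 0 on [0, L].
    m = -(r2 / r1) * np.exp(r2 * L) * np.exp(r1 * (x - L)) + np.exp(r2 * x)
    return m / m[0]


def _grid(geom: DendriteGeometry) -> np.ndarray:
    return np.linspace(0.0, geom.L, geom.n_nodes)


def _validate(species: SpeciesParams, geom: DendriteGeometry) -> None:
    if species.u_p <= 0:
        raise ConfigurationError(
            f"{species.name}: spine entry rate u_p must be > 0 to satisfy the "
            "spine filling constraint"
        )
    if not 0 < geom.phi < 1:
        raise ConfigurationError(f"phi must lie in (0, 1), got {geom.phi}")


def solve_protein_bvp(
    species: SpeciesParams,
    geom: DendriteGeometry,
    m: np.ndarray,
    m_soma: float,
    p_init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Shaft/spine protein profile for a *given* mRNA distribution.

    Solves the protein BVP with somatic influx ``tau*m_soma`` and local
    synthesis ``tau*m(x)`` at fixed amplitude (no filling constraint).
    Returns ``(p, p_spine)``. Exposed for diagnostics and oracle checks.
    """
    x = _grid(geom)
    if len(m) != len(x):
        raise ConfigurationError("mRNA profile does not match the grid")
    E = spine_capacity_density(species, geom)
    cexit = species.nu_p + species.lambda_p
    p = np.zeros_like(x) if p_init is None else p_init.astype(float).copy()
    it = _kernels.protein_newton(
        np.ascontiguousarray(m, dtype=float), species.tau * m_soma,
        species.tau, species.D_p, species.lambda_p, species.u_p, cexit, E,
        geom.grid_dx, p, 1e-12, 200,
    )
    if it < 0:
        raise NumericalError(
            "protein BVP Newton iteration did not converge",
            {"species": species.name, "iterations": -it},
        )
    s = np.asarray(spine_occupancy(p, species, geom))
    return p, s


def solve_steady(
    species: SpeciesParams,
    geom: DendriteGeometry,
    scenario: Scenario,
) -> SpatialProfile:
    """Steady-state profile for one species, geometry and scenario.

    The mRNA amplitude (hence the species' total mRNA and protein copy
    numbers) is scaled until the least-filled spine reaches the filling
    ratio ``phi`` of its capacity; for monotonically decreasing profiles
    this pins the distal boundary value ``p(L) = (1/pi_p) phi/(1-phi)
    rho*eta_p``.
    """
    _validate(species, geom)
    x = _grid(geom)
    n = len(x)
    E = spine_capacity_density(species, geom)
    cexit = species.nu_p + species.lambda_p
    p_target = distal_shaft_density(species, geom)

    if scenario.kind == "somatic":
        m_hat = np.zeros(n)
        m_soma_hat = 1.0
        D_eff = None
        theta = 0.0
    else:
        t = species.transport
        fit = cached_effective_diffusion(
            t.v, t.beta, t.alpha, species.D_m0, species.lambda_m, geom.L
        )
        D_eff, theta = fit.D_eff, fit.theta
        m_hat = mrna_profile_shape(x, geom.L, D_eff, species.lambda_m, t.v_bias)
        int_m_hat = float(np.trapezoid(m_hat, x))
        r = scenario.r_soma
        m_soma_hat = r / (1.0 - r) * int_m_hat

    # initial amplitude guess: synthesis balances degradation of a filled
    # dendrite (shaft at the distal target + spines at phi*E)
    demand = species.lambda_p * (geom.phi * E + p_target) * geom.L
    A_init = demand / (species.tau * (float(np.trapezoid(m_hat, x)) + m_soma_hat))

    A, p, status = _kernels.solve_amplitude(
        np.ascontiguousarray(m_hat, dtype=float), m_soma_hat,
        species.tau, species.D_p, species.lambda_p, species.u_p, cexit, E,
        geom.grid_dx, p_target, A_init, 1e-12, 1e-10,
    )
    if status == 1:
        raise NumericalError(
            "amplitude bracketing failed (filling constraint infeasible?)",
            {"species": species.name, "scenario": scenario.label(), "A": A},
        )
    if status == 2:
        raise NumericalError(
            "protein BVP Newton iteration failed during amplitude search",
            {"species": species.name, "scenario": scenario.label()},
        )

    m = A * m_hat
    m_soma = A * m_soma_hat
    s = np.asarray(spine_occupancy(p, species, geom))

    # flux balance diagnostic: synthesis vs degradation
    synth = species.tau * (m_soma + float(np.trapezoid(m, x)))
    degr = species.lambda_p * float(np.trapezoid(p + s, x))
    diagnostics = {
        "amplitude": float(A),
        "D_eff": D_eff,
        "theta": theta,
        "J0": species.tau * m_soma,
        "flux_imbalance": abs(synth - degr) / max(synth, 1e-300),
        "min_fill": float(np.min(s) / (geom.phi * E)),
    }
    return SpatialProfile(
        x=x, m=m, p=p, p_spine=s, m_soma=float(m_soma), p_soma=0.0,
        r_soma=scenario.r_soma if scenario.kind == "dendritic" else 1.0,
        scenario=scenario, diagnostics=diagnostics,
    )


def total_counts(profile: SpatialProfile, geom: DendriteGeometry) -> dict:
    """Integrated mRNA and protein copy numbers (soma + dendrite + spines)."""
    M = profile.m_soma + float(np.trapezoid(profile.m, profile.x))
    P = (
        profile.p_soma
        + float(np.trapezoid(profile.p, profile.x))
        + float(np.trapezoid(profile.p_spine, profile.x))
    )
    return {"M_total": M, "P_total": P}
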