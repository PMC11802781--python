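"""Model parameters for molecular species, dendrite geometry and transport.

Units are fixed project-wide: seconds, micrometres, ATP. Counts are absolute
molecule numbers; linear densities are molecules per micrometre of dendrite.

A molecular species is described by the parameters entering the
reaction-diffusion equations for dendritic mRNA (density ``m``), shaft
protein (``p``) and spine protein (``p_spine``), plus the lengths that set
its synthesis costs. Degradation rates are always derived from half-lives,
``lambda = ln2 / halflife``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .errors import ConfigurationError

LN2 = math.log(2.0)

HOUR = 3600.0
DAY = 86400.0


def decay_rate(halflife: float) -> float:
    """First-order decay rate (1/s) for an exponential half-life (s).

    Raises
    ------
    ConfigurationError
        If the half-life is not strictly positive.
    """
    if not halflife > 0:
        raise ConfigurationError(f"half-life must be > 0, got {halflife!r}")
    return LN2 / halflife


@dataclass(frozen=True)
class TransportParams:
    """Run-and-pause motor transport kinetics of an mRNA granule.

    ``v`` is the instantaneous run velocity (um/s), ``beta`` the
    run-termination rate (1/s, reciprocal mean run duration) and ``alpha``
    the re-entry rate into *each* of the two moving states (1/s). ``v_bias``
    is an optional net anterograde drift used by the advection variant of
    the one-state equation.
    """

    v: float = 1.0
    beta: float = 0.5
    alpha: float = 0.05
    v_bias: float = 0.0

    def __post_init__(self):
        if self.v < 0:
            raise ConfigurationError(f"run velocity must be >= 0, got {self.v}")
        if not self.beta > 0:
            raise ConfigurationError(
                f"run-termination rate beta must be > 0 (beta=0 means "
                f"infinite runs), got {self.beta}"
            )
        if self.alpha < 0:
            raise ConfigurationError(f"re-entry rate alpha must be >= 0, got {self.alpha}")

    @property
    def theta(self) -> float:
        """Steady-state fraction of molecules in the two moving states."""
        return 2.0 * self.alpha / (2.0 * self.alpha + self.beta)


def transported_fraction(alpha: float, beta: float) -> float:
    """Fraction of cargoes in transit, ``2*alpha / (2*alpha + beta)``.

    Follows from the occupancy balance of the three-state model at steady
    state: each moving state holds ``(alpha/beta) * m0``.
    """
    if alpha < 0:
        raise ConfigurationError(f"alpha must be >= 0, got {alpha}")
    if not beta > 0:
        raise ConfigurationError(f"beta must be > 0, got {beta}")
    return 2.0 * alpha / (2.0 * alpha + beta)


@dataclass(frozen=True)
class SpeciesParams:
    """All per-species model parameters.

    Parameters
    ----------
    name : str
        Species identifier.
    D_m0 : float
        Diffusion constant of the non-transported (resting) mRNA state, um^2/s.
    D_p : float
        Protein diffusion constant, um^2/s.
    halflife_m, halflife_p : float
        mRNA / protein half-lives in seconds.
    tau : float
        Translation rate, proteins per mRNA per second.
    eta_p : float
        Maximal protein copies per spine.
    u_p, nu_p : float
        Spine entry / exit rates, 1/s.
    N_aa : int
        Protein length in amino acids.
    N_nt : int
        Transcript length in nucleotides (coding + non-coding).
    transport : TransportParams
        Motor transport kinetics used in the dendritic-mRNA scenario.
    mrnas_per_granule : float
        mRNA copies per transport granule (cargo bookkeeping for the
        transport cost).
    labels : dict
        Optional low/medium/high group labels per sampled dimension.
    """

    name: str
    D_m0: float
    D_p: float
    halflife_m: float
    halflife_p: float
    tau: float
    eta_p: float
    u_p: float
    nu_p: float
    N_aa: int
    N_nt: int
    transport: TransportParams = field(default_factory=TransportParams)
    mrnas_per_granule: float = 1.0
    labels: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        positives = {
            "D_m0": self.D_m0, "D_p": self.D_p,
            "halflife_m": self.halflife_m, "halflife_p": self.halflife_p,
            "tau": self.tau, "eta_p": self.eta_p,
            "u_p": self.u_p, "nu_p": self.nu_p,
            "N_aa": self.N_aa, "N_nt": self.N_nt,
            "mrnas_per_granule": self.mrnas_per_granule,
        }
        for key, val in positives.items():
            if not val > 0:
                raise ConfigurationError(f"{self.name}: {key} must be > 0, got {val!r}")
        if self.N_nt < 3 * self.N_aa:
            raise ConfigurationError(
                f"{self.name}: transcript length N_nt={self.N_nt} shorter than "
                f"coding sequence 3*N_aa={3 * self.N_aa}"
            )

    @property
    def lambda_m(self) -> float:
        """mRNA degradation rate, 1/s."""
        return decay_rate(self.halflife_m)

    @property
    def lambda_p(self) -> float:
        """Protein degradation rate, 1/s."""
        return decay_rate(self.halflife_p)

    @property
    def noncoding_ratio(self) -> float:
        """Non-coding / coding nucleotide ratio, ``N_nt / (3*N_aa) - 1``."""
        return self.N_nt / (3.0 * self.N_aa) - 1.0

    def with_(self, **kwargs) -> "SpeciesParams":
        """Copy with fields replaced (convenience for sweeps)."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DendriteGeometry:
    """Linear dendrite with the soma at x = 0 and a closed tip at x = L.

    ``rho`` is the spine density (spines per um), ``phi`` the required
    filling ratio of the maximal spine capacity, ``grid_dx`` the spatial
    step of the finite-volume grid.
    """

    L: float
    rho: float = 1.0
    phi: float = 0.95
    grid_dx: float = 1.0

    def __post_init__(self):
        if not self.L > 0:
            raise ConfigurationError(f"dendrite length must be > 0, got {self.L}")
        if not 0 < self.phi < 1:
            raise ConfigurationError(
                f"filling ratio phi must lie strictly in (0, 1), got {self.phi}"
            )
        if not self.rho > 0:
            raise ConfigurationError(f"spine density must be > 0, got {self.rho}")
        n = self.L / self.grid_dx
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"grid_dx={self.grid_dx} does not divide L={self.L}"
            )

    @property
    def n_nodes(self) -> int:
        return int(round(self.L / self.grid_dx)) + 1


def spine_capacity_density(species: SpeciesParams, geom: DendriteGeometry) -> float:
    """Maximal spine protein density ``rho * eta_p`` (per um)."""
    return geom.rho * species.eta_p


def spine_permeability(species: SpeciesParams) -> float:
    """``pi_p = u_p / (nu_p + lambda_p)``: entry over total exit rate."""
    return species.u_p / (species.nu_p + species.lambda_p)


def distal_shaft_density(species: SpeciesParams, geom: DendriteGeometry) -> float:
    """Shaft density at which a spine equilibrates at the filling ratio.

    Algebraic solution of the spine balance at occupancy ``phi*rho*eta_p``:
    ``p = (1/pi_p) * phi/(1-phi) * rho*eta_p`` (the distal boundary value).
    """
    return (
        (1.0 / spine_permeability(species))
        * (geom.phi / (1.0 - geom.phi))
        * spine_capacity_density(species, geom)
    )
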