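"""ATP budgets per species and the energy-optimal localisation decision.

Three cost categories per second of maintained steady state:

* transcription: ``C_nt * N_nt * lambda_m * (m_soma + int m)`` — every
  decayed transcript must be re-synthesised at 2.17 ATP per nucleotide
  (chain elongation plus post-transcriptional processing);
* translation: ``C_aa * N_aa * tau * (m_soma + int m)`` — protein synthesis
  and eventual degradation together at 5 ATP per amino acid (at steady
  state synthesised and degraded counts match, so one term covers both);
* transport: ``C_cargo * theta_m * int m / granule`` — each cargo in
  transit burns 125 ATP/s at the 1 um/s reference run speed, scaled
  linearly with the actual run velocity.

The all-somatic scenario needs no transport machinery, so its transport
cost is identically zero. Comparing the somatic budget against the best
dendritic budget over a grid of somatic mRNA shares yields the
energy-optimal localisation strategy of a species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DendrocostError
from .params import DendriteGeometry, SpeciesParams
from .steady_state import Scenario, SpatialProfile, solve_steady

C_NT = 2.17     # ATP per nucleotide transcribed
C_AA = 5.0      # ATP per amino acid synthesised + degraded
C_CARGO = 125.0  # ATP/s per cargo in transit at the 1 um/s reference speed
V_REFERENCE = 1.0  # um/s

DEFAULT_R_SOMA_GRID = tuple(np.round(np.arange(0.1, 0.95, 0.1), 10))


@dataclass(frozen=True)
class EnergyBudget:
    """ATP/s split into the three cost categories for one scenario."""

    scenario: Scenario
    transcription: float
    translation: float
    transport: float

    @property
    def total(self) -> float:
        return self.transcription + self.translation + self.transport


@dataclass(frozen=True)
class LocalisationDecision:
    """Energy comparison of somatic vs best dendritic mRNA localisation."""

    species: str
    budget_somatic: EnergyBudget
    budget_dendritic: EnergyBudget
    preferred: str            # "somatic" | "dendritic"
    cost_ratio: float         # somatic total / dendritic total

    @property
    def budget_preferred(self) -> EnergyBudget:
        return (
            self.budget_dendritic if self.preferred == "dendritic"
            else self.budget_somatic
        )


def transcription_cost(profile: SpatialProfile, species: SpeciesParams) -> float:
    """ATP/s to replace decaying transcripts (2.17 ATP per nucleotide)."""
    return C_NT * species.N_nt * species.lambda_m * profile.m_total


def translation_cost(profile: SpatialProfile, species: SpeciesParams) -> float:
    """ATP/s for protein synthesis + degradation (5 ATP per amino acid)."""
    return C_AA * species.N_aa * species.tau * profile.m_total


def transport_cost(profile: SpatialProfile, species: SpeciesParams) -> float:
    """ATP/s for motor transport of the granules currently in transit."""
    if profile.scenario.kind == "somatic":
        return 0.0
    theta = profile.diagnostics.get("theta", species.transport.theta)
    granules = theta * profile.m_dendrite / species.mrnas_per_granule
    return C_CARGO * (species.transport.v / V_REFERENCE) * granules


def budget_for(profile: SpatialProfile, species: SpeciesParams) -> EnergyBudget:
    """Assemble the full ATP/s budget of a solved profile."""
    return EnergyBudget(
        scenario=profile.scenario,
        transcription=transcription_cost(profile, species),
        translation=translation_cost(profile, species),
        transport=transport_cost(profile, species),
    )


def decide(
    species: SpeciesParams,
    geom: DendriteGeometry,
    r_soma_grid: tuple[float, ...] = DEFAULT_R_SOMA_GRID,
    return_profiles: bool = False,
):
    """Energy-optimal localisation strategy for one species.

    The dendritic budget is the minimum total over the candidate somatic
    shares ``r_soma_grid``; ties between somatic and dendritic go to the
    somatic strategy (no transport machinery required).
    """
    if not r_soma_grid:
        raise ConfigurationError("r_soma_grid must not be empty")
    try:
        prof_som = solve_steady(species, geom, Scenario.somatic())
        bud_som = budget_for(prof_som, species)

        best = None
        for r in r_soma_grid:
            prof = solve_steady(species, geom, Scenario.dendritic(r))
            bud = budget_for(prof, species)
            if best is None or bud.total < best[1].total:
                best = (prof, bud)
    except DendrocostError as exc:
        raise type(exc)(f"{species.name}: {exc}") from exc
    prof_den, bud_den = best

    preferred = "dendritic" if bud_den.total < bud_som.total else "somatic"
    decision = LocalisationDecision(
        species=species.name,
        budget_somatic=bud_som,
        budget_dendritic=bud_den,
        preferred=preferred,
        cost_ratio=bud_som.total / bud_den.total,
    )
    if return_profiles:
        return decision, {"somatic": prof_som, "dendritic": prof_den}
    return decision


def cumulative_cost_profile(
    profile: SpatialProfile,
    species: SpeciesParams,
    geom: DendriteGeometry,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised cumulative dendritic cost vs distance from the soma.

    Attributes the spatially resolvable dendritic costs — local translation
    (proportional to ``tau * m(x) * N_aa * C_aa``) and transport
    (proportional to ``theta * m(x) * C_cargo / granule``) — to position x
    and returns ``(x, cumulative share)`` with the tip value normalised
    to 1.
    """
    if profile.scenario.kind != "dendritic":
        raise ConfigurationError("cumulative cost profile needs a dendritic scenario")
    theta = profile.diagnostics.get("theta", species.transport.theta)
    density = (
        C_AA * species.N_aa * species.tau * profile.m
        + C_CARGO * (species.transport.v / V_REFERENCE)
        * theta * profile.m / species.mrnas_per_granule
    )
    cum = np.concatenate([
        [0.0],
        np.cumsum(0.5 * (density[1:] + density[:-1]) * np.diff(profile.x)),
    ])
    if cum[-1] <= 0:
        raise ConfigurationError("no dendritic cost to attribute")
    return profile.x, cum / cum[-1]
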