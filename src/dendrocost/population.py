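"""Population-level analyses over the synthetic species grid.

Drives the per-species energy decision across the full factorial grid and
summarises it: the fraction of species for which dendritic mRNA is the
energy-optimal strategy, per-dimension preference-ratio panels, predicted
rank-abundance curves of total copy numbers, the abundance split between
the two strategy groups, and the population-wide energy demand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .energy import DEFAULT_R_SOMA_GRID, decide
from .errors import ConfigurationError
from .params import DendriteGeometry, SpeciesParams
from .screens import ranksum_test
from .steady_state import total_counts

LEVEL_ORDER = ("low", "medium", "high")


def run_grid(
    species: list[SpeciesParams],
    geom: DendriteGeometry,
    r_soma_grid=DEFAULT_R_SOMA_GRID,
    progress: bool = False,
) -> pd.DataFrame:
    """Solve both scenarios for every species; one tidy row per species.

    Columns: the per-dimension group labels, the somatic and (best)
    dendritic budget components, the preferred strategy, the somatic/
    dendritic cost ratio, the transcription+translation saving of the
    dendritic scenario, and total mRNA/protein counts under the preferred
    strategy.
    """
    if not species:
        raise ConfigurationError("empty species population")
    rows = []
    for k, sp in enumerate(species):
        decision, profiles = decide(
            sp, geom, r_soma_grid=r_soma_grid, return_profiles=True
        )
        bs, bd = decision.budget_somatic, decision.budget_dendritic
        counts = total_counts(profiles[decision.preferred], geom)
        tc_tl_som = bs.transcription + bs.translation
        tc_tl_den = bd.transcription + bd.translation
        row = {
            "species": sp.name,
            **{f"label_{dim}": lab for dim, lab in sp.labels.items()},
            "somatic_transcription": bs.transcription,
            "somatic_translation": bs.translation,
            "somatic_total": bs.total,
            "dendritic_transcription": bd.transcription,
            "dendritic_translation": bd.translation,
            "dendritic_transport": bd.transport,
            "dendritic_total": bd.total,
            "dendritic_r_soma": bd.scenario.r_soma,
            "preferred": decision.preferred,
            "cost_ratio": decision.cost_ratio,
            "tc_tl_reduction": 1.0 - tc_tl_den / tc_tl_som,
            "M_total": counts["M_total"],
            "P_total": counts["P_total"],
        }
        rows.append(row)
        if progress and (k + 1) % 200 == 0:
            print(f"  solved {k + 1}/{len(species)} species", flush=True)
    frame = pd.DataFrame(rows)
    frame.attrs["L"] = geom.L
    return frame


def preference_fraction(decisions: pd.DataFrame) -> float:
    """Fraction of the population preferring dendritic mRNA localisation."""
    if len(decisions) == 0:
        raise ConfigurationError("empty decision table")
    return float((decisions["preferred"] == "dendritic").mean())


@dataclass(frozen=True)
class PreferencePanel:
    """Per-dimension somatic/dendritic cost-ratio medians, medium == 1."""

    dimension: str
    values: dict  # level -> normalised median ratio

    def __post_init__(self):
        for level, val in self.values.items():
            if not val > 0:
                raise ConfigurationError(
                    f"panel {self.dimension}: non-positive value at {level}"
                )


def preference_panel(decisions: pd.DataFrame, dimension: str) -> PreferencePanel:
    """Group medians of somatic/dendritic total-cost ratios, normalised.

    Species are grouped by their low/medium/high label along ``dimension``;
    the group median of per-species ``somatic_total / dendritic_total`` is
    divided by the medium group's median, so the medium bar is exactly 1.
    """
    col = f"label_{dimension}"
    if col not in decisions.columns:
        raise ConfigurationError(f"decision table lacks labels for {dimension!r}")
    medians = {}
    for level in LEVEL_ORDER:
        sub = decisions.loc[decisions[col] == level, "cost_ratio"]
        if len(sub) == 0:
            raise ConfigurationError(f"dimension {dimension}: no species at {level}")
        medians[level] = float(sub.median())
    norm = medians["medium"]
    return PreferencePanel(
        dimension=dimension,
        values={lvl: medians[lvl] / norm for lvl in LEVEL_ORDER},
    )


def rank_abundance(counts) -> dict:
    """Rank-sorted abundance curve with summary statistics.

    Returns the monotone non-increasing curve, median and quartiles, and
    the goodness (R^2) of a log-linear (exponential rank law) fit of
    log10(count) against rank.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ConfigurationError("empty abundance vector")
    curve = np.sort(counts)[::-1]
    ranks = np.arange(1, len(curve) + 1)
    pos = curve > 0
    if pos.sum() >= 3:
        y = np.log10(curve[pos])
        r = ranks[pos]
        slope, intercept = np.polyfit(r, y, 1)
        fitted = slope * r + intercept
        ss_res = float(np.sum((y - fitted) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        slope = intercept = np.nan
        r_squared = np.nan
    return {
        "curve": curve,
        "ranks": ranks,
        "median": float(np.median(curve)),
        "q25": float(np.percentile(curve, 25)),
        "q75": float(np.percentile(curve, 75)),
        "log_slope": float(slope),
        "log_intercept": float(intercept),
        "r_squared_log_linear": float(r_squared),
    }


def strategy_split_abundance(decisions: pd.DataFrame, count_col: str = "P_total") -> dict:
    """Compare copy numbers between somatic- and dendritic-preferring species.

    Returns group sizes, medians and a two-sided rank-sum p-value; if one
    strategy group is empty the comparison is reported as skipped.
    """
    if count_col not in decisions.columns:
        raise ConfigurationError(f"decision table lacks column {count_col!r}")
    som = decisions.loc[decisions["preferred"] == "somatic", count_col].to_numpy()
    den = decisions.loc[decisions["preferred"] == "dendritic", count_col].to_numpy()
    out = {
        "count_col": count_col,
        "n_somatic": int(len(som)),
        "n_dendritic": int(len(den)),
    }
    if len(som) == 0 or len(den) == 0:
        out["skipped"] = "one strategy group is empty"
        return out
    out.update({
        "median_somatic": float(np.median(som)),
        "median_dendritic": float(np.median(den)),
        "p_value": ranksum_test(som, den),
    })
    return out


def population_energy_demand(
    decisions: pd.DataFrame,
    n_species: int = 10_000,
    exclude_top_quantile: float = 0.05,
) -> dict:
    """Projected population energy demand from per-species optimal budgets.

    The most cost-intense ``exclude_top_quantile`` share of species (by
    total cost under the preferred strategy) is removed via the empirical
    quantile; the demand is the mean cost of the remaining group scaled to
    ``n_species`` species.
    """
    totals = np.where(
        decisions["preferred"] == "dendritic",
        decisions["dendritic_total"],
        decisions["somatic_total"],
    ).astype(float)
    cutoff = float(np.quantile(totals, 1.0 - exclude_top_quantile))
    kept = totals[totals <= cutoff]
    return {
        "mean_cost_kept": float(kept.mean()),
        "cutoff": cutoff,
        "n_kept": int(len(kept)),
        "demand_atp_per_s": float(kept.mean() * n_species),
        "n_species_assumed": int(n_species),
    }
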