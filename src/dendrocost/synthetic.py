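"""Synthetic species grid and synthetic enrichment screens.

Two generators live here. ``grid_sample`` builds the full factorial grid of
synthetic molecular species (three levels per parameter dimension) used by
the population analyses. ``synthetic_screen`` emulates a compartment-resolved
enrichment screen: a table of genes with soma/neurite enrichment scores and
matched molecular properties, with two latent groups whose property
distributions differ by configurable multiplicative effects under lognormal
noise. It stands in for the published screen tables so that every downstream
statistic runs without downloads.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import GRID_DIMENSIONS, load_defaults, species_from_dimensions
from .errors import ConfigurationError
from .params import SpeciesParams

LEVEL_NAMES = ("low", "medium", "high")

SCREEN_COLUMNS = (
    "gene", "enrichment", "mrna_halflife_h", "transcript_nt",
    "protein_halflife_d", "protein_aa", "spine_copies",
    "mrna_abundance", "protein_abundance",
)


def grid_sample(
    levels: dict | None = None,
    baseline: dict | None = None,
) -> list[SpeciesParams]:
    """Full factorial sample of synthetic species, three levels per dimension.

    Parameters
    ----------
    levels : mapping dimension -> sequence of exactly three values
        Defaults to the bundled level configuration (7 dimensions,
        3^7 = 2187 species).
    baseline : mapping
        Non-sampled baseline parameters; defaults to the bundled baseline.

    Returns
    -------
    list of SpeciesParams in deterministic (row-major) order; each species
    carries its low/medium/high group label per dimension in ``labels``.
    """
    cfg = load_defaults()
    if levels is None:
        levels = cfg["grid_levels"]
    if baseline is None:
        baseline = cfg["baseline"]

    dims = [d for d in GRID_DIMENSIONS if d in levels]
    extra = set(levels) - set(GRID_DIMENSIONS)
    if extra:
        raise ConfigurationError(f"unknown grid dimensions: {sorted(extra)}")
    for dim in dims:
        if len(levels[dim]) != 3:
            raise ConfigurationError(
                f"dimension {dim!r} needs exactly 3 levels, got {len(levels[dim])}"
            )

    # Non-sampled dimensions fall back to their medium bundled level.
    fixed = {
        d: cfg["grid_levels"][d][1] for d in GRID_DIMENSIONS if d not in dims
    }

    species = []
    n_total = 3 ** len(dims)
    width = len(str(n_total - 1))
    for idx, combo in enumerate(itertools.product(range(3), repeat=len(dims))):
        values = dict(fixed)
        labels = {}
        for dim, lvl in zip(dims, combo):
            values[dim] = levels[dim][lvl]
            labels[dim] = LEVEL_NAMES[lvl]
        species.append(
            species_from_dimensions(f"S{idx:0{width}d}", values, baseline, labels)
        )
    return species


@dataclass(frozen=True)
class ScreenConfig:
    """Study conditions of a synthetic enrichment screen.

    ``effects`` are multiplicative medians of the neurite-destined group
    relative to the soma-destined group; the default directions follow the
    model's predictions (longer mRNA half-life, longer transcripts, shorter
    protein half-life, longer proteins, equal spine copy numbers, higher
    abundances in the neurite group). ``sigma_log`` is the lognormal noise
    scale (natural-log standard deviation) of every property.
    """

    n_soma: int = 400
    n_neurite: int = 200
    effects: dict = field(default_factory=lambda: {
        "mrna_halflife_h": 1.5,
        "transcript_nt": 1.3,
        "protein_halflife_d": 1.0 / 1.4,
        "protein_aa": 1.3,
        "spine_copies": 1.0,
        "mrna_abundance": 2.0,
        "protein_abundance": 2.0,
    })
    medians: dict = field(default_factory=lambda: {
        "mrna_halflife_h": 8.0,
        "transcript_nt": 2500.0,
        "protein_halflife_d": 8.0,
        "protein_aa": 450.0,
        "spine_copies": 1000.0,
        "mrna_abundance": 50.0,
        "protein_abundance": 1.0e4,
    })
    sigma_log: float = 0.6
    enrichment_median_neurite: float = 4.0
    enrichment_median_soma: float = 0.25
    enrichment_sigma_log: float = 0.7

    def __post_init__(self):
        if self.n_soma < 1 or self.n_neurite < 1:
            raise ConfigurationError("group sizes must be >= 1")
        if self.sigma_log < 0 or self.enrichment_sigma_log < 0:
            raise ConfigurationError("noise scales must be >= 0")

    def with_null_effects(self) -> "ScreenConfig":
        """Copy with all between-group effects removed (calibration runs)."""
        return ScreenConfig(
            n_soma=self.n_soma, n_neurite=self.n_neurite,
            effects={k: 1.0 for k in self.effects},
            medians=dict(self.medians),
            sigma_log=self.sigma_log,
            enrichment_median_neurite=self.enrichment_median_neurite,
            enrichment_median_soma=self.enrichment_median_soma,
            enrichment_sigma_log=self.enrichment_sigma_log,
        )


def synthetic_screen(config: ScreenConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Generate one synthetic enrichment-screen table.

    Returns a DataFrame with columns ``gene, enrichment, mrna_halflife_h,
    transcript_nt, protein_halflife_d, protein_aa, spine_copies,
    mrna_abundance, protein_abundance`` plus the latent ``group_true`` label.
    Deterministic for a fixed (config, seed).
    """
    cfg = config or ScreenConfig()
    rng = np.random.default_rng(seed)
    n = cfg.n_soma + cfg.n_neurite
    group = np.array(["soma"] * cfg.n_soma + ["neurite"] * cfg.n_neurite)
    is_neurite = group == "neurite"

    data = {"gene": [f"G{i:05d}" for i in range(n)]}
    enr_median = np.where(
        is_neurite, cfg.enrichment_median_neurite, cfg.enrichment_median_soma
    )
    data["enrichment"] = enr_median * rng.lognormal(
        0.0, cfg.enrichment_sigma_log, size=n
    )
    for prop, median in cfg.medians.items():
        effect = cfg.effects.get(prop, 1.0)
        centre = np.where(is_neurite, median * effect, median)
        data[prop] = centre * rng.lognormal(0.0, cfg.sigma_log, size=n)
    frame = pd.DataFrame(data)
    frame["group_true"] = group
    return frame
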