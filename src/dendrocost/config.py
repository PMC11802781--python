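"""Configuration loading: bundled defaults, user overrides, named presets."""

from __future__ import annotations

import copy
from importlib import resources

import yaml

from .errors import ConfigurationError
from .params import DAY, HOUR, DendriteGeometry, SpeciesParams, TransportParams

GRID_DIMENSIONS = (
    "mrna_halflife_h",
    "noncoding_ratio",
    "protein_halflife_d",
    "protein_aa",
    "eta_p",
    "D_p",
    "alpha",
)


def load_defaults() -> dict:
    """Read the bundled defaults file (baseline rates, grid levels, presets)."""
    ref = resources.files("dendrocost").joinpath("data/defaults.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def _deep_update(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_update(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | None = None) -> dict:
    """Bundled defaults, deep-updated with an optional user YAML file."""
    cfg = load_defaults()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigurationError(f"config file {path!r} must hold a mapping")
        cfg = _deep_update(cfg, user)
        # the level block defines *which* dimensions are sampled, so a user
        # block replaces the bundled one instead of merging into it
        if "grid_levels" in user:
            cfg["grid_levels"] = copy.deepcopy(user["grid_levels"])
    return cfg


def species_from_dimensions(
    name: str,
    values: dict,
    baseline: dict,
    labels: dict | None = None,
) -> SpeciesParams:
    """Build a SpeciesParams from the seven sampled dimension values.

    ``values`` holds the grid dimensions (half-lives in hours/days, the
    non-coding ratio, protein length, spine capacity, protein diffusion
    constant and motor re-entry rate alpha); everything else comes from the
    baseline block.
    """
    n_aa = int(values["protein_aa"])
    n_nt = int(round(3 * n_aa * (1.0 + float(values["noncoding_ratio"]))))
    transport = TransportParams(
        v=float(baseline["v"]),
        beta=float(baseline["beta"]),
        alpha=float(values["alpha"]),
    )
    return SpeciesParams(
        name=name,
        D_m0=float(baseline["D_m0"]),
        D_p=float(values["D_p"]),
        halflife_m=float(values["mrna_halflife_h"]) * HOUR,
        halflife_p=float(values["protein_halflife_d"]) * DAY,
        tau=float(baseline["tau"]),
        eta_p=float(values["eta_p"]),
        u_p=float(baseline["u_p"]),
        nu_p=float(baseline["nu_p"]),
        N_aa=n_aa,
        N_nt=n_nt,
        transport=transport,
        mrnas_per_granule=float(baseline.get("mrnas_per_granule", 1)),
        labels=dict(labels or {}),
    )


def _preset(name: str, config: dict | None = None) -> SpeciesParams:
    cfg = config or load_defaults()
    try:
        block = cfg["presets"][name]
    except KeyError as exc:
        raise ConfigurationError(f"no preset named {name!r}") from exc
    baseline = cfg["baseline"]
    transport = TransportParams(
        v=float(baseline["v"]),
        beta=float(baseline["beta"]),
        alpha=float(block.get("alpha", baseline.get("alpha", 0.05))),
    )
    return SpeciesParams(
        name=name,
        D_m0=float(baseline["D_m0"]),
        D_p=float(block["D_p"]),
        halflife_m=float(block["halflife_m_h"]) * HOUR,
        halflife_p=float(block["halflife_p_d"]) * DAY,
        tau=float(block.get("tau", baseline["tau"])),
        eta_p=float(block["eta_p"]),
        u_p=float(block.get("u_p", baseline["u_p"])),
        nu_p=float(block.get("nu_p", baseline["nu_p"])),
        N_aa=int(block["N_aa"]),
        N_nt=int(block["N_nt"]),
        transport=transport,
        mrnas_per_granule=float(baseline.get("mrnas_per_granule", 1)),
    )


def camkii_preset(config: dict | None = None) -> SpeciesParams:
    """CaMKIIalpha: 478 aa, ~4900 nt, 32336 copies/spine, 8 d / 20 h half-lives."""
    return _preset("camkii", config)


def shank3_preset(config: dict | None = None) -> SpeciesParams:
    """Shank3 scaffold protein (photoactivation paradigm); values provisional."""
    return _preset("shank3", config)


def default_geometry(L: float, config: dict | None = None) -> DendriteGeometry:
    cfg = config or load_defaults()
    g = cfg["geometry"]
    return DendriteGeometry(
        L=float(L), rho=float(g["rho"]), phi=float(g["phi"]),
        grid_dx=float(g["grid_dx"]),
    )
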