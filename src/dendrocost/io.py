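"""Delimited-text interchange: species tables, profiles, provenance headers.

Species tables are CSV with one row per species and the documented header
below; all values are in project units (seconds, micrometres, counts).
Output files written by the pipeline carry a provenance comment header
(package version, seed, config hash) so a run can be reproduced from its
artefacts.
"""

from __future__ import annotations

import hashlib
import json

import pandas as pd

from . import __version__
from .errors import DataError
from .params import SpeciesParams, TransportParams
from .steady_state import SpatialProfile

#: canonical species-table columns (label_* columns are optional extras)
SPECIES_COLUMNS = (
    "name", "D_m0", "D_p", "halflife_m", "halflife_p", "tau", "eta_p",
    "u_p", "nu_p", "N_aa", "N_nt", "v", "beta", "alpha", "v_bias",
    "mrnas_per_granule",
)


def species_to_frame(species: list[SpeciesParams]) -> pd.DataFrame:
    rows = []
    for sp in species:
        row = {
            "name": sp.name, "D_m0": sp.D_m0, "D_p": sp.D_p,
            "halflife_m": sp.halflife_m, "halflife_p": sp.halflife_p,
            "tau": sp.tau, "eta_p": sp.eta_p, "u_p": sp.u_p, "nu_p": sp.nu_p,
            "N_aa": sp.N_aa, "N_nt": sp.N_nt,
            "v": sp.transport.v, "beta": sp.transport.beta,
            "alpha": sp.transport.alpha, "v_bias": sp.transport.v_bias,
            "mrnas_per_granule": sp.mrnas_per_granule,
        }
        for dim, lab in sp.labels.items():
            row[f"label_{dim}"] = lab
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_species(frame: pd.DataFrame) -> list[SpeciesParams]:
    missing = [c for c in SPECIES_COLUMNS if c not in frame.columns]
    if missing:
        raise DataError(f"species table missing columns {missing}")
    label_cols = [c for c in frame.columns if c.startswith("label_")]
    species = []
    for _, row in frame.iterrows():
        labels = {
            c.removeprefix("label_"): row[c]
            for c in label_cols if pd.notna(row[c])
        }
        species.append(SpeciesParams(
            name=str(row["name"]),
            D_m0=float(row["D_m0"]), D_p=float(row["D_p"]),
            halflife_m=float(row["halflife_m"]),
            halflife_p=float(row["halflife_p"]),
            tau=float(row["tau"]), eta_p=float(row["eta_p"]),
            u_p=float(row["u_p"]), nu_p=float(row["nu_p"]),
            N_aa=int(row["N_aa"]), N_nt=int(row["N_nt"]),
            transport=TransportParams(
                v=float(row["v"]), beta=float(row["beta"]),
                alpha=float(row["alpha"]), v_bias=float(row["v_bias"]),
            ),
            mrnas_per_granule=float(row["mrnas_per_granule"]),
            labels=labels,
        ))
    return species


def write_species_table(species: list[SpeciesParams], path: str,
                        header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        species_to_frame(species).to_csv(fh, index=False)


def read_species_table(path: str) -> list[SpeciesParams]:
    return frame_to_species(pd.read_csv(path, comment="#"))


def profile_to_frame(profile: SpatialProfile) -> pd.DataFrame:
    return pd.DataFrame({
        "x": profile.x, "m": profile.m, "p": profile.p,
        "p_spine": profile.p_spine,
    })


def write_profile_csv(profile: SpatialProfile, path: str,
                      header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write(f"# scenario={profile.scenario.label()} "
                 f"m_soma={profile.m_soma:.8g} p_soma={profile.p_soma:.8g}\n")
        profile_to_frame(profile).to_csv(fh, index=False)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(config: dict, seed: int | None = None) -> str:
    parts = [f"# dendrocost v{__version__}", f"config_hash={config_hash(config)}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    return " ".join(parts) + "\n"
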