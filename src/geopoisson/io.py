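"""File schemas and serialisation.

Every table is header-first UTF-8 CSV; each written artefact gets a JSON
sidecar (``<name>.meta.json``) recording the master seed, the config hash
and the package version, so two runs with identical configs produce
identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    CovariateTable,
    GeoHierarchy,
    IncidencePanel,
    PatientTable,
    SchemaError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_panel", "write_panel",
    "read_geography", "write_geography",
    "read_covariates", "write_covariates",
    "read_patients", "write_patients",
    "write_sidecar", "config_hash", "file_checksum",
]

PANEL_COLUMNS = ["county_id", "disease", "gender", "y", "N"]
STATE_COLUMNS = ["state_id", "CFR", "DSM", "ASDcrit", "Eval"]
COUNTY_COLUMNS = ["county_id", "state_id", "pop_male", "pop_female"]
PATIENT_COLUMNS = ["patient_id", "county_id", "gender",
                   "flag_ASD", "flag_ID", "flag_ConGen"]


def _check_schema(df: pd.DataFrame, expected: list[str], what: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing or extra:
        raise SchemaError(f"{what}: missing columns {missing}, extra columns {extra}")


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_sidecar(path, seed: int | None, config: dict | None) -> None:
    meta = {
        "seed": seed,
        "config": config,
        "config_hash": config_hash(config or {}),
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2, default=str))


# -- panel ------------------------------------------------------------------

def read_panel(path) -> IncidencePanel:
    df = pd.read_csv(path, dtype={"county_id": str, "disease": str, "gender": str})
    _check_schema(df, PANEL_COLUMNS, "panel")
    for col in ("y", "N"):
        if not np.issubdtype(df[col].dtype, np.integer):
            try:
                df[col] = df[col].astype(np.int64)
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"panel column {col} is not integer: {exc}") from exc
    return IncidencePanel(data=df)


def write_panel(panel: IncidencePanel, path, seed=None, config=None) -> None:
    panel.data[PANEL_COLUMNS].to_csv(path, index=False)
    write_sidecar(path, seed, config)


# -- geography --------------------------------------------------------------

def read_geography(states_path, counties_path) -> GeoHierarchy:
    states = pd.read_csv(states_path, dtype={"state_id": str})
    counties = pd.read_csv(counties_path, dtype={"county_id": str, "state_id": str})
    _check_schema(states, STATE_COLUMNS, "states")
    _check_schema(counties, COUNTY_COLUMNS, "counties")
    return GeoHierarchy(states=states, counties=counties)


def write_geography(geo: GeoHierarchy, states_path, counties_path,
                    seed=None, config=None) -> None:
    geo.states[STATE_COLUMNS].to_csv(states_path, index=False)
    geo.counties[COUNTY_COLUMNS].to_csv(counties_path, index=False)
    write_sidecar(counties_path, seed, config)


# -- covariates -------------------------------------------------------------

def read_covariates(path) -> CovariateTable:
    df = pd.read_csv(path, dtype={"county_id": str})
    return CovariateTable(data=df)


def write_covariates(covars: CovariateTable, path, seed=None, config=None) -> None:
    covars.data.to_csv(path, index=False)
    write_sidecar(path, seed, config)


# -- patients ---------------------------------------------------------------

def read_patients(path) -> PatientTable:
    df = pd.read_csv(path, dtype={"patient_id": str, "county_id": str, "gender": str})
    _check_schema(df, PATIENT_COLUMNS, "patients")
    for col in ("flag_ASD", "flag_ID", "flag_ConGen"):
        df[col] = df[col].astype(bool)
    return PatientTable(data=df)


def write_patients(patients: PatientTable, path, seed=None, config=None) -> None:
    patients.data[PATIENT_COLUMNS].to_csv(path, index=False)
    write_sidecar(path, seed, config)
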