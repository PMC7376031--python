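"""CSV/YAML readers and writers plus run manifests.

Interchange formats: wide CSV for abundance (``site_id`` column plus one
column per species) and covariates, YAML for configuration sidecars and
run manifests. UTF-8, comma-separated, header row, ``.`` decimal.
"""
from __future__ import annotations

import hashlib
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import (ANCILLARY, TARGET, CommunityDataset, SimulationConfig,
                      assign_roles_by_prevalence)

ABUNDANCE_FILE = "abundance.csv"
COVARIATES_FILE = "covariates.csv"
SIDECAR_FILE = "community.yaml"


def write_community(dataset: CommunityDataset, directory,
                    config: SimulationConfig | None = None) -> Path:
    """Write abundance + covariate CSVs and a YAML sidecar with roles/config."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ab = pd.DataFrame(dataset.abundance, columns=dataset.species_names)
    ab.insert(0, "site_id", dataset.site_ids)
    # %.17g keeps every float64 exactly recoverable from text
    ab.to_csv(directory / ABUNDANCE_FILE, index=False, float_format="%.17g")
    cov_names = [f"env{i + 1}" for i in range(dataset.covariates.shape[1])]
    cov = pd.DataFrame(dataset.covariates, columns=cov_names)
    cov.insert(0, "site_id", dataset.site_ids)
    cov.to_csv(directory / COVARIATES_FILE, index=False, float_format="%.17g")
    sidecar = {
        "roles": dict(zip(dataset.species_names, dataset.roles)),
        "config": asdict(config) if config is not None else None,
    }
    with open(directory / SIDECAR_FILE, "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)
    return directory


def read_community(abundance_csv, covariates_csv,
                   roles_spec: dict | None = None) -> CommunityDataset:
    """Read and validate a community dataset from its two CSV tables.

    Roles come from ``roles_spec`` (species name -> role) when given;
    otherwise species occurring in under 15% of sites become targets.
    """
    ab = pd.read_csv(abundance_csv, float_precision="round_trip")
    cov = pd.read_csv(covariates_csv, float_precision="round_trip")
    for frame, path in ((ab, abundance_csv), (cov, covariates_csv)):
        if "site_id" not in frame.columns:
            raise ValueError(f"{path}: missing site_id column")
        if frame.isna().any().any():
            col = frame.columns[frame.isna().any()][0]
            raise ValueError(f"{path}: missing values in column {col!r}")
    if list(ab["site_id"]) != list(cov["site_id"]):
        raise ValueError("site_id columns of abundance and covariates disagree")
    species = [c for c in ab.columns if c != "site_id"]
    A = ab[species].to_numpy(float)
    if np.any(A < 0):
        i, j = np.argwhere(A < 0)[0]
        raise ValueError(
            f"negative abundance at site {ab['site_id'].iloc[i]!r}, "
            f"species {species[j]!r}")
    if roles_spec is not None:
        missing = [s for s in species if s not in roles_spec]
        if missing:
            raise ValueError(f"roles_spec lacks species: {missing}")
        roles = [roles_spec[s] for s in species]
    else:
        roles = assign_roles_by_prevalence(A)
    X = cov[[c for c in cov.columns if c != "site_id"]].to_numpy(float)
    return CommunityDataset(abundance=A, covariates=X, species_names=species,
                            roles=roles, site_ids=list(ab["site_id"]))


def read_community_dir(directory) -> CommunityDataset:
    """Read a dataset written by :func:`write_community` (roles from sidecar)."""
    directory = Path(directory)
    roles = None
    sidecar = directory / SIDECAR_FILE
    if sidecar.exists():
        with open(sidecar) as fh:
            roles = yaml.safe_load(fh).get("roles")
    return read_community(directory / ABUNDANCE_FILE,
                          directory / COVARIATES_FILE, roles_spec=roles)


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, config: dict, seeds: dict,
                   inputs: dict | None = None) -> Path:
    """Record everything needed to reproduce a run bit-for-bit."""
    from . import __version__

    manifest = {
        "raresdm_version": __version__,
        "config": config,
        "seeds": seeds,
        "input_digests": {k: file_digest(v) for k, v in (inputs or {}).items()},
    }
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path
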