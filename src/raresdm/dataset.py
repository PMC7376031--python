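"""Community dataset containers.

A :class:`CommunityDataset` is the single object every stage of the
pipeline consumes: a site-by-species abundance matrix (effort-standardized
catch), a site-by-covariate matrix (standardized environmental gradients),
and a role flag per species marking it as a rare prediction *target* or a
common *ancillary* species.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

TARGET = "target"
ANCILLARY = "ancillary"

#: Occurrence frequency below which a species counts as a rare target.
RARE_PREVALENCE_CUTOFF = 0.15

# Occurrence frequencies of the six rare target species (fraction of
# stations occupied) and the range spanned by the 31 common ancillaries.
DEFAULT_RARE_PREVALENCES = (0.035, 0.043, 0.061, 0.088, 0.096, 0.123)
DEFAULT_COMMON_PREVALENCE_RANGE = (0.23, 0.87)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design constants for the synthetic community generator.

    Defaults emulate the survey structure the analysis assumes: 118
    sampling stations, three environmental covariates (bottom temperature,
    salinity and depth analogues), six rare target species with occurrence
    3.5-12.3% and 31 common ancillary species spanning 23-87%.
    """

    n_sites: int = 118
    n_covariates: int = 3
    n_common: int = 31
    n_rare: int = 6
    rare_prevalence_targets: tuple = DEFAULT_RARE_PREVALENCES
    common_prevalence_range: tuple = DEFAULT_COMMON_PREVALENCE_RANGE
    n_factors: int = 2
    loading_scale: float = 1.0
    residual_sd: float = 1.0
    response_shape: str = "quadratic"  # {"linear", "quadratic"}
    mechanism: str = "tobit"  # {"tobit", "hurdle_lognormal"}
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        if min(self.n_covariates, self.n_common, self.n_rare) < 1:
            raise ValueError("n_covariates, n_common, n_rare must be positive")
        if self.n_factors < 0:
            raise ValueError("n_factors must be non-negative")
        if len(self.rare_prevalence_targets) != self.n_rare:
            raise ValueError(
                "rare_prevalence_targets must have length n_rare "
                f"({len(self.rare_prevalence_targets)} != {self.n_rare})"
            )
        for p in tuple(self.rare_prevalence_targets) + tuple(self.common_prevalence_range):
            if not (0.0 < p < 1.0):
                raise ValueError(f"prevalence {p} not strictly inside (0, 1)")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        if self.response_shape not in ("linear", "quadratic"):
            raise ValueError(f"unknown response_shape {self.response_shape!r}")
        if self.mechanism not in ("tobit", "hurdle_lognormal"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")

    @property
    def n_species(self) -> int:
        return self.n_rare + self.n_common


@dataclass
class CommunityDataset:
    """Site-by-species abundance plus site-by-covariate data.

    ``truth`` optionally retains the generating parameters (intercepts,
    coefficient matrix, loadings, factor scores) so recovery tests can
    compare estimates against them; it is absent for data read from files.
    """

    abundance: np.ndarray  # (n_sites, n_species), non-negative
    covariates: np.ndarray  # (n_sites, n_covariates)
    species_names: list
    roles: list  # per species: "target" | "ancillary"
    site_ids: list
    truth: Optional[dict] = field(default=None, repr=False)

    def __post_init__(self):
        self.abundance = np.asarray(self.abundance, dtype=float)
        self.covariates = np.asarray(self.covariates, dtype=float)
        self.validate()

    # -- basic views -----------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_species(self) -> int:
        return self.abundance.shape[1]

    @property
    def target_indices(self) -> np.ndarray:
        return np.flatnonzero([r == TARGET for r in self.roles])

    @property
    def ancillary_indices(self) -> np.ndarray:
        return np.flatnonzero([r == ANCILLARY for r in self.roles])

    @property
    def target_names(self) -> list:
        return [self.species_names[i] for i in self.target_indices]

    def species_index(self, name: str) -> int:
        return self.species_names.index(name)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.abundance.ndim != 2 or self.covariates.ndim != 2:
            raise ValueError("abundance and covariates must be 2-D")
        if self.abundance.shape[0] != self.covariates.shape[0]:
            raise ValueError(
                "abundance and covariates disagree on the number of sites: "
                f"{self.abundance.shape[0]} vs {self.covariates.shape[0]}"
            )
        if not np.all(np.isfinite(self.abundance)):
            raise ValueError("abundance contains missing or non-finite values")
        if not np.all(np.isfinite(self.covariates)):
            raise ValueError("covariates contain missing or non-finite values")
        if np.any(self.abundance < 0):
            i, j = np.argwhere(self.abundance < 0)[0]
            raise ValueError(
                f"negative abundance at site {self.site_ids[i]!r}, "
                f"species {self.species_names[j]!r}"
            )
        if len(self.species_names) != self.abundance.shape[1]:
            raise ValueError("species_names length mismatch")
        if len(self.roles) != self.abundance.shape[1]:
            raise ValueError("roles length mismatch")
        if len(self.site_ids) != self.abundance.shape[0]:
            raise ValueError("site_ids length mismatch")
        bad = set(self.roles) - {TARGET, ANCILLARY}
        if bad:
            raise ValueError(f"unknown species roles: {sorted(bad)}")


def assign_roles_by_prevalence(abundance: np.ndarray,
                               cutoff: float = RARE_PREVALENCE_CUTOFF) -> list:
    """Role per species: target below the occurrence cutoff, else ancillary."""
    prevalence = np.mean(np.asarray(abundance) > 0, axis=0)
    return [TARGET if p < cutoff else ANCILLARY for p in prevalence]
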