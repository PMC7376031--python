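"""Prediction-improvement procedures.

Two ways community data are funnelled into a rare-species model:

* **Species filtering** for joint models — ancillary species are ranked by
  their (Spearman, by default) correlation with the target and trimmed to
  three nested levels: LV1 keeps all of them, LV2 the top two-thirds, LV3
  the top third.
* **Conditional prediction** for single-species models — ancillary
  abundances are compressed by a correlation-matrix PCA (components kept
  by the Kaiser eigenvalue-above-one rule) and appended to the
  environmental covariates, either as observed values or as joint-model
  predictions at the prediction sites.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from . import models
from .dataset import CommunityDataset

LEVELS = ("LV1", "LV2", "LV3")
#: Fraction of the ancillary pool each filter level retains.
LEVEL_FRACTIONS = {"LV1": 1.0, "LV2": 2.0 / 3.0, "LV3": 1.0 / 3.0}


@dataclass
class FilterLevel:
    level: str
    selected: np.ndarray       # ancillary indices, descending |correlation|
    correlations: np.ndarray   # per-ancillary correlation with the target


@dataclass
class PCAReduction:
    loadings: np.ndarray       # (n_variables, n_retained), orthonormal columns
    center: np.ndarray
    scale: np.ndarray
    eigenvalues: np.ndarray    # all eigenvalues, descending
    kept_variables: np.ndarray  # indices of non-constant training variables

    @property
    def n_retained(self) -> int:
        return self.loadings.shape[1]


def _correlation(x, y, method):
    if np.ptp(y) == 0:
        return 0.0
    if method == "spearman":
        rx, ry = rankdata(x), rankdata(y)  # midranks for ties
        return float(np.corrcoef(rx, ry)[0, 1])
    if method == "pearson":
        return float(np.corrcoef(x, y)[0, 1])
    if method == "phi":  # presence-absence correlation
        bx, by = (x > 0).astype(float), (y > 0).astype(float)
        if np.ptp(bx) == 0 or np.ptp(by) == 0:
            return 0.0
        return float(np.corrcoef(bx, by)[0, 1])
    raise ValueError(f"unknown correlation method {method!r}")


def rank_ancillary(dataset: CommunityDataset, target,
                   method: str = "spearman",
                   sites: np.ndarray | None = None) -> np.ndarray:
    """Correlation of the target species with every ancillary species.

    ``target`` is a species index or name and must carry the target role.
    ``sites`` restricts the computation to a subset of sites (training
    folds); constant ancillary columns get correlation 0 with a warning.
    """
    if isinstance(target, str):
        target = dataset.species_index(target)
    if target not in dataset.target_indices:
        raise ValueError(f"species {dataset.species_names[target]!r} is not a target")
    rows = slice(None) if sites is None else np.asarray(sites)
    y = dataset.abundance[rows, target]
    out = np.empty(len(dataset.ancillary_indices))
    for k, j in enumerate(dataset.ancillary_indices):
        x = dataset.abundance[rows, j]
        if np.ptp(x) == 0:
            warnings.warn(
                f"ancillary species {dataset.species_names[j]!r} is constant; "
                "correlation set to 0", RuntimeWarning)
            out[k] = 0.0
        else:
            out[k] = _correlation(x, y, method)
    return out


def filter_species(correlations: np.ndarray, level: str,
                   signed: bool = False) -> FilterLevel:
    """Select the level's share of most-correlated ancillary species.

    Ranking uses |correlation| by default (``signed=True`` ranks by the
    raw value); ties break toward the lower species index. LV2 keeps
    ceil(2/3 n) species and LV3 ceil(1/3 n), so LV3 ⊆ LV2 ⊆ LV1.
    """
    correlations = np.asarray(correlations, float)
    if correlations.size == 0:
        raise ValueError("empty correlation vector")
    if level not in LEVELS:
        raise ValueError(f"unknown filter level {level!r}")
    key = correlations if signed else np.abs(correlations)
    order = np.lexsort((np.arange(key.size), -key))  # desc key, asc index
    count = math.ceil(LEVEL_FRACTIONS[level] * key.size)
    return FilterLevel(level=level, selected=order[:count],
                       correlations=correlations)


def fit_pca(train_ancillary: np.ndarray) -> PCAReduction:
    """Correlation-matrix PCA of the training ancillary abundances.

    Variables are centered and scaled to unit variance so the Kaiser
    eigenvalue-above-one retention rule is meaningful; constant columns
    are dropped with a warning before the eigendecomposition.
    """
    A = np.asarray(train_ancillary, float)
    if A.ndim != 2 or A.shape[0] < 2 or A.shape[1] < 2:
        raise ValueError("need at least 2 sites and 2 ancillary species")
    if not np.all(np.isfinite(A)):
        raise ValueError("missing values in ancillary matrix")
    sd = A.std(axis=0)
    kept = np.flatnonzero(sd > 0)
    if kept.size < A.shape[1]:
        warnings.warn(f"dropping {A.shape[1] - kept.size} constant ancillary "
                      "column(s) before PCA", RuntimeWarning)
    if kept.size < 1:
        raise ValueError("all ancillary columns are constant")
    A = A[:, kept]
    center, scale = A.mean(axis=0), A.std(axis=0)
    Z = (A - center) / scale
    corr = (Z.T @ Z) / Z.shape[0]
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_keep = int(np.sum(evals > 1.0))
    return PCAReduction(loadings=evecs[:, :n_keep], center=center, scale=scale,
                        eigenvalues=evals, kept_variables=kept)


def project(reduction: PCAReduction, ancillary_new: np.ndarray) -> np.ndarray:
    """Apply training centering/scaling and loadings to new ancillary data."""
    A = np.asarray(ancillary_new, float)
    if A.ndim != 2:
        raise ValueError("ancillary_new must be 2-D")
    expected = int(reduction.kept_variables.max()) + 1
    if A.shape[1] == reduction.center.shape[0]:
        pass  # already restricted to the kept variables
    elif A.shape[1] >= expected:
        A = A[:, reduction.kept_variables]
    else:
        raise ValueError(
            f"ancillary_new has {A.shape[1]} variables; training PCA used "
            f"{reduction.center.shape[0]}")
    return (A - reduction.center) / reduction.scale @ reduction.loadings


def fit_conditional(X: np.ndarray, scores: np.ndarray, y: np.ndarray,
                    spec: models.ModelSpec) -> models.FittedModel:
    """Fit a single-species model on [covariates | ancillary PCA scores].

    With zero retained components this degenerates to the unconditional
    model on the environmental covariates alone.
    """
    if spec.family not in ("rf", "ann"):
        raise ValueError("conditional prediction applies to single-species models")
    X = np.asarray(X, float)
    scores = np.asarray(scores, float)
    if scores.ndim != 2 or scores.shape[0] != X.shape[0]:
        raise ValueError("scores must be 2-D and row-aligned with X")
    design = np.column_stack([X, scores]) if scores.shape[1] else X
    return models.fit(design, np.asarray(y, float), spec)
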