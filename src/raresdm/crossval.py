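"""Presence-stratified k-fold cross-validation over models and treatments.

Rare species have so few presences that an unstratified split can leave a
fold with none; sites with and without the target are therefore permuted
and dealt round-robin to folds separately, so per-fold presence (and
absence) counts differ by at most one. Every data-derived statistic a
model consumes — correlation rankings, PCA constants, JSDM posteriors —
is recomputed on the training folds only. The single deliberate exception
is the occurrence-binarization threshold (the species' mean abundance over
the whole area), which is computed once on the full dataset.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import enhancement, jsdm, metrics, models
from .dataset import CommunityDataset

TREATMENTS = ("baseline", "LV1", "LV2", "LV3", "conditional_obs", "conditional_jsdm")
_MULTI_FAMILIES = ("mrf", "mann", "jsdm")
_SINGLE_FAMILIES = ("rf", "ann")


@dataclass(frozen=True)
class FoldAssignment:
    """Fold label in {1..k} per site, presence-stratified."""

    labels: np.ndarray
    k: int

    def test_sites(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.labels == fold)

    def train_sites(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.labels != fold)


@dataclass
class CVConfig:
    """Settings for one benchmark run.

    ``models`` mixes :class:`raresdm.models.ModelSpec` instances and
    :class:`raresdm.jsdm.JSDMConfig` instances (the latter are labelled
    ``jsdm``). Treatments that do not apply to a family (filter levels for
    single-species models, conditioning for joint models) are skipped.
    """

    k: int = 4
    n_repetitions: int = 500
    seed: int = 0
    models: Sequence = field(default_factory=lambda: [models.ModelSpec("rf")])
    treatments: Sequence[str] = ("baseline",)
    targets: Optional[Sequence[str]] = None  # default: every target species
    correlation_method: str = "spearman"
    jsdm_predict_draws: int = 100

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        for t in self.treatments:
            if t not in TREATMENTS:
                raise ValueError(f"unknown treatment {t!r}")


def stratified_folds(occurrence: np.ndarray, k: int, seed: int) -> FoldAssignment:
    """Permute presences and absences separately; deal each round-robin."""
    occurrence = np.asarray(occurrence).astype(bool)
    n = occurrence.size
    if k > n:
        raise ValueError(f"k={k} exceeds the number of sites ({n})")
    if occurrence.sum() < 1:
        raise ValueError("target species is absent everywhere")
    rng = np.random.default_rng(seed)
    labels = np.empty(n, dtype=int)
    for mask in (occurrence, ~occurrence):
        idx = np.flatnonzero(mask)
        perm = rng.permutation(idx)
        labels[perm] = np.arange(perm.size) % k + 1
    return FoldAssignment(labels=labels, k=k)


def _model_label(entry) -> str:
    if isinstance(entry, jsdm.JSDMConfig):
        return "jsdm"
    return entry.family


def _compatible(family: str, treatment: str) -> bool:
    if treatment == "baseline":
        return True
    if treatment in ("LV1", "LV2", "LV3"):
        return family in _MULTI_FAMILIES
    return family in _SINGLE_FAMILIES  # conditional_*


def run_cv(dataset: CommunityDataset, config: CVConfig,
           audit_hook: Optional[Callable[[dict], None]] = None) -> list:
    """Full benchmark: models x targets x treatments x repetitions x folds.

    Returns a flat list of :class:`raresdm.metrics.MetricRecord`. A model
    failure on a fold yields a record flagged ``failed`` (metrics NaN) and
    the pipeline continues.
    """
    target_names = list(config.targets) if config.targets else dataset.target_names
    for name in target_names:
        if name not in dataset.target_names:
            raise ValueError(f"{name!r} is not a target species")
    anc_idx = dataset.ancillary_indices
    X = dataset.covariates
    records: list[metrics.MetricRecord] = []
    root = np.random.SeedSequence(config.seed)

    # Occurrence threshold: mean abundance over the whole study area,
    # computed once per species on the full dataset (see docs/methods.md).
    rules = {name: metrics.OccurrenceRule.from_abundance(
        dataset.abundance[:, dataset.species_index(name)])
        for name in target_names}

    for t_pos, name in enumerate(target_names):
        j = dataset.species_index(name)
        occ = dataset.abundance[:, j] > 0
        for rep in range(config.n_repetitions):
            fold_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
            assignment = stratified_folds(occ, config.k, seed=fold_seed)
            for fold in range(1, config.k + 1):
                train = assignment.train_sites(fold)
                test = assignment.test_sites(fold)
                if audit_hook:
                    audit_hook({"stage": "split", "target": name, "rep": rep,
                                "fold": fold, "train_sites": train.copy(),
                                "test_sites": test.copy()})
                ctx = _FoldContext(dataset, j, anc_idx, X, train, test,
                                   config, rep, fold, audit_hook)
                for entry in config.models:
                    fam = _model_label(entry)
                    for treatment in config.treatments:
                        if not _compatible(fam, treatment):
                            continue
                        records.append(
                            ctx.evaluate(entry, fam, treatment,
                                         rules[name], name))
    return records


class _FoldContext:
    """Fits and scores every model/treatment on one train/test split."""

    def __init__(self, dataset, target_j, anc_idx, X, train, test,
                 config, rep, fold, audit_hook):
        self.d = dataset
        self.j = target_j
        self.anc_idx = anc_idx
        self.Xtr, self.Xte = X[train], X[test]
        self.train, self.test = train, test
        self.cfg = config
        self.rep, self.fold = rep, fold
        self.audit = audit_hook
        self.ytr = dataset.abundance[train, target_j]
        self.yte = dataset.abundance[test, target_j]
        self.Atr = dataset.abundance[np.ix_(train, anc_idx)]
        self.Ate = dataset.abundance[np.ix_(test, anc_idx)]
        self._jsdm_anc_cache = {}

    def _audit_fit(self, what):
        if self.audit:
            self.audit({"stage": "fit", "what": what, "rep": self.rep,
                        "fold": self.fold, "train_sites": self.train.copy()})

    def _seed(self, entry):
        base = entry.seed if hasattr(entry, "seed") else 0
        return int((base + 7919 * self.rep + 104729 * self.fold) % (2 ** 31))

    def _filtered_columns(self, level):
        corrs = enhancement.rank_ancillary(
            self.d, self.j, method=self.cfg.correlation_method, sites=self.train)
        sel = enhancement.filter_species(corrs, level).selected
        return self.anc_idx[sel]

    def _response_matrix(self, columns):
        cols = np.concatenate([[self.j], columns])
        return self.d.abundance[np.ix_(self.train, cols)]

    def evaluate(self, entry, fam, treatment, rule, name):
        try:
            predicted = self._predict(entry, fam, treatment)
            scores = metrics.score_prediction_set(
                metrics.PredictionSet(species=name, predicted=predicted,
                                      observed=self.yte), rule)
            return metrics.MetricRecord(model=fam, species=name,
                                        treatment=treatment, repetition=self.rep,
                                        fold=self.fold, failed=False, **scores)
        except Exception as exc:  # noqa: BLE001 — fold failures are recorded
            warnings.warn(f"{fam}/{treatment} failed on {name} "
                          f"rep {self.rep} fold {self.fold}: {exc}",
                          RuntimeWarning)
            nan = float("nan")
            return metrics.MetricRecord(model=fam, species=name,
                                        treatment=treatment, repetition=self.rep,
                                        fold=self.fold, auc=nan, kappa=nan,
                                        tss=nan, rmse=nan, prb=nan, failed=True)

    # -- prediction paths ------------------------------------------------
    def _predict(self, entry, fam, treatment):
        self._audit_fit(f"{fam}:{treatment}")
        seed = self._seed(entry)
        if fam == "jsdm":
            return self._predict_jsdm(entry, treatment, seed)
        if fam in ("mrf", "mann"):
            columns = (self.anc_idx if treatment in ("baseline", "LV1")
                       else self._filtered_columns(treatment))
            spec = replace(entry, seed=seed)
            fitted = models.fit(self.Xtr, self._response_matrix(columns), spec)
            return models.predict(fitted, self.Xte)[:, 0]
        # single-species families
        spec = replace(entry, seed=seed)
        if treatment == "baseline":
            fitted = models.fit(self.Xtr, self.ytr, spec)
            return models.predict(fitted, self.Xte)
        # conditional prediction
        reduction = enhancement.fit_pca(self.Atr)
        scores_tr = enhancement.project(reduction, self.Atr)
        if treatment == "conditional_obs":
            anc_te = self.Ate
        else:  # conditional_jsdm
            anc_te = self._jsdm_ancillary_predictions(seed)
        scores_te = enhancement.project(reduction, anc_te)
        fitted = enhancement.fit_conditional(self.Xtr, scores_tr, self.ytr, spec)
        return models.predict(fitted, np.column_stack([self.Xte, scores_te])
                              if scores_tr.shape[1] else self.Xte)

    def _predict_jsdm(self, entry, treatment, seed):
        columns = (self.anc_idx if treatment in ("baseline", "LV1")
                   else self._filtered_columns(treatment))
        cfg = replace(entry, seed=seed)
        posterior = jsdm.fit_latent_jsdm(self.Xtr, self._response_matrix(columns), cfg)
        pred = jsdm.predict_marginal(posterior, self.Xte,
                                     n_draws=self.cfg.jsdm_predict_draws,
                                     seed=seed + 1)
        return pred[:, 0]

    def _jsdm_ancillary_predictions(self, seed):
        """Ancillary abundances at test sites predicted by a training-fold JSDM."""
        key = "anc"
        if key not in self._jsdm_anc_cache:
            cfg = _default_conditioning_jsdm(self.cfg, seed)
            posterior = jsdm.fit_latent_jsdm(self.Xtr, self.Atr, cfg)
            self._jsdm_anc_cache[key] = jsdm.predict_marginal(
                posterior, self.Xte, n_draws=self.cfg.jsdm_predict_draws,
                seed=seed + 1)
        return self._jsdm_anc_cache[key]


def _default_conditioning_jsdm(config: CVConfig, seed: int) -> jsdm.JSDMConfig:
    for entry in config.models:
        if isinstance(entry, jsdm.JSDMConfig):
            return replace(entry, seed=seed)
    return jsdm.JSDMConfig(n_iterations=600, burn_in=300, thin=1, seed=seed)


# -- aggregation ---------------------------------------------------------

def records_to_frame(records: Sequence[metrics.MetricRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def aggregate(records: Sequence[metrics.MetricRecord],
              dataset: Optional[CommunityDataset] = None) -> pd.DataFrame:
    """Mean and sd of each metric per model x species x treatment.

    When ``dataset`` is given, an all-zero-prediction RMSE baseline row is
    appended per species (model ``zero``).
    """
    if not records:
        raise ValueError("no records to aggregate")
    frame = records_to_frame(records)
    frame = frame[~frame["failed"]]
    cols = ["auc", "kappa", "tss", "rmse", "prb"]
    grouped = frame.groupby(["model", "species", "treatment"])[cols]
    out = grouped.agg(["mean", "std"])
    out.columns = [f"{m}_{s}" for m, s in out.columns]
    out = out.reset_index()
    if dataset is not None:
        rows = []
        for name in sorted(frame["species"].unique()):
            j = dataset.species_index(name)
            base = metrics.zero_baseline_rmse(dataset.abundance[:, j])
            rows.append({"model": "zero", "species": name,
                         "treatment": "baseline", "rmse_mean": base})
        out = pd.concat([out, pd.DataFrame(rows)], ignore_index=True)
    return out


def delta_rmse(enhanced: Sequence[metrics.MetricRecord],
               baseline: Sequence[metrics.MetricRecord]) -> pd.DataFrame:
    """Per-species ΔRMSE = baseline RMSE - enhanced RMSE (positive = better).

    Records are matched on (species, repetition, fold); a mismatch in the
    key sets raises with the offending keys listed.
    """
    keys = ["species", "repetition", "fold"]
    e = records_to_frame(list(enhanced)).set_index(keys)
    b = records_to_frame(list(baseline)).set_index(keys)
    missing = sorted(set(e.index.unique()) ^ set(b.index.unique()))
    if missing:
        raise ValueError(f"unmatched evaluation keys: {missing[:10]}")
    merged = b[["rmse"]].join(e[["rmse"]], lsuffix="_baseline", rsuffix="_enhanced")
    merged["delta_rmse"] = merged["rmse_baseline"] - merged["rmse_enhanced"]
    per_species = (merged.reset_index().groupby("species")["delta_rmse"]
                   .agg(["mean", "std", "count"]).reset_index())
    return per_species
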