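"""Evaluation metrics for abundance and occurrence predictions.

Abundance accuracy is measured by RMSE and, at presence sites only, by the
partial relative bias PRB = mean((P_p - O_p) / O_p); an all-zero prediction
therefore scores PRB = -1 (complete underestimation). Occurrence skill is
measured threshold-free by AUC (Mann-Whitney formulation, ties count 1/2)
and, after binarizing predictions at the species' mean abundance over the
whole study area, by Cohen's kappa and the True Skill Statistic
(sensitivity + specificity - 1). Observed occurrence is always observed
abundance > 0.

Undefined cases (no presences for PRB, single-class occurrence for
AUC/TSS) return NaN with a warning rather than raising, so a
cross-validation fold with an unlucky split degrades gracefully.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


@dataclass
class PredictionSet:
    """Predictions paired with observations for one species at test sites."""

    species: object
    predicted: np.ndarray
    observed: np.ndarray

    def __post_init__(self):
        self.predicted = np.asarray(self.predicted, float)
        self.observed = np.asarray(self.observed, float)
        if self.predicted.shape != self.observed.shape:
            raise ValueError("predicted and observed lengths differ")
        if np.any(self.observed < 0):
            raise ValueError("observed abundance must be non-negative")

    @property
    def n(self) -> int:
        return self.predicted.size

    @property
    def presence_mask(self) -> np.ndarray:
        return self.observed > 0


@dataclass(frozen=True)
class OccurrenceRule:
    """Binarization threshold: the species' mean abundance over all sites."""

    threshold: float

    def __post_init__(self):
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")

    @classmethod
    def from_abundance(cls, abundance_column: np.ndarray) -> "OccurrenceRule":
        return cls(threshold=float(np.mean(abundance_column)))


@dataclass
class MetricRecord:
    """One evaluation result: model x species x treatment x repetition x fold."""

    model: str
    species: str
    treatment: str
    repetition: int
    fold: int
    auc: float
    kappa: float
    tss: float
    rmse: float
    prb: float
    failed: bool = False


def rmse(pred: PredictionSet) -> float:
    """Root mean square error sqrt(sum((P_i - O_i)^2) / N)."""
    if pred.n == 0:
        raise ValueError("empty prediction set")
    return float(np.sqrt(np.mean((pred.predicted - pred.observed) ** 2)))


def zero_baseline_rmse(observed: np.ndarray) -> float:
    """RMSE of the all-zero prediction: sqrt(mean(O^2))."""
    observed = np.asarray(observed, float)
    if observed.size == 0:
        raise ValueError("empty observation vector")
    return float(np.sqrt(np.mean(observed ** 2)))


def prb(pred: PredictionSet, aggregation: str = "mean_ratio") -> float:
    """Partial relative bias over presence sites.

    Default: mean over presence sites of (P_p - O_p) / O_p. The
    ``ratio_of_sums`` alternative computes (sum P_p - sum O_p) / sum O_p.
    """
    mask = pred.presence_mask
    if not mask.any():
        warnings.warn("no presence sites: PRB undefined", RuntimeWarning)
        return float("nan")
    P, O = pred.predicted[mask], pred.observed[mask]
    if aggregation == "mean_ratio":
        return float(np.mean((P - O) / O))
    if aggregation == "ratio_of_sums":
        return float((P.sum() - O.sum()) / O.sum())
    raise ValueError(f"unknown PRB aggregation {aggregation!r}")


def auc(scores: np.ndarray, occurrence: np.ndarray) -> float:
    """Probability a random presence site outscores a random absence site.

    Mann-Whitney formulation via midranks; tied scores count one half.
    Continuous predicted abundance is used directly as the score.
    """
    scores = np.asarray(scores, float)
    occurrence = np.asarray(occurrence).astype(bool)
    n_pos = int(occurrence.sum())
    n_neg = occurrence.size - n_pos
    if n_pos == 0 or n_neg == 0:
        warnings.warn("single-class occurrence: AUC undefined", RuntimeWarning)
        return float("nan")
    ranks = rankdata(scores)
    u = ranks[occurrence].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def binarize(pred_abundance: np.ndarray, rule: OccurrenceRule) -> np.ndarray:
    """Predicted occurrence: 1 where predicted abundance exceeds the threshold."""
    return (np.asarray(pred_abundance, float) > rule.threshold).astype(int)


def kappa(pred_bin: np.ndarray, obs_bin: np.ndarray) -> float:
    """Cohen's kappa: chance-corrected binary agreement.

    When both marginals are degenerate (chance agreement 1) kappa is
    defined as 1 for identical vectors and 0 otherwise, with a warning.
    """
    p = np.asarray(pred_bin).astype(int)
    o = np.asarray(obs_bin).astype(int)
    if p.shape != o.shape:
        raise ValueError("length mismatch")
    n = p.size
    po = float(np.mean(p == o))
    fp, fo = p.mean(), o.mean()
    pe = fp * fo + (1 - fp) * (1 - fo)
    if pe >= 1.0 - 1e-15:
        warnings.warn("degenerate marginals: chance agreement is 1", RuntimeWarning)
        return 1.0 if po == 1.0 else 0.0
    return float((po - pe) / (1.0 - pe))


def tss(pred_bin: np.ndarray, obs_bin: np.ndarray) -> float:
    """True Skill Statistic: sensitivity + specificity - 1."""
    p = np.asarray(pred_bin).astype(bool)
    o = np.asarray(obs_bin).astype(bool)
    if p.shape != o.shape:
        raise ValueError("length mismatch")
    n_pos, n_neg = int(o.sum()), int((~o).sum())
    if n_pos == 0 or n_neg == 0:
        warnings.warn("single-class observations: TSS undefined", RuntimeWarning)
        return float("nan")
    sensitivity = float(np.sum(p & o)) / n_pos
    specificity = float(np.sum(~p & ~o)) / n_neg
    return sensitivity + specificity - 1.0


def score_prediction_set(pred: PredictionSet, rule: OccurrenceRule) -> dict:
    """All five metrics for one prediction set under one occurrence rule."""
    obs_occ = pred.presence_mask.astype(int)
    pred_occ = binarize(pred.predicted, rule)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return {
            "auc": auc(pred.predicted, obs_occ),
            "kappa": kappa(pred_occ, obs_occ),
            "tss": tss(pred_occ, obs_occ),
            "rmse": rmse(pred),
            "prb": prb(pred),
        }
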