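"""The four machine-learning species distribution models.

Single-species models (one response species per fit):

* ``rf``  — random-forest regression on abundance.
* ``ann`` — single-hidden-layer neural network with weight decay.

Their multi-output community extensions:

* ``mrf``  — multivariate random forest; splits maximize the summed
  variance reduction across all species on per-species standardized
  responses (a Euclidean multivariate impurity); a Mahalanobis impurity
  with the fixed training covariance is available via whitening.
* ``mann`` — one shared hidden layer, one output neuron per species,
  joint least-squares loss on standardized responses.

Abundance is non-negative, so network predictions are floored at zero;
forest predictions are leaf means of non-negative responses and need no
flooring.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from ._mlp import TinyMLP

FOREST_DEFAULTS = {"trees": 500, "min_leaf": 5, "max_features": "sqrt"}
NETWORK_DEFAULTS = {"hidden": 8, "decay": 0.01, "max_iter": 500, "restarts": 5}

_SINGLE = ("rf", "ann")
_MULTI = ("mrf", "mann")


@dataclass
class ModelSpec:
    """Model family plus hyperparameters and seed.

    ``response_species`` (indices into the response matrix) must have
    length 1 for single-species families and >= 2 for multi-output ones;
    it may be omitted, in which case it is inferred from the response at
    fit time.
    """

    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0
    response_species: Optional[Sequence[int]] = None
    log_transform: bool = False  # model log1p(abundance) instead of raw

    def __post_init__(self):
        if self.family not in _SINGLE + _MULTI:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.response_species is not None:
            k = len(self.response_species)
            if self.family in _SINGLE and k != 1:
                raise ValueError(f"{self.family} takes exactly one response species")
            if self.family in _MULTI and k < 2:
                raise ValueError(f"{self.family} needs at least two response species")

    def params(self) -> dict:
        base = dict(FOREST_DEFAULTS if self.family in ("rf", "mrf") else NETWORK_DEFAULTS)
        base.update(self.hyperparameters)
        return base


@dataclass
class FittedModel:
    spec: ModelSpec
    n_features: int
    training_summary: dict
    _predictor: object = field(repr=False, default=None)

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        return predict(self, X_new)


def _check_xy(X, y, multi):
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    want = 2 if multi else 1
    if y.ndim != want:
        raise ValueError(f"response must be {want}-D for this family")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and response disagree on the number of rows")
    if np.any(y < 0):
        raise ValueError("abundance responses must be non-negative")
    return X, y


def _maybe_log(y, spec):
    return np.log1p(y) if spec.log_transform else y


def _maybe_unlog(pred, spec):
    return np.expm1(pred) if spec.log_transform else pred


def fit_rf(X, y, spec: ModelSpec) -> FittedModel:
    """Regression random forest on a single species' abundance."""
    X, y = _check_xy(X, y, multi=False)
    hp = spec.params()
    if X.shape[0] < hp["min_leaf"]:
        raise ValueError("fewer training rows than the minimum leaf size")
    forest = RandomForestRegressor(
        n_estimators=hp["trees"], min_samples_leaf=hp["min_leaf"],
        max_features=hp["max_features"], random_state=spec.seed,
    )
    forest.fit(X, _maybe_log(y, spec))

    def _pred(Xn):
        return _maybe_unlog(forest.predict(Xn), spec)

    summary = {"oob": None, "in_sample_rmse": _rmse(_pred(X), y)}
    return FittedModel(spec=spec, n_features=X.shape[1],
                       training_summary=summary, _predictor=_pred)


def fit_ann(X, y, spec: ModelSpec) -> FittedModel:
    """Single-hidden-layer network on one species; predictions floored at 0."""
    X, y = _check_xy(X, y, multi=False)
    hp = spec.params()
    xm, xs = X.mean(axis=0), _safe_sd(X)
    yt = _maybe_log(y, spec)
    ym, ys = yt.mean(), max(yt.std(), 1e-12)
    net = TinyMLP(hidden=hp["hidden"], decay=hp["decay"], max_iter=hp["max_iter"],
                  n_restarts=hp["restarts"], seed=spec.seed)
    net.fit((X - xm) / xs, (yt - ym) / ys)
    if not net.converged_:
        warnings.warn("network did not converge within max_iter", RuntimeWarning)

    def _pred(Xn):
        raw = net.predict((Xn - xm) / xs) * ys + ym
        return np.maximum(0.0, _maybe_unlog(raw, spec))

    summary = {"converged": net.converged_, "loss": net.loss_,
               "in_sample_rmse": _rmse(_pred(X), y)}
    return FittedModel(spec=spec, n_features=X.shape[1],
                       training_summary=summary, _predictor=_pred)


def fit_mrf(X, Y, spec: ModelSpec) -> FittedModel:
    """Multivariate random forest over all response species jointly.

    Default (Euclidean) criterion: per-species standardization then the
    multi-output variance-reduction split; constant species have zero
    variance and contribute nothing. ``hyperparameters["criterion"] =
    "mahalanobis"`` whitens responses with the fixed training covariance
    instead, which turns the Euclidean impurity into the Mahalanobis one.
    """
    X, Y = _check_xy(X, Y, multi=True)
    hp = spec.params()
    if X.shape[0] < hp["min_leaf"]:
        raise ValueError("fewer training rows than the minimum leaf size")
    Yt = _maybe_log(Y, spec)
    sds = Yt.std(axis=0)
    if np.all(sds == 0):
        raise ValueError("all response species are constant")
    criterion = hp.get("criterion", "euclidean")
    mean = Yt.mean(axis=0)
    if criterion == "euclidean":
        # with one species the criterion is scale-free: pass through so a
        # single-column fit coincides exactly with fit_rf
        if Yt.shape[1] == 1:
            mean = np.zeros(1)
            scale = np.ones(1)
        else:
            scale = np.where(sds > 0, sds, 1.0)
        transform = lambda M: (M - mean) / scale
        inverse = lambda Z: Z * scale + mean
    elif criterion == "mahalanobis":
        cov = np.cov(Yt, rowvar=False)
        cov += 1e-8 * np.eye(cov.shape[0]) * max(np.trace(cov), 1.0)
        L = np.linalg.cholesky(cov)
        Linv = np.linalg.inv(L)
        transform = lambda M: (M - mean) @ Linv.T
        inverse = lambda Z: Z @ L.T + mean
    else:
        raise ValueError(f"unknown MRF criterion {criterion!r}")
    forest = RandomForestRegressor(
        n_estimators=hp["trees"], min_samples_leaf=hp["min_leaf"],
        max_features=hp["max_features"], random_state=spec.seed,
    )
    Ytr = transform(Yt)
    forest.fit(X, Ytr.ravel() if Ytr.shape[1] == 1 else Ytr)

    def _pred(Xn):
        Z = forest.predict(Xn)
        if Z.ndim == 1:
            Z = Z[:, None]
        return np.maximum(0.0, _maybe_unlog(inverse(Z), spec))

    summary = {"criterion": criterion,
               "in_sample_rmse": _rmse(_pred(X), Y)}
    return FittedModel(spec=spec, n_features=X.shape[1],
                       training_summary=summary, _predictor=_pred)


def fit_mann(X, Y, spec: ModelSpec) -> FittedModel:
    """Multi-response network: shared hidden layer, one output per species."""
    X, Y = _check_xy(X, Y, multi=True)
    hp = spec.params()
    xm, xs = X.mean(axis=0), _safe_sd(X)
    Yt = _maybe_log(Y, spec)
    ym = Yt.mean(axis=0)
    ys = np.where(Yt.std(axis=0) > 0, Yt.std(axis=0), 1.0)
    net = TinyMLP(hidden=hp["hidden"], decay=hp["decay"], max_iter=hp["max_iter"],
                  n_restarts=hp["restarts"], seed=spec.seed)
    net.fit((X - xm) / xs, (Yt - ym) / ys)
    if not net.converged_:
        warnings.warn("network did not converge within max_iter", RuntimeWarning)

    def _pred(Xn):
        raw = net.predict((Xn - xm) / xs) * ys + ym
        return np.maximum(0.0, _maybe_unlog(raw, spec))

    summary = {"converged": net.converged_, "loss": net.loss_,
               "in_sample_rmse": _rmse(_pred(X), Y)}
    return FittedModel(spec=spec, n_features=X.shape[1],
                       training_summary=summary, _predictor=_pred)


def fit(X, Y, spec: ModelSpec) -> FittedModel:
    """Dispatch to the family-specific fitter."""
    return {"rf": fit_rf, "ann": fit_ann, "mrf": fit_mrf, "mann": fit_mann}[spec.family](X, Y, spec)


def predict(model: FittedModel, X_new: np.ndarray) -> np.ndarray:
    """Non-negative predicted abundance for each response species."""
    X_new = np.asarray(X_new, float)
    if X_new.ndim != 2:
        raise ValueError("X_new must be 2-D")
    if X_new.shape[1] != model.n_features:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns; model was trained on "
            f"{model.n_features}"
        )
    if X_new.shape[0] == 0:
        probe = model._predictor(np.zeros((1, model.n_features)))
        shape = (0,) if probe.ndim == 1 else (0, probe.shape[1])
        return np.zeros(shape)
    return model._predictor(X_new)


def _safe_sd(X):
    s = X.std(axis=0)
    return np.where(s > 0, s, 1.0)


def _rmse(pred, obs):
    return float(np.sqrt(np.mean((np.asarray(pred) - np.asarray(obs)) ** 2)))
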