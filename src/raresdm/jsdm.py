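"""Latent-factor censored (Tobit) joint species distribution model.

The model treats observed abundance as a zero-censored latent Gaussian:

    y_ij = max(0, z_ij),    z_i ~ Normal(B x_i + Lambda eta_i, diag(sigma^2))

where x_i are covariates (plus intercept), eta_i ~ N(0, I_K) are site-level
latent factors and Lambda their species loadings. The marginal species
covariance Sigma = Lambda Lambda' + diag(sigma^2) carries the residual
associations that make joint modelling informative for rare species.

Fitting is by Gibbs sampling with data augmentation: censored cells are
imputed from their truncated-normal full conditional, after which every
other update (coefficients, loadings, factor scores, variances) is
conjugate. Loadings are identified by a lower-triangular constraint with
non-negative diagonal; the rotation is immaterial to Sigma and prediction.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri


@dataclass(frozen=True)
class JSDMConfig:
    """Sampler settings and (weakly informative) prior scales."""

    n_factors: int = 2
    n_iterations: int = 4000
    burn_in: int = 2000
    thin: int = 2
    coef_prior_sd: float = 10.0
    loading_prior_sd: float = 1.0
    variance_prior_shape: float = 2.0
    variance_prior_rate: float = 1.0
    seed: int = 0
    rhat_threshold: float = 1.1  # split-chain diagnostic warning level on B

    def __post_init__(self):
        if self.n_factors < 0:
            raise ValueError("n_factors must be non-negative")
        if not (0 < self.burn_in < self.n_iterations):
            raise ValueError("need 0 < burn_in < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


@dataclass
class JSDMPosterior:
    """Thinned post-burn-in posterior draws.

    ``B`` includes the intercept as its first column and refers to
    standardized covariates; ``x_mean``/``x_sd`` hold the training
    standardization constants applied before prediction.
    """

    B: np.ndarray        # (n_draws, n_species, n_covariates + 1)
    loadings: np.ndarray  # (n_draws, n_species, n_factors)
    sigma2: np.ndarray   # (n_draws, n_species)
    x_mean: np.ndarray
    x_sd: np.ndarray
    config: JSDMConfig
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_species(self) -> int:
        return self.B.shape[1]

    def sigma_draws(self) -> np.ndarray:
        """Per-draw species covariance Sigma = Lambda Lambda' + diag(sigma^2)."""
        lam = self.loadings
        out = np.einsum("djk,dlk->djl", lam, lam)
        idx = np.arange(self.n_species)
        out[:, idx, idx] += self.sigma2
        return out

    def mean_sigma(self) -> np.ndarray:
        return self.sigma_draws().mean(axis=0)


def _truncated_normal_below_zero(mu, sd, rng):
    """Draw z ~ Normal(mu, sd^2) conditioned on z <= 0, vectorized.

    Inverse-CDF sampling; probabilities are clipped away from 0/1 so the
    draw stays finite even when mu/sd puts almost no mass below zero.
    """
    p0 = ndtr(-mu / sd)  # P(z <= 0)
    u = rng.uniform(0.0, 1.0, size=np.shape(mu)) * p0
    u = np.clip(u, 1e-300, 1.0 - 1e-16)
    return mu + sd * ndtri(u)


def fit_latent_jsdm(X: np.ndarray, Y: np.ndarray, config: JSDMConfig) -> JSDMPosterior:
    """Gibbs sampler for the zero-censored latent-factor regression.

    Parameters
    ----------
    X : (n_sites, n_covariates)
        Environmental covariates; standardized internally.
    Y : (n_sites, n_species)
        Non-negative abundance; zeros are treated as censored.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with matching row counts")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite values in X or Y")
    if np.any(Y < 0):
        raise ValueError("Y must be non-negative (zeros are censored cells)")

    x_mean, x_sd = X.mean(axis=0), X.std(axis=0)
    x_sd = np.where(x_sd > 0, x_sd, 1.0)
    Xs = np.column_stack([np.ones(X.shape[0]), (X - x_mean) / x_sd])
    rank = np.linalg.matrix_rank(Xs)
    if rank < Xs.shape[1]:
        bad = _dependent_columns(Xs)
        raise ValueError(f"rank-deficient design matrix; offending covariate "
                         f"columns (0-based, excluding intercept): {bad}")

    n, S = Y.shape
    p = Xs.shape[1]
    K = config.n_factors
    rng = np.random.default_rng(config.seed)
    censored = Y == 0.0

    # init
    Z = np.where(censored, -0.5, Y)
    B = np.linalg.lstsq(Xs, Z, rcond=None)[0].T          # (S, p)
    if K > S:
        raise ValueError("n_factors may not exceed the number of species")
    lam = np.zeros((S, K))
    if K:
        lam[np.arange(K), np.arange(K)] = 0.1
    eta = np.zeros((n, K))
    sigma2 = np.maximum(Z.var(axis=0), 0.1)

    tau_b2 = config.coef_prior_sd ** 2
    tau_l2 = config.loading_prior_sd ** 2
    a0, b0 = config.variance_prior_shape, config.variance_prior_rate
    XtX = Xs.T @ Xs

    keep = []
    for it in range(config.n_iterations):
        # 1. impute censored latent values
        mu = Xs @ B.T + eta @ lam.T
        sd = np.sqrt(sigma2)
        draws = _truncated_normal_below_zero(mu[censored],
                                             np.broadcast_to(sd, mu.shape)[censored],
                                             rng)
        Z[censored] = draws

        # 2. factor scores eta_i | rest (shared precision across sites)
        if K:
            Dinv_lam = lam / sigma2[:, None]             # (S, K)
            prec = np.eye(K) + lam.T @ Dinv_lam
            cov = np.linalg.inv(prec)
            mean = (Z - Xs @ B.T) @ Dinv_lam @ cov.T
            eta = mean + rng.standard_normal((n, K)) @ np.linalg.cholesky(cov).T

        # 3. coefficient rows B_j | rest
        resid_target = Z - eta @ lam.T                   # (n, S)
        for j in range(S):
            V = np.linalg.inv(XtX / sigma2[j] + np.eye(p) / tau_b2)
            m = V @ (Xs.T @ resid_target[:, j]) / sigma2[j]
            B[j] = m + np.linalg.cholesky(V) @ rng.standard_normal(p)

        # 4. loading rows lam_j | rest (lower-triangular support)
        if K:
            resid_b = Z - Xs @ B.T
            for j in range(S):
                k = min(j + 1, K)
                E = eta[:, :k]
                V = np.linalg.inv(E.T @ E / sigma2[j] + np.eye(k) / tau_l2)
                m = V @ (E.T @ resid_b[:, j]) / sigma2[j]
                lam[j, :k] = m + np.linalg.cholesky(V) @ rng.standard_normal(k)
                lam[j, k:] = 0.0
            # sign convention: non-negative diagonal (flip factor + column)
            for k in range(min(K, S)):
                if lam[k, k] < 0:
                    lam[:, k] *= -1.0
                    eta[:, k] *= -1.0

        # 5. residual variances
        R = Z - Xs @ B.T - eta @ lam.T
        shape = a0 + n / 2.0
        rate = b0 + 0.5 * (R * R).sum(axis=0)
        sigma2 = rate / rng.gamma(shape, 1.0, size=S)

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            keep.append((B.copy(), lam.copy(), sigma2.copy()))

    Bd = np.stack([k[0] for k in keep])
    Ld = np.stack([k[1] for k in keep])
    s2d = np.stack([k[2] for k in keep])
    diagnostics = {"rhat_B_max": _split_rhat(Bd)}
    if diagnostics["rhat_B_max"] > config.rhat_threshold:
        warnings.warn(
            f"split-chain R-hat on coefficients reached "
            f"{diagnostics['rhat_B_max']:.3f} (> {config.rhat_threshold}); "
            "consider a longer chain", RuntimeWarning)
    return JSDMPosterior(B=Bd, loadings=Ld, sigma2=s2d, x_mean=x_mean,
                         x_sd=x_sd, config=config, diagnostics=diagnostics)


def predict_marginal(posterior: JSDMPosterior, X_new: np.ndarray,
                     n_draws: int = 200, seed: int = 0) -> np.ndarray:
    """Posterior-mean censored prediction at new sites.

    For each retained posterior draw (cycled up to ``n_draws``) a latent
    vector z ~ Normal(B x, Sigma) is sampled per site and censored at
    zero; the returned matrix is the mean over draws, hence non-negative.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    X_new = np.asarray(X_new, float)
    if X_new.shape[1] != posterior.x_mean.shape[0]:
        raise ValueError("X_new width does not match the training covariates")
    Xs = np.column_stack([np.ones(X_new.shape[0]),
                          (X_new - posterior.x_mean) / posterior.x_sd])
    rng = np.random.default_rng(seed)
    D = posterior.B.shape[0]
    n, S = X_new.shape[0], posterior.n_species
    total = np.zeros((n, S))
    for d in range(n_draws):
        i = d % D
        mean = Xs @ posterior.B[i].T
        z = mean + rng.standard_normal((n, posterior.loadings.shape[2])) \
            @ posterior.loadings[i].T
        z += rng.standard_normal((n, S)) * np.sqrt(posterior.sigma2[i])
        total += np.maximum(0.0, z)
    return total / n_draws


def residual_correlation(posterior: JSDMPosterior) -> np.ndarray:
    """Posterior-mean species covariance converted to a correlation matrix."""
    sigma = posterior.mean_sigma()
    d = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return (corr + corr.T) / 2.0


def _dependent_columns(Xs) -> list:
    """Indices of covariate columns involved in exact linear dependence."""
    bad = []
    for j in range(1, Xs.shape[1]):  # skip intercept
        others = np.delete(Xs, j, axis=1)
        fit, *_ = np.linalg.lstsq(others, Xs[:, j], rcond=None)
        if np.allclose(others @ fit, Xs[:, j], atol=1e-8):
            bad.append(j - 1)
    return bad


def _split_rhat(draws: np.ndarray) -> float:
    """Max split-chain R-hat over all coefficient entries."""
    d = draws.reshape(draws.shape[0], -1)
    m = d.shape[0] // 2
    if m < 2:
        return 1.0
    halves = np.stack([d[:m], d[m:2 * m]])          # (2, m, q)
    means = halves.mean(axis=1)
    W = halves.var(axis=1, ddof=1).mean(axis=0)
    Bv = m * means.var(axis=0, ddof=1)
    var_hat = (m - 1) / m * W + Bv / m
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / W)
    rhat = rhat[np.isfinite(rhat)]
    return float(rhat.max()) if rhat.size else 1.0
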