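"""Seeded synthetic community generator.

Emulates the statistical structure of a trawl-survey community table:
smooth correlated environmental gradients, species with linear or unimodal
(quadratic) responses, residual inter-species correlation induced by shared
latent factors, and zero inflation from censoring of a latent abundance.
Rare-species intercepts are calibrated by Monte Carlo so realized occurrence
frequencies hit their targets in expectation.
"""
from __future__ import annotations

import numpy as np

from .dataset import CommunityDataset, SimulationConfig, TARGET, ANCILLARY

#: Monte-Carlo pool size used when calibrating species intercepts.
CALIBRATION_POOL = 20_000


class CalibrationError(RuntimeError):
    """Raised when a target prevalence cannot be reached by any intercept."""


def simulate_environment(n_sites: int, n_covariates: int, seed: int) -> np.ndarray:
    """Smooth, mutually correlated covariate gradients, standardized per column.

    Each covariate is a monotone function of a shared latitudinal site index
    plus independent noise, mimicking how bottom temperature, salinity and
    depth co-vary along a coastal gradient. Columns are standardized to mean
    0, sd 1, so downstream models see unit-free inputs.
    """
    if n_sites < 2:
        raise ValueError("n_sites must be >= 2")
    if n_covariates < 1:
        raise ValueError("n_covariates must be positive")
    rng = np.random.default_rng(seed)
    t = rng.uniform(0.0, 1.0, size=n_sites)  # shared site index along the gradient
    cols = []
    for k in range(n_covariates):
        power = 0.5 + 0.75 * (k % 3)  # 0.5, 1.25, 2.0, 0.5, ...
        sign = 1.0 if k % 2 == 0 else -1.0
        smooth = sign * t ** power
        noise = rng.normal(0.0, 0.35, size=n_sites)
        cols.append(smooth + noise)
    X = np.column_stack(cols)
    X -= X.mean(axis=0)
    X /= X.std(axis=0)
    return X


def calibrate_intercept(target_prevalence: float,
                        linear_predictor_samples: np.ndarray,
                        residual_sd: float = 0.0,
                        rng: np.random.Generator | None = None) -> float:
    """Intercept a with P(a + lp + eps > 0) == target_prevalence in expectation.

    Implemented as the negated empirical quantile of (lp + eps) at level
    (1 - target_prevalence) over the supplied Monte-Carlo sample.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target_prevalence must lie in (0, 1)")
    lp = np.asarray(linear_predictor_samples, dtype=float)
    if lp.size < 100:
        raise ValueError("need at least 100 linear-predictor samples")
    if residual_sd > 0:
        rng = np.random.default_rng() if rng is None else rng
        total = lp + rng.normal(0.0, residual_sd, size=lp.shape)
    else:
        total = lp
    if np.ptp(total) == 0.0:
        raise CalibrationError(
            "constant latent predictor: no intercept can realize prevalence "
            f"{target_prevalence}"
        )
    return float(-np.quantile(total, 1.0 - target_prevalence))


def empirical_prevalence(dataset: CommunityDataset) -> np.ndarray:
    """Per-species fraction of sites with abundance strictly above zero."""
    return np.mean(dataset.abundance > 0, axis=0)


def _species_responses(config: SimulationConfig, rng: np.random.Generator):
    """Draw environmental response coefficients per species.

    Quadratic responses are concave (negative curvature), giving unimodal
    niches along each gradient; linear responses set curvature to zero.
    """
    S, p = config.n_species, config.n_covariates
    linear = rng.normal(0.0, 0.6, size=(S, p))
    if config.response_shape == "quadratic":
        curvature = -np.abs(rng.normal(0.0, 0.35, size=(S, p)))
    else:
        curvature = np.zeros((S, p))
    return linear, curvature


def _env_effect(X: np.ndarray, linear: np.ndarray, curvature: np.ndarray) -> np.ndarray:
    # (n_sites, n_species): f_j(x_i) = x_i . b_j + x_i^2 . q_j
    return X @ linear.T + (X ** 2) @ curvature.T


def simulate_community(config: SimulationConfig,
                       loadings: np.ndarray | None = None,
                       responses: tuple | None = None) -> CommunityDataset:
    """Generate a community dataset under a latent-factor censored model.

    The latent value for species j at site i is

        z_ij = a_j + f_j(x_i) + (Lambda eta_i)_j + eps_ij

    with standard-normal factor scores eta_i, normal(0, residual_sd^2)
    noise, and f_j linear or quadratic per ``config.response_shape``. The
    ``tobit`` mechanism observes y = max(0, z); ``hurdle_lognormal`` uses
    z > 0 for occurrence and draws positive abundance lognormally. Rare
    intercepts are calibrated to hit ``rare_prevalence_targets``; common
    intercepts are spread to cover ``common_prevalence_range`` evenly.

    Parameters
    ----------
    loadings
        Optional (n_species, n_factors) loading matrix overriding the
        random default — used to build communities with a prescribed
        correlation structure.
    responses
        Optional (linear, curvature) coefficient pair, each
        (n_species, n_covariates), overriding the random environmental
        responses — used to build communities where chosen species share
        (or do not share) the target's niche.
    """
    rng = np.random.default_rng(config.seed)
    child = np.random.SeedSequence(config.seed).spawn(3)
    S, K, n = config.n_species, config.n_factors, config.n_sites

    X = simulate_environment(n, config.n_covariates,
                             seed=int(child[0].generate_state(1)[0] % (2 ** 31)))
    linear, curvature = _species_responses(config, rng)
    if responses is not None:
        linear = np.asarray(responses[0], float)
        curvature = np.asarray(responses[1], float)
        if linear.shape != (S, config.n_covariates) or curvature.shape != linear.shape:
            raise ValueError("responses must be a pair of (n_species, n_covariates) arrays")
    if loadings is None:
        lam = rng.normal(0.0, config.loading_scale, size=(S, K)) if K else np.zeros((S, 0))
    else:
        lam = np.asarray(loadings, dtype=float)
        if lam.shape != (S, K):
            raise ValueError(f"loadings must have shape {(S, K)}, got {lam.shape}")

    # Monte-Carlo calibration pool: fresh environment/factors/noise with the
    # same distribution as the actual sites.
    cal_rng = np.random.default_rng(child[1])
    X_cal = simulate_environment(CALIBRATION_POOL, config.n_covariates,
                                 seed=int(child[2].generate_state(1)[0] % (2 ** 31)))
    lp_cal = _env_effect(X_cal, linear, curvature)
    if K:
        lp_cal += cal_rng.standard_normal((CALIBRATION_POOL, K)) @ lam.T
    lp_cal += cal_rng.normal(0.0, config.residual_sd, size=lp_cal.shape)

    targets = list(config.rare_prevalence_targets)
    lo, hi = config.common_prevalence_range
    common = list(np.linspace(lo, hi, config.n_common))
    prevalences = targets + common
    intercepts = np.array([
        calibrate_intercept(p, lp_cal[:, j]) for j, p in enumerate(prevalences)
    ])

    eta = rng.standard_normal((n, K)) if K else np.zeros((n, 0))
    eps = rng.normal(0.0, config.residual_sd, size=(n, S))
    z = intercepts + _env_effect(X, linear, curvature) + eta @ lam.T + eps

    if config.mechanism == "tobit":
        Y = np.maximum(0.0, z)
    else:  # hurdle_lognormal
        mu = rng.normal(0.0, 0.5, size=S)
        positive = rng.lognormal(mean=mu, sigma=0.75, size=(n, S))
        Y = np.where(z > 0, positive, 0.0)

    names = [f"Sp{j + 1}" for j in range(config.n_rare)]
    names += [f"Anc{j + 1:02d}" for j in range(config.n_common)]
    roles = [TARGET] * config.n_rare + [ANCILLARY] * config.n_common
    site_ids = [f"st{i + 1:03d}" for i in range(n)]
    truth = {
        "intercepts": intercepts,
        "linear": linear,
        "curvature": curvature,
        "loadings": lam,
        "factors": eta,
        "residual_sd": config.residual_sd,
        "config": config,
    }
    return CommunityDataset(abundance=Y, covariates=X, species_names=names,
                            roles=roles, site_ids=site_ids, truth=truth)
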