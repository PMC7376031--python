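# raresdm

Predicting **rare species' distributions from community data**: tools for
testing whether, and how, the abundant members of an ecological community
can improve distribution models for its rare members.

Rare species — here, species occurring at under 15% of surveyed sites — are
the hardest targets for species distribution models (SDMs): a handful of
presences must support a model with several environmental predictors, so
single-species models overfit or collapse to "never present". Community
surveys, however, record dozens of common species alongside each rare one,
and their covariation (shared environmental responses, biotic association,
shared sampling noise) is information a model can borrow. `raresdm`
implements a full benchmarking pipeline for this idea on trawl-survey-style
data: effort-standardized catch abundance at ~100 stations with a few
hydrographic covariates (bottom temperature, salinity, depth analogues).

## What is implemented

**Models** (all predict non-negative abundance from covariates):

| family | description |
|---|---|
| `rf` | single-species random-forest regression |
| `ann` | single-species one-hidden-layer network with weight decay |
| `mrf` | multivariate random forest — splits maximize summed variance reduction across all species on per-species standardized responses (Mahalanobis impurity available by response whitening) |
| `mann` | multi-response network — one shared hidden layer, one output neuron per species, joint least-squares loss |
| `jsdm` | latent-factor censored (Tobit) regression fitted by Gibbs sampling |

The joint SDM treats observed abundance as a zero-censored latent Gaussian

```
y_ij = max(0, z_ij),   z_i ~ N(B x_i + Λ η_i, diag(σ²)),   η_i ~ N(0, I_K)
```

so the species covariance `Σ = ΛΛᵀ + diag(σ²)` carries residual
associations; censored cells are imputed by data augmentation and every
other update is conjugate.

**Enhancements**:

* *Species filtering* for joint models — ancillary (common) species are
  ranked by Spearman correlation with the target and trimmed to nested
  levels: LV1 = all, LV2 = top two-thirds, LV3 = top third.
* *Conditional prediction* for single-species models — ancillary abundances
  are compressed by correlation-matrix PCA (Kaiser eigenvalue-above-one
  rule) and appended to the covariates, using either observed values or
  joint-model predictions at the prediction sites.

**Evaluation**: presence-stratified 4-fold cross-validation (presences and
absences dealt round-robin to folds so per-fold presence counts differ by
at most one), repeated; metrics are AUC, Cohen's κ, TSS for occurrence
(predictions binarized at the species' mean abundance over the whole
area), RMSE and partial relative bias `PRB = mean((P_p − O_p)/O_p)` over
presence sites for abundance, plus an all-zero-prediction RMSE baseline.

**Synthetic surveys**: a seeded generator emulating the study design the
pipeline assumes — 118 sites, 3 covariates, 6 rare targets with calibrated
occurrence 3.5–12.3%, 31 ancillary species spanning 23–87%, zero inflation
from latent-Gaussian censoring, residual correlation from shared latent
factors.

## Worked example

```python
import raresdm as rs
from raresdm.models import ModelSpec

community = rs.simulate_community(rs.SimulationConfig(seed=42))

cv = rs.CVConfig(k=4, n_repetitions=10, seed=0,
                 models=[ModelSpec("rf", hyperparameters={"trees": 200})],
                 treatments=("baseline", "conditional_obs"),
                 targets=["Sp4"])
records = rs.run_cv(community, cv)
print(rs.aggregate(records, dataset=community)[
    ["model", "species", "treatment", "auc_mean", "kappa_mean",
     "rmse_mean", "prb_mean"]].round(3).to_string(index=False))

base = [r for r in records if r.treatment == "baseline"]
cond = [r for r in records if r.treatment == "conditional_obs"]
print(rs.delta_rmse(cond, base).round(4).to_string(index=False))
```

prints

```
model species       treatment  auc_mean  kappa_mean  rmse_mean  prb_mean
   rf     Sp4        baseline     0.713       0.176      0.253    -0.383
   rf     Sp4 conditional_obs     0.715       0.201      0.229    -0.520
 zero     Sp4        baseline       NaN         NaN      0.283       NaN
species   mean    std  count
    Sp4 0.0237 0.0222     40
```

Reading: the rare target Sp4 (~9% occurrence) is predictable in occurrence
(AUC 0.71) but its abundance is underestimated (negative PRB). Both model
variants beat the all-zero baseline RMSE of 0.283, and conditioning the
forest on the observed community (PCA-reduced ancillary abundances) lowers
RMSE from 0.253 to 0.229 — a per-fold ΔRMSE of +0.024 (positive =
improvement), the "community data help" direction.

The same pipeline is scriptable from the shell:

```sh
raresdm simulate --seed 1 --out survey/
raresdm benchmark --config bench.yaml --out results/
raresdm report results/metrics.csv
```

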