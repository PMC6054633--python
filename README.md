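# fossilclim

Quantitative palaeoclimate inference from fossil pollen assemblages: a tested,
reusable implementation of the full chain used in high-resolution
interglacial lake-sediment studies —

* **compositional primitives** — pollen percentages on the terrestrial
  pollen + spore sum, marker-based concentrations, squared chord distance,
  AP/NAP ratios (`fossilclim.io`);
* **stratigraphic zonation** — a multivariate regression tree with core depth
  as the sole predictor and cross-validated 1-SE pruning
  (`fossilclim.zonation`);
* **a six-model pollen–climate calibration ensemble** — weighted averaging
  (WA), WA partial least squares (WA-PLS), the modern analogue technique
  (MAT), maximum-likelihood response curves (MLRC), boosted regression trees
  (BRT) and random forests (RF), with cross-validated RMSEP/R²/max-bias, a
  pointwise ensemble median and a robust LOESS smoother
  (`fossilclim.calibration`);
* **analogue diagnostics** — nearest-analogue distances, good/poor analogue
  flags, analogue geography (`fossilclim.analogue`);
* **reconstruction significance** — the random-transfer-function redundancy
  analysis permutation test (`fossilclim.significance`);
* **age–depth modelling** — a Poisson-process (gamma-increment) model between
  dated tie points with Monte-Carlo uncertainty (`fossilclim.chronology`);
* **synthetic studies with known truth** — Gaussian taxon responses over two
  correlated climate gradients, multinomial count noise, and a fossil
  trajectory with decoupled seasonal trends and injected abrupt cooling
  events (`fossilclim.synthetic`), so every stage can be validated against
  ground truth.

The calibration models follow the scikit-learn estimator contract
(`fit(X, y)` / `predict(X)`, `get_params`/`set_params`), so they compose with
sklearn model selection; `X` is a samples × taxa percentage matrix and `y` a
climate variable in °C.

## The core statistics

**Weighted averaging.** Taxon optimum and raw sample estimate

u_k = Σᵢ y_ik xᵢ / Σᵢ y_ik,  x̂ᵢ = Σ_k y_ik u_k / Σ_k y_ik,

followed by inverse (regress x on x̂) or classical deshrinking. WA-PLS
extracts further components from abundance-weighted residuals; with one
component it reproduces WA with inverse deshrinking exactly.

**MAT.** Prediction is the inverse-distance-weighted mean climate of the k
(default 5) calibration samples with the smallest squared chord distance
d(p, q) = Σ_k (√p_k − √q_k)², d ∈ [0, 2].

**MLRC.** Per-taxon Gaussian-logit response curves
logit p_k(x) = b₀ + b₁x + b₂x²; the fossil estimate maximises
Σ_k [y_k ln p_k(x) + (1 − y_k) ln(1 − p_k(x))] over a grid.

**Significance.** VE = SS(fitted)/SS(total) of the centred fossil matrix
projected on the reconstruction; the null distribution retrains the same
method on variables drawn uniformly over the observed climate range and
p = (1 + #{VE_null ≥ VE_obs}) / (1 + n_perm).

**Age model.** Between tie points with Normal age priors, time is allocated
across depth increments by a Dirichlet (normalised gamma) bridge with shape
k·Δd per increment — the Poisson-process deposition model; every draw is a
strictly monotone depth → age function.

## Worked example

```python
import numpy as np
from fossilclim import default_scenario, reconstruct_ensemble
from fossilclim.pipeline import default_event_windows, event_magnitude

scen = default_scenario(seed=1)            # 300 calibration samples, 25 taxa,
                                           # pollen sum 400, 200 fossil samples
ens = reconstruct_ensemble(scen.calibration, scen.climate, scen.fossil,
                           climate_var="t_jul", seed=7)
rmse = np.sqrt(((ens.median - scen.trajectory.t_jul) ** 2).mean())
print(f"ensemble-median T_jul RMSE: {rmse:.2f} C")
for m, s in ens.cv_stats.items():
    print(f"  {m}: RMSEP={s.rmsep:.2f} R2={s.r2:.2f}")
w = default_event_windows(scen.trajectory)[1]   # the larger injected event
rep = event_magnitude(ens, w["event_window"], w["reference_window"], w["name"])
print(f"{rep.name}: mean cooling {rep.mean_delta_t:.2f} C "
      f"(range {rep.range[0]:.2f}-{rep.range[1]:.2f})")
```

prints

```
ensemble-median T_jul RMSE: 0.22 C
  WA: RMSEP=0.66 R2=0.95
  WAPLS: RMSEP=0.31 R2=0.99
  MAT: RMSEP=0.30 R2=0.99
  MLRC: RMSEP=0.43 R2=0.98
  BRT: RMSEP=0.55 R2=0.97
  RF: RMSEP=0.47 R2=0.98
tunturi: mean cooling 2.75 C (range 2.59-2.94)
```

i.e. the ensemble median recovers the true July trajectory to ~0.2 °C —
well inside the cross-validated error of any single model — and the injected
2.7 °C abrupt cooling is recovered to within ~0.1 °C by the mean of the six
per-method magnitudes.

The same chain is available from the shell:

```
fossilclim simulate --seed 1 --out demo/
fossilclim zones --fossil demo/fossil_counts.csv --out demo/zones.csv
fossilclim reconstruct --calib-counts demo/calibration_counts.csv \
    --calib-climate demo/calibration_climate.csv --fossil demo/fossil_counts.csv \
    --var t_jul --seed 7 --out demo/recon.csv
fossilclim run --config config.yaml        # the whole pipeline at once
```

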