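# gwcrash

Zonal crash-frequency analysis with **geographically weighted negative
binomial regression** (GWNBR).

Crash counts aggregated to spatial zones (districts, traffic analysis
zones) are almost always overdispersed — the variance far exceeds the
mean — and spatially structured: both the counts and their relationships
with built-environment and climate covariates vary over the map. A
single global regression then misleads twice, once by assuming a common
coefficient everywhere and once by leaving spatially correlated
residuals. `gwcrash` implements the full workflow for this situation:

* **Spatial autocorrelation** — global Moran's I with analytic
  (randomization/normality) and permutation inference, and local Moran
  (LISA) with High-High / Low-Low / Low-High / High-Low cluster labels;
* **Screening** — per-covariate Moran tests and variance inflation
  factors (VIF), with one-shot or iterative exclusion above VIF 10;
* **Global baselines** — OLS, Poisson, and NB2 (Var = μ + αμ²) with
  offsets, profile-likelihood dispersion estimation, and the Pearson
  χ²/df overdispersion diagnostic;
* **GWNBR** — the core model

      y_j ~ NB( t_j · exp(Σ_k β_k(u_j, v_j) x_jk), α(u_j, v_j) ),

  fitted by locally weighted maximum likelihood (IRLS for β alternating
  with 1-D dispersion updates) at every zone under an adaptive bisquare
  kernel, with the bandwidth chosen by golden-section search of AIC or
  leave-one-out CV;
* **Model comparison** — AIC (with trace-based effective parameters for
  the local model), MAD, RMSE, and residual Moran diagnostics;
* **Synthetic studies** — a generator of lattice zone systems with
  spatially autocorrelated covariates and NB2 counts drawn from known,
  recorded coefficient and dispersion surfaces, so every stage can be
  verified against ground truth.

See `docs/methods.md` for the statistical details and conventions.

## Worked example

```python
import gwcrash as gw

study = gw.paper_like_study(seed=1)          # 196 zones, overdispersed counts
units = study.units
y = units.response_vector()
print(f"counts: mean={y.mean():.2f} sd={y.std(ddof=1):.2f} max={y.max():.0f}")

wm = gw.build_moran_weights(units, "queen")
mor = gw.global_moran(y, wm, n_permutations=999, seed=1)
print(f"Moran's I = {mor.I:.4f}  E[I] = {mor.expected_I:.4f} "
      f"z = {mor.z_score:.2f}  p_perm = {mor.p_permutation:.4f}")

po, nb = gw.fit_poisson(units), gw.fit_negbin(units)
print(f"Poisson dispersion chi2/df = {gw.dispersion_statistic(po):.1f}")
print(f"NB alpha = {nb.alpha:.3f}")

sel = gw.select_bandwidth(units, criterion="aic", global_alpha=True)
fit = gw.fit_gwnbr(units, kernel=gw.KernelSpec("adaptive_bisquare", sel.optimum))
print(f"selected adaptive bandwidth = {sel.optimum:.0f} neighbours")
print(f"AIC: Poisson {po.aic:.1f} | NB {nb.aic:.1f} | GWNBR {fit.aic:.1f}")
print(fit.local_summary().round(3))
resid = gw.global_moran(fit.residuals(), wm)
print(f"GWNBR residual Moran I = {resid.I:.4f} (p = {resid.p_analytic:.3f})")
```

Output:

```
counts: mean=16.22 sd=24.26 max=225
Moran's I = 0.0841  E[I] = -0.0051 z = 2.65  p_perm = 0.0180
Poisson dispersion chi2/df = 18.9
NB alpha = 0.680
selected adaptive bandwidth = 65 neighbours
AIC: Poisson 3340.9 | NB 1432.5 | GWNBR 1392.4
                      Min     LQ  Median     UQ    Max
Intercept           2.114  2.360   2.486  2.791  3.366
road_density        0.024  0.296   0.418  0.558  0.776
population_density -0.441 -0.127  -0.038  0.024  0.138
precipitation       0.063  0.316   0.387  0.466  0.545
GWNBR residual Moran I = -0.0657 (p = 0.109)
```

Reading it: the simulated counts cluster significantly (z = 2.65 against
a null expectation of −1/195 = −0.0051), are far too dispersed for a
Poisson model (χ²/df ≈ 19), and the NB2 fit absorbs that with α ≈ 0.68.
The locally weighted model improves the AIC over the global NB and its
five-number summaries show coefficients drifting across the map (e.g.
road density from 0.02 to 0.78 on the log scale). Its residuals show no
significant spatial autocorrelation — the local model has absorbed the
spatial structure the global one left behind.

The same workflow runs from the shell:

```sh
gwcrash simulate --n-side 14 --seed 1 --preset paper_like --out data/
gwcrash moran --data data/units.csv --variable crash_count --weights knn:8 \
    --permutations 999 --seed 1
gwcrash gwnbr --data data/units.csv --response crash_count \
    --covariates road_density,population_density,precipitation \
    --criterion aic --seed 1 --out fit/
gwcrash run --config analysis.json     # full pipeline from a JSON config
```

Inputs may be GeoJSON (polygons + attributes) or CSV (attributes with
planar `x`,`y` centroids); all outputs are CSV/GeoJSON/JSON.

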