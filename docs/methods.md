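# Methods

This note documents the statistical machinery in `gwcrash`: the models it
fits, the conventions it adopts where several are defensible, and the
limits of what its synthetic benchmarks demonstrate.

## Problem setting

The package targets zonal (areal) count data: a study region divided into
n spatial units (districts, traffic analysis zones), each with a
nonnegative integer outcome y_j (e.g. crashes per year), planar centroid
coordinates (u_j, v_j), and real-valued covariates x_jk. Such data are
typically overdispersed (Var(y) >> E(y)) and spatially structured: both
the outcome and the covariate–outcome relationships vary over the map.

## Spatial autocorrelation

**Global Moran's I.**

    I = (N / W0) * Σ_ij w_ij (x_i − x̄)(x_j − x̄) / Σ_i (x_i − x̄)²

with W0 = Σ_ij w_ij. Under the null, E[I] = −1/(N−1). Inference uses the
analytic variance under the randomization assumption by default (the
common GIS default; the normality variant is available by flag) and,
optionally, permutation: the p-value counts permuted statistics at least
as far from E[I] as the observed one, with the observed statistic
included in numerator and denominator so p is never 0. The two-sided 99%
reference threshold for z-scores is 2.58.

**Local Moran (LISA).** local_I_i = (z_i/m2)·Σ_j w_ij z_j, with z the
mean deviations and m2 = Σz²/n; with row-standardized weights the mean of
the local statistics equals the global I (checked numerically in tests).
Significance uses conditional permutation (focal value held fixed,
neighbour values resampled from the remaining n−1 observations; 999
draws by default). Cluster labels come from the quadrant of
(z_i, spatial lag): HH, LL (clusters), LH, HL (outliers), NS when the
p-value fails the gate. No multiplicity correction is applied by default,
matching common mapping practice; an FDR flag exists.

**Weights.** Queen/rook contiguity from polygon geometry (binary, then
row-standardized for Moran use), k-nearest-neighbour weights as the
point-only fallback (k = 8 by default). Ties at the adaptive-kernel
radius receive weight zero — a deterministic rule independent of sort
order. All distances are Euclidean on projected planar coordinates; the
readers refuse inputs that look like lon/lat degrees rather than
silently computing spherical nonsense.

## Screening

VIF_k = 1/(1 − R²_k), from regressing covariate k on the others plus an
intercept; exact collinearity yields +inf rather than an exception. The
default screen removes all covariates with VIF > 10 in one pass
(`one_shot`); `iterative` mode removes the worst offender and recomputes,
which can keep variables the one-shot pass would discard. The Moran
screen flags covariates whose global spatial autocorrelation is not
significant at α = 0.05; it is advisory by default (a spatially
patternless covariate is suspicious in a spatial model, but lack of
autocorrelation is not by itself grounds for exclusion), with a strict
mode that enforces removal.

## Global count models

Poisson and NB2 use the log link ln μ = ln t + Xβ, with t an optional
exposure offset (default t = 1). NB2 has Var(y) = μ + αμ². The NB fit
profiles α: for fixed α, β comes from IRLS; the profiled log-likelihood
is maximized over ln α ∈ [ln 1e-8, ln 9.2] by bounded Brent search
(absolute tolerance 1e-8 on ln α; IRLS tolerance 1e-10, max 200
iterations). Underdispersed data drive α̂ to the lower bound; the fit is
then flagged `boundary_alpha` and numerically reproduces Poisson. β
standard errors come from the Fisher information at (β̂, α̂); the α
standard error from the numerical curvature of the profile. The Gaussian
ML log-likelihood (−n/2·(ln 2πσ̂² + 1)) is used for the OLS baseline so
the cross-family AIC column of the comparison table is well defined —
cross-family AIC comparison is this analysis tradition's practice and is
retained for fidelity, not endorsed.

The Pearson dispersion statistic χ²/(n−k) = Σ(y−μ̂)²/V(μ̂)/(n−k)
diagnoses variance misspecification: ≈1 when the family's variance is
right, ≫1 under overdispersion.

## GWNBR

The core model lets coefficients and dispersion vary over space:

    y_j ~ NB( t_j · exp(Σ_k β_k(u_j, v_j) x_jk), α(u_j, v_j) ).

At each focal unit i, kernel weights w(d_ij) define the local weighted
NB2 log-likelihood (written with log-gamma; the Gamma integrals are never
evaluated directly). Estimation alternates:

* IRLS for β: β ← [X′WAX]⁻¹X′WAz with A = diag(μ_j/(1+αμ_j)) and
  adjusted response z_j = x_j′β + (y_j − μ_j)/μ_j. (The equivalent form
  (y−μ)/[a_j(1+αμ_j)] with a_j the IRLS weight reduces to (y−μ)/μ;
  both appear in the literature.) Step-halving keeps the weighted
  likelihood non-decreasing — the monotone-ascent property is tested.
* A bounded 1-D update of ln α maximizing the local weighted likelihood
  at the current β (accepted only if it does not decrease the
  likelihood).

Outer convergence: weighted log-likelihood change < 1e-8, max 100
iterations. Every local fit warm-starts from the global NB estimates,
which stabilizes small bandwidths. Local covariance is [X′WAX]⁻¹ at
convergence; local t-statistics use a two-sided normal reference with no
multiplicity correction by default. A `global_alpha` switch holds the
dispersion at the global NB estimate (some formulations prefer this).
Identifiability requires at least p+2 positive weights at each focal
unit; a unit failing this (or a singular weighted cross-product) raises
"locally unidentified", and more than 10% local failures aborts the fit.

**Kernels.** Adaptive bisquare (bandwidth = integer neighbour count N_k;
with b the distance to the N_k-th nearest unit, w = (1−(d/b)²)² for
d < b, ties at b excluded) is the default, following the standard
adaptive-kernel choice in locally weighted regression. A fixed Gaussian
kernel (bandwidth = distance) and a uniform all-ones debug kernel are
provided; under the uniform kernel every local fit reproduces the global
NB solution (tested to 1e-5).

**Complexity and AIC.** Effective parameters = trace of the hat-like
matrix S with rows x_i′[X′W_iA_iX]⁻¹X′W_iA_i (+1 for the dispersion when
α is global); AIC = −2·Σ_i lnNB2(y_i; μ̂_i, α̂_i) + 2·trace(S), where
each unit's density uses its own local estimates.

**Bandwidth selection.** Golden-section search over the admissible range
(default [max(p+2, ⌈0.1n⌉), n] for adaptive kernels), with integer
rounding, full caching of evaluations, and termination when the bracket
narrows to one integer; the reported optimum is the best evaluated
probe, so it is never worse than any probe (asserted as an invariant).
Two criteria: the fit's AIC, and leave-one-out CV = Σ_i (y_i − ŷ_(i))²
with the focal weight forced to zero. The two criteria may disagree;
both are reported side by side.

One caveat discovered during development and worth stating plainly: when
α is estimated locally, trace(S) does not count the n free local
dispersions, so the AIC objective under-penalizes small bandwidths and
can select badly overfit local models even on data with constant
coefficients — visible as significant *negative* Moran autocorrelation
in the residuals. The pipeline therefore selects the AIC bandwidth with
α held global (making the complexity accounting coherent) and then fits
the final model with locally varying α at the chosen bandwidth. Under
this scheme, constant-coefficient data select bandwidths at or near the
number of units (the near-global model) while spatially varying data
select strictly interior bandwidths, as they should. `select_bandwidth`
exposes both behaviours via its `global_alpha` flag.

## Model comparison

AIC = −2 ln L̂ + 2k (k = effective parameters for GWNBR), MAD = mean
absolute deviation, RMSE = root mean squared deviation between observed
and fitted counts; RMSE ≥ MAD always (quadratic vs arithmetic mean),
asserted on every run. The comparison table adds the global Moran's I of
each model's residuals — deviance residuals by default (Pearson by
flag) — because a spatial model that has absorbed the spatial structure
should leave approximately uncorrelated residuals.

## Synthetic data generator

The generator is first-class, tested code: it defines the conditions
under which every claim about the estimators is verified.

* **Lattice**: n_side² square zones with cell polygons (so contiguity is
  well defined), row-major stable ids.
* **Covariates**: simultaneous-autoregressive fields x = (I − ρW)⁻¹ε on
  the row-standardized queen graph, standardized to zero mean and unit
  variance so preset coefficient magnitudes are comparable; ρ controls
  clustering strength.
* **Counts**: gamma–Poisson mixture with gamma shape 1/α, so the NB2
  variance μ + αμ² holds exactly; coefficient surfaces (constant, linear
  gradient, Gaussian bump) are recorded per unit as ground truth.
* **paper_like preset** (default 14×14 = 196 zones): an intercept
  hotspot (Gaussian bump, base ln 6.5, amplitude 2.4) over three SAR
  covariates (ρ = 0.7, 0.6, 0.5) with gradient/constant coefficient
  surfaces and α = 0.45. Across seeds this yields counts with mean ≈ 16,
  standard deviation ≈ 26 and maxima of order a few hundred — the
  structure of a national district-level motorcycle-crash table with one
  dominant urban centre. These values are the preset's definition, fixed
  here, not free knobs.
* **gradient preset** (default 20×20 = 400 zones, α = 0.5): one SAR
  covariate whose coefficient ramps linearly across the map — the
  recovery benchmark for the locally weighted fit.
* **constant preset** (β0 = ln 16, α = 1): the moment-recovery and
  dispersion-calibration benchmark.

What the generator does **not** emulate: irregular polygon geometries
and island units, heavy-tailed covariates, measurement error and crash
under-reporting, exposure heterogeneity (t = 1 throughout), and real
administrative geography. Passing tests therefore demonstrate
correctness of the estimators under a known NB2 data-generating process
with smooth coefficient surfaces on a regular lattice — not that any
particular real-world dataset satisfies those assumptions.

## Numerical conventions

* All randomness flows through `numpy.random.default_rng(seed)`; equal
  seeds give bit-identical studies, permutation inferences and fits.
* α is bounded to [1e-8, 1e4]; simulated means above 1e12 raise rather
  than silently overflowing.
* Degenerate inputs fail loudly with specific errors: constant variables
  in Moran statistics, rank-deficient designs, coincident coordinates
  that collapse a kernel bandwidth, fewer than p+2 positive local
  weights, empty models after screening.
* Golden-section probes on integer bandwidths are rounded and cached;
  tied radius distances get zero kernel weight.

## Known limitations

* The per-unit α update is a profile step at the current β, not a full
  joint Newton step; it is robust but can need many outer iterations at
  very small bandwidths.
* Effective parameters ignore the locally varying α (see the bandwidth
  caveat above); absolute GWNBR AIC values are therefore not comparable
  across software with different complexity conventions.
* Only Euclidean geometry is supported: no spherical distances, network
  distances, or CRS re-projection; supply projected coordinates.
* No semi-parametric (mixed) variant with some coefficients held global;
  no zero-inflated or hurdle families.
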