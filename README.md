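# areakrig

Deriving small-area (neighbourhood-level) health indicators from
individual-level survey points, and using them as exposures in a two-level
model of a binary birth outcome.

## The problem

Community health surveys are designed for inference at the health-region
level: their respondents cluster in cities and towns, and many small census
areas contain few or no sample points, so survey variables cannot simply be
averaged within each small area. When the variables are spatially
autocorrelated, geostatistical interpolation can bridge the gap: predict the
variable on a fine regular grid from the scattered respondent locations, then
average the grid cells inside each small-area polygon. `areakrig` implements
that workflow end to end for researchers in spatial epidemiology and health
geography, together with the synthetic data generators needed to exercise it
without access to restricted survey microdata.

## Methods at the core

* **Screening** — global Moran's I with inverse-distance-squared weights
  truncated at the largest nearest-neighbour distance,
  `I = (n/S0) · Σᵢⱼ wᵢⱼ(zᵢ−z̄)(zⱼ−z̄) / Σᵢ(zᵢ−z̄)²`, with the
  randomization- or normality-assumption variance, Z score, and two-sided
  normal p.
* **Spatial structure** — empirical semi-variogram
  `γ̂(h) = (1/2n_h) Σ (zᵢ−zⱼ)²` binned by lag, fitted by Cressie-weighted
  least squares to exponential / spherical / Gaussian models parameterized by
  nugget `c₀`, partial sill `c` and effective range `a`.
* **Interpolation** — ordinary kriging (weights from
  `[Γ 1; 1ᵀ 0][w; λ] = [γ₀; 1]`, prediction standard error
  `√(wᵀγ₀ + λ)`), universal kriging (polynomial trend + kriged residuals),
  and Shepard/Liszka inverse-distance weighting, all over a configurable
  neighbourhood (default: 50 nearest neighbours).
* **Selection** — leave-one-out cross-validation (mean error, RMSE, average
  standard error, standardized statistics) and RMSE ranking.
* **Aggregation** — grid prediction, then per-polygon averaging of cell
  values and cell variances (`NB_RISK_j`, `NB_VARIANCE_j`).
* **Outcome model** — the two-level random-intercept logistic model
  `logit(p_ij) = γ₀₀ + γ₀₁·NB_RISK_j + u₀ⱼ + Σβ_m x_mij`,
  `u₀ⱼ ~ N(0, σ_u²)`, fitted by marginal maximum likelihood with adaptive
  Gauss–Hermite quadrature; optionally the exposure is treated as latent,
  `NB_VAR_j ~ N(NB_RISK_j, NB_VARIANCE_j)`, and marginalized by a product
  quadrature rule.

## Worked example

```python
import numpy as np
from areakrig.synthetic_data import default_scenario
from areakrig.core_geo import max_min_neighbor_distance
from areakrig.autocorr import idw_weights_matrix, morans_i
from areakrig.variogram import empirical_variogram, fit_variogram
from areakrig.evaluate import InterpolatorSpec, loocv
from areakrig.interpolate import NeighborhoodSpec

# income-like field; duplicate_rate=0 skips the shared-postal-code
# co-location (the full pipeline keeps it and jitters before screening)
region, pts = default_scenario(seed=1, n_points=1000, duplicate_rate=0.0)
W = idw_weights_matrix(pts, power=2,
                       threshold=max_min_neighbor_distance(pts))
res = morans_i(pts.variable("HINC"), W)
print(f"Moran's I = {res.I:.4f}  Z = {res.z:.2f}  p = {res.p:.2e}")

emp = empirical_variogram(pts, pts.variable("HINC"), lag_size=1000, n_lags=45)
model = fit_variogram(emp, "exponential")
print(f"nugget {model.nugget:.2f}  partial sill {model.partial_sill:.2f}  "
      f"range {model.range_a:.0f} m")

cv = loocv(pts, "HINC", InterpolatorSpec(method="ok", model=model,
                                         neighborhood=NeighborhoodSpec(k=50)))
print(f"LOOCV rmse {cv.rmse:.3f}  rms standardized {cv.rms_standardized:.3f}")
```

Output:

```
Moran's I = 0.9165  Z = 4.92  p = 8.48e-07
nugget 5.87  partial sill 21.75  range 26753 m
LOOCV rmse 2.939  rms standardized 0.984
```

The field was generated with nugget 5, partial sill 20 and a 20 km effective
range: the screen detects strong positive autocorrelation (inverse-distance
-squared weights emphasize the closest, most correlated pairs, hence the
large index), the fitted variogram recovers the generating structure, and
the RMS standardized error near 1 says the kriging standard errors are well
calibrated.

The same stages run from the shell (`areakrig simulate | moran | variogram |
interpolate | cv | aggregate | mlm | pipeline`); `areakrig pipeline
--config cfg.yaml --out-dir out` executes the whole chain and writes
screening, cross-validation, indicator and regression tables plus a manifest.

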