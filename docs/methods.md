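# Methods

## Scope and model

`areakrig` turns scattered, urban-clustered survey point data into
small-area indicators and feeds them into a two-level outcome model. The
statistical backbone is:

1. a wide-sense-stationary Gaussian model for each continuous survey
   variable, summarized by a semi-variogram γ(h) with nugget c₀, partial
   sill c and effective range a;
2. ordinary kriging as the best linear unbiased predictor under that model,
   with a fixed-size nearest-neighbour search;
3. centre-point aggregation of the predicted grid into polygons;
4. a random-intercept logistic regression linking an individual binary birth
   outcome to the aggregated area exposure.

## Conventions and numerical choices

**Coordinates** are planar metres in a projected CRS throughout; no
geographic math. **Effective-range convention**: the exponential and
Gaussian models include the factor 3 (and 3h²/a²) so that `range_a` is the
distance at which ~95% of the sill is reached; the spherical model reaches
the sill exactly at `range_a`. Fitted ranges are therefore comparable across
model families and with common GIS output.

**Exact interpolation**: γ(0) = 0 — the nugget applies only for h > 0. A
query coinciding with a datum returns that datum with zero kriging standard
error, and the simulated random fields use the matching covariance
C(h) = (c₀+c) − γ(h) (independent nugget on the diagonal). The alternative
(nugget-honouring, smoothing) convention would change predictions only
within the nugget scale at data points; the exact convention keeps the
LOOCV error definition clean. Exactly co-located records are rejected
everywhere with an instruction to run `jitter_duplicates` (uniform angle,
uniform radius < 1 m, seeded), mirroring how shared postal codes are handled
before variogram estimation.

**Variogram fitting** minimizes Σ n_h (γ̂(h) − γ(h))²/γ(h)² (Cressie-style
weights) by L-BFGS-B from 5 deterministic starts spreading the range guess
and the nugget/sill split; bounds c₀ ≥ 0, c > 0, a ∈ (0, 2·max lag]. Lags
with fewer than 10 pairs are excluded (small n_h averages are
unrepresentative). Default lag settings are 200 m × 100 lags, the best
cross-validated setting for the income-like variable; both are per-variable
configuration.

**Anisotropy check**: directional variograms at k·180°/n azimuths with
±90°/n tolerance. The nugget and sill are anchored at the omnidirectional
fit and only the range is re-fitted per direction (a bounded 1-D
optimization): the full 3-parameter fit on a sector's worth of pairs is too
weakly identified, producing heavy-tailed range estimates that would flag
isotropic fields as anisotropic. Isotropy is declared when fitted
directional ranges differ by less than 50% (configurable).

**Kriging system**: dense solve of the (m+1)×(m+1) ordinary-kriging system
per query; weights must sum to 1 within 1e−8 (asserted). Negative weights
are allowed — corrections would change the estimator. Universal kriging
removes a global least-squares polynomial (order 1 or 2, coordinates
centred and scaled) and kriges the residuals; its reported standard error
ignores trend-coefficient uncertainty (regression-kriging approximation),
flagged in the API documentation.

**Cross-validation** excludes the target point from the neighbour search but
does not refit the variogram per fold, matching standard geostatistical
practice and keeping LOOCV O(n) solves.

**Aggregation** assigns each grid cell to the polygon containing its centre
(boundary ties to the lowest area id); the area standard error is
√(mean cell variance), i.e. cell prediction errors are treated as
independent. This ignores the positive spatial covariance of kriging errors
and therefore understates NB_VARIANCE_j somewhat; it is the documented
approximation feeding the measurement-error model. Areas containing no cell
centre default to a single centroid prediction (`empty_rule="centroid"`).
Default grid cell: min(50 m, extent/500), finer than the smallest lag.

## Two-level model estimation

The marginal likelihood integrates the area random intercept out by
*adaptive* Gauss–Hermite quadrature: per area, a Newton search finds the
mode of the integrand, the curvature sets the scale, and 15 nodes (default)
are placed accordingly. The optimizer is L-BFGS-B on (coefficients, log σ_u)
with an analytic quadrature score, followed by Newton polishing steps using
a numerically differentiated Hessian of the score; that Hessian also gives
the observed-information Wald standard errors. p-values use the normal
reference (the area count in the target scenario is large). The fit matches
an independent adaptive-quadrature implementation (lme4::glmer, nAGQ=15) to
~1e−5 in estimates, standard errors and log-likelihood on a frozen test
dataset.

The measurement-error variant treats the area exposure as latent,
NB_VAR_j ~ N(NB_RISK_j, NB_VARIANCE_j), and marginalizes it with outer
Gauss–Hermite nodes (9 by default) around each area's measured value,
re-using the adaptive intercept quadrature inside — a product rule. With all
exposure variances zero the outer rule collapses and the plug-in fit is
reproduced exactly. Two properties of this flat-prior formulation are worth
stating plainly: with *constant* per-area error it is an exact
reparameterization of the plug-in model (γ₀₁²s² is absorbed into σ_u²), so
the exposure coefficient cannot move; with *heterogeneous* per-area error —
the realistic case, since kriging variances vary strongly with local sample
density — precise areas are upweighted and the attenuation of γ₀₁ shrinks
measurably. Estimation is frequentist ML throughout; no priors are
specified, and a fully Bayesian treatment is out of scope.

One exposure is fitted at a time; multi-exposure models are out of scope.
The preterm-birth indicator is an ordinary optional covariate.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *statistical* structure the pipeline assumes:
648 rectangular areas tiling 54 × 48 km, 4,086 survey points with 80% of
them in Gaussian urban clusters (so some rural areas receive no points),
~15% co-located duplicates sharing a group label, latent fields that are
exactly stationary Gaussian with an exponential variogram (nugget 5, partial
sill 20, range 20 km, mean 50 — an income-like variable in $1000 units),
rank-thresholded binary indicators, and birth outcomes from the two-level
logistic model (γ₀₀ = −2.565, γ₀₁ = −0.0087 per $1000, σ_u = 0.3, five
Bernoulli indicator covariates with conventional perinatal effect sizes
0.4/0.3/0.2/1.5/2.0 and prevalences 0.05/0.15/0.49/0.03/0.08, ~8% outcome
prevalence). Cluster count/spread and the duplicate rate are free knobs, not
calibrated claims.

Real survey data differ in ways the generator does not emulate: postal-code
geocoding error is not a 1 m jitter, fields need not be stationary or
Gaussian, income is not normal, survey weights and non-response are absent,
and area populations vary. Passing tests therefore demonstrate that the
machinery is correct under its own assumptions — not that those assumptions
hold for any particular survey.

## Simulation sizes used by tests and the acceptance script

Chosen to exercise each property at the smallest scale where it is
statistically decidable: variogram recovery at n = 1500 over a 60 km square
(10 field draws, lag 1 km × 50); LOOCV calibration and kriging-vs-IDW
ranking at n = 800 clustered points (10 draws, k = 50); aggregation
diagnostics on an 8 × 6 region at n = 300; exposure-coefficient recovery and
Wald coverage at the full 648 areas × 30 births over 100 studies;
measurement-error comparison on an 80-area region with unit-scale exposure
effects, where the flat-prior correction is detectable (see above).

## Known limitations

- Kriging standard errors assume the fitted variogram is the truth; fitting
  uncertainty is not propagated.
- Area-level SEs ignore spatial covariance between cell errors (see above).
- The Moran variance is a normal approximation; permutation p-values are not
  provided.
- The LOOCV neighbourhood excludes only the target record; co-located
  duplicates of the target (pre-jitter) would leak information, which is why
  jittering is enforced upstream.
- Universal kriging standard errors omit trend-estimation variance.
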