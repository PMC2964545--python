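"""Semi-variogram estimation and model fitting.

The semi-variogram gamma(h) is half the expected squared difference between
field values at separation h; kriging weights are built from a fitted
parametric model of it.  Three standard models are provided (exponential,
spherical, gaussian), all in the *effective-range* convention: ``range_a`` is
the distance at which the model reaches ~95% of the sill (exactly the sill
for the spherical), so fitted ranges are directly comparable across kinds and
with GIS-tool output.

gamma(0) is 0 exactly: the nugget applies only for h > 0, which makes
ordinary kriging an exact interpolator at data locations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

KINDS = ("exponential", "spherical", "gaussian")

#: lags with fewer pairs than this are excluded from fitting
MIN_PAIRS_PER_LAG = 10


@dataclass(frozen=True)
class VariogramModel:
    """Parametric semi-variogram: kind + nugget + partial sill + range.

    ``nugget`` (c0) is the semivariance as h -> 0+ (measurement error and
    micro-scale variation, inflated here by co-located postal-code points);
    ``partial_sill`` (c) is the spatially structured variance; ``range_a``
    is the effective range in metres.  Total sill = c0 + c.
    """

    kind: str
    nugget: float
    partial_sill: float
    range_a: float

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.nugget < 0:
            raise ValueError("nugget must be >= 0")
        if self.partial_sill <= 0:
            raise ValueError("partial sill must be > 0")
        if self.range_a <= 0:
            raise ValueError("range must be > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def __call__(self, h) -> np.ndarray:
        return model_gamma(self, h)


@dataclass(frozen=True)
class EmpiricalVariogram:
    """Binned empirical semi-variogram.

    ``gamma`` is NaN for lags with zero pairs (undefined, not zero).
    ``direction`` is ``(azimuth_deg, tolerance_deg)`` for directional
    variograms, None when omnidirectional.
    """

    lag_size: float
    n_lags: int
    lag_centers: np.ndarray
    gamma: np.ndarray
    pair_counts: np.ndarray
    direction: tuple[float, float] | None = None

    @property
    def defined(self) -> np.ndarray:
        return self.pair_counts > 0


def model_gamma(model: VariogramModel, h) -> np.ndarray:
    """Evaluate the model semivariance at separation(s) h (metres).

    gamma(0) = 0 exactly; for h > 0:

    - exponential: c0 + c*(1 - exp(-3h/a))
    - spherical:   c0 + c*(1.5 h/a - 0.5 (h/a)^3) for h <= a, c0 + c beyond
    - gaussian:    c0 + c*(1 - exp(-3 h^2 / a^2))
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("separation distance must be >= 0")
    c0, c, a = model.nugget, model.partial_sill, model.range_a
    r = h / a
    if model.kind == "exponential":
        g = c0 + c * (1.0 - np.exp(-3.0 * r))
    elif model.kind == "spherical":
        g = np.where(r <= 1.0, c0 + c * (1.5 * r - 0.5 * r**3), c0 + c)
    else:  # gaussian
        g = c0 + c * (1.0 - np.exp(-3.0 * r**2))
    return np.where(h == 0.0, 0.0, g)


def _pair_arrays(pts, values):
    """Upper-triangle pair distances, squared value differences and angles."""
    coords = pts.coords
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    if not ok.all():
        coords = coords[ok]
        values = values[ok]
    n = len(values)
    iu, ju = np.triu_indices(n, k=1)
    d = pdist(coords)
    sqdiff = (values[iu] - values[ju]) ** 2
    dx = coords[ju, 0] - coords[iu, 0]
    dy = coords[ju, 1] - coords[iu, 1]
    return d, sqdiff, dx, dy


def empirical_variogram(pts, values, lag_size: float, n_lags: int,
                        direction: tuple[float, float] | None = None) -> EmpiricalVariogram:
    """Bin pairwise squared differences into distance lags.

    Pair (i, j) goes to bin ``floor(d_ij / lag_size)`` when that is below
    ``n_lags``; gamma(h) = sum of squared differences / (2 n_h) per bin.
    With ``direction=(azimuth_deg, tol_deg)`` only pairs whose separation
    vector lies within ``tol`` of the azimuth (axial, i.e. mod 180deg) are
    used.  Lag centres are at ``(k + 0.5) * lag_size``.
    """
    if lag_size <= 0:
        raise ValueError("lag_size must be positive")
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    d, sqdiff, dx, dy = _pair_arrays(pts, values)
    if direction is not None:
        az, tol = direction
        # axial angle of the separation vector, degrees in [0, 180)
        ang = np.degrees(np.arctan2(dy, dx)) % 180.0
        diff = np.abs(ang - (az % 180.0))
        diff = np.minimum(diff, 180.0 - diff)
        keep = diff <= tol
        d, sqdiff = d[keep], sqdiff[keep]
    bins = np.floor(d / lag_size).astype(int)
    inside = bins < n_lags
    bins, sqdiff = bins[inside], sqdiff[inside]
    counts = np.bincount(bins, minlength=n_lags)[:n_lags]
    sums = np.bincount(bins, weights=sqdiff, minlength=n_lags)[:n_lags]
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sums / (2.0 * np.maximum(counts, 1)), np.nan)
    if counts.sum() == 0:
        logger.warning("empirical_variogram: no pairs fell in any lag bin")
    centers = (np.arange(n_lags) + 0.5) * lag_size
    return EmpiricalVariogram(lag_size=float(lag_size), n_lags=int(n_lags),
                              lag_centers=centers, gamma=gamma,
                              pair_counts=counts, direction=direction)


def _wls_objective(params, h, g_emp, n_h, kind):
    c0, c, a = params
    m = VariogramModel(kind=kind, nugget=max(c0, 0.0),
                       partial_sill=max(c, 1e-12), range_a=max(a, 1e-9))
    g_mod = model_gamma(m, h)
    g_mod = np.maximum(g_mod, 1e-12)
    return float(np.sum(n_h * (g_emp - g_mod) ** 2 / g_mod**2))


def fit_variogram(emp: EmpiricalVariogram, kind: str = "exponential",
                  min_pairs: int = MIN_PAIRS_PER_LAG) -> VariogramModel:
    """Weighted-least-squares fit of (nugget, partial sill, range).

    Minimizes ``sum_h n_h * (gamma_emp - gamma_model)^2 / gamma_model^2``
    (Cressie-style weights: trust well-populated short lags most) over
    c0 >= 0, c > 0, 0 < a <= 2 * max lag, from 5 deterministic starts that
    spread the range guess and split the sill between nugget and structure.
    Lags with fewer than ``min_pairs`` pairs are excluded with a warning.
    """
    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}")
    use = emp.defined & np.isfinite(emp.gamma) & (emp.pair_counts >= min_pairs)
    dropped = int(emp.defined.sum() - use.sum())
    if dropped:
        logger.warning("fit_variogram: excluding %d sparse lag(s) (< %d pairs)",
                       dropped, min_pairs)
    h = emp.lag_centers[use]
    g = emp.gamma[use]
    n_h = emp.pair_counts[use].astype(float)
    if use.sum() < 3:
        raise ValueError("fit_variogram needs at least 3 usable lags")

    s_guess = max(float(np.mean(g[-max(3, len(g) // 4):])), 1e-9)
    h_max = float(h.max())
    a_hi = 2.0 * h_max
    starts = [
        (0.0, s_guess, h_max / 3.0),
        (0.0, s_guess, h_max),
        (0.25 * s_guess, 0.75 * s_guess, h_max / 2.0),
        (0.5 * s_guess, 0.5 * s_guess, h_max / 5.0),
        (0.1 * s_guess, 0.9 * s_guess, a_hi * 0.75),
    ]
    bounds = [(0.0, None), (1e-9 * s_guess, None), (1e-6 * h_max, a_hi)]
    best = None
    for x0 in starts:
        res = minimize(_wls_objective, x0, args=(h, g, n_h, kind),
                       method="L-BFGS-B", bounds=bounds)
        if best is None or (res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("fit_variogram: no start converged to a finite objective")
    c0, c, a = best.x
    model = VariogramModel(kind=kind, nugget=max(float(c0), 0.0),
                           partial_sill=max(float(c), 1e-12),
                           range_a=float(a))
    if model.partial_sill < 1e-6 * model.sill or model.range_a <= bounds[2][0] * 1.01:
        logger.warning("fit_variogram: no spatial structure detected "
                       "(partial sill ~ 0 or range at lower bound)")
    return model


def anisotropy_check(pts, values, n_directions: int = 4,
                     lag_size: float = 200.0, n_lags: int = 100,
                     kind: str = "exponential",
                     max_range_ratio: float = 1.5):
    """Directional variograms at evenly spaced azimuths + an isotropy flag.

    Azimuths are ``k * 180 / n_directions`` with angular tolerance
    ``90 / n_directions``; isotropy is declared when the fitted ranges in all
    directions with enough defined lags differ by less than
    ``max_range_ratio`` (max/min), mirroring the sector/ellipse search
    comparison used to justify a purely circular neighbourhood.

    Returns ``(directional_variograms, isotropic_flag, fitted_ranges)``.
    """
    if n_directions < 2:
        raise ValueError("n_directions must be >= 2")
    tol = 90.0 / n_directions
    # anchor nugget and sill on the omnidirectional fit so that only the
    # range is re-estimated per direction: the full 3-parameter fit is too
    # weakly identified on a sector's worth of pairs to compare ranges
    try:
        omni = fit_variogram(empirical_variogram(pts, values, lag_size, n_lags),
                             kind=kind)
    except (ValueError, RuntimeError):
        omni = None
    emps, ranges = [], []
    for k in range(n_directions):
        az = k * 180.0 / n_directions
        e = empirical_variogram(pts, values, lag_size, n_lags, direction=(az, tol))
        emps.append(e)
        usable = (e.pair_counts >= MIN_PAIRS_PER_LAG) & np.isfinite(e.gamma)
        if usable.sum() >= 3 and omni is not None:
            h = e.lag_centers[usable]
            g = e.gamma[usable]
            n_h = e.pair_counts[usable].astype(float)

            def obj(loga):
                m = VariogramModel(kind, omni.nugget, omni.partial_sill,
                                   float(np.exp(loga)))
                gm = np.maximum(model_gamma(m, h), 1e-12)
                return float(np.sum(n_h * (g - gm) ** 2 / gm**2))

            from scipy.optimize import minimize_scalar

            res = minimize_scalar(obj, bounds=(np.log(h.min()),
                                               np.log(2.0 * h.max())),
                                  method="bounded")
            ranges.append(float(np.exp(res.x)))
        else:
            ranges.append(np.nan)
    ranges = np.asarray(ranges)
    finite = ranges[np.isfinite(ranges)]
    if len(finite) >= 2:
        isotropic = bool(finite.max() / finite.min() < max_range_ratio)
    else:
        isotropic = True  # cannot detect a directional effect
        logger.warning("anisotropy_check: fewer than 2 directions fittable")
    return emps, isotropic, ranges
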