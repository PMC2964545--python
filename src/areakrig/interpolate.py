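"""Point prediction: inverse-distance weighting and kriging.

IDW (Shepard's weights ``1/d^p``, or Liszka's smoothed ``1/(d + delta^2)^p``)
is a local deterministic interpolator; ordinary kriging (OK) is the best
linear unbiased predictor under a constant-unknown-mean stationary model,
with weights from the fitted semi-variogram and a Lagrange multiplier
enforcing sum(w) = 1.  Universal kriging (UK) removes a global polynomial
trend first and kriges the residuals.

All predictors operate on a neighbourhood around the query point; the
default is the 50 nearest neighbours by plain Euclidean distance, with
ellipse and sector searches available for anisotropy experiments.

Exact-interpolator convention: gamma(0) = 0, so a query coinciding with a
datum returns that datum with zero kriging standard error.  Negative OK
weights are left uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from areakrig.core_geo import SamplePointSet, knn
from areakrig.variogram import VariogramModel, model_gamma

#: distance below which a query is treated as coinciding with a datum
COINCIDENT_TOL = 1e-9


@dataclass(frozen=True)
class NeighborhoodSpec:
    """How to pick the samples used for one prediction.

    strategy ``"knn"``: the k nearest by Euclidean distance (default k=50).
    strategy ``"ellipse"``: points inside a rotated ellipse
    (``semi_major, semi_minor, azimuth_deg``), thinned to the nearest k when
    more fall inside.  strategy ``"sector"``: the nearest ``quota`` points in
    each of ``n_sectors`` equal angular sectors (k = n_sectors * quota).
    """

    strategy: str = "knn"
    k: int = 50
    semi_major: float | None = None
    semi_minor: float | None = None
    azimuth_deg: float = 0.0
    n_sectors: int | None = None
    quota: int | None = None

    def __post_init__(self):
        if self.strategy not in ("knn", "ellipse", "sector"):
            raise ValueError("strategy must be knn, ellipse or sector")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.strategy == "ellipse" and (self.semi_major is None or self.semi_minor is None):
            raise ValueError("ellipse strategy needs semi_major and semi_minor")
        if self.strategy == "sector" and (self.n_sectors is None or self.quota is None):
            raise ValueError("sector strategy needs n_sectors and quota")


@dataclass(frozen=True)
class Prediction:
    """Predicted value, kriging standard error (None for IDW), and the
    number of neighbours used."""

    value: float
    se: float | None
    n_used: int


def select_neighbors(pts: SamplePointSet, query, spec: NeighborhoodSpec,
                     exclude: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Indices and distances of the neighbourhood for one query.

    ``exclude`` drops one record index before searching (leave-one-out).
    Raises on an empty selection.
    """
    query = np.asarray(query, dtype=float)
    coords = pts.coords
    active = np.arange(len(pts))
    if exclude is not None:
        active = active[active != exclude]
    dx = coords[active, 0] - query[0]
    dy = coords[active, 1] - query[1]
    d = np.hypot(dx, dy)

    if spec.strategy == "knn":
        if spec.k > len(active):
            raise ValueError(f"k={spec.k} exceeds available points {len(active)}")
        order = np.lexsort((pts.ids[active], d))[: spec.k]
    elif spec.strategy == "ellipse":
        th = np.radians(spec.azimuth_deg)
        # rotate into the ellipse frame
        u = dx * np.cos(th) + dy * np.sin(th)
        v = -dx * np.sin(th) + dy * np.cos(th)
        inside = (u / spec.semi_major) ** 2 + (v / spec.semi_minor) ** 2 <= 1.0
        cand = np.flatnonzero(inside)
        if len(cand) == 0:
            raise ValueError("no points inside the search ellipse")
        order = cand[np.lexsort((pts.ids[active][cand], d[cand]))][: spec.k]
    else:  # sector
        ang = np.degrees(np.arctan2(dy, dx)) % 360.0
        width = 360.0 / spec.n_sectors
        sector = np.minimum((ang // width).astype(int), spec.n_sectors - 1)
        chosen = []
        for s in range(spec.n_sectors):
            cand = np.flatnonzero(sector == s)
            if len(cand) == 0:
                continue
            take = cand[np.lexsort((pts.ids[active][cand], d[cand]))][: spec.quota]
            chosen.append(take)
        if not chosen:
            raise ValueError("no points in any sector")
        order = np.concatenate(chosen)
        order = order[np.lexsort((pts.ids[active][order], d[order]))]
    return active[order], d[order]


def idw_predict(query, coords: np.ndarray, values: np.ndarray,
                power: float = 2.0, variant: str = "shepard",
                delta2: float = 0.0) -> Prediction:
    """Inverse-distance-weighted prediction from a neighbour set.

    Shepard: ``w_i = 1/d_i^p`` — exact at data points (a zero distance
    short-circuits to that datum).  Liszka: ``w_i = 1/(d_i + delta2)^p`` —
    the smoothing constant delta2 (same length units as d) absorbs
    positional/measurement error; as delta2 -> infinity the prediction tends
    to the plain neighbour mean.
    """
    if power <= 0:
        raise ValueError("power must be positive")
    if variant not in ("shepard", "liszka"):
        raise ValueError("variant must be 'shepard' or 'liszka'")
    if variant == "liszka" and delta2 < 0:
        raise ValueError("delta2 must be >= 0")
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("need at least one neighbour")
    query = np.asarray(query, dtype=float)
    d = np.hypot(coords[:, 0] - query[0], coords[:, 1] - query[1])
    at = d <= COINCIDENT_TOL
    if variant == "shepard" and at.any():
        vals = values[at]
        if np.ptp(vals) > 0:
            raise ValueError("conflicting values at zero distance; jitter first")
        return Prediction(value=float(vals[0]), se=None, n_used=len(values))
    eff = d if variant == "shepard" else d + delta2
    if np.any(eff == 0.0):
        vals = values[eff == 0.0]
        if np.ptp(vals) > 0:
            raise ValueError("conflicting values at zero distance; jitter first")
        return Prediction(value=float(vals[0]), se=None, n_used=len(values))
    w = 1.0 / eff**power
    return Prediction(value=float(np.sum(w * values) / np.sum(w)),
                      se=None, n_used=len(values))


def ok_system(neighbor_coords: np.ndarray, query,
              model: VariogramModel) -> tuple[np.ndarray, float, np.ndarray]:
    """Solve the ordinary-kriging system for one query.

    Builds the (m+1)x(m+1) system ``[Gamma 1; 1' 0][w; lam] = [g0; 1]`` with
    ``Gamma_ij = gamma(d_ij)`` (zero diagonal) and ``g0_i = gamma(d(x_i, x))``
    and returns ``(weights, lagrange multiplier, g0)``.  A tiny ridge is
    applied to Gamma's off-diagonal block if the plain solve is singular;
    persistent singularity (co-located neighbours) is an error.
    """
    from scipy.spatial.distance import cdist

    neighbor_coords = np.asarray(neighbor_coords, dtype=float)
    m = len(neighbor_coords)
    if m < 1:
        raise ValueError("need at least one neighbour")
    query = np.asarray(query, dtype=float)
    D = cdist(neighbor_coords, neighbor_coords)
    if m > 1 and np.min(D[np.triu_indices(m, k=1)]) == 0.0:
        raise ValueError("co-located neighbours make the kriging system "
                         "singular; run jitter_duplicates first")
    G = model_gamma(model, D)
    g0 = model_gamma(model, np.hypot(neighbor_coords[:, 0] - query[0],
                                     neighbor_coords[:, 1] - query[1]))
    A = np.zeros((m + 1, m + 1))
    A[:m, :m] = G
    A[m, :m] = 1.0
    A[:m, m] = 1.0
    b = np.append(g0, 1.0)
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        A[:m, :m] += 1e-10 * np.eye(m)
        try:
            sol = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular kriging system: co-located neighbours? "
                "run jitter_duplicates first") from exc
    w, lam = sol[:m], float(sol[m])
    if abs(w.sum() - 1.0) > 1e-8:
        raise RuntimeError(f"kriging weights sum to {w.sum():.12f}, not 1")
    return w, lam, g0


def ok_predict(query, pts: SamplePointSet, variable: str | np.ndarray,
               model: VariogramModel,
               spec: NeighborhoodSpec = NeighborhoodSpec(),
               exclude: int | None = None) -> Prediction:
    """Ordinary-kriging prediction with neighbourhood search.

    ``variable`` may be a column name or a value array aligned with ``pts``.
    Returns the predicted value and the kriging standard error
    ``sqrt(max(0, w.g0 + lambda))``; a query coinciding with a datum returns
    that datum with se = 0.
    """
    values = pts.variable(variable) if isinstance(variable, str) else np.asarray(variable, dtype=float)
    idx, d = select_neighbors(pts, query, spec, exclude=exclude)
    at = d <= COINCIDENT_TOL
    if at.any():
        return Prediction(value=float(values[idx[at][0]]), se=0.0, n_used=len(idx))
    w, lam, g0 = ok_system(pts.coords[idx], query, model)
    var = float(w @ g0 + lam)
    return Prediction(value=float(w @ values[idx]),
                      se=float(np.sqrt(max(0.0, var))), n_used=len(idx))


def _trend_design(coords: np.ndarray, order: int, scale: tuple) -> np.ndarray:
    x0, y0, s = scale
    x = (coords[:, 0] - x0) / s
    y = (coords[:, 1] - y0) / s
    cols = [np.ones_like(x), x, y]
    if order == 2:
        cols += [x * x, x * y, y * y]
    return np.column_stack(cols)


def fit_trend(pts: SamplePointSet, values: np.ndarray, order: int):
    """Global least-squares polynomial trend in (x, y); returns a callable."""
    if order not in (1, 2):
        raise ValueError("trend_order must be 1 or 2")
    need = 3 if order == 1 else 6
    if len(pts) < need:
        raise ValueError(f"order-{order} trend needs >= {need} points")
    coords = pts.coords
    scale = (coords[:, 0].mean(), coords[:, 1].mean(),
             max(np.ptp(coords[:, 0]), np.ptp(coords[:, 1]), 1.0))
    X = _trend_design(coords, order, scale)
    coef, *_ = np.linalg.lstsq(X, values, rcond=None)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient trend design (degenerate geometry)")

    def trend(q):
        q = np.atleast_2d(np.asarray(q, dtype=float))
        return _trend_design(q, order, scale) @ coef

    return trend, coef


def uk_predict(query, pts: SamplePointSet, variable: str | np.ndarray,
               model: VariogramModel | None = None, trend_order: int = 1,
               spec: NeighborhoodSpec = NeighborhoodSpec(),
               exclude: int | None = None,
               fit_kwargs: dict | None = None) -> Prediction:
    """Universal kriging: global polynomial trend + OK on the residuals.

    ``model`` is the residual variogram; when None it is fitted on the
    detrended values (``fit_kwargs`` forwards lag settings to the fit).  The
    reported standard error comes from the residual OK system only — the
    trend-coefficient uncertainty is ignored (regression-kriging
    approximation).
    """
    values = pts.variable(variable) if isinstance(variable, str) else np.asarray(variable, dtype=float)
    trend, _ = fit_trend(pts, values, trend_order)
    resid = values - trend(pts.coords)
    if model is None:
        from areakrig.variogram import empirical_variogram, fit_variogram

        kw = dict(lag_size=200.0, n_lags=100, kind="exponential")
        kw.update(fit_kwargs or {})
        kind = kw.pop("kind")
        emp = empirical_variogram(pts, resid, **kw)
        model = fit_variogram(emp, kind=kind)
    pred = ok_predict(query, pts, resid, model, spec=spec, exclude=exclude)
    return Prediction(value=float(trend(query)[0] + pred.value),
                      se=pred.se, n_used=pred.n_used)
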