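"""Synthetic study generator.

Emulates the statistical structure of a pooled community-health survey over a
small-area tessellation: ~4,086 geocoded points over ~648 areas, urban
clustering with rural sparsity (some areas receive no points at all),
co-located points from shared postal codes, latent Gaussian random fields
with nugget/sill/range structure reaching the sill near 20,000 m, binary
indicators with moderate positive spatial autocorrelation, and birth records
drawn from a two-level random-intercept logistic model with an area-level
exposure.

Every generator takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from shapely.geometry import box, mapping, shape

from areakrig.core_geo import SamplePointSet
from areakrig.variogram import VariogramModel, model_gamma


@dataclass(frozen=True)
class AreaPolygons:
    """Small-area polygons: a stand-in for census dissemination areas.

    ``area_id`` labels are unique; polygons are non-overlapping and jointly
    cover the study rectangle.
    """

    area_ids: np.ndarray
    geometries: list  # shapely polygons, planar metres

    def __post_init__(self):
        if len(self.area_ids) != len(self.geometries):
            raise ValueError("area_ids and geometries must align")
        if len(np.unique(self.area_ids)) != len(self.area_ids):
            raise ValueError("area ids must be unique")

    def __len__(self):
        return len(self.area_ids)

    @property
    def bounds(self):
        xs0, ys0, xs1, ys1 = zip(*(g.bounds for g in self.geometries))
        return min(xs0), min(ys0), max(xs1), max(ys1)

    def to_geojson(self, path) -> None:
        feats = [
            {"type": "Feature", "properties": {"area_id": str(a)},
             "geometry": mapping(g)}
            for a, g in zip(self.area_ids, self.geometries)
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)

    @classmethod
    def from_geojson(cls, path) -> "AreaPolygons":
        with open(path) as fh:
            gj = json.load(fh)
        ids, geoms = [], []
        for feat in gj["features"]:
            ids.append(feat["properties"]["area_id"])
            geoms.append(shape(feat["geometry"]))
        return cls(area_ids=np.asarray(ids, dtype=object), geometries=geoms)


#: default study scale: 648 rectangular areas tiling ~54 x 48 km,
#: 4,086 survey points, exponential field with sill reached near 20 km
DEFAULT_N_COLS = 27
DEFAULT_N_ROWS = 24
DEFAULT_CELL = 2000.0
DEFAULT_N_POINTS = 4086
DEFAULT_URBAN_SHARE = 0.8
DEFAULT_N_CLUSTERS = 12
DEFAULT_CLUSTER_SD = 2500.0
DEFAULT_DUPLICATE_RATE = 0.15
DEFAULT_FIELD = VariogramModel(kind="exponential", nugget=5.0,
                               partial_sill=20.0, range_a=20000.0)

#: birth-outcome generator defaults: ~5% outcome prevalence at the mean
#: exposure, a modest protective exposure effect per $1000 of income-scaled
#: exposure, and conventional perinatal covariate effects/prevalences
DEFAULT_GAMMA00 = -2.565
DEFAULT_GAMMA01 = -0.0087
DEFAULT_SIGMA_U = 0.3
DEFAULT_BETAS = (0.4, 0.3, 0.2, 1.5, 2.0)
DEFAULT_COV_PREVALENCES = (0.05, 0.15, 0.49, 0.03, 0.08)
COVARIATE_NAMES = ("AGE19", "AGE36", "FEMALE", "MLTIBIRTH", "PRETERMBIRTH")


def make_region(n_cols: int = DEFAULT_N_COLS, n_rows: int = DEFAULT_N_ROWS,
                cell: float = DEFAULT_CELL) -> AreaPolygons:
    """Rectangular tessellation of ``[0, n_cols*cell] x [0, n_rows*cell]``.

    Area ids are ``A0000, A0001, ...`` in row-major order from the lower-left.
    """
    if n_cols < 1 or n_rows < 1:
        raise ValueError("n_cols and n_rows must be >= 1")
    if cell <= 0:
        raise ValueError("cell must be positive")
    ids, geoms = [], []
    k = 0
    for i in range(n_rows):
        for j in range(n_cols):
            ids.append(f"A{k:04d}")
            geoms.append(box(j * cell, i * cell, (j + 1) * cell, (i + 1) * cell))
            k += 1
    return AreaPolygons(area_ids=np.asarray(ids, dtype=object), geometries=geoms)


def sample_survey_locations(region: AreaPolygons, n: int = DEFAULT_N_POINTS,
                            urban_share: float = DEFAULT_URBAN_SHARE,
                            n_clusters: int = DEFAULT_N_CLUSTERS,
                            cluster_sd: float = DEFAULT_CLUSTER_SD,
                            duplicate_rate: float = DEFAULT_DUPLICATE_RATE,
                            seed: int = 0) -> SamplePointSet:
    """Survey point locations: urban clusters + rural background + duplicates.

    ``round(n * urban_share)`` points come from a Gaussian mixture whose
    cluster centres are uniform over the region (spread ``cluster_sd``); the
    remainder are uniform.  Out-of-rectangle draws are rejected and redrawn.
    A ``duplicate_rate`` fraction of points then copy the coordinates and
    group label of a randomly chosen earlier point — the shared-postal-code
    surrogate that jitter_duplicates later separates.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= urban_share <= 1 and 0 <= duplicate_rate <= 1):
        raise ValueError("urban_share and duplicate_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = region.bounds
    n_urban = int(round(n * urban_share))
    centres = np.column_stack([rng.uniform(x0, x1, n_clusters),
                               rng.uniform(y0, y1, n_clusters)])
    pts = np.empty((n, 2))
    filled = 0
    while filled < n_urban:
        need = n_urban - filled
        which = rng.integers(0, n_clusters, need)
        cand = centres[which] + rng.normal(0.0, cluster_sd, (need, 2))
        ok = ((cand[:, 0] >= x0) & (cand[:, 0] <= x1)
              & (cand[:, 1] >= y0) & (cand[:, 1] <= y1))
        cand = cand[ok]
        pts[filled:filled + len(cand)] = cand
        filled += len(cand)
    pts[n_urban:, 0] = rng.uniform(x0, x1, n - n_urban)
    pts[n_urban:, 1] = rng.uniform(y0, y1, n - n_urban)
    order = rng.permutation(n)
    pts = pts[order]

    group = np.array([f"G{i:05d}" for i in range(n)], dtype=object)
    if duplicate_rate > 0 and n > 1:
        dup = np.flatnonzero(rng.random(n) < duplicate_rate)
        dup = dup[dup > 0]
        src = np.array([rng.integers(0, i) for i in dup])
        pts[dup] = pts[src]
        group[dup] = group[src]
    return SamplePointSet(
        ids=np.arange(n),
        x=pts[:, 0], y=pts[:, 1],
        values=pd.DataFrame(index=range(n)),
        group=group,
        cycle=np.full(n, 0, dtype=object),
    )


def grf_covariance(coords: np.ndarray, model: VariogramModel) -> np.ndarray:
    """Dense covariance matrix C(h) = (c0 + c) - gamma(h), variance c0 + c.

    The nugget sits on the diagonal only (gamma(0) = 0 by convention), which
    is the covariance counterpart of the exact-interpolator rule used by the
    kriging solver.
    """
    from scipy.spatial.distance import squareform, pdist

    h = squareform(pdist(coords))
    C = model.sill - model_gamma(model, h)
    np.fill_diagonal(C, model.sill)
    return C


def simulate_grf(pts: SamplePointSet, model: VariogramModel,
                 mean: float = 0.0, seed: int = 0) -> np.ndarray:
    """One draw of a stationary Gaussian random field at the point locations.

    Constant mean, covariance from :func:`grf_covariance`; dense Cholesky
    factorisation (intended for n up to a few thousand).  For h > 0 the
    covariance is ``c * corr(h)`` plus an independent nugget on the diagonal,
    so near-coincident points differ by nugget-scale noise.  Exactly
    coincident points make the matrix singular — jitter first.
    """
    n = len(pts)
    coords = pts.coords
    uniq = len(np.unique(coords.round(12), axis=0))
    if uniq < n:
        raise ValueError("covariance matrix is not positive semi-definite: "
                         "coincident points (jitter_duplicates first)")
    C = grf_covariance(coords, model)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        # tiny regularization for numerically semi-definite cases
        try:
            L = np.linalg.cholesky(C + 1e-8 * model.sill * np.eye(n))
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariance matrix is not positive semi-definite") from exc
    rng = np.random.default_rng(seed)
    return mean + L @ rng.standard_normal(n)


def binarize_latent(latent: np.ndarray, prevalence: float) -> np.ndarray:
    """Threshold a latent field at its empirical (1 - prevalence)-quantile.

    Produces a binary indicator (e.g. "daily smoker") whose observed
    prevalence is within 1/n of the target and which inherits the latent
    field's spatial autocorrelation.  Rank-based, so invariant to monotone
    transforms of the latent values.
    """
    latent = np.asarray(latent, dtype=float)
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    if np.ptp(latent) == 0:
        raise ValueError("latent field is constant; cannot binarize")
    n = len(latent)
    k = int(round(n * prevalence))  # number of ones
    order = np.argsort(latent, kind="stable")
    out = np.zeros(n, dtype=int)
    if k > 0:
        out[order[-k:]] = 1
    return out


def simulate_births(areas: AreaPolygons, nb_risk: np.ndarray,
                    gamma00: float = DEFAULT_GAMMA00,
                    gamma01: float = DEFAULT_GAMMA01,
                    sigma_u: float = DEFAULT_SIGMA_U,
                    betas=DEFAULT_BETAS,
                    covariate_prevalences=DEFAULT_COV_PREVALENCES,
                    n_per_area: int = 30,
                    seed: int = 0) -> pd.DataFrame:
    """Birth records from the two-level random-intercept logistic model.

    Per area j: ``u0j ~ N(0, sigma_u^2)``; per birth i: independent Bernoulli
    covariates, then

        logit(p_ij) = gamma00 + gamma01 * nb_risk_j + u0j + sum_m beta_m x_mij
        LBW_ij ~ Bernoulli(p_ij)

    Returns a DataFrame with columns ``area_id, LBW`` + covariate indicators.
    """
    if sigma_u < 0:
        raise ValueError("sigma_u must be >= 0")
    if n_per_area < 1:
        raise ValueError("n_per_area must be >= 1")
    nb_risk = np.asarray(nb_risk, dtype=float)
    if len(nb_risk) != len(areas):
        raise ValueError("nb_risk must have one value per area")
    betas = np.asarray(betas, dtype=float)
    prevs = np.asarray(covariate_prevalences, dtype=float)
    if len(betas) != len(COVARIATE_NAMES) or len(prevs) != len(COVARIATE_NAMES):
        raise ValueError(f"expected {len(COVARIATE_NAMES)} betas and prevalences")
    rng = np.random.default_rng(seed)
    J = len(areas)
    u = rng.normal(0.0, sigma_u, J)
    n_tot = J * n_per_area
    X = (rng.random((n_tot, len(betas))) < prevs).astype(int)
    area_idx = np.repeat(np.arange(J), n_per_area)
    eta = gamma00 + gamma01 * nb_risk[area_idx] + u[area_idx] + X @ betas
    if not np.isfinite(eta).all():
        raise ValueError("non-finite linear predictor (check nb_risk)")
    y = (rng.random(n_tot) < expit(eta)).astype(int)
    out = pd.DataFrame({"area_id": areas.area_ids[area_idx], "LBW": y})
    for m, name in enumerate(COVARIATE_NAMES):
        out[name] = X[:, m]
    return out


def default_scenario(seed: int = 0, n_points: int = DEFAULT_N_POINTS,
                     n_cols: int = DEFAULT_N_COLS, n_rows: int = DEFAULT_N_ROWS,
                     cell: float = DEFAULT_CELL,
                     field: VariogramModel = DEFAULT_FIELD,
                     field_mean: float = 50.0,
                     variable: str = "HINC",
                     duplicate_rate: float = DEFAULT_DUPLICATE_RATE):
    """Region + survey points carrying one continuous field draw.

    The continuous variable emulates household income in $1000 units: mean
    ~50, spatial structure from ``field``.  Returns ``(region, points)``
    where ``points.values[variable]`` holds the field draw.
    """
    from areakrig.core_geo import jitter_duplicates

    region = make_region(n_cols, n_rows, cell)
    pts = sample_survey_locations(region, n=n_points, seed=seed,
                                  duplicate_rate=duplicate_rate)
    pts = jitter_duplicates(pts, max_offset=1.0, seed=seed + 2)
    z = simulate_grf(pts, field, mean=field_mean, seed=seed + 1)
    values = pts.values.copy()
    values[variable] = z
    return region, SamplePointSet(ids=pts.ids, x=pts.x, y=pts.y,
                                  values=values, group=pts.group, cycle=pts.cycle)
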