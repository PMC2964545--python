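"""Leave-one-out cross-validation and model comparison.

Each sample point is predicted from all the others (the variogram model is
fitted once on the full data, not per fold — standard GIS cross-validation
semantics) and the error summaries used for model selection are reported:
mean error, RMSE, and for kriging the average standard error plus the
standardized statistics.  A well-calibrated kriging model has RMS
standardized error near 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from areakrig.core_geo import SamplePointSet
from areakrig.interpolate import NeighborhoodSpec, idw_predict, ok_predict, select_neighbors, uk_predict
from areakrig.variogram import VariogramModel


@dataclass(frozen=True)
class CVStats:
    """Cross-validation error summaries (one table row per model).

    ``avg_se``, ``mean_standardized`` and ``rms_standardized`` are None for
    methods without a standard error (IDW).
    """

    mean_error: float
    rmse: float
    avg_se: float | None
    mean_standardized: float | None
    rms_standardized: float | None
    n: int

    def __post_init__(self):
        if self.rmse < abs(self.mean_error) - 1e-9:
            raise ValueError("rmse cannot be smaller than |mean error|")


@dataclass(frozen=True)
class InterpolatorSpec:
    """One cross-validation candidate.

    ``method``: ``"ok"``, ``"uk"`` or ``"idw"``; kriging methods need a
    ``model`` (VariogramModel); IDW uses ``power``/``variant``/``delta2``.
    """

    method: str = "ok"
    model: VariogramModel | None = None
    neighborhood: NeighborhoodSpec = NeighborhoodSpec()
    power: float = 2.0
    variant: str = "shepard"
    delta2: float = 0.0
    trend_order: int = 1

    def __post_init__(self):
        if self.method not in ("ok", "uk", "idw"):
            raise ValueError("method must be ok, uk or idw")
        if self.method in ("ok", "uk") and self.model is None:
            raise ValueError(f"{self.method} requires a variogram model")

    def predict(self, query, pts: SamplePointSet, values: np.ndarray,
                exclude: int | None = None):
        if self.method == "ok":
            return ok_predict(query, pts, values, self.model,
                              spec=self.neighborhood, exclude=exclude)
        if self.method == "uk":
            return uk_predict(query, pts, values, self.model,
                              trend_order=self.trend_order,
                              spec=self.neighborhood, exclude=exclude)
        idx, _ = select_neighbors(pts, query, self.neighborhood, exclude=exclude)
        return idw_predict(query, pts.coords[idx], values[idx],
                           power=self.power, variant=self.variant,
                           delta2=self.delta2)


def loocv(pts: SamplePointSet, variable: str | np.ndarray,
          spec: InterpolatorSpec) -> CVStats:
    """Leave-one-out cross-validation of one interpolator configuration.

    For each point i the prediction at x_i uses every point except i; the
    variogram model inside ``spec`` is global (no per-fold refit).  Records
    with a missing value for ``variable`` are excluded.
    """
    values = pts.variable(variable) if isinstance(variable, str) else np.asarray(variable, dtype=float)
    ok_mask = np.isfinite(values)
    if not ok_mask.all():
        pts = pts.subset(ok_mask)
        values = values[ok_mask]
    n = len(pts)
    if spec.neighborhood.strategy == "knn" and n < spec.neighborhood.k + 1:
        raise ValueError(f"LOOCV with k={spec.neighborhood.k} needs at least "
                         f"{spec.neighborhood.k + 1} points, have {n}")
    errors = np.empty(n)
    ses = np.full(n, np.nan)
    coords = pts.coords
    for i in range(n):
        pred = spec.predict(coords[i], pts, values, exclude=i)
        errors[i] = pred.value - values[i]
        if pred.se is not None:
            ses[i] = pred.se
    have_se = np.isfinite(ses).all()
    if have_se:
        zero_se = ses == 0.0
        if np.any(zero_se & (errors != 0.0)):
            raise RuntimeError("zero standard error with nonzero error: "
                               "exactness contract violated")
    mean_error = float(errors.mean())
    rmse = float(np.sqrt(np.mean(errors**2)))
    if have_se and np.all(ses > 0):
        std = errors / ses
        return CVStats(mean_error=mean_error, rmse=rmse,
                       avg_se=float(ses.mean()),
                       mean_standardized=float(std.mean()),
                       rms_standardized=float(np.sqrt(np.mean(std**2))), n=n)
    if have_se:
        # exact predictions everywhere: standardized statistics undefined
        return CVStats(mean_error=mean_error, rmse=rmse,
                       avg_se=float(ses.mean()),
                       mean_standardized=None, rms_standardized=None, n=n)
    return CVStats(mean_error=mean_error, rmse=rmse, avg_se=None,
                   mean_standardized=None, rms_standardized=None, n=n)


def rank_models(entries: list[tuple[str, CVStats]]) -> list[str]:
    """Order candidate models for selection: ascending RMSE, ties by
    ascending |mean error|, then label."""
    if len(entries) < 2:
        raise ValueError("ranking needs at least two candidates")
    return [label for label, _ in
            sorted(entries, key=lambda e: (e[1].rmse, abs(e[1].mean_error), e[0]))]


def surface_vs_reference(values_a: dict, values_b: dict) -> float:
    """Mean squared difference between two per-area value maps.

    Areas present in only one map are dropped pairwise (count logged);
    entirely disjoint id sets are an error.
    """
    import logging

    common = sorted(set(values_a) & set(values_b))
    if not common:
        raise ValueError("area id sets are disjoint")
    dropped = len(set(values_a) | set(values_b)) - len(common)
    if dropped:
        logging.getLogger(__name__).info(
            "surface_vs_reference: dropping %d unmatched area(s)", dropped)
    a = np.array([values_a[k] for k in common], dtype=float)
    b = np.array([values_b[k] for k in common], dtype=float)
    keep = np.isfinite(a) & np.isfinite(b)
    return float(np.mean((a[keep] - b[keep]) ** 2))
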