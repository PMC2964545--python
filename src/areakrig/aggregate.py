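"""Two-step areal derivation: predict a regular grid, average it by polygon.

Step 1 interpolates the variable (and, for kriging, its standard error) at
every cell centre of a regular grid over the study region.  Step 2 assigns
each cell to the polygon containing its centre and averages per polygon,
yielding the area-level indicator and an aggregated standard error — the
exposure and its uncertainty entering the two-level outcome model.

The per-area SE is ``sqrt(mean of cell variances)``, i.e. cell prediction
errors are treated as independent; spatial covariance between cell errors is
ignored (documented approximation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.strtree import STRtree

from areakrig.core_geo import SamplePointSet
from areakrig.evaluate import InterpolatorSpec
from areakrig.synthetic_data import AreaPolygons

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridSpec:
    """Regular prediction grid: origin at the lower-left, row-major cells.

    Cell (i, j) has its centre at ``(x0 + (j+0.5)*cell, y0 + (i+0.5)*cell)``.
    """

    x0: float
    y0: float
    cell: float
    n_cols: int
    n_rows: int

    def __post_init__(self):
        if self.cell <= 0:
            raise ValueError("cell must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one cell")

    @classmethod
    def for_region(cls, region: AreaPolygons, cell: float | None = None) -> "GridSpec":
        """Grid covering the region bounds; default cell is
        ``min(50 m, extent / 500)`` — finer than the smallest lag used."""
        x0, y0, x1, y1 = region.bounds
        if cell is None:
            cell = min(50.0, max(x1 - x0, y1 - y0) / 500.0)
        return cls(x0=x0, y0=y0, cell=float(cell),
                   n_cols=int(np.ceil((x1 - x0) / cell)),
                   n_rows=int(np.ceil((y1 - y0) / cell)))

    def centers(self) -> np.ndarray:
        """(n_rows * n_cols, 2) cell-centre coordinates, row-major."""
        jj, ii = np.meshgrid(np.arange(self.n_cols), np.arange(self.n_rows))
        xs = self.x0 + (jj.ravel() + 0.5) * self.cell
        ys = self.y0 + (ii.ravel() + 0.5) * self.cell
        return np.column_stack([xs, ys])


@dataclass(frozen=True)
class PredictionSurface:
    """Gridded predictions (and optional kriging SEs); NaN = masked/missing."""

    spec: GridSpec
    values: np.ndarray  # (n_rows, n_cols)
    ses: np.ndarray | None = None
    method: str = ""

    def __post_init__(self):
        if self.values.shape != (self.spec.n_rows, self.spec.n_cols):
            raise ValueError("values shape does not match grid spec")
        if self.ses is not None and self.ses.shape != self.values.shape:
            raise ValueError("ses shape does not match grid spec")

    def write_ascii(self, path, field: str = "values") -> None:
        """ESRI ASCII grid output (row 0 of the file is the top row)."""
        arr = self.values if field == "values" else self.ses
        if arr is None:
            raise ValueError("surface has no standard errors")
        with open(path, "w") as fh:
            fh.write(f"ncols {self.spec.n_cols}\n"
                     f"nrows {self.spec.n_rows}\n"
                     f"xllcorner {self.spec.x0}\n"
                     f"yllcorner {self.spec.y0}\n"
                     f"cellsize {self.spec.cell}\n"
                     f"NODATA_value -9999\n")
            out = np.where(np.isfinite(arr), arr, -9999.0)
            for row in out[::-1]:
                fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def predict_grid(pts: SamplePointSet, variable: str | np.ndarray,
                 spec: InterpolatorSpec, grid: GridSpec,
                 mask: AreaPolygons | None = None) -> PredictionSurface:
    """Interpolate every (unmasked) grid-cell centre: step 1 of the two-step
    areal derivation.

    With ``mask`` given, only cells whose centres fall in some polygon are
    predicted; the rest are NaN.
    """
    values = pts.variable(variable) if isinstance(variable, str) else np.asarray(variable, dtype=float)
    centers = grid.centers()
    keep = np.ones(len(centers), dtype=bool)
    if mask is not None:
        assign = assign_cells(centers, mask)
        keep = assign >= 0
    vals = np.full(len(centers), np.nan)
    ses = np.full(len(centers), np.nan)
    has_se = spec.method in ("ok", "uk")
    for i in np.flatnonzero(keep):
        pred = spec.predict(centers[i], pts, values)
        vals[i] = pred.value
        if pred.se is not None:
            ses[i] = pred.se
    shape = (grid.n_rows, grid.n_cols)
    return PredictionSurface(spec=grid, values=vals.reshape(shape),
                             ses=ses.reshape(shape) if has_se else None,
                             method=spec.method)


def assign_cells(centers: np.ndarray, areas: AreaPolygons) -> np.ndarray:
    """Index of the area covering each point; -1 when none.

    A centre on a shared boundary goes to the area with the lowest
    ``area_id`` (deterministic tie rule).
    """
    tree = STRtree(areas.geometries)
    assign = np.full(len(centers), -1, dtype=int)
    pts = [Point(xy) for xy in centers]
    pairs = tree.query(pts, predicate="intersects")
    order = np.argsort(areas.area_ids, kind="stable")
    rank = np.empty(len(areas), dtype=int)
    rank[order] = np.arange(len(areas))
    for pt_i, area_i in zip(*pairs):
        cur = assign[pt_i]
        if cur < 0 or rank[area_i] < rank[cur]:
            assign[pt_i] = area_i
    return assign


@dataclass(frozen=True)
class AreaIndicators:
    """Per-area aggregated value, aggregated SE and cell coverage count."""

    table: pd.DataFrame  # columns: area_id, value, se, n_cells

    def values_dict(self) -> dict:
        return dict(zip(self.table["area_id"], self.table["value"]))

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def aggregate_surface(surface: PredictionSurface, areas: AreaPolygons,
                      empty_rule: str = "centroid",
                      pts: SamplePointSet | None = None,
                      variable: str | np.ndarray | None = None,
                      spec: InterpolatorSpec | None = None) -> AreaIndicators:
    """Average grid cells within each polygon: step 2.

    ``value_j`` is the mean of the cell predictions whose centres fall in
    polygon j; ``se_j = sqrt(mean cell variance)``.  Areas covering no cell
    centre follow ``empty_rule``: ``"centroid"`` makes one extra prediction
    at the polygon centroid (requires ``pts``/``variable``/``spec``),
    ``"missing"`` leaves the area absent (NaN).
    """
    if empty_rule not in ("centroid", "missing"):
        raise ValueError("empty_rule must be 'centroid' or 'missing'")
    centers = surface.spec.centers()
    vals = surface.values.ravel()
    ses = surface.ses.ravel() if surface.ses is not None else None
    defined = np.isfinite(vals)
    assign = assign_cells(centers[defined], areas)
    vals_d = vals[defined]
    ses_d = ses[defined] if ses is not None else None

    rows = []
    n_empty = 0
    for j, aid in enumerate(areas.area_ids):
        in_j = assign == j
        n_cells = int(in_j.sum())
        if n_cells > 0:
            value = float(vals_d[in_j].mean())
            se = (float(np.sqrt(np.mean(ses_d[in_j] ** 2)))
                  if ses_d is not None else None)
        elif empty_rule == "centroid":
            n_empty += 1
            if pts is None or variable is None or spec is None:
                raise ValueError("empty_rule='centroid' needs pts, variable "
                                 "and spec for the fallback prediction")
            c = areas.geometries[j].centroid
            pred = spec.predict((c.x, c.y), pts,
                                pts.variable(variable) if isinstance(variable, str)
                                else np.asarray(variable, dtype=float))
            value = float(pred.value)
            se = float(pred.se) if pred.se is not None else None
        else:
            n_empty += 1
            value, se = np.nan, np.nan
        rows.append({"area_id": aid, "value": value,
                     "se": se if se is not None else np.nan,
                     "n_cells": n_cells})
    if n_empty:
        logger.info("aggregate_surface: %d area(s) contained no cell centre "
                    "(rule=%s)", n_empty, empty_rule)
    return AreaIndicators(table=pd.DataFrame(rows))
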