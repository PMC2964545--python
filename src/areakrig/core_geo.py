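"""Spatial primitives shared by all pipeline stages.

Survey records live in a :class:`SamplePointSet`: projected planar coordinates
in metres, one or more named variables per record, a co-location group label
(postal-code surrogate) and a survey-cycle label.  All distance computations
are Euclidean in the projected plane; there is no geographic (lat/lon) math
anywhere in the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: columns that are structural, not survey variables
_RESERVED = ("id", "x", "y", "group", "cycle")


@dataclass(frozen=True)
class SamplePointSet:
    """Geocoded survey points with per-record variable values.

    Parameters
    ----------
    ids : array of record identifiers (unique)
    x, y : planar coordinates in metres (projected CRS)
    values : DataFrame of variable columns, row-aligned with ``ids``;
        missing values allowed (NaN)
    group : co-location group labels (shared postal-code surrogate)
    cycle : survey-cycle labels
    """

    ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    values: pd.DataFrame
    group: np.ndarray = field(default=None)  # type: ignore[assignment]
    cycle: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        object.__setattr__(self, "ids", np.asarray(self.ids))
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        n = len(self.ids)
        if self.group is None:
            object.__setattr__(self, "group", np.asarray(self.ids).astype(str))
        if self.cycle is None:
            object.__setattr__(self, "cycle", np.zeros(n, dtype=object))
        if not (len(self.x) == len(self.y) == n == len(self.values)):
            raise ValueError("ids, x, y and values must have equal length")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("coordinates must be finite")
        if len(np.unique(self.ids)) != n:
            raise ValueError("record ids must be unique")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) coordinate array."""
        return np.column_stack([self.x, self.y])

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    def variable(self, name: str) -> np.ndarray:
        """Values of one variable as a float array (NaN for missing)."""
        return self.values[name].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "SamplePointSet":
        """Row subset by boolean mask or integer index array."""
        return SamplePointSet(
            ids=self.ids[mask],
            x=self.x[mask],
            y=self.y[mask],
            values=self.values.iloc[np.flatnonzero(mask) if np.asarray(mask).dtype == bool else mask].reset_index(drop=True),
            group=self.group[mask],
            cycle=self.cycle[mask],
        )

    # -- CSV dialect: id,x,y,group,cycle,<var1>,<var2>,... ------------------
    @classmethod
    def from_frame(cls, df: pd.DataFrame, cycle: object | None = None) -> "SamplePointSet":
        """Build from a table in the point-CSV dialect.

        Required columns: ``id, x, y``; ``group``/``cycle`` optional;
        every other column is a survey variable.
        """
        for col in ("id", "x", "y"):
            if col not in df.columns:
                raise ValueError(f"point table missing required column {col!r}")
        var_cols = [c for c in df.columns if c not in _RESERVED]
        n = len(df)
        return cls(
            ids=df["id"].to_numpy(),
            x=df["x"].to_numpy(dtype=float),
            y=df["y"].to_numpy(dtype=float),
            values=df[var_cols].reset_index(drop=True),
            group=(df["group"].to_numpy() if "group" in df else df["id"].astype(str).to_numpy()),
            cycle=(df["cycle"].to_numpy() if "cycle" in df
                   else np.full(n, cycle if cycle is not None else 0, dtype=object)),
        )

    @classmethod
    def read_csv(cls, path) -> "SamplePointSet":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        base = pd.DataFrame({"id": self.ids, "x": self.x, "y": self.y,
                             "group": self.group, "cycle": self.cycle})
        return pd.concat([base, self.values.reset_index(drop=True)], axis=1)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def pool_cycles(tables: list[pd.DataFrame | SamplePointSet]) -> SamplePointSet:
    """Pool point tables from several survey cycles into one set.

    Records are concatenated and restricted to the variables common to every
    cycle; per-cycle provenance is kept in the ``cycle`` field.  Pooling
    cycles is what gives the interpolation a workable sample size when any
    single cycle leaves many small areas empty.

    Raises
    ------
    ValueError
        on empty input, or when the cycles share no variable at all.
    """
    if not tables:
        raise ValueError("pool_cycles requires at least one table")
    sets = [
        t if isinstance(t, SamplePointSet) else SamplePointSet.from_frame(t, cycle=i)
        for i, t in enumerate(tables)
    ]
    schemas = [set(s.variables) for s in sets]
    common = set.intersection(*schemas)
    if not common:
        raise ValueError(
            f"cycles share no variables: schemas {sorted(map(sorted, schemas))}"
        )
    union = set.union(*schemas)
    if common != union:
        logger.warning(
            "pool_cycles: keeping common variables %s; dropping %s",
            sorted(common), sorted(union - common),
        )
    keep = sorted(common)
    # preserve the column order of the first table where possible
    keep = [v for v in sets[0].variables if v in common]
    return SamplePointSet(
        ids=np.concatenate([s.ids for s in sets]),
        x=np.concatenate([s.x for s in sets]),
        y=np.concatenate([s.y for s in sets]),
        values=pd.concat([s.values[keep] for s in sets], ignore_index=True),
        group=np.concatenate([s.group for s in sets]),
        cycle=np.concatenate([np.asarray(s.cycle, dtype=object) for s in sets]),
    )


def jitter_duplicates(pts: SamplePointSet, max_offset: float = 1.0,
                      seed: int = 0) -> SamplePointSet:
    """Displace co-located records by a tiny random offset.

    Shared postal codes geocode multiple records to one representative point;
    exact co-location makes pairwise distances zero, which breaks
    inverse-distance weights and makes kriging systems singular.  Every
    record in a coordinate-duplicate group except the first encountered is
    moved by a uniform angle and a uniform radius in ``(0, max_offset)``;
    records at unique coordinates are untouched.  Values, ids, groups and
    cycles are preserved exactly.  Deterministic given ``seed``.
    """
    if max_offset <= 0:
        raise ValueError("max_offset must be positive")
    rng = np.random.default_rng(seed)
    x = pts.x.copy()
    y = pts.y.copy()
    seen: dict[tuple[float, float], int] = {}
    taken = {(float(a), float(b)) for a, b in zip(x, y)}
    moved = 0
    for i in range(len(x)):
        key = (float(x[i]), float(y[i]))
        if key not in seen:
            seen[key] = i
            continue
        # duplicate: draw until the new spot is itself unoccupied
        while True:
            theta = rng.uniform(0.0, 2.0 * np.pi)
            r = rng.uniform(0.0, max_offset)
            nx, ny = key[0] + r * np.cos(theta), key[1] + r * np.sin(theta)
            if (nx, ny) not in taken:
                break
        x[i], y[i] = nx, ny
        taken.add((nx, ny))
        moved += 1
    if moved:
        logger.info("jitter_duplicates: moved %d co-located records (<= %g m)",
                    moved, max_offset)
        return replace(pts, x=x, y=y)
    return pts


def knn(pts: SamplePointSet, query, k: int) -> tuple[np.ndarray, np.ndarray]:
    """k nearest records to a query location.

    Returns ``(indices, distances)`` sorted by ascending Euclidean distance,
    ties broken by ascending record id for cross-platform determinism.
    """
    n = len(pts)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    tree = cKDTree(pts.coords)
    d, idx = tree.query(np.asarray(query, dtype=float), k=k)
    d = np.atleast_1d(d)
    idx = np.atleast_1d(idx)
    # stable re-order: distance first, record id second
    order = np.lexsort((pts.ids[idx], d))
    return idx[order], d[order]


def max_min_neighbor_distance(pts: SamplePointSet) -> float:
    """Largest nearest-neighbour distance over all points.

    A spatial-weights threshold set to this value guarantees every point has
    at least one neighbour, which is the rule used to pick the Moran's I
    search radius.
    """
    n = len(pts)
    if n < 2:
        raise ValueError("need at least two points")
    tree = cKDTree(pts.coords)
    d, _ = tree.query(pts.coords, k=2)
    return float(d[:, 1].max())
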