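"""Global Moran's I screening with inverse-distance weights.

Spatial interpolation presumes spatial dependence; each candidate survey
variable is screened with global Moran's I under an inverse-distance-squared
weight matrix truncated at a search threshold.  The threshold is normally set
to the largest nearest-neighbour distance so that no point is left without a
neighbour.  Values near +1 indicate clustering, values near -1/(n-1)
randomness; a normal-approximation Z score and two-sided p decide
significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree
from scipy.stats import norm

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpatialWeights:
    """Sparse symmetric inverse-distance weights, no self-weights.

    ``w_ij = 1 / d_ij**power`` for ``d_ij <= threshold``, else 0.
    """

    matrix: sparse.csr_matrix
    power: float
    threshold: float

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def s0(self) -> float:
        """Sum of all weights."""
        return float(self.matrix.sum())


@dataclass(frozen=True)
class MoranResult:
    """Moran's I with its normal-approximation inference.

    ``assumption`` records which variance closed form was used:
    ``"randomization"`` (permutation moments, the common GIS default) or
    ``"normality"``.
    """

    I: float
    expected: float
    variance: float
    z: float
    p: float
    assumption: str
    n: int


def idw_weights_matrix(pts, power: float = 2.0, threshold: float = None) -> SpatialWeights:
    """Inverse-distance weights truncated at a neighbourhood threshold.

    ``threshold=None`` uses :func:`~areakrig.core_geo.max_min_neighbor_distance`
    so every point keeps at least one neighbour.  Zero pairwise distances are
    an error: jitter co-located points first (``jitter_duplicates``).
    """
    from areakrig.core_geo import max_min_neighbor_distance

    if threshold is None:
        threshold = max_min_neighbor_distance(pts)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    coords = pts.coords
    n = len(pts)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=threshold, output_type="ndarray")
    if len(pairs) == 0:
        logger.warning("idw_weights_matrix: threshold %g below all pairwise "
                       "distances; weight matrix is empty", threshold)
        return SpatialWeights(sparse.csr_matrix((n, n)), float(power), float(threshold))
    d = np.hypot(coords[pairs[:, 0], 0] - coords[pairs[:, 1], 0],
                 coords[pairs[:, 0], 1] - coords[pairs[:, 1], 1])
    if np.any(d == 0.0):
        raise ValueError("zero pairwise distance found; run jitter_duplicates "
                         "before building inverse-distance weights")
    w = 1.0 / d**power
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
    data = np.concatenate([w, w])
    W = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
    return SpatialWeights(W, float(power), float(threshold))


def _moments(W: SpatialWeights, z: np.ndarray, assumption: str):
    """E[I] and Var[I] closed forms (Cliff & Ord moments)."""
    n = len(z)
    M = W.matrix
    s0 = W.s0
    A = (M + M.T).tocsr()
    S1 = 0.5 * float(A.multiply(A).sum())
    row = np.asarray(M.sum(axis=1)).ravel()
    col = np.asarray(M.sum(axis=0)).ravel()
    S2 = float(np.sum((row + col) ** 2))
    EI = -1.0 / (n - 1)
    if assumption == "normality":
        var = ((n**2 * S1 - n * S2 + 3 * s0**2)
               / (s0**2 * (n**2 - 1))) - EI**2
    elif assumption == "randomization":
        b2 = n * float(np.sum(z**4)) / float(np.sum(z**2)) ** 2
        num = (n * ((n**2 - 3 * n + 3) * S1 - n * S2 + 3 * s0**2)
               - b2 * ((n**2 - n) * S1 - 2 * n * S2 + 6 * s0**2))
        var = num / ((n - 1) * (n - 2) * (n - 3) * s0**2) - EI**2
    else:
        raise ValueError("assumption must be 'randomization' or 'normality'")
    return EI, var


def morans_i(values, W: SpatialWeights, assumption: str = "randomization",
             row_standardize: bool = False) -> MoranResult:
    """Global Moran's I with normal-approximation inference.

        I = (n / S0) * sum_ij w_ij (z_i - zbar)(z_j - zbar) / sum_i (z_i - zbar)^2

    Records with a missing value are dropped (with their weight rows) and n
    adjusted.  ``row_standardize`` rescales each row of W to sum to 1 before
    computing (off by default: the raw inverse-distance scheme).
    """
    values = np.asarray(values, dtype=float)
    if W.n != len(values):
        raise ValueError("weights and values length mismatch")
    keep = np.isfinite(values)
    if not keep.all():
        logger.info("morans_i: dropping %d record(s) with missing values",
                    int((~keep).sum()))
        idx = np.flatnonzero(keep)
        M = W.matrix[idx][:, idx]
        W = SpatialWeights(M.tocsr(), W.power, W.threshold)
        values = values[keep]
    n = len(values)
    if n < 4:
        raise ValueError("Moran's I inference needs at least 4 points")
    if np.ptp(values) == 0:
        raise ValueError("values are constant; Moran's I undefined")
    M = W.matrix
    if row_standardize:
        rs = np.asarray(M.sum(axis=1)).ravel()
        rs[rs == 0] = 1.0
        M = sparse.diags(1.0 / rs) @ M
        W = SpatialWeights(M.tocsr(), W.power, W.threshold)
    s0 = W.s0
    if s0 == 0:
        raise ValueError("all weights are zero (threshold too small)")
    z = values - values.mean()
    num = float(z @ (M @ z))
    I = (n / s0) * num / float(z @ z)
    EI, var = _moments(W, z, assumption)
    zscore = (I - EI) / np.sqrt(var)
    return MoranResult(I=float(I), expected=float(EI), variance=float(var),
                       z=float(zscore), p=two_sided_p(zscore),
                       assumption=assumption, n=n)


def two_sided_p(z: float) -> float:
    """Two-sided normal p-value: ``2 * (1 - Phi(|z|))``."""
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    return float(2.0 * norm.sf(abs(z)))


def screen_variables(pts, W: SpatialWeights, variables=None,
                     assumption: str = "randomization", alpha: float = 0.05):
    """Moran screening of several variables; the Table-1 workflow.

    Returns a DataFrame with one row per variable (I, variance, Z, p,
    significant flag at ``alpha``).  Non-significant variables are flagged,
    not dropped: downstream stages may still interpolate them with caution.
    """
    import pandas as pd

    variables = variables if variables is not None else pts.variables
    rows = []
    for v in variables:
        res = morans_i(pts.variable(v), W, assumption=assumption)
        rows.append({"variable": v, "I": res.I, "variance": res.variance,
                     "z": res.z, "p": res.p,
                     "significant": res.p < alpha})
    return pd.DataFrame(rows)
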