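"""Genetic landscapes: within-population diversity, among-population
divergence on a Delaunay network, and inverse-distance-weighted surfaces.

Two point statistics are interpolated per species:

* ``pi`` — mean number of pairwise sequence differences among the
  individuals of one population (units: nucleotide differences), placed at
  the population's coordinates;
* ``zi`` — mean proportion of mismatched sites over all cross-population
  sequence pairs for two populations joined by a Delaunay edge, placed at
  the edge midpoint.

Surfaces are interpolated on the full grid by inverse distance weighting
and then cropped to the species' range polygon; composite maps rescale the
per-species surfaces to [0, 1] on either a single shared scale or a
species-specific scale.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import Delaunay, QhullError, cKDTree
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .grid import GridSpec
from .sequences import pairwise_differences, encode

logger = logging.getLogger(__name__)

__all__ = [
    "population_pi",
    "delaunay_network",
    "edge_genetic_distance",
    "IDWInterpolator",
    "idw_interpolate",
    "crop_to_range",
    "composite_scale",
]


def population_pi(sequences: list[str]) -> float:
    """Mean pairwise difference count over all unordered individual pairs.

    Computed in haplotype-frequency-weighted form: collapsing to unique
    sequences with counts c_i, pi = sum_{i<j} c_i c_j d_ij / C(n, 2)
    (within-haplotype pairs contribute 0 differences).
    """
    n = len(sequences)
    if n < 2:
        raise ValueError("pi needs at least 2 sequences")
    uniq: dict[str, int] = {}
    for s in sequences:
        uniq[s] = uniq.get(s, 0) + 1
    seqs = list(uniq)
    counts = np.array([uniq[s] for s in seqs], dtype=float)
    total = 0.0
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            d, _, _ = pairwise_differences(seqs[i], seqs[j])
            total += counts[i] * counts[j] * d
    return total / (n * (n - 1) / 2.0)


def delaunay_network(coords: np.ndarray, jitter: float = 1e-6) -> list[tuple[int, int]]:
    """Delaunay edges (index pairs) over population coordinates.

    Degenerate inputs fall back gracefully: 2 points give the single edge,
    collinear sets give the path graph along the line, and duplicate
    coordinates are deterministically jittered (with a logged warning).
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        return []
    if n == 2:
        return [(0, 1)]
    work = coords.copy()
    _, first_idx, inv = np.unique(work, axis=0, return_index=True, return_inverse=True)
    if len(first_idx) < n:
        logger.warning("duplicate population coordinates jittered by %g degrees", jitter)
        for i in range(n):
            if i not in first_idx:
                work[i] = work[i] + jitter * np.array([i + 1, 2 * i + 1])
    try:
        tri = Delaunay(work)
    except QhullError:
        # collinear: chain points along their principal axis
        center = work.mean(axis=0)
        u, _, vt = np.linalg.svd(work - center, full_matrices=False)
        order = np.argsort((work - center) @ vt[0])
        return [tuple(sorted((int(order[i]), int(order[i + 1])))) for i in range(n - 1)]
    edges: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            edges.add((min(i, j), max(i, j)))
    return sorted(edges)


def edge_genetic_distance(
    seqs_a: list[str],
    seqs_b: list[str],
    coord_a: tuple[float, float],
    coord_b: tuple[float, float],
) -> dict:
    """Mean cross-population mismatch proportion, placed at the edge midpoint."""
    if not seqs_a or not seqs_b:
        raise ValueError("both populations need at least one sequence")
    enc_a = [encode(s) for s in seqs_a]
    enc_b = [encode(s) for s in seqs_b]
    props = [pairwise_differences(x, y)[2] for x in enc_a for y in enc_b]
    return {
        "lon": (coord_a[0] + coord_b[0]) / 2.0,
        "lat": (coord_a[1] + coord_b[1]) / 2.0,
        "value": float(np.mean(props)),
        "kind": "zi",
    }


class IDWInterpolator(RegressorMixin, BaseEstimator):
    """Inverse-distance-weighted interpolation over scattered value points.

    Each prediction is the d^(-power)-weighted mean of the ``k`` nearest
    sample values (planar Euclidean distance in degrees); a query within
    ``exact_tol`` of a sample point returns that sample's value exactly.

    Parameters
    ----------
    power : float, default 2.0
        Distance-decay exponent (> 0).
    k : int, default 12
        Number of nearest neighbours contributing to each cell.
    exact_tol : float, default 1e-9
        Distance below which a query snaps to the sample value.
    """

    def __init__(self, power: float = 2.0, k: int = 12, exact_tol: float = 1e-9):
        self.power = power
        self.k = k
        self.exact_tol = exact_tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n, 2) lon/lat coordinates")
        if len(X) == 0:
            raise ValueError("at least one value point is required")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if not self.power > 0:
            raise ValueError("power must be > 0")
        self.X_ = X
        self.y_ = y
        self.tree_ = cKDTree(X)
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        check_is_fitted(self, "tree_")
        X = np.asarray(X, dtype=float)
        k = min(self.k, len(self.X_))
        dist, idx = self.tree_.query(X, k=k)
        dist = np.atleast_2d(dist.reshape(len(X), k))
        idx = np.atleast_2d(idx.reshape(len(X), k))
        with np.errstate(divide="ignore"):
            w = dist ** (-self.power)
        exact = dist[:, 0] < self.exact_tol
        vals = np.empty(len(X))
        ok = ~exact
        if ok.any():
            ww = w[ok]
            vals[ok] = (ww * self.y_[idx[ok]]).sum(axis=1) / ww.sum(axis=1)
        if exact.any():
            vals[exact] = self.y_[idx[exact, 0]]
        return vals


def idw_interpolate(
    points: pd.DataFrame, grid: GridSpec, power: float = 2.0, k: int = 12
) -> np.ndarray:
    """IDW surface of a ValuePoint table (columns lon, lat, value) on a grid."""
    est = IDWInterpolator(power=power, k=k).fit(
        points[["lon", "lat"]].to_numpy(), points["value"].to_numpy()
    )
    lons, lats = grid.center_mesh()
    flat = np.column_stack([lons.ravel(), lats.ravel()])
    return est.predict(flat).reshape(grid.shape)


def crop_to_range(raster: np.ndarray, grid: GridSpec, polygon) -> np.ndarray:
    """Set cells whose centers fall outside the polygon to nodata (NaN)."""
    if not polygon.is_valid:
        raise ValueError("invalid range polygon")
    lons, lats = grid.center_mesh()
    inside = shapely.contains_xy(polygon, lons.ravel(), lats.ravel()).reshape(grid.shape)
    out = np.where(inside, raster, np.nan)
    if not inside.any():
        warnings.warn("range polygon is disjoint from the raster; output is all nodata")
    return out


def composite_scale(
    landscapes: dict[str, np.ndarray], mode: str = "global"
) -> dict[str, np.ndarray]:
    """Min-max rescale per-species rasters to [0, 1].

    ``global`` normalizes over the union of all species' non-nodata cells
    (directly comparable colors across species); ``per_species`` normalizes
    each species on its own scale.  Constant rasters map to 0.5.
    """
    if mode not in ("global", "per_species"):
        raise ValueError("mode must be 'global' or 'per_species'")
    if not landscapes:
        raise ValueError("no landscapes to scale")

    def rescale(arr: np.ndarray, lo: float, hi: float) -> np.ndarray:
        if hi - lo < 1e-300:
            return np.where(np.isfinite(arr), 0.5, np.nan)
        return (arr - lo) / (hi - lo)

    if mode == "global":
        pooled = np.concatenate([a[np.isfinite(a)].ravel() for a in landscapes.values()])
        if pooled.size == 0:
            return {sp: a.copy() for sp, a in landscapes.items()}
        lo, hi = float(pooled.min()), float(pooled.max())
        return {sp: rescale(a, lo, hi) for sp, a in landscapes.items()}
    out = {}
    for sp, a in landscapes.items():
        vals = a[np.isfinite(a)]
        if vals.size == 0:
            out[sp] = a.copy()
        else:
            out[sp] = rescale(a, float(vals.min()), float(vals.max()))
    return out
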