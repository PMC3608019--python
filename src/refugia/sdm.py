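"""Hinge-feature maximum-entropy species distribution modelling.

The estimator fits the Gibbs distribution over background cells that
maximizes the L1-penalized presence log-likelihood

    sum_presence eta(x)  -  n_p * log sum_background exp(eta(x))  -  sum_j lambda_j |w_j|

with eta linear in hinge features of the screened climate variables and
lambda_j = beta * s_j / sqrt(n_p) (s_j = feature standard deviation over
presences).  The objective is concave; it is solved as a box-constrained
smooth problem by splitting each weight into positive and negative parts
(L-BFGS-B).  The raw output is the normalized Gibbs density over background
cells; the logistic output maps it into (0, 1) through c*raw/(1 + c*raw)
with c = exp(H), H the entropy of the fitted background distribution.

Supporting steps: greedy |r| < 0.7 collinearity screening of layers, and
background (pseudo-absence) sampling restricted to a fixed-radius buffer
around the genus' known localities.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .grid import GridSpec, RasterStack

logger = logging.getLogger(__name__)

KM_PER_DEGREE = 111.32

__all__ = [
    "screen_variables",
    "BackgroundSet",
    "build_background",
    "HingeBasis",
    "MaxentSDM",
    "fit_entropy_model",
    "project_model",
]


def screen_variables(
    stack: RasterStack,
    background_cells: np.ndarray,
    threshold: float = 0.7,
    priority: list[str] | None = None,
) -> list[str]:
    """Greedy collinearity screen: keep a layer iff |Pearson r| with every
    already-kept layer (over background cells) stays below ``threshold``.

    ``priority`` fixes the order in which layers are considered (first =
    most biologically meaningful); constant layers are dropped with a
    warning.
    """
    order = priority if priority is not None else stack.layer_names
    if len(order) < 2:
        raise ValueError("need at least 2 layers to screen")
    values = {n: stack.layers[n][background_cells[:, 0], background_cells[:, 1]] for n in order}
    kept: list[str] = []
    for name in order:
        v = values[name]
        if np.std(v) == 0:
            warnings.warn(f"layer {name!r} is constant over the background; dropped")
            continue
        if all(abs(np.corrcoef(v, values[k])[0, 1]) < threshold for k in kept):
            kept.append(name)
    return kept


@dataclass
class BackgroundSet:
    """Pseudo-absence cells drawn from the genus-accessible buffer."""

    cells: np.ndarray          # (n, 2) row/col indices
    coords: np.ndarray         # (n, 2) lon/lat of cell centers
    X: np.ndarray              # (n, L) layer values
    layer_names: list[str]
    buffer_km: float
    buffer_mask: np.ndarray    # boolean in-buffer mask on the full grid


def buffer_mask(
    localities: pd.DataFrame, grid: GridSpec, buffer_km: float = 200.0
) -> np.ndarray:
    """Cells whose center lies within ``buffer_km`` of any locality.

    Distances use an equirectangular approximation: 1 degree = 111.32 km,
    with a cosine-latitude correction on longitude.
    """
    lat0 = np.deg2rad(float(localities["lat"].mean()))
    scale = np.array([KM_PER_DEGREE * np.cos(lat0), KM_PER_DEGREE])
    pts = localities[["lon", "lat"]].to_numpy() * scale
    tree = cKDTree(pts)
    lons, lats = grid.center_mesh()
    centers = np.column_stack([lons.ravel(), lats.ravel()]) * scale
    dist, _ = tree.query(centers, k=1)
    return (dist <= buffer_km).reshape(grid.shape)


def build_background(
    localities: pd.DataFrame,
    stack: RasterStack,
    buffer_km: float = 200.0,
    n_background: int = 10000,
    layer_names: list[str] | None = None,
    seed: int = 0,
) -> BackgroundSet:
    """Sample background cells uniformly from the buffered genus region."""
    if len(localities) < 1:
        raise ValueError("need at least one locality to define the buffer")
    names = layer_names or stack.layer_names
    mask = buffer_mask(localities, stack.grid, buffer_km) & stack.finite_mask()
    cells = np.argwhere(mask)
    if len(cells) == 0:
        raise ValueError("buffer contains no usable cells")
    rng = np.random.default_rng(seed)
    if n_background > len(cells):
        warnings.warn(
            f"requested {n_background} background cells but only {len(cells)} available; using all"
        )
        chosen = cells
    else:
        chosen = cells[rng.choice(len(cells), size=n_background, replace=False)]
    chosen = chosen[np.lexsort((chosen[:, 1], chosen[:, 0]))]
    coords = np.array([stack.grid.cell_center(r, c) for r, c in chosen])
    X = stack.values_at_cells(chosen, names)
    return BackgroundSet(
        cells=chosen, coords=coords, X=X, layer_names=names, buffer_km=buffer_km, buffer_mask=mask
    )


class HingeBasis:
    """Forward and reverse hinge features of each variable.

    Forward hinges h(x; k) = max(0, x - k) / (max - k) and reverse hinges
    h'(x; k) = max(0, k - x) / (k - min), with knots at ``n_knots`` equally
    spaced quantiles of the background values per direction; evaluation
    clamps x into the background [min, max] so projections outside the
    training range behave like range-edge values.
    """

    def __init__(self, background_X: np.ndarray, layer_names: list[str], n_knots: int = 30):
        self.layer_names = list(layer_names)
        self.n_knots = n_knots
        self.vmin = background_X.min(axis=0)
        self.vmax = background_X.max(axis=0)
        self.features: list[tuple[int, float, str]] = []  # (var index, knot, direction)
        for j, name in enumerate(self.layer_names):
            v = background_X[:, j]
            if np.std(v) == 0:
                raise ValueError(f"variable {name!r} is constant over the background")
            qs = np.linspace(0.0, 1.0, n_knots + 1)
            knots = np.quantile(v, qs)
            for k in knots[:-1]:  # forward: exclude the max knot (degenerate)
                if self.vmax[j] - k > 0:
                    self.features.append((j, float(k), "forward"))
            for k in knots[1:]:  # reverse: exclude the min knot
                if k - self.vmin[j] > 0:
                    self.features.append((j, float(k), "reverse"))
        if not self.features:
            raise ValueError("no usable hinge features")

    def __len__(self) -> int:
        return len(self.features)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.clip(np.asarray(X, dtype=float), self.vmin, self.vmax)
        out = np.empty((len(X), len(self.features)))
        for f, (j, k, direction) in enumerate(self.features):
            if direction == "forward":
                out[:, f] = np.maximum(0.0, X[:, j] - k) / (self.vmax[j] - k)
            else:
                out[:, f] = np.maximum(0.0, k - X[:, j]) / (k - self.vmin[j])
        return out

    def describe(self) -> list[dict]:
        return [
            {"variable": self.layer_names[j], "knot": k, "direction": d}
            for j, k, d in self.features
        ]


class MaxentSDM(BaseEstimator):
    """L1-penalized hinge-feature maximum-entropy species distribution model.

    Follows the scikit-learn estimator protocol: ``fit(X, y)`` with y = 1
    for presence rows and y = 0 for background rows (X = climate variable
    values), then ``predict_raw`` / ``predict_logistic`` on new variable
    matrices.

    Parameters
    ----------
    beta : float, default 1.0
        Regularization multiplier scaling every lambda_j.
    n_knots : int, default 30
        Hinge knots per direction per variable.
    tol : float, default 1e-5
        Gradient-norm convergence tolerance.
    max_iter : int, default 20000
        Maximum L-BFGS-B iterations.
    layer_names : list of str, optional
        Names of the columns of X (used for projection onto raster stacks).
    """

    def __init__(
        self,
        beta: float = 1.0,
        n_knots: int = 30,
        tol: float = 1e-5,
        max_iter: int = 20000,
        layer_names: list[str] | None = None,
    ):
        self.beta = beta
        self.n_knots = n_knots
        self.tol = tol
        self.max_iter = max_iter
        self.layer_names = layer_names

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (rows = cells, columns = variables)")
        pres = X[y == 1]
        bg = X[y == 0]
        if len(pres) < 5:
            raise ValueError("need at least 5 presence cells")
        if len(bg) < 2:
            raise ValueError("need background cells")
        names = self.layer_names or [f"var{j}" for j in range(X.shape[1])]
        self.basis_ = HingeBasis(bg, names, n_knots=self.n_knots)
        Fp = self.basis_.transform(pres)
        Fb = self.basis_.transform(bg)
        n_p = len(Fp)
        # features nearly constant over presences get a floored spread so the
        # penalty never vanishes and full shrinkage is attainable
        lam = self.beta * np.maximum(Fp.std(axis=0), 0.05) / np.sqrt(n_p)

        sum_fp = Fp.sum(axis=0)
        nf = len(self.basis_)

        def neg_penalized(u: np.ndarray):
            a, b = u[:nf], u[nf:]
            w = a - b
            eta_b = Fb @ w
            lse = logsumexp(eta_b)
            p_b = np.exp(eta_b - lse)
            ll = sum_fp @ w - n_p * lse
            grad_w = sum_fp - n_p * (Fb.T @ p_b)
            val = -(ll) + lam @ (a + b)
            grad = np.concatenate([-grad_w + lam, grad_w + lam])
            return val, grad

        u0 = np.zeros(2 * nf)
        res = minimize(
            neg_penalized,
            u0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(0, None)] * (2 * nf),
            # gradient entries scale with n_presence; tolerance follows suit
            options={"maxiter": self.max_iter, "ftol": 1e-12, "gtol": self.tol * max(1.0, n_p)},
        )
        if not res.success and "ITERATIONS" in str(res.message).upper():
            raise RuntimeError(
                f"maxent fit did not converge in {self.max_iter} iterations: {res.message}"
            )
        self.weights_ = res.x[:nf] - res.x[nf:]
        eta_b = Fb @ self.weights_
        self.log_z_ = float(logsumexp(eta_b))
        p_b = np.exp(eta_b - self.log_z_)
        self.entropy_ = float(-(p_b * np.log(np.clip(p_b, 1e-300, None))).sum())
        self.lambda_ = lam
        self.objective_ = float(-res.fun)
        self.n_presence_ = n_p
        self.n_background_ = len(bg)
        self.n_features_in_ = X.shape[1]
        return self

    def linear_predictor(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        return self.basis_.transform(np.asarray(X, dtype=float)) @ self.weights_

    def predict_raw(self, X) -> np.ndarray:
        """Gibbs density normalized over the training background (sums to 1 there)."""
        return np.exp(self.linear_predictor(X) - self.log_z_)

    def predict_logistic(self, X) -> np.ndarray:
        """Suitability in (0, 1): c*raw / (1 + c*raw), c = exp(background entropy)."""
        raw = self.predict_raw(X)
        c = np.exp(self.entropy_)
        return c * raw / (1.0 + c * raw)

    def predict(self, X) -> np.ndarray:
        return self.predict_logistic(X)

    def penalized_objective(self, weights: np.ndarray, X, y) -> float:
        """Penalized log-likelihood at arbitrary weights (for oracle checks)."""
        check_is_fitted(self, "basis_")
        X = np.asarray(X, dtype=float)
        Fp = self.basis_.transform(X[np.asarray(y) == 1])
        Fb = self.basis_.transform(X[np.asarray(y) == 0])
        eta_b = Fb @ weights
        return float(
            Fp.sum(axis=0) @ weights
            - len(Fp) * logsumexp(eta_b)
            - self.lambda_ @ np.abs(weights)
        )

    def to_dict(self) -> dict:
        check_is_fitted(self, "weights_")
        return {
            "features": self.basis_.describe(),
            "weights": self.weights_.tolist(),
            "log_partition": self.log_z_,
            "entropy": self.entropy_,
            "beta": self.beta,
            "layer_names": self.basis_.layer_names,
            "clamp_min": self.basis_.vmin.tolist(),
            "clamp_max": self.basis_.vmax.tolist(),
        }


def fit_entropy_model(
    presence_X: np.ndarray,
    background: BackgroundSet,
    beta: float = 1.0,
    n_knots: int = 30,
) -> MaxentSDM:
    """Fit a :class:`MaxentSDM` from presence values and a background set."""
    X = np.vstack([presence_X, background.X])
    y = np.concatenate([np.ones(len(presence_X)), np.zeros(len(background.X))])
    model = MaxentSDM(beta=beta, n_knots=n_knots, layer_names=background.layer_names)
    return model.fit(X, y)


def project_model(
    model: MaxentSDM, stack: RasterStack
) -> tuple[np.ndarray, np.ndarray]:
    """Project a fitted model onto any scenario stack.

    Returns ``(raw, logistic)`` rasters; nodata cells stay NaN.  Values
    outside the training range are clamped to the background envelope by the
    hinge basis.
    """
    check_is_fitted(model, "weights_")
    for name in model.basis_.layer_names:
        if name not in stack.layers:
            raise ValueError(f"scenario stack is missing layer {name!r}")
    mask = stack.finite_mask()
    cells = np.argwhere(mask)
    X = stack.values_at_cells(cells, model.basis_.layer_names)
    raw = np.full(stack.grid.shape, np.nan)
    logistic = np.full(stack.grid.shape, np.nan)
    raw[mask] = model.predict_raw(X)
    logistic[mask] = model.predict_logistic(X)
    return raw, logistic
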