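"""Moran's Eigenvector Maps (MEMs) and eigenvector-based spatial detrending.

A spatial weighting matrix (SWM) ``W`` encodes which plots are neighbours and
with what weight.  Double-centering ``W`` with ``H = I - J/n`` and
eigendecomposing ``H W H`` yields orthogonal, zero-mean spatial patterns (the
MEMs); the Moran's I of eigenvector ``v_k`` equals ``(n / sum(W)) * lambda_k``,
so large positive eigenvalues correspond to broad-scale positive spatial
autocorrelation.

The SWM is picked from a candidate grid (distance-threshold graphs crossed
with binary / linear / concave weighting functions, plus union-symmetrized
k-nearest-neighbour graphs) by maximising the adjusted R^2 of a linear model
of the response variables on the full MEM basis.  Significant MEMs are then
chosen per response by forward selection with permutation p-values and a
double stopping rule, and the response is detrended by taking the residuals
of an ordinary least-squares fit on the selected MEMs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .io_formats import PlotCoordinates

_EIG_RTOL = 1e-9  # relative eigenvalue retention threshold


@dataclass
class SpatialWeights:
    W: np.ndarray
    descriptor: str
    params: dict = field(default_factory=dict)
    connected: bool = True

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W must be square")
        if not np.allclose(W, W.T):
            raise ValueError("W must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("W must have a zero diagonal")
        if np.any(W < 0):
            raise ValueError("W must be non-negative")
        if not np.any(W > 0):
            raise ValueError("W must have at least one positive entry")
        self.W = W
        n_comp, _ = connected_components(W > 0, directed=False)
        self.connected = bool(n_comp == 1)


@dataclass
class MEMBasis:
    vectors: np.ndarray   # (n, m), unit-norm columns, zero mean
    values: np.ndarray    # (m,), sorted descending
    weights: SpatialWeights

    @property
    def n_mems(self) -> int:
        return self.vectors.shape[1]

    def positive(self) -> "MEMBasis":
        """Sub-basis of positive-eigenvalue MEMs (positive autocorrelation)."""
        keep = self.values > 0
        return MEMBasis(self.vectors[:, keep], self.values[keep], self.weights)


@dataclass
class DetrendResult:
    response: str
    selected: list[int]            # indices into the basis
    p_values: dict[int, float]
    r2: float
    adj_r2: float
    residuals: np.ndarray          # the detrended variable


def euclidean_distances(coords: Sequence[PlotCoordinates]) -> np.ndarray:
    if len(coords) < 3:
        raise ValueError("need at least 3 plots for spatial analysis")
    pts = np.array([[c.x, c.y] for c in coords], dtype=float)
    d = squareform(pdist(pts))
    if np.any(d[~np.eye(len(coords), dtype=bool)] == 0):
        raise ValueError("duplicate plot coordinates")
    return d


def candidate_weights(
    dist: np.ndarray,
    n_thresholds: int = 10,
    concavity: float = 2.0,
    knn: bool = True,
) -> list[SpatialWeights]:
    """Default candidate grid of spatial weighting matrices.

    Distance-threshold graphs with dmax sweeping ``n_thresholds`` evenly
    spaced values from the longest minimum-spanning-tree edge (the smallest
    threshold keeping the graph connected) to the maximum pairwise distance,
    each crossed with weighting functions binary, linear ``1 - d/D`` and
    concave ``1 - (d/D)^concavity`` (``D`` the maximum pairwise distance);
    plus binary k-nearest-neighbour graphs, k = 1..n//2, symmetrized by
    union.
    """
    n = dist.shape[0]
    mst = minimum_spanning_tree(dist).toarray()
    d_connect = mst.max()
    d_max = dist.max()
    out: list[SpatialWeights] = []
    for dmax in np.linspace(d_connect, d_max, n_thresholds):
        adj = (dist <= dmax) & (dist > 0)
        # decay scaled by the global maximum so edges at the threshold keep
        # a positive weight (only the single longest pair can reach zero)
        ratio = np.where(adj, dist / d_max, 0.0)
        for fn, Wf in (
            ("binary", adj.astype(float)),
            ("linear", np.where(adj, 1.0 - ratio, 0.0)),
            ("concave", np.where(adj, 1.0 - ratio ** concavity, 0.0)),
        ):
            W = np.asarray(Wf, dtype=float)
            np.fill_diagonal(W, 0.0)
            if np.any(W > 0):
                out.append(SpatialWeights(
                    W, f"dnn(dmax={dmax:.3f},{fn})",
                    {"graph": "distance", "dmax": float(dmax), "weight_fn": fn},
                ))
    if knn:
        order = np.argsort(dist + np.eye(n) * (d_max + 1), axis=1)
        for k in range(1, n // 2 + 1):
            A = np.zeros((n, n))
            rows = np.repeat(np.arange(n), k)
            A[rows, order[:, :k].ravel()] = 1.0
            A = np.maximum(A, A.T)  # union symmetrization
            np.fill_diagonal(A, 0.0)
            out.append(SpatialWeights(
                A, f"knn(k={k})", {"graph": "knn", "k": k, "weight_fn": "binary"},
            ))
    return out


def mem_basis(weights: SpatialWeights) -> MEMBasis:
    """Eigendecompose the doubly-centered SWM; keep eigenpairs with
    ``|lambda| > 1e-9 * max|lambda|``, unit-normalize, orient each vector so
    its first nonzero component is positive, and sort by eigenvalue
    descending."""
    W = weights.W
    n = W.shape[0]
    H = np.eye(n) - np.ones((n, n)) / n
    omega = H @ W @ H
    omega = (omega + omega.T) / 2  # enforce symmetry against roundoff
    vals, vecs = np.linalg.eigh(omega)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = np.abs(vals) > _EIG_RTOL * np.abs(vals).max()
    vals, vecs = vals[keep], vecs[:, keep]
    if vals.size == 0:
        raise ValueError("degenerate spatial weighting matrix: no MEMs")
    vecs = vecs / np.linalg.norm(vecs, axis=0)
    for j in range(vecs.shape[1]):
        nz = np.flatnonzero(np.abs(vecs[:, j]) > 1e-12)
        if nz.size and vecs[nz[0], j] < 0:
            vecs[:, j] = -vecs[:, j]
    return MEMBasis(vecs, vals, weights)


def moran_i(x: np.ndarray, weights: SpatialWeights) -> float:
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    denom = xc @ xc
    if denom == 0:
        raise ValueError("Moran's I undefined for a constant vector")
    W = weights.W
    return float(len(x) / W.sum() * (xc @ W @ xc) / denom)


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    """R^2 of an intercept-included least-squares fit of y on X."""
    n = len(y)
    X1 = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ beta
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return 0.0
    return float(1.0 - np.sum(resid ** 2) / ss_tot)


def adjusted_r2(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        raise ValueError("adjusted R^2 undefined: n - p - 1 <= 0")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def select_swm(
    Y: np.ndarray,
    candidates: list[SpatialWeights],
    nperm: int = 999,
    seed: int = 20200603,
) -> tuple[SpatialWeights, MEMBasis, list[dict]]:
    """Pick the SWM maximising mean adjusted R^2 of the full-MEM model across
    response variables; ties broken by fewer MEMs, then grid order.

    ``Y`` has one column per response.  Candidates whose full basis leaves no
    residual degrees of freedom are evaluated on positive-eigenvalue MEMs
    only and skipped (with a diagnostic row) if still ill-posed.
    """
    if not candidates:
        raise ValueError("no candidate spatial weighting matrices")
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] < Y.shape[1] and Y.ndim == 2 and Y.shape[0] == 1:
        Y = Y.T
    n = Y.shape[0]
    diagnostics: list[dict] = []
    best: tuple[float, int, int] | None = None  # (-adjR2, n_mems, index)
    best_basis: MEMBasis | None = None
    for i, cand in enumerate(candidates):
        basis = mem_basis(cand)
        use = basis
        if n - basis.n_mems - 1 <= 0:
            use = basis.positive()
        if use.n_mems == 0 or n - use.n_mems - 1 <= 0:
            diagnostics.append({"descriptor": cand.descriptor, "adj_r2": None,
                                "n_mems": use.n_mems, "skipped": True})
            continue
        adj = [
            adjusted_r2(_ols_r2(Y[:, j], use.vectors), n, use.n_mems)
            for j in range(Y.shape[1])
        ]
        mean_adj = float(np.mean(adj))
        diagnostics.append({"descriptor": cand.descriptor, "adj_r2": mean_adj,
                            "n_mems": use.n_mems, "skipped": False})
        key = (-mean_adj, use.n_mems, i)
        if best is None or key < best:
            best, best_basis, best_cand = key, use, cand
    if best_basis is None:
        raise ValueError("every candidate was ill-posed")
    for d in diagnostics:
        d["chosen"] = d["descriptor"] == best_cand.descriptor
    return best_cand, best_basis, diagnostics


def significant_mems(
    y: np.ndarray,
    basis: MEMBasis,
    alpha: float = 0.05,
    nperm: int = 999,
    seed: int = 20200603,
    positive_only: bool = True,
) -> tuple[list[int], dict[int, float]]:
    """Forward-select MEMs for one response.

    MEMs (positive-eigenvalue ones by default) are ranked by marginal R^2;
    walking down that ranking, each candidate gets a permutation p-value for
    the R^2 it explains of the current residual, and selection stops when the
    candidate's p exceeds ``alpha`` or the cumulative adjusted R^2 exceeds
    the adjusted R^2 of the full-basis model (double stopping rule).
    Returned indices refer to columns of the *full* basis.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if positive_only:
        index_map = np.flatnonzero(basis.values > 0)
    else:
        index_map = np.arange(basis.n_mems)
    if index_map.size == 0:
        return [], {}
    vectors = basis.vectors[:, index_map]
    m = vectors.shape[1]
    m_full = min(m, n - 2)
    r2_full = _ols_r2(y, vectors[:, :m_full])
    adj_full = adjusted_r2(r2_full, n, m_full)
    marginal = np.array([_ols_r2(y, vectors[:, [j]]) for j in range(m)])
    ranking = np.argsort(marginal)[::-1]
    rng = np.random.default_rng(seed)
    selected: list[int] = []
    p_values: dict[int, float] = {}
    resid = y.copy()
    for j in ranking:
        v = vectors[:, [j]]
        obs = _ols_r2(resid, v)
        perm_ge = 0
        for _ in range(nperm):
            if _ols_r2(rng.permutation(resid), v) >= obs:
                perm_ge += 1
        p = (1 + perm_ge) / (nperm + 1)
        p_values[int(index_map[j])] = p
        if p > alpha:
            break
        selected.append(int(index_map[j]))
        X = basis.vectors[:, selected]
        adj_sel = adjusted_r2(_ols_r2(y, X), n, len(selected))
        resid = _residuals(y, X)
        if adj_sel > adj_full:
            break
    return selected, p_values


def _residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    n = len(y)
    X1 = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    return y - X1 @ beta


def detrend(
    y: np.ndarray,
    basis: MEMBasis,
    selected: Sequence[int],
    response: str = "y",
    p_values: Optional[dict[int, float]] = None,
) -> DetrendResult:
    """OLS of y on the selected MEMs plus intercept; residuals are the
    detrended variable.  Empty selection is a documented passthrough."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    selected = list(selected)
    if not selected:
        return DetrendResult(response, [], p_values or {}, 0.0, 0.0, y.copy())
    X = basis.vectors[:, selected]
    r2 = _ols_r2(y, X)
    adj = adjusted_r2(r2, n, len(selected)) if n - len(selected) - 1 > 0 else np.nan
    return DetrendResult(response, selected, p_values or {}, r2, float(adj),
                         _residuals(y, X))
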