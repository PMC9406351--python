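"""Sample ordination and clustering.

Sammon mapping minimizes the stress

    E = (1 / sum_{i<j} d_ij) * sum_{i<j} (d_ij - D_ij)**2 / d_ij

where d are input-space and D embedded distances; the 1/d weighting
preserves small distances preferentially, which is what separates
time-point clusters within a dose arm.  Optimization is Sammon's diagonal
pseudo-Newton update with step halving (so accepted stress never increases),
initialized from classical MDS coordinates for determinism.

Uncentered Pearson distance (1 - cosine-like correlation without mean
centering) feeds average-linkage hierarchical clustering, exportable as a
Newick tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist, squareform

from .errors import DataError
from .io import ExpressionMatrix

_EPS = 1e-12
_MAGIC = 0.35  # Sammon's step-scaling factor


@dataclass
class SammonEmbedding:
    coords: np.ndarray  # (n, dims)
    stress: float
    n_iter: int
    converged: bool


def sammon_stress(distances: np.ndarray, coords: np.ndarray) -> float:
    """Sammon stress of an embedding against an input distance matrix."""
    d = squareform(np.asarray(distances, dtype=float), checks=False)
    D = pdist(coords)
    c = d.sum()
    return float(((d - D) ** 2 / np.maximum(d, _EPS)).sum() / c)


def _check_distances(distances: np.ndarray) -> np.ndarray:
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise DataError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise DataError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise DataError("distance matrix must have a zero diagonal")
    off = d[~np.eye(d.shape[0], dtype=bool)]
    if (off < 0).any():
        raise DataError("negative distances")
    if (off < _EPS).any():
        import warnings

        warnings.warn(
            "zero off-diagonal distances perturbed by 1e-12 (Sammon weights 1/d)"
        )
        d = d + _EPS * (1.0 - np.eye(d.shape[0]))
        np.fill_diagonal(d, 0.0)
    return d


def classical_mds(distances: np.ndarray, dims: int = 2) -> np.ndarray:
    """Deterministic classical-MDS (principal-coordinate) embedding."""
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(lam)
    # sign convention for determinism: largest-|loading| entry positive
    for k in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, k])))
        if coords[i, k] < 0:
            coords[:, k] = -coords[:, k]
    return coords


def sammon_map(
    distances: np.ndarray,
    dims: int = 2,
    max_iter: int = 500,
    tol: float = 1e-9,
    seed: int | None = None,
    init: np.ndarray | None = None,
) -> SammonEmbedding:
    """Minimize Sammon stress from a classical-MDS start.

    ``seed`` only drives an optional tiny jitter when the MDS start is
    degenerate (coincident points); the optimization itself is deterministic.
    Accepted iterations never increase the stress (step halving).
    """
    d = _check_distances(distances)
    n = d.shape[0]
    if n < 2:
        raise DataError("need at least 2 points")
    y = classical_mds(d, dims) if init is None else np.array(init, dtype=float)
    if np.any(pdist(y) < _EPS):
        rng = np.random.default_rng(0 if seed is None else seed)
        y = y + 1e-6 * rng.standard_normal(y.shape)

    c = squareform(d, checks=False).sum()
    stress = sammon_stress(d, y)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        D = squareform(pdist(y), checks=False)
        np.fill_diagonal(D, 1.0)
        dd = d.copy()
        np.fill_diagonal(dd, 1.0)
        # gradient and diagonal Hessian of E wrt each coordinate
        w = (dd - D) / (D * dd)  # (n, n), zero-ish diagonal handled below
        np.fill_diagonal(w, 0.0)
        diff = y[:, None, :] - y[None, :, :]  # (n, n, dims)
        grad = -2.0 / c * np.einsum("ij,ijk->ik", w, diff)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = (
                1.0
                / (D * dd)
                * ((dd - D) - diff.transpose(2, 0, 1) ** 2 / D * (1.0 + (dd - D) / D))
            )
        h = np.nan_to_num(h)
        for k in range(dims):
            np.fill_diagonal(h[k], 0.0)
        hess = -2.0 / c * h.sum(axis=2).T  # (n, dims)
        step = grad / np.maximum(np.abs(hess), _EPS)

        # step halving preserves the descent property
        accepted = False
        scale = _MAGIC
        for _ in range(20):
            y_new = y - scale * step
            s_new = sammon_stress(d, y_new)
            if s_new <= stress:
                accepted = True
                break
            scale *= 0.5
        if not accepted:
            converged = True
            break
        rel = (stress - s_new) / max(stress, _EPS)
        y, stress = y_new, s_new
        if rel < tol:
            converged = True
            break
    return SammonEmbedding(coords=y, stress=stress, n_iter=it, converged=converged)


def uncentered_pearson_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - sum(x*y) / (||x|| * ||y||); in [0, 2], 0 iff proportional (+)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("vectors must be equal-length 1-D")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise DataError("uncentered Pearson distance undefined for all-zero vector")
    return float(1.0 - float(x @ y) / (nx * ny))


def uncentered_pearson_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise uncentered Pearson distances between columns of ``values``."""
    v = np.asarray(values, dtype=float)
    norms = np.linalg.norm(v, axis=0)
    if (norms == 0).any():
        raise DataError("uncentered Pearson distance undefined for all-zero vector")
    corr = (v.T @ v) / np.outer(norms, norms)
    dmat = 1.0 - corr
    np.fill_diagonal(dmat, 0.0)
    return np.clip(dmat, 0.0, 2.0)


def hier_cluster(distances: np.ndarray, method: str = "average") -> np.ndarray:
    """Agglomerative clustering on a distance matrix; returns a linkage matrix.

    Deterministic: scipy's nearest-neighbor chain breaks ties by the smallest
    index pair.
    """
    d = np.asarray(distances, dtype=float)
    if d.shape[0] < 2:
        raise DataError("need at least 2 samples to cluster")
    return linkage(squareform(d, checks=False), method=method)


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Export a scipy linkage matrix as a Newick string with branch lengths."""
    tree = to_tree(link)

    def _recurse(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = _recurse(node.left, node.dist)
        right = _recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return _recurse(tree, tree.dist) + ";"


def expression_distances(
    matrix: ExpressionMatrix,
    metric: str = "euclidean",
    top_n_variable: int | None = 500,
) -> np.ndarray:
    """Sample-pairwise distances, optionally on the most variable genes only.

    ``metric`` is 'euclidean' (default for ordination runs) or
    'uncentered_pearson' (the clustering distance).
    """
    values = matrix.values
    if top_n_variable is not None and top_n_variable < matrix.n_probes:
        variances = values.var(axis=1)
        keep = variances.nlargest(top_n_variable).index
        values = values.loc[keep]
    arr = values.to_numpy(dtype=float)
    if metric == "euclidean":
        return squareform(pdist(arr.T))
    if metric == "uncentered_pearson":
        return uncentered_pearson_matrix(arr)
    raise DataError(f"unknown metric {metric!r}")
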