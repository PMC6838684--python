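"""Adaptive-kernel affinity graphs, data-diffusion imputation and diffusion maps.

The geometric engine for the whole package.  Cell-cell affinities use an
adaptive Gaussian kernel: for cell *i* the bandwidth sigma_i is the distance to
its ka-th nearest neighbor, affinities exp(-(d/sigma_i)^2) are assigned to the
k nearest neighbors, and the matrix is symmetrized by averaging.  Row
normalization yields a diffusion operator M; powering it smooths ("imputes")
expression; its spectrum gives diffusion components, with multiscale
coordinates scaled by lambda/(1-lambda) so that Euclidean distance in the
selected components approximates multi-scale diffusion distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse
from scipy.linalg import eigh
from sklearn.neighbors import NearestNeighbors

from .sc_preprocess import ExpressionMatrix

logger = logging.getLogger("dc2scape")


@dataclass
class AffinityGraph:
    """Symmetric non-negative cell-cell affinity matrix with its kernel params."""

    weights: sparse.csr_matrix
    k: int
    ka: int

    def __post_init__(self) -> None:
        W = sparse.csr_matrix(self.weights)
        asym = abs(W - W.T)
        if asym.nnz and asym.max() > 1e-12:
            raise ValueError("affinity matrix must be symmetric")
        if W.nnz and W.data.min() < 0:
            raise ValueError("affinities must be non-negative")
        self.weights = W

    @property
    def n_cells(self) -> int:
        return self.weights.shape[0]


@dataclass
class TransitionOperator:
    """Row-stochastic diffusion operator."""

    matrix: sparse.csr_matrix

    def __post_init__(self) -> None:
        M = sparse.csr_matrix(self.matrix)
        rows = np.asarray(M.sum(axis=1)).ravel()
        if np.any(np.abs(rows - 1) > 1e-10):
            raise ValueError("transition matrix rows must sum to 1")
        self.matrix = M

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]


@dataclass
class DiffusionMap:
    """Nontrivial eigenpairs of the diffusion operator plus multiscale coords."""

    eigenvalues: np.ndarray  # descending, trivial lambda_0 = 1 excluded
    components: np.ndarray  # cells x D right eigenvectors of M
    n_selected: int

    def __post_init__(self) -> None:
        lam = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(lam) > 1e-10):
            raise ValueError("eigenvalues must be in descending order")
        self.eigenvalues = lam

    @property
    def multiscale(self) -> np.ndarray:
        lam = self.eigenvalues
        return self.components * (lam / (1.0 - lam))[None, :]

    def selected_multiscale(self) -> np.ndarray:
        return self.multiscale[:, : self.n_selected]


@dataclass
class StabilityGrid:
    """Median per-gene R^2 of each (k, t) imputation against a reference."""

    k_values: list[int]
    t_values: list[int]
    reference: tuple[int, int]
    median_r2: np.ndarray  # len(k_values) x len(t_values)

    def __post_init__(self) -> None:
        r2 = np.asarray(self.median_r2, dtype=float)
        if np.any(r2 < -1e-9) or np.any(r2 > 1 + 1e-9):
            raise ValueError("R^2 values must lie in [0, 1]")
        self.median_r2 = r2


def adaptive_affinity(embedding: np.ndarray, k: int = 30, ka: int = 10) -> AffinityGraph:
    """Adaptive Gaussian kernel graph on a low-dimensional embedding.

    sigma_i = Euclidean distance from cell i to its ka-th nearest neighbor;
    affinity(i, j) = exp(-(d_ij / sigma_i)^2) for the k nearest neighbors of
    i, self-affinity 1; symmetrized as (A + A^T) / 2.
    """
    X = np.asarray(embedding, dtype=float)
    n = X.shape[0]
    if not (0 < ka < k):
        raise ValueError("require 0 < ka < k")
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    # drop each point itself; under exact duplicates it may appear at any
    # zero-distance position, so remove by index rather than by column
    keep_rows = []
    for i in range(n):
        self_pos = np.flatnonzero(idx[i] == i)
        drop = self_pos[0] if self_pos.size else 0
        cols = np.r_[0:drop, drop + 1: k + 1]
        keep_rows.append(cols)
    rows_idx = np.vstack(keep_rows)
    dist = np.take_along_axis(dist, rows_idx, axis=1)
    idx = np.take_along_axis(idx, rows_idx, axis=1)
    sigma = dist[:, ka - 1].copy()
    if np.any(sigma == 0):
        for i in np.flatnonzero(sigma == 0):
            positive = dist[i][dist[i] > 0]
            if positive.size == 0:
                raise ValueError("cell has no distinct neighbors; duplicate-only data")
            sigma[i] = positive.min()
        logger.warning(
            "adaptive_affinity: zero adaptive bandwidth for %d cells; "
            "fell back to smallest positive neighbor distance",
            int((dist[:, ka - 1] == 0).sum()),
        )
    aff = np.exp(-((dist / sigma[:, None]) ** 2))
    rows = np.repeat(np.arange(n), k)
    A = sparse.csr_matrix((aff.ravel(), (rows, idx.ravel())), shape=(n, n))
    A = A.maximum(sparse.identity(n, format="csr"))  # self-affinity 1
    A = (A + A.T) / 2.0
    return AffinityGraph(weights=A.tocsr(), k=k, ka=ka)


def markov_normalize(graph: AffinityGraph) -> TransitionOperator:
    """Row-normalize affinities into a row-stochastic operator M = D^-1 A."""
    W = graph.weights
    rows = np.asarray(W.sum(axis=1)).ravel()
    if np.any(rows <= 0):
        raise ValueError("isolated cell with zero affinity row sum")
    Dinv = sparse.diags(1.0 / rows)
    return TransitionOperator(matrix=(Dinv @ W).tocsr())


def impute(expr: ExpressionMatrix, op: TransitionOperator, t: int = 4) -> ExpressionMatrix:
    """Diffuse expression t steps: values = M^t X by repeated multiplication."""
    if t < 0:
        raise ValueError("t must be non-negative")
    if op.n_cells != expr.n_cells:
        raise ValueError("operator and expression matrix cell counts differ")
    X = expr.values
    for _ in range(t):
        X = op.matrix @ X
    return replace(expr, values=np.asarray(X), state_tag="imputed")


def imputation_stability(
    expr: ExpressionMatrix,
    embedding: np.ndarray,
    k_values: list[int],
    t_values: list[int],
    reference: tuple[int, int],
    ka_fraction: float = 1 / 3,
) -> StabilityGrid:
    """Median per-gene R^2 between each (k, t) imputation and the reference.

    ``ka`` scales with k (``round(k * ka_fraction)``, floor 1) so the sweep
    varies the neighborhood size coherently.  Zero-variance genes are excluded
    from the median.
    """
    k_ref, t_ref = reference
    if k_ref not in k_values or t_ref not in t_values:
        raise ValueError("reference (k, t) must be contained in the grid")

    def run(k: int, t: int) -> np.ndarray:
        ka = max(1, int(round(k * ka_fraction)))
        op = markov_normalize(adaptive_affinity(embedding, k=k, ka=ka))
        return impute(expr, op, t=t).values

    ref = run(k_ref, t_ref)
    ref_centered = ref - ref.mean(axis=0, keepdims=True)
    ref_sd = ref_centered.std(axis=0)
    grid = np.zeros((len(k_values), len(t_values)))
    cache: dict[int, sparse.csr_matrix] = {}
    for i, k in enumerate(k_values):
        ka = max(1, int(round(k * ka_fraction)))
        if k not in cache:
            cache[k] = markov_normalize(adaptive_affinity(embedding, k=k, ka=ka)).matrix
        M = cache[k]
        X = expr.values
        t_prev = 0
        for j, t in enumerate(sorted(t_values)):
            for _ in range(t - t_prev):
                X = M @ X
            t_prev = t
            jj = t_values.index(t)
            cur = np.asarray(X)
            cur_centered = cur - cur.mean(axis=0, keepdims=True)
            cur_sd = cur_centered.std(axis=0)
            valid = (ref_sd > 0) & (cur_sd > 0)
            if valid.sum() < 2:
                raise ValueError("fewer than 2 genes with variance")
            r = (ref_centered[:, valid] * cur_centered[:, valid]).mean(axis=0) / (
                ref_sd[valid] * cur_sd[valid]
            )
            grid[i, jj] = float(np.median(np.clip(r**2, 0.0, 1.0)))
    return StabilityGrid(
        k_values=list(k_values), t_values=list(t_values), reference=reference,
        median_r2=grid,
    )


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    out = vectors.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] *= -1
    return out


def diffusion_map(graph: AffinityGraph, max_components: int = 10) -> DiffusionMap:
    """Multi-scale diffusion map from the symmetric conjugate of M.

    Eigenpairs of S = D^{-1/2} A D^{-1/2} are computed (dense for small
    graphs, Lanczos otherwise) and mapped back to right eigenvectors of
    M = D^{-1} A.  The trivial stationary eigenvector (lambda = 1) is
    dropped; ``n_selected`` is set at the largest relative eigen gap
    (lambda_i - lambda_{i+1}) / lambda_i and can be overridden by the caller
    by assigning to the returned object.
    """
    n = graph.n_cells
    if max_components >= n:
        raise ValueError("max_components must be smaller than the number of cells")
    W = graph.weights
    rows = np.asarray(W.sum(axis=1)).ravel()
    if np.any(rows <= 0):
        raise ValueError("isolated cell in affinity graph")
    dhalf = 1.0 / np.sqrt(rows)
    S = sparse.diags(dhalf) @ W @ sparse.diags(dhalf)
    want = max_components + 1  # room for the trivial eigenpair
    if n <= 400:
        lam, vec = eigh(np.asarray(S.todense()))
        lam, vec = lam[::-1], vec[:, ::-1]
        lam, vec = lam[:want], vec[:, :want]
    else:
        from scipy.sparse.linalg import eigsh

        lam, vec = eigsh(S.tocsc(), k=want, which="LA", v0=np.ones(n), tol=1e-10)
        order = np.argsort(lam)[::-1]
        lam, vec = lam[order], vec[:, order]
    # multiplicity of the unit eigenvalue flags disconnected components
    n_unit = int(np.sum(lam > 1 - 1e-10))
    if n_unit > 1:
        raise ValueError(
            f"affinity graph is disconnected ({n_unit} components detected); "
            "analyze components separately"
        )
    lam, vec = lam[1:], vec[:, 1:]
    lam = np.clip(lam, None, 1 - 1e-12)
    components = _fix_signs(vec * dhalf[:, None])  # right eigenvectors of M
    # normalize each component to unit norm for scale stability
    components = components / np.linalg.norm(components, axis=0, keepdims=True)
    pos = lam > 1e-12
    lam_pos = lam[pos]
    rel_gap = (lam_pos[:-1] - lam_pos[1:]) / lam_pos[:-1]
    n_selected = int(np.argmax(rel_gap)) + 1 if rel_gap.size else len(lam)
    return DiffusionMap(eigenvalues=lam, components=components, n_selected=n_selected)


class MultiscaleDistances:
    """Pairwise / k-NN Euclidean distance provider on selected multiscale coords."""

    def __init__(self, dm: DiffusionMap, n_components: int | None = None):
        n_comp = dm.n_selected if n_components is None else n_components
        if n_comp < 1:
            raise ValueError("need at least one selected component")
        self.coords = dm.multiscale[:, :n_comp]
        self._nn: NearestNeighbors | None = None

    @classmethod
    def from_coords(cls, coords: np.ndarray) -> "MultiscaleDistances":
        obj = cls.__new__(cls)
        obj.coords = np.atleast_2d(np.asarray(coords, dtype=float))
        if obj.coords.shape[0] == 1:
            obj.coords = obj.coords.T
        obj._nn = None
        return obj

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    def pairwise(self) -> np.ndarray:
        from scipy.spatial.distance import squareform, pdist

        return squareform(pdist(self.coords))

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.coords[i] - self.coords[j]))

    def knn(self, n_neighbors: int) -> tuple[np.ndarray, np.ndarray]:
        """Distances and indices of each cell's n_neighbors nearest others."""
        if self._nn is None:
            self._nn = NearestNeighbors(
                n_neighbors=min(self.n_cells, 64)
            ).fit(self.coords)
        nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(self.coords)
        dist, idx = nn.kneighbors(self.coords)
        return dist[:, 1:], idx[:, 1:]


def multiscale_distances(dm: DiffusionMap, n_components: int | None = None) -> MultiscaleDistances:
    """Distance provider over the selected multiscale diffusion coordinates."""
    return MultiscaleDistances(dm, n_components=n_components)
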