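"""Shortest-path trajectory robustness on diffusion-distance k-NN graphs.

Cells become nodes of a k-nearest-neighbor graph under multi-scale diffusion
distances; the trajectory from a start cell to a terminal cell is the
shortest path.  Robustness is probed with k-l-NN sampling: each cell keeps
only l of its k edges, chosen uniformly at random, and the shortest path is
recomputed on the thinned graph.  Across samples one obtains, per cell, the
probability of lying within the n-nearest-neighborhood of a sampled path, the
cluster composition of those neighborhoods, and step-size profiles whose
outliers would indicate discontinuities between states.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffusion import MultiscaleDistances

logger = logging.getLogger("dc2scape")


@dataclass
class CellGraph:
    """Directed k-NN graph: edges[i] lists (neighbor, distance) for cell i."""

    edges: list[list[tuple[int, float]]]
    k: int
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cell_ids:
            self.cell_ids = [str(i) for i in range(len(self.edges))]
        for out in self.edges:
            if len(out) > self.k:
                raise ValueError("out-degree exceeds k")
            if any(d <= 0 for _, d in out):
                raise ValueError("edge weights must be positive")

    @property
    def n_cells(self) -> int:
        return len(self.edges)

    def undirected_adjacency(self) -> list[dict[int, float]]:
        adj: list[dict[int, float]] = [dict() for _ in range(self.n_cells)]
        for i, out in enumerate(self.edges):
            for j, d in out:
                adj[i][j] = min(adj[i].get(j, np.inf), d)
                adj[j][i] = min(adj[j].get(i, np.inf), d)
        return adj


@dataclass
class PathEnsemble:
    source: int
    target: int
    paths: list[list[int]]  # successful sampled paths (node indices)
    step_sizes: list[list[float]]
    n_samples: int
    n_failures: int
    l: int
    seed: int

    def __post_init__(self) -> None:
        for p in self.paths:
            if p[0] != self.source or p[-1] != self.target:
                raise ValueError("path endpoints do not match ensemble endpoints")

    @property
    def failure_rate(self) -> float:
        return self.n_failures / self.n_samples if self.n_samples else 0.0


def knn_graph(distances: MultiscaleDistances, k: int) -> CellGraph:
    """Exact k-NN graph under the distance provider, id-order tie-breaking.

    Ties at the k-th neighbor distance are resolved toward the smaller cell
    index, so the graph is bitwise reproducible.
    """
    n = distances.n_cells
    if k < 1:
        raise ValueError("k must be at least 1")
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    D = distances.pairwise()
    edges: list[list[tuple[int, float]]] = []
    idx = np.arange(n)
    for i in range(n):
        others = idx[idx != i]
        order = np.lexsort((others, D[i, others]))  # distance, then id
        chosen = others[order[:k]]
        edges.append([(int(j), float(D[i, j])) for j in chosen])
    return CellGraph(edges=edges, k=k)


def _dijkstra(adj: list[dict[int, float]], source: int, target: int):
    n = len(adj)
    dist = np.full(n, np.inf)
    # predecessor chosen lexicographically under exact distance ties
    pred = np.full(n, -1, dtype=int)
    dist[source] = 0.0
    heap = [(0.0, source)]
    done = np.zeros(n, dtype=bool)
    while heap:
        d, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        if u == target:
            break
        for v, w in sorted(adj[u].items()):
            nd = d + w
            if nd < dist[v] or (nd == dist[v] and u < pred[v]):
                dist[v] = nd
                pred[v] = u
                heapq.heappush(heap, (nd, v))
    if not np.isfinite(dist[target]):
        return None
    path = [target]
    while path[-1] != source:
        path.append(int(pred[path[-1]]))
    return path[::-1], float(dist[target])


def shortest_path(
    graph: CellGraph, source: int, target: int
) -> tuple[list[int], list[float], float]:
    """Dijkstra shortest path (edges treated as undirected symmetric distances).

    Returns (path node list, per-step distances, total length).  Distance
    ties break toward the lexicographically smaller predecessor.
    """
    adj = graph.undirected_adjacency()
    res = _dijkstra(adj, source, target)
    if res is None:
        comp = _component_of(adj, source)
        raise ValueError(
            f"target {target} unreachable from source {source}; source component "
            f"has {len(comp)} of {graph.n_cells} cells"
        )
    path, total = res
    steps = [adj[a][b] for a, b in zip(path, path[1:])]
    return path, steps, total


def _component_of(adj: list[dict[int, float]], start: int) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return seen


def sample_kl_paths(
    graph: CellGraph,
    source: int,
    target: int,
    l: int = 5,
    n_samples: int = 100,
    seed: int = 0,
) -> PathEnsemble:
    """Shortest paths over random k-l-NN subgraphs.

    Per sample, every cell independently retains l of its k out-edges
    (uniform, without replacement); the shortest path is recomputed on the
    resulting (undirected) subgraph.  Samples where the target is
    unreachable count as failures and are excluded downstream.
    """
    if l > graph.k:
        raise ValueError("l must not exceed k")
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    rng = np.random.default_rng(seed)
    paths: list[list[int]] = []
    steps: list[list[float]] = []
    n_failures = 0
    for _ in range(n_samples):
        adj: list[dict[int, float]] = [dict() for _ in range(graph.n_cells)]
        for i, out in enumerate(graph.edges):
            if len(out) <= l:
                kept = out
            else:
                sel = rng.choice(len(out), size=l, replace=False)
                kept = [out[s] for s in sel]
            for j, d in kept:
                adj[i][j] = min(adj[i].get(j, np.inf), d)
                adj[j][i] = min(adj[j].get(i, np.inf), d)
        res = _dijkstra(adj, source, target)
        if res is None:
            n_failures += 1
            continue
        path, _total = res
        paths.append(path)
        steps.append([adj[a][b] for a, b in zip(path, path[1:])])
    if not paths:
        raise ValueError("target unreachable in every sampled subgraph")
    if n_failures:
        logger.info(
            "sample_kl_paths: %d/%d samples failed to reach the target",
            n_failures, n_samples,
        )
    return PathEnsemble(
        source=source, target=target, paths=paths, step_sizes=steps,
        n_samples=n_samples, n_failures=n_failures, l=l, seed=seed,
    )


def _neighborhoods(
    distances: MultiscaleDistances, n_neighbors: int
) -> np.ndarray:
    """For each cell, indices of its n_neighbors nearest other cells."""
    D = distances.pairwise()
    n = D.shape[0]
    idx = np.arange(n)
    hoods = np.empty((n, n_neighbors), dtype=int)
    for i in range(n):
        others = idx[idx != i]
        order = np.lexsort((others, D[i, others]))
        hoods[i] = others[order[:n_neighbors]]
    return hoods


def path_proximity(
    ensemble: PathEnsemble,
    distances: MultiscaleDistances,
    n_neighbors: int = 20,
    direction: str = "from_path",
) -> pd.Series:
    """Per cell, the probability of lying near a sampled path.

    With ``direction="from_path"`` (default) the proximal set of a sample is
    the union over path nodes of each node's ``n_neighbors``-nearest-cell
    neighborhood (path nodes included).  The dual reading,
    ``direction="from_cell"``, instead asks whether any path node is among
    the cell's own ``n_neighbors`` nearest cells.
    """
    if n_neighbors < 1:
        raise ValueError("n_neighbors must be at least 1")
    n = distances.n_cells
    hoods = _neighborhoods(distances, n_neighbors)
    counts = np.zeros(n)
    for path in ensemble.paths:
        proximal = np.zeros(n, dtype=bool)
        nodes = np.array(path)
        if direction == "from_path":
            proximal[nodes] = True
            proximal[hoods[nodes].ravel()] = True
        elif direction == "from_cell":
            on_path = np.zeros(n, dtype=bool)
            on_path[nodes] = True
            proximal = on_path | on_path[hoods].any(axis=1)
        else:
            raise ValueError("direction must be 'from_path' or 'from_cell'")
        counts += proximal
    return pd.Series(counts / len(ensemble.paths), name="proximity_probability")


def path_membership(
    ensemble: PathEnsemble,
    labels,
    distances: MultiscaleDistances,
    n_neighbors: int = 20,
) -> pd.DataFrame:
    """Per-sample label composition of the path-proximal cell set.

    Returns one row per (sample, label) with the fraction of proximal cells
    carrying the label, plus aggregate mean and SD per label (fractions per
    sample sum to 1).
    """
    labels = np.asarray(pd.Series(labels).astype(str))
    n = distances.n_cells
    if labels.shape[0] != n:
        raise ValueError("labels must cover all cells")
    hoods = _neighborhoods(distances, n_neighbors)
    label_names = sorted(set(labels))
    rows = []
    for si, path in enumerate(ensemble.paths):
        proximal = np.zeros(n, dtype=bool)
        nodes = np.array(path)
        proximal[nodes] = True
        proximal[hoods[nodes].ravel()] = True
        total = int(proximal.sum())
        for lname in label_names:
            frac = float((labels[proximal] == lname).sum() / total)
            rows.append({"sample": si, "label": lname, "fraction": frac})
    df = pd.DataFrame(rows)
    agg = df.groupby("label")["fraction"].agg(["mean", "std"]).fillna(0.0)
    df = df.merge(agg, on="label")
    return df


def step_size_profile(
    steps: list[float], mad_multiplier: float = 5.0
) -> pd.DataFrame:
    """Ordered step distances with outlier flags.

    A step is flagged when it exceeds median + mad_multiplier * MAD of the
    path's steps.  Single-node paths yield an empty profile.
    """
    steps = list(map(float, steps))
    if not steps:
        return pd.DataFrame(columns=["step", "distance", "outlier"])
    arr = np.asarray(steps)
    med = float(np.median(arr))
    mad = float(np.median(np.abs(arr - med)))
    cutoff = med + mad_multiplier * mad
    return pd.DataFrame(
        {
            "step": np.arange(len(steps)),
            "distance": arr,
            "outlier": arr > cutoff,
        }
    )
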