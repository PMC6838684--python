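"""Clustering-stability analysis: consolidation + adjusted Rand index sweeps.

A clustering solution is compared against others obtained under perturbed
parameters (number of PCs fed to the clusterer, neighborhood size k).  Before
comparison, clusters are *consolidated*: any cluster whose plurality of cells
falls inside a named reference group is relabeled to that group, so that
stability is measured at the resolution of the biological populations rather
than of arbitrary fine cluster ids.  Agreement is the Hubert-Arabie adjusted
Rand index over all unordered pairs of solutions along each sweep axis.

Clustering itself is pluggable: any callable ``(embedding, k, seed) ->
Partition`` works; :func:`default_clusterer` offers a k-NN-graph +
greedy-modularity convenience (not a Phenograph reimplementation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import networkx as nx
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger("dc2scape")


@dataclass
class Partition:
    """cell_id -> cluster label mapping (labels are opaque strings)."""

    labels: dict[str, str]

    @classmethod
    def from_arrays(cls, cell_ids, labels) -> "Partition":
        return cls(dict(zip(map(str, cell_ids), map(str, labels))))

    @property
    def cell_ids(self) -> list[str]:
        return list(self.labels)

    def to_array(self, cell_ids: list[str]) -> np.ndarray:
        return np.array([self.labels[c] for c in cell_ids])

    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for cell, lab in self.labels.items():
            out.setdefault(lab, []).append(cell)
        return out


@dataclass
class RobustnessResult:
    n_pcs_values: list[int]
    k_values: list[int]
    ri_pc_mean: float
    ri_pc_sd: float
    ri_k_mean: float
    ri_k_sd: float
    pairwise_pc: pd.DataFrame
    pairwise_k: pd.DataFrame
    reference_groups: dict[str, list[str]]
    failures: list[tuple[str, int, str]] = field(default_factory=list)


def adjusted_rand_index(p1: Partition, p2: Partition) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions of one cell set."""
    if set(p1.labels) != set(p2.labels):
        raise ValueError("partitions are defined on different cell sets")
    cells = sorted(p1.labels)
    a = p1.to_array(cells)
    b = p2.to_array(cells)
    return float(adjusted_rand_score(a, b))


def consolidate(p: Partition, reference_groups: dict[str, list[str]]) -> Partition:
    """Relabel clusters by plurality membership in named reference cell groups.

    ``reference_groups`` maps a group name to the cell ids it contains.  Any
    cluster of ``p`` whose plurality of cells lies in one group is renamed to
    that group; plurality ties leave the cluster unconsolidated with a warning.
    """
    member_of: dict[str, str] = {}
    for gname, cells in reference_groups.items():
        if not cells:
            raise ValueError(f"reference group {gname!r} is empty")
        for c in cells:
            member_of[str(c)] = gname
    out: dict[str, str] = {}
    for clab, cells in p.clusters().items():
        counts: dict[str, int] = {}
        for c in cells:
            g = member_of.get(c)
            if g is not None:
                counts[g] = counts.get(g, 0) + 1
        new_label = clab
        if counts:
            best = max(counts.values())
            winners = sorted(g for g, n in counts.items() if n == best)
            if len(winners) == 1:
                new_label = winners[0]
            else:
                logger.warning(
                    "consolidate: cluster %r ties between groups %s; left as is",
                    clab, winners,
                )
        for c in cells:
            out[c] = new_label
    return Partition(out)


def default_clusterer(embedding: np.ndarray, k: int, seed: int = 0) -> Partition:
    """k-NN graph + greedy modularity communities; a deterministic convenience.

    Cells get ids "0", "1", ... matching their row order.  This is a stand-in
    community detector, not a Phenograph reimplementation.
    """
    X = np.atleast_2d(np.asarray(embedding, dtype=float))
    n = X.shape[0]
    if k < 2:
        raise ValueError("k must be at least 2")
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in idx[i, 1:]:
            g.add_edge(i, int(j))
    communities = nx.community.greedy_modularity_communities(g)
    labels = np.empty(n, dtype=object)
    for ci, members in enumerate(sorted(communities, key=lambda s: min(s))):
        for m in members:
            labels[m] = str(ci)
    return Partition.from_arrays(map(str, range(n)), labels)


def _pairwise_ari(solutions: dict[int, Partition]) -> tuple[pd.DataFrame, float, float]:
    keys = sorted(solutions)
    rows = []
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            rows.append(
                {"value_a": a, "value_b": b,
                 "ari": adjusted_rand_index(solutions[a], solutions[b])}
            )
    df = pd.DataFrame(rows, columns=["value_a", "value_b", "ari"])
    if len(df) == 0:
        return df, float("nan"), float("nan")
    return df, float(df["ari"].mean()), float(df["ari"].std(ddof=0))


def robustness_sweep(
    expr_values: np.ndarray,
    clusterer: Callable[[np.ndarray, int, int], Partition],
    n_pcs_values: list[int],
    k_values: list[int],
    reference_groups: dict[str, list[str]],
    default_n_pcs: int | None = None,
    default_k: int = 40,
    seed: int = 0,
) -> RobustnessResult:
    """Sweep PCs and k independently, consolidate each solution, ARI all pairs.

    ``expr_values`` is a cells x features matrix (typically normalized
    expression); each grid point re-derives the PCA embedding at the requested
    dimensionality and clusters it.  Clusterer failures are recorded and the
    sweep continues.
    """
    from .sc_preprocess import ExpressionMatrix, compute_pca

    X = np.asarray(expr_values, dtype=float)
    n = X.shape[0]
    expr = ExpressionMatrix(
        values=X, cell_ids=[str(i) for i in range(n)],
        gene_ids=[f"f{j}" for j in range(X.shape[1])],
    )
    max_pcs = max(max(n_pcs_values), default_n_pcs or 0)
    pca = compute_pca(expr, n_components=min(max_pcs, min(X.shape)))
    if default_n_pcs is None:
        default_n_pcs = max(n_pcs_values)
    failures: list[tuple[str, int, str]] = []

    def solve(n_pcs: int, k: int) -> Partition | None:
        try:
            p = clusterer(pca.scores[:, :n_pcs], k, seed)
            return consolidate(p, reference_groups)
        except Exception as exc:  # noqa: BLE001 - contract: record and continue
            failures.append((f"pcs={n_pcs},k={k}", k, str(exc)))
            return None

    pc_solutions = {
        v: s for v in n_pcs_values if (s := solve(v, default_k)) is not None
    }
    k_solutions = {
        v: s for v in k_values if (s := solve(default_n_pcs, v)) is not None
    }
    df_pc, m_pc, s_pc = _pairwise_ari(pc_solutions)
    df_k, m_k, s_k = _pairwise_ari(k_solutions)
    return RobustnessResult(
        n_pcs_values=list(n_pcs_values), k_values=list(k_values),
        ri_pc_mean=m_pc, ri_pc_sd=s_pc, ri_k_mean=m_k, ri_k_sd=s_k,
        pairwise_pc=df_pc, pairwise_k=df_k,
        reference_groups={k: list(v) for k, v in reference_groups.items()},
        failures=failures,
    )
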