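"""Quality filtering, normalization, PCA and factor correction for scRNA-seq counts.

The preprocessing contract mirrors common droplet-based workflows: cells are
removed when their mitochondrial molecule fraction is high, when they express
too few unique genes, or when their library is too shallow; genes are kept when
detected in sufficiently many cells.  Normalized expression is library-size
scaled to the median total molecule count and log2 transformed with a small
pseudocount, the scale on which every downstream statistic operates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

logger = logging.getLogger("dc2scape")

#: Named threshold presets for the tissue/platform combinations supported out
#: of the box.  All values are overridable per call.
FILTER_PRESETS: dict[str, dict[str, float]] = {
    "mouse_spleen": {"max_mito_frac": 0.20, "min_genes": 1000, "min_molecules": 0},
    "human_spleen": {"max_mito_frac": 0.20, "min_genes": 0, "min_molecules": 6000},
    "melanoma": {"max_mito_frac": 0.20, "min_genes": 0, "min_molecules": 1000},
}

#: Gene-id prefixes treated as mitochondrial when no explicit mask is given.
MITO_PREFIXES: tuple[str, ...] = ("mt-", "MT-")


def _as_dense(values) -> np.ndarray:
    if sparse.issparse(values):
        return np.asarray(values.todense())
    return np.asarray(values)


@dataclass
class CountMatrix:
    """Raw cells x genes molecule counts with identifiers.

    ``mito_mask`` marks mitochondrial genes; if ``None`` it is derived from
    :data:`MITO_PREFIXES` on demand.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    mito_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = _as_dense(self.values)
        self.cell_ids = list(self.cell_ids)
        self.gene_ids = list(self.gene_ids)
        if self.values.ndim != 2:
            raise ValueError("count matrix must be 2-D (cells x genes)")
        n_cells, n_genes = self.values.shape
        if len(self.cell_ids) != n_cells or len(self.gene_ids) != n_genes:
            raise ValueError("identifier lists do not match matrix dimensions")
        if len(set(self.cell_ids)) != n_cells or len(set(self.gene_ids)) != n_genes:
            raise ValueError("cell and gene identifiers must be unique")
        if np.any(self.values < 0):
            raise ValueError("counts must be non-negative")
        if self.mito_mask is not None:
            self.mito_mask = np.asarray(self.mito_mask, dtype=bool)
            if self.mito_mask.shape != (n_genes,):
                raise ValueError("mito_mask length must equal gene count")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def mito_mask_or_default(self) -> np.ndarray:
        if self.mito_mask is not None:
            return self.mito_mask
        return np.array(
            [g.startswith(MITO_PREFIXES) for g in self.gene_ids], dtype=bool
        )


@dataclass
class ExpressionMatrix:
    """Normalized (optionally imputed / residualized) log expression."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    state_tag: str = "normalized"

    _STATES = ("normalized", "imputed", "residualized")

    def __post_init__(self) -> None:
        self.values = np.asarray(_as_dense(self.values), dtype=float)
        self.cell_ids = list(self.cell_ids)
        self.gene_ids = list(self.gene_ids)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-D (cells x genes)")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("identifier lists do not match matrix dimensions")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if self.state_tag not in self._STATES:
            raise ValueError(f"state_tag must be one of {self._STATES}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class QCReport:
    """Per-filter removal bookkeeping for one filtering pass."""

    axis: str  # "cells" or "genes"
    n_in: int
    n_out: int
    removals: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        removed = sum(n for _, n in self.removals)
        if self.n_in - removed != self.n_out:
            raise ValueError("removal counts inconsistent with in/out totals")

    def as_rows(self) -> list[dict]:
        rows = []
        for name, n in self.removals:
            rows.append(
                {
                    "axis": self.axis,
                    "filter": name,
                    "removed": n,
                    "fraction_of_input": n / self.n_in if self.n_in else 0.0,
                }
            )
        return rows


@dataclass
class PCAResult:
    scores: np.ndarray  # cells x K
    loadings: np.ndarray  # genes x K
    explained_variance_fraction: np.ndarray

    def __post_init__(self) -> None:
        evf = np.asarray(self.explained_variance_fraction, dtype=float)
        if np.any(evf < -1e-12) or np.any(evf > 1 + 1e-12):
            raise ValueError("explained-variance fractions must lie in [0, 1]")
        if np.any(np.diff(evf) > 1e-10):
            raise ValueError("explained-variance fractions must be non-increasing")
        self.explained_variance_fraction = evf

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def filter_cells(
    counts: CountMatrix,
    max_mito_frac: float | None = 0.20,
    min_genes: int = 0,
    min_molecules: int = 0,
) -> tuple[CountMatrix, QCReport]:
    """Remove low-quality cells: mito fraction, then unique genes, then depth.

    A cell is removed when its mitochondrial molecule fraction is strictly
    greater than ``max_mito_frac``, when it expresses strictly fewer than
    ``min_genes`` unique genes, or when its total molecule count is not
    strictly greater than ``min_molecules`` (``min_molecules=0`` disables the
    depth filter entirely).  Filters are applied in that fixed order and the
    report itemizes removals per stage.
    """
    if max_mito_frac is not None and max_mito_frac < 0:
        raise ValueError("max_mito_frac must be non-negative")
    if min_genes < 0 or min_molecules < 0:
        raise ValueError("thresholds must be non-negative")

    values = counts.values
    n_in = counts.n_cells
    keep = np.ones(n_in, dtype=bool)
    removals: list[tuple[str, int]] = []

    if max_mito_frac is not None:
        mito = counts.mito_mask_or_default()
        totals = values.sum(axis=1)
        mito_counts = values[:, mito].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
        bad = keep & (frac > max_mito_frac)
        removals.append(("mito_fraction", int(bad.sum())))
        keep &= ~bad
    else:
        removals.append(("mito_fraction", 0))

    n_unique = (values > 0).sum(axis=1)
    bad = keep & (n_unique < min_genes)
    removals.append(("min_genes", int(bad.sum())))
    keep &= ~bad

    if min_molecules > 0:
        totals = values.sum(axis=1)
        bad = keep & (totals <= min_molecules)
    else:
        bad = np.zeros(n_in, dtype=bool)
    removals.append(("min_molecules", int(bad.sum())))
    keep &= ~bad

    if not keep.any():
        raise ValueError("all cells removed by quality filters")

    out = CountMatrix(
        values=values[keep],
        cell_ids=[c for c, k in zip(counts.cell_ids, keep) if k],
        gene_ids=counts.gene_ids,
        mito_mask=counts.mito_mask,
    )
    report = QCReport("cells", n_in, out.n_cells, removals)
    return out, report


def filter_genes(counts: CountMatrix, min_cells: int = 10) -> tuple[CountMatrix, QCReport]:
    """Retain genes with nonzero counts in strictly more than ``min_cells`` cells."""
    if min_cells < 0:
        raise ValueError("min_cells must be non-negative")
    n_expressing = (counts.values > 0).sum(axis=0)
    keep = n_expressing > min_cells
    if not keep.any():
        raise ValueError("all genes removed by detection filter")
    out = CountMatrix(
        values=counts.values[:, keep],
        cell_ids=counts.cell_ids,
        gene_ids=[g for g, k in zip(counts.gene_ids, keep) if k],
        mito_mask=None if counts.mito_mask is None else counts.mito_mask[keep],
    )
    report = QCReport(
        "genes", counts.n_genes, out.n_genes, [("min_cells", int((~keep).sum()))]
    )
    return out, report


def normalize(counts: CountMatrix, pseudocount: float = 0.1) -> ExpressionMatrix:
    """Library-size normalize to the median total, then log2 with a pseudocount.

    value(c, g) = log2(count(c, g) / total(c) * median_total + pseudocount).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    totals = counts.values.sum(axis=1).astype(float)
    if np.any(totals <= 0):
        raise ValueError(
            "cells with zero total count present; filter cells before normalizing"
        )
    median_total = float(np.median(totals))
    scaled = counts.values / totals[:, None] * median_total
    return ExpressionMatrix(
        values=np.log2(scaled + pseudocount),
        cell_ids=counts.cell_ids,
        gene_ids=counts.gene_ids,
        state_tag="normalized",
    )


def denormalize(expr: ExpressionMatrix, totals: np.ndarray, pseudocount: float = 0.1) -> np.ndarray:
    """Invert :func:`normalize` given the original per-cell totals."""
    totals = np.asarray(totals, dtype=float)
    median_total = float(np.median(totals))
    scaled = np.exp2(expr.values) - pseudocount
    return scaled * totals[:, None] / median_total


def compute_pca(expr: ExpressionMatrix, n_components: int = 20) -> PCAResult:
    """Top-K PCA of gene-centered (not scaled) expression with fixed signs.

    Signs follow a deterministic convention: the largest-magnitude loading of
    each component is made positive.
    """
    if n_components < 1:
        raise ValueError("n_components must be at least 1")
    if n_components > min(expr.n_cells, expr.n_genes):
        raise ValueError("n_components exceeds matrix rank bound")
    X = expr.values - expr.values.mean(axis=0, keepdims=True)
    if min(X.shape) > 300 and n_components < min(X.shape) // 4:
        # Lanczos with a fixed start vector: deterministic and much cheaper
        # than a full SVD at pipeline scale
        from scipy.sparse.linalg import svds

        U, s, Vt = svds(X, k=n_components, v0=np.ones(min(X.shape)))
        order = np.argsort(s)[::-1]
        U, s, Vt = U[:, order], s[order], Vt[order]
    else:
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    total_var = float((X**2).sum())
    evf = (s**2) / total_var if total_var > 0 else np.zeros(n_components)
    loadings = Vt.T
    for j in range(n_components):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            U[:, j] *= -1
    return PCAResult(
        scores=U * s, loadings=loadings, explained_variance_fraction=evf
    )


def score_signature(
    expr: ExpressionMatrix, gene_set: list[str], zscore: bool = True
) -> np.ndarray:
    """Per-cell mean expression of a gene signature, z-scored per gene by default.

    Genes absent from the matrix are ignored (and logged); zero-variance genes
    contribute 0 rather than NaN.
    """
    index = {g: i for i, g in enumerate(expr.gene_ids)}
    present = [g for g in gene_set if g in index]
    missing = [g for g in gene_set if g not in index]
    if missing:
        logger.info("score_signature: %d/%d signature genes absent", len(missing), len(gene_set))
    if not present:
        raise ValueError("no signature genes present in the expression matrix")
    sub = expr.values[:, [index[g] for g in present]]
    if not zscore:
        return sub.mean(axis=1)
    mu = sub.mean(axis=0, keepdims=True)
    sd = sub.std(axis=0, keepdims=True)
    z = np.divide(sub - mu, sd, out=np.zeros_like(sub), where=sd > 0)
    return z.mean(axis=1)


def pc_gene_sets(
    pca: PCAResult, gene_ids: list[str], top_n: int = 30
) -> list[list[str]]:
    """Per component, the ``top_n`` most-positive plus ``top_n`` most-negative
    loading genes (2 x top_n members), ties broken by gene id."""
    n_genes = pca.loadings.shape[0]
    if top_n > n_genes // 2:
        raise ValueError("top_n must not exceed half the gene count")
    gene_ids = list(gene_ids)
    sets = []
    for j in range(pca.n_components):
        load = pca.loadings[:, j]
        # sort by (-loading, gene_id) for the positive end, (loading, gene_id)
        # for the negative end: deterministic under ties
        order_pos = sorted(range(n_genes), key=lambda i: (-load[i], gene_ids[i]))
        order_neg = sorted(range(n_genes), key=lambda i: (load[i], gene_ids[i]))
        members = [gene_ids[i] for i in order_pos[:top_n]]
        members += [gene_ids[i] for i in order_neg[:top_n]]
        sets.append(members)
    return sets


def regress_out_factors(
    expr: ExpressionMatrix, factor_scores: np.ndarray
) -> ExpressionMatrix:
    """OLS-residualize each gene on the factor matrix (with intercept).

    The output is residual + gene mean, tagged ``residualized``, so the
    expression scale is preserved.  Zero-variance factors are dropped (they are
    absorbed by the intercept); a rank-deficient factor matrix raises, naming
    the first collinear column.
    """
    F = np.atleast_2d(np.asarray(factor_scores, dtype=float))
    if F.shape[0] != expr.n_cells:
        raise ValueError("factor_scores rows must match cell count")
    if not np.all(np.isfinite(F)):
        raise ValueError("factor scores must be finite")
    keep = F.std(axis=0) > 0
    F = F[:, keep]
    n = expr.n_cells
    design = np.column_stack([np.ones(n), F])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify the first factor column not adding rank
        r = 1
        for j in range(F.shape[1]):
            sub = design[:, : j + 2]
            if np.linalg.matrix_rank(sub) == r:
                raise ValueError(f"factor column {j} is collinear with preceding factors")
            r += 1
        raise ValueError("factor matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(design, expr.values, rcond=None)
    fitted = design @ beta
    residual = expr.values - fitted
    out = residual + expr.values.mean(axis=0, keepdims=True)
    return replace(expr, values=out, state_tag="residualized")
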