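"""Cluster-to-bulk and cross-species correspondence analyses.

Covers: z-scored centroid correlation between cluster average profiles (within
one dataset against bulk references, or across species through an ortholog
map); sparse one-vs-rest elastic-net cluster signatures and their correlation
with bulk expression; core-signature derivation from differential-expression
tables; ANOVA selection of cluster-variable transcription factors with BH
correction; TF program clustering and cross-species overlap counting; and the
two-sample Kolmogorov-Smirnov signature-shift comparison of fold-change
distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .robustness import Partition
from .sc_preprocess import CountMatrix, ExpressionMatrix

logger = logging.getLogger("dc2scape")


# ---------------------------------------------------------------- centroids


@dataclass
class CentroidMatrix:
    """clusters x genes mean-expression matrix with an optional z-scored view."""

    values: pd.DataFrame  # index: cluster labels, columns: gene ids

    def zscored(self) -> pd.DataFrame:
        """Z-score each gene across clusters (population SD; zero variance -> 0)."""
        v = self.values
        mu = v.mean(axis=0)
        sd = v.std(axis=0, ddof=0)
        z = (v - mu).div(sd.replace(0.0, np.inf), axis=1)
        return z


def centroid_profiles(expr: ExpressionMatrix, labels) -> CentroidMatrix:
    """Per-cluster mean expression profiles."""
    lab = pd.Series(labels).reindex(expr.cell_ids)
    if lab.isna().any():
        raise ValueError("labels missing for some cells")
    df = pd.DataFrame(expr.values, index=expr.cell_ids, columns=expr.gene_ids)
    cent = df.groupby(lab.astype(str)).mean()
    if (cent.isna().any().any()):
        raise ValueError("empty cluster encountered")
    return CentroidMatrix(values=cent.sort_index())


# ------------------------------------------------------------ ortholog maps


@dataclass
class OrthologMap:
    """Cross-species gene pairs, with a deterministic one-to-one reduction."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if not a or not b:
                raise ValueError("ortholog pairs must not contain empty ids")

    @classmethod
    def from_tsv(cls, path) -> "OrthologMap":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        return cls([(r[0], r[1]) for r in df.itertuples(index=False)])

    def reduce_one_to_one(
        self, expression_a: pd.Series | None = None
    ) -> list[tuple[str, str]]:
        """At most one partner per gene.

        Pairs where both genes appear exactly once in the map are kept
        outright; remaining genes keep the partner with the highest total
        expression (``expression_a`` indexed by species-A gene id) or, absent
        expression, the lexicographically smallest partner.  The rule is
        logged.
        """
        count_a: dict[str, int] = {}
        count_b: dict[str, int] = {}
        for a, b in self.pairs:
            count_a[a] = count_a.get(a, 0) + 1
            count_b[b] = count_b.get(b, 0) + 1
        kept: list[tuple[str, str]] = []
        used_a: set[str] = set()
        used_b: set[str] = set()
        for a, b in self.pairs:
            if count_a[a] == 1 and count_b[b] == 1:
                kept.append((a, b))
                used_a.add(a)
                used_b.add(b)
        ambiguous = [
            (a, b) for a, b in self.pairs if a not in used_a and b not in used_b
        ]

        def score(pair: tuple[str, str]) -> tuple:
            a, b = pair
            expr = 0.0
            if expression_a is not None and a in expression_a.index:
                expr = float(expression_a[a])
            return (-expr, a, b)

        for a, b in sorted(ambiguous, key=score):
            if a in used_a or b in used_b:
                continue
            kept.append((a, b))
            used_a.add(a)
            used_b.add(b)
        logger.info(
            "ortholog reduction: %d/%d pairs retained one-to-one",
            len(kept), len(self.pairs),
        )
        return sorted(kept)


def correlate_profiles(
    a: CentroidMatrix,
    b: CentroidMatrix,
    ortholog_map: OrthologMap | None = None,
    zscore: bool = True,
) -> pd.DataFrame:
    """Pearson correlation of every cluster pair over the shared gene universe.

    With an ortholog map, species-B genes are translated through the
    one-to-one reduction first.  Profiles are z-scored per gene across
    clusters within each dataset before correlating (disable with
    ``zscore=False``).
    """
    av = a.zscored() if zscore else a.values
    bv = b.zscored() if zscore else b.values
    if ortholog_map is not None:
        pairs = [
            (ga, gb)
            for ga, gb in ortholog_map.reduce_one_to_one()
            if ga in av.columns and gb in bv.columns
        ]
        if len(pairs) < 3:
            raise ValueError("fewer than 3 shared orthologous genes")
        av = av[[p[0] for p in pairs]]
        bv = bv[[p[1] for p in pairs]]
        bv.columns = av.columns
    else:
        shared = sorted(set(av.columns) & set(bv.columns))
        if len(shared) < 3:
            raise ValueError("fewer than 3 shared genes")
        av, bv = av[shared], bv[shared]
    logger.info("correlate_profiles: %d shared genes", av.shape[1])
    out = pd.DataFrame(index=av.index, columns=bv.index, dtype=float)
    for ca in av.index:
        for cb in bv.index:
            out.loc[ca, cb] = float(np.corrcoef(av.loc[ca], bv.loc[cb])[0, 1])
    return out


# -------------------------------------------------- elastic-net signatures


@dataclass
class SignatureCoefficients:
    """Per-cluster one-vs-rest elastic-net gene coefficients."""

    coefficients: pd.DataFrame  # genes x clusters
    intercepts: pd.Series
    chosen_penalty: pd.Series  # per cluster, the C maximizing held-out AUC
    cv_auc: pd.Series
    alpha: float

    @property
    def sparsity(self) -> pd.Series:
        return (self.coefficients == 0).mean(axis=0)


def _signature_transform(counts: CountMatrix, total_count_min: int) -> pd.DataFrame:
    """Gene filter (total count strictly > threshold), median-total library
    normalization, log2(x + 1) — the transform specific to this procedure."""
    totals_per_gene = counts.values.sum(axis=0)
    keep = totals_per_gene > total_count_min
    if not keep.any():
        raise ValueError("no genes pass the total-count filter")
    vals = counts.values[:, keep].astype(float)
    cell_totals = counts.values.sum(axis=1).astype(float)
    if np.any(cell_totals <= 0):
        raise ValueError("cells with zero totals present")
    norm = vals / cell_totals[:, None] * np.median(cell_totals)
    genes = [g for g, k in zip(counts.gene_ids, keep) if k]
    return pd.DataFrame(np.log2(norm + 1.0), index=counts.cell_ids, columns=genes)


def signature_coefficients(
    counts: CountMatrix,
    labels,
    total_count_min: int = 300,
    alpha: float = 0.99,
    n_folds: int = 10,
    n_penalties: int = 20,
    seed: int = 0,
) -> SignatureCoefficients:
    """One-vs-rest penalized binomial regression cluster signatures.

    ``alpha`` is the elastic-net mixing weight (1 = pure lasso).  For each
    cluster a logistic model is fit along a log-spaced inverse-penalty path;
    stratified ``n_folds`` cross-validation picks the penalty maximizing
    held-out ROC AUC, and coefficients refit on all cells at that penalty are
    returned together with the achieved AUC.
    """
    lab = pd.Series(labels).reindex(counts.cell_ids).astype(str)
    if lab.isna().any():
        raise ValueError("labels missing for some cells")
    clusters = sorted(lab.unique())
    if len(clusters) < 2:
        raise ValueError("at least two clusters are required")
    X = _signature_transform(counts, total_count_min)
    Xv = X.to_numpy()
    Cs = np.logspace(-3, 2, n_penalties)
    coef = pd.DataFrame(0.0, index=X.columns, columns=clusters)
    intercepts = pd.Series(0.0, index=clusters)
    best_C = pd.Series(0.0, index=clusters)
    cv_auc = pd.Series(0.0, index=clusters)
    for cl in clusters:
        y = (lab == cl).astype(int).to_numpy()
        if y.sum() < n_folds or (len(y) - y.sum()) < n_folds:
            raise ValueError(f"cluster {cl!r} too small for {n_folds}-fold CV")
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = list(skf.split(Xv, y))
        aucs = np.zeros(len(Cs))
        for ci, C in enumerate(Cs):
            fold_scores = []
            for tr, te in folds:
                try:
                    m = LogisticRegression(
                        penalty="elasticnet", solver="saga", l1_ratio=alpha,
                        C=C, max_iter=2000, tol=1e-4,
                    ).fit(Xv[tr], y[tr])
                except Exception as exc:  # noqa: BLE001
                    logger.warning("penalty C=%g skipped: %s", C, exc)
                    continue
                p = m.decision_function(Xv[te])
                fold_scores.append(roc_auc_score(y[te], p))
            aucs[ci] = np.mean(fold_scores) if fold_scores else 0.0
        ci = int(np.argmax(aucs))
        model = LogisticRegression(
            penalty="elasticnet", solver="saga", l1_ratio=alpha,
            C=Cs[ci], max_iter=5000, tol=1e-4,
        ).fit(Xv, y)
        coef[cl] = model.coef_.ravel()
        intercepts[cl] = float(model.intercept_[0])
        best_C[cl] = Cs[ci]
        cv_auc[cl] = float(aucs[ci])
    return SignatureCoefficients(
        coefficients=coef, intercepts=intercepts, chosen_penalty=best_C,
        cv_auc=cv_auc, alpha=alpha,
    )


def bulk_similarity(
    sig: SignatureCoefficients, bulk: pd.DataFrame, zscore_columns: bool = False
) -> pd.DataFrame:
    """Pearson r between cluster coefficient vectors and bulk sample profiles.

    ``bulk`` is samples x genes (normalized counts).  Correlation runs over
    the genes shared between the coefficient universe and the bulk table.
    Column z-scoring is available for display parity with heatmap figures.
    """
    shared = sorted(set(sig.coefficients.index) & set(bulk.columns))
    if len(shared) < 3:
        raise ValueError("fewer than 3 genes shared with the bulk table")
    out = pd.DataFrame(index=sig.coefficients.columns, columns=bulk.index, dtype=float)
    for cl in out.index:
        c = sig.coefficients.loc[shared, cl].to_numpy()
        for s in out.columns:
            b = bulk.loc[s, shared].to_numpy(dtype=float)
            out.loc[cl, s] = float(np.corrcoef(c, b)[0, 1])
    if zscore_columns:
        out = (out - out.mean(axis=0)) / out.std(axis=0, ddof=0)
    return out


# ------------------------------------------------------------ core signature


def core_signature(
    tables: dict[str, pd.DataFrame],
    fdr_max: float = 0.1,
    log2fc_min: float = 1.5,
    mean_count_min: float = 50.0,
) -> dict:
    """Per-tissue stringent DE gene sets and their cross-tissue overlap.

    Each table needs columns ``log2fc``, ``fdr``, ``mean_count``.  A gene
    passes when fdr < fdr_max AND |log2fc| strictly > log2fc_min AND
    mean_count >= mean_count_min; passers are split by fold-change sign and
    intersected across tissues per direction.
    """
    required = {"log2fc", "fdr", "mean_count"}
    per_tissue: dict[str, dict[str, list[str]]] = {}
    for tissue, tab in tables.items():
        if not required.issubset(tab.columns):
            raise ValueError(
                f"table {tissue!r} missing columns {sorted(required - set(tab.columns))}"
            )
        passing = tab[
            (tab["fdr"] < fdr_max)
            & (tab["log2fc"].abs() > log2fc_min)
            & (tab["mean_count"] >= mean_count_min)
        ]
        per_tissue[tissue] = {
            "up": sorted(passing.index[passing["log2fc"] > 0]),
            "down": sorted(passing.index[passing["log2fc"] < 0]),
        }
    tissues = list(per_tissue)
    overlap = {}
    for direction in ("up", "down"):
        sets = [set(per_tissue[t][direction]) for t in tissues]
        overlap[direction] = sorted(set.intersection(*sets)) if sets else []
    return {"per_tissue": per_tissue, "overlap": overlap}


# ---------------------------------------------------------- TF programs


@dataclass
class TFProgramResult:
    selected: dict[str, list[str]]  # per species
    clusters: dict[str, Partition]  # per species, TF gene -> program label
    overlap: pd.DataFrame  # A programs x B programs, counts of shared TFs
    shared_tfs: list[tuple[str, str]] = field(default_factory=list)


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def select_variable_tfs(
    expr_by_species: dict[str, ExpressionMatrix],
    labels_by_species: dict[str, pd.Series],
    tf_list: dict[str, list[str]],
    ortholog_map: OrthologMap,
    expression_min: float = 10.0,
    fdr_max: float = 1e-5,
    expression_counts: dict[str, pd.Series] | None = None,
) -> dict:
    """Cluster-variable transcription factors shared between two species.

    Per species: TFs passing the expression pre-filter (mean library-size
    normalized count > ``expression_min`` when raw means are supplied,
    otherwise all TFs present in the matrix) are tested for between-cluster
    variation by one-way ANOVA on the normalized log expression; p-values are
    BH adjusted and TFs selected at FDR < ``fdr_max``.  The final list keeps
    ortholog pairs selected in both species.
    """
    if not tf_list:
        raise ValueError("tf_list must be non-empty")
    selected: dict[str, list[str]] = {}
    tested: dict[str, pd.DataFrame] = {}
    for sp, expr in expr_by_species.items():
        lab = pd.Series(labels_by_species[sp]).reindex(expr.cell_ids).astype(str)
        tfs = [g for g in tf_list[sp] if g in expr.gene_ids]
        if expression_counts is not None and sp in expression_counts:
            means = expression_counts[sp]
            tfs = [g for g in tfs if means.get(g, 0.0) > expression_min]
        gi = {g: i for i, g in enumerate(expr.gene_ids)}
        # clusters with < 2 cells cannot contribute a within-group variance
        sizes = lab.value_counts()
        ok_clusters = sizes.index[sizes >= 2]
        dropped = sorted(set(sizes.index) - set(ok_clusters))
        if dropped:
            logger.warning("select_variable_tfs[%s]: clusters %s excluded (<2 cells)", sp, dropped)
        groups_idx = [np.flatnonzero((lab == c).to_numpy()) for c in sorted(ok_clusters)]
        pvals, fstats = [], []
        for g in tfs:
            samples = [expr.values[ix, gi[g]] for ix in groups_idx]
            if all(np.var(s) == 0 for s in samples) and len({s[0] for s in samples if len(s)}) <= 1:
                f, p = 0.0, 1.0
            else:
                with np.errstate(invalid="ignore", divide="ignore"):
                    f, p = stats.f_oneway(*samples)
                if not np.isfinite(p):
                    f, p = 0.0, 1.0
            pvals.append(p)
            fstats.append(f)
        q = benjamini_hochberg(np.array(pvals)) if tfs else np.array([])
        df = pd.DataFrame({"tf": tfs, "F": fstats, "p": pvals, "q": q}).set_index("tf")
        tested[sp] = df
        selected[sp] = sorted(df.index[df["q"] < fdr_max])
    species = list(expr_by_species)
    if len(species) != 2:
        raise ValueError("exactly two species are required")
    a, b = species
    sel_a, sel_b = set(selected[a]), set(selected[b])
    shared = [
        (ga, gb)
        for ga, gb in ortholog_map.reduce_one_to_one()
        if ga in sel_a and gb in sel_b
    ]
    return {"selected": selected, "tables": tested, "shared_pairs": sorted(shared)}


def cosine_knn_clusterer(profiles: np.ndarray, k: int, seed: int = 0) -> Partition:
    """k-NN (cosine metric) graph + greedy modularity over TF profiles."""
    import networkx as nx
    from sklearn.neighbors import NearestNeighbors

    X = np.asarray(profiles, dtype=float)
    n = X.shape[0]
    if k >= n:
        raise ValueError("fewer profiles than k; use a smaller k")
    nn = NearestNeighbors(n_neighbors=k + 1, metric="cosine").fit(X)
    _, idx = nn.kneighbors(X)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in idx[i, 1:]:
            g.add_edge(i, int(j))
    comms = nx.community.greedy_modularity_communities(g)
    labels = np.empty(n, dtype=object)
    for ci, members in enumerate(sorted(comms, key=lambda s: min(s))):
        for m in members:
            labels[m] = str(ci)
    return Partition.from_arrays(map(str, range(n)), labels)


def tf_program_overlap(
    profiles_by_species: dict[str, pd.DataFrame],
    shared_pairs: list[tuple[str, str]],
    k: int = 10,
    clusterer=cosine_knn_clusterer,
    seed: int = 0,
) -> TFProgramResult:
    """Cluster TF expression programs per species; count cross-species overlap.

    ``profiles_by_species`` maps species -> (TFs x features) profile matrix
    (e.g. imputed expression over cells or centroids), z-scored per TF before
    clustering.  The overlap matrix counts ortholog TF pairs falling in each
    (species-A program, species-B program) combination; its total equals the
    number of shared TFs.
    """
    species = list(profiles_by_species)
    if len(species) != 2:
        raise ValueError("exactly two species are required")
    a, b = species
    clusters: dict[str, Partition] = {}
    for sp in species:
        prof = profiles_by_species[sp]
        if prof.shape[0] <= k:
            raise ValueError(
                f"species {sp!r} has {prof.shape[0]} TFs but k={k}; use a smaller k"
            )
        v = prof.to_numpy(dtype=float)
        mu = v.mean(axis=1, keepdims=True)
        sd = v.std(axis=1, keepdims=True)
        z = np.divide(v - mu, sd, out=np.zeros_like(v), where=sd > 0)
        part = clusterer(z, k, seed)
        clusters[sp] = Partition(
            {prof.index[int(i)]: lab for i, lab in part.labels.items()}
        )
    labs_a = sorted(set(clusters[a].labels.values()))
    labs_b = sorted(set(clusters[b].labels.values()))
    overlap = pd.DataFrame(0, index=labs_a, columns=labs_b)
    usable = [
        (ga, gb) for ga, gb in shared_pairs
        if ga in clusters[a].labels and gb in clusters[b].labels
    ]
    for ga, gb in usable:
        overlap.loc[clusters[a].labels[ga], clusters[b].labels[gb]] += 1
    return TFProgramResult(
        selected={a: [p[0] for p in usable], b: [p[1] for p in usable]},
        clusters=clusters, overlap=overlap, shared_tfs=usable,
    )


# ------------------------------------------------------------------ KS shift


def signature_shift_test(
    background_log2fc: pd.Series, signature_genes: list[str]
) -> dict:
    """Two-sided two-sample KS test of signature fold changes vs background.

    Returns the KS statistic D, the p-value, and step-CDF curves for both
    samples, ready for plotting or TSV export.
    """
    bg = pd.Series(background_log2fc).astype(float)
    sig_genes = [g for g in signature_genes if g in bg.index]
    if len(sig_genes) < 3:
        raise ValueError("fewer than 3 signature genes overlap the background")
    sig = bg.loc[sig_genes]
    res = stats.ks_2samp(sig.to_numpy(), bg.to_numpy(), alternative="two-sided")

    def cdf_curve(v: np.ndarray) -> pd.DataFrame:
        x = np.sort(v)
        return pd.DataFrame({"value": x, "cdf": np.arange(1, len(x) + 1) / len(x)})

    return {
        "D": float(res.statistic),
        "pvalue": float(res.pvalue),
        "signature_cdf": cdf_curve(sig.to_numpy()),
        "background_cdf": cdf_curve(bg.to_numpy()),
        "n_signature": len(sig_genes),
        "n_background": int(bg.size),
    }
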