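"""Synthetic data with planted ground truth for every pipeline stage.

Four generators, all pure functions of (config, seed):

* :func:`make_sc_counts` — droplet-style count matrices: discrete cell
  subsets with planted marker genes, a shared cell-cycle program, lognormal
  library-size variation, Poisson counting noise and Bernoulli dropout.
* :func:`make_branching_traj` — expression over a latent one-dimensional
  pseudotime with a branch point, for diffusion-map and shortest-path tests.
* :func:`make_atac_toy` — a toy genome with gene models, summit peaks, PWMs
  with implanted instances, and two-condition counts whose log2 fold changes
  are a sparse linear function of motif presence plus noise.
* :func:`make_bulk_profiles` — noisy bulk replicates of cluster centroids.

Defaults are sized so each generator runs in well under a minute and so that
planted effects are realistic rather than trivially separable (50% dropout,
subset markers at ~2 log2 units — the strong end of what distinguishes real
DC subsets — and accessibility effects at half a log2 unit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atac import GeneModel, MotifModel
from .sc_preprocess import CountMatrix, ExpressionMatrix

_BASES = np.array(list("ACGT"))


# ----------------------------------------------------------- scRNA counts


@dataclass
class ScTruth:
    subset: pd.Series  # per cell
    marker_effects: dict[str, dict[str, float]]  # subset -> gene -> log2 effect
    cycle_genes: list[str]
    cycle_intensity: pd.Series  # per cell
    library_size: pd.Series
    dropout: float

    @property
    def marker_genes(self) -> dict[str, list[str]]:
        return {s: sorted(g) for s, g in self.marker_effects.items()}

    def all_marker_genes(self) -> list[str]:
        out: set[str] = set()
        for genes in self.marker_effects.values():
            out |= set(genes)
        return sorted(out)


def make_sc_counts(
    n_cells: int = 2000,
    n_genes: int = 2000,
    n_subsets: int = 3,
    n_markers_per_subset: int = 10,
    marker_effect: float = 2.0,
    n_cycle_genes: int = 50,
    cycle_fraction: float = 0.15,
    cycle_effect: float = 1.5,
    mean_library_size: float = 5000.0,
    library_sigma: float = 0.35,
    dropout: float = 0.5,
    n_mito_genes: int = 5,
    mito_fraction: float = 0.05,
    seed: int = 0,
) -> tuple[CountMatrix, ScTruth]:
    """Planted-marker scRNA-seq counts with cell-cycle structure and dropout.

    Per-cell rates are baseline x 2^(subset marker effect) x 2^(cycle
    intensity x program loading); molecule counts are Poisson at those rates
    scaled by the cell's library size, then thinned per molecule with
    probability ``dropout``.  Marker genes are disjoint across subsets and
    from the cycle program.  A handful of "mt-" genes carry a fixed fraction
    of each library so mitochondrial filtering is exercisable.
    """
    rng = np.random.default_rng(seed)
    need = n_subsets * n_markers_per_subset + n_cycle_genes + n_mito_genes
    if need > n_genes:
        raise ValueError("not enough genes for the requested structure")
    gene_ids = [f"g{i:05d}" for i in range(n_genes - n_mito_genes)]
    gene_ids += [f"mt-{i}" for i in range(n_mito_genes)]
    cell_ids = [f"c{i:05d}" for i in range(n_cells)]

    subsets = np.array([f"S{i}" for i in rng.integers(0, n_subsets, n_cells)])
    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    # marker genes are, by definition, expressed in their subset: floor their
    # baseline at the typical gene's level so the planted effect is observable
    n_marker_genes = n_subsets * n_markers_per_subset
    baseline[:n_marker_genes] = np.maximum(
        baseline[:n_marker_genes], np.median(baseline)
    )
    log2_shift = np.zeros((n_cells, n_genes))

    marker_effects: dict[str, dict[str, float]] = {}
    cursor = 0
    for s in range(n_subsets):
        name = f"S{s}"
        genes = list(range(cursor, cursor + n_markers_per_subset))
        cursor += n_markers_per_subset
        marker_effects[name] = {gene_ids[g]: marker_effect for g in genes}
        mask = subsets == name
        for g in genes:
            log2_shift[mask, g] += marker_effect

    cycle_idx = list(range(cursor, cursor + n_cycle_genes))
    cycle_genes = [gene_ids[g] for g in cycle_idx]
    intensity = np.where(
        rng.random(n_cells) < cycle_fraction, rng.uniform(0.5, 1.0, n_cells), 0.0
    )
    loadings = rng.uniform(0.5, 1.0, n_cycle_genes)
    log2_shift[:, cycle_idx] += cycle_effect * intensity[:, None] * loadings[None, :]

    rates = baseline[None, :] * np.exp2(log2_shift)
    # mito genes get a dedicated share of each library
    mito_cols = np.arange(n_genes - n_mito_genes, n_genes)
    rates[:, mito_cols] = 0.0
    row_sums = rates.sum(axis=1, keepdims=True)
    rates = rates / row_sums * (1 - mito_fraction)
    rates[:, mito_cols] = mito_fraction / n_mito_genes

    libraries = rng.lognormal(np.log(mean_library_size), library_sigma, n_cells)
    lam = rates * libraries[:, None]
    counts = rng.poisson(lam)
    if dropout > 0:
        counts = rng.binomial(counts, 1.0 - dropout)

    cm = CountMatrix(
        values=counts, cell_ids=cell_ids, gene_ids=gene_ids,
        mito_mask=np.array([g.startswith("mt-") for g in gene_ids]),
    )
    truth = ScTruth(
        subset=pd.Series(subsets, index=cell_ids),
        marker_effects=marker_effects,
        cycle_genes=cycle_genes,
        cycle_intensity=pd.Series(intensity, index=cell_ids),
        library_size=pd.Series(libraries, index=cell_ids),
        dropout=dropout,
    )
    return cm, truth


# ------------------------------------------------------ branching manifold


@dataclass
class TrajTruth:
    pseudotime: pd.Series  # in [0, 1]
    branch: pd.Series  # "root", "A" or "B"


def make_branching_traj(
    n_cells: int = 600,
    n_genes: int = 120,
    branch_point: float = 0.4,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[ExpressionMatrix, TrajTruth]:
    """Smooth branching expression manifold over latent pseudotime.

    A third of the genes follow logistic trends shared by all cells; the
    rest split evenly into branch-A and branch-B programs that diverge after
    ``branch_point``.  Gaussian noise of SD ``noise_sd`` is added on the log
    scale.
    """
    if not (0 < branch_point < 1):
        raise ValueError("branch_point must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    t = rng.uniform(0, 1, n_cells)
    t.sort()
    branch = np.where(
        t <= branch_point, "root", np.where(rng.random(n_cells) < 0.5, "A", "B")
    )

    def logistic(x, center, rate, sign):
        return sign / (1.0 + np.exp(-rate * (x - center)))

    n_shared = n_genes // 3
    n_branch = (n_genes - n_shared) // 2
    values = np.zeros((n_cells, n_genes))
    centers = rng.uniform(0.1, 0.9, n_genes)
    rates = rng.uniform(5, 12, n_genes)
    signs = rng.choice([-2.0, 2.0], n_genes)
    for g in range(n_shared):
        values[:, g] = logistic(t, centers[g], rates[g], signs[g])
    prog = np.clip(t - branch_point, 0, None)
    # quadratic ramp keeps branch programs continuous (value and slope zero)
    # at the branch point, so the manifold has no density gap at the split
    onset = np.clip(prog / (0.3 * (1 - branch_point)), 0, 1) ** 2
    on_a = (branch == "A").astype(float) * onset
    on_b = (branch == "B").astype(float) * onset
    for g in range(n_shared, n_shared + n_branch):
        values[:, g] = 2.0 * on_a * logistic(prog, centers[g] * 0.3, rates[g], 1.0)
    for g in range(n_shared + n_branch, n_genes):
        values[:, g] = 2.0 * on_b * logistic(prog, centers[g] * 0.3, rates[g], 1.0)
    values += rng.normal(0, noise_sd, values.shape)

    cell_ids = [f"c{i:05d}" for i in range(n_cells)]
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    expr = ExpressionMatrix(values=values, cell_ids=cell_ids, gene_ids=gene_ids)
    truth = TrajTruth(
        pseudotime=pd.Series(t, index=cell_ids),
        branch=pd.Series(branch, index=cell_ids),
    )
    return expr, truth


# ------------------------------------------------------------- ATAC toy


@dataclass
class AtacTruth:
    genome: dict[str, str]
    w_star: pd.Series  # per motif, true association coefficient
    motif_presence: pd.DataFrame  # peaks x motifs, 0/1 implanted
    log2fc: pd.Series  # realized latent fold change per peak
    noise_sd: float
    active_motifs: list[str] = field(default_factory=list)


def _random_ppm(rng: np.random.Generator, length: int, concentration: float) -> np.ndarray:
    """PPM rows drawn from a Dirichlet sharpened toward a random consensus."""
    consensus = rng.integers(0, 4, length)
    alpha = np.full((length, 4), 0.5)
    alpha[np.arange(length), consensus] = concentration
    return np.vstack([rng.dirichlet(alpha[i]) for i in range(length)])


def _sample_site(rng: np.random.Generator, ppm: np.ndarray) -> str:
    u = rng.random(ppm.shape[0])
    idx = (u[:, None] > np.cumsum(ppm, axis=1)).sum(axis=1)
    return "".join(_BASES[idx])


def make_atac_toy(
    n_peaks: int = 2000,
    n_motifs: int = 120,
    n_active_motifs: int = 5,
    effect_size: float = 0.5,
    snr: float = 2.0,
    n_genes: int = 40,
    motif_length: int = 10,
    window: int = 150,
    presence_prob: float = 0.05,
    n_replicates: int = 3,
    base_count_mean: float = 200.0,
    seed: int = 0,
) -> dict:
    """Toy genome + peaks + motifs with a planted motif->accessibility model.

    Each peak window carries each motif with probability ``presence_prob``
    (an instance sampled from the PWM is written into the sequence at a
    random offset).  The latent fold change is y = X w* + eps with
    ``n_active_motifs`` nonzero coefficients of magnitude ``effect_size``
    (alternating sign) and eps scaled so sd(Xw*)/sd(eps) = ``snr`` (pure
    noise of unit-effect scale when no motif is active).  Two-condition
    counts realize y as Poisson-lognormal replicates.  Gene models are laid
    out so every annotation class (promoter, exonic, intronic, intergenic,
    unclassified) occurs.
    """
    if n_active_motifs > n_motifs:
        raise ValueError("n_active_motifs must not exceed n_motifs")
    rng = np.random.default_rng(seed)
    spacing = 2000
    chrom = "chr1"
    genome_len = (n_peaks + 2) * spacing
    seq = rng.choice(4, genome_len)

    motifs = [
        MotifModel(
            motif_id=f"M{m:03d}",
            ppm=_random_ppm(rng, motif_length, concentration=20.0),
        )
        for m in range(n_motifs)
    ]
    summits = (np.arange(n_peaks) + 1) * spacing
    half = window // 2
    presence = rng.random((n_peaks, n_motifs)) < presence_prob
    # cap per-window site load so placement stays feasible
    max_sites = window // (2 * motif_length)
    for p in range(n_peaks):
        heavy = np.flatnonzero(presence[p])
        if heavy.size > max_sites:
            drop = rng.choice(heavy, size=heavy.size - max_sites, replace=False)
            presence[p, drop] = False
    for p in range(n_peaks):
        offsets_used: list[tuple[int, int]] = []
        for m in np.flatnonzero(presence[p]):
            site = _sample_site(rng, motifs[m].ppm)
            # rejection-sample an offset that does not collide with other sites
            for _attempt in range(200):
                off = int(rng.integers(0, window - motif_length))
                if all(
                    off + motif_length <= s or off >= s + l for s, l in offsets_used
                ):
                    break
            else:
                raise RuntimeError("could not place motif instance without collision")
            start = summits[p] - half + off
            enc = np.array([_BASE_LOOKUP[b] for b in site])
            seq[start: start + motif_length] = enc
            offsets_used.append((off, motif_length))

    active = sorted(rng.choice(n_motifs, size=n_active_motifs, replace=False))
    w = np.zeros(n_motifs)
    for i, m in enumerate(active):
        w[m] = effect_size * (1 if i % 2 == 0 else -1)
    signal = presence.astype(float) @ w
    if n_active_motifs > 0 and signal.std() > 0:
        noise_sd = signal.std() / snr
    else:
        noise_sd = effect_size / snr if effect_size > 0 else 0.25
    y = signal + rng.normal(0, noise_sd, n_peaks)

    base = rng.lognormal(np.log(base_count_mean), 0.5, n_peaks)
    counts = {}
    for cond, sign in (("condA", +0.5), ("condB", -0.5)):
        for r in range(n_replicates):
            lam = base * np.exp2(sign * y) * rng.lognormal(0, 0.05, n_peaks)
            counts[f"{cond}_r{r}"] = rng.poisson(lam)
    count_table = pd.DataFrame(counts, index=[f"peak_{i}" for i in range(n_peaks)])

    peaks = pd.DataFrame(
        {
            "chrom": chrom,
            "start": summits - 150,
            "end": summits + 150,
            "summit": summits,
            "peak_id": [f"peak_{i}" for i in range(n_peaks)],
        }
    )

    # gene models spread over the first genes' worth of peaks so each
    # annotation class appears: TSS near some summits (promoter), exons over
    # others, gene bodies without exon overlap (intronic), nearby genes
    # (intergenic) and long empty stretches (unclassified)
    gene_rows, tss_rows, exon_rows = [], [], []
    stride = max(1, n_peaks // max(n_genes, 1))
    for gi in range(n_genes):
        p = gi * stride
        if p >= n_peaks:
            break
        s = summits[p]
        kind = gi % 5
        gid = f"gene_{gi:03d}"
        if kind == 0:  # promoter: TSS at the summit
            start, end, tss = s, s + 5000, s
            exon_rows.append({"gene_id": gid, "start": s + 3000, "end": s + 3500})
        elif kind == 1:  # exonic: exon across the window, TSS far away
            start, end, tss = s - 20_000, s + 5000, s - 20_000
            exon_rows.append({"gene_id": gid, "start": s - 200, "end": s + 200})
        elif kind == 2:  # intronic: body spans window, exons elsewhere
            start, end, tss = s - 20_000, s + 5000, s - 20_000
            exon_rows.append({"gene_id": gid, "start": s + 3000, "end": s + 3400})
        elif kind == 3:  # intergenic: gene within 50 kb but not overlapping
            start, end, tss = s + 10_000, s + 15_000, s + 10_000
            exon_rows.append({"gene_id": gid, "start": s + 10_000, "end": s + 10_400})
        else:  # leave this peak unclassified (no gene within 50 kb)
            continue
        gene_rows.append(
            {"gene_id": gid, "chrom": chrom, "strand": "+", "start": start, "end": end}
        )
        tss_rows.append({"gene_id": gid, "pos": tss})
    gene_model = GeneModel(
        genes=pd.DataFrame(gene_rows),
        tss=pd.DataFrame(tss_rows),
        exons=pd.DataFrame(exon_rows),
    )

    genome = {chrom: "".join(_BASES[seq])}
    truth = AtacTruth(
        genome=genome,
        w_star=pd.Series(w, index=[m.motif_id for m in motifs]),
        motif_presence=pd.DataFrame(
            presence.astype(int),
            index=[f"peak_{i}" for i in range(n_peaks)],
            columns=[m.motif_id for m in motifs],
        ),
        log2fc=pd.Series(y, index=[f"peak_{i}" for i in range(n_peaks)]),
        noise_sd=float(noise_sd),
        active_motifs=[f"M{m:03d}" for m in active],
    )
    return {
        "genome": genome,
        "genes": gene_model,
        "peaks": peaks,
        "motifs": motifs,
        "counts": count_table,
        "truth": truth,
    }


_BASE_LOOKUP = {"A": 0, "C": 1, "G": 2, "T": 3}


# ------------------------------------------------------------ bulk profiles


def make_bulk_profiles(
    centroids: pd.DataFrame,
    n_replicates: int = 3,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Bulk replicates: centroid + lognormal noise, as normalized counts.

    ``centroids`` is clusters x genes on the log2 scale; each replicate adds
    Gaussian noise on that scale and exponentiates.
    """
    rng = np.random.default_rng(seed)
    rows = {}
    for cl in centroids.index:
        base = centroids.loc[cl].to_numpy(dtype=float)
        for r in range(n_replicates):
            noisy = base + rng.normal(0, noise_sd, base.size)
            rows[f"{cl}_rep{r}"] = np.exp2(noisy)
    return pd.DataFrame(rows, index=centroids.columns).T
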