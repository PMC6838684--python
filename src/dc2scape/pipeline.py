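"""Run configuration and end-to-end recipes chaining the analysis modules.

A :class:`RunConfig` validates per-stage parameter blocks (unknown keys are
rejected) and every run writes a resolved-config copy plus a provenance
manifest (package version, seed, parameters, input checksums) next to its
outputs.  Recipes persist intermediate artifacts so a run can be inspected or
resumed stage by stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("dc2scape")

_STAGE_SCHEMAS: dict[str, set[str]] = {
    "global": {"seed", "out_dir"},
    "preprocess": {
        "preset", "max_mito_frac", "min_genes", "min_molecules", "min_cells",
        "pseudocount", "n_pcs",
    },
    "impute": {"k", "ka", "t"},
    "diffmap": {"max_components", "n_components"},
    "markers": {"auc_min", "emd_sd_multiplier", "two_sided", "contrasts"},
    "paths": {"k", "l", "n_samples", "n_neighbors", "source", "target"},
    "robustness": {"n_pcs_values", "k_values", "default_k"},
    "correspond": {"total_count_min", "alpha", "n_folds", "fdr_max"},
    "atac": {
        "window", "min_peak_size", "p_threshold", "min_prevalence",
        "max_prevalence", "top_n_peaks", "n_folds",
    },
    "simulate": {
        "n_cells", "n_genes", "n_subsets", "n_markers_per_subset",
        "marker_effect", "dropout", "n_peaks", "n_motifs", "n_active_motifs",
        "effect_size", "snr",
    },
}


@dataclass
class RunConfig:
    stages: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for stage, params in self.stages.items():
            if stage not in _STAGE_SCHEMAS:
                raise ValueError(f"unknown config stage {stage!r}")
            unknown = set(params) - _STAGE_SCHEMAS[stage]
            if unknown:
                raise ValueError(
                    f"unknown keys in stage {stage!r}: {sorted(unknown)}"
                )
        if "seed" not in self.stages.get("global", {}):
            raise ValueError("global.seed is mandatory (no silent defaults)")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls(stages=data)

    @property
    def seed(self) -> int:
        return int(self.stages["global"]["seed"])

    def get(self, stage: str, key: str, default=None):
        return self.stages.get(stage, {}).get(key, default)

    def resolved(self) -> dict:
        return {s: dict(p) for s, p in self.stages.items()}


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def _write_manifest(out_dir: Path, config: RunConfig, recipe: str, inputs: dict) -> None:
    from . import __version__

    manifest = {
        "package": "dc2scape",
        "version": __version__,
        "recipe": recipe,
        "seed": config.seed,
        "parameters": config.resolved(),
        "input_checksums": {
            k: _checksum(Path(v)) for k, v in inputs.items() if Path(str(v)).is_file()
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    (out_dir / "resolved_config.json").write_text(
        json.dumps(config.resolved(), indent=2) + "\n"
    )


def run_recipe(config: RunConfig, recipe: str, inputs: dict | None = None) -> dict:
    """Execute a named recipe end to end, persisting artifacts + manifest.

    Recipes: ``sc_markers`` (simulate or load counts -> preprocess -> impute
    -> marker table -> selection), ``trajectory`` (branching data ->
    diffusion map -> sampled shortest paths), ``correspondence`` (two
    simulated datasets -> centroid correlation), ``atac`` (toy genome ->
    atlas -> scan -> lasso).  Inputs override simulation with file paths.
    Any stage failure aborts with the stage name; artifacts persisted so far
    remain on disk.
    """
    inputs = inputs or {}
    out_dir = Path(config.get("global", "out_dir", "dc2scape_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        if recipe == "sc_markers":
            result = _recipe_sc_markers(config, inputs, out_dir)
        elif recipe == "trajectory":
            result = _recipe_trajectory(config, out_dir)
        elif recipe == "correspondence":
            result = _recipe_correspondence(config, out_dir)
        elif recipe == "atac":
            result = _recipe_atac(config, out_dir)
        else:
            raise ValueError(f"unknown recipe {recipe!r}")
    except Exception as exc:
        stage = getattr(exc, "_dc2scape_stage", stage)
        raise RuntimeError(f"recipe {recipe!r} failed at stage {stage!r}: {exc}") from exc
    _write_manifest(out_dir, config, recipe, inputs)
    return result


def _tag(exc: Exception, stage: str) -> Exception:
    exc._dc2scape_stage = stage  # type: ignore[attr-defined]
    return exc


def _recipe_sc_markers(config: RunConfig, inputs: dict, out_dir: Path) -> dict:
    from . import io as dio
    from . import markers as mk
    from . import sc_preprocess as pp
    from .diffusion import adaptive_affinity, impute, markov_normalize
    from .simulate import make_sc_counts

    seed = config.seed
    if "counts_csv" in inputs:
        counts = dio.read_counts_csv(inputs["counts_csv"])
        labels = pd.read_csv(
            inputs["labels_tsv"], sep="\t", header=None, index_col=0
        )[1].astype(str)
    else:
        sim_kwargs = dict(config.stages.get("simulate", {}))
        counts, truth = make_sc_counts(seed=seed, **sim_kwargs)
        labels = truth.subset
    preset = config.get("preprocess", "preset", "mouse_spleen")
    from .sc_preprocess import FILTER_PRESETS

    thresholds = dict(FILTER_PRESETS[preset])
    for key in ("max_mito_frac", "min_genes", "min_molecules"):
        v = config.get("preprocess", key)
        if v is not None:
            thresholds[key] = v
    counts, cell_report = pp.filter_cells(counts, **thresholds)
    counts, gene_report = pp.filter_genes(
        counts, min_cells=config.get("preprocess", "min_cells", 10)
    )
    pd.DataFrame(cell_report.as_rows() + gene_report.as_rows()).to_csv(
        out_dir / "qc_report.tsv", sep="\t", index=False
    )
    expr = pp.normalize(counts, pseudocount=config.get("preprocess", "pseudocount", 0.1))
    pca = pp.compute_pca(expr, n_components=config.get("preprocess", "n_pcs", 20))
    op = markov_normalize(
        adaptive_affinity(
            pca.scores, k=config.get("impute", "k", 30), ka=config.get("impute", "ka", 10)
        )
    )
    imputed = impute(expr, op, t=config.get("impute", "t", 4))
    table = mk.marker_table(imputed, labels.reindex(imputed.cell_ids))
    table.to_csv(out_dir / "marker_table.tsv", sep="\t", index=False)
    rule = mk.SelectionRule(
        auc_min=config.get("markers", "auc_min", 0.99),
        emd_sd_multiplier=config.get("markers", "emd_sd_multiplier", 3.0),
        two_sided=config.get("markers", "two_sided", False),
    )
    selected = mk.select_markers(table, rule)
    selected.to_csv(out_dir / "selected_markers.tsv", sep="\t", index=False)
    return {"marker_table": table, "selected": selected, "out_dir": out_dir}


def _recipe_trajectory(config: RunConfig, out_dir: Path) -> dict:
    from .diffusion import adaptive_affinity, diffusion_map, multiscale_distances
    from .simulate import make_branching_traj
    from .trajectory import knn_graph, path_membership, sample_kl_paths

    seed = config.seed
    expr, truth = make_branching_traj(seed=seed)
    graph = adaptive_affinity(expr.values, k=30, ka=10)
    dm = diffusion_map(graph, max_components=config.get("diffmap", "max_components", 10))
    n_comp = config.get("diffmap", "n_components")
    dist = multiscale_distances(dm, n_components=n_comp)
    cg = knn_graph(dist, k=config.get("paths", "k", 15))
    t = truth.pseudotime.to_numpy()
    source = int(np.argmin(t))
    branch = truth.branch.to_numpy()
    tips_a = np.flatnonzero(branch == "A")
    target = int(tips_a[np.argmax(t[tips_a])])
    ens = sample_kl_paths(
        cg, source, target,
        l=config.get("paths", "l", 5),
        n_samples=config.get("paths", "n_samples", 100),
        seed=seed,
    )
    membership = path_membership(
        ens, truth.branch, dist, n_neighbors=config.get("paths", "n_neighbors", 20)
    )
    membership.to_csv(out_dir / "path_membership.tsv", sep="\t", index=False)
    return {"ensemble": ens, "membership": membership, "out_dir": out_dir}


def _recipe_correspondence(config: RunConfig, out_dir: Path) -> dict:
    from .correspondence import OrthologMap, centroid_profiles, correlate_profiles
    from .sc_preprocess import filter_genes, normalize
    from .simulate import make_sc_counts

    seed = config.seed
    corr_pair = []
    labels = []
    for offset in (0, 1):
        counts, truth = make_sc_counts(seed=seed + offset)
        counts, _ = filter_genes(counts, 10)
        expr = normalize(counts)
        corr_pair.append(centroid_profiles(expr, truth.subset))
        labels.append(truth.subset)
    omap = OrthologMap([(g, g) for g in corr_pair[0].values.columns])
    corr = correlate_profiles(corr_pair[0], corr_pair[1], ortholog_map=omap)
    corr.to_csv(out_dir / "cluster_correlation.tsv", sep="\t")
    return {"correlation": corr, "out_dir": out_dir}


def _recipe_atac(config: RunConfig, out_dir: Path) -> dict:
    from .atac import (
        annotate_peaks, build_atlas, differential_accessibility,
        extract_window_sequences, lasso_association, scan_motifs, top_motifs,
    )
    from .simulate import make_atac_toy

    seed = config.seed
    sim_kwargs = {
        k: v for k, v in config.stages.get("simulate", {}).items()
        if k in {"n_peaks", "n_motifs", "n_active_motifs", "effect_size", "snr"}
    }
    toy = make_atac_toy(seed=seed, **sim_kwargs)
    atlas = build_atlas(
        toy["peaks"],
        window=config.get("atac", "window", 150),
        min_peak_size=config.get("atac", "min_peak_size", 76),
    )
    annotation = annotate_peaks(atlas, toy["genes"])
    annotation.to_csv(out_dir / "peak_annotation.tsv", sep="\t", index=False)
    groups = {
        "condA": [c for c in toy["counts"].columns if c.startswith("condA")],
        "condB": [c for c in toy["counts"].columns if c.startswith("condB")],
    }
    da = differential_accessibility(toy["counts"], groups)
    da.table.to_csv(out_dir / "differential_accessibility.tsv", sep="\t")
    seqs = extract_window_sequences(atlas, toy["genome"])
    hits = scan_motifs(
        seqs, toy["motifs"], p_threshold=config.get("atac", "p_threshold", 5e-4)
    )
    fit = lasso_association(
        da, hits,
        top_n_peaks=config.get("atac", "top_n_peaks", 20_000),
        n_folds=config.get("atac", "n_folds", 5),
        seed=seed,
    )
    ranked = top_motifs(fit, 50)
    ranked.to_csv(out_dir / "top_motifs.tsv", sep="\t", index=False)
    return {"fit": fit, "top_motifs": ranked, "truth": toy["truth"], "out_dir": out_dir}
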