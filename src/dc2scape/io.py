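"""Readers and writers for the plain-text formats the pipeline consumes.

Count matrices travel as MatrixMarket triplets with barcode/gene TSVs (the
10X convention) or as dense CSV with cells in rows; partitions as two-column
TSV; motifs in MEME minimal format; genomes as FASTA; peaks as BED-derived
tables.  Everything round-trips bit-exactly through these functions.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .atac import MotifModel
from .robustness import Partition
from .sc_preprocess import CountMatrix, ExpressionMatrix


# ------------------------------------------------------------ count matrix


def read_counts_mtx(mtx_path, barcodes_path, genes_path) -> CountMatrix:
    """10X-convention triplet: matrix.mtx (genes x cells), barcodes, genes."""
    m = scipy_io.mmread(str(mtx_path))
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
    values = np.asarray(sparse.csr_matrix(m).T.todense())  # cells x genes
    return CountMatrix(values=values, cell_ids=barcodes, gene_ids=genes)


def write_counts_mtx(counts: CountMatrix, mtx_path, barcodes_path, genes_path) -> None:
    scipy_io.mmwrite(str(mtx_path), sparse.coo_matrix(counts.values.T))
    Path(barcodes_path).write_text("\n".join(counts.cell_ids) + "\n")
    Path(genes_path).write_text("\n".join(counts.gene_ids) + "\n")


def read_counts_csv(path) -> CountMatrix:
    """Dense CSV, cells in rows, first column = cell id, header = gene ids."""
    df = pd.read_csv(path, index_col=0)
    return CountMatrix(
        values=df.to_numpy(), cell_ids=df.index.astype(str).tolist(),
        gene_ids=df.columns.astype(str).tolist(),
    )


def write_counts_csv(counts: CountMatrix, path) -> None:
    pd.DataFrame(
        counts.values, index=counts.cell_ids, columns=counts.gene_ids
    ).to_csv(path)


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    pd.DataFrame(
        expr.values, index=expr.cell_ids, columns=expr.gene_ids
    ).to_csv(path, sep="\t")


def read_expression_tsv(path, state_tag: str = "normalized") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float), cell_ids=df.index.astype(str).tolist(),
        gene_ids=df.columns.astype(str).tolist(), state_tag=state_tag,
    )


# -------------------------------------------------------------- partitions


def read_partition_tsv(path) -> Partition:
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "label"], dtype=str)
    return Partition(dict(zip(df["cell_id"], df["label"])))


def write_partition_tsv(p: Partition, path) -> None:
    with open(path, "w") as fh:
        for cell, lab in sorted(p.labels.items()):
            fh.write(f"{cell}\t{lab}\n")


# ------------------------------------------------------------------ motifs


def read_meme_minimal(path, background=None) -> list[MotifModel]:
    """MEME minimal-format motif file -> PWM models (via Bio.motifs)."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
    out = []
    for rec in records:
        counts = np.array(
            [[rec.counts[b][i] for b in "ACGT"] for i in range(rec.length)],
            dtype=float,
        )
        ppm = counts / counts.sum(axis=1, keepdims=True)
        kwargs = {} if background is None else {"background": background}
        out.append(MotifModel(motif_id=rec.name, ppm=ppm, **kwargs))
    return out


def write_meme_minimal(motifs: list[MotifModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = motifs[0].background if motifs else np.full(4, 0.25)
        fh.write(
            "Background letter frequencies\n"
            f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n"
        )
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.length} "
                f"nsites= 1000000 E= 0\n"
            )
            for row in m.ppm:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


# ------------------------------------------------------------------- fasta


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


# --------------------------------------------------------------------- bed


def read_summit_bed(path) -> pd.DataFrame:
    """MACS2 summit-BED dialect: chrom, start, end, name[, score].

    Summit position is taken as the interval start (summit BEDs are
    single-base intervals); the peak is the enclosing interval when a
    companion peak BED is merged by the caller.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end", 3: "peak_id"})
    df["summit"] = df["start"]
    return df


def write_bed(df: pd.DataFrame, path, columns=("chrom", "start", "end", "peak_id")) -> None:
    df[list(columns)].to_csv(path, sep="\t", header=False, index=False)


# ------------------------------------------------------------------- misc


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene-set collection: name, description, genes..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
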