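"""Readers and writers for the plain-text interchange formats.

Counts travel as MatrixMarket MTX plus genes/barcodes/metadata TSVs; spatial
data as tissue-positions and proportions CSVs; gene sets as GMT; gene panels
and survival tables as TSV/CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from tissuestates._errors import InvalidArgumentError
from tissuestates.synthetic import (
    AnnotatedCountMatrix,
    GenePanel,
    SpatialDataset,
    SurvivalTable,
)

# --- gene panel -------------------------------------------------------------


def write_gene_panel(panel: GenePanel, path: str | Path) -> None:
    panel.to_frame().to_csv(path, sep="\t", index=False)


def read_gene_panel(path: str | Path) -> GenePanel:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return GenePanel(
        gene_ids=df["gene_id"].to_numpy(dtype=object),
        chromosomes=df["chromosome"].to_numpy(dtype=object),
        position_index=df["position_index"].to_numpy(dtype=int),
    )


# --- snRNA-seq counts -------------------------------------------------------


def write_snrnaseq(matrix: AnnotatedCountMatrix, outdir: str | Path) -> None:
    """Write counts as matrix.mtx + genes.tsv + barcodes.tsv + metadata.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy_io.mmwrite(outdir / "matrix.mtx", sparse.coo_matrix(matrix.counts))
    pd.Series(matrix.gene_ids).to_csv(
        outdir / "genes.tsv", sep="\t", index=False, header=False
    )
    pd.Series(matrix.nucleus_ids).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    meta = matrix.nucleus_meta.join(matrix.qc)
    meta.to_csv(outdir / "metadata.tsv", sep="\t")


def read_snrnaseq(indir: str | Path) -> AnnotatedCountMatrix:
    indir = Path(indir)
    counts = np.asarray(scipy_io.mmread(indir / "matrix.mtx").todense()).astype(
        np.int64
    )
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].to_numpy(
        dtype=object
    )
    meta = pd.read_csv(indir / "metadata.tsv", sep="\t", index_col=0)
    qc_cols = ["n_genes", "total_reads", "mito_fraction"]
    missing = [c for c in qc_cols if c not in meta.columns]
    if missing:
        raise InvalidArgumentError(f"metadata missing QC columns: {missing}")
    return AnnotatedCountMatrix(
        counts=counts,
        gene_ids=genes,
        nucleus_meta=meta.drop(columns=qc_cols),
        qc=meta[qc_cols],
    )


# --- spatial ----------------------------------------------------------------


def write_spatial(ds: SpatialDataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.positions.to_csv(outdir / "tissue_positions.csv")
    ds.proportions.to_csv(outdir / "proportions.csv")


def read_spatial(indir: str | Path, sample_id: str | None = None) -> SpatialDataset:
    indir = Path(indir)
    positions = pd.read_csv(indir / "tissue_positions.csv", index_col=0)
    proportions = pd.read_csv(indir / "proportions.csv", index_col=0)
    return SpatialDataset(
        positions=positions,
        proportions=proportions,
        sample_id=sample_id or indir.name,
    )


# --- survival ---------------------------------------------------------------


def write_survival(table: SurvivalTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def read_survival(path: str | Path) -> SurvivalTable:
    return SurvivalTable(data=pd.read_csv(path))


# --- gene sets (GMT) --------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: one set per line — name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise InvalidArgumentError(f"malformed GMT line: {line[:50]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, "na", *genes]) for name, genes in gene_sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# --- expression tables ------------------------------------------------------


def read_expression(path: str | Path) -> pd.DataFrame:
    """Gene x sample table from CSV or TSV (extension-sniffed)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, index_col=0)
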