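"""Readers and writers for the plain-text formats used throughout.

Expression matrices are TSV with genes as rows and a header row of sample
ids; counts may alternatively be MatrixMarket (.mtx) with separate gene and
sample index files.  The regulatory model is a weighted edge-list TSV.
Gene sets use standard GMT (name, description, then tab-separated genes).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import ExpressionMatrix, RegulatoryModel


def read_expression_tsv(path, space: str = "counts") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, space)


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id")


def read_expression_mtx(mtx_path, gene_path, sample_path, space: str = "counts") -> ExpressionMatrix:
    """MatrixMarket counts with one-column gene/sample index files (genes rows)."""
    mat = scipy.io.mmread(mtx_path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    genes = pd.read_csv(gene_path, sep="\t", header=None)[0].astype(str)
    samples = pd.read_csv(sample_path, sep="\t", header=None)[0].astype(str)
    df = pd.DataFrame(mat, index=genes, columns=samples)
    return ExpressionMatrix(df, space)


def read_metadata_tsv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample_id")
    meta.index = meta.index.astype(str)
    return meta


def write_metadata_tsv(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_annotation_tsv(path) -> pd.DataFrame:
    """Gene annotation with columns gene_id, and optionally biotype, chromosome, arm."""
    ann = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in ann.columns:
        raise ValueError("annotation requires a gene_id column")
    return ann.set_index("gene_id")


def read_model_tsv(path) -> RegulatoryModel:
    edges = pd.read_csv(path, sep="\t", dtype={"predictor": str, "target": str})
    provenance = {}
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        provenance = json.loads(sidecar.read_text())
    return RegulatoryModel(edges, provenance)


def write_model_tsv(model: RegulatoryModel, path) -> None:
    model.edges.to_csv(path, sep="\t", index=False)
    if model.provenance:
        Path(str(path) + ".json").write_text(json.dumps(model.provenance, indent=2, default=str))


def read_gmt(path) -> dict:
    """Parse a GMT file into {set name: list of gene ids}.

    Each line: name <tab> description <tab> gene1 <tab> gene2 ...
    """
    sets: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line[:60]!r}")
            name = parts[0]
            genes = [g for g in parts[2:] if g]
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            sets[name] = genes
    return sets


def write_gmt(sets: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *map(str, genes)]) + "\n")


def write_rnk(scores: pd.Series, path) -> None:
    """Ranked gene list (gene, score) for external preranked enrichment tools."""
    scores.sort_values(ascending=False).to_csv(path, sep="\t", header=False)
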