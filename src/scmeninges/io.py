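"""Readers and writers for the pipeline's on-disk formats.

Counts travel as a Matrix Market sparse file with TSV sidecars for cell
metadata and gene ids; annotations, gene sets, atlases and spatial transcript
tables are plain TSV.  All readers validate and reject malformed data rather
than coercing it; gene-name matching across files is exact and case-sensitive,
with dropped genes reported through the module logger.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import (
    CountMatrix,
    FormatError,
    GeneAnnotation,
    GeneSet,
    ReferenceAtlas,
    SpatialTranscripts,
)

logger = logging.getLogger("scmeninges")

_MATRIX = "matrix.mtx"
_CELLS = "cells.tsv"
_GENES = "genes.tsv"


def write_counts(m: CountMatrix, path: str | Path) -> None:
    """Write ``m`` into directory ``path`` as matrix.mtx + cells/genes TSV."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(path / _MATRIX), sparse.coo_matrix(m.counts))
    cells = m.cell_meta.copy()
    cells.insert(0, "cell_id", m.cell_ids)
    cells.to_csv(path / _CELLS, sep="\t", index=False)
    pd.DataFrame({"gene_id": m.gene_ids}).to_csv(path / _GENES, sep="\t", index=False)


def read_counts(path: str | Path) -> CountMatrix:
    """Read a count matrix written by :func:`write_counts` (lossless)."""
    path = Path(path)
    for name in (_MATRIX, _CELLS, _GENES):
        if not (path / name).exists():
            raise FileNotFoundError(f"missing sidecar {name} under {path}")
    mat = spio.mmread(str(path / _MATRIX)).tocsr()
    cells = pd.read_csv(path / _CELLS, sep="\t", dtype={"cell_id": str})
    genes = pd.read_csv(path / _GENES, sep="\t", dtype=str)
    if "cell_id" not in cells.columns or "gene_id" not in genes.columns:
        raise FormatError(f"sidecars under {path} lack cell_id/gene_id headers")
    cell_ids = cells.pop("cell_id").to_numpy(dtype=object)
    if mat.shape != (len(cell_ids), len(genes)):
        raise FormatError(
            f"{path}: matrix is {mat.shape} but sidecars describe "
            f"{len(cell_ids)} cells x {len(genes)} genes"
        )
    meta = cells.set_axis(pd.Index(cell_ids))
    return CountMatrix(cell_ids, genes["gene_id"].to_numpy(dtype=object), mat, meta)


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    """Read gene coordinates from TSV.

    Two dialects, auto-detected by header:

    * 3-column: ``gene  chromosome  position``
    * BED-style: ``chrom  start  end  gene`` (0-based half-open;
      position := start)
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if {"gene", "position"} <= set(cols) and ("chromosome" in cols or "chrom" in cols):
        chrom_col = "chromosome" if "chromosome" in cols else "chrom"
        table = pd.DataFrame(
            {"chromosome": df[chrom_col].to_numpy(),
             "position": df["position"].to_numpy(dtype=np.int64)},
            index=pd.Index(df["gene"].to_numpy(), name="gene"),
        )
    elif {"chrom", "start", "end", "gene"} <= set(cols):
        table = pd.DataFrame(
            {"chromosome": df["chrom"].to_numpy(),
             "position": df["start"].to_numpy(dtype=np.int64)},
            index=pd.Index(df["gene"].to_numpy(), name="gene"),
        )
    else:
        raise FormatError(
            f"{path}: unrecognized annotation header {list(df.columns)}; expected "
            "(gene, chromosome, position) or BED-style (chrom, start, end, gene)"
        )
    return GeneAnnotation(table)


def write_gene_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    out = ann.table.reset_index()
    out.columns = ["gene", "chromosome", "position"]
    out.to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str | Path) -> dict[str, GeneSet]:
    """Read gene sets from a 2-column TSV (``set`` and ``gene``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"set", "gene"} <= set(df.columns):
        raise FormatError(f"{path}: gene-set TSV needs columns 'set' and 'gene'")
    out: dict[str, GeneSet] = {}
    for name, sub in df.groupby("set", sort=False):
        genes = list(sub["gene"])
        if len(set(genes)) != len(genes):
            raise FormatError(f"{path}: duplicate gene within set {name!r}")
        out[str(name)] = GeneSet(str(name), tuple(genes))
    return out


def write_gene_sets(sets: dict[str, GeneSet], path: str | Path) -> None:
    rows = [(s.name, g) for s in sets.values() for g in s.genes]
    pd.DataFrame(rows, columns=["set", "gene"]).to_csv(path, sep="\t", index=False)


def read_atlas(path: str | Path) -> ReferenceAtlas:
    """Read a cluster x gene atlas TSV (first column = cluster id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ReferenceAtlas(
        cluster_ids=df.index.to_numpy(dtype=object),
        gene_ids=df.columns.to_numpy(dtype=object),
        values=df.to_numpy(dtype=float),
    )


def write_atlas(atlas: ReferenceAtlas, path: str | Path) -> None:
    pd.DataFrame(
        atlas.values, index=pd.Index(atlas.cluster_ids), columns=atlas.gene_ids
    ).to_csv(path, sep="\t")


def read_spatial_transcripts(path: str | Path) -> SpatialTranscripts:
    df = pd.read_csv(
        path, sep="\t", dtype={"gene": str, "cell_id": str}, keep_default_na=False
    )
    return SpatialTranscripts(df)


def write_spatial_transcripts(s: SpatialTranscripts, path: str | Path) -> None:
    s.table.to_csv(path, sep="\t", index=False)


def match_genes(
    source: np.ndarray | list, target: np.ndarray | list, context: str = "join"
) -> tuple[list, list]:
    """Exact, case-sensitive gene matching between two id lists.

    Returns ``(shared in source order, dropped from source)`` and logs the
    dropped genes so every cross-file join leaves an audit trail.
    """
    target_set = set(target)
    shared = [g for g in source if g in target_set]
    dropped = [g for g in source if g not in target_set]
    if dropped:
        logger.warning(
            "%s: dropped %d/%d genes absent from target (first: %s)",
            context, len(dropped), len(source), dropped[:5],
        )
    return shared, dropped
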