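"""Two-round single-cell QC and targeted spatial-panel QC/normalization.

Round 1 filters individual cells on total UMIs, unspliced-molecule fraction
and doublet score.  Round 2, applied after clustering, removes whole
clusters dominated by low-UMI cells.  Spatial QC keeps only
nucleus-assigned transcripts, applies per-sample-type minima on detected
genes and total transcripts, and normalizes kept cells to a fixed total
followed by log(1+x).

Boundary semantics are uniform: "fewer than"/"less than" thresholds are
strict (<); "at least" is >=.  The doublet criterion removes high scores
(score >= cutoff), matching doublet-caller semantics in which a high score
marks a likely doublet; ``doublet_high_is_doublet=False`` flips the
direction for users who want the opposite reading.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import sparse

from .containers import CountMatrix, SpatialTranscripts

logger = logging.getLogger("scmeninges")


@dataclass(frozen=True)
class QcThresholds:
    min_umis: float = 1000
    min_unspliced_fraction: float = 0.1
    doublet_score_cutoff: float = 0.4
    round2_min_umis: float = 1800
    round2_low_fraction: float = 0.40
    spatial_min_genes: int = 8          # 3 for tumour panels
    spatial_min_transcripts: int = 20   # 5 for tumour panels
    spatial_norm_total: float = 10_000

    def __post_init__(self) -> None:
        for name in ("min_umis", "doublet_score_cutoff", "round2_min_umis",
                     "spatial_min_genes", "spatial_min_transcripts",
                     "spatial_norm_total"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("min_unspliced_fraction", "round2_low_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @classmethod
    def fetal(cls) -> "QcThresholds":
        return cls()

    @classmethod
    def tumour(cls) -> "QcThresholds":
        return replace(cls(), spatial_min_genes=3, spatial_min_transcripts=5)


def filter_cells(
    m: CountMatrix,
    t: QcThresholds = QcThresholds(),
    doublet_high_is_doublet: bool = True,
) -> tuple[np.ndarray, list[tuple[str, ...]]]:
    """Round-1 per-cell filter.

    Returns (pass mask, per-cell reason tuples).  A cell fails iff any
    criterion fails; its reasons list every failed criterion, so pass is
    equivalent to an empty reason set.  Criteria whose metadata column is
    absent are skipped with a warning.
    """
    totals = m.total_counts()
    n = m.n_cells
    reasons: list[list[str]] = [[] for _ in range(n)]

    for i in np.flatnonzero(totals < t.min_umis):
        reasons[i].append("low_umis")

    if "unspliced_fraction" in m.cell_meta:
        frac = np.asarray(m.cell_meta["unspliced_fraction"], float)
        for i in np.flatnonzero(frac < t.min_unspliced_fraction):
            reasons[i].append("low_unspliced_fraction")
    else:
        logger.warning("unspliced_fraction missing; criterion skipped")

    if "doublet_score" in m.cell_meta:
        score = np.asarray(m.cell_meta["doublet_score"], float)
        if doublet_high_is_doublet:
            bad = score >= t.doublet_score_cutoff
        else:
            bad = score < t.doublet_score_cutoff
        for i in np.flatnonzero(bad):
            reasons[i].append("doublet")
    else:
        logger.warning("doublet_score missing; criterion skipped")

    out = [tuple(r) for r in reasons]
    mask = np.array([not r for r in out])
    return mask, out


def filter_clusters(
    m: CountMatrix,
    clusters: np.ndarray | pd.Series | list,
    t: QcThresholds = QcThresholds(),
) -> set:
    """Round-2 cluster filter: remove a cluster iff at least
    ``round2_low_fraction`` of its cells have fewer than ``round2_min_umis``
    UMIs.  Empty clusters are skipped with a warning."""
    clusters = np.asarray(clusters, dtype=object)
    if len(clusters) != m.n_cells:
        raise ValueError("cluster labels do not match cell count")
    totals = m.total_counts()
    removed = set()
    for c in pd.unique(clusters):
        idx = clusters == c
        n = int(idx.sum())
        if n == 0:
            logger.warning("cluster %r is empty; skipped", c)
            continue
        low = int((totals[idx] < t.round2_min_umis).sum())
        if low / n >= t.round2_low_fraction:
            removed.add(c)
    return removed


def spatial_qc_normalize(
    s: SpatialTranscripts,
    t: QcThresholds = QcThresholds(),
    panel: list[str] | None = None,
) -> CountMatrix:
    """Build a QC'd, normalized cell x gene matrix from a transcript table.

    Keeps only nucleus-assigned transcripts (and panel genes when a panel is
    given), drops cells below the detected-gene / total-transcript minima,
    scales each kept cell to ``spatial_norm_total`` and stores log(1+x) in
    ``layers["lognorm"]`` alongside the raw counts.  With no surviving cells
    the returned matrix simply has zero rows.
    """
    tab = s.table
    keep = tab["in_nucleus"] & (tab["cell_id"] != "")
    if panel is not None:
        keep &= tab["gene"].isin(panel)
    tab = tab[keep]

    genes = sorted(panel) if panel is not None else sorted(tab["gene"].unique())
    pivot = (
        tab.groupby(["cell_id", "gene"]).size().unstack(fill_value=0)
        .reindex(columns=genes, fill_value=0)
    )
    if len(pivot):
        n_genes_det = (pivot > 0).sum(axis=1)
        n_txp = pivot.sum(axis=1)
        pivot = pivot[(n_genes_det >= t.spatial_min_genes)
                      & (n_txp >= t.spatial_min_transcripts)]
    if not len(pivot):
        logger.warning("spatial QC left no surviving cells")
        return CountMatrix(
            np.array([], dtype=object), np.array(genes, dtype=object),
            sparse.csr_matrix((0, len(genes))),
        )
    counts = pivot.to_numpy(dtype=np.int64)
    totals = counts.sum(axis=1, keepdims=True)
    norm = counts / totals * t.spatial_norm_total
    m = CountMatrix(
        pivot.index.to_numpy(dtype=object), np.array(genes, dtype=object),
        sparse.csr_matrix(counts),
        pd.DataFrame({"total_umis": totals.ravel()}, index=pivot.index),
    )
    m.layers["norm"] = norm
    m.layers["lognorm"] = np.log1p(norm)
    return m
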