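"""Gene-set and cluster-level scoring.

Covers four related analyses:

* **cell-cycle score** — the fraction of a cell's UMIs falling on a set of
  well-known cell-cycle genes, and the percentage of cycling cells per
  cluster (score > 0.01);
* **cluster enrichment** — overexpression of a gene in a cluster relative
  to all other clusters, combining the mean-expression ratio with the
  nonzero-cell-fraction ratio;
* **signature (gene-profile) score** — mean relative expression of a gene
  set minus that of expression-bin-matched control genes, per cell; a
  generalized reimplementation of the Tirosh/Neftel scoring scheme that
  works with any gene set;
* **layer-maturation assignment** — labelling fetal fibroblasts by the
  meningeal layer (pia / arachnoid / dura) whose maturation signature they
  express, with genes already expressed at the earliest ages filtered out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneSet
from .io import match_genes

logger = logging.getLogger("scmeninges")

ENRICHMENT_EPS = 0.01


@dataclass(frozen=True)
class SignatureScoreParams:
    n_bins: int = 25
    n_controls_per_gene: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.n_controls_per_gene < 1:
            raise ValueError("n_controls_per_gene must be >= 1")


@dataclass(frozen=True)
class MaturationCriteria:
    top_n: int = 50
    early_expressed_cell_fraction: float = 0.15
    min_gene_count: int = 2          # expressed means count strictly above this
    min_set_fraction: float = 0.05
    other_label: str = "Other"

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        for f in (self.early_expressed_cell_fraction, self.min_set_fraction):
            if not 0.0 < f < 1.0:
                raise ValueError("fractions must lie in (0, 1)")


@dataclass
class EnrichmentTable:
    """Cluster x gene enrichment values plus per-cluster rankings."""

    values: pd.DataFrame                 # clusters x genes
    rankings: dict[object, list[str]]    # cluster -> genes, best first


# ---------------------------------------------------------------------------
# cell cycle

def cell_cycle_score(m: CountMatrix, cycle_genes: GeneSet) -> np.ndarray:
    """Per-cell fraction of UMIs on cycle genes, in [0, 1]."""
    shared, _ = match_genes(list(cycle_genes.genes), list(m.gene_ids),
                            context="cell cycle genes")
    totals = m.total_counts()
    if not shared:
        return np.zeros(m.n_cells)
    in_set = np.asarray(m.counts[:, m.gene_index(shared)].sum(axis=1)).ravel()
    zero = totals == 0
    if zero.any():
        logger.warning("%d cells with zero UMIs scored 0", int(zero.sum()))
    with np.errstate(invalid="ignore"):
        score = np.where(zero, 0.0, in_set / np.where(zero, 1, totals))
    return score


def cycling_fraction(
    scores: np.ndarray,
    clusters: np.ndarray | list,
    cutoff: float = 0.01,
) -> pd.Series:
    """Percentage of cells per cluster with score strictly above ``cutoff``."""
    df = pd.DataFrame({"score": np.asarray(scores, float),
                       "cluster": np.asarray(clusters, dtype=object)})
    return df.groupby("cluster")["score"].apply(
        lambda s: 100.0 * float((s > cutoff).mean()))


# ---------------------------------------------------------------------------
# cluster enrichment

def _normalized_expression(m: CountMatrix) -> np.ndarray:
    """Depth-normalize each cell to the median total (dense)."""
    totals = m.total_counts().astype(float)
    med = np.median(totals[totals > 0]) if (totals > 0).any() else 1.0
    factors = np.where(totals > 0, med / np.where(totals > 0, totals, 1), 0.0)
    return m.dense() * factors[:, None]


def cluster_enrichment(
    m: CountMatrix, clusters: np.ndarray | list
) -> EnrichmentTable:
    """Per-cluster gene enrichment against the pool of all other clusters.

    enrichment(g, c) = [(mean_in + eps) / (mean_out + eps)]
                     x [(nnz_frac_in + eps) / (nnz_frac_out + eps)],
    eps = 0.01, means over depth-normalized expression, nonzero fractions
    over raw counts.  Rankings sort descending with a lexicographic gene-id
    tie-break.
    """
    clusters = np.asarray(clusters, dtype=object)
    labels = pd.unique(clusters)
    if len(labels) < 2:
        raise ValueError("cluster enrichment needs at least 2 clusters")
    norm = _normalized_expression(m)
    nnz = m.dense() > 0
    eps = ENRICHMENT_EPS

    rows = {}
    for c in labels:
        inside = clusters == c
        mean_in = norm[inside].mean(axis=0)
        mean_out = norm[~inside].mean(axis=0)
        frac_in = nnz[inside].mean(axis=0)
        frac_out = nnz[~inside].mean(axis=0)
        rows[c] = ((mean_in + eps) / (mean_out + eps)) * \
                  ((frac_in + eps) / (frac_out + eps))
    values = pd.DataFrame.from_dict(rows, orient="index", columns=m.gene_ids)

    rankings = {}
    for c in labels:
        order = sorted(
            range(m.n_genes),
            key=lambda i: (-values.loc[c].iloc[i], str(m.gene_ids[i])),
        )
        rankings[c] = [m.gene_ids[i] for i in order]
    return EnrichmentTable(values, rankings)


def top_enriched_genes(e: EnrichmentTable, n: int = 50) -> dict[object, GeneSet]:
    """First ``n`` genes of each cluster's ranking as a GeneSet."""
    return {c: GeneSet(str(c), tuple(r[:n])) for c, r in e.rankings.items()}


# ---------------------------------------------------------------------------
# signature (gene-profile) score

def log_normalize(m: CountMatrix, target_total: float = 10_000) -> np.ndarray:
    """Counts scaled to ``target_total`` per cell then log(1+x); dense."""
    totals = m.total_counts().astype(float)
    safe = np.where(totals > 0, totals, 1.0)
    return np.log1p(m.dense() / safe[:, None] * target_total)


def expression_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign genes to ``n_bins`` equal-size bins by aggregate expression.

    ``values`` is cells x genes (log-normalized); aggregate = mean over
    cells.  Returns a per-gene bin index.  Ties break by position, which is
    deterministic for a fixed gene order.
    """
    aggregate = values.mean(axis=0)
    order = np.argsort(aggregate, kind="mergesort")
    bins = np.empty(len(aggregate), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = b
    return bins


def score_profiles(
    values: np.ndarray,
    gene_ids: np.ndarray,
    gene_set: GeneSet,
    params: SignatureScoreParams = SignatureScoreParams(),
) -> np.ndarray:
    """Signature score on an already log-normalized cells x genes matrix.

    Relative expression is the value minus the gene's mean across cells.
    For each signature gene, ``n_controls_per_gene`` control genes are drawn
    with replacement from the non-signature genes of the same
    aggregate-expression bin; the score is the mean relative expression over
    the set minus the mean over the pooled controls.  Excluding the set from
    the control pool keeps the score sensitive when the signature itself
    dominates its expression bin.
    """
    gene_ids = np.asarray(gene_ids, dtype=object)
    lut = {g: i for i, g in enumerate(gene_ids)}
    set_idx = [lut[g] for g in gene_set.genes if g in lut]
    dropped = [g for g in gene_set.genes if g not in lut]
    if dropped:
        logger.warning("signature %r: %d genes absent from matrix",
                       gene_set.name, len(dropped))
    if not set_idx:
        raise ValueError(f"no genes of set {gene_set.name!r} in matrix")
    if len(gene_set) > len(gene_ids):
        raise ValueError("gene set larger than matrix vocabulary")

    rel = values - values.mean(axis=0, keepdims=True)
    bins = expression_bins(values, params.n_bins)
    rng = np.random.default_rng(params.seed)

    in_set = np.zeros(len(gene_ids), dtype=bool)
    in_set[set_idx] = True
    control_idx: list[np.ndarray] = []
    for gi in set_idx:
        pool = np.flatnonzero((bins == bins[gi]) & ~in_set)
        if not len(pool):
            # signature fills the whole bin; widen to all non-set genes
            pool = np.flatnonzero(~in_set)
            logger.warning("bin %d holds only signature genes; control pool "
                           "widened", bins[gi])
        control_idx.append(rng.choice(pool, size=params.n_controls_per_gene,
                                      replace=True))
    controls = np.concatenate(control_idx)
    return rel[:, set_idx].mean(axis=1) - rel[:, controls].mean(axis=1)


def signature_score(
    m: CountMatrix,
    gene_set: GeneSet,
    params: SignatureScoreParams = SignatureScoreParams(),
) -> np.ndarray:
    """Signature score per cell, computed on log-normalized counts."""
    return score_profiles(log_normalize(m), m.gene_ids, gene_set, params)


# ---------------------------------------------------------------------------
# COSMIC-style driver sets

def build_driver_sets(per_cancer: dict[str, list[str]]) -> dict[str, tuple[str, ...]]:
    """De-overlap per-cancer driver gene lists.

    Any gene appearing in two or more input lists is removed from every
    output, so each remaining set is exclusive to its cancer.  Outputs may
    be empty (e.g. identical inputs); input order is preserved.
    """
    counts: dict[str, int] = {}
    for genes in per_cancer.values():
        for g in set(genes):
            counts[g] = counts.get(g, 0) + 1
    return {
        name: tuple(g for g in genes if counts[g] == 1)
        for name, genes in per_cancer.items()
    }


# ---------------------------------------------------------------------------
# layer maturation

def maturation_assign(
    fetal: CountMatrix,
    layer_sets: dict[str, GeneSet],
    criteria: MaturationCriteria = MaturationCriteria(),
    early_timepoints: list | None = None,
) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Assign each fetal cell to the meningeal layer it is maturing toward.

    1. Genes of each layer set already detected (count >= 1) in more than
       ``early_expressed_cell_fraction`` of early-group cells are dropped, so
       the filtered sets reflect maturation rather than baseline expression.
       The early group defaults to the two earliest distinct timepoints.
    2. Within a cell, a set gene counts as expressed iff its raw count is
       strictly above ``min_gene_count``.
    3. A cell takes the layer with the maximal expressed-gene fraction,
       provided that fraction reaches ``min_set_fraction``; otherwise it is
       labelled ``other_label``.  Ties resolve by the order of ``layer_sets``
       (pass pia, arachnoid, dura in priority order) and are logged.

    Returns (per-cell labels, per-timepoint label fractions summing to 1,
    per-timepoint median filtered-set expression).  The median for a layer
    at a timepoint is taken over the cells attributed to that layer's
    lineage — those whose mean filtered-set expression is maximal for it —
    so it follows the maturation of the lineage rather than being diluted
    by cells maturing toward other layers.
    """
    if "timepoint" not in fetal.cell_meta:
        raise ValueError("fetal matrix needs a 'timepoint' metadata column")
    tps = np.asarray(fetal.cell_meta["timepoint"])
    uniq_tp = np.sort(pd.unique(tps))
    if early_timepoints is None:
        early_timepoints = list(uniq_tp[:2])
    early_cells = np.isin(tps, early_timepoints)
    if not early_cells.any():
        raise ValueError("no cells in the designated early timepoints")

    dense = fetal.dense()
    lut = {g: i for i, g in enumerate(fetal.gene_ids)}

    filtered: dict[str, list[int]] = {}
    for layer, gs in layer_sets.items():
        shared, _ = match_genes(list(gs.genes), list(fetal.gene_ids),
                                context=f"layer set {layer}")
        idx = np.array([lut[g] for g in shared], dtype=int)
        if len(idx):
            detected_frac = (dense[np.ix_(early_cells, idx)] >= 1).mean(axis=0)
            idx = idx[detected_frac <= criteria.early_expressed_cell_fraction]
        filtered[layer] = list(idx)
        if not len(idx):
            logger.warning("layer %r: filtered set empty; never assigned", layer)

    layers = list(layer_sets)
    frac = np.zeros((fetal.n_cells, len(layers)))
    for j, layer in enumerate(layers):
        idx = filtered[layer]
        if idx:
            expressed = dense[:, idx] > criteria.min_gene_count
            frac[:, j] = expressed.mean(axis=1)

    best = frac.argmax(axis=1)  # argmax takes the first maximum: priority order
    ties = (frac == frac[np.arange(len(best)), best][:, None]).sum(axis=1) > 1
    n_ties = int((ties & (frac.max(axis=1) >= criteria.min_set_fraction)).sum())
    if n_ties:
        logger.info("%d cells tied between layers; resolved by priority order",
                    n_ties)
    labels = np.where(
        frac.max(axis=1) >= criteria.min_set_fraction,
        np.array(layers, dtype=object)[best],
        criteria.other_label,
    ).astype(object)

    # lineage attribution for the median trajectories: argmax of mean
    # filtered-set expression (first maximum = priority order)
    mean_expr = np.full((fetal.n_cells, len(layers)), np.nan)
    for j, layer in enumerate(layers):
        idx = filtered[layer]
        if idx:
            mean_expr[:, j] = dense[:, idx].mean(axis=1)
    lineage = np.nanargmax(np.nan_to_num(mean_expr, nan=-np.inf), axis=1)

    all_labels = layers + [criteria.other_label]
    frac_rows, med_rows = [], []
    for tp in uniq_tp:
        sel = tps == tp
        lab = labels[sel]
        frac_rows.append([float((lab == L).mean()) for L in all_labels])
        meds = []
        for j, layer in enumerate(layers):
            members = sel & (lineage == j) if filtered[layer] else np.zeros(0, bool)
            meds.append(float(np.median(mean_expr[members, j]))
                        if members.any() else np.nan)
        med_rows.append(meds)
    tp_index = pd.Index(uniq_tp, name="timepoint")
    label_fractions = pd.DataFrame(frac_rows, index=tp_index, columns=all_labels)
    median_expression = pd.DataFrame(med_rows, index=tp_index, columns=layers)
    return labels, label_fractions, median_expression
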