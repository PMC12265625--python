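"""Expression-based copy-number inference (HMM karyotyping).

Chromosomal copy-number aberrations are inferred from UMI counts alone,
against an external reference atlas of cluster mean-expression profiles —
using an external reference avoids having to identify normal cells within
each tumour sample.  The pipeline, per sample:

1. depth-normalize every cell to the median total UMIs;
2. keep only autosomal genes expressed above 10% of the 99th-percentile
   expression level in at least half of the reference clusters;
3. match each cell to the reference cluster with the greatest Pearson
   correlation over the kept genes;
4. ploidy per gene = 2 x (cell expression / matched reference expression),
   smoothed along each chromosome in sliding windows of 25 genes, then
   recentred so the track's median is exactly 2 (diploid);
5. group cells into metacells: PCA (5 components) on the ploidy matrix,
   mutual kNN graph (k = 30), Leiden partition;
6. per metacell and per chromosome, Viterbi-decode a hidden Markov model
   whose states are integer copy numbers 0..6 with Gaussian emissions
   centred on the state value, yielding integer copy-number segments.

Because every step is a ratio of depth-normalized quantities, calls are
invariant to rescaling all counts by a constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .containers import (
    CountMatrix,
    GeneAnnotation,
    KaryotypeCall,
    PloidyTracks,
    ReferenceAtlas,
)
from .io import match_genes

logger = logging.getLogger("scmeninges")


@dataclass(frozen=True)
class KaryotyperParams:
    expr_quantile: float = 0.99
    expr_fraction_of_quantile: float = 0.10
    min_cluster_fraction: float = 0.5
    autosomes_only: bool = True
    percentile_scope: str = "cluster"   # or "pooled"
    smoothing_window: int = 25
    n_pcs: int = 5
    knn: int = 30
    mutual_knn: bool = False
    leiden_resolution: float = 1.0
    max_copies: int = 6
    emission_sd: float = 0.3            # ploidy units
    stay_probability: float = 0.999
    #: genes whose reference value in the matched cluster falls below this
    #: fraction of that cluster's mean (over kept genes) are masked for the
    #: cell: the expression ratio is dominated by shot noise there
    ref_mask_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be >= 1")
        for f in (self.expr_fraction_of_quantile, self.min_cluster_fraction):
            if not 0.0 < f < 1.0:
                raise ValueError("fractions must lie in (0, 1)")
        if self.max_copies < 2:
            raise ValueError("max_copies must be >= 2")


# ---------------------------------------------------------------------------
# gene selection and normalization

def select_genes(
    atlas: ReferenceAtlas,
    ann: GeneAnnotation,
    p: KaryotyperParams = KaryotyperParams(),
) -> list[str]:
    """Genome-ordered list of genes informative for karyotyping.

    A gene passes in a cluster iff its atlas value exceeds
    ``expr_fraction_of_quantile`` x that cluster's 99th-percentile
    expression level (or the pooled atlas percentile when
    ``percentile_scope="pooled"``); it is kept iff it passes in at least
    ``min_cluster_fraction`` of clusters and, by default, is autosomal.
    """
    shared, _ = match_genes(list(atlas.gene_ids), list(ann.gene_ids),
                            context="atlas vs annotation")
    idx = atlas.gene_index(shared)
    vals = atlas.values[:, idx]

    if p.percentile_scope == "pooled":
        thresh = p.expr_fraction_of_quantile * np.percentile(
            atlas.values, 100 * p.expr_quantile)
        passes = vals > thresh
    else:
        q = np.percentile(atlas.values, 100 * p.expr_quantile, axis=1)
        passes = vals > (p.expr_fraction_of_quantile * q)[:, None]

    need = int(np.ceil(p.min_cluster_fraction * atlas.n_clusters))
    keep = passes.sum(axis=0) >= need
    if p.autosomes_only:
        keep &= ann.is_autosomal(shared)

    kept = [g for g, k in zip(shared, keep) if k]
    if len(kept) < 50:
        raise ValueError(
            f"only {len(kept)} genes survive selection; track too sparse to smooth"
        )
    return ann.order_genes(kept)


def normalize_cells(m: CountMatrix) -> np.ndarray:
    """Scale each cell's counts to the median total UMIs across cells."""
    totals = m.total_counts().astype(float)
    med = float(np.median(totals))
    safe = np.where(totals > 0, totals, 1.0)
    return m.dense() * (med / safe)[:, None]


def match_reference(
    cell: np.ndarray, atlas: ReferenceAtlas, kept_idx: np.ndarray
) -> str:
    """Best-correlated reference cluster for one cell (kept genes only)."""
    v = np.asarray(cell, float)[kept_idx]
    if np.std(v) == 0:
        raise ValueError("constant cell vector: correlation undefined")
    ref = atlas.values[:, kept_idx]
    r = _rowwise_correlation(v[None, :], ref)[0]
    best = np.flatnonzero(r == r.max())
    # lexicographic tie-break on the cluster label
    labels = atlas.cluster_ids[best]
    return labels[np.argsort(labels.astype(str), kind="mergesort")[0]]


def _rowwise_correlation(cells: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Pearson correlation of every cell row against every reference row."""
    c = cells - cells.mean(axis=1, keepdims=True)
    r = ref - ref.mean(axis=1, keepdims=True)
    c_norm = np.linalg.norm(c, axis=1, keepdims=True)
    r_norm = np.linalg.norm(r, axis=1, keepdims=True)
    if (c_norm == 0).any():
        raise ValueError("constant cell vector: correlation undefined")
    return (c @ r.T) / (c_norm @ r_norm.T)


# ---------------------------------------------------------------------------
# ploidy tracks

def _smooth_within_chromosomes(
    values: np.ndarray, chroms: np.ndarray, window: int
) -> np.ndarray:
    """Centred sliding mean per chromosome, truncated at boundaries.

    NaN entries (masked genes) are ignored within each window; a window
    larger than the chromosome degrades to the whole-chromosome mean.
    """
    out = np.empty_like(values)
    half = window // 2
    start = 0
    n = values.shape[1]
    for i in range(1, n + 1):
        if i == n or chroms[i] != chroms[start]:
            block = values[:, start:i]
            L = i - start
            sm = np.empty_like(block)
            for j in range(L):
                lo = max(0, j - half)
                hi = min(L, j + half + 1)
                with np.errstate(invalid="ignore"):
                    sm[:, j] = np.nanmean(block[:, lo:hi], axis=1)
            out[:, start:i] = sm
            start = i
    return out


def ploidy_tracks(
    m: CountMatrix,
    atlas: ReferenceAtlas,
    ann: GeneAnnotation,
    p: KaryotyperParams = KaryotyperParams(),
) -> PloidyTracks:
    """Per-cell smoothed ploidy along genome-ordered kept genes.

    For each cell: ratio 2 x cell / matched-reference over kept genes,
    sliding-mean smoothing within chromosomes, then the track is divided by
    its median and multiplied by 2 so the genome-wide median is exactly
    diploid.  Genes whose reference value in the matched cluster is below
    ``ref_mask_fraction`` of that cluster's mean are masked (NaN) for the
    cell before smoothing: with an expected expression that low the ratio
    is a shot-noise coin flip, and because metacells are later grouped by
    track similarity such noise would not average out.
    """
    kept = select_genes(atlas, ann, p)
    kept_in_m, _ = match_genes(kept, list(m.gene_ids), context="kept genes vs matrix")
    if len(kept_in_m) < len(kept):
        kept = kept_in_m
    norm = normalize_cells(m)
    cell_idx = m.gene_index(kept)
    atlas_idx = atlas.gene_index(kept)

    cells = norm[:, cell_idx]
    ref = atlas.values[:, atlas_idx]
    r = _rowwise_correlation(cells, ref)
    best = r.argmax(axis=1)
    # resolve exact ties lexicographically on the cluster label
    for i in range(len(best)):
        tied = np.flatnonzero(r[i] == r[i, best[i]])
        if len(tied) > 1:
            labels = atlas.cluster_ids[tied].astype(str)
            best[i] = tied[np.argsort(labels, kind="mergesort")[0]]
    matched = atlas.cluster_ids[best]

    ref_per_cell = ref[best]
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = 2.0 * cells / ref_per_cell
    floor = p.ref_mask_fraction * ref.mean(axis=1, keepdims=True)
    raw[ref_per_cell < np.maximum(floor[best], 1e-9)] = np.nan

    chroms = ann.chromosome_of(kept)
    smooth = _smooth_within_chromosomes(raw, chroms, p.smoothing_window)
    med = np.nanmedian(smooth, axis=1, keepdims=True)
    med[med == 0] = 1.0
    smooth = smooth / med * 2.0

    return PloidyTracks(
        cell_ids=m.cell_ids,
        gene_ids=np.array(kept, dtype=object),
        chromosomes=chroms,
        values=smooth,
        matched_cluster=matched,
    )


# ---------------------------------------------------------------------------
# metacells

def metacells(
    tracks: PloidyTracks,
    p: KaryotyperParams = KaryotyperParams(),
    seed: int = 0,
) -> np.ndarray:
    """Leiden partition of cells with similar ploidy profiles.

    PCA (centred, unscaled) to ``n_pcs`` components on the cell x gene
    ploidy matrix, kNN graph with k = min(knn, n-1), Leiden with fixed seed.
    Edges are symmetrized by union by default, which leaves no cell
    isolated; ``mutual_knn`` keeps only reciprocated edges instead, at the
    cost of possible singleton metacells whose one-cell tracks are noisy.
    Returns per-cell integer metacell labels.
    """
    X = np.nan_to_num(tracks.values, nan=2.0)
    n = X.shape[0]
    if n < 2:
        return np.zeros(n, dtype=int)
    n_pcs = min(p.n_pcs, n - 1, X.shape[1])
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(X)

    k = min(p.knn, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, nbr = nn.kneighbors(pcs)
    nbr = nbr[:, 1:]  # drop self
    is_nbr = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    is_nbr[rows, nbr.ravel()] = True
    if p.mutual_knn:
        adj = is_nbr & is_nbr.T
    else:
        adj = is_nbr | is_nbr.T
    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if adj[i, j]]

    g = igraph.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=p.leiden_resolution,
        seed=int(seed),
    )
    return np.asarray(part.membership, dtype=int)


# ---------------------------------------------------------------------------
# HMM segmentation

def viterbi_decode(
    observations: np.ndarray,
    n_states: int,
    emission_sd: float,
    stay_probability: float,
) -> np.ndarray:
    """Most likely integer-state path for a 1-D ploidy track.

    States are copy numbers 0..n_states-1 with Gaussian emissions centred on
    the state value; uniform initial distribution; transition matrix with
    ``stay_probability`` on the diagonal and the remainder spread uniformly
    over the other states.  NaN observations are uninformative (equal
    emission likelihood in every state).
    """
    obs = np.asarray(observations, float)
    T = len(obs)
    states = np.arange(n_states)
    log_stay = np.log(stay_probability)
    log_move = np.log((1.0 - stay_probability) / (n_states - 1))
    trans = np.full((n_states, n_states), log_move)
    np.fill_diagonal(trans, log_stay)

    def emit(x: float) -> np.ndarray:
        if np.isnan(x):
            return np.zeros(n_states)
        return -0.5 * ((x - states) / emission_sd) ** 2

    delta = np.full(n_states, -np.log(n_states)) + emit(obs[0])
    back = np.zeros((T, n_states), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + trans
        back[t] = cand.argmax(axis=0)
        delta = cand[back[t], states] + emit(obs[t])
    path = np.empty(T, dtype=int)
    path[-1] = int(delta.argmax())
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def _segments_from_path(
    chrom: str, path: np.ndarray, offset: int
) -> list[tuple[str, int, int, int]]:
    segs = []
    start = 0
    for i in range(1, len(path) + 1):
        if i == len(path) or path[i] != path[start]:
            segs.append((chrom, offset + start, offset + i, int(path[start])))
            start = i
    return segs


def call_copy_numbers(
    mean_track: np.ndarray,
    chroms: np.ndarray,
    p: KaryotyperParams = KaryotyperParams(),
    metacell_id: str = "metacell",
    member_cell_ids: np.ndarray | None = None,
) -> KaryotypeCall:
    """Viterbi-segment one metacell's mean ploidy track, per chromosome."""
    segments: list[tuple[str, int, int, int]] = []
    start = 0
    n = len(mean_track)
    for i in range(1, n + 1):
        if i == n or chroms[i] != chroms[start]:
            path = viterbi_decode(
                mean_track[start:i], p.max_copies + 1,
                p.emission_sd, p.stay_probability,
            )
            segments.extend(_segments_from_path(str(chroms[start]), path, start))
            start = i
    if member_cell_ids is None:
        member_cell_ids = np.array([], dtype=object)
    return KaryotypeCall(metacell_id, member_cell_ids, segments)


# ---------------------------------------------------------------------------
# full pipeline

def karyotype(
    m: CountMatrix,
    atlas: ReferenceAtlas,
    ann: GeneAnnotation,
    p: KaryotyperParams = KaryotyperParams(),
    seed: int = 0,
) -> tuple[PloidyTracks, np.ndarray, list[KaryotypeCall]]:
    """Run the full karyotyping pipeline on one sample.

    Returns the per-cell ploidy tracks, per-cell metacell labels, and one
    :class:`KaryotypeCall` per metacell (mean member track, HMM-segmented).
    """
    tracks = ploidy_tracks(m, atlas, ann, p)
    labels = metacells(tracks, p, seed=seed)
    calls = []
    for mc in np.unique(labels):
        members = labels == mc
        mean_track = np.nanmean(tracks.values[members], axis=0)
        calls.append(call_copy_numbers(
            mean_track, tracks.chromosomes, p,
            metacell_id=f"metacell{mc}",
            member_cell_ids=tracks.cell_ids[members],
        ))
    logger.info("karyotyped %d cells into %d metacells", m.n_cells, len(calls))
    return tracks, labels, calls
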