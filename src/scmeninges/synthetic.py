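"""Synthetic-data generators with known ground truth.

Every pipeline input — the reference atlas, CNA-bearing cell populations,
topic-structured corpora, timepoint-graded layer signatures, spatial
transcript tables and QC boundary fixtures — can be simulated here, so each
stage is testable without external downloads.  All generators are pure
functions of their seed.

The noise model for expression counts is Poisson around scaled means (an
optional negative-binomial over-dispersion is off by default): it is the
simplest model under which the expression-ratio ploidy estimator used by the
karyotyper is unbiased, with expected expression of a gene on an affected
chromosome scaled exactly by copy/2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse

from .containers import (
    AUTOSOMES,
    CHROMOSOMES,
    CnaSpec,
    CountMatrix,
    GeneAnnotation,
    GeneSet,
    ReferenceAtlas,
    SimTruth,
    SpatialTranscripts,
)
from .topics import TopicModel

#: Approximate protein-coding gene counts per human chromosome, used to
#: apportion simulated genes across the genome.
CHROMOSOME_GENE_COUNTS: dict[str, int] = {
    "1": 2000, "2": 1200, "3": 1050, "4": 750, "5": 850, "6": 1000,
    "7": 900, "8": 650, "9": 780, "10": 730, "11": 1300, "12": 1000,
    "13": 320, "14": 600, "15": 600, "16": 850, "17": 1150, "18": 270,
    "19": 1400, "20": 540, "21": 230, "22": 440, "X": 840, "Y": 70,
}

DEFAULT_DEPTH = 10_000  # mean UMIs per simulated cell


def _apportion(n_genes: int, chromosomes: tuple[str, ...]) -> dict[str, int]:
    """Largest-remainder apportionment of genes to chromosomes."""
    weights = np.array([CHROMOSOME_GENE_COUNTS[c] for c in chromosomes], float)
    quotas = weights / weights.sum() * n_genes
    counts = np.floor(quotas).astype(int)
    rem = n_genes - counts.sum()
    order = np.argsort(-(quotas - counts), kind="mergesort")
    counts[order[:rem]] += 1
    return dict(zip(chromosomes, counts))


def generate_reference_atlas(
    n_clusters: int,
    n_genes: int,
    seed: int,
    include_sex_chromosomes: bool = True,
) -> tuple[ReferenceAtlas, GeneAnnotation]:
    """Simulate cluster mean-expression profiles plus a gene map.

    Cluster profiles are drawn from a log-normal prior (independent across
    clusters, so profiles are mutually distinguishable) and normalized to a
    common total.  Genes are apportioned across chromosomes in proportion to
    real human gene counts, with strictly increasing positions.
    """
    if n_clusters < 2:
        raise ValueError("need at least 2 reference clusters")
    if n_genes < 100:
        raise ValueError("need at least 100 genes")
    rng = np.random.default_rng(seed)
    chroms = CHROMOSOMES if include_sex_chromosomes else AUTOSOMES
    per_chrom = _apportion(n_genes, chroms)

    gene_ids, gene_chrom, gene_pos = [], [], []
    g = 0
    for c in chroms:
        gaps = rng.integers(1_000, 100_000, size=per_chrom[c])
        positions = np.cumsum(gaps)
        for p in positions:
            gene_ids.append(f"G{g:05d}")
            gene_chrom.append(c)
            gene_pos.append(int(p))
            g += 1
    ann = GeneAnnotation(pd.DataFrame(
        {"chromosome": gene_chrom, "position": gene_pos},
        index=pd.Index(gene_ids, name="gene"),
    ))

    values = rng.lognormal(mean=0.0, sigma=1.0, size=(n_clusters, n_genes))
    values = values / values.sum(axis=1, keepdims=True) * DEFAULT_DEPTH
    atlas = ReferenceAtlas(
        cluster_ids=np.array([f"cluster{i}" for i in range(n_clusters)], object),
        gene_ids=np.array(gene_ids, dtype=object),
        values=values,
    )
    return atlas, ann


def simulate_cells(
    atlas: ReferenceAtlas,
    annotation: GeneAnnotation,
    n_cells: int,
    cna: list[CnaSpec] | tuple[CnaSpec, ...] = (),
    depth: float = DEFAULT_DEPTH,
    seed: int = 0,
    dispersion: float | None = None,
) -> tuple[CountMatrix, SimTruth]:
    """Draw cells from atlas profiles, with clone-specific chromosome CNAs.

    Each cell picks a reference cluster uniformly; clone membership follows
    the CnaSpec fractions (remainder diploid).  Genes on an event chromosome
    have their expected expression scaled by copy/2 before the profile is
    renormalized to the requested depth and Poisson-sampled.  ``dispersion``
    adds gamma-mixed (negative binomial) noise when set.
    """
    fractions = [spec.fraction for spec in cna]
    if sum(fractions) > 1.0 + 1e-12:
        raise ValueError("clone fractions sum to more than 1")
    ann_chroms = set(annotation.chromosomes())
    for spec in cna:
        for chrom, _ in spec.events:
            if chrom not in ann_chroms:
                raise ValueError(f"CNA event on unknown chromosome {chrom!r}")

    rng = np.random.default_rng(seed)
    gene_chrom = annotation.chromosome_of(atlas.gene_ids)

    # per-clone expression scaling vectors
    clone_ids = ["diploid"] + [spec.clone_id for spec in cna]
    scales = {"diploid": np.ones(len(atlas.gene_ids))}
    for spec in cna:
        s = np.ones(len(atlas.gene_ids))
        for chrom, copy in spec.events:
            s[gene_chrom == chrom] = copy / 2.0
        scales[spec.clone_id] = s

    probs = np.array([1.0 - sum(fractions)] + fractions)
    probs = np.clip(probs, 0, None)
    clone_draw = rng.choice(len(clone_ids), size=n_cells, p=probs / probs.sum())
    cluster_draw = rng.integers(atlas.n_clusters, size=n_cells)

    counts = np.empty((n_cells, len(atlas.gene_ids)), dtype=np.int64)
    for i in range(n_cells):
        mean = atlas.values[cluster_draw[i]] * scales[clone_ids[clone_draw[i]]]
        total = mean.sum()
        if total == 0:
            counts[i] = 0
            continue
        lam = mean / total * depth
        if dispersion is not None and dispersion > 0:
            lam = lam * rng.gamma(1.0 / dispersion, dispersion, size=lam.shape)
        counts[i] = rng.poisson(lam)

    cell_ids = np.array([f"C{i:05d}" for i in range(n_cells)], dtype=object)
    mat = sparse.csr_matrix(counts)
    meta = pd.DataFrame(
        {"total_umis": np.asarray(mat.sum(axis=1)).ravel(), "sample": "sim"},
        index=pd.Index(cell_ids),
    )
    truth = SimTruth(
        clone=np.array([clone_ids[c] for c in clone_draw], dtype=object),
        cluster=np.array([atlas.cluster_ids[c] for c in cluster_draw], dtype=object),
    )
    return CountMatrix(cell_ids, atlas.gene_ids, mat, meta), truth


def simulate_topic_corpus(
    n_topics: int,
    vocab: int,
    n_docs: int,
    doc_len: int,
    alpha: float,
    seed: int,
    topic_concentration: float = 0.1,
) -> tuple[CountMatrix, TopicModel]:
    """Standard LDA generative draws; returns corpus and the true model.

    Topic-gene rows are Dirichlet(topic_concentration) draws (sparse by
    default, so topics are distinguishable); document mixtures are
    Dirichlet(alpha); each document holds exactly ``doc_len`` tokens.
    """
    if n_topics < 2:
        raise ValueError("need at least 2 topics")
    rng = np.random.default_rng(seed)
    phi = rng.dirichlet(np.full(vocab, topic_concentration), size=n_topics)
    theta = rng.dirichlet(np.full(n_topics, alpha), size=n_docs)
    counts = np.zeros((n_docs, vocab), dtype=np.int64)
    for d in range(n_docs):
        z_counts = rng.multinomial(doc_len, theta[d])
        for k in range(n_topics):
            if z_counts[k]:
                counts[d] += rng.multinomial(z_counts[k], phi[k])
    doc_ids = np.array([f"D{d:04d}" for d in range(n_docs)], dtype=object)
    gene_ids = np.array([f"G{g:04d}" for g in range(vocab)], dtype=object)
    m = CountMatrix(doc_ids, gene_ids, sparse.csr_matrix(counts))
    truth = TopicModel(n_topics, phi, theta, gene_ids, doc_ids,
                       alpha=alpha, eta=topic_concentration,
                       iterations=0, seed=seed)
    return m, truth


def simulate_layer_gradient(
    layers: list[str],
    n_timepoints: int,
    cells_per_point: int,
    genes_per_layer: int = 50,
    n_background_genes: int = 200,
    seed: int = 0,
) -> tuple[CountMatrix, SimTruth, dict[str, GeneSet]]:
    """Timepoint-graded layer signatures for the maturation analysis.

    Each layer owns ``genes_per_layer`` signature genes whose Poisson rate in
    that layer's cells rises monotonically (geometrically, 0.02 to 6) across
    timepoints.  The geometric ramp keeps detection low through the two
    earliest timepoints — under 15% of early-group cells see any transcript —
    so the signatures survive the maturation analysis's early-expression
    filter, while late cells express most of their layer's genes.
    ``cells_per_point`` cells are drawn per (layer, timepoint) pair;
    background genes at rate 1 give all cells nonzero totals.
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    rng = np.random.default_rng(seed)
    n_layers = len(layers)
    sig_rates = np.geomspace(0.02, 6.0, n_timepoints)

    gene_ids, layer_sets = [], {}
    for li, layer in enumerate(layers):
        genes = tuple(f"{layer}_sig{j:03d}" for j in range(genes_per_layer))
        layer_sets[layer] = GeneSet(layer, genes)
        gene_ids.extend(genes)
    gene_ids.extend(f"bg{j:04d}" for j in range(n_background_genes))
    gene_ids = np.array(gene_ids, dtype=object)
    n_genes = len(gene_ids)

    n_cells = n_layers * n_timepoints * cells_per_point
    counts = np.zeros((n_cells, n_genes), dtype=np.int64)
    layer_lab = np.empty(n_cells, dtype=object)
    tp_lab = np.empty(n_cells, dtype=np.int64)
    row = 0
    for t in range(n_timepoints):
        for li, layer in enumerate(layers):
            for _ in range(cells_per_point):
                lam = np.full(n_genes, 0.05)
                lam[-n_background_genes:] = 1.0
                sl = slice(li * genes_per_layer, (li + 1) * genes_per_layer)
                lam[sl] = sig_rates[t]
                counts[row] = rng.poisson(lam)
                layer_lab[row] = layer
                tp_lab[row] = t
                row += 1

    cell_ids = np.array([f"F{i:05d}" for i in range(n_cells)], dtype=object)
    mat = sparse.csr_matrix(counts)
    meta = pd.DataFrame(
        {
            "total_umis": np.asarray(mat.sum(axis=1)).ravel(),
            "timepoint": tp_lab,
            "age_pcw": 5.0 + tp_lab,  # earliest two timepoints = PCW 5-6
        },
        index=pd.Index(cell_ids),
    )
    truth = SimTruth(layer=layer_lab, timepoint=tp_lab)
    return CountMatrix(cell_ids, gene_ids, mat, meta), truth, layer_sets


#: QC boundary grid: one cell per combination, straddling every threshold.
_QC_UMIS = (999, 1000, 1001)
_QC_UNSPLICED = (0.09, 0.10, 0.11)
_QC_DOUBLET = (0.39, 0.40, 0.41)


def generate_qc_fixture(seed: int = 0) -> tuple[CountMatrix, SimTruth]:
    """Cells straddling each QC boundary, with truth pass/fail flags.

    A cell fails iff total UMIs < 1000, unspliced fraction < 0.1, or doublet
    score >= 0.4 (high score = likely doublet); reasons enumerate every
    failed criterion.
    """
    rng = np.random.default_rng(seed)
    rows, meta_rows, ids = [], [], []
    qc_pass, reasons = [], []
    i = 0
    for umis in _QC_UMIS:
        for frac in _QC_UNSPLICED:
            for score in _QC_DOUBLET:
                a = int(rng.integers(0, umis + 1))
                rows.append((a, umis - a))
                meta_rows.append((umis, frac, score))
                ids.append(f"Q{i:03d}")
                why = []
                if umis < 1000:
                    why.append("low_umis")
                if frac < 0.1:
                    why.append("low_unspliced_fraction")
                if score >= 0.4:
                    why.append("doublet")
                qc_pass.append(not why)
                reasons.append(tuple(why))
                i += 1
    cell_ids = np.array(ids, dtype=object)
    meta = pd.DataFrame(
        meta_rows, columns=["total_umis", "unspliced_fraction", "doublet_score"],
        index=pd.Index(cell_ids),
    )
    m = CountMatrix(cell_ids, np.array(["geneA", "geneB"], dtype=object),
                    sparse.csr_matrix(np.array(rows)), meta)
    truth = SimTruth(qc_pass=np.array(qc_pass), qc_reasons=reasons)
    return m, truth


def simulate_spatial_transcripts(
    panel: list[str],
    n_cells: int,
    mean_transcripts: float = 30.0,
    nucleus_fraction: float = 0.6,
    unassigned_fraction: float = 0.1,
    seed: int = 0,
) -> SpatialTranscripts:
    """Flat transcript table mimicking a targeted in-situ panel readout.

    Each cell emits Poisson(mean_transcripts) transcripts over the panel;
    a fraction land outside the segmented nucleus and a further fraction are
    unassigned to any cell.  Geometry is a flat scatter (no tissue structure).
    """
    rng = np.random.default_rng(seed)
    recs = []
    for c in range(n_cells):
        n = rng.poisson(mean_transcripts)
        genes = rng.choice(panel, size=n)
        cx, cy = rng.uniform(0, 1000, size=2)
        for g in genes:
            unassigned = rng.random() < unassigned_fraction
            recs.append((
                g,
                float(cx + rng.normal(0, 5)), float(cy + rng.normal(0, 5)),
                "" if unassigned else f"S{c:05d}",
                bool(rng.random() < nucleus_fraction) and not unassigned,
            ))
    df = pd.DataFrame(recs, columns=["gene", "x", "y", "cell_id", "in_nucleus"])
    return SpatialTranscripts(df)
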