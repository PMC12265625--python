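"""LDA topic modeling of count data and transfer of fitted topics.

Topics are probability distributions over genes; a cell (or bulk sample)
is modeled as a mixture of topics.  Fitting uses collapsed Gibbs sampling
over token-topic assignments.  Fitted topic-gene distributions can be
restricted to the genes shared with a new dataset (a targeted spatial panel,
or bulk profiles) and per-document weights re-inferred by fold-in Gibbs with
the topic-gene rows frozen — the standard mechanism for scoring new data
against a trained model.

Topic quality control (dropping contamination, sex-chromosome or otherwise
uninterpretable topics) is a judgement call and therefore an explicit
exclusion list supplied by the analyst, never automatic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from ._gibbs import gibbs_fit, gibbs_fold_in
from .containers import CountMatrix
from .io import match_genes

logger = logging.getLogger("scmeninges")

#: tokens a bulk expression profile is discretized into before fold-in
BULK_TOKENS = 10_000


@dataclass
class TopicModel:
    """A fitted LDA model: K topic-gene distributions + document weights."""

    n_topics: int
    topic_word: np.ndarray      # K x V, rows sum to 1
    doc_topic: np.ndarray       # D x K, rows sum to 1
    vocabulary: np.ndarray      # V gene labels
    doc_ids: np.ndarray
    alpha: float
    eta: float
    iterations: int
    seed: int
    loglik: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.topic_word = np.asarray(self.topic_word, dtype=float)
        self.doc_topic = np.asarray(self.doc_topic, dtype=float)
        self.vocabulary = np.asarray(self.vocabulary, dtype=object)
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise ValueError("duplicate gene in topic-model vocabulary")
        for name, mat in (("topic_word", self.topic_word), ("doc_topic", self.doc_topic)):
            if (mat < 0).any():
                raise ValueError(f"{name} has negative probabilities")
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} rows do not sum to 1")

    def vocabulary_hash(self) -> str:
        joined = "\n".join(str(g) for g in self.vocabulary)
        return hashlib.sha256(joined.encode()).hexdigest()[:16]


@dataclass
class TopicGeneRanking:
    """Per-topic specificity-filtered gene rankings."""

    specificity_threshold: float
    # topic index -> DataFrame(gene, specificity, probability) sorted
    tables: dict[int, pd.DataFrame]


def _expand_tokens(counts: sparse.csr_matrix) -> tuple[np.ndarray, np.ndarray]:
    coo = sparse.coo_matrix(counts)
    reps = coo.data.astype(np.int64)
    doc_idx = np.repeat(coo.row, reps).astype(np.int32)
    word_idx = np.repeat(coo.col, reps).astype(np.int32)
    return doc_idx, word_idx


def fit_lda(
    m: CountMatrix,
    n_topics: int = 35,
    alpha: float | None = None,
    eta: float = 0.1,
    iterations: int = 1000,
    burn_in: int = 200,
    thin: int = 10,
    seed: int = 0,
) -> TopicModel:
    """Fit LDA by collapsed Gibbs sampling on raw UMI counts.

    ``alpha`` defaults to 50/K.  A fixed seed yields an identical model.
    Raises on empty documents, naming the first offender.
    """
    if n_topics < 1:
        raise ValueError("n_topics must be >= 1")
    totals = m.total_counts()
    if (totals == 0).any():
        empty = m.cell_ids[int(np.flatnonzero(totals == 0)[0])]
        raise ValueError(f"empty document: {empty!r}")
    if alpha is None:
        alpha = 50.0 / n_topics

    if n_topics == 1:
        word_totals = np.asarray(m.counts.sum(axis=0)).ravel()
        phi = ((word_totals + eta) / (word_totals + eta).sum())[None, :]
        theta = np.ones((m.n_cells, 1))
        return TopicModel(1, phi, theta, m.gene_ids, m.cell_ids,
                          alpha, eta, iterations, seed)

    if burn_in >= iterations:
        # always collect at least one posterior sample
        burn_in = max(iterations - 1, 0)
        logger.warning("burn_in >= iterations; clamped to %d", burn_in)

    doc_idx, word_idx = _expand_tokens(m.counts)
    phi, theta, loglik = gibbs_fit(
        doc_idx, word_idx, m.n_cells, m.n_genes, n_topics,
        float(alpha), float(eta), int(iterations), int(burn_in), int(thin),
        int(seed) % (2**31),
    )
    return TopicModel(n_topics, phi, theta, m.gene_ids, m.cell_ids,
                      float(alpha), float(eta), int(iterations), int(seed),
                      loglik=loglik)


def rank_topic_genes(model: TopicModel, specificity_threshold: float) -> TopicGeneRanking:
    """Rank genes per topic: filter by specificity, sort by raw probability.

    Specificity of gene g in topic t is p(g|t) normalized by the gene's
    summed probability across all topics.  Genes at or above the threshold
    are kept and sorted by descending unnormalized p(g|t); ties break
    lexicographically on the gene label.
    """
    phi = model.topic_word
    col_sums = phi.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        spec = np.where(col_sums > 0, phi / col_sums, 0.0)
    tables: dict[int, pd.DataFrame] = {}
    genes = model.vocabulary
    for t in range(model.n_topics):
        keep = spec[t] >= specificity_threshold
        df = pd.DataFrame(
            {"gene": genes[keep], "specificity": spec[t, keep],
             "probability": phi[t, keep]}
        )
        df = df.sort_values(
            ["probability", "gene"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        tables[t] = df
    return TopicGeneRanking(specificity_threshold, tables)


def _restricted_phi(model: TopicModel, target_genes: np.ndarray) -> tuple[np.ndarray, list]:
    shared, _ = match_genes(list(model.vocabulary), list(target_genes),
                            context="topic transfer")
    if not shared:
        raise ValueError("no shared genes between model vocabulary and target")
    vocab_pos = {g: i for i, g in enumerate(model.vocabulary)}
    idx = np.array([vocab_pos[g] for g in shared], dtype=int)
    phi = model.topic_word[:, idx]
    row_sums = phi.sum(axis=1, keepdims=True)
    if (row_sums == 0).any():
        # a topic with no mass on shared genes gets a uniform stand-in
        logger.warning("topic(s) with zero mass on shared genes; using uniform")
        phi = np.where(row_sums > 0, phi, 1.0)
        row_sums = phi.sum(axis=1, keepdims=True)
    return phi / row_sums, shared


def transfer_topics_cells(
    model: TopicModel,
    target: CountMatrix,
    sweeps: int = 100,
    burn_in: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Score target cells against frozen topics restricted to shared genes.

    Returns a cells x topics DataFrame of weights summing to 1 per cell.
    Cells with no counts on shared genes receive uniform weights (warned).
    """
    if burn_in >= sweeps:
        burn_in = max(sweeps - 1, 0)
    phi, shared = _restricted_phi(model, target.gene_ids)
    sub = target.counts[:, target.gene_index(shared)]
    doc_idx, word_idx = _expand_tokens(sub)
    theta = np.full((target.n_cells, model.n_topics), 1.0 / model.n_topics)
    covered = np.unique(doc_idx)
    if len(covered) < target.n_cells:
        logger.warning(
            "%d target cells have no transcripts on shared genes; uniform weights",
            target.n_cells - len(covered),
        )
    if len(doc_idx):
        inferred = gibbs_fold_in(
            doc_idx, word_idx, target.n_cells, phi, model.alpha,
            int(sweeps), int(burn_in), int(seed) % (2**31),
        )
        theta[covered] = inferred[covered]
    return pd.DataFrame(theta, index=pd.Index(target.cell_ids),
                        columns=[f"topic_{t}" for t in range(model.n_topics)])


def transfer_topics_bulk(
    model: TopicModel,
    bulk: pd.DataFrame,
    grouping: dict[str, str] | pd.Series | None = None,
    tokens: int = BULK_TOKENS,
    sweeps: int = 100,
    burn_in: int = 50,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Relative topic contributions for bulk profiles and sample groups.

    ``bulk`` is samples x genes (nonnegative expression).  Each profile is
    discretized to ``tokens`` pseudo-tokens over the genes shared with the
    model vocabulary and folded in as one document.  Per-group contribution
    is the mean over member samples, renormalized to sum to exactly 1.
    """
    if burn_in >= sweeps:
        burn_in = max(sweeps - 1, 0)
    vals = bulk.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("bulk profiles must be nonnegative")
    phi, shared = _restricted_phi(model, bulk.columns.to_numpy(dtype=object))
    col_pos = {g: i for i, g in enumerate(bulk.columns)}
    sub = vals[:, [col_pos[g] for g in shared]]
    row_sums = sub.sum(axis=1, keepdims=True)
    if (row_sums == 0).any():
        bad = bulk.index[int(np.flatnonzero(row_sums.ravel() == 0)[0])]
        raise ValueError(f"bulk sample {bad!r} has zero expression on shared genes")
    pseudo = np.round(sub / row_sums * tokens).astype(np.int64)
    doc_idx, word_idx = _expand_tokens(sparse.csr_matrix(pseudo))
    theta = gibbs_fold_in(
        doc_idx, word_idx, len(bulk), phi, model.alpha,
        int(sweeps), int(burn_in), int(seed) % (2**31),
    )
    theta /= theta.sum(axis=1, keepdims=True)
    per_sample = pd.DataFrame(theta, index=bulk.index,
                              columns=[f"topic_{t}" for t in range(model.n_topics)])
    if grouping is None:
        return per_sample, None
    groups = pd.Series(grouping).reindex(per_sample.index)
    per_group = per_sample.groupby(groups).mean()
    per_group = per_group.div(per_group.sum(axis=1), axis=0)
    return per_sample, per_group


def save_topic_model(model: TopicModel, path: str | Path) -> None:
    """Serialize as two TSV matrices plus a JSON header."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(model.topic_word, columns=model.vocabulary).to_csv(
        path / "topic_word.tsv", sep="\t", index=False)
    pd.DataFrame(model.doc_topic, index=pd.Index(model.doc_ids, name="doc")).to_csv(
        path / "doc_topic.tsv", sep="\t")
    header = {
        "n_topics": model.n_topics, "alpha": model.alpha, "eta": model.eta,
        "iterations": model.iterations, "seed": model.seed,
        "vocabulary_hash": model.vocabulary_hash(),
    }
    (path / "model.json").write_text(json.dumps(header, indent=2))


def load_topic_model(path: str | Path) -> TopicModel:
    path = Path(path)
    header = json.loads((path / "model.json").read_text())
    tw = pd.read_csv(path / "topic_word.tsv", sep="\t")
    dt = pd.read_csv(path / "doc_topic.tsv", sep="\t", index_col=0)
    model = TopicModel(
        header["n_topics"], tw.to_numpy(), dt.to_numpy(),
        tw.columns.to_numpy(dtype=object), dt.index.to_numpy(dtype=object),
        header["alpha"], header["eta"], header["iterations"], header["seed"],
    )
    if model.vocabulary_hash() != header["vocabulary_hash"]:
        raise ValueError("vocabulary hash mismatch in serialized topic model")
    return model
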