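"""Core in-memory containers shared by every pipeline stage.

The universal expression container is :class:`CountMatrix` (cells x genes UMI
counts plus per-cell metadata).  :class:`GeneAnnotation` supplies the
(chromosome, position) ordering that the karyotyper walks along, and
:class:`ReferenceAtlas` holds cluster mean expression profiles playing the
role of a normal-tissue reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

#: Canonical chromosome order: autosomes 1-22 then X, Y.
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
AUTOSOMES: tuple[str, ...] = CHROMOSOMES[:22]

_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}


class FormatError(ValueError):
    """Raised when an input file or container violates its format contract."""


def normalize_chromosome(label: str) -> str:
    """Strip a leading ``chr`` prefix; ``chr22`` and ``22`` are the same."""
    label = str(label)
    return label[3:] if label.lower().startswith("chr") else label


def chromosome_rank(label: str) -> int:
    label = normalize_chromosome(label)
    if label not in _CHROM_RANK:
        raise ValueError(f"unknown chromosome label: {label!r}")
    return _CHROM_RANK[label]


def _as_count_array(counts) -> sparse.csr_matrix:
    if sparse.issparse(counts):
        mat = counts.tocsr().astype(np.float64)
        data = mat.data
    else:
        mat = sparse.csr_matrix(np.asarray(counts, dtype=np.float64))
        data = mat.data
    if data.size and data.min() < 0:
        bad = int(np.argmin(data))
        raise FormatError(f"negative count entry {data[bad]} in matrix")
    if data.size and not np.allclose(data, np.round(data)):
        bad = data[~np.isclose(data, np.round(data))][0]
        raise FormatError(f"non-integer count entry {bad} in matrix")
    return mat


@dataclass
class CountMatrix:
    """Cells x genes nonnegative integer UMI counts with per-cell metadata.

    ``cell_meta`` is a DataFrame indexed like ``cell_ids`` with optional
    columns ``total_umis``, ``unspliced_fraction``, ``doublet_score``,
    ``sample``, ``age_pcw``, ``cluster``, ``timepoint``.
    """

    cell_ids: np.ndarray
    gene_ids: np.ndarray
    counts: sparse.csr_matrix
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    #: named secondary matrices (e.g. "lognorm"); same shape, not validated
    layers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("duplicate cell ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids")
        self.counts = _as_count_array(self.counts)
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids))
        else:
            self.cell_meta = pd.DataFrame(self.cell_meta)
            if not np.array_equal(
                self.cell_meta.index.to_numpy(dtype=object), self.cell_ids
            ):
                self.cell_meta = self.cell_meta.set_axis(pd.Index(self.cell_ids))
        if "total_umis" in self.cell_meta:
            stated = np.asarray(self.cell_meta["total_umis"], dtype=float)
            actual = self.total_counts()
            off = ~np.isclose(stated, actual)
            if off.any():
                i = int(np.flatnonzero(off)[0])
                raise FormatError(
                    f"cell {self.cell_ids[i]!r}: total_umis={stated[i]} but row "
                    f"sum is {actual[i]}"
                )

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def total_counts(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def dense(self) -> np.ndarray:
        return self.counts.toarray()

    def gene_index(self, genes) -> np.ndarray:
        """Positions of ``genes`` in this matrix; missing genes are an error."""
        lut = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lut]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return np.array([lut[g] for g in genes], dtype=int)

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            cell_ids=self.cell_ids[idx],
            gene_ids=self.gene_ids,
            counts=self.counts[idx],
            cell_meta=self.cell_meta.iloc[idx],
        )

    def with_meta(self, **columns) -> "CountMatrix":
        meta = self.cell_meta.copy()
        for k, v in columns.items():
            meta[k] = np.asarray(v)
        return CountMatrix(self.cell_ids, self.gene_ids, self.counts, meta)


@dataclass
class GeneAnnotation:
    """Per-gene chromosome and genomic position (0-based)."""

    table: pd.DataFrame  # index gene_id, columns chromosome, position

    def __post_init__(self) -> None:
        t = pd.DataFrame(self.table)
        if t.index.duplicated().any():
            dup = t.index[t.index.duplicated()][0]
            raise FormatError(f"duplicate gene id in annotation: {dup!r}")
        t = t.copy()
        t["chromosome"] = [normalize_chromosome(c) for c in t["chromosome"]]
        t["position"] = t["position"].astype(np.int64)
        if (t["position"] < 0).any():
            raise FormatError("negative genomic position in annotation")
        t["_rank"] = [chromosome_rank(c) for c in t["chromosome"]]
        t = t.sort_values(["_rank", "position"], kind="mergesort").drop(columns="_rank")
        self.table = t

    @property
    def gene_ids(self) -> np.ndarray:
        return self.table.index.to_numpy(dtype=object)

    def chromosomes(self) -> np.ndarray:
        return self.table["chromosome"].to_numpy(dtype=object)

    def order_genes(self, genes) -> list[str]:
        """Return ``genes`` sorted by (chromosome, position); total order."""
        sub = self.table.loc[list(genes)].copy()
        sub["_rank"] = [chromosome_rank(c) for c in sub["chromosome"]]
        sub = sub.sort_values(["_rank", "position"], kind="mergesort")
        return list(sub.index)

    def chromosome_of(self, genes) -> np.ndarray:
        return self.table.loc[list(genes), "chromosome"].to_numpy(dtype=object)

    def is_autosomal(self, genes) -> np.ndarray:
        return np.array([c in AUTOSOMES for c in self.chromosome_of(genes)])


@dataclass(frozen=True)
class GeneSet:
    """A named, duplicate-free, nonempty collection of gene labels."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        if not genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(genes)) != len(genes):
            raise ValueError(f"gene set {self.name!r} contains duplicates")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class SpatialTranscripts:
    """Decoded in-situ transcripts: gene, x/y (micrometres), cell, nucleus flag.

    ``cell_id`` of empty string means the transcript was not assigned to any
    segmented cell.
    """

    table: pd.DataFrame  # columns: gene, x, y, cell_id, in_nucleus

    def __post_init__(self) -> None:
        t = pd.DataFrame(self.table)
        required = {"gene", "x", "y", "cell_id", "in_nucleus"}
        missing = required - set(t.columns)
        if missing:
            raise FormatError(f"spatial table missing columns: {sorted(missing)}")
        xy = t[["x", "y"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            raise FormatError("non-finite transcript coordinate")
        t = t.copy()
        t["in_nucleus"] = t["in_nucleus"].astype(bool)
        t["cell_id"] = t["cell_id"].fillna("").astype(str)
        self.table = t

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ReferenceAtlas:
    """Cluster x gene mean normalized expression profiles."""

    cluster_ids: np.ndarray
    gene_ids: np.ndarray
    values: np.ndarray  # clusters x genes, >= 0

    def __post_init__(self) -> None:
        self.cluster_ids = np.asarray(self.cluster_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.cluster_ids), len(self.gene_ids)):
            raise FormatError("atlas shape inconsistent with id lists")
        if (self.values < 0).any():
            raise FormatError("negative atlas expression value")
        if (self.values.sum(axis=1) == 0).any():
            raise FormatError("atlas contains an all-zero cluster row")

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    def gene_index(self, genes) -> np.ndarray:
        lut = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lut[g] for g in genes], dtype=int)


@dataclass(frozen=True)
class CnaSpec:
    """Ground-truth copy-number aberrations carried by one simulated clone.

    ``events`` maps whole chromosomes to integer copy numbers in 0..6; the
    expected expression of every gene on an affected chromosome scales by
    copy/2 relative to the diploid baseline.
    """

    clone_id: str
    fraction: float
    events: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"clone fraction {self.fraction} outside [0, 1]")
        events = tuple((normalize_chromosome(c), int(k)) for c, k in self.events)
        for chrom, copy in events:
            if chrom not in CHROMOSOMES:
                raise ValueError(f"unknown chromosome in CNA event: {chrom!r}")
            if not 0 <= copy <= 6:
                raise ValueError(f"copy number {copy} outside 0..6")
        object.__setattr__(self, "events", events)


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated data."""

    clone: np.ndarray | None = None          # per-cell clone label
    cluster: np.ndarray | None = None        # per-cell reference cluster
    layer: np.ndarray | None = None          # per-cell true layer label
    timepoint: np.ndarray | None = None      # per-cell timepoint index
    qc_pass: np.ndarray | None = None        # per-cell boolean
    qc_reasons: list[tuple[str, ...]] | None = None


@dataclass
class PloidyTracks:
    """Smoothed per-cell ploidy (diploid = 2) along genome-ordered kept genes."""

    cell_ids: np.ndarray
    gene_ids: np.ndarray          # ordered by (chromosome, position)
    chromosomes: np.ndarray       # per kept gene
    values: np.ndarray            # cells x kept genes
    matched_cluster: np.ndarray   # per-cell best reference cluster

    def chromosome_slices(self) -> list[tuple[str, slice]]:
        out: list[tuple[str, slice]] = []
        chroms = self.chromosomes
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out.append((chroms[start], slice(start, i)))
                start = i
        return out


@dataclass
class KaryotypeCall:
    """Integer copy-number segments for one metacell."""

    metacell_id: str
    member_cell_ids: np.ndarray
    # (chromosome, start gene index, end gene index exclusive, copy number)
    segments: list[tuple[str, int, int, int]]

    def copy_by_chromosome(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for chrom, _, _, copy in self.segments:
            out.setdefault(chrom, []).append(copy)
        return out

    def single_copy_per_chromosome(self) -> dict[str, int]:
        """Chromosome -> copy number where the call is one whole segment."""
        by = self.copy_by_chromosome()
        return {c: v[0] for c, v in by.items() if len(v) == 1}
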