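# Methods

This note documents the models implemented in `scmeninges`, the parameters
that matter, the numerical choices made where the design was open, what the
synthetic generators do and do not emulate, and known limitations.

## Expression-based karyotyping

### Model

Copy-number aberrations (CNAs) at chromosome scale leave a multiplicative
footprint on expression: a gene at copy number k is expected to be
expressed at k/2 of its diploid level. The karyotyper estimates that ratio
per cell against an *external* reference atlas of cluster mean-expression
profiles, which removes the need to identify normal cells inside each
tumour sample.

Pipeline, per sample:

1. **Depth normalization.** Each cell's counts are scaled to the median
   total UMIs across cells. A pure rescaling — all later quantities are
   ratios, so the whole pipeline is invariant to multiplying every count by
   a constant (tested).
2. **Gene selection.** A gene passes in a reference cluster iff its value
   exceeds `expr_fraction_of_quantile` (0.10) × that cluster's
   99th-percentile expression level; it is kept iff it passes in at least
   `min_cluster_fraction` (0.5) of clusters and is autosomal. The
   within-cluster percentile is the default; a pooled-atlas percentile is
   available via `percentile_scope="pooled"` since the choice is ambiguous
   in principle. Fewer than 50 surviving genes is an error — the track
   would be too sparse to smooth.
3. **Reference matching.** Pearson correlation over kept genes; argmax
   cluster, ties broken lexicographically. A constant cell vector is an
   error (correlation undefined).
4. **Ploidy track.** 2 × cell / reference per kept gene, smoothed by a
   centred sliding mean of `smoothing_window` (25) genes truncated at
   chromosome boundaries (no cross-chromosome bleed; a window longer than
   the chromosome degrades to the whole-chromosome mean), then divided by
   the track median and multiplied by 2 — the genome-wide median of every
   track is exactly 2 afterwards (tested).
5. **Masking.** Genes whose reference value in the matched cluster is
   below `ref_mask_fraction` (0.10) of that cluster's mean over kept genes
   are masked (NaN) for that cell. Rationale: at an expected expression
   well below one UMI the ratio estimator is a 0-or-huge coin flip, and
   because metacells are later clustered *by track similarity*, such noise
   co-clusters rather than averaging out — we observed 50-cell metacells
   with coherent false gains driven entirely by a handful of such genes.
   Masked positions are simply ignored by the window mean and treated as
   uninformative by the HMM.
6. **Metacells.** PCA (centred, unscaled) to `n_pcs` (5) components on the
   cell × gene ploidy matrix; k-nearest-neighbour graph with
   k = min(30, n−1), symmetrized by union so no cell is isolated (a
   mutual-only variant exists but can strand single cells as singleton
   metacells whose one-cell tracks are noisy); Leiden partition at
   resolution 1.0 with a fixed seed.
7. **Segmentation.** Per metacell, the member-mean track is decoded per
   chromosome by Viterbi on an HMM with states 0..`max_copies` (6),
   Gaussian emissions N(state, `emission_sd`²) with `emission_sd` = 0.3,
   uniform initial distribution, and transitions with `stay_probability`
   = 0.999 on the diagonal, the remainder uniform over other states.
   The defaults are chosen so that a single-window outlier cannot flip a
   call but an event sustained over roughly a smoothing window can. The
   decoder is verified exactly against exhaustive path enumeration on
   short tracks.

### What the defaults mean

| parameter | default | unit / meaning |
| --- | --- | --- |
| `expr_quantile`, `expr_fraction_of_quantile` | 0.99, 0.10 | gene-selection floor: 10% of the within-cluster 99th percentile |
| `min_cluster_fraction` | 0.5 | gene must pass in at least half the clusters |
| `smoothing_window` | 25 | genes per sliding window |
| `n_pcs`, `knn` | 5, 30 | metacell graph construction |
| `max_copies` | 6 | highest HMM copy state |
| `emission_sd` | 0.3 | ploidy units around each integer state |
| `stay_probability` | 0.999 | per-gene probability of staying in a state |
| `ref_mask_fraction` | 0.1 | per-cell mask floor, fraction of cluster mean |

## Topic modeling

LDA is fitted by collapsed Gibbs sampling over token–topic assignments
(numba kernels; the corpus is token-expanded). Defaults: α = 50/K,
η = 0.1, 1,000 sweeps with 200 burn-in; point estimates are posterior
means averaged over every 10th post-burn-in sweep, which is markedly more
stable than the final sample. A fixed seed gives a bit-identical model.
The per-sweep log of the total unnormalized sampling mass is recorded as a
convergence trace; it climbs from random initialization on block average.

**Ranking.** Specificity of gene g in topic t is p(g|t) normalized by the
gene's summed probability across topics; genes at or above a caller-chosen
threshold are kept and sorted by descending unnormalized p(g|t) with a
lexicographic tie-break. The threshold is a required analysis parameter
with no asserted default. Discarding quality topics (contamination,
sex-chromosome, uninterpretable) is a judgement call: the API takes an
explicit exclusion list and never drops topics automatically.

**Transfer.** Topic–gene rows are restricted to the genes shared with the
target (exact, case-sensitive matching; dropped genes logged), renormalized
per topic, and frozen; per-document weights are re-inferred by fold-in
Gibbs (100 sweeps, 50 burn-in, seeded). Bulk profiles are discretized to
10,000 pseudo-tokens over shared genes — making transfer invariant to
profile scaling — and folded in as single documents; group contributions
are the mean over member samples, renormalized to sum to exactly 1. We
normalize per sample first, then average, then renormalize.

## Signature (gene-profile) scoring

Counts are scaled to 10,000 per cell and log(1+x)-transformed; relative
expression subtracts each gene's mean across cells. Genes are ranked by
aggregate (mean) expression and split into `n_bins` (25) equal-size bins;
each signature gene draws `n_controls_per_gene` (100) control genes with
replacement from the *non-signature* members of its bin. The score is the
mean relative expression over the set minus the mean over the pooled
controls. Excluding the signature from the control pool matters: a
strongly and coherently regulated signature can dominate its own
expression bins, and controls drawn from the set itself would cancel the
very signal being measured. If a bin contains only signature genes the
pool widens to all non-signature genes (logged). Under an exchangeable
null the score has zero expectation (tested at 500 cells, |mean| < 0.05);
a shift planted in a cell subset is recovered as the subset-vs-complement
score difference.

The cell-cycle score is simpler — the fraction of a cell's UMIs on a
cycle gene set — and is exactly scale-free. Cluster-level cycling is the
percentage of cells with score strictly above 0.01.

**Cluster enrichment** combines the two signals the underlying measure is
defined by: enrichment(g,c) = [(mean_in+ε)/(mean_out+ε)] ×
[(nnz_in+ε)/(nnz_out+ε)] with ε = 0.01, means over depth-normalized
expression, nonzero fractions over raw counts, and "out" pooling all other
clusters. The exact formula of the original framework is not published;
ours preserves its two stated factors and is validated against a
hand-computed oracle only.

## Layer-maturation assignment

Inputs: a fetal matrix with a `timepoint` column and one gene set per
meningeal layer (in practice, the top-50 layer-enriched genes of an adult
atlas). Genes detected (count ≥ 1) in more than 15% of early-group cells
(default: the two earliest timepoints, i.e. PCW 5–6) are dropped, so the
filtered sets reflect maturation rather than baseline expression. Within a
cell a set gene counts as expressed iff its raw count is strictly above 2.
A cell takes the layer with the highest expressed-gene fraction if that
fraction reaches 5%, else "Other"; ties resolve deterministically by the
order layers are supplied (pass pia, arachnoid, dura for that priority).
Whether tie-breaking should use summed expression instead of the fraction
is unspecified in principle; we use the fraction and log ties.

Per-timepoint median set expression is reported over the cells *attributed*
to each layer's lineage (argmax of mean filtered-set expression), not over
all cells — the median over a mixed population would be dominated by cells
maturing toward other layers and would not track the lineage's own
trajectory.

## QC

Thresholds are uniform in their boundary semantics: "fewer/less than" is
strict (<), "at least" is ≥. The doublet criterion removes cells with
score ≥ 0.4, the direction consistent with doublet-caller semantics where
high scores mark likely doublets; the opposite (literal) direction is
available via `doublet_high_is_doublet=False`. Round-1 filters are
per-cell; the round-2 rule removes a cluster iff ≥ 40% of its cells have
< 1,800 UMIs, and is applied after round-1 filtering. Manual removals
(visually spotted doublet or erythrocyte-contaminated clusters) are
judgement calls and are out of scope. Filters are idempotent and a cell
passes iff its reason list is empty (both tested).

Spatial QC keeps only nucleus-assigned transcripts (deliberately
discarding reads to avoid mis-segmentation artefacts), optionally
restricts to the probe panel, drops cells under the detected-gene /
total-transcript minima (8/20 fetal, 3/5 tumour), normalizes each kept
cell to 10,000 total transcripts and stores log(1+x) alongside raw counts.

## Synthetic data: what it does and does not emulate

Generators are pure functions of their seed and cover: a log-normal
reference atlas with genes apportioned to chromosomes in proportion to
real human gene counts; Poisson cells drawn from atlas profiles with
clone-specific chromosome-scale scaling by copy/2 (optional negative
binomial over-dispersion, off by default — Poisson is the simplest model
under which the ratio estimator is unbiased); standard LDA generative
corpora; a timepoint-graded layer gradient whose signature rates rise
geometrically from 0.02 to 6 so that detection stays under 15% through the
two earliest timepoints while late cells express most of their set; a QC
fixture with one cell per boundary combination (UMIs 999/1000/1001 ×
unspliced 0.09/0.10/0.11 × doublet 0.39/0.40/0.41); and a flat spatial
transcript table with nucleus and assignment flags.

Deliberately not emulated: cross-cluster expression correlation (real
atlases are far from independent log-normal, which if anything makes our
gene-selection pathology stress-test harsher than reality), cell-type
composition shifts, batch effects, spliced/unspliced kinetics, doublet
formation, spatial tissue geometry, and sequencing-level artefacts.
Passing tests therefore demonstrate correctness of the computations and
robustness to shot noise at realistic depth (10,000 UMIs/cell), not
performance on real tissue.

## Problem sizes used in verification

The acceptance script and test suite run the karyotyper on a 4-cluster,
2,200-autosomal-gene atlas with 300 cells (one third a two-event clone)
over ten simulations, plus a matched diploid null; LDA on a 3-topic corpus
of 200 documents × 500 tokens over 100 genes; signature calibration on 500
exchangeable cells × 1,000 genes; and the maturation gradient on 3 layers ×
4 timepoints × 50 cells. These sizes give tight statistics (e.g. 880
chromosome calls for the karyotyper) while each stage completes in seconds.

## Known limitations

- The karyotyper calls whole-chromosome and large segmental events; with a
  25-gene window and sticky HMM, focal events spanning only a few genes are
  (by design) smoothed away.
- Copy-number 0 regions conflict with median recentring if they cover most
  of the genome; the estimator assumes the majority of each track is
  diploid.
- Reference-free operation is not supported: a mismatched atlas (wrong
  tissue) degrades matching and hence tracks.
- Collapsed Gibbs gives a point estimate from a single chain; label
  switching across seeds is expected and handled in comparisons by
  Hungarian matching.
- Bulk transfer discretizes profiles to 10,000 tokens; extremely skewed
  profiles lose sub-token mass.
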