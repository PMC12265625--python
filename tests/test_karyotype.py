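import itertools

import numpy as np
import pandas as pd
import pytest

import scmeninges as sm
from scmeninges.karyotype import (
    KaryotyperParams,
    _smooth_within_chromosomes,
    viterbi_decode,
)


def brute_force_viterbi(obs, n_states, sd, stay):
    """Exhaustive max-probability path; independent oracle for the HMM."""
    obs = np.asarray(obs, float)
    T = len(obs)
    log_stay = np.log(stay)
    log_move = np.log((1 - stay) / (n_states - 1))
    best_path, best_score = None, -np.inf
    for path in itertools.product(range(n_states), repeat=T):
        score = -np.log(n_states)
        for t in range(T):
            if t > 0:
                score += log_stay if path[t] == path[t - 1] else log_move
            if not np.isnan(obs[t]):
                score += -0.5 * ((obs[t] - path[t]) / sd) ** 2
        if score > best_score:
            best_score, best_path = score, path
    return np.array(best_path)


class TestSelectGenes:
    def test_sparse_survivor_floor(self):
        # 4 clusters x 6 genes, far below the 50-gene smoothing floor
        values = np.full((4, 6), 10.0)
        genes = [f"g{i}" for i in range(6)]
        atlas = sm.ReferenceAtlas(["a", "b", "c", "d"], genes, values)
        ann = sm.GeneAnnotation(pd.DataFrame(
            {"chromosome": ["1", "1", "2", "2", "3", "X"],
             "position": [10, 20, 10, 20, 10, 10]},
            index=pd.Index(genes, name="gene")))
        with pytest.raises(ValueError, match="survive selection"):
            sm.select_genes(atlas, ann, KaryotyperParams())

    def test_half_of_clusters_rule_and_autosome_restriction(self):
        atlas, ann = sm.generate_reference_atlas(4, 600, seed=21)
        kept = sm.select_genes(atlas, ann, KaryotyperParams())
        chroms = set(ann.chromosome_of(kept))
        assert "X" not in chroms and "Y" not in chroms
        # kept genes pass in >= 2 of 4 clusters (within-cluster 99th pct rule)
        idx = atlas.gene_index(kept)
        q = np.percentile(atlas.values, 99, axis=1)
        passes = atlas.values[:, idx] > 0.1 * q[:, None]
        assert (passes.sum(axis=0) >= 2).all()

    def test_dropped_genes_fail_cluster_rule(self):
        atlas, ann = sm.generate_reference_atlas(4, 600, seed=21)
        kept = set(sm.select_genes(atlas, ann, KaryotyperParams()))
        q = np.percentile(atlas.values, 99, axis=1)
        passes = atlas.values > 0.1 * q[:, None]
        autosomal = ann.is_autosomal(atlas.gene_ids)
        for i, g in enumerate(atlas.gene_ids):
            expected = passes[:, i].sum() >= 2 and autosomal[i]
            assert (g in kept) == expected

    def test_output_is_genome_ordered(self, small_atlas):
        atlas, ann = small_atlas
        kept = sm.select_genes(atlas, ann)
        assert kept == ann.order_genes(kept)


class TestNormalizeCells:
    def test_equal_depth_unchanged(self):
        counts = np.array([[2, 3], [4, 1]])  # both cells total 5
        m = sm.CountMatrix(["a", "b"], ["g1", "g2"], counts)
        assert np.allclose(sm.normalize_cells(m), counts)

    def test_double_depth_halved_and_totals_equal_median(self):
        counts = np.array([[2, 3], [4, 6], [1, 4]])  # totals 5, 10, 5
        m = sm.CountMatrix(["a", "b", "c"], ["g1", "g2"], counts)
        norm = sm.normalize_cells(m)
        assert np.allclose(norm[1], [2, 3])
        assert np.allclose(norm.sum(axis=1), 5.0)


class TestMatchReference:
    def test_exact_profile_matches_itself(self, small_atlas):
        atlas, _ = small_atlas
        idx = np.arange(atlas.values.shape[1])
        got = sm.match_reference(atlas.values[2], atlas, idx)
        assert got == atlas.cluster_ids[2]

    def test_constant_vector_rejected(self, small_atlas):
        atlas, _ = small_atlas
        idx = np.arange(atlas.values.shape[1])
        with pytest.raises(ValueError, match="constant"):
            sm.match_reference(np.ones(atlas.values.shape[1]), atlas, idx)

    def test_noisy_cells_recover_their_cluster(self, small_atlas):
        atlas, ann = small_atlas
        m, truth = sm.simulate_cells(atlas, ann, 100, [], depth=10_000, seed=6)
        tracks = sm.ploidy_tracks(m, atlas, ann)
        assert (tracks.matched_cluster == truth.cluster).mean() >= 0.99


class TestPloidyTracks:
    def test_cell_equal_to_reference_is_exactly_diploid(self, small_atlas):
        atlas, ann = small_atlas
        # cells are exact copies of cluster profiles (integer-rounded)
        counts = np.round(atlas.values).astype(int)
        m = sm.CountMatrix([f"c{i}" for i in range(4)], atlas.gene_ids, counts)
        atlas_int = sm.ReferenceAtlas(
            atlas.cluster_ids, atlas.gene_ids, counts.astype(float))
        tracks = sm.ploidy_tracks(m, atlas_int, ann)
        assert np.allclose(tracks.values, 2.0)

    def test_amplified_chromosome_reads_three(self, small_atlas):
        atlas, ann = small_atlas
        kept = sm.select_genes(atlas, ann)
        chr1 = ann.chromosome_of(atlas.gene_ids) == "1"
        profile = atlas.values[0].copy()
        profile[chr1] *= 1.5  # 3 copies relative to diploid baseline
        scale = 20.0  # integer-friendly scale
        counts = np.round(np.vstack([profile, atlas.values[0]]) * scale).astype(int)
        m = sm.CountMatrix(["amp", "ref"], atlas.gene_ids, counts)
        atlas_s = sm.ReferenceAtlas(atlas.cluster_ids, atlas.gene_ids,
                                    np.round(atlas.values * scale))
        tracks = sm.ploidy_tracks(m, atlas_s, ann)
        chroms = tracks.chromosomes
        interior = slice(10, int((chroms == "1").sum()) - 10)
        amp_on_1 = tracks.values[0, chroms == "1"][interior]
        amp_off_1 = tracks.values[0, chroms != "1"]
        assert np.abs(amp_on_1 - 3.0).max() < 0.2
        assert np.abs(np.median(amp_off_1) - 2.0) < 0.1

    def test_window_larger_than_chromosome_uses_whole_mean(self):
        vals = np.array([[1.0, 2.0, 3.0, 10.0]])
        chroms = np.array(["1", "1", "1", "2"], dtype=object)
        sm_vals = _smooth_within_chromosomes(vals, chroms, window=99)
        assert np.allclose(sm_vals[0, :3], 2.0)   # whole-chr1 mean
        assert sm_vals[0, 3] == 10.0              # chr2 untouched

    def test_smoothing_does_not_bleed_across_chromosomes(self):
        vals = np.array([[0.0, 0.0, 8.0, 8.0]])
        chroms = np.array(["1", "1", "2", "2"], dtype=object)
        out = _smooth_within_chromosomes(vals, chroms, window=3)
        assert out[0, 1] == 0.0 and out[0, 2] == 8.0

    def test_genomewide_median_exactly_two(self, small_atlas):
        atlas, ann = small_atlas
        m, _ = sm.simulate_cells(atlas, ann, 20, [], seed=9)
        tracks = sm.ploidy_tracks(m, atlas, ann)
        assert np.nanmedian(tracks.values, axis=1) == pytest.approx(2.0)


class TestMetacells:
    def test_identical_cells_one_metacell(self):
        tracks = sm.PloidyTracks(
            cell_ids=np.array([f"c{i}" for i in range(10)], dtype=object),
            gene_ids=np.array(["g0", "g1"], dtype=object),
            chromosomes=np.array(["1", "1"], dtype=object),
            values=np.full((10, 2), 2.0),
            matched_cluster=np.array(["a"] * 10, dtype=object),
        )
        labels = sm.metacells(tracks, seed=0)
        assert len(set(labels)) == 1

    def test_single_cell_single_metacell(self):
        tracks = sm.PloidyTracks(
            cell_ids=np.array(["c0"], dtype=object),
            gene_ids=np.array(["g0"], dtype=object),
            chromosomes=np.array(["1"], dtype=object),
            values=np.array([[2.0]]),
            matched_cluster=np.array(["a"], dtype=object),
        )
        assert list(sm.metacells(tracks, seed=0)) == [0]

    def test_clones_with_disjoint_cnas_separate(self, small_atlas):
        atlas, ann = small_atlas
        clones = [sm.CnaSpec("del22", 0.5, (("22", 1),)),
                  sm.CnaSpec("gain9", 0.5, (("9", 3),))]
        m, truth = sm.simulate_cells(atlas, ann, 200, clones, seed=12)
        tracks = sm.ploidy_tracks(m, atlas, ann)
        labels = sm.metacells(tracks, seed=1)
        # each clone's cells should co-cluster: >= 95% purity via majority map
        df = pd.DataFrame({"mc": labels, "clone": truth.clone})
        majority = df.groupby("mc")["clone"].agg(lambda s: s.mode()[0])
        agree = (df["clone"] == majority[df["mc"]].to_numpy()).mean()
        assert agree >= 0.95

    def test_seed_reproducible(self, small_atlas):
        atlas, ann = small_atlas
        m, _ = sm.simulate_cells(atlas, ann, 60, [], seed=2)
        tracks = sm.ploidy_tracks(m, atlas, ann)
        assert np.array_equal(sm.metacells(tracks, seed=5),
                              sm.metacells(tracks, seed=5))


class TestViterbi:
    def test_constant_near_one_calls_single_copy_segment(self):
        path = viterbi_decode(np.full(30, 1.02), 7, 0.3, 0.999)
        assert (path == 1).all()

    def test_constant_two_is_all_diploid(self):
        path = viterbi_decode(np.full(30, 2.0), 7, 0.3, 0.999)
        assert (path == 2).all()

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            T = int(rng.integers(2, 9))
            obs = rng.uniform(-0.5, 3.5, size=T)
            got = viterbi_decode(obs, 4, 0.3, 0.9)
            expected = brute_force_viterbi(obs, 4, 0.3, 0.9)
            assert np.array_equal(got, expected)

    def test_nan_observations_are_uninformative(self):
        obs = np.array([1.0, np.nan, np.nan, 1.0])
        assert (viterbi_decode(obs, 4, 0.3, 0.999) == 1).all()

    def test_segments_tile_chromosomes(self, small_atlas):
        atlas, ann = small_atlas
        m, _ = sm.simulate_cells(atlas, ann, 30, [], seed=3)
        tracks, labels, calls = sm.karyotype(m, atlas, ann, seed=3)
        for call in calls:
            for chrom, sl in tracks.chromosome_slices():
                segs = [s for s in call.segments if s[0] == chrom]
                assert segs[0][1] == sl.start and segs[-1][2] == sl.stop
                for a, b in zip(segs, segs[1:]):
                    assert a[2] == b[1]


class TestEndToEnd:
    def test_clone_events_called_and_diploid_elsewhere(self, small_atlas):
        atlas, ann = small_atlas
        clone = sm.CnaSpec("clone1", 1 / 3, (("22", 1), ("9", 3)))
        m, truth = sm.simulate_cells(atlas, ann, 150, [clone], seed=7)
        _, labels, calls = sm.karyotype(m, atlas, ann, seed=7)
        idx = {cid: i for i, cid in enumerate(m.cell_ids)}
        for call in calls:
            members = [truth.clone[idx[c]] for c in call.member_cell_ids]
            is_clone = pd.Series(members).mode()[0] == "clone1"
            copies = call.single_copy_per_chromosome()
            expected = {"22": 1, "9": 3} if is_clone else {}
            for chrom, copy in copies.items():
                assert copy == expected.get(chrom, 2)

    def test_scale_invariance(self, small_atlas):
        atlas, ann = small_atlas
        m, _ = sm.simulate_cells(atlas, ann, 80,
                                 [sm.CnaSpec("c", 0.4, (("22", 1),))], seed=8)
        m3 = sm.CountMatrix(m.cell_ids, m.gene_ids, m.dense() * 3)
        _, l1, c1 = sm.karyotype(m, atlas, ann, seed=8)
        _, l3, c3 = sm.karyotype(m3, atlas, ann, seed=8)
        assert np.array_equal(l1, l3)
        assert [c.segments for c in c1] == [c.segments for c in c3]

    def test_diploid_null_all_chromosomes_two(self, small_atlas):
        atlas, ann = small_atlas
        m, _ = sm.simulate_cells(atlas, ann, 100, [], seed=10)
        _, _, calls = sm.karyotype(m, atlas, ann, seed=10)
        for call in calls:
            assert all(copy == 2 for _, _, _, copy in call.segments)


def test_params_validation():
    with pytest.raises(ValueError):
        KaryotyperParams(smoothing_window=0)
    with pytest.raises(ValueError):
        KaryotyperParams(max_copies=1)
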