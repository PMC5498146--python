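"""Embedding, density clustering, bin filtering and truth scoring."""

import numpy as np
import pytest

import minimeta as mm
from minimeta.binning import Embedding, GenomeBin, UNBINNED_LABEL
from minimeta.cooccurrence import OccurrenceMatrix


def three_genome_occurrence(rng, n_sub=96, contigs_per_genome=10):
    """Three genomes with distinct chamber presence patterns plus dropout."""
    presence = []
    truth = {}
    base = rng.integers(0, 2, size=(3, n_sub))
    for g in range(3):
        for c in range(contigs_per_genome):
            cid = f"g{g}_c{c}"
            row = base[g] & (rng.random(n_sub) > 0.1)
            presence.append(row)
            truth[cid] = f"g{g}"
    ids = list(truth)
    return OccurrenceMatrix(ids, [f"s{j}" for j in range(n_sub)], np.array(presence), 2048), truth


class TestEmbedding:
    @pytest.mark.parametrize("method", ["cmds", "tsne"])
    def test_one_point_per_contig(self, rng, method):
        occ, _ = three_genome_occurrence(rng)
        pm = mm.pairwise_pvalues(occ)
        emb = mm.embed_pvalue_distances(pm, seed=1, method=method)
        assert emb.coordinates.shape == (len(pm.contig_ids), 2)

    @pytest.mark.parametrize("method", ["cmds", "tsne"])
    def test_identical_seed_identical_coordinates(self, rng, method):
        occ, _ = three_genome_occurrence(rng)
        pm = mm.pairwise_pvalues(occ)
        a = mm.embed_pvalue_distances(pm, seed=7, method=method)
        b = mm.embed_pvalue_distances(pm, seed=7, method=method)
        assert np.array_equal(a.coordinates, b.coordinates)

    def test_within_genome_tighter_than_between(self, rng):
        occ, truth = three_genome_occurrence(rng)
        pm = mm.pairwise_pvalues(occ)
        emb = mm.embed_pvalue_distances(pm, seed=0)
        coords = {cid: emb.coordinates[i] for i, cid in enumerate(emb.contig_ids)}
        within, between = [], []
        ids = list(truth)
        for i, ci in enumerate(ids):
            for cj in ids[i + 1 :]:
                d = float(np.linalg.norm(coords[ci] - coords[cj]))
                (within if truth[ci] == truth[cj] else between).append(d)
        assert np.mean(within) < np.mean(between)

    def test_too_few_contigs_rejected(self):
        pm = mm.PValueMatrix(["a", "b"], np.full((2, 2), 0.5))
        with pytest.raises(Exception, match="3 contigs"):
            mm.embed_pvalue_distances(pm)


class TestClustering:
    def test_two_separated_blobs_give_two_bins(self, rng):
        blob1 = rng.normal(0, 1, size=(50, 2))
        blob2 = rng.normal(0, 1, size=(50, 2)) + [200, 0]
        coords = np.vstack([blob1, blob2])
        emb = Embedding([f"c{i}" for i in range(100)], coords, seed=0)
        bins = [b for b in mm.cluster_embedding(emb) if not b.is_unbinned]
        assert len(bins) == 2
        assert sorted(len(b) for b in bins) == [50, 50]

    def test_identical_points_form_one_bin(self):
        emb = Embedding([f"c{i}" for i in range(10)], np.zeros((10, 2)), seed=0)
        bins = mm.cluster_embedding(emb)
        real = [b for b in bins if not b.is_unbinned]
        assert len(real) == 1 and len(real[0]) == 10

    def test_isolated_point_is_unbinned(self, rng):
        coords = np.vstack([rng.normal(0, 1, size=(30, 2)), [[500.0, 500.0]]])
        emb = Embedding([f"c{i}" for i in range(31)], coords, seed=0)
        bins = mm.cluster_embedding(emb)
        unbinned = next(b for b in bins if b.is_unbinned)
        assert "c30" in unbinned.contig_ids

    def test_small_clusters_are_unbinned(self, rng):
        coords = np.vstack([rng.normal(0, 0.5, size=(40, 2)),
                            rng.normal(0, 0.5, size=(3, 2)) + [300, 0]])
        emb = Embedding([f"c{i}" for i in range(43)], coords, seed=0)
        bins = mm.cluster_embedding(emb, eps=5.0, min_points=3, min_bin_contigs=5)
        real = [b for b in bins if not b.is_unbinned]
        assert len(real) == 1
        unbinned = next(b for b in bins if b.is_unbinned)
        assert len(unbinned) == 3

    def test_nonpositive_eps_rejected(self):
        emb = Embedding(["a", "b", "c"], np.zeros((3, 2)), seed=0)
        with pytest.raises(ValueError, match="eps"):
            mm.cluster_embedding(emb, eps=0.0)


class TestSizeFilter:
    lengths = {"a": 300_000, "b": 250_000, "c": 400_000, "d": 3_300_000}

    def test_bin_over_cutoff_retained(self):
        bins = [GenomeBin("bin_001", ["a", "b"])]
        out = mm.filter_bins_by_size(bins, self.lengths)
        assert [b.bin_id for b in out if not b.is_unbinned] == ["bin_001"]

    def test_bin_under_cutoff_dropped(self):
        bins = [GenomeBin("bin_001", ["c"])]
        out = mm.filter_bins_by_size(bins, self.lengths)
        assert [b.bin_id for b in out if not b.is_unbinned] == []
        assert "c" in next(b for b in out if b.is_unbinned).contig_ids

    def test_long_singleton_promoted_when_allowed(self):
        bins = [GenomeBin(UNBINNED_LABEL, ["d"])]
        out = mm.filter_bins_by_size(bins, self.lengths, allow_singletons=True)
        promoted = [b for b in out if not b.is_unbinned]
        assert len(promoted) == 1 and promoted[0].contig_ids == ["d"]
        assert promoted[0].total_length == 3_300_000

    def test_missing_length_rejected(self):
        with pytest.raises(Exception, match="length"):
            mm.filter_bins_by_size([GenomeBin("bin_001", ["zzz"])], self.lengths)


class TestConsensusLineage:
    def test_majority_among_assigned(self):
        b = GenomeBin("bin_001", [f"c{i}" for i in range(10)])
        lineages = {f"c{i}": "Bacteroidetes" for i in range(7)}
        assert mm.consensus_lineage(b, lineages) == ("Bacteroidetes", 1.0)

    def test_all_unassigned(self):
        b = GenomeBin("bin_001", ["c1", "c2"])
        assert mm.consensus_lineage(b, {}) == ("unassigned", 0.0)

    def test_mixed_labels(self):
        b = GenomeBin("bin_001", [f"c{i}" for i in range(7)])
        lineages = {f"c{i}": ("Chlorobi" if i < 4 else "Spirochaetes") for i in range(7)}
        label, frac = mm.consensus_lineage(b, lineages)
        assert label == "Chlorobi" and frac == pytest.approx(4 / 7)


def pair_counting_ari(labels_a, labels_b):
    """Brute-force adjusted Rand index by counting concordant pairs."""
    n = len(labels_a)
    same_a = same_b = same_both = 0
    for i in range(n):
        for j in range(i + 1, n):
            a_same = labels_a[i] == labels_a[j]
            b_same = labels_b[i] == labels_b[j]
            same_a += a_same
            same_b += b_same
            same_both += a_same and b_same
    n_pairs = n * (n - 1) // 2
    expected = same_a * same_b / n_pairs
    maximum = (same_a + same_b) / 2
    if maximum == expected:
        return 0.0
    return (same_both - expected) / (maximum - expected)


class TestEvaluate:
    def test_perfect_agreement(self):
        bins = [GenomeBin("x", ["a", "b"]), GenomeBin("y", ["c", "d"])]
        truth = {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}
        scores = mm.evaluate_binning(bins, truth)
        assert scores.ari == pytest.approx(1.0)
        assert all(p == 1.0 for p in scores.purity.values())
        assert all(c == 1.0 for c in scores.completeness.values())

    def test_single_bin_of_balanced_genomes_scores_zero(self):
        bins = [GenomeBin("x", ["a", "b", "c", "d"])]
        truth = {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}
        assert mm.evaluate_binning(bins, truth).ari == pytest.approx(0.0)

    def test_random_labelings_match_pair_counting_oracle(self, rng):
        for _ in range(5):
            n = 30
            truth_labels = rng.integers(0, 4, n)
            pred_labels = rng.integers(0, 3, n)
            contigs = [f"c{i}" for i in range(n)]
            truth = {c: f"g{t}" for c, t in zip(contigs, truth_labels)}
            bins = [
                GenomeBin(f"b{k}", [c for c, p in zip(contigs, pred_labels) if p == k])
                for k in range(3)
            ]
            bins = [b for b in bins if b.contig_ids]
            scores = mm.evaluate_binning(bins, truth)
            assert scores.ari == pytest.approx(
                pair_counting_ari(list(pred_labels), list(truth_labels)), abs=1e-10
            )

    def test_missing_truth_rejected(self):
        with pytest.raises(Exception, match="missing"):
            mm.evaluate_binning([GenomeBin("x", ["a"])], {})


class TestPipelineInvariants:
    def test_bin_membership_invariant_under_contig_order(self, reference_sim):
        cov = reference_sim.coverage
        perm = np.random.default_rng(3).permutation(len(cov.contig_ids))
        shuffled = mm.CoverageMatrix(
            [cov.contig_ids[i] for i in perm],
            cov.subsample_ids,
            cov.values[perm],
            cov.contig_lengths[perm],
        )
        cfg = mm.PipelineConfig()
        res_a = mm.bin_contigs(cov, reference_sim.contig_lengths, cfg)
        res_b = mm.bin_contigs(shuffled, reference_sim.contig_lengths, cfg)
        sets_a = sorted(frozenset(b.contig_ids) for b in res_a.bins if not b.is_unbinned)
        sets_b = sorted(frozenset(b.contig_ids) for b in res_b.bins if not b.is_unbinned)
        assert sets_a == sets_b

    def test_every_contig_binned_or_unbinned_exactly_once(self, reference_sim, reference_binning):
        seen = [c for b in reference_binning.bins for c in b.contig_ids]
        assert sorted(seen) == sorted(reference_sim.coverage.contig_ids)

    def test_dropout_degrades_recovery(self):
        """Median ARI over seeds does not improve when MDA dropout worsens."""
        medians = {}
        for dropout in (0.2, 0.6):
            aris = []
            for seed in range(5):
                cfg = mm.reference_scenario(seed=300 + seed)
                cfg.contig_dropout = dropout
                sim = mm.simulate_community(cfg)
                res = mm.bin_contigs(sim.coverage, sim.contig_lengths,
                                     mm.PipelineConfig(seed=seed))
                aris.append(mm.evaluate_binning(res.bins, sim.truth.contig_to_genome,
                                                sim.contig_lengths).ari)
            medians[dropout] = float(np.median(aris))
        assert medians[0.2] >= 0.9
        assert medians[0.6] < medians[0.2]
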