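"""Diversity metrics vs hand computation and scikit-bio oracles."""

import itertools

import numpy as np
import pytest

from ileodef.diversity import (
    DistanceMatrix,
    OtuTable,
    PhyloTree,
    collapse_taxonomy,
    faith_pd,
    observed_otus,
    pcoa,
    permanova,
    rarefy,
    taxon_label,
    unifrac_matrix,
    unweighted_unifrac,
)

from conftest import random_table_and_tree


class TestObservedOtus:
    def test_counts_nonzero(self):
        assert observed_otus([5, 0, 2, 0]) == 2
        assert observed_otus([0, 0, 0]) == 0

    def test_invariant_to_count_scaling(self):
        counts = np.array([5, 0, 2, 9])
        assert observed_otus(counts) == observed_otus(counts * 100)


class TestFaithPD:
    def test_hand_summed_subtree(self, toy_tree, toy_otu_ids):
        assert faith_pd([1, 0, 1], toy_tree, toy_otu_ids) == pytest.approx(4.5)

    def test_total_branch_length(self, toy_tree, toy_otu_ids):
        assert faith_pd([1, 1, 1], toy_tree, toy_otu_ids) == pytest.approx(6.5)

    def test_empty_sample_zero(self, toy_tree, toy_otu_ids):
        assert faith_pd([0, 0, 0], toy_tree, toy_otu_ids) == 0.0

    def test_missing_otu_reported(self, toy_tree):
        with pytest.raises(KeyError, match="ZZ"):
            faith_pd([1, 0, 1], toy_tree, ["A", "B", "ZZ"])

    def test_monotone_adding_otu(self, toy_tree, toy_otu_ids):
        for base in itertools.product([0, 1], repeat=3):
            pd0 = faith_pd(list(base), toy_tree, toy_otu_ids)
            for j in range(3):
                grown = list(base)
                grown[j] = 1
                assert faith_pd(grown, toy_tree, toy_otu_ids) >= pd0

    def test_presence_based(self, toy_tree, toy_otu_ids):
        assert faith_pd([1, 0, 7], toy_tree, toy_otu_ids) == faith_pd(
            [99, 0, 1], toy_tree, toy_otu_ids
        )

    def test_matches_skbio_on_random_trees(self):
        import skbio.diversity

        for seed in range(3):
            table, tree, newick = random_table_and_tree(seed)
            import io as _io

            import skbio as _skbio

            sk_tree = _skbio.TreeNode.read(_io.StringIO(newick))
            for row in table.counts:
                mine = faith_pd(row, tree, table.otu_ids)
                ref = skbio.diversity.alpha.faith_pd(
                    row, taxa=table.otu_ids, tree=sk_tree
                )
                assert mine == pytest.approx(ref, rel=1e-9)


class TestUniFrac:
    def test_identical_presence_zero(self, toy_tree, toy_otu_ids):
        assert unweighted_unifrac([1, 1, 0], [2, 5, 0], toy_tree, toy_otu_ids) == 0.0

    def test_disjoint_clades_distance_one(self, toy_tree, toy_otu_ids):
        assert unweighted_unifrac([1, 0, 0], [0, 0, 1], toy_tree, toy_otu_ids) == pytest.approx(1.0)

    def test_hand_branch_partition(self, toy_tree, toy_otu_ids):
        d = unweighted_unifrac([1, 1, 0], [1, 0, 0], toy_tree, toy_otu_ids)
        assert d == pytest.approx(2.0 / 3.5)

    def test_empty_sample_rejected(self, toy_tree, toy_otu_ids):
        with pytest.raises(ValueError):
            unweighted_unifrac([0, 0, 0], [1, 0, 0], toy_tree, toy_otu_ids)

    def test_matrix_symmetric_bounded(self):
        table, tree, _ = random_table_and_tree(1)
        dm = unifrac_matrix(table, tree)
        assert np.all(dm.data >= 0) and np.all(dm.data <= 1 + 1e-12)

    def test_matches_skbio(self):
        import io as _io

        import skbio
        from skbio.diversity import beta_diversity

        for seed in range(3):
            table, tree, newick = random_table_and_tree(seed)
            dm = unifrac_matrix(table, tree)
            ref = beta_diversity(
                "unweighted_unifrac",
                table.counts,
                ids=table.sample_ids,
                taxa=table.otu_ids,
                tree=skbio.TreeNode.read(_io.StringIO(newick)),
            )
            np.testing.assert_allclose(dm.data, ref.data, atol=1e-9)

    def test_triangle_inequality_on_random_trees(self):
        rng = np.random.default_rng(0)
        checked = 0
        for seed in range(5):
            table, tree, _ = random_table_and_tree(seed, n_samples=10, n_otus=16)
            dm = unifrac_matrix(table, tree).data
            n = dm.shape[0]
            for _ in range(200):
                i, j, k = rng.choice(n, 3, replace=False)
                assert dm[i, j] <= dm[i, k] + dm[k, j] + 1e-9
                checked += 1
        assert checked == 1000


class TestRarefaction:
    def test_depth_equal_total_identity(self):
        t = OtuTable(["s1"], ["a", "b"], np.array([[3, 7]]))
        r = rarefy(t, 10, seed=1)
        np.testing.assert_array_equal(r.counts, t.counts)

    def test_totals_equal_depth(self):
        table, _, _ = random_table_and_tree(2)
        depth = int(table.sample_totals.min())
        r = rarefy(table, depth, seed=3)
        assert np.all(r.counts.sum(axis=1) == depth)

    def test_deterministic_given_seed(self):
        table, _, _ = random_table_and_tree(2)
        r1 = rarefy(table, 20, seed=5)
        r2 = rarefy(table, 20, seed=5)
        np.testing.assert_array_equal(r1.counts, r2.counts)

    def test_hypergeometric_mean(self):
        t = OtuTable(["s1"], ["a", "b", "c"], np.array([[50, 30, 20]]))
        depth = 40
        rng_means = np.mean(
            [rarefy(t, depth, seed=s).counts[0] for s in range(1000)], axis=0
        )
        expected = depth * np.array([0.5, 0.3, 0.2])
        np.testing.assert_allclose(rng_means, expected, atol=0.5)

    def test_shallow_samples_dropped(self, caplog):
        t = OtuTable(["deep", "shallow"], ["a", "b"], np.array([[60, 60], [2, 1]]))
        r = rarefy(t, 50, seed=1)
        assert r.sample_ids == ["deep"]

    def test_unreachable_depth_rejected(self):
        t = OtuTable(["s1"], ["a"], np.array([[5]]))
        with pytest.raises(ValueError):
            rarefy(t, 50, seed=1)


class TestTaxonomyCollapse:
    TAX = {
        "o1": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Lachnospiraceae;g__Blautia",
        "o2": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Lachnospiraceae;g__",
        "o3": "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;f__Bacteroidaceae;g__Bacteroides",
    }

    def test_family_abundance_worked_example(self):
        t = OtuTable(["s1"], list(self.TAX), np.array([[30, 20, 50]]))
        fam = collapse_taxonomy(t, self.TAX, "family")
        assert fam.loc["s1", "Lachnospiraceae"] == pytest.approx(0.5)
        assert fam.loc["s1", "Bacteroidaceae"] == pytest.approx(0.5)

    def test_rows_sum_to_one(self):
        table, _, _ = random_table_and_tree(4)
        tax = {
            o: self.TAX[("o1", "o2", "o3")[i % 3]] for i, o in enumerate(table.otu_ids)
        }
        fam = collapse_taxonomy(table, tax, "family")
        np.testing.assert_allclose(fam.sum(axis=1), 1.0, atol=1e-9)

    def test_genus_other_convention(self):
        t = OtuTable(["s1"], list(self.TAX), np.array([[10, 10, 80]]))
        gen = collapse_taxonomy(t, self.TAX, "genus")
        assert gen.loc["s1", "Lachnospiraceae;Other"] == pytest.approx(0.1)

    def test_unknown_rank_rejected(self):
        t = OtuTable(["s1"], ["o1"], np.array([[5]]))
        with pytest.raises(ValueError):
            collapse_taxonomy(t, self.TAX, "species")

    def test_label_fallback_chain(self):
        assert taxon_label("k__Bacteria;p__Firmicutes", "genus") == "Firmicutes;Other"


class TestPCoA:
    def test_collinear_points(self):
        d = DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float),
        )
        res = pcoa(d)
        rec = res.coordinates
        for i in range(3):
            for j in range(3):
                assert np.linalg.norm(rec[i] - rec[j]) == pytest.approx(
                    d.data[i, j], abs=1e-9
                )
        assert res.eigenvalues[1] == pytest.approx(0.0, abs=1e-9)

    def test_all_zero_distances(self):
        d = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        res = pcoa(d)
        assert res.coordinates.size == 0 or np.allclose(res.coordinates, 0.0)

    def test_euclidean_embedding_recovered(self):
        rng = np.random.default_rng(6)
        pts = rng.standard_normal((7, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(7)], d))
        rec = res.coordinates
        d2 = np.linalg.norm(rec[:, None] - rec[None, :], axis=-1)
        np.testing.assert_allclose(d2, d, atol=1e-9)

    def test_asymmetric_rejected(self):
        m = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], m)

    def test_matches_skbio_eigenvalues(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa
        from skbio import DistanceMatrix as SkbioDM

        table, tree, _ = random_table_and_tree(3, n_samples=8)
        dm = unifrac_matrix(table, tree)
        mine = pcoa(dm)
        ref = skbio_pcoa(SkbioDM(dm.data, ids=dm.sample_ids))
        n_pos = (mine.eigenvalues > 1e-9).sum()
        np.testing.assert_allclose(
            mine.eigenvalues[:n_pos], ref.eigvals.to_numpy()[:n_pos], atol=1e-8
        )
        np.testing.assert_allclose(
            np.abs(mine.coordinates[:, 0]),
            np.abs(ref.samples.to_numpy()[:, 0]),
            atol=1e-8,
        )


class TestPermanova:
    @staticmethod
    def _euclidean_dm(pts, ids=None):
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        return DistanceMatrix(ids or [f"s{i}" for i in range(len(pts))], d)

    def test_separated_clusters_minimum_p(self):
        rng = np.random.default_rng(1)
        pts = np.vstack([rng.normal(0, 0.01, (5, 2)), rng.normal(50, 0.01, (5, 2))])
        dm = self._euclidean_dm(pts)
        f, p = permanova(dm, ["x"] * 5 + ["y"] * 5, n_perm=199, seed=2)
        assert p == pytest.approx(1 / 200)

    def test_statistic_matches_exhaustive_enumeration(self):
        """Observed pseudo-F and exact p agree with a full 6!-permutation oracle."""
        rng = np.random.default_rng(4)
        pts = rng.standard_normal((6, 2))
        labels = np.array(["x", "x", "x", "y", "y", "y"])
        dm = self._euclidean_dm(pts)
        f_obs, _ = permanova(dm, labels, n_perm=199, seed=0)

        d2 = dm.data**2

        def brute_f(lbls):
            n = 6
            ss_t = d2[np.triu_indices(n, 1)].sum() / n
            ss_w = 0.0
            for g in ("x", "y"):
                idx = np.flatnonzero(np.asarray(lbls) == g)
                ss_w += d2[np.ix_(idx, idx)][np.triu_indices(idx.size, 1)].sum() / idx.size
            return (ss_t - ss_w) / 1 / (ss_w / 4)

        assert f_obs == pytest.approx(brute_f(labels), rel=1e-12)
        # exact permutation p by full enumeration
        perms = [brute_f(p) for p in itertools.permutations(labels)]
        p_exact = np.mean([f >= f_obs - 1e-12 for f in perms])
        _, p_mc = permanova(dm, labels, n_perm=999, seed=3)
        assert p_mc == pytest.approx(p_exact, abs=0.05)

    def test_matches_skbio_statistic(self):
        import skbio
        from skbio.stats.distance import permanova as skbio_permanova

        table, tree, _ = random_table_and_tree(7, n_samples=10)
        dm = unifrac_matrix(table, tree)
        labels = ["g1"] * 5 + ["g2"] * 5
        f_mine, _ = permanova(dm, labels, n_perm=99, seed=1)
        ref = skbio_permanova(
            skbio.DistanceMatrix(dm.data, ids=dm.sample_ids), grouping=labels,
            permutations=99,
        )
        assert f_mine == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_small_group_rejected(self):
        dm = self._euclidean_dm(np.random.default_rng(0).standard_normal((4, 2)))
        with pytest.raises(ValueError):
            permanova(dm, ["x", "y", "y", "y"], n_perm=99, seed=0)
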