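"""RRHS sampling, p-distances, neighbor joining, and the majority-rule
consensus with mean branch lengths."""

import dendropy
import numpy as np
import pytest

from scerpop import phylo
from scerpop.containers import MISSING

from conftest import make_gm


class TestSampleHaplotype:
    def test_homozygous_and_missing_sites_copied(self):
        d = np.array([[0, 2], [2, 0], [MISSING, 1]], dtype=np.int8)
        hm = phylo.sample_haplotype(make_gm(d), seed=1)
        assert hm.alleles[0].tolist() == [0, 1]
        assert hm.alleles[1].tolist() == [1, 0]
        assert hm.alleles[2, 0] == MISSING
        assert hm.alleles[2, 1] in (0, 1)

    def test_same_seed_identical_matrix(self):
        d = np.ones((20, 4), dtype=np.int8)
        gm = make_gm(d)
        h1 = phylo.sample_haplotype(gm, seed=3, rep=7)
        h2 = phylo.sample_haplotype(gm, seed=3, rep=7)
        assert np.array_equal(h1.alleles, h2.alleles)
        h3 = phylo.sample_haplotype(gm, seed=3, rep=8)
        assert not np.array_equal(h1.alleles, h3.alleles)

    def test_het_resolution_is_fair(self):
        """Across many replicates a het site resolves to alt half the time
        (within 3 binomial SD)."""
        gm = make_gm(np.ones((1, 1), dtype=np.int8))
        n = 10_000
        alts = sum(
            int(phylo.sample_haplotype(gm, seed=0, rep=r).alleles[0, 0]) for r in range(n)
        )
        assert abs(alts / n - 0.5) <= 3 * np.sqrt(0.25 / n)


class TestPairwiseDistance:
    def test_identical_and_simple_fraction(self):
        alleles = np.zeros((10, 2), dtype=np.int8)
        hm = phylo.HaplotypeMatrix(make_gm(alleles).sites, ["a", "b"], alleles)
        assert phylo.pairwise_distance(hm)[0, 1] == 0.0
        alleles = np.zeros((10, 2), dtype=np.int8)
        alleles[0, 1] = 1
        hm = phylo.HaplotypeMatrix(make_gm(alleles).sites, ["a", "b"], alleles)
        assert phylo.pairwise_distance(hm)[0, 1] == pytest.approx(0.1)

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(9)
        alleles = rng.integers(0, 2, size=(40, 6)).astype(np.int8)
        alleles[rng.random(alleles.shape) < 0.15] = MISSING
        names = [f"t{i}" for i in range(6)]
        hm = phylo.HaplotypeMatrix(make_gm(alleles, isolates=names).sites, names, alleles)
        d = phylo.pairwise_distance(hm)
        for i in range(6):
            for j in range(6):
                shared = mism = 0
                for s in range(40):
                    a, b = alleles[s, i], alleles[s, j]
                    if a != MISSING and b != MISSING:
                        shared += 1
                        mism += a != b
                assert d[i, j] == pytest.approx(mism / shared)

    def test_zero_shared_sites_names_the_pair(self):
        alleles = np.array([[0, MISSING], [MISSING, 1]], dtype=np.int8)
        hm = phylo.HaplotypeMatrix(make_gm(alleles, isolates=["x", "y"]).sites, ["x", "y"], alleles)
        with pytest.raises(ValueError, match="'x' and 'y'"):
            phylo.pairwise_distance(hm)


class TestBuildTree:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
        tree = phylo.build_tree(d, ["A", "B", "C"])
        _, term = tree.splits()
        assert term["A"] == pytest.approx(0.05)
        assert term["B"] == pytest.approx(0.15)
        assert term["C"] == pytest.approx(0.25)

    def test_additive_four_taxon_matrix_recovered(self):
        # tree: (A:0.1, B:0.2)-0.05-(C:0.15, D:0.25)
        term_true = {"A": 0.1, "B": 0.2, "C": 0.15, "D": 0.25}
        d = np.array(
            [
                [0.00, 0.30, 0.30, 0.40],
                [0.30, 0.00, 0.40, 0.50],
                [0.30, 0.40, 0.00, 0.40],
                [0.40, 0.50, 0.40, 0.00],
            ]
        )
        tree = phylo.build_tree(d, ["A", "B", "C", "D"])
        internal, term = tree.splits()
        assert len(internal) == 1
        (split, length), = internal.items()
        assert split in (frozenset("CD"), frozenset("BD"))  # canonical side excludes A
        assert split == frozenset("CD")
        assert length == pytest.approx(0.05)
        for leaf, bl in term_true.items():
            assert term[leaf] == pytest.approx(bl)

    def test_identical_taxa_form_zero_length_cherry(self):
        d = np.array(
            [[0.0, 0.0, 0.3], [0.0, 0.0, 0.3], [0.3, 0.3, 0.0]]
        )
        tree = phylo.build_tree(d, ["A", "B", "C"])
        _, term = tree.splits()
        assert term["A"] == pytest.approx(0.0)
        assert term["B"] == pytest.approx(0.0)

    def test_newick_parses_with_dendropy(self):
        d = np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
        t = dendropy.Tree.get(data=phylo.build_tree(d, ["A", "B", "C"]).newick(), schema="newick")
        assert {leaf.taxon.label for leaf in t.leaf_node_iter()} == {"A", "B", "C"}


class TestRrhsConsensus:
    def hom_gm(self):
        rng = np.random.default_rng(10)
        d = (2 * rng.integers(0, 2, size=(60, 8))).astype(np.int8)
        return make_gm(d, isolates=[f"t{i}" for i in range(8)])

    def test_zero_het_all_supports_100_and_equals_single_tree(self):
        gm = self.hom_gm()
        ct = phylo.rrhs_consensus(gm, reps=20, seed=4)
        assert (ct.splits["support"] == 100.0).all()
        single, trees = phylo.rrhs_consensus(gm, reps=1, seed=4, return_replicates=True)
        internal, _ = trees[0].splits()
        assert dict(zip(single.splits["members"], single.splits["mean_length"])) == internal
        assert set(ct.splits["members"]) == set(internal)

    def test_consensus_matches_bruteforce_split_tabulation(self):
        """Independent oracle: parse each replicate newick with dendropy,
        tabulate bipartitions, and compare supports and mean lengths."""
        rng = np.random.default_rng(11)
        d = rng.integers(0, 3, size=(80, 7)).astype(np.int8)
        gm = make_gm(d, isolates=[f"t{i}" for i in range(7)])
        reps = 40
        ct, trees = phylo.rrhs_consensus(gm, reps=reps, seed=6, return_replicates=True)
        taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(7)])
        counts, lengths = {}, {}
        ref = min(gm.isolates)
        for tree in trees:
            dt = dendropy.Tree.get(data=tree.newick(), schema="newick", taxon_namespace=taxa)
            dt.encode_bipartitions()
            for edge in dt.preorder_edge_iter():
                if edge.head_node is dt.seed_node:
                    continue
                members = frozenset(
                    leaf.taxon.label for leaf in edge.head_node.leaf_iter()
                )
                if len(members) in (1, len(gm.isolates) - 1):
                    continue
                if ref in members:
                    members = frozenset(gm.isolates) - members
                counts[members] = counts.get(members, 0) + 1
                lengths.setdefault(members, []).append(edge.length or 0.0)
        want = {s: c for s, c in counts.items() if c > reps / 2}
        got = dict(zip(ct.splits["members"], ct.splits["support"]))
        assert got == {s: 100.0 * c / reps for s, c in want.items()}
        got_len = dict(zip(ct.splits["members"], ct.splits["mean_length"]))
        for s in want:
            assert got_len[s] == pytest.approx(float(np.mean(lengths[s])))

    def test_support_invariant_to_isolate_order(self):
        rng = np.random.default_rng(12)
        d = rng.integers(0, 3, size=(60, 6)).astype(np.int8)
        names = [f"t{i}" for i in range(6)]
        gm = make_gm(d, isolates=names)
        perm = rng.permutation(6)
        gm_perm = make_gm(d[:, perm], isolates=[names[k] for k in perm])
        c1 = phylo.rrhs_consensus(gm, reps=15, seed=9)
        c2 = phylo.rrhs_consensus(gm_perm, reps=15, seed=9)
        s1 = dict(zip(c1.splits["members"], c1.splits["support"]))
        s2 = dict(zip(c2.splits["members"], c2.splits["support"]))
        assert s1 == s2

    def test_planted_groups_monophyletic(self, cohort):
        gm, pm, _ = cohort
        ct = phylo.rrhs_consensus(gm, reps=30, seed=2)
        for grp in pm.groups:
            assert ct.support_for(pm.members("group", grp)) >= 90.0

    def test_no_minority_split_retained(self):
        rng = np.random.default_rng(13)
        d = rng.integers(0, 3, size=(30, 6)).astype(np.int8)
        gm = make_gm(d, isolates=[f"t{i}" for i in range(6)])
        ct = phylo.rrhs_consensus(gm, reps=21, seed=5)
        assert (ct.splits["support"] > 50.0).all()
        assert sorted(ct.leaves) == sorted(gm.isolates)

    def test_reroot_on_outgroup(self):
        gm = self.hom_gm()
        ct = phylo.rrhs_consensus(gm, reps=5, seed=1)
        nwk = ct.rerooted_newick("t3")
        t = dendropy.Tree.get(data=nwk, schema="newick")
        assert {l.taxon.label for l in t.leaf_node_iter()} == set(gm.isolates)
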