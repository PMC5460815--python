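"""p-distance, neighbor joining, bootstrap support, Newick round-trips."""

import dendropy
import numpy as np
import pytest

from dwdfam import (
    AlignedSet,
    generate_aligned_family,
    midpoint_root,
    nj_tree,
    p_distance,
    resample_support,
)
from dwdfam.errors import DwdfamError, UndefinedDistanceError
from dwdfam.phylogeny import cut_clades

from conftest import random_additive_tree


class TestPDistance:
    def test_one_difference_in_four_sites(self):
        dm = p_distance(AlignedSet(["a", "b"], ["AAAA", "AAAT"]))
        assert dm[0, 1] == pytest.approx(0.25)

    def test_identical_rows_have_zero_distance(self):
        dm = p_distance(AlignedSet(["a", "b"], ["WDIR", "WDIR"]))
        assert dm[0, 1] == 0.0

    def test_pairwise_deletion_excludes_gap_columns(self):
        # hand count: column 3 excluded, 0 differences / 3 compared sites
        dm = p_distance(AlignedSet(["a", "b"], ["AA-A", "AATA"]))
        assert dm[0, 1] == 0.0

    def test_complete_deletion_drops_columns_for_all_pairs(self):
        aligned = AlignedSet(["a", "b", "c"], ["AA-A", "AATA", "ATTA"])
        pair = p_distance(aligned, gap_policy="pairwise-delete")
        comp = p_distance(aligned, gap_policy="complete-delete")
        # b vs c differ at column 2 only; pairwise compares 4 sites, complete 3
        assert pair[1, 2] == pytest.approx(1 / 4)
        assert comp[1, 2] == pytest.approx(1 / 3)

    def test_all_gap_pair_is_undefined(self):
        with pytest.raises(UndefinedDistanceError) as err:
            p_distance(AlignedSet(["a", "b"], ["A---", "--TT"]))
        assert err.value.pair == ("a", "b")

    def test_bounds_and_symmetry(self):
        ids, rows = generate_aligned_family(n_taxa=10, n_columns=80, seed=2)
        dm = p_distance(AlignedSet(ids, rows))
        assert np.allclose(dm, dm.T)
        assert (dm >= 0).all() and (dm <= 1).all()
        assert np.diagonal(dm).sum() == 0


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
        tree = nj_tree(dm, ["a", "b", "c"])
        lengths = {child.label: length for child, length in tree.root.children}
        assert lengths["a"] == pytest.approx((0.4 + 0.6 - 0.8) / 2)
        assert lengths["b"] == pytest.approx((0.4 + 0.8 - 0.6) / 2)
        assert lengths["c"] == pytest.approx((0.6 + 0.8 - 0.4) / 2)

    def test_additive_matrices_recover_generating_topology(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            n = int(rng.integers(5, 9))
            dm, expected = random_additive_tree(n, rng)
            tree = nj_tree(dm, [f"L{k:02d}" for k in range(n)])
            assert tree.bipartitions() == expected

    def test_taxon_order_does_not_change_topology(self):
        rng = np.random.default_rng(9)
        dm, _ = random_additive_tree(7, rng)
        ids = [f"L{k:02d}" for k in range(7)]
        perm = rng.permutation(7)
        tree1 = nj_tree(dm, ids)
        tree2 = nj_tree(dm[np.ix_(perm, perm)], [ids[k] for k in perm])
        assert tree1.bipartitions() == tree2.bipartitions()

    def test_branch_lengths_recovered_on_additive_input(self):
        rng = np.random.default_rng(4)
        dm, _ = random_additive_tree(6, rng)
        tree = nj_tree(dm, [f"L{k:02d}" for k in range(6)])
        assert tree.clamped_deficit == 0.0
        # leaf-to-leaf path lengths in the tree must reproduce the matrix
        dt = dendropy.Tree.get(data=tree.newick(), schema="newick")
        pdm = dt.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in dt.taxon_namespace}
        for i in range(6):
            for j in range(i + 1, 6):
                got = pdm.distance(taxa[f"L{i:02d}"], taxa[f"L{j:02d}"])
                assert got == pytest.approx(dm[i, j], abs=1e-9)

    def test_negative_branch_lengths_clamped_and_logged(self):
        dm = np.array(
            [[0, 0.1, 0.5, 0.5], [0.1, 0, 0.5, 0.5],
             [0.5, 0.5, 0, 0.02], [0.5, 0.5, 0.02, 0]]
        )
        tree = nj_tree(dm, list("abcd"))
        assert tree.clamped_deficit >= 0.0
        text = tree.newick()
        assert "-" not in text.replace("e-", "")  # no negative lengths serialized

    def test_invalid_matrices_rejected(self):
        with pytest.raises(DwdfamError):
            nj_tree(np.zeros((2, 2)), ["a", "b"])
        bad = np.array([[0, 1.0, 1], [2, 0, 1], [1, 1, 0.0]])
        with pytest.raises(DwdfamError):
            nj_tree(bad, list("abc"))

    def test_newick_round_trip_is_idempotent(self):
        ids, rows = generate_aligned_family(n_taxa=9, n_columns=120, seed=6)
        tree = nj_tree(p_distance(AlignedSet(ids, rows)), ids)
        once = dendropy.Tree.get(data=tree.newick(), schema="newick").as_string(
            schema="newick"
        )
        twice = dendropy.Tree.get(data=once, schema="newick").as_string(
            schema="newick"
        )
        assert once == twice


class TestBootstrap:
    @staticmethod
    def two_block_alignment():
        # two clusters of identical sequences; every column supports the split
        rows = ["AAAAAAAAAA"] * 3 + ["TTTTTTTTTT"] * 3
        # add within-block variation so distances are finite and distinct
        rows = [r[:k] + "C" + r[k + 1 :] for k, r in enumerate(rows)]
        return AlignedSet([f"s{i}" for i in range(6)], rows)

    def test_fully_supported_split_scores_100(self):
        aligned = self.two_block_alignment()
        _, supports = resample_support(aligned, replicates=100, seed=0)
        split = frozenset({"s3", "s4", "s5"})
        assert supports[split] == 100.0

    def test_single_replicate_gives_all_or_nothing(self):
        ids, rows = generate_aligned_family(n_taxa=8, n_columns=100, seed=3)
        _, supports = resample_support(AlignedSet(ids, rows), replicates=1, seed=5)
        assert set(supports.values()) <= {0.0, 100.0}

    def test_fixed_seed_reproducible(self):
        ids, rows = generate_aligned_family(n_taxa=8, n_columns=100, seed=3)
        aligned = AlignedSet(ids, rows)
        _, s1 = resample_support(aligned, replicates=60, seed=42)
        _, s2 = resample_support(aligned, replicates=60, seed=42)
        assert s1 == s2

    def test_replicates_must_be_positive(self):
        ids, rows = generate_aligned_family(n_taxa=5, n_columns=50, seed=1)
        with pytest.raises(DwdfamError):
            resample_support(AlignedSet(ids, rows), replicates=0)


class TestDisplayHelpers:
    def test_midpoint_rooting_preserves_leaves(self):
        ids, rows = generate_aligned_family(n_taxa=7, n_columns=90, seed=8)
        tree = nj_tree(p_distance(AlignedSet(ids, rows)), ids)
        rooted = dendropy.Tree.get(data=midpoint_root(tree.newick()), schema="newick")
        assert sorted(l.taxon.label for l in rooted.leaf_node_iter()) == sorted(ids)

    def test_cut_clades_partitions_leaves(self):
        ids, rows = generate_aligned_family(n_taxa=10, n_columns=120, seed=12)
        tree = nj_tree(p_distance(AlignedSet(ids, rows)), ids)
        groups = cut_clades(tree.newick(), k=3)
        flat = sorted(x for g in groups for x in g)
        assert flat == sorted(ids) and len(groups) == 3
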