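"""Alignment, trimming, concatenation, distances, NJ and rooting."""

import math

import dendropy
import numpy as np
import pytest

from conftest import random_peptide
from yrscan.phylo import (concat_partitions, distance_matrix, neighbor_joining,
                          progressive_align, root_with_outgroup, tree_to_newick,
                          trim_columns)
from yrscan.seqio import Alignment


class TestProgressiveAlign:
    def test_identical_pair_gapless(self):
        a = progressive_align(["MKLVWAGH", "MKLVWAGH"])
        assert a.rows == ["MKLVWAGH", "MKLVWAGH"]

    def test_single_deletion_gap_opposite_d(self):
        # exhaustive check: the only optimal global alignment of ACDEFG vs
        # ACEFG under BLOSUM62 with affine gaps places one gap opposite 'D'
        a = progressive_align(["ACDEFG", "ACEFG"])
        assert a.rows[0] == "ACDEFG"
        assert a.rows[1] == "AC-EFG"

    def test_projection_identity_bound(self, rng):
        """Pairwise projections of the MSA never beat the optimal pairwise
        alignment in match count (sanity bound from the pairwise oracle)."""
        import edlib

        base = random_peptide(rng, 60)
        seqs = [base]
        for _ in range(4):
            s = list(base)
            for i in rng.choice(60, size=8, replace=False):
                s[int(i)] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(0, 20)]
            seqs.append("".join(s))
        msa = progressive_align(seqs)
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                proj_matches = sum(
                    1 for a, b in zip(msa.rows[i], msa.rows[j])
                    if a == b and a != "-"
                )
                d = edlib.align(seqs[i], seqs[j], mode="NW")["editDistance"]
                max_matches = max(len(seqs[i]), len(seqs[j])) - d
                assert proj_matches <= max_matches + 8  # loose sanity bound

    def test_requires_two(self):
        with pytest.raises(ValueError):
            progressive_align(["MKLV"])

    def test_deterministic(self, rng):
        seqs = [random_peptide(rng, 40) for _ in range(5)]
        a = progressive_align(seqs)
        b = progressive_align(seqs)
        assert a.rows == b.rows


class TestTrimColumns:
    def test_gapless_unchanged(self):
        a = Alignment(ids=["a", "b"], rows=["ACDEF", "ACDEF"])
        assert trim_columns(a).rows == a.rows

    def test_half_gap_column_removed_at_strict_threshold(self):
        a = Alignment(ids=["a", "b"], rows=["A-CDE", "AXCDE"])
        t = trim_columns(a, max_gap_fraction=0.05)
        assert t.rows == ["ACDE", "ACDE"]

    def test_threshold_one_is_identity(self):
        a = Alignment(ids=["a", "b"], rows=["A--DE", "AXCDE"])
        assert trim_columns(a, max_gap_fraction=1.0).rows == a.rows

    def test_all_removed_is_error(self):
        a = Alignment(ids=["a", "b"], rows=["A-", "-A"])
        with pytest.raises(ValueError):
            trim_columns(a, max_gap_fraction=0.0)

    def test_never_increases_columns_and_partitions_recomputed(self):
        a = Alignment(ids=["a", "b"], rows=["AC-DEF", "ACXD-F"],
                      partitions={"RT": (0, 3), "RH": (3, 6)})
        t = trim_columns(a, max_gap_fraction=0.05)
        assert t.n_cols == 4
        assert t.partitions == {"RT": (0, 2), "RH": (2, 4)}


class TestConcatPartitions:
    def test_widths_and_partition_map(self):
        parts = {
            "RT": Alignment(ids=["a", "b"], rows=["AAA", "AAA"]),
            "RH": Alignment(ids=["a", "b"], rows=["CCCC", "CCCC"]),
            "YR": Alignment(ids=["a", "b"], rows=["DDDDD", "DDDDD"]),
        }
        c = concat_partitions(parts)
        assert c.n_cols == 12
        assert c.partitions == {"RH": (0, 4), "RT": (4, 7), "YR": (7, 12)}

    def test_missing_domain_padded_with_gaps(self):
        parts = {
            "RT": Alignment(ids=["a", "b"], rows=["AAA", "AAA"]),
            "YR": Alignment(ids=["a"], rows=["DDDD"]),
        }
        c = concat_partitions(parts)
        row_b = c.rows[c.ids.index("b")]
        assert row_b.endswith("----")

    def test_single_partition_identity(self):
        a = Alignment(ids=["x", "y"], rows=["MKL", "MKV"])
        c = concat_partitions({"RT": a})
        assert c.rows == a.rows


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        a = Alignment(ids=["a", "b"], rows=["ACDEF", "ACDEF"])
        assert distance_matrix(a)[0, 1] == 0.0

    def test_p_distance_and_poisson(self):
        a = Alignment(ids=["a", "b"], rows=["AAAAAAAAAA", "AAAAAAAACC"])
        assert distance_matrix(a, "p-distance")[0, 1] == pytest.approx(0.2)
        assert distance_matrix(a, "poisson")[0, 1] == pytest.approx(-math.log(0.8), abs=1e-9)

    def test_saturated_pair_poisson_error(self):
        a = Alignment(ids=["a", "b"], rows=["AAAA", "CCCC"])
        with pytest.raises(ValueError, match="p=1"):
            distance_matrix(a, "poisson")

    def test_zero_overlap_error(self):
        a = Alignment(ids=["a", "b"], rows=["AA--", "--CC"])
        with pytest.raises(ValueError, match="no ungapped"):
            distance_matrix(a)

    def test_symmetric_nonnegative(self, rng):
        rows = ["".join("ACDE"[i] for i in rng.integers(0, 4, 30)) for _ in range(5)]
        d = distance_matrix(Alignment(ids=list("abcde"), rows=rows))
        assert np.allclose(d, d.T) and (d >= 0).all() and np.allclose(np.diag(d), 0)


def _tree_distances(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    out = {}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            out[(a.label, b.label)] = pdm.distance(a, b)
    return out


def _random_additive_matrix(rng, n):
    """Random binary tree with positive branch lengths -> (ids, distance matrix)."""
    ids = [f"t{i}" for i in range(n)]
    ns = dendropy.TaxonNamespace(ids)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n, taxon_namespace=ns,
        rng=__import__("random").Random(int(rng.integers(0, 2**31))))
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = float(rng.uniform(0.05, 1.0))
    pdm = tree.phylogenetic_distance_matrix()
    d = np.zeros((n, n))
    for i, a in enumerate(ns):
        for j, b in enumerate(ns):
            if i < j:
                d[i, j] = d[j, i] = pdm.distance(a, b)
    return ids, d, tree


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        ids = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        tree = neighbor_joining(d, ids)
        got = _tree_distances(tree)
        assert got[("A", "B")] == pytest.approx(3)
        assert got[("A", "C")] == pytest.approx(5)
        assert got[("B", "D")] == pytest.approx(7)
        assert got[("C", "D")] == pytest.approx(7)

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        tree = neighbor_joining(d, ["a", "b", "c"])
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx((4 + 6 - 8) / 2)
        assert lengths["b"] == pytest.approx((4 + 8 - 6) / 2)
        assert lengths["c"] == pytest.approx((6 + 8 - 4) / 2)

    def test_additive_matrices_recovered_exactly(self, rng):
        for _ in range(100):
            n = 10
            ids, d, true_tree = _random_additive_matrix(rng, n)
            tree = neighbor_joining(d, ids)
            got = _tree_distances(tree)
            want = _tree_distances(true_tree)
            for key, value in want.items():
                assert got[key] == pytest.approx(value, abs=1e-8)

    def test_matches_scikit_bio_topology(self, rng):
        """Independent cross-check against the scikit-bio NJ implementation."""
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj

        for _ in range(5):
            ids, d, _ = _random_additive_matrix(rng, 8)
            ours = neighbor_joining(d, ids)
            theirs = nj(DistanceMatrix(d, ids))
            got = _tree_distances(ours)
            for (a, b), value in got.items():
                assert theirs.find(a).distance(theirs.find(b)) == pytest.approx(value, abs=1e-6)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(np.array([[0, 1], [1, 0]]), ["a", "b"])
        with pytest.raises(ValueError):
            neighbor_joining(np.array([[0, 1, 2], [9, 0, 3], [2, 3, 0]]), list("abc"))

    def test_negative_branch_clamped(self, caplog):
        # a strongly non-additive matrix can push NJ lengths negative
        d = np.array([
            [0, 1, 10, 10],
            [1, 0, 10, 10],
            [10, 10, 0, 1],
            [10, 10, 1, 0],
        ], dtype=float)
        with caplog.at_level("WARNING", logger="yrscan"):
            tree = neighbor_joining(d, list("abcd"))
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0


class TestRooting:
    def _tree(self):
        d = np.array([
            [0, 2, 8, 8],
            [2, 0, 8, 8],
            [8, 8, 0, 2],
            [8, 8, 2, 0],
        ], dtype=float)
        return neighbor_joining(d, ["in1", "in2", "og1", "og2"])

    def test_outgroup_rooting(self):
        rooted = root_with_outgroup(self._tree(), ["og1", "og2"])
        children = rooted.seed_node.child_nodes()
        assert len(children) == 2
        sides = [sorted(lf.taxon.label for lf in c.leaf_iter()) for c in children]
        assert ["in1", "in2"] in sides and ["og1", "og2"] in sides

    def test_scattered_outgroup_rejected(self):
        with pytest.raises(ValueError, match="monophyletic"):
            root_with_outgroup(self._tree(), ["in1", "og1"])

    def test_unknown_leaf_rejected(self):
        with pytest.raises(ValueError, match="not in tree"):
            root_with_outgroup(self._tree(), ["nope"])

    def test_root_unroot_preserves_distances(self):
        t = self._tree()
        before = _tree_distances(t)
        rooted = root_with_outgroup(t, ["og1", "og2"])
        after = _tree_distances(rooted)
        for key, value in before.items():
            assert after[key] == pytest.approx(value, abs=1e-9)

    def test_newick_of_rooted_tree_parses(self, tmp_path):
        rooted = root_with_outgroup(self._tree(), ["og1", "og2"])
        text = tree_to_newick(rooted)
        back = dendropy.Tree.get(data=text, schema="newick")
        assert {lf.taxon.label for lf in back.leaf_node_iter()} == {"in1", "in2", "og1", "og2"}
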