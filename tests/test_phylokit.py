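"""Alignment, Jukes-Cantor distances, Neighbor-Joining and tree I/O."""

import numpy as np
import pytest
from skbio import DistanceMatrix

from cpfkit import phylokit as pk
from cpfkit.seqio import ProteinRecord

from conftest import (
    all_sequences,
    bipartitions,
    enumerate_best_score,
    random_unrooted_tree,
)


def _rec(residues, id="s"):
    return ProteinRecord(id=id, residues=residues)


class TestGlobalAlign:
    def test_identity_alignment_scores_diagonal(self, pam100):
        aln = pk.global_align(_rec("ACDE", "a"), _rec("ACDE", "b"))
        assert aln.rows == ("ACDE", "ACDE")
        assert aln.score == sum(pam100[c, c] for c in "ACDE")

    def test_single_gap_case(self, pam100):
        aln = pk.global_align(_rec("ACDE", "a"), _rec("ACE", "b"))
        expected = pam100["A", "A"] + pam100["C", "C"] + pam100["E", "E"] - 10
        assert aln.score == expected
        assert sorted(aln.rows) == ["AC-E", "ACDE"]

    def test_gap_extension_costs_one(self, pam100):
        aln = pk.global_align(_rec("ACDEF", "a"), _rec("ACF", "b"))
        expected = pam100["A", "A"] + pam100["C", "C"] + pam100["F", "F"] - 11
        assert aln.score == expected

    def test_score_symmetric(self, pam100):
        rng = np.random.default_rng(3)
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(20):
            a = "".join(letters[rng.integers(0, 20, 8)])
            b = "".join(letters[rng.integers(0, 20, 8)])
            sa = pk.global_align(_rec(a, "a"), _rec(b, "b")).score
            sb = pk.global_align(_rec(b, "b"), _rec(a, "a")).score
            assert sa == sb

    def test_rows_ungap_to_inputs(self):
        aln = pk.global_align(_rec("MKWVTFISLL", "a"), _rec("MKWVISLL", "b"))
        assert aln.rows[0].replace("-", "") == "MKWVTFISLL"
        assert aln.rows[1].replace("-", "") == "MKWVISLL"

    def test_matches_enumeration_oracle_short(self, pam100):
        # exhaustive over all pairs of length <= 2 on a 4-letter sub-alphabet
        seqs = list(all_sequences("ACDE", 2))
        for a in seqs:
            for b in seqs:
                got = pk.global_align(_rec(a, "a"), _rec(b, "b")).score
                want = enumerate_best_score(a, b, pam100, 10.0, 1.0)
                assert got == pytest.approx(want)

    def test_unknown_matrix_is_error(self):
        with pytest.raises(ValueError, match="unknown"):
            pk.global_align(_rec("ACDE", "a"), _rec("ACD", "b"), matrix_name="NOPE42")


class TestJukesCantor:
    def test_zero_distance_for_identical_rows(self):
        aln = pk.PairwiseAlignment(ids=("a", "b"), rows=("ACDE", "ACDE"), score=0)
        assert pk.jc_distance(aln) == 0.0

    def test_closed_form_at_p_ten_percent(self):
        # d = -0.95 ln(1 - 0.10/0.95), evaluated independently
        assert pk.jc_correct(0.10) == pytest.approx(0.1056643533547131, abs=1e-12)

    def test_saturated_p_capped(self):
        assert pk.jc_correct(0.95) == pk.D_CAP

    def test_gap_columns_excluded_from_p(self):
        aln = pk.PairwiseAlignment(ids=("a", "b"), rows=("ACD-E", "ACDW-"), score=0)
        # comparable columns: 3 (positions 0-2), all matches
        assert pk.p_distance(aln) == 0.0

    def test_no_comparable_columns_is_error(self):
        aln = pk.PairwiseAlignment(ids=("a", "b"), rows=("A-", "-C"), score=0)
        with pytest.raises(ValueError):
            pk.p_distance(aln)

    def test_strictly_increasing_and_dominates_p(self):
        grid = [i / 100 for i in range(95)]
        values = [pk.jc_correct(p) for p in grid]
        assert all(b > a for a, b in zip(values, values[1:]))
        assert all(d >= p for d, p in zip(values, grid))


class TestNeighborJoining:
    def test_quartet_recovers_generating_tree(self):
        dm = DistanceMatrix(
            np.array(
                [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], dtype=float
            ),
            list("ABCD"),
        )
        tree = pk.nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 2.0, "B": 3.0, "C": 4.0, "D": 5.0}
        # split AB|CD with internal edge length 1
        assert bipartitions(tree) == {
            frozenset([frozenset("AB"), frozenset("CD")])
        }
        paths = pk.tree_distance_matrix(tree)
        np.testing.assert_allclose(paths.filter(list("ABCD")).data, dm.data, atol=1e-9)

    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float), list("ABC"))
        tree = pk.nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_equidistant_tie_break_joins_first_pair(self):
        dm = DistanceMatrix(np.ones((4, 4)) - np.eye(4), list("ABCD"))
        tree = pk.nj_tree(dm)
        # lexicographic tie-break joins (A, B) first
        parent_a = next(t for t in tree.tips() if t.name == "A").parent
        assert {t.name for t in parent_a.children if t.is_tip()} >= {"A", "B"}

    def test_fewer_than_three_labels_is_error(self):
        dm = DistanceMatrix(np.array([[0, 1], [1, 0]], float), list("AB"))
        with pytest.raises(ValueError):
            pk.nj_tree(dm)

    def test_additive_matrices_recovered_exactly(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            n = int(rng.integers(4, 9))
            source = random_unrooted_tree(rng, n)
            dm = source.tip_tip_distances()
            tree = pk.nj_tree(DistanceMatrix(dm.data, list(dm.ids)))
            assert bipartitions(tree) == bipartitions(source)
            paths = pk.tree_distance_matrix(tree).filter(list(dm.ids))
            np.testing.assert_allclose(paths.data, dm.data, atol=1e-9)

    def test_agrees_with_skbio_reference_nj(self):
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(5)
        source = random_unrooted_tree(rng, 7)
        data = source.tip_tip_distances()
        # perturb slightly so the matrix is non-additive but tie-free
        noise = rng.uniform(0, 0.01, size=data.data.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        dm = DistanceMatrix(data.data + noise, list(data.ids))
        mine = pk.nj_tree(dm)
        theirs = skbio_nj(dm)
        assert bipartitions(mine) == bipartitions(theirs)

    def test_negative_branch_lengths_clamped(self):
        dm = DistanceMatrix(
            np.array([[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 2], [1, 1, 2, 0]], float),
            list("ABCD"),
        )
        tree = pk.nj_tree(dm)
        for node in tree.traverse(include_self=False):
            assert node.length >= 0


class TestNewick:
    def test_roundtrip_preserves_topology_and_lengths(self, tmp_path):
        rng = np.random.default_rng(9)
        tree = random_unrooted_tree(rng, 6)
        path = tmp_path / "tree.nwk"
        pk.write_newick(tree, path)
        back = pk.read_newick(path)
        assert bipartitions(back) == bipartitions(tree)
        a = tree.tip_tip_distances()
        b = back.tip_tip_distances().filter(list(a.ids))
        np.testing.assert_allclose(a.data, b.data, atol=1e-9)

    def test_quoted_labels_survive(self, tmp_path):
        dm = DistanceMatrix(
            np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float),
            ["Danio rerio", "Mus musculus", "E coli"],
        )
        tree = pk.nj_tree(dm)
        path = tmp_path / "tree.nwk"
        pk.write_newick(tree, path)
        back = pk.read_newick(path)
        assert {t.name for t in back.tips()} == {"Danio rerio", "Mus musculus", "E coli"}


class TestPhylipMatrix:
    def test_roundtrip(self, tmp_path):
        dm = DistanceMatrix(np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float), list("ABC"))
        path = tmp_path / "dm.phy"
        pk.write_phylip_dm(dm, path)
        back = pk.read_phylip_dm(path)
        assert list(back.ids) == list("ABC")
        np.testing.assert_allclose(back.data, dm.data, atol=1e-9)


class TestNearestReference:
    def test_exact_panel_member_ranks_first(self):
        refs = [_rec("MKWVTFISLLFLFSSAYS", "r1"), _rec("GATTACAKLMNPQRSTVW", "r2")]
        ranked = pk.nearest_reference(_rec("MKWVTFISLLFLFSSAYS", "q"), refs)
        assert ranked[0] == ("r1", 0.0)

    def test_ranking_invariant_under_panel_order(self):
        refs = [_rec("MKWVTFISLLFLFSSAYS", "r1"), _rec("GATTACAKLMNPQRSTVW", "r2")]
        q = _rec("MKWVTFISLLFLFSSAYT", "q")
        assert pk.nearest_reference(q, refs) == pk.nearest_reference(q, refs[::-1])

    def test_mutated_query_finds_its_scaffold(self):
        from cpfkit.synthetic_data import make_scaffold
        from cpfkit.util import stream_rng

        rng = stream_rng(4, "test")
        refs = [
            _rec(make_scaffold(120, [], rng), f"r{i}") for i in range(3)
        ]
        # mutate 5% of reference r1
        base = list(refs[1].residues)
        for pos in rng.choice(len(base), size=6, replace=False):
            base[int(pos)] = "W" if base[int(pos)] != "W" else "Y"
        ranked = pk.nearest_reference(_rec("".join(base), "q"), refs)
        assert ranked[0][0] == "r1"


class TestCenterStar:
    def test_identical_sequences_stack_without_gaps(self):
        records = [_rec("MKWVTFIS", f"s{i}") for i in range(3)]
        rows = pk.center_star_rows(records)
        assert rows == ["MKWVTFIS"] * 3

    def test_rows_equal_length_and_ungap_to_inputs(self):
        records = [
            _rec("MKWVTFISLL", "a"),
            _rec("MKWVFISLL", "b"),
            _rec("MKWVTFISLLQQ", "c"),
        ]
        rows = pk.center_star_rows(records)
        assert len({len(r) for r in rows}) == 1
        for rec, row in zip(records, rows):
            assert row.replace("-", "") == rec.residues
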