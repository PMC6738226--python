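"""Alignment filtering, distances, NJ, bipartitions and consensus."""

import math

import dendropy
import numpy as np
import pytest

from halopop import treescan
from halopop.treescan import GeneAlignment, SaturatedDistanceError
from halopop.variants import DistanceMatrix

from conftest import random_binary_tree_newick


def _aln(seqs, gene_id="g"):
    return GeneAlignment(
        gene_id, [f"s{i}" for i in range(len(seqs))], list(seqs)
    )


def _parse(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


class TestFilterAlignment:
    def _make(self, length, n_diff):
        a = "A" * length
        b = "G" * n_diff + "A" * (length - n_diff)
        return _aln([a, b])

    def test_length_boundary_is_strict(self):
        aln = self._make(200, 20)
        assert aln.mean_pairwise_diff == 20
        assert not treescan.filter_alignment(aln)

    def test_mean_diff_boundary_is_strict(self):
        aln = self._make(300, 15)
        assert aln.mean_pairwise_diff == 15.0
        assert not treescan.filter_alignment(aln)

    def test_passing_alignment(self):
        # mean diff 15.5 over pairs: 2 seqs at 16 and 15 diffs vs a third
        a = "A" * 300
        b = "G" * 16 + "A" * 284
        aln = _aln([a, b])
        assert aln.mean_pairwise_diff == 16
        assert treescan.filter_alignment(aln)

    def test_commutes_with_sample_reordering(self):
        rng = np.random.default_rng(0)
        seqs = [
            "".join(rng.choice(list("ACGT"), 250)) for _ in range(5)
        ]
        a1 = _aln(seqs)
        a2 = _aln(seqs[::-1])
        assert treescan.filter_alignment(a1) == treescan.filter_alignment(a2)
        assert a1.mean_pairwise_diff == pytest.approx(a2.mean_pairwise_diff)


class TestDistanceMatrix:
    def test_identical_sequences_zero_under_all_models(self):
        aln = _aln(["ACGTACGT" * 10] * 3)
        for model in ("raw", "JC69", "K2P"):
            d = treescan.distance_matrix(aln, model)
            assert np.allclose(d.d, 0)

    def test_closed_form_raw_and_jc69(self):
        a = "A" * 100
        b = "G" * 10 + "A" * 90
        aln = _aln([a, b, a])
        raw = treescan.distance_matrix(aln, "raw")
        assert raw.d[0, 1] == pytest.approx(0.10)
        jc = treescan.distance_matrix(aln, "JC69")
        assert jc.d[0, 1] == pytest.approx(-0.75 * math.log(1 - 0.4 / 3), abs=1e-10)

    def test_k2p_transitions_only_closed_form(self):
        # A->G is a transition: P=0.1, Q=0
        a = "A" * 100
        b = "G" * 10 + "A" * 90
        aln = _aln([a, b, a])
        k2p = treescan.distance_matrix(aln, "K2P")
        expected = -0.5 * math.log(1 - 0.2) - 0.25 * math.log(1.0)
        assert k2p.d[0, 1] == pytest.approx(expected, abs=1e-10)

    def test_gap_and_n_columns_excluded_pairwise(self):
        aln = _aln(["ACGTAC", "ACGTNC", "AC-TAC"])
        raw = treescan.distance_matrix(aln, "raw")
        assert np.allclose(raw.d, 0)
        assert raw.n_compared[0, 1] == 5
        assert raw.n_compared[0, 2] == 5

    def test_saturation_raises_naming_pair(self):
        a = "A" * 100
        b = "C" * 80 + "A" * 20
        aln = _aln([a, b, a])
        with pytest.raises(SaturatedDistanceError, match="s1"):
            treescan.distance_matrix(aln, "JC69")


def _dm(ids, m):
    m = np.asarray(m, dtype=float)
    return DistanceMatrix(ids, m, np.full_like(m, 1))


class TestNJTree:
    def test_recovers_additive_four_taxon_tree(self):
        # tree ((A:1,B:2):1,(C:3,D:4):1) -> additive distances
        d = _dm(
            ["A", "B", "C", "D"],
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
        )
        tree = treescan.nj_tree(d)
        splits = treescan.bipartitions(tree)
        assert splits == {frozenset({"C", "D"})}

    def test_three_taxon_closed_form(self):
        d = _dm(["a", "b", "c"], [[0, 4, 6], [4, 0, 8], [6, 8, 0]])
        tree = treescan.nj_tree(d)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths == {"a": 1.0, "b": 3.0, "c": 5.0}

    def test_tie_break_is_deterministic(self):
        # ultrametric with symmetric ties
        d = _dm(
            ["a", "b", "c", "d"],
            [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]],
        )
        t1 = treescan.nj_tree(d).as_string(schema="newick")
        t2 = treescan.nj_tree(d).as_string(schema="newick")
        assert t1 == t2

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            treescan.nj_tree(_dm(["a", "b"], [[0, 1], [1, 0]]))


class TestBipartitions:
    def test_four_taxon_binary_tree_has_one_split(self):
        t = _parse("((A,B),(C,D));")
        assert len(treescan.bipartitions(t)) == 1

    @pytest.mark.parametrize("n", [5, 6, 8, 10])
    def test_binary_tree_has_n_minus_3_splits(self, n):
        rng = np.random.default_rng(n)
        nw = random_binary_tree_newick(rng, [f"t{i}" for i in range(n)])
        assert len(treescan.bipartitions(_parse(nw))) == n - 3

    def test_star_tree_has_no_splits(self):
        t = _parse("(A,B,C,D,E);")
        assert treescan.bipartitions(t) == set()


class TestMajorityConsensus:
    def test_identical_binary_trees_keep_all_splits(self):
        rng = np.random.default_rng(1)
        nw = random_binary_tree_newick(rng, [f"t{i}" for i in range(8)])
        trees = [_parse(nw) for _ in range(10)]
        res = treescan.majority_consensus(trees)
        assert res.n_majority_splits == 5
        assert all(f == 1.0 for f in res.split_frequencies.values())
        # the consensus tree contains exactly the majority splits
        assert treescan.bipartitions(res.consensus_tree) == res.majority_splits

    def test_three_conflicting_quartets_give_empty_consensus(self):
        trees = [
            _parse("((A,B),(C,D));"),
            _parse("((A,C),(B,D));"),
            _parse("((A,D),(B,C));"),
        ]
        res = treescan.majority_consensus(trees)
        assert res.n_majority_splits == 0
        assert all(f == pytest.approx(1 / 3) for f in res.split_frequencies.values())

    def test_frequencies_match_independent_dendropy_tally(self):
        rng = np.random.default_rng(2)
        labels = [f"t{i}" for i in range(8)]
        tns = dendropy.TaxonNamespace(labels)
        news = [random_binary_tree_newick(rng, labels) for _ in range(9)]
        trees = [_parse(nw) for nw in news]
        res = treescan.majority_consensus(trees)
        # oracle: dendropy's own bipartition encoding
        dtrees = [
            dendropy.Tree.get(data=nw, schema="newick", taxon_namespace=tns)
            for nw in news
        ]
        tally: dict[frozenset, int] = {}
        for t in dtrees:
            t.encode_bipartitions()
            for edge in t.preorder_edge_iter():
                bp = edge.bipartition
                if bp is None or edge.head_node.is_leaf() or edge.head_node.parent_node is None:
                    continue
                side = frozenset(
                    taxon.label
                    for taxon in tns
                    if bp.leafset_bitmask & tns.taxon_bitmask(taxon)
                )
                if len(side) < 2 or len(side) > len(labels) - 2:
                    continue
                canon = side if "t0" not in side else frozenset(labels) - side
                tally[canon] = tally.get(canon, 0) + 1
        oracle = {sp: c / 9 for sp, c in tally.items()}
        assert res.split_frequencies == oracle

    def test_majority_splits_pairwise_compatible(self):
        rng = np.random.default_rng(3)
        labels = [f"t{i}" for i in range(8)]
        all_taxa = frozenset(labels)
        trees = [
            _parse(random_binary_tree_newick(rng, labels)) for _ in range(7)
        ]
        res = treescan.majority_consensus(trees)
        for s1 in res.majority_splits:
            for s2 in res.majority_splits:
                assert treescan.splits_compatible(s1, s2, all_taxa)

    def test_leaf_set_mismatch_rejected(self):
        t1 = _parse("((A,B),(C,D));")
        t2 = _parse("((A,B),(C,E));")
        with pytest.raises(ValueError, match="tree 1"):
            treescan.majority_consensus([t1, t2])


class TestGeneTreeSurvey:
    def test_clonal_windows_share_true_genealogy_splits(self, small_dataset):
        # sanity: the survey runs end-to-end on simulated alignments
        trees, cons = treescan.gene_tree_survey(
            small_dataset.gene_alignments, min_length=200, min_mean_diff=15.0
        )
        assert len(trees) >= 2
        assert cons is not None
        assert 0 <= cons.n_majority_splits <= len(small_dataset.genotypes.sample_ids) - 3
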