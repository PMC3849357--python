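"""Maximal-subtree decomposition, ranks, seeds, scores, clustering.

The decomposition is checked against an exhaustive oracle that
enumerates every clade of the tree, tests conservation, and keeps the
maximal conserved ones.
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from allonet.coevolution import (
    CoevolutionMatrix,
    ResidueClassScheme,
    SubtreeDecomposition,
    cluster_networks,
    coevolution_score,
    decompose_position,
    rank_profile,
    score_matrix,
    select_seeds,
)
from allonet.datatypes import AMINO_ACIDS, Alignment, SeqRecord
from allonet.io_formats import read_tree_string
from allonet.synthetic import gen_tree


def _aln_from_column(ids, column):
    return Alignment([SeqRecord(i, c) for i, c in zip(ids, column)])


def oracle_decompose(tree, aln, pos, scheme):
    """Exhaustive oracle: every clade, conservation test, maximality test."""
    cls = dict(zip(aln.ids, scheme.classes_of(aln.column(pos))))
    clades = []
    for node in tree.preorder_node_iter():
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        parent = node.parent_node
        parent_leaves = (
            None
            if parent is None
            else frozenset(lf.taxon.label for lf in parent.leaf_iter())
        )
        clades.append((leaves, parent_leaves))
    conserved = {
        leaves
        for leaves, _ in clades
        if len({cls[l] for l in leaves}) == 1
    }
    return {
        leaves
        for leaves, parent in clades
        if leaves in conserved and (parent is None or parent not in conserved)
    }


# ----------------------------------------------------------------------
# decompose_position
# ----------------------------------------------------------------------

def test_conserved_column_is_one_block():
    tree = read_tree_string("((a:1,b:1):1,(c:1,d:1):1);")
    aln = _aln_from_column("abcd", "AAAA")
    d = decompose_position(tree, aln, 0)
    assert d.rank == 1
    assert d.blocks == [frozenset("abcd")]


def test_two_conserved_clades():
    tree = read_tree_string("((a:1,b:1):1,(c:1,d:1):1);")
    aln = _aln_from_column("abcd", "AADD")
    d = decompose_position(tree, aln, 0)
    assert sorted(d.blocks, key=sorted) == [frozenset("ab"), frozenset("cd")]


def test_all_distinct_classes_are_singletons():
    tree = read_tree_string("((a:1,b:1):1,(c:1,d:1):1);")
    aln = _aln_from_column("abcd", "AFKG")  # four different classes
    d = decompose_position(tree, aln, 0)
    assert d.rank == 4
    assert all(len(b) == 1 for b in d.blocks)


@pytest.mark.parametrize("case", range(60))
def test_decomposition_matches_exhaustive_oracle(case):
    rng = np.random.default_rng(case)
    n = int(rng.integers(4, 9))
    tree = gen_tree(n, seed=case)
    ids = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    aas = np.array(list(AMINO_ACIDS))
    column = "".join(aas[rng.integers(0, 20, size=n)])
    aln = _aln_from_column(ids, column)
    scheme = ResidueClassScheme.default()
    got = set(decompose_position(tree, aln, 0, scheme).blocks)
    assert got == oracle_decompose(tree, aln, 0, scheme)


def test_gap_clade_counts_as_conserved():
    tree = read_tree_string("((a:1,b:1):1,(c:1,d:1):1);")
    aln = _aln_from_column("abcd", "--AA")
    d = decompose_position(tree, aln, 0)
    assert frozenset("ab") in d.blocks


# ----------------------------------------------------------------------
# rank profile
# ----------------------------------------------------------------------

def test_rank_profile_matches_per_column_decomposition(make_alignment):
    tree = gen_tree(12, seed=9)
    ids = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    aln = make_alignment(ids, 25)
    ranks = rank_profile(tree, aln)
    expected = [decompose_position(tree, aln, j).rank for j in range(25)]
    assert list(ranks) == expected


def test_all_conserved_alignment_ranks_one():
    tree = gen_tree(8, seed=0)
    ids = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    aln = Alignment([SeqRecord(i, "AAAA") for i in ids])
    assert list(rank_profile(tree, aln)) == [1, 1, 1, 1]


def test_single_column_profile_length_one():
    tree = gen_tree(4, seed=0)
    ids = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    aln = Alignment([SeqRecord(i, "A") for i in ids])
    assert rank_profile(tree, aln).shape == (1,)


@given(st.integers(0, 10_000))
def test_rank_non_increasing_under_class_merge(seed):
    """Merging two residue classes can only coarsen the decomposition."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 10))
    tree = gen_tree(n, seed=seed % 997)
    ids = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    aas = np.array(list(AMINO_ACIDS))
    aln = _aln_from_column(ids, "".join(aas[rng.integers(0, 20, size=n)]))
    fine = ResidueClassScheme.identity()
    merged_groups = ["".join(sorted(set(AMINO_ACIDS) - set("KR"))), "KR", "X", "-"]
    # a scheme where all amino acids except K/R share one class is coarser
    coarse = ResidueClassScheme.from_groups(merged_groups, "coarse")
    r_fine = decompose_position(tree, aln, 0, fine).rank
    r_coarse = decompose_position(tree, aln, 0, coarse).rank
    assert r_coarse <= r_fine


# ----------------------------------------------------------------------
# seed selection
# ----------------------------------------------------------------------

def test_select_seeds_mean_rule():
    ranks = np.array([2, 2, 8, 9, 9])  # mean 6
    assert select_seeds(ranks, alpha=1.0) == [0, 1]


def test_select_seeds_all_equal_include_invariant():
    ranks = np.ones(5, dtype=int) * 3
    assert select_seeds(ranks, alpha=1.0, include_invariant=True) == list(range(5))


def test_select_seeds_excludes_invariant_columns():
    ranks = np.array([1, 1, 2, 3])
    seeds = select_seeds(ranks, alpha=2.0)
    assert 0 not in seeds and 1 not in seeds


def test_select_seeds_empty_warns():
    with pytest.warns(UserWarning):
        out = select_seeds(np.array([1, 1, 1]), alpha=0.1)
    assert out == []


# ----------------------------------------------------------------------
# co-evolution score
# ----------------------------------------------------------------------

def _decomp(blocks):
    return SubtreeDecomposition(position=0, blocks=[frozenset(b) for b in blocks])


def test_identical_decompositions_score_one():
    d = _decomp([["a", "b"], ["c"], ["d"]])
    assert coevolution_score(d, d) == pytest.approx(1.0)


def test_whole_tree_vs_singletons_scores_quarter():
    d1 = _decomp([["a", "b", "c", "d"]])
    d2 = _decomp([["a"], ["b"], ["c"], ["d"]])
    assert coevolution_score(d1, d2) == pytest.approx(0.25)


@pytest.mark.parametrize("seed", range(10))
def test_score_symmetric_and_bounded(seed):
    rng = np.random.default_rng(seed)
    n = 8
    tree = gen_tree(n, seed=seed)
    ids = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    aas = np.array(list(AMINO_ACIDS))
    a1 = _aln_from_column(ids, "".join(aas[rng.integers(0, 20, size=n)]))
    a2 = _aln_from_column(ids, "".join(aas[rng.integers(0, 20, size=n)]))
    d1 = decompose_position(tree, a1, 0)
    d2 = decompose_position(tree, a2, 0)
    s12 = coevolution_score(d1, d2)
    s21 = coevolution_score(d2, d1)
    assert s12 == pytest.approx(s21)
    assert 0.0 <= s12 <= 1.0


def test_score_matrix_unit_diagonal(make_alignment):
    tree = gen_tree(6, seed=2)
    ids = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    aln = make_alignment(ids, 10)
    decomps = [decompose_position(tree, aln, j) for j in range(5)]
    M = score_matrix(decomps)
    np.testing.assert_allclose(np.diag(M.scores), 1.0)
    np.testing.assert_allclose(M.scores, M.scores.T)


# ----------------------------------------------------------------------
# clustering
# ----------------------------------------------------------------------

def test_block_matrix_two_networks():
    m = 8
    S = np.zeros((m, m))
    S[:4, :4] = 1.0
    S[4:, 4:] = 1.0
    M = CoevolutionMatrix(positions=list(range(10, 10 + m)), scores=S)
    res = cluster_networks(M, tau=0.5, min_size=4)
    assert len(res.networks) == 2
    members = sorted(tuple(n.positions) for n in res.networks)
    assert members == [(10, 11, 12, 13), (14, 15, 16, 17)]


def test_all_ones_single_network():
    m = 6
    M = CoevolutionMatrix(positions=list(range(m)), scores=np.ones((m, m)))
    res = cluster_networks(M, tau=0.5, min_size=4)
    assert len(res.networks) == 1
    assert res.networks[0].positions == list(range(m))
    assert res.networks[0].mean_internal_score == pytest.approx(1.0)


def test_too_few_seeds_empty_result():
    M = CoevolutionMatrix(positions=[1, 2], scores=np.eye(2))
    assert cluster_networks(M, min_size=4).networks == []


def test_leaf_order_is_permutation():
    rng = np.random.default_rng(0)
    m = 12
    S = np.clip((rng.random((m, m)) + rng.random((m, m)).T) / 2, 0, 1)
    S = (S + S.T) / 2
    np.fill_diagonal(S, 1.0)
    M = CoevolutionMatrix(positions=list(range(m)), scores=S)
    res = cluster_networks(M)
    assert sorted(res.leaf_order) == list(range(m))
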