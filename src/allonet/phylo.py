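"""Alignment preprocessing and distance-tree construction.

The subtree analysis needs a rooted tree over exactly the alignment's
sequences. This module provides the default route when the user supplies
none: gap-fraction column filtering, uncorrected p-distances computed on
comparable (gap-free in both sequences) columns, neighbor joining, and
midpoint rooting. A user-supplied Newick tree bypasses all of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import skbio

from .datatypes import Alignment
from .errors import EmptyResultError, IdentifierError, TreeError
from .io_formats import read_tree_string


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    labels: list[str]
    values: np.ndarray  # (n, n)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        self.values = v


def filter_columns(
    aln: Alignment, max_gap_fraction: float = 0.5
) -> tuple[Alignment, list[int]]:
    """Drop columns whose gap fraction exceeds ``max_gap_fraction``.

    Returns the filtered alignment and the kept original column indices
    (0-based), which map filtered positions back to the input alignment.
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    mat = aln.to_matrix()
    gap_frac = (mat == "-").mean(axis=0)
    kept = [j for j in range(aln.length) if gap_frac[j] <= max_gap_fraction]
    if not kept:
        raise EmptyResultError("gap filter removed every column")
    return aln.subset_columns(kept), kept


def pairwise_distance(aln: Alignment) -> DistanceMatrix:
    """Uncorrected p-distances on pairwise comparable columns.

    d(i, j) = 1 - identical/comparable, where a column is comparable for
    the pair iff neither sequence has a gap there. With zero comparable
    columns the distance is 1.
    """
    mat = aln.to_matrix()
    n = aln.n
    nongap = mat != "-"
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            m = int(both.sum())
            if m == 0:
                dij = 1.0
            else:
                ident = int((mat[i][both] == mat[j][both]).sum())
                dij = 1.0 - ident / m
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(labels=aln.ids, values=d)


def build_nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree, negative branch lengths clamped to 0,
    then midpoint-rooted.

    Exact on additive distance matrices: reconstructs the generating
    topology with branch lengths to numerical precision.
    """
    if len(dm.labels) < 3:
        raise TreeError("neighbor joining needs at least 3 sequences")
    sk_dm = skbio.DistanceMatrix(dm.values, ids=dm.labels)
    sk_tree = skbio.tree.nj(sk_dm)
    newick = str(sk_tree)
    tree = read_tree_string(newick)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return midpoint_root(tree)


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    tree = tree.clone(depth=1)
    tree.reroot_at_midpoint(update_bipartitions=False)
    tree.is_rooted = True
    return tree


def check_tree_matches_alignment(tree: dendropy.Tree, aln: Alignment) -> None:
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    ids = set(aln.ids)
    if leaf_labels != ids:
        missing = sorted(ids - leaf_labels)[:5]
        extra = sorted(leaf_labels - ids)[:5]
        raise IdentifierError(
            f"tree leaves and alignment ids differ "
            f"(missing from tree: {missing}, extra in tree: {extra})"
        )
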