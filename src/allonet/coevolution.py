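"""Maximal-subtree co-evolution analysis.

For each alignment column, the leaves of a rooted phylogeny are
partitioned into *maximal conserved clades*: the largest clades within
which every sequence carries the same residue class at that column. The
number of such clades is the column's *rank*; strongly constrained
positions have low rank. Columns whose rank is low relative to the mean
("seed positions") are scored pairwise by comparing their decompositions
through a correspondence matrix of block overlaps, and positions with
mutually similar decompositions are clustered into residue networks.

Conservation is judged on a configurable physicochemical residue-class
scheme (identity mode available); the gap character is its own class, so
a clade of all-gap sequences counts as conserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from .datatypes import ALPHABET, Alignment
from .errors import IdentifierError
from .phylo import check_tree_matches_alignment

# ----------------------------------------------------------------------
# residue class schemes
# ----------------------------------------------------------------------

_DEFAULT_GROUPS = ["AVLIMC", "FWYH", "STNQ", "KR", "DE", "G", "P", "X", "-"]


@dataclass(frozen=True)
class ResidueClassScheme:
    """Total mapping from the residue alphabet to class labels."""

    mapping: dict[str, int]
    name: str = "physicochemical"

    def __post_init__(self):
        missing = ALPHABET - set(self.mapping)
        if missing:
            raise ValueError(f"scheme does not cover {sorted(missing)}")

    @classmethod
    def from_groups(cls, groups: list[str], name: str) -> "ResidueClassScheme":
        mapping = {}
        for label, group in enumerate(groups):
            for ch in group:
                mapping[ch] = label
        return cls(mapping=mapping, name=name)

    @classmethod
    def default(cls) -> "ResidueClassScheme":
        return cls.from_groups(_DEFAULT_GROUPS, "physicochemical")

    @classmethod
    def identity(cls) -> "ResidueClassScheme":
        return cls.from_groups(sorted(ALPHABET), "identity")

    def classes_of(self, column: str) -> np.ndarray:
        return np.array([self.mapping[c] for c in column.upper()], dtype=np.int64)


# ----------------------------------------------------------------------
# decompositions and ranks
# ----------------------------------------------------------------------

@dataclass
class SubtreeDecomposition:
    """Partition of the leaf set into maximal conserved clades."""

    position: int
    blocks: list[frozenset[str]]

    @property
    def rank(self) -> int:
        return len(self.blocks)

    def leaf_set(self) -> frozenset[str]:
        out: set[str] = set()
        for b in self.blocks:
            out |= b
        return frozenset(out)


def decompose_position(
    tree: dendropy.Tree,
    aln: Alignment,
    pos: int,
    scheme: ResidueClassScheme | None = None,
) -> SubtreeDecomposition:
    """Greedy top-down maximal-subtree decomposition of one column.

    Starting at the root, a clade is emitted as a block iff all its
    leaves share one residue class; otherwise its children are visited.
    Leaves are trivially conserved, so the blocks always partition the
    leaf set, and each emitted block is maximal (its parent clade is not
    conserved).
    """
    scheme = scheme or ResidueClassScheme.default()
    check_tree_matches_alignment(tree, aln)
    column = aln.column(pos)
    cls_by_id = dict(zip(aln.ids, scheme.classes_of(column)))

    blocks: list[frozenset[str]] = []

    def visit(node) -> None:
        leaves = [lf.taxon.label for lf in node.leaf_iter()]
        classes = {cls_by_id[l] for l in leaves}
        if len(classes) == 1:
            blocks.append(frozenset(leaves))
        else:
            for child in node.child_nodes():
                visit(child)

    visit(tree.seed_node)
    return SubtreeDecomposition(position=pos, blocks=blocks)


def rank_profile(
    tree: dendropy.Tree,
    aln: Alignment,
    scheme: ResidueClassScheme | None = None,
) -> np.ndarray:
    """Rank (maximal-subtree count) of every column, vectorized.

    One postorder sweep propagates, per column, the shared class of each
    clade (or a sentinel when mixed); a clade is a block iff conserved
    while its parent is not. Equivalent to calling
    :func:`decompose_position` per column.
    """
    scheme = scheme or ResidueClassScheme.default()
    check_tree_matches_alignment(tree, aln)
    mat = aln.to_matrix()
    row_of = {sid: i for i, sid in enumerate(aln.ids)}
    return _rank_from_states(tree, mat, row_of, scheme, aln.length)


def _rank_from_states(tree, mat, row_of, scheme, L) -> np.ndarray:
    MIXED = np.int64(-1)
    state: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            row = mat[row_of[node.taxon.label]]
            state[id(node)] = np.array(
                [scheme.mapping[c] for c in row], dtype=np.int64
            )
        else:
            children = node.child_nodes()
            acc = state[id(children[0])].copy()
            for ch in children[1:]:
                acc[acc != state[id(ch)]] = MIXED
            state[id(node)] = acc
    ranks = np.zeros(L, dtype=np.int64)
    for node in tree.preorder_node_iter():
        conserved = state[id(node)] != MIXED
        if node.parent_node is None:
            ranks += conserved
        else:
            parent_mixed = state[id(node.parent_node)] == MIXED
            ranks += conserved & parent_mixed
    return ranks


def select_seeds(
    ranks: np.ndarray,
    alpha: float = 2.0,
    include_invariant: bool = False,
) -> list[int]:
    """Columns whose rank is at most ``alpha`` times the mean rank.

    The default ``alpha`` of 2.0 discards only clearly hyper-variable
    columns: outlier sequences inflate the rank of genuinely co-evolving
    positions to around (sometimes above) the mean, so a cut at the mean
    discards much of the signal; the pairwise score and cluster cut do
    the real discrimination. Rank-1 columns (one block covering the whole
    tree, i.e. invariant columns) carry no co-evolution signal and are
    excluded unless ``include_invariant`` is set.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    ranks = np.asarray(ranks)
    threshold = alpha * ranks.mean()
    seeds = [
        int(j)
        for j in range(len(ranks))
        if ranks[j] <= threshold and (include_invariant or ranks[j] > 1)
    ]
    if not seeds:
        warnings.warn("no seed positions selected", stacklevel=2)
    return seeds


# ----------------------------------------------------------------------
# co-evolution scores
# ----------------------------------------------------------------------

def coevolution_score(
    d1: SubtreeDecomposition, d2: SubtreeDecomposition
) -> float:
    """Symmetric size-weighted best-match similarity of two decompositions.

    The correspondence matrix C[a][b] holds the Jaccard index of block a
    of the first decomposition with block b of the second. Each side
    contributes the average of its blocks' best matches, weighted by
    block size (fraction of leaves), and the two sides are averaged.
    Size weighting makes the score reflect how much of the tree the two
    positions partition identically, so a handful of noise singletons
    cannot drown the agreement of the large clades. Identical
    decompositions score 1; unrelated partitions score near 0.
    """
    if d1.leaf_set() != d2.leaf_set():
        raise IdentifierError("decompositions cover different leaf sets")
    leaves = sorted(d1.leaf_set())
    index = {label: i for i, label in enumerate(leaves)}
    return _pair_score(_block_matrix(d1, index), _block_matrix(d2, index))


def _block_matrix(d: SubtreeDecomposition, index: dict[str, int]) -> np.ndarray:
    B = np.zeros((len(d.blocks), len(index)), dtype=np.float64)
    for k, block in enumerate(d.blocks):
        for label in block:
            B[k, index[label]] = 1.0
    return B


def _pair_score(B1: np.ndarray, B2: np.ndarray) -> float:
    n = B1.shape[1]
    inter = B1 @ B2.T
    s1 = B1.sum(axis=1)
    s2 = B2.sum(axis=1)
    C = inter / (s1[:, None] + s2[None, :] - inter)
    return float(
        0.5 * ((s1 / n * C.max(axis=1)).sum() + (s2 / n * C.max(axis=0)).sum())
    )


def correspondence_matrix(
    d1: SubtreeDecomposition, d2: SubtreeDecomposition
) -> np.ndarray:
    C = np.zeros((len(d1.blocks), len(d2.blocks)))
    for a, A in enumerate(d1.blocks):
        for b, B in enumerate(d2.blocks):
            inter = len(A & B)
            if inter:
                C[a, b] = inter / len(A | B)
    return C


@dataclass
class CoevolutionMatrix:
    """Pairwise co-evolution scores over the seed positions."""

    positions: list[int]  # labels carried through to network output
    scores: np.ndarray  # (m, m), symmetric, unit diagonal

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        m = len(self.positions)
        if s.shape != (m, m):
            raise ValueError("score matrix shape mismatch")
        self.scores = s


def score_matrix(
    decompositions: list[SubtreeDecomposition],
    positions: list[int] | None = None,
) -> CoevolutionMatrix:
    """All-against-all co-evolution scores for the given decompositions."""
    m = len(decompositions)
    if positions is None:
        positions = [d.position for d in decompositions]
    if m:
        leaves = sorted(decompositions[0].leaf_set())
        index = {label: i for i, label in enumerate(leaves)}
        mats = [_block_matrix(d, index) for d in decompositions]
    S = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            S[i, j] = S[j, i] = _pair_score(mats[i], mats[j])
    return CoevolutionMatrix(positions=list(positions), scores=S)


# ----------------------------------------------------------------------
# clustering into residue networks
# ----------------------------------------------------------------------

@dataclass
class ResidueNetwork:
    """A cluster of co-evolved positions."""

    name: str
    positions: list[int]
    mean_internal_score: float

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class ClusterResult:
    networks: list[ResidueNetwork] = field(default_factory=list)
    leaf_order: list[int] = field(default_factory=list)  # heat-map ordering


def cluster_networks(
    M: CoevolutionMatrix,
    tau: float = 0.9,
    min_size: int = 4,
) -> ClusterResult:
    """Average-linkage clustering of positions on distance 1 - score.

    The dendrogram is cut at height ``1 - tau``; clusters smaller than
    ``min_size`` are dropped. Two unrelated positions evolving on the
    same tree already share clade structure by descent, which puts the
    background similarity near 0.5; the default ``tau`` of 0.75 sits
    between that baseline and the near-1 similarity of genuinely
    co-evolving positions. Networks are ordered by size (descending),
    ties broken by the smallest member position, and named network_1,
    network_2, ... The dendrogram leaf order is returned for heat-map
    export.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    if min_size < 2:
        raise ValueError("min_size must be at least 2")
    m = len(M.positions)
    if m < min_size:
        return ClusterResult(networks=[], leaf_order=list(range(m)))
    dist = np.clip(1.0 - M.scores, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=1.0 - tau, criterion="distance")
    order = [int(i) for i in leaves_list(Z)]

    clusters: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(idx)
    kept = [idxs for idxs in clusters.values() if len(idxs) >= min_size]
    kept.sort(key=lambda idxs: (-len(idxs), min(M.positions[i] for i in idxs)))

    networks = []
    for k, idxs in enumerate(kept, start=1):
        sub = M.scores[np.ix_(idxs, idxs)]
        off_diag = sub[~np.eye(len(idxs), dtype=bool)]
        networks.append(
            ResidueNetwork(
                name=f"network_{k}",
                positions=sorted(M.positions[i] for i in idxs),
                mean_internal_score=float(off_diag.mean()),
            )
        )
    return ClusterResult(networks=networks, leaf_order=order)
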