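"""Synthetic data with the statistical structure the pipeline assumes.

Two generators, each deterministic per seed and each emitting its ground
truth alongside the data:

* :func:`gen_tree` + :func:`evolve_msa` — alignments evolved down a Yule
  phylogeny in which designated position sets ("planted networks")
  switch residue class coherently on the same internal edges, against an
  independent-mutation background. Matching switch edges directly create
  matching maximal-subtree partitions, which is exactly the signal the
  co-evolution analysis measures.
* :func:`gen_structure` — a compact self-avoiding chain with a
  clustered source ("heme") node set and a planted stiff-spring pathway
  from the source to a distal target window, the testbed for the ATD
  claim that heat travels along coupled routes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import networkx as nx
import numpy as np

from .atd import ElasticNetwork, build_enm, stiffen_springs
from .coevolution import ResidueClassScheme
from .datatypes import (
    AMINO_ACIDS,
    Alignment,
    Chain,
    HeteroGroup,
    ONE_TO_THREE,
    Residue,
    SeqRecord,
    SIDECHAIN_HEAVY_ATOMS,
    StructureModel,
)
from .errors import DataError

_AA_INT_TO_THREE = {i: ONE_TO_THREE[a] for i, a in enumerate(AMINO_ACIDS)}


class GenerationError(DataError):
    """Generator failed (e.g. self-avoiding walk stuck); retry with a new seed."""


# ----------------------------------------------------------------------
# trees
# ----------------------------------------------------------------------

def gen_tree(
    n_leaves: int, seed: int = 0, mean_branch_length: float = 0.1
) -> dendropy.Tree:
    """Yule (pure-birth) topology with i.i.d. exponential branch lengths.

    Topology: starting from a cherry, a uniformly chosen leaf is split
    until ``n_leaves`` are present. Leaves are labelled t000, t001, ...
    in traversal order. Deterministic per seed.
    """
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    rng = np.random.default_rng(seed)
    tree = dendropy.Tree()
    tree.is_rooted = True
    root = tree.seed_node
    leaves = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        leaves.append(child)
    while len(leaves) < n_leaves:
        idx = int(rng.integers(len(leaves)))
        node = leaves.pop(idx)
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            leaves.append(child)
    width = max(3, len(str(n_leaves - 1)))
    counter = 0
    for node in tree.preorder_node_iter():
        if node is not root:
            node.edge.length = float(rng.exponential(mean_branch_length))
        if node.is_leaf():
            taxon = tree.taxon_namespace.new_taxon(f"t{counter:0{width}d}")
            node.taxon = taxon
            counter += 1
    return tree


def leaf_depths(tree: dendropy.Tree) -> list[int]:
    """Edge-count depth of every leaf (topological, not branch-length)."""
    out = []
    for leaf in tree.leaf_node_iter():
        d = 0
        node = leaf
        while node.parent_node is not None:
            d += 1
            node = node.parent_node
        out.append(d)
    return out


# ----------------------------------------------------------------------
# alignments with planted co-evolving networks
# ----------------------------------------------------------------------

@dataclass
class PlantedNetwork:
    """Positions that switch residue class together on the same edges."""

    positions: list[int]                  # 0-based column indices
    switch_edges: list[frozenset[str]]    # each edge = leaf set below it
    epsilon: float = 0.05                 # per-leaf noise probability

    def __post_init__(self):
        if not self.switch_edges:
            raise ValueError("a planted network needs at least one switch edge")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must be in [0, 1]")


@dataclass
class MSAGenSpec:
    """Generator settings for a synthetic alignment."""

    n_leaves: int = 64
    n_columns: int = 200
    mu: float = 0.5                       # background mutations per unit branch length
    networks: list[PlantedNetwork] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        seen: set[int] = set()
        for net in self.networks:
            overlap = seen & set(net.positions)
            if overlap:
                raise ValueError(f"planted position sets overlap: {sorted(overlap)}")
            seen |= set(net.positions)
        if seen and max(seen) >= self.n_columns:
            raise ValueError("planted positions exceed the number of columns")


def sample_switch_edges(
    tree: dendropy.Tree,
    rng: np.random.Generator,
    n_edges: int = 6,
    min_clade: int = 2,
    max_clade: int = 12,
    exclude: set[frozenset[str]] | None = None,
) -> list[frozenset[str]]:
    """Sample mutually disjoint internal edges (as leaf sets).

    Clades between ``min_clade`` and ``max_clade`` leaves, pairwise
    disjoint and disjoint from ``exclude``: several mid-sized coherent
    switches give a planted network a partition signature that a lone
    background substitution cannot mimic by chance.
    """
    exclude = exclude or set()
    eligible = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        leafset = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if (
            min_clade <= len(leafset) <= max_clade
            and leafset not in exclude
            and not any(leafset & e for e in exclude)
        ):
            eligible.append(leafset)
    edges: list[frozenset[str]] = []
    for i in rng.permutation(len(eligible)):
        leafset = eligible[int(i)]
        if any(leafset & e for e in edges):
            continue
        edges.append(leafset)
        if len(edges) == n_edges:
            break
    if len(edges) < n_edges:
        raise GenerationError(
            f"found only {len(edges)} disjoint eligible edges; need {n_edges}"
        )
    return edges


def default_msa_spec(
    tree: dendropy.Tree,
    seed: int = 0,
    n_networks: int = 2,
    network_size: int = 8,
    n_columns: int = 200,
    mu: float = 0.5,
    epsilon: float = 0.05,
    edges_per_network: int = 6,
) -> MSAGenSpec:
    """Two planted 8-position networks on disjoint switch edges."""
    rng = np.random.default_rng(seed)
    cols = rng.choice(n_columns, size=n_networks * network_size, replace=False)
    used: set[frozenset[str]] = set()
    networks = []
    for k in range(n_networks):
        edges = sample_switch_edges(
            tree, rng, n_edges=edges_per_network, exclude=used
        )
        used |= set(edges)
        positions = sorted(int(c) for c in cols[k * network_size:(k + 1) * network_size])
        networks.append(
            PlantedNetwork(positions=positions, switch_edges=edges, epsilon=epsilon)
        )
    return MSAGenSpec(
        n_leaves=len(tree.leaf_nodes()),
        n_columns=n_columns,
        mu=mu,
        networks=networks,
        seed=seed,
    )


_AA_ARRAY = np.array(list(AMINO_ACIDS))
_SCHEME = ResidueClassScheme.default()
_AA_CLASS = np.array([_SCHEME.mapping[a] for a in AMINO_ACIDS])


def _random_other_class_residue(rng: np.random.Generator, current: int) -> int:
    """Uniform residue from a uniformly chosen different amino-acid class."""
    current_class = int(_AA_CLASS[current])
    classes = sorted(set(int(c) for c in _AA_CLASS) - {current_class})
    new_class = classes[int(rng.integers(len(classes)))]
    members = np.flatnonzero(_AA_CLASS == new_class)
    return int(members[int(rng.integers(len(members)))])


def evolve_msa(
    tree: dendropy.Tree, spec: MSAGenSpec
) -> tuple[Alignment, dict]:
    """Evolve an alignment down the tree; returns it with its ground truth.

    Background columns start from a uniform root residue and mutate with
    probability 1 - exp(-mu*t) per edge to a uniform different residue.
    Planted columns change only on their network's switch edges — the
    whole subtree below the edge adopts a residue of a new class, the
    same edges for every position of the network — and then receive
    per-leaf noise: for each network, each leaf independently becomes an
    outlier with probability epsilon, and an outlier leaf carries an
    independent uniform random residue at every position of that
    network. An outlier leaf's residue is drawn uniformly from a residue
    class other than the one it would have carried, so the corruption is
    unambiguous at every position. This emulates a divergent or
    misaligned sequence, which corrupts a co-evolving position set
    coherently rather than cell by cell.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.n_columns
    planted_cols = sorted({p for net in spec.networks for p in net.positions})
    network_of = {}
    for k, net in enumerate(spec.networks):
        for p in net.positions:
            network_of[p] = k
    bg_cols = np.array(
        [j for j in range(L) if j not in network_of], dtype=np.int64
    )

    root_seq = rng.integers(0, 20, size=L)
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    leaf_rows: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            pass
        else:
            parent = seqs[id(node.parent_node)]
            seq = parent.copy()
            t = node.edge.length or 0.0
            p_mut = 1.0 - np.exp(-spec.mu * t)
            if bg_cols.size and p_mut > 0:
                mask = rng.random(bg_cols.size) < p_mut
                hit = bg_cols[mask]
                if hit.size:
                    shift = rng.integers(1, 20, size=hit.size)
                    seq[hit] = (seq[hit] + shift) % 20
            leafset = frozenset(lf.taxon.label for lf in node.leaf_iter())
            for k, pnet in enumerate(spec.networks):
                if leafset in pnet.switch_edges:
                    for pos in pnet.positions:
                        seq[pos] = _random_other_class_residue(rng, int(seq[pos]))
            seqs[id(node)] = seq
        if node.is_leaf():
            leaf_rows[node.taxon.label] = seqs[id(node)]

    # per-leaf outlier noise: shared leaf set per network
    labels = sorted(leaf_rows)
    noisy_leaves: dict[int, list[str]] = {}
    for k, pnet in enumerate(spec.networks):
        noisy = []
        for label in labels:
            if pnet.epsilon > 0 and rng.random() < pnet.epsilon:
                noisy.append(label)
                row = leaf_rows[label].copy()
                for pos in pnet.positions:
                    row[pos] = _random_other_class_residue(rng, int(row[pos]))
                leaf_rows[label] = row
        noisy_leaves[k] = noisy

    records = [
        SeqRecord(label, "".join(_AA_ARRAY[leaf_rows[label]]))
        for label in labels
    ]
    truth = {
        "networks": [
            {
                "positions": list(net.positions),
                "switch_edges": [sorted(e) for e in net.switch_edges],
                "epsilon": net.epsilon,
                "noisy_leaves": noisy_leaves[k],
            }
            for k, net in enumerate(spec.networks)
        ],
        "n_leaves": spec.n_leaves,
        "n_columns": spec.n_columns,
        "mu": spec.mu,
        "seed": spec.seed,
    }
    return Alignment(records), truth


def simulate_msa(spec_seed: int = 0, **kwargs) -> tuple[dendropy.Tree, Alignment, dict]:
    """Convenience: generate tree + default planted-network alignment."""
    n_leaves = kwargs.pop("n_leaves", 64)
    tree = gen_tree(n_leaves, seed=spec_seed)
    spec = default_msa_spec(tree, seed=spec_seed, **kwargs)
    aln, truth = evolve_msa(tree, spec)
    return tree, aln, truth


# ----------------------------------------------------------------------
# structures with a planted stiff pathway
# ----------------------------------------------------------------------

@dataclass
class StructGenSpec:
    """Generator settings for a synthetic compact structure."""

    n_residues: int = 120
    spacing: float = 3.8                  # consecutive CA distance, Å
    source_size: int = 4                  # heme-like source nodes
    pathway_stiffness: float = 5.0        # multiplier on pathway springs
    target_window: int = 6                # residues in the distal window
    min_source_target: float = 15.0       # Å
    cutoff: float = 10.0                  # ENM cutoff
    k_default: float = 1.0
    sequence: str | None = None           # optional one-letter residue types
    seed: int = 0

    def __post_init__(self):
        if self.sequence is not None:
            self.n_residues = len(self.sequence)


def _self_avoiding_walk(
    rng: np.random.Generator, n: int, spacing: float, radius: float,
    min_sep: float = 4.0, max_attempts: int = 10_000,
) -> np.ndarray:
    """Compact self-avoiding CA trace inside a sphere of given radius."""
    attempts = 0
    while True:
        pts = [np.zeros(3)]
        ok = True
        while len(pts) < n:
            placed = False
            for _ in range(60):
                attempts += 1
                if attempts > max_attempts:
                    raise GenerationError(
                        "self-avoiding walk exceeded the placement budget; "
                        "retry with a new seed"
                    )
                d = rng.standard_normal(3)
                d /= np.linalg.norm(d)
                cand = pts[-1] + spacing * d
                if np.linalg.norm(cand) > radius:
                    continue
                if len(pts) > 1:
                    prev = np.array(pts[:-1])
                    if np.min(np.linalg.norm(prev - cand, axis=1)) < min_sep:
                        continue
                pts.append(cand)
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return np.array(pts)


def gen_structure(
    spec: StructGenSpec,
) -> tuple[StructureModel, ElasticNetwork, dict]:
    """Compact chain with a source node cluster and a stiff pathway.

    The pathway is a chain of side-chain nodes, each consecutive pair
    5.2-9.5 Å apart (beyond the mutation model's 5 Å long-contact
    threshold, so an alanine substitution severs it), leading from the
    source cluster to a sequence window whose CA centroid is at least
    ``min_source_target`` Å away. Springs between consecutive pathway
    nodes are stiffened by ``pathway_stiffness``. The ground truth
    records pathway, source, target window, and suggested mutation and
    control residues.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    # sphere radius from a typical packing density of ~110 Å^3 per residue
    radius = (3.0 * 110.0 * n / (4.0 * np.pi)) ** (1.0 / 3.0)

    for _ in range(20):
        try:
            ca = _self_avoiding_walk(rng, n, spec.spacing, radius)
        except GenerationError:
            continue
        result = _assemble_structure(rng, ca, spec)
        if result is not None:
            return result
    raise GenerationError(
        "could not generate a structure with a valid planted pathway; "
        "retry with a new seed"
    )


def _assemble_structure(rng, ca, spec: StructGenSpec):
    n = spec.n_residues
    if spec.sequence is not None:
        names = [ONE_TO_THREE.get(ch.upper(), "ALA") for ch in spec.sequence]
    else:
        names = [_AA_INT_TO_THREE[int(i)] for i in rng.integers(0, 20, size=n)]
    centroids: list[np.ndarray | None] = []
    for i in range(n):
        if names[i] == "GLY":
            centroids.append(None)
            continue
        best = None
        for _ in range(30):
            d = rng.standard_normal(3)
            d /= np.linalg.norm(d)
            cand = ca[i] + d * rng.uniform(1.5, 3.0)
            others = np.delete(ca, i, axis=0)
            sep = float(np.min(np.linalg.norm(others - cand, axis=1)))
            if best is None or sep > best[0]:
                best = (sep, cand)
            if sep >= 2.5:
                break
        centroids.append(best[1])

    # pathway graph over side-chain nodes with step lengths in (5.2, 9.5)
    g = nx.Graph()
    for i in range(n):
        if centroids[i] is None:
            continue
        g.add_node(i)
        for j in range(i + 1, n):
            if centroids[j] is None:
                continue
            d = float(np.linalg.norm(centroids[i] - centroids[j]))
            if 5.2 < d < 9.5:
                g.add_edge(i, j, weight=d)

    # approximate ENM degree of each side-chain node: nodes within the
    # cutoff leak the conduit's energy, so low-density routes carry best
    all_points = np.array(
        [p for p in ca] + [c for c in centroids if c is not None]
    )
    approx_deg = {}
    for i in range(n):
        if centroids[i] is None:
            continue
        approx_deg[i] = int(
            (np.linalg.norm(all_points - centroids[i], axis=1) <= spec.cutoff).sum()
        )

    w = spec.target_window
    order = list(rng.permutation([i for i in range(n) if centroids[i] is not None]))
    for src in order:
        src_point = centroids[src]
        # candidate windows, farthest first
        windows = []
        for start in range(0, n - w + 1):
            if abs(start + w // 2 - src) < 10:
                continue
            block = ca[start:start + w]
            centre = block.mean(axis=0)
            dist = float(np.linalg.norm(centre - src_point))
            # compact (helix-turn-like) windows only: the conduit's
            # terminal node must be able to reach the whole window
            spread = float(
                max(np.linalg.norm(block[a] - block[b])
                    for a in range(w) for b in range(a + 1, w))
            )
            if dist >= spec.min_source_target and spread <= 12.0:
                windows.append((dist, start))
        # nearest window that still satisfies the distance floor: a conduit
        # of 2-4 hops, whose far end still carries measurable heat
        windows.sort()
        for dist, start in windows[:8]:
            targets = [
                i for i in range(start, start + w)
                if centroids[i] is not None and g.has_node(i)
            ]
            best_path = None
            best_score = np.inf
            for tgt in targets:
                if src in g and tgt in g and nx.has_path(g, src, tgt):
                    path = nx.shortest_path(g, src, tgt)
                    if len(path) < 3:
                        continue
                    # springs couple longitudinally, so a kinked conduit
                    # converts the motion to transverse modes and stalls;
                    # and every neighbouring node within the cutoff leaks
                    # energy out of the route. Prefer straight routes
                    # through low-density regions.
                    steps = sum(
                        float(np.linalg.norm(centroids[a] - centroids[b]))
                        for a, b in zip(path, path[1:])
                    )
                    span = float(np.linalg.norm(centroids[path[0]] - centroids[path[-1]]))
                    straightness = span / steps
                    if straightness < 0.8:
                        continue
                    # per-joint deviation from straight; transfer drops as
                    # cos^2 of this angle, so one sharp kink kills the route
                    max_dev = 0.0
                    for a, b, c in zip(path, path[1:], path[2:]):
                        v1 = centroids[b] - centroids[a]
                        v2 = centroids[c] - centroids[b]
                        cosang = float(
                            np.dot(v1, v2)
                            / (np.linalg.norm(v1) * np.linalg.norm(v2))
                        )
                        dev = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                        max_dev = max(max_dev, dev)
                    if max_dev > 50.0:
                        continue
                    mean_deg = float(np.mean([approx_deg[r] for r in path]))
                    score = mean_deg + 100.0 * (1.0 - straightness) + 0.5 * max_dev
                    if score < best_score:
                        best_score = score
                        best_path = path
            if best_path is None or best_score > 110.0:
                continue
            return _finalize_structure(
                rng, ca, names, centroids, best_path, start, w, spec
            )
    return None


def _finalize_structure(rng, ca, names, centroids, pathway, win_start, w, spec):
    n = spec.n_residues
    src_res = pathway[0]
    src_point = centroids[src_res]
    if spec.sequence is None:
        # Uniform light side chains along the conduit and in the target
        # window keep those nodes mutually resonant (equal mass, hence
        # equal local frequency) and resonant with the unit-mass source
        # nodes; mass mismatch detunes neighbouring oscillators and
        # chokes harmonic energy transfer.
        for r in list(pathway) + [
            i for i in range(win_start, win_start + w) if centroids[i] is not None
        ]:
            names[r] = "CYS"
    # source ("heme") nodes clustered 2-4 Å from the pathway start
    offsets = np.array(
        [[1.0, 1.0, 1.0], [-1.0, -1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0]]
    ) / np.sqrt(3.0)
    source = []
    for i in range(spec.source_size):
        off = offsets[i % 4] * rng.uniform(2.0, 4.0) + 0.3 * rng.standard_normal(3)
        source.append(src_point + off)
    source = np.array(source)

    residues = [
        Residue(
            number=i + 1,
            name=names[i],
            ca=tuple(ca[i]),
            sidechain_centroid=None if centroids[i] is None else tuple(centroids[i]),
            sidechain_count=SIDECHAIN_HEAVY_ATOMS[names[i]],
        )
        for i in range(n)
    ]
    model = StructureModel(
        chains=[Chain(id="A", residues=residues)],
        hetero_groups=[HeteroGroup(name="HEM", coords=source)],
    )
    net = build_enm(model, cutoff=spec.cutoff, k_default=spec.k_default)
    pairs = [
        (net.sidechain_node[pathway[i]], net.sidechain_node[pathway[i + 1]])
        for i in range(len(pathway) - 1)
    ]
    # the conduit starts at the source and ends in the target window:
    # entry links and terminal-to-window links are stiff as well
    start_sc = int(net.sidechain_node[pathway[0]])
    pairs += [(int(h), start_sc) for h in net.hetero_nodes["HEM"]]
    term_sc = int(net.sidechain_node[pathway[-1]])
    spring_set = {
        (int(i), int(j)) for i, j in zip(net.springs_i, net.springs_j)
    }
    for i in range(win_start, win_start + w):
        s = int(net.sidechain_node[i])
        if s < 0 or s == term_sc:
            continue
        pair = (min(term_sc, s), max(term_sc, s))
        if pair in spring_set:  # only pairs already within the ENM cutoff
            pairs.append(pair)
    net = stiffen_springs(net, pairs, spec.pathway_stiffness)

    window_residues = list(range(win_start, win_start + w))
    mutation_residue = pathway[len(pathway) // 2]
    control = _pick_control(net, ca, centroids, pathway, window_residues,
                            source, mutation_residue)
    truth = {
        "pathway": [str(r + 1) for r in pathway],
        "source_group": "HEM",
        "target_window": [str(r + 1) for r in window_residues],
        "mutation_residue": str(mutation_residue + 1),
        "control_residue": str(control + 1) if control is not None else None,
        "pathway_stiffness": spec.pathway_stiffness,
        "seed": spec.seed,
    }
    return model, net, truth


def _pick_control(net, ca, centroids, pathway, window, source, mut_res):
    """Degree-matched off-pathway residue far from source, path, and window."""
    sc_degree = {}
    for r in range(net.n_residues):
        s = net.sidechain_node[r]
        if s < 0:
            continue
        sc_degree[r] = int(
            ((net.springs_i == s) | (net.springs_j == s)).sum()
        )
    excluded = set(pathway) | set(window)
    excluded |= {p + d for p in pathway for d in (-1, 1)}
    target_deg = sc_degree.get(mut_res, 0)
    best = None
    for r, deg in sc_degree.items():
        if r in excluded or centroids[r] is None:
            continue
        d_src = float(np.min(np.linalg.norm(source - centroids[r], axis=1)))
        d_win = float(
            np.min(np.linalg.norm(ca[window] - centroids[r], axis=1))
        )
        if d_src < 12.0 or d_win < 10.0:
            continue
        score = abs(deg - target_deg)
        if best is None or score < best[0]:
            best = (score, r)
    return best[1] if best else None


def degree_matched_off_pathway(
    net: ElasticNetwork,
    pathway: list[int],
    source_group: str = "HEM",
    source_shell: float = 8.0,
) -> list[int]:
    """For each pathway residue pick the closest-degree off-pathway residue
    (without replacement), for fluctuation-contrast controls.

    Residues that are coupled to the heated system by construction are
    excluded from the control pool: those whose readout node lies within
    ``source_shell`` of a source node (heated trivially by proximity —
    the "proximal" shell in the structure-mapping sense) and those whose
    side-chain node shares a direct spring with a pathway side-chain
    node (first coordination shell of the conduit). Sequence neighbours
    of pathway residues are excluded too.
    """
    sc_degree = {}
    for r in range(net.n_residues):
        s = net.sidechain_node[r]
        if s < 0:
            continue
        sc_degree[r] = int(((net.springs_i == s) | (net.springs_j == s)).sum())
    excluded = set(pathway) | {p + d for p in pathway for d in (-1, 1)}
    if source_group in net.hetero_nodes:
        src = net.coords[net.hetero_nodes[source_group]]
        for r in list(sc_degree):
            node = net.readout_node(r)
            if np.min(np.linalg.norm(src - net.coords[node], axis=1)) <= source_shell:
                excluded.add(r)
    conduit_nodes = {int(net.sidechain_node[p]) for p in pathway
                     if net.sidechain_node[p] >= 0}
    partners: dict[int, set[int]] = {}
    for i, j in zip(net.springs_i, net.springs_j):
        partners.setdefault(int(i), set()).add(int(j))
        partners.setdefault(int(j), set()).add(int(i))
    for r in list(sc_degree):
        s = int(net.sidechain_node[r])
        if partners.get(s, set()) & conduit_nodes:
            excluded.add(r)
    pool = {r: d for r, d in sc_degree.items() if r not in excluded}
    controls = []
    for p in pathway:
        if p not in sc_degree or not pool:
            continue
        r = min(pool, key=lambda q: (abs(pool[q] - sc_degree[p]), q))
        controls.append(r)
        del pool[r]
    return controls


def apply_planted_stiffening(
    net: ElasticNetwork, truth: dict, factor: float | None = None
) -> ElasticNetwork:
    """Re-apply a ground truth's conduit stiffening to a rebuilt network.

    PDB files carry geometry only, so an elastic network rebuilt from a
    written synthetic structure lacks the planted stiff springs; this
    restores them (consecutive conduit links, source entry, terminal to
    window) from the generator's truth record.
    """
    factor = truth.get("pathway_stiffness", 5.0) if factor is None else factor
    pw = [net.residue_index(r) for r in truth["pathway"]]
    pairs = [
        (int(net.sidechain_node[a]), int(net.sidechain_node[b]))
        for a, b in zip(pw, pw[1:])
    ]
    start_sc = int(net.sidechain_node[pw[0]])
    source = truth.get("source_group", "HEM")
    if source in net.hetero_nodes:
        pairs += [(int(h), start_sc) for h in net.hetero_nodes[source]]
    term_sc = int(net.sidechain_node[pw[-1]])
    spring_set = {
        (int(i), int(j)) for i, j in zip(net.springs_i, net.springs_j)
    }
    for rid in truth.get("target_window", []):
        s = int(net.sidechain_node[net.residue_index(rid)])
        if s < 0 or s == term_sc:
            continue
        pair = (min(term_sc, s), max(term_sc, s))
        if pair in spring_set:
            pairs.append(pair)
    return stiffen_springs(net, pairs, factor)


def gen_linear_chain(n_residues: int, spacing: float = 3.8) -> StructureModel:
    """Straight glycine chain along x — one backbone node per residue."""
    residues = [
        Residue(
            number=i + 1,
            name="GLY",
            ca=(i * spacing, 0.0, 0.0),
            sidechain_centroid=None,
            sidechain_count=0,
        )
        for i in range(n_residues)
    ]
    return StructureModel(chains=[Chain(id="A", residues=residues)])


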