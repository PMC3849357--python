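"""Self-validation suite: the package's core claims, each computable
from scratch with synthetic data.

Every function here regenerates its own inputs from a seed, runs the
relevant pipeline stage, and returns summary statistics:

* the maximal-subtree decomposition agrees with exhaustive clade
  enumeration;
* planted co-evolving networks are recovered with high precision and
  recall at the generators' default noise level;
* neighbor joining is exact on additive distances;
* the Langevin thermostats hold their setpoints and produce no spurious
  ΔRMSF signal;
* heat injected at one end of a chain decays monotonically with
  distance;
* ΔRMSF separates a planted stiff pathway from degree-matched controls,
  and severing the pathway is flagged by the mutant screen while an
  off-pathway control is not;
* the full pipeline is byte-reproducible from its seed.

These are the checks behind ``scripts/acceptance.py`` and the
acceptance test suite.
"""

from __future__ import annotations

import tempfile
from dataclasses import replace
from pathlib import Path

import dendropy
import numpy as np
from scipy.stats import spearmanr

from .atd import (
    ATDProtocol,
    atd_run,
    build_enm,
    delta_rmsf,
    discrimination_auc,
    mutant_screen,
    trajectory_rmsf,
    _node_rmsf,
)
from .coevolution import (
    ResidueClassScheme,
    decompose_position,
)
from .datatypes import AMINO_ACIDS, Alignment, SeqRecord
from .phylo import DistanceMatrix, build_nj_tree
from .pipeline import full_pipeline, load_config, run_coevolution
from .synthetic import (
    StructGenSpec,
    default_msa_spec,
    degree_matched_off_pathway,
    evolve_msa,
    gen_linear_chain,
    gen_structure,
    gen_tree,
)

#: Screen/transport protocol: weak cold-bath coupling extends the heat
#: propagation length; heated runs are replicated at moderate length and
#: compared to a shared four-times-longer reference (see atd module).
TRANSPORT_PROTOCOL = dict(gamma_cold=0.05, production_steps=60_000)


# ----------------------------------------------------------------------
# 1. decomposition vs exhaustive oracle
# ----------------------------------------------------------------------

def oracle_decompose(tree, aln, pos, scheme) -> set[frozenset]:
    """Enumerate every clade, test conservation, keep the maximal ones."""
    cls = dict(zip(aln.ids, scheme.classes_of(aln.column(pos))))
    clades = []
    for node in tree.preorder_node_iter():
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        parent = node.parent_node
        parent_leaves = (
            None if parent is None
            else frozenset(lf.taxon.label for lf in parent.leaf_iter())
        )
        clades.append((leaves, parent_leaves))
    conserved = {
        leaves for leaves, _ in clades if len({cls[l] for l in leaves}) == 1
    }
    return {
        leaves
        for leaves, parent in clades
        if leaves in conserved and (parent is None or parent not in conserved)
    }


def mst_oracle_agreement(n_cases: int = 200, seed: int = 0) -> float:
    """Fraction of random (tree <= 8 leaves, random column) cases where
    the greedy decomposition equals the exhaustive oracle."""
    rng = np.random.default_rng(seed)
    scheme = ResidueClassScheme.default()
    aas = np.array(list(AMINO_ACIDS))
    agree = 0
    for case in range(n_cases):
        n = int(rng.integers(4, 9))
        tree = gen_tree(n, seed=int(rng.integers(2 ** 31)))
        ids = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        column = "".join(aas[rng.integers(0, 20, size=n)])
        aln = Alignment([SeqRecord(i, c) for i, c in zip(ids, column)])
        got = set(decompose_position(tree, aln, 0, scheme).blocks)
        agree += got == oracle_decompose(tree, aln, 0, scheme)
    return agree / n_cases


# ----------------------------------------------------------------------
# 2. planted-network recovery
# ----------------------------------------------------------------------

def planted_network_recovery(
    n_seeds: int = 10, seed: int = 0, threshold: float = 0.8
) -> dict:
    """Recover two planted 8-position networks per seed; a seed passes
    iff each planted network's best-matching recovered network has
    precision and recall >= ``threshold``."""
    passed = 0
    details = []
    for k in range(n_seeds):
        s = seed * 1000 + k
        tree = gen_tree(64, seed=s)
        spec = default_msa_spec(tree, seed=s)
        aln, truth = evolve_msa(tree, spec)
        run = run_coevolution(aln, tree=tree)
        ok = True
        per_net = []
        for net_t in truth["networks"]:
            tpos = {p + 1 for p in net_t["positions"]}
            best = (0.0, 0.0, 0.0)
            for net in run.clusters.networks:
                got = set(net.positions)
                tp = len(got & tpos)
                if tp:
                    p, r = tp / len(got), tp / len(tpos)
                    f = 2 * p * r / (p + r)
                    if f > best[2]:
                        best = (p, r, f)
            per_net.append((best[0], best[1]))
            if best[0] < threshold or best[1] < threshold:
                ok = False
        passed += ok
        details.append(per_net)
    return {"passed": passed, "n_seeds": n_seeds, "details": details}


# ----------------------------------------------------------------------
# 3. NJ exactness on additive distances
# ----------------------------------------------------------------------

def _patristic(tree: dendropy.Tree) -> dict[frozenset, float]:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    return {
        frozenset((a.label, b.label)): pdm.patristic_distance(a, b)
        for i, a in enumerate(taxa)
        for b in taxa[i + 1:]
    }


def nj_additive_recovery(n_trees: int = 20, seed: int = 0) -> dict:
    """Reconstruct random trees from their additive distance matrices."""
    rng = np.random.default_rng(seed)
    exact = 0
    max_branch_error = 0.0
    total_rf = 0
    for k in range(n_trees):
        n = int(rng.integers(5, 13))
        true_tree = gen_tree(n, seed=int(rng.integers(2 ** 31)),
                             mean_branch_length=0.5)
        dists = _patristic(true_tree)
        labels = sorted({l for pair in dists for l in pair})
        m = np.zeros((len(labels), len(labels)))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j:
                    m[i, j] = dists[frozenset((a, b))]
        nj = build_nj_tree(DistanceMatrix(labels=labels, values=m))
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=true_tree.as_string(schema="newick"),
                               schema="newick", taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=nj.as_string(schema="newick"),
                               schema="newick", taxon_namespace=tns)
        for t in (t1, t2):
            t.is_rooted = False
            t.update_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
        total_rf += rf
        nj_dists = _patristic(nj)
        err = max(abs(nj_dists[k2] - v) for k2, v in dists.items())
        max_branch_error = max(max_branch_error, err)
        exact += rf == 0 and err < 1e-9
    return {
        "n_trees": n_trees,
        "exact": exact,
        "total_rf": total_rf,
        "max_branch_error": max_branch_error,
    }


# ----------------------------------------------------------------------
# 4. thermostat fidelity and null ΔRMSF
# ----------------------------------------------------------------------

def thermostat_fidelity(seed: int = 0) -> dict:
    """All-cold run on the default synthetic structure: per-node kinetic
    temperature (long averaging window) and the null ΔRMSF contrast
    between independent all-cold runs."""
    model, net, truth = gen_structure(StructGenSpec(seed=seed))
    proto = ATDProtocol(production_steps=200_000, seed=seed)
    traj = atd_run(net, proto, (), seed=seed + 1)
    t = traj.kinetic_temperature
    max_dev = float(np.max(np.abs(t - proto.t_cold)) / proto.t_cold)

    # null signal: window-mean ΔRMSF between paired all-cold runs
    null_proto = ATDProtocol(seed=seed)
    win = [net.residue_index(r) for r in truth["target_window"]]
    means = []
    for rep in range(4):
        a = atd_run(net, null_proto, (), seed=seed + 10 + rep)
        b = atd_run(net, null_proto, (), seed=seed + 200 + rep)
        d = delta_rmsf(a, b).delta
        means.append(float(np.mean(d[win])))
    means = np.array(means)
    return {
        "max_temperature_deviation": max_dev,
        "mean_temperature": float(t.mean()),
        "null_window_mean": float(means.mean()),
        "null_window_sd": float(means.std(ddof=1)),
    }


# ----------------------------------------------------------------------
# 5. heat-distance monotonicity on a chain
# ----------------------------------------------------------------------

def chain_monotonicity(n_seeds: int = 10, seed: int = 0) -> dict:
    """30-node chain heated at one end: smoothed ΔRMSF must decrease
    with chain index (Spearman rho < -0.8)."""
    net = build_enm(gen_linear_chain(30))
    proto = ATDProtocol(production_steps=100_000, seed=seed)
    passed = 0
    rhos = []
    for k in range(n_seeds):
        deltas = []
        for rep in range(2):
            s = seed * 100 + k * 2 + rep
            hot = atd_run(net, proto, [0], seed=s)
            ref = atd_run(net, proto, (), seed=s + 500_009)
            b = int(0.2 * hot.n_frames)
            deltas.append(
                _node_rmsf(hot.frames[b:]) - _node_rmsf(ref.frames[b:])
            )
        d = np.mean(deltas, axis=0)
        sm = np.convolve(d, np.ones(7) / 7, mode="valid")
        rho = float(spearmanr(sm, np.arange(len(sm))).statistic)
        rhos.append(rho)
        passed += rho < -0.8
    return {"passed": passed, "n_seeds": n_seeds, "rhos": rhos}


# ----------------------------------------------------------------------
# 6. planted-pathway discrimination and mutant screen
# ----------------------------------------------------------------------

def pathway_auc(n_seeds: int = 20, seed: int = 0) -> dict:
    """Pooled AUC of ΔRMSF for pathway vs degree-matched off-pathway
    residues over ``n_seeds`` default synthetic structures."""
    proto = ATDProtocol(seed=seed, **TRANSPORT_PROTOCOL)
    pos_all, neg_all, per_seed = [], [], []
    for k in range(n_seeds):
        s = seed * 1000 + k
        model, net, truth = gen_structure(StructGenSpec(seed=s))
        pw = [net.residue_index(r) for r in truth["pathway"]]
        ctrl = degree_matched_off_pathway(net, pw)
        ref_proto = replace(proto, production_steps=proto.production_steps * 2)
        ref = atd_run(net, ref_proto, (), seed=s + 500_009)
        rmsf_ref = trajectory_rmsf(ref)
        deltas = []
        for rep in range(2):
            hot = atd_run(net, proto, net.hetero_nodes["HEM"], seed=s * 10 + rep)
            deltas.append(trajectory_rmsf(hot) - rmsf_ref)
        d = np.mean(deltas, axis=0)
        pos_all += list(d[pw])
        neg_all += list(d[ctrl])
        per_seed.append(float(discrimination_auc(d[pw], d[ctrl])))
    return {
        "auc": float(discrimination_auc(np.array(pos_all), np.array(neg_all))),
        "per_seed": per_seed,
        "n_seeds": n_seeds,
    }


def mutant_screen_validation(n_seeds: int = 10, seed: int = 0) -> dict:
    """Severing the planted pathway must significantly reduce the target
    window's ΔRMSF; an off-pathway control mutation must not."""
    sever_hits = 0
    control_ok = 0
    rows = []
    for k in range(n_seeds):
        s = seed * 1000 + k
        model, net, truth = gen_structure(StructGenSpec(seed=s))
        proto = ATDProtocol(seed=s * 100, **TRANSPORT_PROTOCOL)
        muts = {
            "sever": (truth["mutation_residue"], "ALA"),
            "control": (truth["control_residue"], "ALA"),
        }
        res = mutant_screen(
            net, muts, proto, "HEM", truth["target_window"], n_replicates=4
        )
        sever = res["sever"]
        ctrl = res["control"]
        sever_hit = sever.significant and sever.direction == "decrease"
        sever_hits += sever_hit
        control_ok += not ctrl.significant
        rows.append(
            {
                "seed": s,
                "sever_diff": sever.mutant.mean - sever.wt.mean,
                "sever_threshold": sever.threshold,
                "sever_significant": bool(sever.significant),
                "control_diff": ctrl.mutant.mean - ctrl.wt.mean,
                "control_significant": bool(ctrl.significant),
            }
        )
    return {
        "sever_significant_decrease": sever_hits,
        "control_non_significant": control_ok,
        "n_seeds": n_seeds,
        "rows": rows,
    }


# ----------------------------------------------------------------------
# 7. pipeline determinism
# ----------------------------------------------------------------------

def pipeline_determinism(seed: int = 0, scratch: str | Path | None = None) -> dict:
    """Run the full synthetic pipeline twice with one seed and compare
    every CSV/TSV output byte for byte."""
    config = load_config(overrides={"seed": seed})
    files = (
        "seeds.tsv", "coevolution_scores.csv", "networks.tsv",
        "annotated_networks.tsv", "delta_rmsf.csv", "peaks.tsv",
    )
    with tempfile.TemporaryDirectory(dir=scratch) as tmp:
        out1 = Path(tmp) / "run1"
        out2 = Path(tmp) / "run2"
        full_pipeline(config, out1)
        full_pipeline(config, out2)
        identical = all(
            (out1 / f).read_bytes() == (out2 / f).read_bytes() for f in files
        )
    return {"identical": bool(identical), "n_files": len(files)}
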