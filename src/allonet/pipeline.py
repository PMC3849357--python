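"""End-to-end orchestration: configuration, stage runners, file outputs.

Every tunable of every stage lives in one nested configuration tree with
the defaults below; unknown keys are rejected. Each stage runner returns
in-memory results and can write its standard CSV/TSV outputs plus a JSON
run manifest (config hash, seed, version, timestamp) to an output
directory. All randomness flows from the single top-level seed.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atd import ATDProtocol, atd_run, delta_rmsf, detect_peaks
from .coevolution import (
    ClusterResult,
    CoevolutionMatrix,
    ResidueClassScheme,
    decompose_position,
    cluster_networks,
    rank_profile,
    score_matrix,
    select_seeds,
)
from .datatypes import Alignment, StructureModel
from .errors import ConfigError
from .io_formats import write_matrix, write_table
from .phylo import build_nj_tree, filter_columns, pairwise_distance
from .structmap import SiteDefinition, align_ref_to_structure, classify_proximity
from .synthetic import (
    StructGenSpec,
    default_msa_spec,
    evolve_msa,
    gen_structure,
    gen_tree,
)

DEFAULTS: dict = {
    "seed": 0,
    "msa": {
        "n_leaves": 64,
        "n_columns": 200,
        "mu": 0.5,
        "n_networks": 2,
        "network_size": 8,
        "epsilon": 0.05,
        "edges_per_network": 6,
    },
    "filter": {"max_gap_fraction": 0.5},
    "coevolution": {
        "alpha": 2.0,
        "include_invariant": False,
        "tau": 0.9,
        "min_size": 4,
        "scheme": "physicochemical",
    },
    "structure": {
        "n_residues": 120,
        "spacing": 3.8,
        "source_size": 4,
        "pathway_stiffness": 5.0,
        "target_window": 6,
        "min_source_target": 15.0,
        "cutoff": 10.0,
        "k_default": 1.0,
    },
    "structmap": {"site_cutoff": 8.0},
    "atd": {
        "t_cold": 10.0,
        "t_hot": 300.0,
        "restraint_k": 5.0,
        "equil_rmsf": 0.05,
        "equil_steps": 2000,
        "production_steps": 20000,
        "dt": 0.01,
        "gamma_hot": 1.0,
        "gamma_cold": 0.1,
        "sample_every": 10,
        "burn_in": 0.2,
        "z_threshold": 2.0,
        "hot_group": "HEM",
    },
    "screen": {"n_replicates": 4},
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge defaults <- YAML file <- overrides; reject unknown keys."""
    config = copy.deepcopy(DEFAULTS)
    for source, name in ((path, "config file"), (overrides, "override")):
        if source is None:
            continue
        data = source
        if not isinstance(source, dict):
            data = yaml.safe_load(Path(source).read_text()) or {}
        _merge(config, data, name, [])
    return config


def _merge(base: dict, update: dict, source: str, trail: list[str]) -> None:
    for key, value in update.items():
        here = ".".join(trail + [str(key)])
        if key not in base:
            raise ConfigError(f"unknown {source} key: {here!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"{source} key {here!r} must be a mapping")
            _merge(base[key], value, source, trail + [str(key)])
        else:
            base[key] = value


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(outdir: Path, config: dict, extra: dict | None = None) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config,
        "config_hash": config_hash(config),
        "seed": config.get("seed"),
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if extra:
        manifest.update(extra)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def protocol_from_config(config: dict) -> ATDProtocol:
    a = config["atd"]
    return ATDProtocol(
        t_cold=a["t_cold"],
        t_hot=a["t_hot"],
        restraint_k=a["restraint_k"],
        equil_rmsf=a["equil_rmsf"],
        equil_steps=a["equil_steps"],
        production_steps=a["production_steps"],
        dt=a["dt"],
        gamma_hot=a["gamma_hot"],
        gamma_cold=a["gamma_cold"],
        sample_every=a["sample_every"],
        seed=config["seed"],
    )


# ----------------------------------------------------------------------
# co-evolution stage
# ----------------------------------------------------------------------

@dataclass
class CoevolutionRun:
    """All intermediate and final products of the co-evolution stage."""

    alignment: Alignment          # filtered
    kept_columns: list[int]       # original column index per filtered column
    ranks: np.ndarray
    seeds: list[int]              # filtered column indices
    seed_labels: list[int]        # reference positions (1-based)
    matrix: CoevolutionMatrix
    clusters: ClusterResult
    tree: object = None


def run_coevolution(
    aln: Alignment,
    tree=None,
    config: dict | None = None,
) -> CoevolutionRun:
    """Filter columns, build (or accept) a tree, rank, score, cluster."""
    config = config or load_config()
    scheme = (
        ResidueClassScheme.identity()
        if config["coevolution"]["scheme"] == "identity"
        else ResidueClassScheme.default()
    )
    filtered, kept = filter_columns(aln, config["filter"]["max_gap_fraction"])
    if tree is None:
        tree = build_nj_tree(pairwise_distance(filtered))
    ranks = rank_profile(tree, filtered, scheme)
    seeds = select_seeds(
        ranks,
        alpha=config["coevolution"]["alpha"],
        include_invariant=config["coevolution"]["include_invariant"],
    )
    ref_pos = aln.ref_positions()
    labels = []
    for j in seeds:
        orig = kept[j]
        labels.append(ref_pos[orig] if ref_pos[orig] is not None else -(orig + 1))
    decomps = [decompose_position(tree, filtered, j, scheme) for j in seeds]
    matrix = score_matrix(decomps, positions=labels)
    clusters = cluster_networks(
        matrix,
        tau=config["coevolution"]["tau"],
        min_size=config["coevolution"]["min_size"],
    )
    return CoevolutionRun(
        alignment=filtered,
        kept_columns=kept,
        ranks=ranks,
        seeds=seeds,
        seed_labels=labels,
        matrix=matrix,
        clusters=clusters,
        tree=tree,
    )


def write_coevolution_outputs(run: CoevolutionRun, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed_rows = pd.DataFrame(
        {
            "position": run.seed_labels,
            "column_index": [run.kept_columns[j] for j in run.seeds],
            "rank": [int(run.ranks[j]) for j in run.seeds],
        }
    )
    write_table(seed_rows, outdir / "seeds.tsv")
    write_matrix(
        run.matrix.scores,
        outdir / "coevolution_scores.csv",
        labels=[str(p) for p in run.matrix.positions],
        index_labels=[str(p) for p in run.matrix.positions],
    )
    order = [str(run.matrix.positions[i]) for i in run.clusters.leaf_order]
    (outdir / "heatmap_order.txt").write_text("\n".join(order) + "\n")
    rows = [
        {"network": net.name, "position": pos,
         "mean_internal_score": net.mean_internal_score}
        for net in run.clusters.networks
        for pos in net.positions
    ]
    write_table(
        pd.DataFrame(rows, columns=["network", "position", "mean_internal_score"]),
        outdir / "networks.tsv",
    )


# ----------------------------------------------------------------------
# structure mapping stage
# ----------------------------------------------------------------------

def run_structmap(
    run: CoevolutionRun,
    model: StructureModel,
    site: SiteDefinition,
    ref_seq: str | None = None,
) -> tuple[pd.DataFrame, list]:
    """Map every network onto the structure and classify proximity."""
    ref_seq = ref_seq or run.alignment.ref_sequence()
    mapping = align_ref_to_structure(ref_seq, model)
    rows = []
    reports = []
    for net in run.clusters.networks:
        report = classify_proximity(net, mapping, model, site)
        reports.append(report)
        for pos in sorted(net.positions):
            rows.append(
                {
                    "network": net.name,
                    "position": pos,
                    "chain": mapping.chain_id,
                    "residue": mapping.pairs.get(pos, ""),
                    "label": report.labels[pos],
                    "min_site_distance": report.min_distance.get(pos, -1.0),
                }
            )
    columns = ["network", "position", "chain", "residue", "label",
               "min_site_distance"]
    return pd.DataFrame(rows, columns=columns), reports


# ----------------------------------------------------------------------
# ATD stage
# ----------------------------------------------------------------------

@dataclass
class ATDStage:
    profile: object               # DeltaRMSFProfile
    peaks: list[str]              # residue ids
    kinetic_temperature_hot: np.ndarray
    kinetic_temperature_ref: np.ndarray


def run_atd_stage(net, config: dict, hot_group: str | None = None) -> ATDStage:
    protocol = protocol_from_config(config)
    hot_group = hot_group or config["atd"]["hot_group"]
    hot_nodes = net.hetero_nodes[hot_group]
    hot = atd_run(net, protocol, hot_nodes, seed=config["seed"])
    ref = atd_run(net, protocol, (), seed=config["seed"] + 500_009)
    profile = delta_rmsf(hot, ref, config["atd"]["burn_in"])
    peak_idx = detect_peaks(profile.delta, config["atd"]["z_threshold"])
    return ATDStage(
        profile=profile,
        peaks=[profile.residue_ids[i] for i in peak_idx],
        kinetic_temperature_hot=hot.kinetic_temperature,
        kinetic_temperature_ref=ref.kinetic_temperature,
    )


def write_atd_outputs(stage: ATDStage, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prof = stage.profile
    df = pd.DataFrame(
        {
            "residue": prof.residue_ids,
            "rmsf_hot": prof.rmsf_hot,
            "rmsf_ref": prof.rmsf_ref,
            "delta_rmsf": prof.delta,
        }
    )
    df.to_csv(outdir / "delta_rmsf.csv", index=False, float_format="%.10g")
    write_table(
        pd.DataFrame({"residue": stage.peaks}), outdir / "peaks.tsv"
    )


def write_screen_outputs(results: dict, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    summary = {}
    for label, cmp_ in results.items():
        rows.append(
            {
                "construct": label,
                "wt_mean": cmp_.wt.mean,
                "wt_sd": cmp_.wt.sd,
                "mut_mean": cmp_.mutant.mean,
                "mut_sd": cmp_.mutant.sd,
                "threshold": cmp_.threshold,
                "significant": cmp_.significant,
                "direction": cmp_.direction,
            }
        )
        summary[label] = {
            "significant": bool(cmp_.significant),
            "direction": cmp_.direction,
            "wt_mean": cmp_.wt.mean,
            "mut_mean": cmp_.mutant.mean,
            "threshold": cmp_.threshold,
        }
    write_table(pd.DataFrame(rows), outdir / "mutant_screen.tsv")
    (outdir / "mutant_screen.json").write_text(json.dumps(summary, indent=2))


# ----------------------------------------------------------------------
# full pipeline
# ----------------------------------------------------------------------

def full_pipeline(config: dict, outdir: str | Path) -> dict:
    """Synthetic end-to-end run: MSA -> networks -> structure map -> ATD.

    The synthetic structure reuses the alignment's reference sequence
    (truncated to the configured residue count) so the network-to-
    structure mapping is meaningful. Returns a summary dict; all
    standard outputs plus a manifest are written to ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config["seed"]
    m = config["msa"]
    tree = gen_tree(m["n_leaves"], seed=seed)
    spec = default_msa_spec(
        tree,
        seed=seed,
        n_networks=m["n_networks"],
        network_size=m["network_size"],
        n_columns=m["n_columns"],
        mu=m["mu"],
        epsilon=m["epsilon"],
        edges_per_network=m["edges_per_network"],
    )
    aln, msa_truth = evolve_msa(tree, spec)
    run = run_coevolution(aln, tree=tree, config=config)
    write_coevolution_outputs(run, outdir)

    s = config["structure"]
    ref_seq = aln.ref_sequence()[: s["n_residues"]]
    struct_spec = StructGenSpec(
        n_residues=len(ref_seq),
        spacing=s["spacing"],
        source_size=s["source_size"],
        pathway_stiffness=s["pathway_stiffness"],
        target_window=s["target_window"],
        min_source_target=s["min_source_target"],
        cutoff=s["cutoff"],
        k_default=s["k_default"],
        sequence=ref_seq,
        seed=seed,
    )
    model, net, struct_truth = gen_structure(struct_spec)
    site = SiteDefinition(
        hetero_name=config["atd"]["hot_group"],
        cutoff=config["structmap"]["site_cutoff"],
    )
    annotated, _ = run_structmap(run, model, site, ref_seq=ref_seq)
    write_table(annotated, outdir / "annotated_networks.tsv")

    stage = run_atd_stage(net, config)
    write_atd_outputs(stage, outdir)

    write_manifest(
        outdir,
        config,
        extra={
            "msa_truth": msa_truth,
            "structure_truth": struct_truth,
            "n_networks_found": len(run.clusters.networks),
            "n_peaks": len(stage.peaks),
        },
    )
    return {
        "networks": run.clusters.networks,
        "peaks": stage.peaks,
        "msa_truth": msa_truth,
        "structure_truth": struct_truth,
    }
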