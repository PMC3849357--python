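"""Mapping residue networks onto structures.

A network lives in 1-based positions of the ungapped reference sequence.
To interpret it structurally we align that sequence globally against a
chain of the structure, carry each position to its structure residue,
and then label every network member as *proximal* to a site of interest
(within a distance cutoff of any site node) or *distal* — the distal
members being the candidate allosteric residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from scipy.spatial.distance import cdist

from .coevolution import ResidueNetwork
from .datatypes import StructureModel
from .errors import SiteError
from .io_formats import BACKBONE_ATOMS  # noqa: F401  (re-export convenience)

LOW_IDENTITY_THRESHOLD = 0.30


@dataclass
class PositionMapping:
    """Reference position (1-based) -> (chain id, residue key)."""

    chain_id: str
    pairs: dict[int, str]  # position -> residue key within the chain
    unmapped: list[int]
    identity: float
    low_confidence: bool = False


@dataclass
class SiteDefinition:
    """A site of interest: a hetero-group name or an explicit residue list.

    ``cutoff`` is the node-to-node proximity threshold in Angstrom
    (CA / side-chain-centroid representation).
    """

    hetero_name: str | None = None
    residues: list[str] = field(default_factory=list)  # residue keys
    cutoff: float = 8.0

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not self.hetero_name and not self.residues:
            raise ValueError("site definition must name a hetero group or residues")


def align_ref_to_structure(
    ref_seq: str,
    model: StructureModel,
    chain_id: str | None = None,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> PositionMapping:
    """Globally align the reference sequence to a chain's sequence.

    Mapped pairs are the aligned (identical or substituted) positions;
    reference positions opposite a structure gap are unmapped. A mapping
    with alignment identity below 30% is flagged low-confidence and a
    warning is emitted.
    """
    if not ref_seq:
        raise ValueError("empty reference sequence")
    chain = model.chains[0] if chain_id is None else model.chain(chain_id)
    struct_seq = model.chain_sequence(chain.id)

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    alignment = aligner.align(ref_seq, struct_seq)[0]

    pairs: dict[int, str] = {}
    matches = 0
    aligned_pairs = 0
    for (r0, r1), (s0, s1) in zip(*alignment.aligned):
        for off in range(r1 - r0):
            ref_pos = r0 + off + 1  # 1-based
            res = chain.residues[s0 + off]
            pairs[ref_pos] = res.key
            aligned_pairs += 1
            if ref_seq[r0 + off] == struct_seq[s0 + off]:
                matches += 1
    unmapped = [p for p in range(1, len(ref_seq) + 1) if p not in pairs]
    identity = matches / aligned_pairs if aligned_pairs else 0.0
    low = identity < LOW_IDENTITY_THRESHOLD
    if low:
        warnings.warn(
            f"reference-to-structure alignment identity {identity:.1%} "
            "is below 30%; mapping is low-confidence",
            stacklevel=2,
        )
    return PositionMapping(
        chain_id=chain.id,
        pairs=pairs,
        unmapped=unmapped,
        identity=identity,
        low_confidence=low,
    )


def _site_coords(model: StructureModel, site: SiteDefinition) -> np.ndarray:
    coords: list[np.ndarray] = []
    if site.hetero_name:
        try:
            group = model.hetero(site.hetero_name)
        except KeyError:
            raise SiteError(
                f"hetero group {site.hetero_name!r} not found in structure"
            ) from None
        coords.extend(np.asarray(group.coords, dtype=float))
    if site.residues:
        wanted = set(site.residues)
        found = set()
        for _, res in model.residues():
            if res.key in wanted:
                found.add(res.key)
                coords.append(np.asarray(res.ca, dtype=float))
                if res.sidechain_centroid is not None:
                    coords.append(np.asarray(res.sidechain_centroid, dtype=float))
        missing = wanted - found
        if missing:
            raise SiteError(f"site residues not in structure: {sorted(missing)}")
    return np.array(coords, dtype=float)


@dataclass
class ProximityReport:
    """Per-position proximity labels for one network."""

    network: str
    labels: dict[int, str]  # position -> proximal | distal | unmapped
    min_distance: dict[int, float]  # Angstrom; only for mapped positions
    cutoff: float

    def counts(self) -> dict[str, int]:
        out = {"proximal": 0, "distal": 0, "unmapped": 0}
        for lab in self.labels.values():
            out[lab] += 1
        return out


def classify_proximity(
    network: ResidueNetwork,
    mapping: PositionMapping,
    model: StructureModel,
    site: SiteDefinition,
) -> ProximityReport:
    """Label each network position proximal/distal to the site.

    A residue is proximal iff the minimum distance from its CA or its
    side-chain centroid to any site node is at most ``site.cutoff``.
    Positions without a structure residue are labelled unmapped.
    """
    site_xyz = _site_coords(model, site)
    chain = model.chain(mapping.chain_id)
    res_by_key = {r.key: r for r in chain.residues}

    labels: dict[int, str] = {}
    min_d: dict[int, float] = {}
    for pos in sorted(network.positions):
        key = mapping.pairs.get(pos)
        if key is None or key not in res_by_key:
            labels[pos] = "unmapped"
            continue
        res = res_by_key[key]
        nodes = [np.asarray(res.ca, dtype=float)]
        if res.sidechain_centroid is not None:
            nodes.append(np.asarray(res.sidechain_centroid, dtype=float))
        d = float(cdist(np.array(nodes), site_xyz).min())
        min_d[pos] = d
        labels[pos] = "proximal" if d <= site.cutoff else "distal"
    return ProximityReport(
        network=network.name, labels=labels, min_distance=min_d, cutoff=site.cutoff
    )
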