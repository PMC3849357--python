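"""Sequence-to-structure mapping and proximal/distal classification."""

import numpy as np
import pytest

from allonet.coevolution import ResidueNetwork
from allonet.datatypes import (
    Chain,
    HeteroGroup,
    ONE_TO_THREE,
    Residue,
    StructureModel,
)
from allonet.errors import SiteError
from allonet.structmap import (
    PositionMapping,
    SiteDefinition,
    align_ref_to_structure,
    classify_proximity,
)


def _chain_model(seq, start=1, hetero=None):
    residues = [
        Residue(
            number=start + i,
            name=ONE_TO_THREE[ch],
            ca=(3.8 * i, 0.0, 0.0),
            sidechain_centroid=None if ch == "G" else (3.8 * i, 1.5, 0.0),
            sidechain_count=0 if ch == "G" else 1,
        )
        for i, ch in enumerate(seq)
    ]
    groups = [] if hetero is None else [hetero]
    return StructureModel(chains=[Chain(id="A", residues=residues)],
                          hetero_groups=groups)


# ----------------------------------------------------------------------
# alignment of reference to structure
# ----------------------------------------------------------------------

def test_identity_mapping():
    seq = "ACDEFGHIKL"
    model = _chain_model(seq)
    mapping = align_ref_to_structure(seq, model)
    assert mapping.unmapped == []
    assert mapping.identity == pytest.approx(1.0)
    assert mapping.pairs == {i + 1: str(i + 1) for i in range(len(seq))}


def test_structure_missing_internal_residues():
    ref = "ACDEFGHIKLMNPQRSTVWY"  # 20 residues
    # structure lacks residues 5-7 (F, G, H)
    struct_seq = ref[:4] + ref[7:]
    residues = []
    for i, ch in enumerate(struct_seq):
        number = i + 1 if i < 4 else i + 4  # preserve original numbering
        residues.append(
            Residue(number=number, name=ONE_TO_THREE[ch], ca=(3.8 * i, 0, 0),
                    sidechain_centroid=(3.8 * i, 1.5, 0), sidechain_count=1)
        )
    model = StructureModel(chains=[Chain(id="A", residues=residues)])
    mapping = align_ref_to_structure(ref, model)
    assert mapping.unmapped == [5, 6, 7]
    assert mapping.pairs[4] == "4"
    assert mapping.pairs[8] == "8"
    assert mapping.pairs[20] == "20"


def test_low_identity_warns():
    ref = "AAAAAAAAAA"
    model = _chain_model("WWWWWWWWWW")
    with pytest.warns(UserWarning, match="low-confidence"):
        mapping = align_ref_to_structure(ref, model)
    assert mapping.low_confidence


# ----------------------------------------------------------------------
# proximity classification
# ----------------------------------------------------------------------

def _site_at(xyz, cutoff=8.0):
    return (
        HeteroGroup(name="HEM", coords=np.array([xyz])),
        SiteDefinition(hetero_name="HEM", cutoff=cutoff),
    )


def test_proximal_and_distal_labels():
    seq = "ACDEFCHIKL"
    hetero, site = _site_at((0.0, -3.0, 0.0))  # 3 A from residue 1 CA
    model = _chain_model(seq, hetero=hetero)
    mapping = align_ref_to_structure(seq, model)
    net = ResidueNetwork(name="n", positions=[1, 10], mean_internal_score=1.0)
    report = classify_proximity(net, mapping, model, site)
    assert report.labels[1] == "proximal"
    assert report.labels[10] == "distal"  # 34 A away
    assert report.min_distance[1] == pytest.approx(3.0)


def test_unmapped_positions_labelled():
    seq = "ACDEF"
    hetero, site = _site_at((0, 3, 0))
    model = _chain_model(seq, hetero=hetero)
    mapping = PositionMapping(chain_id="A", pairs={1: "1"}, unmapped=[2, 3, 4, 5],
                              identity=1.0)
    net = ResidueNetwork(name="n", positions=[1, 3], mean_internal_score=1.0)
    report = classify_proximity(net, mapping, model, site)
    assert report.labels == {1: "proximal", 3: "unmapped"}
    counts = report.counts()
    assert counts["proximal"] == 1 and counts["unmapped"] == 1


def test_labels_cover_network_exactly_once():
    seq = "ACDEFCHIKL"
    hetero, site = _site_at((0, 3, 0))
    model = _chain_model(seq, hetero=hetero)
    mapping = align_ref_to_structure(seq, model)
    net = ResidueNetwork(name="n", positions=list(range(1, 11)),
                         mean_internal_score=1.0)
    report = classify_proximity(net, mapping, model, site)
    assert set(report.labels) == set(net.positions)


def test_missing_site_raises():
    seq = "ACDEF"
    model = _chain_model(seq)
    mapping = align_ref_to_structure(seq, model)
    net = ResidueNetwork(name="n", positions=[1], mean_internal_score=1.0)
    with pytest.raises(SiteError):
        classify_proximity(net, mapping, model,
                           SiteDefinition(hetero_name="HEM"))


def test_labels_invariant_under_rigid_motion(rng):
    from scipy.spatial.transform import Rotation

    seq = "ACDEFCHIKLMNPQRSTVWY"
    hetero, site = _site_at((5.0, 4.0, 1.0))
    model = _chain_model(seq, hetero=hetero)
    mapping = align_ref_to_structure(seq, model)
    net = ResidueNetwork(name="n", positions=list(range(1, 21)),
                         mean_internal_score=1.0)
    ref_report = classify_proximity(net, mapping, model, site)

    R = Rotation.random(random_state=7).as_matrix()
    t = np.array([11.0, -3.0, 8.0])

    def move(xyz):
        return tuple(R @ np.asarray(xyz) + t)

    moved = StructureModel(
        chains=[
            Chain(
                id="A",
                residues=[
                    Residue(
                        number=r.number, name=r.name, ca=move(r.ca),
                        sidechain_centroid=(
                            None if r.sidechain_centroid is None
                            else move(r.sidechain_centroid)
                        ),
                        sidechain_count=r.sidechain_count,
                    )
                    for r in model.chains[0].residues
                ],
            )
        ],
        hetero_groups=[
            HeteroGroup(name="HEM", coords=(hetero.coords @ R.T) + t)
        ],
    )
    moved_report = classify_proximity(net, mapping, moved, site)
    assert moved_report.labels == ref_report.labels
    for pos, d in ref_report.min_distance.items():
        assert moved_report.min_distance[pos] == pytest.approx(d, abs=1e-9)


def test_proximity_matches_brute_force_distances():
    from allonet.synthetic import gen_structure, StructGenSpec

    model, _, _ = gen_structure(StructGenSpec(n_residues=50, seed=3))
    seq = model.chain_sequence("A")
    mapping = align_ref_to_structure(seq, model)
    site = SiteDefinition(hetero_name="HEM", cutoff=8.0)
    net = ResidueNetwork(name="n", positions=list(range(1, 51)),
                         mean_internal_score=1.0)
    report = classify_proximity(net, mapping, model, site)
    hem = model.hetero("HEM").coords
    for res in model.chains[0].residues:
        nodes = [np.asarray(res.ca)]
        if res.sidechain_centroid is not None:
            nodes.append(np.asarray(res.sidechain_centroid))
        d = min(np.linalg.norm(n - h) for n in nodes for h in hem)
        expected = "proximal" if d <= 8.0 else "distal"
        assert report.labels[res.number] == expected
        assert report.min_distance[res.number] == pytest.approx(d)
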