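"""Elastic-network construction, Langevin thermostats, RMSF readout,
peak detection, and the mutation model.

Simulation-heavy statistical checks (thermostat fidelity at scale, heat
transport, pathway discrimination) live in the acceptance suite; here the
runs are short and assert mechanics and small-system physics.
"""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from allonet.atd import (
    ATDProtocol,
    apply_mutation,
    atd_run,
    build_enm,
    delta_rmsf,
    detect_peaks,
    discrimination_auc,
    stiffen_springs,
    surface_nodes,
    trajectory_rmsf,
    _node_rmsf,
)
from allonet.datatypes import Chain, Residue, StructureModel
from allonet.errors import ConnectivityError, DataError
from allonet.synthetic import StructGenSpec, gen_linear_chain, gen_structure


def _fast_protocol(**kw):
    kw.setdefault("equil_steps", 500)
    kw.setdefault("production_steps", 4000)
    return ATDProtocol(**kw)


# ----------------------------------------------------------------------
# network construction
# ----------------------------------------------------------------------

def test_build_enm_three_residue_chain():
    model = gen_linear_chain(3)
    net = build_enm(model, cutoff=10.0)
    assert net.n_nodes == 3
    bonds = set(zip(net.springs_i.tolist(), net.springs_j.tolist()))
    assert (0, 1) in bonds and (1, 2) in bonds
    # consecutive backbone springs are stiffened
    for s in range(len(net.springs_i)):
        i, j = net.springs_i[s], net.springs_j[s]
        if j - i == 1:
            assert net.springs_k[s] == pytest.approx(10.0)


def test_build_enm_disconnected_raises():
    model = gen_linear_chain(4, spacing=3.8)
    # a cutoff below the non-bonded spacing still keeps bonded neighbors,
    # so break connectivity with two far-apart chains instead
    res = [
        Residue(number=1, name="GLY", ca=(0, 0, 0)),
        Residue(number=2, name="GLY", ca=(500, 0, 0)),
    ]
    model = StructureModel(chains=[Chain(id="A", residues=res)])
    # consecutive backbone always bonded, so force disconnection via two chains
    model = StructureModel(
        chains=[
            Chain(id="A", residues=[Residue(number=1, name="GLY", ca=(0, 0, 0))]),
            Chain(id="B", residues=[Residue(number=1, name="GLY", ca=(500, 0, 0))]),
        ]
    )
    with pytest.raises(ConnectivityError):
        build_enm(model, cutoff=10.0)


def test_spring_list_matches_all_pairs_scan():
    model, _, _ = gen_structure(StructGenSpec(n_residues=50, seed=1))
    net = build_enm(model, cutoff=10.0)
    d = squareform(pdist(net.coords))
    got = set(zip(net.springs_i.tolist(), net.springs_j.tolist()))
    expected = {
        (i, j)
        for i in range(net.n_nodes)
        for j in range(i + 1, net.n_nodes)
        if d[i, j] <= 10.0
    }
    # bonded pairs may exceed the cutoff; all cutoff pairs must be present
    assert expected <= got
    extra = got - expected
    backbone = set(net.backbone_node.tolist())
    for i, j in extra:
        assert i in backbone and j in backbone  # only bonded backbone pairs


def test_sidechain_mass_from_residue_name():
    res = [
        Residue(number=1, name="TRP", ca=(0, 0, 0),
                sidechain_centroid=(0, 2, 0), sidechain_count=1),
        Residue(number=2, name="ALA", ca=(3.8, 0, 0),
                sidechain_centroid=(3.8, 2, 0), sidechain_count=1),
    ]
    net = build_enm(StructureModel(chains=[Chain(id="A", residues=res)]))
    assert net.masses[net.sidechain_node[0]] == 10.0
    assert net.masses[net.sidechain_node[1]] == 1.0


def test_surface_nodes_extended_chain_all_surface():
    net = build_enm(gen_linear_chain(30))
    surf = surface_nodes(net, neighbor_radius=10.0, density_threshold=10)
    assert surf.all()


def test_surface_nodes_match_recount():
    model, _, _ = gen_structure(StructGenSpec(n_residues=60, seed=2))
    net = build_enm(model)
    surf = surface_nodes(net, neighbor_radius=10.0)
    d = squareform(pdist(net.coords))
    counts = (d <= 10.0).sum(axis=1) - 1
    threshold = np.percentile(counts.astype(float), 40.0)
    np.testing.assert_array_equal(surf, counts < threshold)


def test_stiffen_springs_only_targets():
    net = build_enm(gen_linear_chain(5))
    out = stiffen_springs(net, [(0, 1)], 5.0)
    for s in range(len(out.springs_i)):
        pair = (out.springs_i[s], out.springs_j[s])
        factor = out.springs_k[s] / net.springs_k[s]
        assert factor == pytest.approx(5.0 if pair == (0, 1) else 1.0)


# ----------------------------------------------------------------------
# dynamics
# ----------------------------------------------------------------------

def test_identical_seed_identical_trajectory():
    net = build_enm(gen_linear_chain(10))
    proto = _fast_protocol()
    t1 = atd_run(net, proto, [0], seed=42)
    t2 = atd_run(net, proto, [0], seed=42)
    np.testing.assert_array_equal(t1.frames, t2.frames)
    np.testing.assert_array_equal(t1.kinetic_temperature, t2.kinetic_temperature)


def test_all_cold_run_stays_near_t_cold():
    net = build_enm(gen_linear_chain(10))
    proto = ATDProtocol(equil_steps=1000, production_steps=40000)
    traj = atd_run(net, proto, (), seed=3)
    mean_t = traj.kinetic_temperature.mean()
    assert abs(mean_t - proto.t_cold) / proto.t_cold < 0.2


def test_heated_node_approaches_t_hot():
    # two nodes joined by one spring; node 0 heated
    res = [
        Residue(number=1, name="GLY", ca=(0.0, 0.0, 0.0)),
        Residue(number=2, name="GLY", ca=(3.8, 0.0, 0.0)),
    ]
    net = build_enm(StructureModel(chains=[Chain(id="A", residues=res)]))
    net.restrained[:] = True  # pin against drift; hot node unpinned at run time
    proto = ATDProtocol(equil_steps=1000, production_steps=60000)
    traj = atd_run(net, proto, [0], seed=5)
    assert abs(traj.kinetic_temperature[0] - proto.t_hot) / proto.t_hot < 0.2


def test_hot_set_bounds_checked():
    net = build_enm(gen_linear_chain(4))
    with pytest.raises(DataError):
        atd_run(net, _fast_protocol(), [99], seed=0)


# ----------------------------------------------------------------------
# RMSF readout
# ----------------------------------------------------------------------

def test_delta_rmsf_same_trajectory_is_zero():
    net = build_enm(gen_linear_chain(6))
    traj = atd_run(net, _fast_protocol(), (), seed=1)
    prof = delta_rmsf(traj, traj)
    np.testing.assert_allclose(prof.delta, 0.0)


def test_static_trajectory_rmsf_zero():
    frames = np.ones((50, 4, 3)) * 7.0
    np.testing.assert_allclose(_node_rmsf(frames), 0.0)


def test_rmsf_matches_two_pass_variance(rng):
    frames = rng.standard_normal((100, 5, 3))
    got = _node_rmsf(frames)
    for i in range(5):
        dev = frames[:, i, :] - frames[:, i, :].mean(axis=0)
        expected = np.sqrt((dev ** 2).sum(axis=1).mean())
        assert got[i] == pytest.approx(expected, rel=1e-12)


def test_trajectory_rmsf_uses_sidechain_nodes():
    model, net, _ = gen_structure(StructGenSpec(n_residues=30, seed=4))
    traj = atd_run(net, _fast_protocol(), (), seed=2)
    prof = trajectory_rmsf(traj)
    assert prof.shape == (net.n_residues,)


# ----------------------------------------------------------------------
# peak detection
# ----------------------------------------------------------------------

def test_single_spike_detected():
    d = np.zeros(40)
    d += np.linspace(0, 0.01, 40)  # mild slope so MAD > 0
    d[17] = 1.0
    assert detect_peaks(d, z_threshold=2.0) == [17]


def test_constant_profile_no_peaks():
    assert detect_peaks(np.ones(30)) == []


def test_planted_spikes_recovered(rng):
    hits = 0
    for _ in range(100):
        d = rng.standard_normal(60)
        i, j = 14, 43
        d[i] += 5 * 1.4826  # z ~ 5 on the MAD scale
        d[j] += 5 * 1.4826
        peaks = detect_peaks(d, z_threshold=2.0)
        hits += (i in peaks) + (j in peaks)
    assert hits >= 190  # >= 95% recovery


# ----------------------------------------------------------------------
# mutations
# ----------------------------------------------------------------------

def _trp_fixture():
    res = [
        Residue(number=i + 1, name="TRP", ca=(3.8 * i, 0, 0),
                sidechain_centroid=(3.8 * i, 2.0, 0), sidechain_count=10)
        for i in range(6)
    ]
    return build_enm(StructureModel(chains=[Chain(id="A", residues=res)]))


def test_trp_to_ala_mass_and_pruning():
    net = _trp_fixture()
    out = apply_mutation(net, "3", "ALA")
    s = out.sidechain_node[2]
    assert out.masses[s] == 1.0
    incident = (out.springs_i == s) | (out.springs_j == s)
    assert (out.springs_r0[incident] <= 5.0).all()
    # oracle: surviving springs are exactly the original short ones
    s0 = net.sidechain_node[2]
    orig_incident = (net.springs_i == s0) | (net.springs_j == s0)
    assert incident.sum() == (net.springs_r0[orig_incident] <= 5.0).sum()


def test_ala_to_ala_identity():
    res = [
        Residue(number=i + 1, name="ALA", ca=(3.8 * i, 0, 0),
                sidechain_centroid=(3.8 * i, 2.0, 0), sidechain_count=1)
        for i in range(6)
    ]
    net = build_enm(StructureModel(chains=[Chain(id="A", residues=res)]))
    out = apply_mutation(net, "2", "ALA")
    np.testing.assert_array_equal(out.springs_i, net.springs_i)
    np.testing.assert_array_equal(out.springs_k, net.springs_k)
    np.testing.assert_array_equal(out.masses, net.masses)


def test_mutate_glycine_noop_warns():
    net = build_enm(gen_linear_chain(5))
    with pytest.warns(UserWarning):
        out = apply_mutation(net, "3", "ALA")
    assert out.n_nodes == net.n_nodes


def test_mutation_to_glycine_removes_node():
    net = _trp_fixture()
    out = apply_mutation(net, "3", "GLY")
    assert out.n_nodes == net.n_nodes - 1
    assert out.sidechain_node[2] == -1


def test_unknown_residue_type_rejected():
    net = _trp_fixture()
    with pytest.raises(DataError):
        apply_mutation(net, "3", "XYZ")


# ----------------------------------------------------------------------
# helpers
# ----------------------------------------------------------------------

def test_discrimination_auc_perfect_and_chance():
    assert discrimination_auc([2, 3], [0, 1]) == 1.0
    assert discrimination_auc([1, 1], [1, 1]) == 0.5
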