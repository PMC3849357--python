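"""Coarse-grained anisotropic thermal diffusion (ATD).

The protein is reduced to a two-node-per-residue elastic network: one
backbone node at the CA (unit mass) and, for non-glycine residues, one
side-chain node at the side-chain centroid with mass equal to the side
chain's heavy-atom count; hetero groups (e.g. heme) contribute one
unit-mass node per heavy atom. Nodes within a distance cutoff are
connected by harmonic springs at their initial separation.

The ATD protocol keeps the system super-cooled (10 K) while one node
group — typically the heme — is coupled to a hot bath (300 K). Heat then
propagates preferentially along stiff, well-connected routes, and the
per-residue side-chain RMSF difference between the heated run and an
all-cold reference run (ΔRMSF) reveals residues dynamically coupled to
the heated group over long distances. Backbone and surface nodes are
positionally restrained (5 energy/Å² by default) so that fluctuation
differences reflect internal couplings rather than rigid-body drift.

Dynamics are BAOAB Langevin (velocity-Verlet core with an exact
Ornstein-Uhlenbeck velocity refresh), with per-node friction and bath
temperature so the hot group and the cold remainder can be thermostatted
independently. Runs are bit-reproducible from their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .datatypes import SIDECHAIN_HEAVY_ATOMS, StructureModel
from .errors import (
    ConnectivityError,
    ConvergenceError,
    DataError,
    StabilityError,
)

#: Reduced-unit Boltzmann constant (energy per kelvin). Chosen so that the
#: cold-state (10 K) equilibrium displacement of a typical node — effective
#: stiffness of a few energy/Å² — is ~0.03 Å, comfortably inside the 0.05 Å
#: equilibration criterion, while the 300 K hot group fluctuates at a few
#: tenths of an Å.
KB = 2.0e-4


# ----------------------------------------------------------------------
# network construction
# ----------------------------------------------------------------------

@dataclass
class ElasticNetwork:
    """Elastic network over backbone, side-chain, and hetero nodes."""

    coords: np.ndarray              # (N, 3) initial positions, Å
    masses: np.ndarray              # (N,)
    node_kind: np.ndarray           # (N,) 0=backbone, 1=sidechain, 2=hetero
    residue_ids: list[str]          # per residue, in chain order
    residue_names: list[str]
    backbone_node: np.ndarray       # (n_res,) node index
    sidechain_node: np.ndarray      # (n_res,) node index or -1
    hetero_nodes: dict[str, np.ndarray] = field(default_factory=dict)
    springs_i: np.ndarray = None    # (S,)
    springs_j: np.ndarray = None    # (S,)
    springs_k: np.ndarray = None    # (S,) stiffness, energy/Å²
    springs_r0: np.ndarray = None   # (S,) rest length, Å
    restrained: np.ndarray = None   # (N,) bool

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def readout_node(self, res_idx: int) -> int:
        """Side-chain node of a residue, or its backbone node for glycine."""
        s = int(self.sidechain_node[res_idx])
        return s if s >= 0 else int(self.backbone_node[res_idx])

    def residue_index(self, residue_id: str) -> int:
        try:
            return self.residue_ids.index(residue_id)
        except ValueError:
            raise DataError(f"no residue {residue_id!r} in network") from None

    def copy(self) -> "ElasticNetwork":
        return ElasticNetwork(
            coords=self.coords.copy(),
            masses=self.masses.copy(),
            node_kind=self.node_kind.copy(),
            residue_ids=list(self.residue_ids),
            residue_names=list(self.residue_names),
            backbone_node=self.backbone_node.copy(),
            sidechain_node=self.sidechain_node.copy(),
            hetero_nodes={k: v.copy() for k, v in self.hetero_nodes.items()},
            springs_i=self.springs_i.copy(),
            springs_j=self.springs_j.copy(),
            springs_k=self.springs_k.copy(),
            springs_r0=self.springs_r0.copy(),
            restrained=self.restrained.copy(),
        )


def build_enm(
    model: StructureModel,
    cutoff: float = 10.0,
    k_default: float = 1.0,
    backbone_k_factor: float = 10.0,
    neighbor_radius: float = 10.0,
    density_threshold: float | None = None,
) -> ElasticNetwork:
    """Build the elastic network from a coarse structure model.

    Springs connect every node pair within ``cutoff``; consecutive
    backbone nodes are always bonded, at ``backbone_k_factor`` times the
    default stiffness. Side-chain masses come from the residue name's
    standard heavy-atom count, falling back to the observed atom count
    for non-standard names. The restrained set is all backbone nodes
    plus low-neighbor-density ("surface") nodes.
    """
    if cutoff <= 0 or k_default <= 0:
        raise ValueError("cutoff and k_default must be positive")
    coords, masses, kinds = [], [], []
    residue_ids, residue_names = [], []
    backbone_node, sidechain_node = [], []
    multi_chain = len(model.chains) > 1
    prev_backbone: int | None = None
    bonded: list[tuple[int, int]] = []
    tethered: list[tuple[int, int]] = []
    for chain in model.chains:
        prev_backbone = None
        for res in chain.residues:
            rid = f"{chain.id}:{res.key}" if multi_chain else res.key
            residue_ids.append(rid)
            residue_names.append(res.name)
            b = len(coords)
            coords.append(res.ca)
            masses.append(1.0)
            kinds.append(0)
            backbone_node.append(b)
            if prev_backbone is not None:
                bonded.append((prev_backbone, b))
            prev_backbone = b
            mass = SIDECHAIN_HEAVY_ATOMS.get(res.name, res.sidechain_count)
            if res.sidechain_centroid is not None and mass > 0:
                s = len(coords)
                coords.append(res.sidechain_centroid)
                masses.append(float(mass))
                kinds.append(1)
                sidechain_node.append(s)
                # side chain tethered to its backbone at default stiffness;
                # only the covalent backbone trace gets the stiff bond
                tethered.append((b, s))
            else:
                sidechain_node.append(-1)
    hetero_nodes: dict[str, np.ndarray] = {}
    for group in model.hetero_groups:
        idxs = []
        for xyz in np.asarray(group.coords, dtype=float):
            idxs.append(len(coords))
            coords.append(tuple(xyz))
            masses.append(1.0)
            kinds.append(2)
        hetero_nodes[group.name] = np.array(idxs, dtype=np.int64)

    xyz = np.array(coords, dtype=float)
    pairs = {tuple(sorted(p)): k_default for p in cKDTree(xyz).query_pairs(cutoff)}
    for i, j in tethered:
        pairs[tuple(sorted((i, j)))] = k_default
    for i, j in bonded:
        pairs[tuple(sorted((i, j)))] = k_default * backbone_k_factor

    si = np.array([p[0] for p in sorted(pairs)], dtype=np.int64)
    sj = np.array([p[1] for p in sorted(pairs)], dtype=np.int64)
    kk = np.array([pairs[p] for p in sorted(pairs)], dtype=float)
    r0 = np.linalg.norm(xyz[si] - xyz[sj], axis=1)
    if np.any(r0 <= 0):
        raise DataError("coincident nodes produce zero-length springs")

    net = ElasticNetwork(
        coords=xyz,
        masses=np.array(masses, dtype=float),
        node_kind=np.array(kinds, dtype=np.int64),
        residue_ids=residue_ids,
        residue_names=residue_names,
        backbone_node=np.array(backbone_node, dtype=np.int64),
        sidechain_node=np.array(sidechain_node, dtype=np.int64),
        hetero_nodes=hetero_nodes,
        springs_i=si,
        springs_j=sj,
        springs_k=kk,
        springs_r0=r0,
    )
    _check_connected(net)
    surface = surface_nodes(net, neighbor_radius, density_threshold)
    net.restrained = (net.node_kind == 0) | surface
    return net


def _check_connected(net: ElasticNetwork) -> None:
    n = net.n_nodes
    adj = coo_matrix(
        (np.ones(len(net.springs_i)), (net.springs_i, net.springs_j)),
        shape=(n, n),
    )
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp != 1:
        raise ConnectivityError(
            f"elastic network has {n_comp} disconnected components; "
            "increase the cutoff"
        )


def surface_nodes(
    net: ElasticNetwork,
    neighbor_radius: float = 10.0,
    density_threshold: float | None = None,
) -> np.ndarray:
    """Boolean mask of low-neighbor-density ("surface") nodes.

    A node is surface iff its neighbor count within ``neighbor_radius``
    is below the threshold (default: the 40th percentile of all node
    neighbor counts). This is a geometric proxy for solvent exposure in
    a model without atoms.
    """
    if neighbor_radius <= 0:
        raise ValueError("neighbor_radius must be positive")
    tree = cKDTree(net.coords)
    counts = np.array(
        [len(tree.query_ball_point(p, neighbor_radius)) - 1 for p in net.coords],
        dtype=float,
    )
    if density_threshold is None:
        density_threshold = float(np.percentile(counts, 40.0))
    return counts < density_threshold


def stiffen_springs(
    net: ElasticNetwork, node_pairs: list[tuple[int, int]], factor: float
) -> ElasticNetwork:
    """Return a copy with the given springs' stiffness multiplied by factor."""
    net = net.copy()
    wanted = {tuple(sorted(p)) for p in node_pairs}
    for s in range(len(net.springs_i)):
        if (int(net.springs_i[s]), int(net.springs_j[s])) in wanted:
            net.springs_k[s] *= factor
    return net


# ----------------------------------------------------------------------
# protocol and runs
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ATDProtocol:
    """Tunables of the dual-thermostat ATD protocol (reduced units).

    Temperatures are in kelvin via the package's reduced Boltzmann
    constant; stiffness and restraints in energy/Å²; time in reduced
    units with ``dt`` per step. The defaults mirror the published
    protocol logic: cold bath 10 K, hot bath 300 K, 5 energy/Å² harmonic
    positional restraints, equilibration until the sliding-window RMSF
    drops below 0.05 Å, then a fixed-length velocity-Verlet production
    run.
    """

    t_cold: float = 10.0
    t_hot: float = 300.0
    restraint_k: float = 5.0
    equil_rmsf: float = 0.05
    equil_steps: int = 2000
    production_steps: int = 20000
    dt: float = 0.01
    gamma_hot: float = 1.0
    gamma_cold: float = 0.1
    kB: float = KB
    sample_every: int = 10
    max_equil_factor: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if not self.t_hot > self.t_cold >= 0:
            raise ValueError("require t_hot > t_cold >= 0")
        for name in ("restraint_k", "equil_rmsf", "dt", "gamma_hot",
                     "gamma_cold", "kB"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ATDTrajectory:
    """Sampled node positions from one ATD run."""

    net: ElasticNetwork
    frames: np.ndarray              # (F, N, 3)
    kinetic_temperature: np.ndarray  # (N,) production time average, K
    hot_set: np.ndarray             # node indices
    seed: int
    protocol: ATDProtocol

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@njit(cache=True, fastmath=True)
def _forces(x, si, sj, sk, sr0, rest_mask, rest_k, x0, f):
    f[:] = 0.0
    for s in range(si.shape[0]):
        i = si[s]
        j = sj[s]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        fac = -sk[s] * (r - sr0[s]) / r
        f[i, 0] += fac * dx
        f[i, 1] += fac * dy
        f[i, 2] += fac * dz
        f[j, 0] -= fac * dx
        f[j, 1] -= fac * dy
        f[j, 2] -= fac * dz
    for i in range(x.shape[0]):
        if rest_mask[i]:
            for d in range(3):
                f[i, d] -= rest_k * (x[i, d] - x0[i, d])


@njit(cache=True, fastmath=True)
def _run_steps(
    x, v, masses, si, sj, sk, sr0, rest_mask, rest_k, x0,
    c1, c2, dt, noise, sample_every, frames, v2_accum,
):
    """BAOAB Langevin steps; records frames and accumulates m·v² per node."""
    N = x.shape[0]
    n_steps = noise.shape[0]
    f = np.zeros((N, 3))
    _forces(x, si, sj, sk, sr0, rest_mask, rest_k, x0, f)
    frame = 0
    for t in range(n_steps):
        for i in range(N):
            hdtm = 0.5 * dt / masses[i]
            for d in range(3):
                v[i, d] += hdtm * f[i, d]
                x[i, d] += 0.5 * dt * v[i, d]
            for d in range(3):
                v[i, d] = c1[i] * v[i, d] + c2[i] * noise[t, i, d]
                x[i, d] += 0.5 * dt * v[i, d]
        _forces(x, si, sj, sk, sr0, rest_mask, rest_k, x0, f)
        for i in range(N):
            hdtm = 0.5 * dt / masses[i]
            vsq = 0.0
            for d in range(3):
                v[i, d] += hdtm * f[i, d]
                vsq += v[i, d] * v[i, d]
            v2_accum[i] += masses[i] * vsq
        if (t + 1) % sample_every == 0:
            for i in range(N):
                for d in range(3):
                    frames[frame, i, d] = x[i, d]
            frame += 1
    return frame


def _ou_coefficients(gamma, temps, masses, dt, kB):
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 ** 2) * kB * temps / masses)
    return c1, c2


def _chunked_run(x, v, net, rest_mask, rest_k, c1, c2, protocol, n_steps, rng):
    """Run n_steps in noise-bounded chunks; returns sampled frames and Σm·v²."""
    N = net.n_nodes
    sample_every = protocol.sample_every
    n_frames = n_steps // sample_every
    frames = np.empty((n_frames, N, 3))
    v2 = np.zeros(N)
    chunk = 2000
    done_frames = 0
    done_steps = 0
    while done_steps < n_steps:
        steps = min(chunk, n_steps - done_steps)
        noise = rng.standard_normal((steps, N, 3))
        nf = steps // sample_every
        out = np.empty((nf, N, 3))
        _run_steps(
            x, v, net.masses, net.springs_i, net.springs_j, net.springs_k,
            net.springs_r0, rest_mask, rest_k, net.coords,
            c1, c2, protocol.dt, noise, sample_every, out, v2,
        )
        if np.abs(x).max() > 1e3:
            raise StabilityError(
                "coordinate exceeded 1000 Å during integration; "
                "reduce the timestep"
            )
        frames[done_frames:done_frames + nf] = out
        done_frames += nf
        done_steps += steps
    return frames[:done_frames], v2, done_steps


def atd_run(
    net: ElasticNetwork,
    protocol: ATDProtocol,
    hot_set: np.ndarray | list[int] = (),
    seed: int | None = None,
) -> ATDTrajectory:
    """One ATD run: cold equilibration, then dual-thermostat production.

    Equilibration couples every node to the cold bath until the
    sliding-window RMSF (mean over nodes) falls below the protocol
    criterion, capped at ``max_equil_factor`` times the production
    length. Production couples ``hot_set`` to the hot bath and all other
    nodes weakly to the cold bath, with harmonic restraints (never on
    hot nodes) throughout. Fully reproducible from the seed.
    """
    hot = np.asarray(sorted(set(int(i) for i in hot_set)), dtype=np.int64)
    if hot.size and (hot.min() < 0 or hot.max() >= net.n_nodes):
        raise DataError("hot_set contains node indices outside the network")
    seed = protocol.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    N = net.n_nodes

    x = net.coords.copy()
    # Maxwell-Boltzmann start at the cold temperature
    v = rng.standard_normal((N, 3)) * np.sqrt(
        protocol.kB * protocol.t_cold / net.masses
    )[:, None]

    rest_mask = net.restrained.copy()
    rest_mask[hot] = False  # hot nodes are never restrained

    # --- equilibration: everything cold, strong coupling -------------
    temps = np.full(N, protocol.t_cold)
    gammas = np.full(N, protocol.gamma_hot)
    c1, c2 = _ou_coefficients(gammas, temps, net.masses, protocol.dt, protocol.kB)
    max_steps = int(protocol.max_equil_factor * protocol.production_steps)
    total = 0
    window = max(protocol.equil_steps, 10 * protocol.sample_every)
    converged = False
    while total < max_steps:
        frames, _, steps = _chunked_run(
            x, v, net, rest_mask, protocol.restraint_k, c1, c2,
            protocol, window, rng,
        )
        total += steps
        w_rmsf = float(np.mean(_node_rmsf(frames)))
        if w_rmsf < protocol.equil_rmsf:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"equilibration RMSF stayed above {protocol.equil_rmsf} Å "
            f"after {total} steps"
        )

    # --- production: dual thermostats ---------------------------------
    temps = np.full(N, protocol.t_cold)
    gammas = np.full(N, protocol.gamma_cold)
    if hot.size:
        temps[hot] = protocol.t_hot
        gammas[hot] = protocol.gamma_hot
    c1, c2 = _ou_coefficients(gammas, temps, net.masses, protocol.dt, protocol.kB)
    frames, v2, steps = _chunked_run(
        x, v, net, rest_mask, protocol.restraint_k, c1, c2,
        protocol, protocol.production_steps, rng,
    )
    # ⟨m v²⟩ / (3 kB) averaged over production steps
    kin_temp = v2 / steps / (3.0 * protocol.kB)
    return ATDTrajectory(
        net=net,
        frames=frames,
        kinetic_temperature=kin_temp,
        hot_set=hot,
        seed=seed,
        protocol=protocol,
    )


# ----------------------------------------------------------------------
# RMSF readout
# ----------------------------------------------------------------------

def _node_rmsf(frames: np.ndarray) -> np.ndarray:
    """Per-node RMSF over frames: sqrt(mean |x - <x>|^2)."""
    mean = frames.mean(axis=0)
    dev = frames - mean
    return np.sqrt((dev ** 2).sum(axis=2).mean(axis=0))


@dataclass
class DeltaRMSFProfile:
    """Per-residue side-chain RMSF of heated and reference runs."""

    residue_ids: list[str]
    rmsf_hot: np.ndarray
    rmsf_ref: np.ndarray

    @property
    def delta(self) -> np.ndarray:
        return self.rmsf_hot - self.rmsf_ref


def trajectory_rmsf(traj: ATDTrajectory, burn_in: float = 0.2) -> np.ndarray:
    """Per-residue readout-node RMSF (side chain; backbone for glycine)."""
    if not 0.0 <= burn_in < 1.0:
        raise ValueError("burn_in must be in [0, 1)")
    start = int(burn_in * traj.n_frames)
    node_rmsf = _node_rmsf(traj.frames[start:])
    idx = np.array(
        [traj.net.readout_node(r) for r in range(traj.net.n_residues)]
    )
    return node_rmsf[idx]


def delta_rmsf(
    hot: ATDTrajectory, ref: ATDTrajectory, burn_in: float = 0.2
) -> DeltaRMSFProfile:
    """ΔRMSF profile: heated-run minus reference-run side-chain RMSF."""
    if hot.net.residue_ids != ref.net.residue_ids:
        raise DataError("trajectories cover different residue sets")
    return DeltaRMSFProfile(
        residue_ids=list(hot.net.residue_ids),
        rmsf_hot=trajectory_rmsf(hot, burn_in),
        rmsf_ref=trajectory_rmsf(ref, burn_in),
    )


def detect_peaks(delta: np.ndarray, z_threshold: float = 2.0) -> list[int]:
    """Indices of ΔRMSF peaks: ±2-residue local maxima with robust z-score
    (median/MAD) at least ``z_threshold``. A constant profile has none."""
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    d = np.asarray(delta, dtype=float)
    n = len(d)
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    scale = 1.4826 * mad
    if scale == 0:
        scale = np.mean(np.abs(d - med))  # fallback for heavy ties
        if scale == 0:
            return []
    peaks = []
    for i in range(n):
        lo, hi = max(0, i - 2), min(n, i + 3)
        if d[i] >= d[lo:hi].max() and (d[i] - med) / scale >= z_threshold:
            # strict maximum against equal-valued left neighbours to avoid
            # double-reporting plateaus
            if i > lo and np.any(d[lo:i] == d[i]):
                continue
            peaks.append(i)
    return peaks


# ----------------------------------------------------------------------
# mutations and mutant screening
# ----------------------------------------------------------------------

LONG_CONTACT_LENGTH = 5.0  # Å; side-chain contacts beyond this are lost on truncation


def apply_mutation(
    net: ElasticNetwork, residue_id: str, new_type: str = "ALA"
) -> ElasticNetwork:
    """Model a point mutation as a side-chain mass change plus loss of the
    long-range contacts the original (larger) side chain was making.

    The side-chain node's mass becomes the new residue type's heavy-atom
    count and, when the side chain shrinks, every spring incident to it
    with rest length above 5 Å is removed — the long contacts the larger
    side chain was making cannot be reached by the smaller one. A
    same-size substitution (e.g. ALA to ALA) leaves the network
    unchanged. Mutating to glycine removes the side-chain node entirely;
    mutating a glycine changes nothing (warning).
    """
    new_type = new_type.upper()
    if new_type not in SIDECHAIN_HEAVY_ATOMS:
        raise DataError(f"unknown residue type {new_type!r}")
    r = net.residue_index(residue_id)
    s = int(net.sidechain_node[r])
    if s < 0:
        warnings.warn(
            f"residue {residue_id} has no side-chain node; mutation is a no-op",
            stacklevel=2,
        )
        return net.copy()
    out = net.copy()
    old_mass = float(out.masses[s])
    out.residue_names[r] = new_type
    if new_type == "GLY":
        return _remove_node(out, s, r)
    new_mass = float(SIDECHAIN_HEAVY_ATOMS[new_type])
    out.masses[s] = new_mass
    if new_mass < old_mass:
        keep = ~(
            ((out.springs_i == s) | (out.springs_j == s))
            & (out.springs_r0 > LONG_CONTACT_LENGTH)
        )
        out.springs_i = out.springs_i[keep]
        out.springs_j = out.springs_j[keep]
        out.springs_k = out.springs_k[keep]
        out.springs_r0 = out.springs_r0[keep]
        _check_connected(out)
    return out


def _remove_node(net: ElasticNetwork, node: int, res_idx: int) -> ElasticNetwork:
    keep_mask = np.ones(net.n_nodes, dtype=bool)
    keep_mask[node] = False
    remap = np.cumsum(keep_mask) - 1
    keep_springs = (net.springs_i != node) & (net.springs_j != node)
    net.coords = net.coords[keep_mask]
    net.masses = net.masses[keep_mask]
    net.node_kind = net.node_kind[keep_mask]
    net.restrained = net.restrained[keep_mask]
    net.springs_i = remap[net.springs_i[keep_springs]]
    net.springs_j = remap[net.springs_j[keep_springs]]
    net.springs_k = net.springs_k[keep_springs]
    net.springs_r0 = net.springs_r0[keep_springs]
    net.backbone_node = remap[net.backbone_node]
    sc = net.sidechain_node.copy()
    sc[res_idx] = -1
    pos = sc >= 0
    sc[pos] = remap[sc[pos]]
    net.sidechain_node = sc
    net.hetero_nodes = {k: remap[v] for k, v in net.hetero_nodes.items()}
    _check_connected(net)
    return net


@dataclass
class ConstructResult:
    """Replicate statistics of window-averaged ΔRMSF for one construct."""

    window_means: np.ndarray   # (n_replicates,)
    mean: float
    sd: float
    profile: np.ndarray        # per-residue ΔRMSF, averaged over replicates


@dataclass
class MutantComparison:
    """Wild-type vs mutant window-ΔRMSF comparison."""

    wt: ConstructResult
    mutant: ConstructResult
    key_residues: list[str]
    significant: bool
    direction: str             # increase | decrease | none
    threshold: float           # 2 x pooled SD


REF_PRODUCTION_FACTOR = 4  # reference run length relative to heated runs


def _construct_delta(
    net: ElasticNetwork,
    protocol: ATDProtocol,
    hot_nodes: np.ndarray,
    key_idx: np.ndarray,
    n_replicates: int,
    burn_in: float,
) -> ConstructResult:
    """Replicated ΔRMSF against one shared, extra-long reference run.

    The all-cold reference profile is a property of the construct, not
    of a replicate, so it is estimated once from a run four times the
    production length; each heated replicate (distinct seed) is compared
    against it. This keeps the replicate spread a measure of the heated
    runs alone.
    """
    from dataclasses import replace as _replace

    ref_protocol = _replace(
        protocol,
        production_steps=protocol.production_steps * REF_PRODUCTION_FACTOR,
    )
    ref = atd_run(net, ref_protocol, (), seed=protocol.seed + 500_009)
    rmsf_ref = trajectory_rmsf(ref, burn_in)
    means, profiles = [], []
    for rep in range(n_replicates):
        hot = atd_run(net, protocol, hot_nodes, seed=protocol.seed + rep)
        prof = trajectory_rmsf(hot, burn_in) - rmsf_ref
        profiles.append(prof)
        means.append(float(prof[key_idx].mean()))
    means = np.array(means)
    return ConstructResult(
        window_means=means,
        mean=float(means.mean()),
        sd=float(means.std(ddof=1)),
        profile=np.mean(profiles, axis=0),
    )


def compare_mutant(
    net_wt: ElasticNetwork,
    net_mut: ElasticNetwork,
    protocol: ATDProtocol,
    hot_group: str,
    key_residues: list[str],
    n_replicates: int = 4,
    burn_in: float = 0.2,
) -> MutantComparison:
    """Replicated ATD comparison of a mutant against the wild type.

    For each construct, ``n_replicates`` heated+reference run pairs give
    the window-averaged ΔRMSF over ``key_residues``; the change is
    significant iff |mean_wt - mean_mut| exceeds twice the pooled SD.
    Replicate seeds are the protocol seed plus the replicate index.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    results = []
    for net in (net_wt, net_mut):
        if hot_group not in net.hetero_nodes:
            raise DataError(f"no hetero group {hot_group!r} in network")
        key_idx = np.array([net.residue_index(r) for r in key_residues])
        results.append(
            _construct_delta(
                net, protocol, net.hetero_nodes[hot_group], key_idx,
                n_replicates, burn_in,
            )
        )
    wt, mut = results
    return _comparison(wt, mut, key_residues)


def _comparison(
    wt: ConstructResult, mut: ConstructResult, key_residues: list[str]
) -> MutantComparison:
    pooled = float(np.sqrt(0.5 * (wt.sd ** 2 + mut.sd ** 2)))
    diff = mut.mean - wt.mean
    significant = abs(diff) > 2.0 * pooled
    direction = "none" if not significant else ("increase" if diff > 0 else "decrease")
    return MutantComparison(
        wt=wt,
        mutant=mut,
        key_residues=list(key_residues),
        significant=significant,
        direction=direction,
        threshold=2.0 * pooled,
    )


def mutant_screen(
    net_wt: ElasticNetwork,
    mutations: dict[str, tuple[str, str]],
    protocol: ATDProtocol,
    hot_group: str,
    key_residues: list[str],
    n_replicates: int = 4,
    burn_in: float = 0.2,
) -> dict[str, MutantComparison]:
    """Screen several mutants against one shared set of wild-type runs.

    ``mutations`` maps a construct label to (residue id, new type), e.g.
    {"F419A": ("419", "ALA")}. Equivalent to calling
    :func:`compare_mutant` per mutant, but the wild-type replicates are
    computed once.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    if hot_group not in net_wt.hetero_nodes:
        raise DataError(f"no hetero group {hot_group!r} in network")
    key_idx = np.array([net_wt.residue_index(r) for r in key_residues])
    wt = _construct_delta(
        net_wt, protocol, net_wt.hetero_nodes[hot_group], key_idx,
        n_replicates, burn_in,
    )
    out: dict[str, MutantComparison] = {}
    for label, (residue_id, new_type) in mutations.items():
        net_mut = apply_mutation(net_wt, residue_id, new_type)
        key_idx_m = np.array([net_mut.residue_index(r) for r in key_residues])
        mut = _construct_delta(
            net_mut, protocol, net_mut.hetero_nodes[hot_group], key_idx_m,
            n_replicates, burn_in,
        )
        out[label] = _comparison(wt, mut, key_residues)
    return out


def discrimination_auc(positive: np.ndarray, negative: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney) for how well values separate groups."""
    pos = np.asarray(positive, dtype=float)
    neg = np.asarray(negative, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (
        pos[:, None] == neg[None, :]
    ).sum()
    return float(wins / (pos.size * neg.size))
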