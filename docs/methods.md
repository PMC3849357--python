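# Methods

This note documents the models implemented in `allonet`, the tunable
parameters and their defaults, the synthetic-data generators and what
they do and do not emulate, and the numerical choices made where the
design was genuinely open.

## 1. Maximal-subtree co-evolution analysis

### Model

Input: an alignment over the 20 amino acids plus `X` and the gap
character, and a rooted phylogeny whose leaves are exactly the
alignment's sequences. Conservation is judged on a **residue-class
scheme**; the default groups physicochemically similar residues —
{AVLIMC}, {FWYH}, {STNQ}, {KR}, {DE}, {G}, {P}, {X}, {-} — and an
identity scheme (every character its own class) is available. The gap
is its own class, so a clade of all-gap sequences counts as conserved.

For column *j*, the **maximal-subtree decomposition** partitions the
leaves into maximal conserved clades, computed greedily from the root:
a clade is emitted iff all its leaves share one class, otherwise its
children are visited (leaves are trivially conserved, so this always
terminates in a partition, and every emitted block is maximal). The
block count is the column's **rank**; the package verifies the greedy
procedure against exhaustive clade enumeration. The vectorised
`rank_profile` computes all columns in one postorder sweep.

### Seed selection (α = 2.0)

A column is a seed iff `rank ≤ α · mean(rank)` (invariant rank-1
columns excluded by default). The original formulation suggests a cut
at the mean, but a cut there discards much genuine signal: an outlier
(divergent or misaligned) sequence chops every block containing it into
several clades, inflating the rank of a strongly co-evolving position
to near — and sometimes past — the alignment mean. The default α = 2
therefore discards only clearly hyper-variable columns and leaves the
discrimination to the pairwise score and the cluster cut.

### Co-evolution score (size-weighted best-match Jaccard)

Given two decompositions with blocks {A_a} and {B_b}, the
correspondence matrix holds Jaccard indices of block pairs, and each
side contributes its blocks' best matches weighted by block size
(fraction of leaves); the two sides are averaged. Size weighting is
essential: without it a handful of single-leaf noise blocks dominates
the average, masking the agreement of the large clades that carry the
evolutionary signal. Properties: S ∈ [0, 1], S(p, p) = 1, symmetric; a single whole-tree
block against n singletons scores 1/n (0.25 at n = 4) — for partitions
with uniform block sizes the weighting leaves the score unchanged.

### Clustering (τ = 0.9) and the descent baseline

Positions are clustered by average linkage on distance 1 − S, cut at
height 1 − τ; clusters smaller than `min_size` (default 4) are dropped;
output is ordered by size then smallest member, and the dendrogram leaf
order is exported for heat maps. The default τ = 0.9 is far above the
textbook 0.5 because two *unrelated* positions evolving on the same
tree already share clade structure by descent: measured on synthetic
backgrounds, their similarity distribution centres near 0.5 and its
upper tail reaches 0.85. Genuinely co-evolving positions score ≈ 0.95.
The cut must sit between the tail of the descent baseline and the
signal, not between 0 and the signal.

Statistical significance against an explicit phylogenetic null model is
out of scope; the descent baseline above quantifies the phenomenon the
score must overcome but no p-values are attached.

## 2. Preprocessing: filtering, distances, trees

Columns with gap fraction above `max_gap_fraction` (default 0.5) are
removed, with an index map back to 1-based positions of the ungapped
reference sequence (record 0 by default). When no tree is supplied,
uncorrected p-distances (identity over pairwise gap-free columns; 1.0
when no column is comparable) feed neighbor joining (scikit-bio),
negative branch lengths are clamped to zero, and the tree is
midpoint-rooted — the subtree analysis needs clades, hence a root.
Neighbor joining is exact on additive matrices (verified: topology and
path lengths to 1e-9). Maximum-likelihood trees, bootstrap and model
corrections are out of scope; a user-supplied Newick tree bypasses the
whole stage.

## 3. Structure mapping

The ungapped reference sequence is globally aligned to a chain's
one-letter sequence (match +2, mismatch −1, gap open −5, gap extend −1;
fixed defaults for determinism, configurable). Aligned pairs map
reference positions to residue keys; structure gaps leave positions
unmapped; identity below 30% flags the mapping low-confidence with a
warning. A network member is **proximal** to a site (a hetero group
such as the heme, or an explicit residue list) iff the minimum distance
from its CA or side-chain centroid to any site node is at most the
cutoff (default 8 Å in the node representation), else **distal**.
Labels are rigid-motion invariant, and proximal/distal/unmapped cover a
network exactly once. The cutoff has no canonical published value;
counts of proximal vs distal members should be read qualitatively.

## 4. Coarse-grained anisotropic thermal diffusion

### The elastic network

One backbone node per residue at the CA (unit mass) and, for
non-glycine residues, one side-chain node at the side-chain centroid
with mass equal to the side chain's heavy-atom count (from the residue
name; observed atom count for non-standard names). Hetero groups
contribute one unit-mass node per heavy atom. Springs connect all node
pairs within the cutoff (default 10 Å) at stiffness `k_default`
(default 1 energy/Å²), with rest length equal to the initial
separation. Consecutive backbone nodes are always bonded at 10× — the
covalent trace — while side-chain nodes are tethered to their own
backbone node at the default stiffness: a stiff tether was found to
drain side-chain energy directly into the restrained backbone and was
deliberately avoided. A disconnected network is an error.

### Units

Lengths are in Å, stiffness in energy/Å², masses in heavy-atom units,
and time in reduced units with `dt = 0.01` per step. Temperature enters
through a reduced Boltzmann constant `kB = 2e-4` energy/K, chosen so
that the cold-state (10 K) equilibrium displacement of a typical node
(effective stiffness of a few energy/Å²) is ≈ 0.03 Å — inside the
0.05 Å equilibration criterion — while the 300 K source fluctuates at a
few tenths of an Å. Absolute RMSF values are therefore *not*
comparable to all-atom simulations; only contrasts (ΔRMSF) carry
meaning.

### Protocol

1. **Equilibration**: every node is coupled to the cold bath (10 K) at
   friction `gamma_hot` until the sliding-window RMSF over all nodes
   falls below 0.05 Å, capped at 10× the production length
   (convergence error beyond).
2. **Production**: the hot set (e.g. heme nodes) couples to the 300 K
   bath at `gamma_hot` (default 1.0); all other nodes couple *weakly*
   to the cold bath at `gamma_cold` (default 0.1). The original
   protocol leaves non-heated atoms uncoupled after cooling; a weak
   cold coupling bounds energy drift in the reduced model while
   preserving long-range propagation. Harmonic restraints (default
   5 energy/Å²) act on all backbone nodes and on surface nodes
   throughout; hot nodes are never restrained.
3. **Integration**: BAOAB Langevin (velocity-Verlet core, exact
   Ornstein-Uhlenbeck velocity refresh), per-node friction and bath
   temperature. Runs are bit-reproducible from their seed; any
   coordinate exceeding 10³ Å raises a stability error.

Surface nodes are identified by a neighbor-density proxy (no atoms, so
no solvent-accessible area): a node is surface iff its neighbor count
within 10 Å is below the 40th percentile of all counts.

### Readout

Per-residue RMSF is computed on the side-chain node (backbone node for
glycine) over post-burn-in frames (burn-in fraction 0.2), and
ΔRMSF = RMSF(heated) − RMSF(reference). Peaks are ±2-residue local
maxima with a robust z-score (median/MAD) of at least 2. For replicated
comparisons the all-cold reference profile is estimated **once** per
construct from a run four times the production length and shared across
replicates: the reference is a property of the construct, not of a
replicate, and sharing it makes the replicate spread a property of the
heated runs alone.

### Mutation model and screen

A point mutation sets the side-chain node's mass to the new type's
heavy-atom count and, when the side chain *shrinks*, removes its springs
with rest length above 5 Å — long contacts the larger side chain was
making. Same-size substitutions leave the network unchanged; mutation
to glycine removes the node. This is a deliberately coarse construction
(no repacking, no backbone response). The screen compares window-mean
ΔRMSF over replicates (default 4, seeds = base + replicate index):
a change is significant iff |mean_WT − mean_mut| > 2 × pooled SD. With
few replicates this is an effect-size rule rather than a calibrated
test; it mirrors the qualitative "significantly changed fluctuation"
judgment it replaces. The method flags *that* dynamics at the window
change, not how catalytic activity would change.

### Transport settings for validation

Heat-transport diagnostics (chain monotonicity, pathway discrimination,
mutant screen) run with `gamma_cold = 0.05` and 60k production steps
(reference runs 4× longer): halving the cold friction doubles the
propagation length of injected heat, and the longer averaging brings
the RMSF estimator's noise below the distal signals (ΔRMSF of order
10⁻³ Å). Thermostat fidelity is asserted on a 200k-step run because a
node's kinetic temperature is a time average with ≈ 18% statistical
spread at the default production length — measurement noise, not
thermostat error. Problem sizes used by the validation suite: 200
oracle cases, 10 alignment seeds (64 × 200), 20 trees, 20 pathway
structures (120 residues), 10 screen seeds, one 30-node chain with 10
seeds.

## 5. Synthetic generators

### Alignments with planted networks

A Yule topology (uniform leaf splitting) with i.i.d. exponential branch
lengths (mean 0.1) carries 200 columns over 64 leaves. Background
columns start from a uniform root residue and mutate per edge with
probability 1 − e^(−μt), μ = 0.5, to a uniform different residue — a
deliberately simple model (no WAG/LG rate matrix, no indels) that still
produces the clade-structured background the analysis must reject.
Planted networks (two of 8 positions by default) change **only** on
their network's switch edges: the whole subtree below each edge adopts
a residue of a new class, the same edges for every position of the
network. Default switch edges: six mutually disjoint clades of 2–12
leaves — several mid-sized coherent switches give a partition signature
that a lone background substitution cannot mimic. Per-leaf noise
(ε = 0.05): each leaf independently becomes an outlier *for the whole
network*, carrying an independent random residue of a different class
at each network position. This emulates a divergent or misaligned
sequence — which corrupts a co-evolving position set coherently, not
cell by cell — and makes the corruption unambiguous at every position.
Ground truth (positions, switch edges, outlier leaves) is emitted
alongside.

What passing on these data does *not* show: robustness to realistic
substitution processes, indels, alignment error gradients, or
phylogenetic uncertainty; the tree is known exactly here.

### Structures with a planted conduit

A compact self-avoiding CA trace (3.8 ± 0.01 Å steps, ≥ 4 Å
non-adjacent separation, sphere radius from ≈ 110 Å³/residue packing)
carries side-chain centroids 1.5–3 Å off-backbone with random residue
types. A four-node source ("HEM") cluster sits 2–4 Å from the start of
a planted **conduit**: a chain of side-chain nodes with consecutive
separations in 5.2–9.5 Å — beyond the 5 Å long-contact threshold, so an
alanine substitution severs it — leading to the nearest six-residue
sequence window whose CA centroid is at least 15 Å from the source and
spatially compact (≤ 12 Å spread). Springs between consecutive conduit
nodes, between the source and the first node, and between the last node
and the window's side chains are stiffened by the pathway factor
(default 5).

Three geometric rules make the conduit a genuine heat pipe, all rooted
in harmonic transport physics: conduit and window residues get uniform
light (CYS) side chains, because energy transfer between coupled
oscillators needs matched frequencies (ω = √(k/m)) and mass mismatch
detunes them; routes are straight (per-joint deviation ≤ 50°), because
springs couple longitudinally and a right-angle kink converts the
motion to transverse modes; and routes prefer low-density regions,
because every background neighbor within the cutoff leaks conduit
energy. The ground truth records pathway, window, a severing mutation
site (middle conduit residue) and a degree-matched off-pathway control
far from source and window. Control pools for discrimination
statistics exclude the source's 8 Å proximal shell and residues
directly bonded to the conduit — both are coupled to the heated system
by construction and would be mislabeled negatives.

What passing does *not* show: that real protein folds conduct heat
along evolutionarily conserved pathways; the generator plants an
idealised conduit to verify that the *method* detects one when present
and reports its absence when severed.

## 6. Known limitations

- The co-evolution score and clustering thresholds were calibrated on
  the synthetic generator's regime (64 leaves, coherent outlier noise);
  families with very different depth or alignment quality may need
  different α/τ.
- The ENM/ATD model is harmonic: no anharmonic phonon scattering, no
  side-chain repacking, no solvent; absolute temperatures and RMSF
  magnitudes are reduced-unit quantities.
- The mutant screen's 2×SD rule with 4 replicates controls neither
  type-I nor type-II error rates formally.
- PDB input support is deliberately minimal (first model,
  highest-occupancy altloc, no mmCIF, no trajectories).
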