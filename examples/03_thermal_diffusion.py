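"""Anisotropic thermal diffusion on an elastic network.

Builds a synthetic structure with a planted stiff pathway from a
heme-like source to a distal window, runs a heated (heme at 300 K,
protein at 10 K) and a reference (all 10 K) simulation, and reports the
per-residue ΔRMSF profile with its peaks. Pathway residues should stand
out against the cold background.
"""

import numpy as np

from allonet.atd import ATDProtocol, atd_run, delta_rmsf, detect_peaks
from allonet.synthetic import StructGenSpec, gen_structure

model, net, truth = gen_structure(StructGenSpec(seed=3))
print(f"structure: {net.n_residues} residues, {net.n_nodes} nodes, "
      f"{len(net.springs_i)} springs")
print(f"planted pathway (residues): {truth['pathway']}, "
      f"target window {truth['target_window']}")

protocol = ATDProtocol(gamma_cold=0.05, production_steps=60_000)
hot = atd_run(net, protocol, net.hetero_nodes["HEM"], seed=1)
ref = atd_run(net, protocol, (), seed=900_001)
cold_nodes = np.setdiff1d(np.arange(net.n_nodes), net.hetero_nodes["HEM"])
print(f"heme kinetic temperature: "
      f"{hot.kinetic_temperature[net.hetero_nodes['HEM']].mean():.0f} K "
      f"(bath 300 K); protein median "
      f"{np.median(hot.kinetic_temperature[cold_nodes]):.1f} K "
      "(cold bath 10 K; residues near the heme run warmer)")

profile = delta_rmsf(hot, ref)
peaks = detect_peaks(profile.delta, z_threshold=2.0)
print(f"\nΔRMSF peaks at residues: {[profile.residue_ids[i] for i in peaks]}")
pw = [net.residue_index(r) for r in truth["pathway"]]
print(f"pathway ΔRMSF (Å):   {np.round(profile.delta[pw], 4)}")
others = [i for i in range(net.n_residues) if i not in pw]
print(f"background mean ΔRMSF: {profile.delta[others].mean():.4f} Å")
# Heat injected at the heme travels preferentially along the stiff
# pathway: its residues fluctuate visibly more than the cold background.
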