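# mdgate

Ion-occupancy, free-energy and gating-geometry analysis of
membrane-transporter molecular-dynamics trajectories.

`mdgate` is built for the question of how a SLC26-family anion
transporter (an X-shaped homodimer of a transmembrane [TM] domain —
split into *core* and *gate* subdomains — plus a cytoplasmic STAS
domain) binds chloride and gates its translocation pathway. It turns
raw trajectory coordinates into the quantities that answer it:

* **3D ion-occupancy probability grids** — the simulation volume is
  discretized into 1 Å³ cells; a cell's occupancy is the fraction of
  frames with at least one tracked ion in it. Binding at the putative
  site (a sphere of radius 8.5 Å = 5 carbon van der Waals radii around
  the midpoint of the Cα atoms of residues 128 and 391) is called when
  the peak in-site cell probability exceeds **μ + 50σ**, with μ, σ the
  mean and population standard deviation over all cells. Under the
  Poisson convention σ = μ, that threshold corresponds to an ion
  concentration of 0.15 M × 51 = **7.65 M**.
* **Event-conditioned free-energy landscapes** by Boltzmann inversion,

      ΔG_i = −RT ln(n_i / n_min),

  where n_i counts the frames in reaction-coordinate cell *i* where the
  objective event (e.g. chloride bound) occurred and n_min is the
  smallest nonzero count (grid intervals: 0.25 Å for distances, 1° for
  dihedrals; T = 303.15 K; natural logarithm).
* **Gating geometry** — the core–gate distance (Cα 362 – Cα 201), a
  per-frame dimer reference frame (z = membrane normal, x = inter-chain
  TM center-of-mass axis projected ⊥ z, y = z × x) with the STAS
  center-of-mass trace in it, backbone φ/ψ dihedrals, helix kink
  angles, salt bridges (N–O < 4 Å) and RMSD profiles.
* **Dual-mode dihedral-correlation classifier** — a (φ, ψ) landscape at
  1° resolution is probed at {(−60°, 15°), (−60°, −45°), (−90°, −15°)};
  free energy strictly below −0.9 kcal/mol at all three marks the
  coexistence of crankshaft (anti-correlated) and non-crankshaft
  correlation modes.
* **Synthetic-trajectory generators** with ground-truth sidecars (ion
  wells, dihedral correlation modes, kinked helices, telegraph salt
  bridges, dimer toys), so every stage is verifiable without running MD.

Input formats: PDB topologies, multi-model PDB or DCD/XTC/TRR
trajectories (via MDAnalysis). Outputs: OpenDX density maps, TSV
series, JSON reports.

## Worked example

```python
import numpy as np
from mdgate import occupancy as occ, synthetic as syn

# an ion-well trajectory with 30% site occupancy (ground truth known)
traj, truth = syn.gen_ion_trajectory(syn.IonWellConfig(p_bind=0.30,
                                                       n_frames=2000, seed=1))
ions = np.arange(2, traj.topology.n_atoms)
grid = occ.compute_occupancy_grid(traj, ion_selection=ions)
site = occ.binding_site_from_structure(traj.topology)   # radius 8.5 A
call = occ.classify_binding(grid, site, k=50)
print(f"realized occupancy {truth['bound_fraction']:.4f}")
print(f"peak in-site probability {call.peak_prob:.4f}")
print(f"threshold mu+50sigma = {call.threshold:.4f}  bound = {call.bound}")
print(f"threshold concentration {occ.threshold_concentration():.2f} M")
```

prints

```
realized occupancy 0.2915
peak in-site probability 0.2915
threshold mu+50sigma = 0.0587  bound = True
threshold concentration 7.65 M
```

The peak cell probability equals the realized bound-frame fraction, it
clears the μ+50σ threshold by a factor of five, and the threshold's
concentration equivalent is the 7.65 M worked value.

The same analyses are available from the shell:

```sh
mdgate simulate ionwell --output-dir run --seed 1
mdgate classify  --topology run/ionwell.pdb --trajectory run/ionwell.pdb --output-dir run
mdgate landscapes --topology run/ionwell.pdb --trajectory run/ionwell.pdb --output-dir run
mdgate report --output-dir run
```

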