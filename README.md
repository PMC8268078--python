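# mdpost

Post-simulation analysis of molecular-dynamics trajectories of
multi-component protein complexes — the kind of analysis stack used to
dissect receptor–ligand immune assemblies such as
HLA-E/β2m/peptide bound to the NKG2C/CD94 natural-killer-cell receptor:

* **Dynamic cross-correlation (DCC)** of residue motions and
  **block correlation densities** that condense an N×N residue matrix into
  one score per component pair (HLA-E α1/α2/α3, β2m, CD94, NKG2C, peptide),
* **RMSF / B-factor flexibility profiles**,
* **Hydrogen-bond occupancy** tables, distance series and cross-system
  differential bond networks,
* **Hierarchical conformational clustering** with representative (medoid)
  frames,
* **Single-trajectory MM-GBSA** binding free energies with OBC-II (igb = 5)
  generalized-Born solvation, Shrake–Rupley surface term, and
  per-residue / pairwise decompositions for hotspot ranking,
* a **synthetic-trajectory generator** that plants known correlation
  blocks, hydrogen-bond schedules, conformer mixtures and closed-form
  charged systems, so every stage can be validated against exact ground
  truth.

It is aimed at structural bioinformaticians who have trajectories (as
multi-model PDB) and want the standard post-processing battery in a tested,
scriptable, deterministic form.

## The statistics and models

**Cross-correlation.** After removing rigid-body motion by a mass-weighted
RMS fit of every frame to the iteratively converged average structure, the
correlation between residues *i* and *j* is

```
CC_ij = ⟨Δr_i · Δr_j⟩ / √(⟨Δr_i²⟩ ⟨Δr_j²⟩),   Δr = r − ⟨r⟩ ∈ ℝ³,
```

with CC ∈ [−1, 1]. For components A and B the block correlation density is
`Σ_{i∈A, j∈B} CC_ij / (n_A n_B)`.

**Flexibility.** Per-atom RMSF `√⟨|r − ⟨r⟩|²⟩`, aggregated per residue by
mass-weighted mean; B-factor `B = (8π²/3)·RMSF²`.

**Hydrogen bonds.** D–H···A counts in a frame when d(D, A) ≤ 3.0 Å and the
D–H–A angle ≥ 135° (cpptraj convention; both cutoffs configurable and
inclusive); occupancy is the % of window frames bonded, and network views
keep bonds whose maximum occupancy reaches 10%.

**Clustering.** Best-fit mass-weighted backbone RMSD distance matrix,
average-linkage agglomerative merging until all inter-cluster distances
exceed ~2 Å, medoid representative per cluster.

**MM-GBSA.** Single-trajectory end-state estimate
`ΔG_b = [E_elec + E_vdw + G_GB + G_SA](complex) − receptor − ligand`
per frame (no entropic term), with Born radii from HCT pairwise
descreening rescaled by the OBC-II tanh form (α = 1.0, β = 0.8, γ = 4.85,
offset 0.09 Å), Debye–Hückel salt screening (0.1 M default, 0.73 κ rescale),
and γ·SASA (γ = 0.0072 kcal·mol⁻¹·Å⁻²) for the nonpolar term.

## Worked example

Plant a two-component complex whose blocks are anticorrelated at
ρ = −0.6, run the full fit → reduce → correlate chain, and read the block
densities back:

```python
from mdpost.synthetic import SyntheticSpec, gaussian_block_trajectory
from mdpost.geometry import average_structure, fit_trajectory, select_heavy
from mdpost.correlation import (residue_representative_series,
                                cross_correlation_matrix,
                                block_correlation_density)

spec = SyntheticSpec(components=[("A", 30, 1), ("B", 30, 1)],
                     block_correlations={("A", "B"): -0.6},
                     n_frames=2000, seed=7)
system = gaussian_block_trajectory(spec)

heavy = select_heavy(system.topology)
masses = system.topology.masses[heavy]
mean = average_structure(system.trajectory, heavy, masses)
fitted = fit_trajectory(system.trajectory, mean, heavy, masses)

series, idx = residue_representative_series(fitted, system.topology)
ccm = cross_correlation_matrix(series, system.topology, idx)
print(block_correlation_density(ccm, system.component_map).round(3))
```

prints

```
       bath      A      B
bath  0.002 -0.003 -0.004
A    -0.003  0.610 -0.597
B    -0.004 -0.597  0.612
```

The A–B density recovers the planted −0.6 to within sampling error; the
diagonal blocks report the within-component coherence implied by the
shared-mode construction (0.6 here), and the counterweight "bath"
component — which keeps the displacement field free of rigid-body motion —
is uncorrelated with both.

The same analyses run from the shell on a YAML config, on real or
synthetic systems:

```bash
mdpost run config.yaml -o results_dir
mdpost simulate --kind gaussian --prefix fixture   # writes PDB + sidecar
```

producing `block_density.tsv`, `rmsf.tsv`, `hbond_occupancy.tsv`,
`cluster_summary.json`, `energy_*_{per_frame,per_residue,pairwise}.tsv`
and a `manifest.json` with the seed, config hash and per-stage status.

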