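# Methods

This note documents the models implemented in mdpost, the conventions and
numerical choices behind them, what the synthetic generators do and do not
emulate, and the known limitations.

## Superposition and average structures

All fits are weighted least-squares rigid superpositions (Kabsch, via an
SVD-based solver); the reflection branch is always rejected so chirality is
preserved, and degenerate point sets (fewer than three points, collinear
points, zero total weight) are errors rather than silently ill-conditioned
results. The residual RMSD is recomputed from the transformed coordinates
instead of the solver's accumulated residual, so exact rigid motions report
residuals at machine precision (~1e-15 Å) rather than ~1e-7.

The reference structure for fluctuation and correlation analysis is the
*iterative* average: frames are fitted to the current mean, the mean is
recomputed, and iteration stops when the mean moves by less than `tol`
(default 1e-6 Å, maximum 20 iterations; non-convergence is an error that
reports the last displacement). Fits use the heavy atoms of the whole
complex, mass-weighted — enough to remove global translation/rotation
without biasing any one component.

## Cross-correlation and block densities

The per-residue dynamic cross-correlation uses scalar products of 3D
displacement vectors (the standard DCC definition), which is what gives the
−1…+1 range; per-axis correlations are not computed. The residue
representative is the mass-weighted centroid of its heavy atoms by default;
an alpha-carbon mode is provided because both conventions are common and
they agree closely for compact residues.

The block score for components A, B divides the summed CC over the A×B
block by n_A·n_B, i.e. it is the *mean* cross-correlation of the block; the
A=A diagonal block includes the matrix diagonal. An alternative
normalisation — dividing by the number of summed pairs excluding the
diagonal — differs only on diagonal blocks and only by O(1/n); the product
normalisation is used because it makes the identity partition return the
CC matrix itself, a property the tests rely on.

Zero-variance residues (possible in scripted synthetic data) yield CC = 0
off-diagonal and 1 on the diagonal with a warning, never NaN.

## Flexibility profiles

Per-atom RMSF is computed over the fitted window; per-residue values are
mass-weighted means over the residue's selected atoms (a maximum would be
dominated by single long side-chain atoms), and B-factors use the isotropic
Debye–Waller conversion B = (8π²/3)·RMSF², enforced exactly as an
invariant. The profile requires at least two frames.

## Hydrogen bonds

The geometric criterion is donor-heavy–acceptor-heavy distance
≤ 3.0 Å *and* D–H–A angle ≥ 135°, both inclusive. The distance is
deliberately measured between the heavy atoms (not H···A): upstream
analysis tools that report occupancy tables with these cutoff values use
that convention, and the choice is surfaced here because published
analyses often state cutoffs without the geometry definition. Donors are
N/O/S atoms bonded to at least one hydrogen — one donor pair per proton,
so chemically equivalent protons (arginine NH1/NH2) are reported as
separate rows — and acceptors are all N/O atoms. Intra-residue pairs are
excluded. Occupancies are reported to one decimal in percent.

The differential network takes the union of (donor, H, acceptor) keys over
systems, fills absent bonds with 0%, and marks rows whose maximum occupancy
reaches the 10% report threshold as network edges; sub-threshold rows stay
in the full table. Systems sharing no keys trigger a warning (likely naming
mismatch) rather than an error.

## Clustering

Frames are compared by best-fit mass-weighted backbone (N, CA, C, O) RMSD.
Agglomerative merging proceeds under average linkage (single/complete
available) until every remaining inter-cluster distance exceeds the cutoff
(default 2.0 Å); cluster ids are assigned by descending size with ties
broken by first frame index, and each cluster's representative is its
medoid (argmin of summed intra-cluster distances, ties to the lowest frame
index). "Most representative cluster" means the largest one. The linkage
default follows the common trajectory-clustering default; it is a
convention, not a claim about any particular published run.

## MM-GBSA

Single-trajectory scheme: receptor and ligand geometries are slices of the
complex frame, so bonded and intra-group nonbonded terms cancel and the
molecular-mechanics part reduces to inter-group Coulomb
(k_e = 332.0636 kcal·Å/(mol·e²)) and 12-6 Lennard-Jones sums with
Lorentz–Berthelot combination of per-atom (Rmin/2, ε). No distance cutoffs
anywhere: target systems are desk-scale, where exact O(N²) sums are cheap
and testable.

**Born radii.** HCT pairwise descreening integrals with element-based
scale factors (H 0.85, C 0.72, N 0.79, O 0.85, S 0.96; overridable per
atom), offset radii ρ̃ = ρ − 0.09 Å, and the OBC tanh rescale
`R⁻¹ = ρ̃⁻¹ − ρ⁻¹·tanh(Ψ − 0.8Ψ² + 4.85Ψ³)` — the OBC-II (igb = 5)
constants. The isolated-atom limit is R = ρ − 0.09 Å, and the descreening
integral is validated against a Monte-Carlo volume integration of
1/(4πr⁴) over the scaled neighbor sphere.

**Polar term.** Still's effective distance
`f_ij = √(r² + R_i R_j e^{−r²/(4 R_i R_j)})` with f_ii = R_i, summed as
−½ k_e Σ_{i,j} (1/ε_in − e^{−κ f}/ε_out) q_i q_j / f_ij including self
terms. Salt enters through κ = 0.73·√(0.10806·I) Å⁻¹ for molarity I — the
empirical 0.73 rescale of the Debye length customary in GB codes. Note the
physics: salt *deepens* single-ion solvation (bounded by the κ→∞ conductor
limit), it does not shrink it. Born radii of receptor and ligand are
recomputed for the isolated species — that is what turns the GB difference
into a desolvation penalty, and it is the standard single-trajectory
definition.

**Nonpolar term.** γ·SASA with γ = 0.0072 kcal/(mol·Å²) and zero offset,
probe 1.4 Å, Shrake–Rupley on ≥ 960 points per atom (biotite backend with
the topology's intrinsic radii). The source analyses do not state their
nonpolar model; this is the package's documented convention and γ is
configurable.

**Decomposition.** The per-frame residue matrix stores each residue pair's
full interaction energy (inter-group elec+vdW plus the GB pair-term change
on binding) off-diagonal and the self terms (GB self-energy changes,
intra-residue pairs, the residue's ΔSASA share) on the diagonal; it sums
to the frame's ΔG_b exactly by construction. Per-residue values are
diagonal + half of each off-diagonal row. Pairwise tables can be
restricted to inter-partition pairs for interface hotspot ranking.

Entropy is deliberately excluded (no normal-mode or quasi-harmonic term).

## Synthetic generators: what they emulate, and what not

`gaussian_block_trajectory` plants component-pair correlations through a
shared-mode (factor) model: each requested pair (A, B) with target ρ gets
one latent Gaussian 3-vector per frame, loaded as ±√|ρ| on the two
components, with independent per-residue noise filling the variance to 1.
A direct Cholesky draw of a block-constant correlation matrix would *not*
survive the analysis chain: a field in which whole components co-move is
largely rigid-body translation, and the mandated RMS fit would subtract
it (empirically turning a planted +0.8 into ≈ −0.35). Instead, a
counterweight "bath" component split between the two chain ends carries
per-mode loadings solved so every mode has zero net loading and zero first
moment along the chain axis, making the field orthogonal to rigid motions
by construction; residues are laid out on a gentle helix so the point set
is never collinear. The generator returns the exact correlation matrix
implied by the loadings, and the expected block-density table derived
from it — the requested cross density equals ρ exactly. Residual biases
after the fit (mean-removal of the independent noise, higher-order
rotation effects) are O(1/N_res), observed ≤ 0.007 at 120 residues, well
inside the ±0.05 recovery tolerance used in the tests. A degenerate
within-block target ρ = 1 makes residue displacements identical — this is
exact on the generated frames; the (noise-driven) fitted rotation perturbs
it at the percent level, which is why the degenerate-mode check reads the
generator output directly.

The generator does *not* emulate anharmonicity, time correlation
(frames are i.i.d.), side-chain packing, or solvent effects; passing the
recovery tests demonstrates the estimator chain is correct, not that any
particular biological system behaves harmonically.

`scripted_hbond_trajectory` toggles a minimal N–H···O construct between
d(N,O) = 2.8 Å / 180° (bonded) and 5.0 Å (broken) on a prescribed
schedule; a fraction p places round(p·n) bonded frames first,
deterministically, with a seeded shuffled variant for order-invariance
tests. `conformer_mixture_trajectory` scales random deformation fields
until all conformer pairs exceed the requested best-fit backbone RMSD
separation, then draws frames multinomially and adds isotropic noise.
`toy_charged_complex` and its presets (Born ion, unit-charge pair, LJ
pair, charged dimer) feed the closed-form energy oracles; the charged
dimer's default 8 Å separation keeps the solvent-accessible spheres
disjoint so the ΔSASA term vanishes identically, which makes the rigid-
motion invariance of ΔG_b exact rather than grid-limited (the point-grid
SASA is exactly translation-invariant but only grid-approximately
rotation-invariant).

Synthetic atoms carry uniform carbon-like parameters unless specified, so
mass-weighting code paths are exercised by dedicated non-uniform-mass
fixtures rather than entangled with the statistics.

## Problem sizes and determinism

Default test/acceptance workloads: correlation recovery on 2×30 named
residues plus a 60+60 bath at 5000 frames; clustering on 90 frames of a
20-atom backbone; RMSF recovery at 10⁵ frames of a 4-atom system;
Monte-Carlo descreening oracle at 10⁷ samples; MM-GBSA toys of 1–5 atoms.
These sizes were chosen so each check is statistically decisive (sampling
error well under its tolerance) while the whole battery runs in about a
minute. All randomness flows from explicit seeds through
`numpy.random.default_rng`; the pipeline writes a manifest with the seed
and a config hash, and repeated runs are byte-identical.

## Known limitations

* Multi-model PDB is the only trajectory format (3-decimal coordinate
  precision bounds round-trips); binary formats are out of scope.
* The parameter sidecar is a documented YAML schema, not a force-field
  parser; Amber/CHARMM/GROMACS topologies must be converted upstream.
* H-bond analysis has no water-mediated bridging or salt-bridge-specific
  geometry; clustering offers no density-based or streaming variants.
* GB is the OBC-II model only; no Poisson-Boltzmann solver, no explicit
  solvent, no entropy estimate. Absolute ΔG_b values from end-state GB
  methods are model-dependent; the package's validated guarantees are the
  closed-form limits and internal consistency (component, per-residue and
  pairwise sums), not agreement with experiment.
* The default MHC class I heavy-chain domain split (α1 1–90, α2 91–182,
  α3 183–end) is a convention and should be overridden when the structure's
  domain boundaries are known.
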