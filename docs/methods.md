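# Methods

## Scope and units

The package analyzes (and synthesizes stand-ins for) molecular-dynamics
trajectories of a solvated protein exposed to nanosecond pulsed electric
fields. Internally: lengths in nm, times in ns, charges in elementary
charge units e, fields in V/m, dipoles in e·nm (1 e·nm = 48.0321 D).
Conversions happen only at format boundaries (PDB and XYZ files are
Angstrom, GRO is nm). The MD engine itself is out of scope: trajectories
are inputs (concatenated GRO/XYZ plus a charge/mass/species sidecar
TSV, since structure formats carry no force-field metadata) or come from
the synthetic generators.

## Pulse model

Pulses are piecewise envelopes scaled by an amplitude E₀ and applied
along a unit direction. The monopolar (MP) default is a 2 ns linear
rise, 100 ns hold, 2 ns fall (104 ns support); the bipolar (BP) default
holds +E₀ for 50 ns, reverses linearly to −E₀ over 2 ns, holds 50 ns
and falls over 2 ns. Ramp duration is documented but ramp *shape* is a
choice: linear by default, `smoothstep` available. The reversal duration
is likewise not dictated by the modeled protocol; 2 ns (equal to
rise/fall) is the default. The post-pulse 50 ns tail is represented as
zero amplitude, not truncation, so off-phase analysis windows exist.
A symmetric BP has exactly zero time integral (antisymmetry about the
reversal midpoint); the sampled check allows one grid cell of tolerance.

## Explicit-Coulomb field maps

The local field at node rᵢ is the direct sum of Coulomb kernels over all
atoms, accumulated separately for protein, water and ion species; the
only hard-coded constant is 1 e/(4πε₀·nm²) = 1.439964×10⁹ V/m (ε₀ at
the CODATA value). Implicit-solvent electrostatics are deliberately
absent — the point of the map is the heterogeneous explicit environment.

Grid geometry: an orthonormal right-handed frame is built from three
anchor atoms (Cu origin, x along Cu→O₂⁻, in-plane axis completing the
Cu/O/Zn plane). Plane π″ spans (x, in-plane), π′ spans (x, normal).
Default extent 4.7 nm at 0.05 nm spacing gives 95 × 95 = 9025 nodes,
center node on the Cu. The anchors are taken from a designated reference
frame and held fixed across averaged frames (per-frame re-anchoring
would conflate field changes with frame wobble; it can be done by
evaluating single-frame maps with per-frame grids).

Numerical choices:

- The bare kernel diverges at atom positions. Nodes with any atom inside
  an exclusion radius (default 0.05 nm, one grid cell) are *masked but
  still reported*; masks propagate through averaging (any frame) and
  differences (union).
- Periodic boundaries: `none` by default (the literal sum over box
  contents); `minimum_image` folds displacements into the nearest image
  using each frame's orthorhombic box. Triclinic boxes are rejected.
- Averaging is the arithmetic mean of per-frame fields over the selected
  window. Difference maps are node-wise subtractions (signal-on minus
  reference) per species and total.
- The vectorized kernel is chunked over nodes (default 512/block) to
  bound memory; tests pin it to a naive double loop at 1e-9 relative.

## Dipole spectrograms

M(t) = Σ qᵢrᵢ over a selection (translation-invariant when the selection
is net-neutral). The spectrogram is the squared modulus of the windowed
DFT: Hamming window, 4 ns length, 50% overlap by default, giving 0.25
GHz bins (bin spacing is 1/window_length; with ns input frequencies are
GHz). A published description of this analysis gives a segment length of
4.0×10⁻¹¹ s *and* 0.25 GHz resolution, which are mutually inconsistent;
this package adopts the self-consistent reading — 4 ns windows on a
series sampled every 40 ps — and both are configurable. A quoted "6 ns
time resolution" is likewise not derivable from a 4 ns window with 2 ns
hop and is not reproduced.

Normalization: one-sided bins scaled so that the per-segment bin sum
equals the energy of the windowed segment, Σ_f P_f = Σ_t (w_t x_t)²,
making Parseval's identity exactly testable. No detrending by default —
during a pulse the DC polarization offset is signal; note that any
constant offset also appears in bin 1, because the Hamming window
w[n] = 0.54 − 0.46 cos(2πn/N) has exact DFT components at bins 0 and ±1.
Analyses of pulse-locked power therefore compare bins ≥ 2 (above the
window main lobe). The PSD is the segment average of the same matrix;
the spectral centroid excludes DC by default.

## Structural observables

- RMSD: optional optimal least-squares superposition (rotation +
  translation, weighted Kabsch via `scipy.spatial.transform.Rotation.
  align_vectors`) before the weighted RMS deviation. Collinear
  selections cannot be fitted and are rejected. Superposed RMSD is never
  larger than raw RMSD.
- Radius of gyration: mass-weighted by default,
  Rg = √(Σmᵢ|rᵢ−r_cm|²/Σmᵢ).
- SASA: Shrake–Rupley point sampling — 960 quasi-uniform points
  (golden-spiral lattice) on each atom's sphere of radius r_vdW + probe
  (probe 0.14 nm), occlusion tested against neighbors found with a k-d
  tree. Radii default to the Bondi set; the hydrophobic class is C and S
  elements, everything else hydrophilic. The element is the first letter
  of the atom name unless the name matches an ion-like residue (so
  protein "CA" is carbon, the Ca²⁺ ion is calcium). The area estimate
  converges to <1% on doubling the point count; an independent
  implementation (biotite) agrees within the sampling tolerance.
- Secondary structure: DSSP classification is upstream; the package
  ingests per-frame class-count TSVs (`time_ns`, `beta_sheet`, `coil`,
  optional `helix/turn/other`, `phase` ∈ {no_field, on, off}) and
  validates counts and phase labels. The expected upstream command is a
  DSSP run followed by per-frame class counting.
- Densities: normalized histograms (Freedman–Diaconis default) or
  Gaussian KDE (Scott's rule), with a single-bin density for constant
  input rather than an error.

## Statistics

Percent change is 100·(mean_exposed − mean_reference)/mean_reference,
reported to one decimal with both SD and SEM per sample (conventions for
error bars vary; both are emitted). The attached test is the pooled
two-sided Student's t-test by default (Welch optional), with stars at
*P<0.05, **P<0.01, ***P<0.005. Zero-variance degenerate samples follow a
documented convention: equal means → p = 1, unequal → p = 0.

MD-like series are serially correlated, so samples are thinned at the
integrated autocorrelation time before testing (Sokal's self-consistent
window, τ = dt(1 + 2Σρ_k) summed while the window < 6τ/dt); unthinned
testing remains available by passing the raw arrays. Under the null the
empirical type-I error at α = 0.05 stays within [0.03, 0.07] over 1000
replicates. No multiple-testing correction is applied across condition
grids.

## Synthetic generators

The generators emulate the statistical structure the analysis assumes;
they are not force-field physics.

- **Rotor ensemble**: n non-interacting rigid dipoles (a ±μ/d charge
  pair at fixed separation d = 0.1 nm, so the dipole magnitude is
  exactly μ) pinned at random centers in a 10 × 11 × 9 nm³ box. Each
  orientation u evolves by overdamped rotational Langevin dynamics:
  deterministic tangential drift D_r·(I − uuᵀ)(μE(t)/kT)·dt plus
  tangential Gaussian noise of variance 2D_r·dt, then renormalization
  (Euler on the sphere). This has the right stationary state (Boltzmann
  in x·cosθ with x = μE/kT: mean alignment = the Langevin function,
  verified within 5% at x = 2) and the right free relaxation
  (⟨u(0)·u(t)⟩ = e^(−2D_r t), verified within 10%). Temperature enters
  only through x; default 300 K. Defaults μ = 0.1 e·nm (≈4.8 D) and
  D_r = 1/ns (protein-like slow rotor; the water bath uses a larger
  D_r, e.g. 8–10/ns, enforcing the faster-than-protein relaxation that
  makes its spectrum broader). The step must resolve pulse ramps
  (dt ≤ rise/4).
- **β-sheet↔coil Markov chain**: each of `units` strands flips
  independently with rates k_bc, k_cb (per-step probability
  1 − e^(−k·dt); stability requires dt·k < 0.1), with on-phase rate
  multipliers and a {no_field, on, off} schedule. Defaults
  k_bc = k_cb = 0.25/ns (≈2 ns exchange), reflecting folded/partially
  denatured transitions that complete within a few ns.
  `beta_drop_multiplier` converts a target stationary β-fraction drop
  into the on-phase multiplier in closed form; the statistics stage
  recovers a programmed −37% within ±3 points at units = 200 over a
  500 ns schedule. Choosing the off-phase β fraction as 28/65 makes the
  same count shift simultaneously −37% in β-sheet and +28% in coil.
- **Point-charge fixtures** and the **study-composition topology**
  (2774 protein atoms + 32292 three-site waters + 9 Na⁺ = 99659 atoms)
  exercise the field-map kernel and species bookkeeping.

All generators are deterministic given their seed.

### What the synthetic data does and does not show

The rotors have no mutual interactions, no translation, no hydrodynamic
or dielectric coupling between "protein" and "water" species, and no
link between field exposure and the Markov secondary-structure rates;
the unfolding thresholds of a real enzyme (5–7×10⁸ V/m) are inputs to
the generator, never predictions. Passing tests therefore demonstrate
that the *analysis chain* — field summation, spectral estimation,
observable computation, statistics — is correct on data with known
ground truth, not that any specific protein behaves a given way.

## Problem sizes

Test and acceptance runs use desk-scale problems chosen to make the
statistical tolerances comfortable: ≤2000 rotors for equilibrium
recovery, 100 atoms × 100 nodes for the Coulomb oracle, 200 Markov units
over 500 ns, 1000 t-test replicates. The field-map evaluator handles the
full 9025-node grid; wall-clock scales linearly in nodes × atoms ×
frames.

## Known limitations

- The crystal-structure radius-of-gyration check (≈1.9 nm for the
  Cu/Zn-SOD dimer, PDB 1SXZ) requires coordinates the repository does
  not redistribute; the corresponding test reports as failed when
  `data/1sxz.pdb` is absent rather than substituting a stand-in.
- PDB parsing is fixed-column (wwPDB v3.3 ATOM/HETATM); altloc other
  than blank/'A' is skipped; orthorhombic boxes only.
- No Ewald/reaction-field corrections in the field maps, by design.
- The Euler-on-sphere rotor integrator has O(dt) bias; defaults keep
  D_r·dt ≤ 0.02 where the bias is well below the test tolerances.
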