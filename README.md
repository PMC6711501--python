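# pulsefield

Analysis pipeline for the response of a solvated enzyme to intense
nanosecond pulsed electric fields (nsPEF), built around the Cu/Zn
superoxide dismutase (SOD1) case: the homodimeric enzyme whose active
site — a catalytic Cu²⁺, a structural Zn²⁺ and the approaching
superoxide O₂⁻ — steers its substrate by *electrostatic guidance*.
Fields of 10⁸–7×10⁸ V/m applied for ~100 ns can modulate that
electrostatic environment below (and disrupt the structure above) a
threshold intensity; this package provides the full analysis chain used
to quantify both regimes on molecular-dynamics trajectories, plus
seeded synthetic generators so every stage is testable without MD runs.

## What it computes

- **Pulse waveforms** — monopolar (MP: 2 ns rise, 100 ns hold, 2 ns
  fall) and bipolar (BP: 50 ns per pole with a 2 ns reversal) envelopes,
  amplitude E₀ in V/m along a unit direction (y by default).
- **Local electric-field maps** — the explicit Coulomb sum at grid node
  rᵢ, split by chemical species,

  E(rᵢ) = Σₙ qₙ (rₙ − rᵢ) / (4πε₀ |rₙ − rᵢ|³),  n ∈ {protein, water, ions}

  evaluated on two orthogonal 4.7 × 4.7 nm² planes anchored on the
  Cu→O₂⁻ axis (π″ contains Zn, π′ is perpendicular), meshed at 0.05 nm,
  averaged over frames, with difference maps against a no-field
  reference. No implicit dielectric, no Ewald.
- **Dipole spectrograms** — M(t) = Σ qᵢrᵢ per selection; squared-modulus
  short-time Fourier transform with a 4 ns Hamming window at 50%
  overlap (0.25 GHz frequency bins), Welch-style PSD and spectral
  centroids.
- **Structural observables** — Kabsch-superposed RMSD, mass-weighted
  radius of gyration, Shrake–Rupley SASA with a hydrophobic (C,S) /
  hydrophilic split, DSSP-downstream secondary-structure count tables,
  and histogram/KDE probability densities.
- **Exposure statistics** — percent changes between phases
  (no_field/on/off), two-sided Student's (or Welch) t-tests with the
  *P<0.05, **P<0.01, ***P<0.005 star convention, and integrated
  autocorrelation-time thinning so the tests see effectively
  independent frames.
- **Synthetic data** — point-charge clouds with known fields; dipolar
  rotor ensembles under overdamped rotational Langevin dynamics (the
  stationary alignment of a rotor with coupling x = μE/kT is the
  Langevin function L(x) = coth x − 1/x); a faster-relaxing water-like
  bath; and two-state β-sheet↔coil Markov count series with
  programmable field-on rate changes.

## Worked example

`python examples/05_secondary_structure_stats.py` generates a 200-unit
β-sheet↔coil series whose field-on rates are programmed for a 37%
stationary β-sheet loss, then runs the statistics stage on it:

```
             condition  reference_mean  ...  percent_change      t    df            p stars
beta_sheet on/no_field          99.621  ...           -37.4 28.317 121.0 3.214711e-55   ***
programmed stationary change: -37.0%; recovered: -37.4% (***)
```

The pipeline recovers the programmed −37% within sampling error and
flags it as highly significant. The other examples cover waveforms
(`01`), field maps with the superposition check (`02`), pulse-driven
dipole spectrograms — ramp segments carry more high-frequency power than
the hold plateau (`03`), RMSD/Rg/SASA (`04`) and the end-to-end pipeline
with its manifest (`06`). A thin CLI mirrors the stages:

```bash
pulsefield waveform --shape mp --e0 1e8 --out waveform.tsv
pulsefield run --seed 1 --out artifacts/
```

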