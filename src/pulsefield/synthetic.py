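"""Synthetic inputs with the statistical structure the analysis assumes.

Real inputs to this pipeline are multi-hundred-ns all-atom MD
trajectories; these generators produce seeded, physically structured
stand-ins at desk scale:

* point-charge clouds with exactly known Coulomb fields,
* dipolar rotor ensembles obeying overdamped rotational Langevin
  dynamics — Debye-like relaxation, Langevin-function alignment in a
  static field, and a pulse-following polarization response,
* a faster-relaxing water-like dipole bath,
* two-state (beta-sheet <-> coil) Markov count series with programmable
  field-on transition-rate changes.

Everything is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import K_BOLTZMANN_EV
from .core import Atom, Frame, Topology, Trajectory
from .observables import SSCountSeries
from .waveforms import PulseSpec, make_pulse

__all__ = [
    "RotorEnsembleSpec",
    "SSMarkovSpec",
    "make_point_charge_fixture",
    "simulate_rotor_trajectory",
    "make_water_bath",
    "make_ss_markov_series",
    "beta_drop_multiplier",
    "make_study_composition_topology",
]

#: Fixed charge-pair separation (nm): dipole magnitude maps exactly to mu.
ROTOR_SEPARATION = 0.1


@dataclass(frozen=True)
class RotorEnsembleSpec:
    """Ensemble of non-interacting dipolar rotors.

    Each rotor is a rigid +q/-q pair of separation 0.1 nm pinned at a
    fixed center; only its orientation diffuses, with rotational
    diffusion coefficient ``D_r`` (1/ns) and deterministic torque from
    the applied pulse. The coupling enters only through x = mu E / kT.
    """

    n_rotors: int = 500
    mu: float = 0.1  # e·nm (~4.8 D, a few water dipoles / small residue)
    D_r: float = 1.0  # 1/ns
    temperature: float = 300.0  # K
    seed: int = 0
    dt: float = 0.02  # ns
    pulse: PulseSpec | None = None
    species: str = "protein"
    box: tuple[float, float, float] = (10.0, 11.0, 9.0)  # nm

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.D_r <= 0:
            raise ValueError("D_r must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


@dataclass(frozen=True)
class SSMarkovSpec:
    """Two-state beta_sheet <-> coil Markov dynamics for ``units`` strands.

    ``k_bc``/``k_cb`` are field-off rates (1/ns); during 'on' phases both
    are scaled by their multipliers. The phase schedule is a sequence of
    (label, duration ns) entries with labels in {no_field, on, off}.
    """

    units: int = 200
    k_bc: float = 0.25  # beta -> coil, 1/ns (few-ns exchange)
    k_cb: float = 0.25  # coil -> beta, 1/ns
    on_mult_bc: float = 1.0
    on_mult_cb: float = 1.0
    schedule: tuple = (("no_field", 100.0),)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.units <= 0:
            raise ValueError("units must be > 0")
        if self.k_bc < 0 or self.k_cb < 0:
            raise ValueError("rates must be >= 0")


def make_point_charge_fixture(
    n: int,
    box=(2.0, 2.0, 2.0),
    charge_values=(1.0, -1.0),
    seed: int = 0,
    species: str = "protein",
) -> tuple[Topology, Frame]:
    """Reproducible random point charges inside a box (charges cycled)."""
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    positions = rng.uniform(0.0, 1.0, size=(n, 3)) * box
    charge_values = list(charge_values) or [0.0]
    atoms = [
        Atom(
            index=i,
            name=f"Q{i}",
            residue_name="CHG",
            residue_id=i + 1,
            species=species,
            charge=float(charge_values[i % len(charge_values)]),
            mass=1.0,
        )
        for i in range(n)
    ]
    return Topology(atoms), Frame(time=0.0, positions=positions, box=box)


def make_study_composition_topology(
    n_protein_atoms: int = 2774,
    n_waters: int = 32292,
    n_ions: int = 9,
) -> Topology:
    """Assemble a topology with the solvated-enzyme system composition.

    Defaults mirror the simulated system: a 2774-atom protein model
    solvated by 32292 three-site (SPC) waters with 9 Na+ counterions —
    99659 atoms in total. Coordinates are not assigned; this manifest
    exercises species bookkeeping and atom-count arithmetic at full
    system size.
    """
    atoms = []
    i = 0
    for p in range(n_protein_atoms):
        atoms.append(
            Atom(index=i, name="CA", residue_name="PRO", residue_id=1 + p // 8,
                 species="protein", mass=12.0)
        )
        i += 1
    for w in range(n_waters):
        for name, mass, charge in (("OW", 15.9994, -0.82),
                                   ("HW1", 1.008, 0.41),
                                   ("HW2", 1.008, 0.41)):
            atoms.append(
                Atom(index=i, name=name, residue_name="SOL",
                     residue_id=10000 + w, species="water",
                     charge=charge, mass=mass)
            )
            i += 1
    for ion in range(n_ions):
        atoms.append(
            Atom(index=i, name="NA", residue_name="NA",
                 residue_id=50000 + ion, species="ion", charge=1.0,
                 mass=22.99)
        )
        i += 1
    return Topology(atoms)


def _isotropic_unit_vectors(rng, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def simulate_rotor_trajectory(spec: RotorEnsembleSpec, t_end: float) -> Trajectory:
    """Overdamped rotational Langevin dynamics of the rotor ensemble.

    Per step the orientation u receives the deterministic tangential
    drift D_r * (I - uu^T) (mu E / kT) dt plus isotropic tangential noise
    of variance 2 D_r dt, then is renormalized. The stationary
    distribution in a static field E is Boltzmann in x cos(theta) with
    x = mu E / kT (Langevin-function mean alignment); at E = 0 the
    orientation autocorrelation decays as exp(-2 D_r t).
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if spec.pulse is not None and spec.pulse.rise > 0 and spec.dt > spec.pulse.rise / 4:
        raise ValueError(
            f"dt={spec.dt} ns too coarse to resolve the {spec.pulse.rise} ns "
            "pulse ramp (need dt <= rise/4)"
        )
    rng = np.random.default_rng(spec.seed)
    n = spec.n_rotors
    centers = rng.uniform(0.0, 1.0, size=(n, 3)) * np.asarray(spec.box)
    u = _isotropic_unit_vectors(rng, n) if n else np.zeros((0, 3))

    kT = K_BOLTZMANN_EV * spec.temperature  # eV
    # mu[e·nm] * E[V/m] * 1e-9 -> eV; field_to_x maps E vector to mu E / kT
    field_scale = spec.mu * 1e-9 / kT
    envelope = make_pulse(spec.pulse) if spec.pulse is not None else None
    direction = (
        np.asarray(spec.pulse.direction, dtype=float)
        if spec.pulse is not None
        else np.zeros(3)
    )

    q = spec.mu / ROTOR_SEPARATION if spec.mu > 0 else 0.0
    atoms = []
    for i in range(n):
        atoms.append(
            Atom(index=2 * i, name="DP", residue_name="ROT", residue_id=i + 1,
                 species=spec.species, charge=q, mass=1.0)
        )
        atoms.append(
            Atom(index=2 * i + 1, name="DM", residue_name="ROT",
                 residue_id=i + 1, species=spec.species, charge=-q, mass=1.0)
        )
    topology = Topology(atoms)

    n_steps = int(np.floor(t_end / spec.dt + 1e-9))
    sqrt_noise = np.sqrt(2.0 * spec.D_r * spec.dt)
    half = 0.5 * ROTOR_SEPARATION
    frames = []

    def snapshot(t, u_now):
        pos = np.empty((2 * n, 3))
        pos[0::2] = centers + half * u_now
        pos[1::2] = centers - half * u_now
        return Frame(time=t, positions=pos, box=np.asarray(spec.box, float))

    frames.append(snapshot(0.0, u))
    for step in range(1, n_steps + 1):
        t = step * spec.dt
        if n:
            if envelope is not None:
                e_vec = envelope(t - spec.dt) * direction
                x_vec = field_scale * e_vec  # dimensionless torque vector
                drift = spec.D_r * spec.dt * (
                    x_vec[None, :] - (u @ x_vec)[:, None] * u
                )
            else:
                drift = 0.0
            xi = rng.normal(size=(n, 3))
            noise = sqrt_noise * (xi - (np.sum(xi * u, axis=1))[:, None] * u)
            u = u + drift + noise
            u /= np.linalg.norm(u, axis=1, keepdims=True)
        frames.append(snapshot(t, u))
    return Trajectory(topology=topology, frames=frames)


def make_water_bath(
    n_waters: int,
    D_r_water: float = 10.0,
    protein_D_r: float = 1.0,
    **overrides,
) -> Trajectory:
    """Water-like dipole bath: rotors with faster relaxation than protein.

    ``D_r_water`` must exceed the protein-like ``protein_D_r`` so the
    bath's spectral content is genuinely broader.
    """
    if n_waters and D_r_water <= protein_D_r:
        raise ValueError("water bath must relax faster than the protein rotor")
    t_end = overrides.pop("t_end", 100.0)
    spec = RotorEnsembleSpec(
        n_rotors=n_waters,
        D_r=D_r_water,
        species="water",
        **overrides,
    )
    if n_waters == 0:
        topo = Topology([])
        return Trajectory(topology=topo, frames=[])
    return simulate_rotor_trajectory(spec, t_end=t_end)


def beta_drop_multiplier(k_bc: float, k_cb: float, drop_fraction: float) -> float:
    """On-phase multiplier of k_bc lowering the stationary beta fraction.

    Off-phase stationary beta fraction is p0 = k_cb/(k_bc + k_cb); the
    returned multiplier m makes the on-phase stationary fraction
    (1 - drop_fraction) * p0.
    """
    if not 0 < drop_fraction < 1:
        raise ValueError("drop_fraction must be in (0, 1)")
    p0 = k_cb / (k_bc + k_cb)
    p1 = (1.0 - drop_fraction) * p0
    return (k_cb * (1.0 / p1 - 1.0)) / k_bc


def make_ss_markov_series(
    spec: SSMarkovSpec, dt: float = 0.1, t_end: float | None = None
) -> SSCountSeries:
    """Simulate per-unit two-state dynamics over the phase schedule.

    Each unit flips beta->coil with probability 1 - exp(-k_bc dt) per step
    (k_bc scaled by its on-multiplier during 'on' phases) and back with
    the analogous coil->beta probability. Initial states are drawn from
    the field-off stationary distribution.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    max_rate = max(
        spec.k_bc, spec.k_cb, spec.k_bc * spec.on_mult_bc, spec.k_cb * spec.on_mult_cb
    )
    if dt * max_rate >= 0.1:
        raise ValueError(
            f"dt={dt} ns unstable for max rate {max_rate}/ns "
            "(need dt * rate < 0.1)"
        )
    schedule = list(spec.schedule)
    total = sum(d for _, d in schedule)
    if t_end is not None and abs(total - t_end) > 1e-9:
        raise ValueError(
            f"schedule spans {total} ns but t_end={t_end} ns was requested"
        )
    rng = np.random.default_rng(spec.seed)
    p0 = spec.k_cb / (spec.k_bc + spec.k_cb) if (spec.k_bc + spec.k_cb) > 0 else 1.0
    state = rng.random(spec.units) < p0  # True = beta

    times, beta_counts, phases = [], [], []
    t = 0.0
    for label, duration in schedule:
        n_steps = int(round(duration / dt))
        mult_bc = spec.on_mult_bc if label == "on" else 1.0
        mult_cb = spec.on_mult_cb if label == "on" else 1.0
        p_bc = 1.0 - np.exp(-spec.k_bc * mult_bc * dt)
        p_cb = 1.0 - np.exp(-spec.k_cb * mult_cb * dt)
        for _ in range(n_steps):
            times.append(t)
            beta_counts.append(int(state.sum()))
            phases.append(label)
            r = rng.random(spec.units)
            flips_down = state & (r < p_bc)
            flips_up = (~state) & (r < p_cb)
            state = state ^ flips_down ^ flips_up
            t += dt
    counts_beta = np.array(beta_counts)
    return SSCountSeries(
        times=np.array(times),
        counts={
            "beta_sheet": counts_beta,
            "coil": spec.units - counts_beta,
        },
        phase=np.array(phases, dtype=object),
    )
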