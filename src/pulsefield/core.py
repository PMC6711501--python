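"""Data model for topologies, frames and trajectories.

A :class:`Topology` is an ordered collection of atoms carrying identity
(name, residue), partial charge in elementary-charge units, mass in amu,
and a species label partitioning the system into ``protein``, ``water``
and ``ion`` — the three categories of the explicit-Coulomb field sum.
A :class:`Frame` holds per-atom positions in nm plus an orthorhombic box;
a :class:`Trajectory` is a time-ordered sequence of frames over one
topology.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

SPECIES = ("protein", "water", "ion")

#: Residue names mapped to a default species when no sidecar is attached.
WATER_RESNAMES = {"SOL", "HOH", "WAT"}
ION_RESNAMES = {"NA", "CL", "NA+", "CL-"}


class ParseError(ValueError):
    """Raised when a structure or trajectory file fails to parse."""


class TopologyError(ValueError):
    """Raised on inconsistent topology/frame combinations."""


@dataclass(frozen=True)
class Atom:
    """One atom: identity plus force-field metadata.

    ``charge`` is the partial charge in elementary-charge units entering
    the Coulomb field sum; ``species`` selects which of the three sum
    terms (protein / water / ion) the atom contributes to.
    """

    index: int
    name: str
    residue_name: str
    residue_id: int
    species: str = "protein"
    charge: float = 0.0
    mass: float = 0.0

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise TopologyError(
                f"atom {self.index}: species {self.species!r} not in {SPECIES}"
            )
        if self.mass < 0:
            raise TopologyError(f"atom {self.index}: negative mass {self.mass}")


class Topology:
    """Ordered atom collection with vectorized property access."""

    def __init__(self, atoms: Sequence[Atom]):
        self.atoms = list(atoms)
        indices = [a.index for a in self.atoms]
        if len(set(indices)) != len(indices):
            raise TopologyError("duplicate atom indices in topology")
        self._charges = np.array([a.charge for a in self.atoms], dtype=float)
        self._masses = np.array([a.mass for a in self.atoms], dtype=float)
        self._species = np.array([a.species for a in self.atoms], dtype=object)
        self._names = np.array([a.name for a in self.atoms], dtype=object)
        self._resnames = np.array(
            [a.residue_name for a in self.atoms], dtype=object
        )

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def charges(self) -> np.ndarray:
        return self._charges

    @property
    def masses(self) -> np.ndarray:
        return self._masses

    @property
    def species(self) -> np.ndarray:
        return self._species

    @property
    def names(self) -> np.ndarray:
        return self._names

    @property
    def residue_names(self) -> np.ndarray:
        return self._resnames

    def total_charge(self) -> float:
        return float(self._charges.sum())

    def with_atoms(self, atoms: Sequence[Atom]) -> "Topology":
        return Topology(atoms)


@dataclass
class Frame:
    """Per-atom positions (nm) at one instant, with an orthorhombic box."""

    time: float  # ns
    positions: np.ndarray  # (n_atoms, 3) nm
    box: np.ndarray | None = None  # (3,) edge lengths, nm

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise TopologyError(
                f"positions must be (n, 3), got {self.positions.shape}"
            )
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,):
                raise TopologyError(
                    "box must be three orthorhombic edge lengths; "
                    "triclinic boxes are not supported"
                )
            if np.any(self.box <= 0):
                raise TopologyError(f"box edges must be > 0, got {self.box}")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]


@dataclass
class Trajectory:
    """Time-ordered frames sharing one topology."""

    topology: Topology
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.topology)
        for i, f in enumerate(self.frames):
            if f.n_atoms != n:
                raise TopologyError(
                    f"frame {i} has {f.n_atoms} atoms, topology has {n}"
                )
        times = [f.time for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise TopologyError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=float)


def default_species(residue_name: str) -> str:
    """Heuristic species from a residue name (sidecar-overridable)."""
    resname = residue_name.strip().upper()
    if resname in WATER_RESNAMES:
        return "water"
    if resname in ION_RESNAMES:
        return "ion"
    return "protein"


def select(topology: Topology, selector: str) -> np.ndarray:
    """Indices of atoms matching a species token or an atom-name pattern.

    ``selector`` is one of the species labels (``protein``/``water``/
    ``ion``), or ``all``, or an fnmatch-style pattern on atom names
    (e.g. ``"CA"`` or ``"H*"``). Species selections partition the atom
    set. Unknown bare lowercase tokens raise, so typos like ``watr``
    do not silently match nothing.
    """
    if selector == "all":
        return np.arange(len(topology))
    if selector in SPECIES:
        return np.flatnonzero(topology.species == selector)
    if selector.islower() and selector.isalpha():
        raise ValueError(
            f"unknown species token {selector!r}; expected one of "
            f"{SPECIES + ('all',)} or an atom-name pattern"
        )
    mask = np.array(
        [fnmatch.fnmatchcase(str(n), selector) for n in topology.names],
        dtype=bool,
    )
    return np.flatnonzero(mask)


def update_atom(atom: Atom, **kwargs) -> Atom:
    return replace(atom, **kwargs)
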