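"""Readers and writers for PDB/GRO structures, multi-frame trajectories
and the charge/mass/species sidecar table.

Coordinates are converted to nm at the format boundary: PDB and XYZ files
are interpreted as Angstrom, GRO as nm. Structure formats carry no partial
charges, so atoms come back with zero charge/mass and a heuristic species
(water for SOL/HOH/WAT residues, ion for NA/CL) until a sidecar is
attached with :func:`attach_properties`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .constants import ANGSTROM_TO_NM
from .core import (
    SPECIES,
    Atom,
    Frame,
    ParseError,
    Topology,
    TopologyError,
    Trajectory,
    default_species,
    update_atom,
)

__all__ = [
    "read_structure",
    "attach_properties",
    "read_trajectory",
    "write_gro",
    "write_topology_tsv",
]


def read_structure(path, dialect: str) -> tuple[Topology, Frame]:
    """Read a single-frame structure file.

    Parameters
    ----------
    path : path-like
    dialect : {"pdb", "gro"}

    Returns
    -------
    (Topology, Frame)
        Positions in nm; charges/masses zero and species from the
        residue-name heuristic until a sidecar is attached.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty file")
    if dialect == "pdb":
        return _parse_pdb(text, str(path))
    if dialect == "gro":
        return _parse_gro_frame(text.splitlines(), str(path), 0)[:2]
    raise ValueError(f"unknown structure dialect {dialect!r}")


def _parse_pdb(text: str, label: str) -> tuple[Topology, Frame]:
    atoms: list[Atom] = []
    coords: list[list[float]] = []
    box = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6].strip()
        if record == "CRYST1":
            try:
                box = (
                    np.array(
                        [float(line[6:15]), float(line[15:24]), float(line[24:33])]
                    )
                    * ANGSTROM_TO_NM
                )
            except ValueError as exc:
                raise ParseError(f"{label}:{lineno}: malformed CRYST1: {exc}")
        if record not in ("ATOM", "HETATM"):
            continue
        altloc = line[16:17]
        if altloc not in (" ", "", "A"):
            continue
        try:
            name = line[12:16].strip()
            resname = line[17:20].strip()
            resid = int(line[22:26])
            xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{label}:{lineno}: malformed ATOM record: {exc}")
        atoms.append(
            Atom(
                index=len(atoms),
                name=name,
                residue_name=resname,
                residue_id=resid,
                species=default_species(resname),
            )
        )
        coords.append([c * ANGSTROM_TO_NM for c in xyz])
    if not atoms:
        raise ParseError(f"{label}: no ATOM/HETATM records found")
    return Topology(atoms), Frame(time=0.0, positions=np.array(coords), box=box)


def _parse_gro_frame(
    lines: list[str], label: str, offset: int
) -> tuple[Topology, Frame, int]:
    """Parse one GRO record starting at ``offset``; returns consumed end."""
    if offset >= len(lines):
        raise ParseError(f"{label}: truncated GRO record at line {offset + 1}")
    title = lines[offset]
    time = _time_from_comment(title)
    try:
        n_atoms = int(lines[offset + 1].strip())
    except (ValueError, IndexError):
        raise ParseError(
            f"{label}:{offset + 2}: expected atom count, got "
            f"{lines[offset + 1]!r}"
            if offset + 1 < len(lines)
            else f"{label}: truncated GRO record"
        )
    atoms: list[Atom] = []
    coords = np.empty((n_atoms, 3))
    for i in range(n_atoms):
        lineno = offset + 2 + i
        if lineno >= len(lines):
            raise ParseError(f"{label}:{lineno + 1}: truncated GRO record")
        line = lines[lineno]
        try:
            resid = int(line[0:5])
            resname = line[5:10].strip()
            name = line[10:15].strip()
            coords[i] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{label}:{lineno + 1}: malformed GRO line: {exc}")
        atoms.append(
            Atom(
                index=i,
                name=name,
                residue_name=resname,
                residue_id=resid,
                species=default_species(resname),
            )
        )
    box_lineno = offset + 2 + n_atoms
    if box_lineno >= len(lines):
        raise ParseError(f"{label}:{box_lineno + 1}: missing GRO box line")
    box_fields = lines[box_lineno].split()
    if len(box_fields) not in (3, 9):
        raise ParseError(
            f"{label}:{box_lineno + 1}: expected 3 or 9 box components"
        )
    if len(box_fields) == 9 and any(float(v) != 0.0 for v in box_fields[3:]):
        raise TopologyError(
            f"{label}:{box_lineno + 1}: triclinic box not supported"
        )
    box = np.array([float(v) for v in box_fields[:3]])
    frame = Frame(
        time=0.0 if time is None else time,
        positions=coords,
        box=box if np.all(box > 0) else None,
    )
    return Topology(atoms), frame, box_lineno + 1


def _time_from_comment(comment: str) -> float | None:
    """Extract a time stamp from a GRO title / XYZ comment (``t= 1.5``)."""
    lowered = comment.lower()
    for token in ("t=", "time="):
        if token in lowered.replace(" ", ""):
            tail = lowered.replace(" ", "").split(token, 1)[1]
            number = ""
            for ch in tail:
                if ch in "0123456789.eE+-":
                    number += ch
                else:
                    break
            try:
                return float(number)
            except ValueError:
                return None
    return None


def attach_properties(topology: Topology, sidecar) -> Topology:
    """Attach charges, masses and species from a TSV sidecar.

    Two dialects: per-atom rows keyed by ``index``, or template rows keyed
    by ``(residue_name, atom_name)`` covering every atom. Both carry
    ``charge`` (e), ``mass`` (amu) and ``species`` columns.
    """
    # keep_default_na: residue/atom names like "NA" are names, not missing
    table = pd.read_csv(sidecar, sep="\t", comment="#", keep_default_na=False)
    required_common = {"charge", "mass", "species"}
    missing = required_common - set(table.columns)
    if missing:
        raise ValueError(f"sidecar missing columns: {sorted(missing)}")
    bad_species = set(table["species"]) - set(SPECIES)
    if bad_species:
        raise ValueError(f"sidecar has unknown species labels: {sorted(bad_species)}")

    if "index" in table.columns:
        if table["index"].duplicated().any():
            dup = int(table["index"][table["index"].duplicated()].iloc[0])
            raise ValueError(f"sidecar has duplicate index {dup}")
        if len(table) != len(topology):
            raise ValueError(
                f"sidecar has {len(table)} rows but topology has "
                f"{len(topology)} atoms"
            )
        by_index = table.set_index("index")
        missing_idx = [a.index for a in topology if a.index not in by_index.index]
        if missing_idx:
            raise ValueError(
                f"sidecar does not cover atoms (first 10): {missing_idx[:10]}"
            )
        new_atoms = [
            update_atom(
                a,
                charge=float(by_index.at[a.index, "charge"]),
                mass=float(by_index.at[a.index, "mass"]),
                species=str(by_index.at[a.index, "species"]),
            )
            for a in topology
        ]
    elif {"residue_name", "atom_name"} <= set(table.columns):
        keys = list(zip(table["residue_name"], table["atom_name"]))
        if len(set(keys)) != len(keys):
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise ValueError(f"sidecar has duplicate key {dup}")
        lookup = {
            k: (float(c), float(m), str(s))
            for k, c, m, s in zip(
                keys, table["charge"], table["mass"], table["species"]
            )
        }
        unmatched = [
            (a.residue_name, a.name)
            for a in topology
            if (a.residue_name, a.name) not in lookup
        ]
        if unmatched:
            raise ValueError(
                f"sidecar leaves {len(unmatched)} atoms unmatched "
                f"(first 10): {unmatched[:10]}"
            )
        new_atoms = []
        for a in topology:
            charge, mass, species = lookup[(a.residue_name, a.name)]
            new_atoms.append(
                update_atom(a, charge=charge, mass=mass, species=species)
            )
    else:
        raise ValueError(
            "sidecar needs either an 'index' column or both "
            "'residue_name' and 'atom_name'"
        )
    return topology.with_atoms(new_atoms)


def read_trajectory(
    path,
    topology: Topology,
    dialect: str,
    dt: float | None = None,
) -> Trajectory:
    """Read a concatenated multi-frame trajectory.

    dialect : {"xyz_multi", "gro_multi"}
        XYZ coordinates are Angstrom, GRO nm. Frame times come from the
        comment/title lines (``t= <ns>``) or, failing that, from a uniform
        step ``dt`` in ns starting at 0.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    frames: list[Frame] = []
    n_expected = len(topology)
    offset = 0
    if dialect == "xyz_multi":
        while offset < len(lines) and lines[offset].strip():
            try:
                n_atoms = int(lines[offset].strip())
            except ValueError:
                raise ParseError(
                    f"{path}:{offset + 1}: expected atom count, got "
                    f"{lines[offset]!r}"
                )
            if n_atoms != n_expected:
                raise TopologyError(
                    f"{path}: frame {len(frames)} has {n_atoms} atoms, "
                    f"expected {n_expected}"
                )
            time = _time_from_comment(lines[offset + 1])
            coords = np.empty((n_atoms, 3))
            for i in range(n_atoms):
                lineno = offset + 2 + i
                if lineno >= len(lines):
                    raise ParseError(f"{path}:{lineno + 1}: truncated XYZ frame")
                parts = lines[lineno].split()
                if len(parts) < 4:
                    raise ParseError(
                        f"{path}:{lineno + 1}: expected 'name x y z'"
                    )
                coords[i] = [float(v) for v in parts[1:4]]
            frames.append(
                Frame(
                    time=time if time is not None else 0.0,
                    positions=coords * ANGSTROM_TO_NM,
                )
            )
            offset += 2 + n_atoms
    elif dialect == "gro_multi":
        while offset < len(lines) and lines[offset].strip():
            frame_topo, frame, offset = _parse_gro_frame(lines, str(path), offset)
            if len(frame_topo) != n_expected:
                raise TopologyError(
                    f"{path}: frame {len(frames)} has {len(frame_topo)} atoms, "
                    f"expected {n_expected}"
                )
            frames.append(frame)
    else:
        raise ValueError(f"unknown trajectory dialect {dialect!r}")
    if not frames:
        raise ParseError(f"{path}: no frames found")

    times = np.array([f.time for f in frames])
    if dt is not None or np.all(times == 0.0):
        if dt is None:
            dt = 1.0
        for i, f in enumerate(frames):
            f.time = i * dt
    elif np.any(np.diff(times) <= 0):
        bad = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 1
        raise TopologyError(
            f"{path}: non-monotone frame times at frame {bad} "
            f"(t={times[bad]} after t={times[bad - 1]})"
        )
    return Trajectory(topology=topology, frames=frames)


def write_gro(path, topology: Topology, frame: Frame, title: str = "pulsefield"):
    """Write one frame in GRO format (positions printed to 3 decimals, nm)."""
    with open(path, "w") as fh:
        fh.write(f"{title} t= {frame.time:.6f}\n")
        fh.write(f"{len(topology):5d}\n")
        for atom, pos in zip(topology, frame.positions):
            fh.write(
                f"{atom.residue_id % 100000:5d}{atom.residue_name:<5.5s}"
                f"{atom.name:>5.5s}{(atom.index + 1) % 100000:5d}"
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}\n"
            )
        box = frame.box if frame.box is not None else np.zeros(3)
        fh.write(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}\n")


def write_topology_tsv(path, topology: Topology):
    """Dump a topology as a per-atom TSV (re-readable as an index sidecar)."""
    frame_df = pd.DataFrame(
        {
            "index": [a.index for a in topology],
            "atom_name": [a.name for a in topology],
            "residue_name": [a.residue_name for a in topology],
            "residue_id": [a.residue_id for a in topology],
            "charge": topology.charges,
            "mass": topology.masses,
            "species": topology.species,
        }
    )
    frame_df.to_csv(path, sep="\t", index=False)
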