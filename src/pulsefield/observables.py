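"""Structural observables: RMSD, radius of gyration, solvent-accessible
surface area, secondary-structure count ingestion and density estimates.

RMSD uses optimal least-squares (Kabsch) superposition; Rg is the
mass-weighted RMS distance from the center of mass; SASA is computed by
Shrake-Rupley sphere point sampling with Bondi van der Waals radii and a
0.14 nm water probe, split into hydrophobic (C, S) and hydrophilic
(everything else) totals. Secondary-structure class counts per frame are
ingested from TSV tables produced downstream of a DSSP run — the DSSP
classification itself is upstream of this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation
from scipy.stats import gaussian_kde

from .core import Frame, Topology

__all__ = [
    "ObservableSeries",
    "SSCountSeries",
    "PDFEstimate",
    "BONDI_RADII_NM",
    "kabsch_rmsd",
    "radius_of_gyration",
    "sasa",
    "guess_element",
    "read_ss_counts",
    "estimate_pdf",
]

#: Bondi van der Waals radii, nm, by element symbol.
BONDI_RADII_NM = {
    "H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152, "S": 0.180,
    "P": 0.180, "F": 0.147, "CL": 0.175, "BR": 0.185, "NA": 0.227,
    "K": 0.275, "MG": 0.173, "CA": 0.231, "CU": 0.140, "ZN": 0.139,
    "FE": 0.156,
}

HYDROPHOBIC_ELEMENTS = {"C", "S"}

PHASES = ("no_field", "on", "off")
SS_CLASSES = ("beta_sheet", "coil", "helix", "turn", "other")

_TWO_LETTER_IONS = {"NA", "CL", "CU", "ZN", "MG", "FE", "BR", "CA", "K"}


@dataclass
class ObservableSeries:
    """Scalar observable per frame (rmsd/rgyr in nm, sasa in nm^2)."""

    times: np.ndarray
    values: np.ndarray
    observable: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must match")
        if np.any(self.values < 0):
            raise ValueError(f"{self.observable} values must be >= 0")


@dataclass
class SSCountSeries:
    """Per-frame secondary-structure class counts with exposure phase."""

    times: np.ndarray
    counts: dict  # class name -> integer array
    phase: np.ndarray  # per-frame label in PHASES

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        for cls, c in self.counts.items():
            c = np.asarray(c)
            if np.any(c < 0):
                raise ValueError(f"negative count in class {cls!r}")
            self.counts[cls] = c.astype(int)
        unknown = set(self.phase) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown phase labels: {sorted(unknown)}")

    def in_phase(self, phase: str, cls: str) -> np.ndarray:
        """Counts of one class restricted to one exposure phase."""
        return self.counts[cls][self.phase == phase]


@dataclass
class PDFEstimate:
    """Normalized probability density on a bin grid."""

    bin_edges: np.ndarray
    densities: np.ndarray
    estimator: str


def kabsch_rmsd(
    mobile: Frame,
    reference: Frame,
    selection=None,
    fit: bool = True,
    mass_weighted: bool = False,
    topology: Topology | None = None,
) -> float:
    """RMSD (nm) between two frames, optionally after optimal superposition.

    With ``fit=True`` the mobile selection is translated and rotated onto
    the reference by weighted least squares before measuring; with
    ``fit=False`` the raw coordinate RMSD is returned.
    """
    if selection is None:
        selection = np.arange(mobile.n_atoms)
    selection = np.asarray(selection, dtype=int)
    x = mobile.positions[selection]
    y = reference.positions[selection]
    if x.shape != y.shape:
        raise ValueError("selections differ in size between frames")
    if mass_weighted:
        if topology is None:
            raise ValueError("mass_weighted RMSD needs a topology")
        w = topology.masses[selection]
        if w.sum() <= 0:
            raise ValueError("zero total mass in selection")
    else:
        w = np.ones(len(selection))
    w = w / w.sum()
    if fit:
        if len(selection) < 3:
            raise ValueError("superposition needs at least 3 atoms")
        xc = x - (w @ x)
        yc = y - (w @ y)
        if np.linalg.matrix_rank(np.cov(xc.T, aweights=None)) < 2:
            raise ValueError("degenerate (collinear) selection for fitting")
        rot, _ = Rotation.align_vectors(yc, xc, weights=w)
        diff = rot.apply(xc) - yc
    else:
        diff = x - y
    return float(np.sqrt(np.sum(w * np.sum(diff**2, axis=1))))


def radius_of_gyration(
    frame: Frame,
    topology: Topology | None = None,
    selection=None,
    mass_weighted: bool = True,
) -> float:
    """Rg = sqrt( sum m_i |r_i - r_cm|^2 / sum m_i ), nm."""
    if selection is None:
        selection = np.arange(frame.n_atoms)
    selection = np.asarray(selection, dtype=int)
    r = frame.positions[selection]
    if mass_weighted:
        if topology is None:
            raise ValueError("mass-weighted Rg needs a topology")
        m = topology.masses[selection]
        if m.sum() <= 0:
            raise ValueError("zero total mass in selection")
    else:
        m = np.ones(len(selection))
    m = m / m.sum()
    com = m @ r
    return float(np.sqrt(np.sum(m * np.sum((r - com) ** 2, axis=1))))


def guess_element(name: str, residue_name: str = "") -> str:
    """Element symbol from an atom name.

    Two-letter monatomic-ion/metal names (NA, CL, CU, ZN, ...) are taken
    whole when the residue name matches the atom name (an ion residue) —
    otherwise the first letter wins, so protein "CA" stays carbon.
    """
    stripped = "".join(ch for ch in name if ch.isalpha()).upper()
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    res = "".join(ch for ch in residue_name if ch.isalpha()).upper()
    if stripped in _TWO_LETTER_IONS and res.startswith(stripped):
        return stripped
    return stripped[0]


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def sasa(
    frame: Frame,
    topology: Topology,
    selection=None,
    probe: float = 0.14,
    n_sphere_points: int = 960,
    radii: dict | None = None,
) -> tuple[np.ndarray, float, float]:
    """Shrake-Rupley solvent-accessible surface area.

    Test points are placed on each atom's expanded sphere (vdW radius +
    probe); a point is accessible if it lies outside every neighbor's
    expanded sphere. Returns (per-atom areas nm^2, hydrophobic total,
    hydrophilic total), hydrophobic being C and S atoms.
    """
    if radii is None:
        radii = BONDI_RADII_NM
    if selection is None:
        selection = np.arange(frame.n_atoms)
    selection = np.asarray(selection, dtype=int)
    atoms = [topology.atoms[i] for i in selection]
    elements = [guess_element(a.name, a.residue_name) for a in atoms]
    missing = [a.name for a, e in zip(atoms, elements) if e not in radii]
    if missing:
        raise ValueError(f"no vdW radius for atom(s): {missing[:10]}")
    r_exp = np.array([radii[e] + probe for e in elements])
    pos = frame.positions[selection]
    sphere = _fibonacci_sphere(n_sphere_points)
    tree = cKDTree(pos)
    max_reach = 2 * r_exp.max()
    areas = np.empty(len(selection))
    for i in range(len(selection)):
        pts = pos[i] + r_exp[i] * sphere
        neighbors = [j for j in tree.query_ball_point(pos[i], r_exp[i] + max_reach)
                     if j != i]
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - pos[j]) ** 2, axis=1)
            accessible &= d2 > r_exp[j] ** 2
        areas[i] = accessible.mean() * 4.0 * np.pi * r_exp[i] ** 2
    phobic = np.array([e in HYDROPHOBIC_ELEMENTS for e in elements])
    return areas, float(areas[phobic].sum()), float(areas[~phobic].sum())


def read_ss_counts(path) -> SSCountSeries:
    """Read a per-frame secondary-structure count table.

    TSV columns: time_ns, beta_sheet, coil, [helix, turn, other], phase.
    """
    table = pd.read_csv(path, sep="\t", comment="#")
    required = {"time_ns", "beta_sheet", "coil", "phase"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"SS count table missing columns: {sorted(missing)}")
    counts = {}
    for cls in SS_CLASSES:
        if cls in table.columns:
            col = table[cls].to_numpy()
            if np.any(col < 0):
                raise ValueError(f"negative count in column {cls!r}")
            counts[cls] = col.astype(int)
    return SSCountSeries(
        times=table["time_ns"].to_numpy(dtype=float),
        counts=counts,
        phase=table["phase"].to_numpy(dtype=object),
    )


def write_ss_counts(path, series: SSCountSeries) -> None:
    """Inverse of :func:`read_ss_counts`."""
    data = {"time_ns": series.times}
    data.update({cls: series.counts[cls] for cls in series.counts})
    data["phase"] = series.phase
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def estimate_pdf(
    values,
    estimator: str = "histogram",
    bins="fd",
    bandwidth=None,
    grid_size: int = 512,
) -> PDFEstimate:
    """Normalized probability density of a sample.

    histogram: Freedman-Diaconis bin rule by default; kde: Gaussian kernel
    with Scott's-rule bandwidth, evaluated on a regular grid padded by
    three bandwidths.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("need at least 2 finite values")
    if estimator == "histogram":
        if np.ptp(values) == 0.0:
            edges = np.array([values[0] - 0.5, values[0] + 0.5])
            return PDFEstimate(edges, np.array([1.0]), "histogram")
        densities, edges = np.histogram(values, bins=bins, density=True)
        return PDFEstimate(edges, densities, "histogram")
    if estimator == "kde":
        if np.ptp(values) == 0.0:
            raise ValueError("KDE undefined for constant input")
        kde = gaussian_kde(values, bw_method=bandwidth)  # None -> Scott
        h = np.sqrt(kde.covariance[0, 0])
        lo, hi = values.min() - 3 * h, values.max() + 3 * h
        edges = np.linspace(lo, hi, grid_size + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        return PDFEstimate(edges, kde(centers), "kde")
    raise ValueError(f"unknown estimator {estimator!r}")
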