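"""Dipole-moment time series and short-time Fourier spectrograms.

The polarization response of the protein and the solvating water to an
applied pulse is tracked through the dipole moment M(t) = sum q_i r_i of
an atom selection (e·nm; 1 e·nm = 48.0321 D) and the time-frequency
power content of one of its components, classically the component along
the applied-field axis (y). The spectrogram is the squared modulus of
the Hamming-windowed short-time Fourier transform with 50% segment
overlap; with a 4 ns analysis window the frequency bins are 0.25 GHz
apart.

Normalization: for each segment the one-sided power bins sum to the
energy of the windowed segment (sum_t (w_t x_t)^2), making Parseval's
identity hold exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

from .core import Frame, Topology, Trajectory

__all__ = [
    "DipoleSeries",
    "Spectrogram",
    "dipole_moment",
    "dipole_series",
    "spectrogram",
    "power_spectral_density",
    "spectral_centroid",
]


@dataclass
class DipoleSeries:
    """Dipole vector per frame, in e·nm."""

    times: np.ndarray  # ns
    M: np.ndarray  # (n, 3)
    selection: str = "all"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        if self.M.shape != (self.times.size, 3):
            raise ValueError("M must be (n_times, 3)")
        if not np.all(np.isfinite(self.M)):
            raise ValueError("dipole series contains non-finite values")

    def component(self, axis: str = "y") -> np.ndarray:
        return self.M[:, "xyz".index(axis)]


@dataclass
class Spectrogram:
    """Time-frequency power matrix from the windowed Fourier transform."""

    time_bins: np.ndarray  # ns, segment centers
    freq_bins: np.ndarray  # GHz
    power: np.ndarray  # (n_segments, n_freqs), segment energy per bin
    window_length: float  # ns
    window_shape: str
    overlap: float


def dipole_moment(frame: Frame, topology: Topology, selection) -> np.ndarray:
    """M = sum q_i r_i over the selection, in e·nm.

    Translation-invariant for net-neutral selections. An empty selection
    yields the zero vector with a warning.
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        warnings.warn("empty selection: dipole moment is zero")
        return np.zeros(3)
    q = topology.charges[selection]
    r = frame.positions[selection]
    return q @ r


def dipole_series(trajectory: Trajectory, selection, label: str = "all") -> DipoleSeries:
    """One dipole vector per trajectory frame."""
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    selection = np.asarray(selection, dtype=int)
    q = trajectory.topology.charges[selection]
    M = np.array([q @ f.positions[selection] for f in trajectory.frames])
    return DipoleSeries(times=trajectory.times, M=M, selection=label)


def _check_uniform(times: np.ndarray) -> float:
    dts = np.diff(times)
    if dts.size == 0:
        raise ValueError("series needs at least two samples")
    dt = float(np.mean(dts))
    if np.max(np.abs(dts - dt)) > 1e-6 * dt:
        raise ValueError("series is not uniformly sampled")
    return dt


def spectrogram(
    times: np.ndarray,
    values: np.ndarray,
    window_length: float = 4.0,
    overlap: float = 0.5,
    window_shape: str = "hamming",
    detrend_mean: bool = False,
) -> Spectrogram:
    """Short-time Fourier power of a uniformly sampled scalar series.

    Parameters
    ----------
    times, values : arrays, ns and signal units
    window_length : ns; must span at least 8 samples. Frequency bins are
        spaced 1/window_length (GHz for ns input).
    overlap : fraction in [0, 1); hop = window_length * (1 - overlap).
    detrend_mean : subtract the series mean first. Off by default — during
        a pulse the DC polarization offset is part of the signal.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    dt = _check_uniform(times)
    nperseg = int(round(window_length / dt))
    if nperseg < 8:
        raise ValueError(
            f"window of {window_length} ns spans only {nperseg} samples (< 8)"
        )
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    if values.size < nperseg:
        raise ValueError("series shorter than one analysis window")
    if detrend_mean:
        values = values - values.mean()
    hop = max(1, int(round(nperseg * (1.0 - overlap))))
    window = get_window(window_shape, nperseg, fftbins=True)
    starts = np.arange(0, values.size - nperseg + 1, hop)
    freqs = np.fft.rfftfreq(nperseg, d=dt)  # GHz
    power = np.empty((starts.size, freqs.size))
    # one-sided bins normalized so sum_f power = sum_t (w x)^2 per segment
    double = np.full(freqs.size, 2.0)
    double[0] = 1.0
    if nperseg % 2 == 0:
        double[-1] = 1.0
    for k, s in enumerate(starts):
        seg = values[s : s + nperseg] * window
        spec = np.fft.rfft(seg)
        power[k] = double * np.abs(spec) ** 2 / nperseg
    centers = times[0] + (starts + (nperseg - 1) / 2.0) * dt
    return Spectrogram(
        time_bins=centers,
        freq_bins=freqs,
        power=power,
        window_length=nperseg * dt,
        window_shape=window_shape,
        overlap=overlap,
    )


def power_spectral_density(
    times: np.ndarray,
    values: np.ndarray,
    window_length: float = 4.0,
    overlap: float = 0.5,
    window_shape: str = "hamming",
) -> tuple[np.ndarray, np.ndarray]:
    """Welch-style PSD: segment-averaged spectrogram power.

    Returns (freq GHz, mean power per bin).
    """
    sg = spectrogram(times, values, window_length, overlap, window_shape)
    return sg.freq_bins, sg.power.mean(axis=0)


def spectral_centroid(freqs: np.ndarray, psd: np.ndarray,
                      exclude_dc: bool = True) -> float:
    """Power-weighted mean frequency, GHz; DC excluded by default."""
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    if exclude_dc:
        freqs, psd = freqs[1:], psd[1:]
    total = psd.sum()
    if total <= 0:
        return 0.0
    return float((freqs * psd).sum() / total)
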