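"""Monopolar (MP) and bipolar (BP) nanosecond pulse envelopes.

The MP ramps linearly from zero to the plateau amplitude E0 over ``rise``
ns, holds for ``hold`` ns and ramps back down over ``fall`` ns. The BP
holds +E0 for one pole duration, reverses linearly to -E0 over
``reversal`` ns, holds the negative pole, then ramps back to zero. The
field is applied along a unit direction vector (the y axis by default).
Amplitudes are in V/m, times in ns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

__all__ = ["PulseSpec", "WaveformSeries", "make_pulse", "sample_pulse",
           "export_waveform", "import_waveform", "mp_default", "bp_default"]

_RAMPS = ("linear", "smoothstep")


def _ramp(u: np.ndarray, shape: str) -> np.ndarray:
    """Normalized 0->1 ramp on u in [0, 1]."""
    if shape == "linear":
        return u
    if shape == "smoothstep":
        return u * u * (3.0 - 2.0 * u)
    raise ValueError(f"unknown ramp shape {shape!r}")


@dataclass(frozen=True)
class PulseSpec:
    """Parametric pulse description.

    For MP, ``hold`` is the plateau duration t_ON; for BP it is the
    duration of *each* pole and ``reversal`` the polarity-flip ramp.
    """

    shape: str = "MP"  # "MP" | "BP"
    amplitude: float = 1e8  # V/m
    rise: float = 2.0  # ns
    fall: float = 2.0  # ns
    hold: float = 100.0  # ns (per pole for BP)
    reversal: float = 2.0  # ns, BP only
    t_off_tail: float = 50.0  # ns of zero field appended after the pulse
    direction: tuple[float, float, float] = (0.0, 1.0, 0.0)
    ramp_shape: str = "linear"

    def __post_init__(self) -> None:
        if self.shape not in ("MP", "BP"):
            raise ValueError(f"pulse shape must be MP or BP, got {self.shape!r}")
        for attr in ("rise", "fall", "hold", "reversal", "t_off_tail"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.ramp_shape not in _RAMPS:
            raise ValueError(f"ramp_shape must be one of {_RAMPS}")
        d = np.asarray(self.direction, dtype=float)
        if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-9):
            raise ValueError("direction must be a unit vector")

    @property
    def duration(self) -> float:
        """Support of the nonzero envelope, ns."""
        if self.shape == "MP":
            return self.rise + self.hold + self.fall
        return self.rise + 2 * self.hold + self.reversal + self.fall


def mp_default(amplitude: float = 1e8) -> PulseSpec:
    """The study's monopolar pulse: 2 ns ramps around a 100 ns hold."""
    return PulseSpec(shape="MP", amplitude=amplitude)


def bp_default(amplitude: float = 1e8) -> PulseSpec:
    """The study's bipolar pulse: 50 ns per pole, 2 ns ramps/reversal."""
    return PulseSpec(shape="BP", amplitude=amplitude, hold=50.0)


@dataclass
class WaveformSeries:
    """A sampled pulse: scalar amplitude on a time grid plus direction."""

    times: np.ndarray  # ns
    values: np.ndarray  # V/m
    direction: np.ndarray  # unit 3-vector

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have matching shapes")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def vectors(self) -> np.ndarray:
        """(n, 3) field vectors: amplitude times direction."""
        return self.values[:, None] * self.direction[None, :]


def make_pulse(spec: PulseSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Return the envelope as a vectorized callable t[ns] -> E[V/m].

    Zero before t=0 and after the pulse support; piecewise ramps between.
    """
    e0 = spec.amplitude
    shape = spec.ramp_shape

    def envelope(t):
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        out = np.zeros_like(t)
        if spec.shape == "MP":
            edges = np.cumsum([0.0, spec.rise, spec.hold, spec.fall])
            if spec.rise > 0:
                m = (t >= edges[0]) & (t < edges[1])
                out[m] = e0 * _ramp((t[m] - edges[0]) / spec.rise, shape)
            m = (t >= edges[1]) & (t < edges[2])
            out[m] = e0
            if spec.fall > 0:
                m = (t >= edges[2]) & (t < edges[3])
                out[m] = e0 * (1.0 - _ramp((t[m] - edges[2]) / spec.fall, shape))
        else:  # BP
            edges = np.cumsum(
                [0.0, spec.rise, spec.hold, spec.reversal, spec.hold, spec.fall]
            )
            if spec.rise > 0:
                m = (t >= edges[0]) & (t < edges[1])
                out[m] = e0 * _ramp((t[m] - edges[0]) / spec.rise, shape)
            m = (t >= edges[1]) & (t < edges[2])
            out[m] = e0
            if spec.reversal > 0:
                m = (t >= edges[2]) & (t < edges[3])
                out[m] = e0 * (
                    1.0 - 2.0 * _ramp((t[m] - edges[2]) / spec.reversal, shape)
                )
            m = (t >= edges[3]) & (t < edges[4])
            out[m] = -e0
            if spec.fall > 0:
                m = (t >= edges[4]) & (t < edges[5])
                out[m] = -e0 * (1.0 - _ramp((t[m] - edges[4]) / spec.fall, shape))
        return out[0] if scalar else out

    return envelope


def sample_pulse(spec: PulseSpec, dt: float, t_end: float) -> WaveformSeries:
    """Sample the envelope on a uniform grid 0..t_end with step dt (ns)."""
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")
    n = int(np.floor(t_end / dt + 1e-9)) + 1
    times = np.arange(n) * dt
    values = make_pulse(spec)(times)
    return WaveformSeries(times=times, values=values,
                          direction=np.asarray(spec.direction, dtype=float))


def export_waveform(series: WaveformSeries, path) -> None:
    """Two-column TSV (time ns, amplitude V/m); direction in the header."""
    d = series.direction
    with open(path, "w") as fh:
        fh.write(f"# direction\t{d[0]:.12g}\t{d[1]:.12g}\t{d[2]:.12g}\n")
        fh.write("time_ns\tamplitude_V_per_m\n")
        for t, v in zip(series.times, series.values):
            fh.write(f"{t:.9g}\t{v:.9g}\n")


def import_waveform(path) -> WaveformSeries:
    """Read a waveform written by :func:`export_waveform`."""
    direction = np.array([0.0, 1.0, 0.0])
    times, values = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("# direction"):
                direction = np.array(
                    [float(v) for v in line.split("\t")[1:4]]
                )
                continue
            if line.startswith(("#", "time_ns")) or not line.strip():
                continue
            t, v = line.split("\t")[:2]
            times.append(float(t))
            values.append(float(v))
    return WaveformSeries(
        times=np.array(times), values=np.array(values), direction=direction
    )
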