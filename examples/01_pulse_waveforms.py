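"""Synthesize the monopolar and bipolar nanosecond pulses and sample them.

The MP ramps 0 -> E0 over 2 ns, holds 100 ns, ramps down over 2 ns; the
BP holds +E0 for 50 ns, reverses to -E0 over 2 ns, holds 50 ns and ramps
off. Amplitudes are in V/m along the y axis.
"""

import numpy as np

from pulsefield import bp_default, make_pulse, mp_default, sample_pulse

mp = mp_default(amplitude=1e8)
env = make_pulse(mp)
print(f"MP support duration: {mp.duration:.0f} ns (rise + hold + fall)")
print(f"MP amplitude at t=50 ns (plateau): {env(50.0):.3g} V/m")
print(f"MP amplitude at t=1 ns (ramp midpoint): {env(1.0):.3g} V/m")

bp = bp_default(amplitude=1e8)
series = sample_pulse(bp, dt=0.01, t_end=bp.duration + 10)
integral = np.trapezoid(series.values, series.times)
print(f"BP time integral: {integral:.3g} V/m*ns "
      "(zero: the two poles cancel exactly)")
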