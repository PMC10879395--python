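"""Theta-slow-gamma phase-amplitude coupling and its modulation index.

The entropy-normalized modulation index MI = (log N - H(p)) / log N measures
how far the phase-binned gamma amplitude distribution p deviates from
uniform (MI = 0: no coupling; MI = 1: all amplitude in one phase bin).
Here the generator's coupling strength k is swept to show MI tracking it,
and a comodulogram localizes the programmed (8 Hz, 40 Hz) couple.
"""

import numpy as np

from ripplepac import comodulogram, pac_mi
from ripplepac.synthetic import GammaConfig, RippleConfig, SyntheticConfig, generate


def session(k: float):
    cfg = SyntheticConfig(duration_s=120.0, seed=3,
                          gamma=GammaConfig(coupling_k=k),
                          ripples=RippleConfig(rate=0.0))
    return generate(cfg)[0]


print("coupling k -> modulation index")
for k in (0.0, 0.3, 0.6, 0.9):
    print(f"  k = {k:.1f}   MI = {pac_mi(session(k)).mi:.5f}")

mi, pf, af = comodulogram(session(0.9), np.arange(4.0, 13.0, 1.0),
                          np.arange(20.0, 81.0, 5.0))
i, j = np.unravel_index(np.argmax(mi), mi.shape)
print(f"comodulogram peak: phase {pf[j]:.0f} Hz, amplitude {af[i]:.0f} Hz "
      f"(programmed: 8 Hz -> 40 Hz)")

# MI rises monotonically with the programmed coupling strength, and the
# comodulogram's argmax lands on the programmed theta/gamma pair within one
# grid step.
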