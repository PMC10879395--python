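"""Ripple-onset-triggered z-scored spectrogram and slow-gamma power.

Multitaper spectrograms (100 ms windows, NW=3, K=5 Slepian tapers) are
computed +/-400 ms around each detected ripple onset, averaged, and each
frequency row is z-scored.  Slow-gamma power is the mean z in 30-50 Hz over
the first 100 ms after onset — the transient gamma burst that rides on
ripples.
"""

from ripplepac import (
    SwrDetectionParams,
    detect_swr,
    slow_gamma_power,
    swr_triggered_spectrogram,
)
from ripplepac.synthetic import RippleConfig, SgBurstConfig, SyntheticConfig, generate

cfg = SyntheticConfig(
    duration_s=120.0,
    seed=55,
    ripples=RippleConfig(rate=0.3, duration_ms=50.0),
    sg_burst=SgBurstConfig(amp=10.0),   # ripple-locked 40 Hz burst
)
recording, truth = generate(cfg)
result = detect_swr(recording, SwrDetectionParams(), truth.immobility_mask)
zspec = swr_triggered_spectrogram(recording, result)

sg = slow_gamma_power(zspec)
rows = (zspec.freqs >= 150) & (zspec.freqs <= 250)
peak_t = zspec.times[zspec.zpower[rows].max(axis=0).argmax()]

print(f"events averaged      : {zspec.n_events} ({zspec.n_excluded} too close to edges)")
print(f"ripple-band z peak at: {peak_t * 1000:+.0f} ms relative to onset")
print(f"slow-gamma z power   : {sg:.2f} (30-50 Hz, 1-100 ms post-onset)")

# The ripple-band peak sits at the event onset by construction; the positive
# slow-gamma z reflects the injected ripple-locked gamma burst.  Without that
# burst this value fluctuates around 0.
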