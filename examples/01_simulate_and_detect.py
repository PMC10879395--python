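"""Simulate a hippocampal LFP session and detect sharp-wave ripples.

Generates 120 s of synthetic LFP (pink noise + theta + coupled slow gamma +
injected ripple bursts), runs the 5 SD / 15 ms envelope detector, and
compares the detected events against the generator's ground truth.
"""

import numpy as np

from ripplepac import SwrDetectionParams, detect_swr, duration_stats
from ripplepac.synthetic import RippleConfig, SyntheticConfig, generate

cfg = SyntheticConfig(
    duration_s=120.0,
    seed=7,
    ripples=RippleConfig(rate=0.25, duration_ms=(np.log(50.0), 0.25)),
)
recording, truth = generate(cfg)
result = detect_swr(recording, SwrDetectionParams(), truth.immobility_mask)
stats = duration_stats(result, seed=0)

print(f"injected ripples : {len(truth.ripple_events)}")
print(f"detected events  : {len(result.events)}")
print(f"incidence        : {result.incidence_hz:.3f} Hz over "
      f"{result.analyzed_time_s:.0f} s of immobility")
print(f"median duration  : {stats.median_ms:.1f} ms "
      f"(95% bootstrap CI {stats.ci95[0]:.1f}-{stats.ci95[1]:.1f} ms)")

# Incidence is events per second of immobility; the median duration carries a
# seeded bootstrap CI.  With 8-SD bursts the detector recovers essentially
# every injected event, so incidence ~= the programmed 0.25 Hz rate.
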