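"""Detect single co-aggregate transits in a two-colour photon trace.

Simulates a 0.2 ms-binned confocal trace with bursts from one aggregate
population (true relative FRET efficiency 0.6) on Poisson background, runs the
burst search on the summed channel and fits the efficiency histogram.
"""

import numpy as np

from aggresense import fret
from aggresense.simulate import FretPopulation, FretSimConfig, simulate_fret_trace

cfg = FretSimConfig(
    n_bins=200_000,
    burst_rate_hz=25.0,
    populations=[FretPopulation(donor_rate=40.0, acceptor_rate=60.0)],
    mean_duration_bins=3.0,
    seed=1,
)
trace, truth, _ = simulate_fret_trace(cfg)
bursts, backgrounds = fret.analyze_trace(trace)
efficiencies = [b.e for b in bursts if b.e is not None]
hist = fret.fit_histogram_maximum(efficiencies)

print(f"trace                  : {cfg.n_bins} bins of {cfg.bin_width_ms} ms")
print(f"background (D, A)      : {backgrounds[0]:.3f}, {backgrounds[1]:.3f} counts/bin")
print(f"bursts injected/found  : {len(truth)} / {len(bursts)}")
print(f"mean E                 : {np.mean(efficiencies):.3f} (true 0.600)")
print(f"Gaussian-fit maximum   : {hist.maximum:.3f}")
# The fitted histogram maximum is the per-fraction summary statistic used to
# compare aggregate populations: larger aggregates shift it upward.
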