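"""Quantify per-vesicle Ca2+ influx on a simulated SNR~10 field.

Generates a three-phase TIRF field of 100 dye-loaded vesicles whose true
influx fractions average 0.5, detects the vesicles on the background phase,
measures the three phase intensities and applies the influx ratio
(F_sample - F_background) / (F_ionomycin - F_background).
"""

import numpy as np

from aggresense import vesicles as V
from aggresense.simulate import VesicleSimConfig, simulate_vesicle_experiment

cfg = VesicleSimConfig(n_vesicles=100, seed=1)
stacks, truth, _ = simulate_vesicle_experiment(cfg)

rois = V.detect_vesicles(stacks["background"])
intensities = V.extract_phase_intensities(rois, stacks)
noise_sd = cfg.background_noise_sd / np.sqrt(cfg.frames_per_phase)
records = V.compute_influx_table(intensities, noise_sd=noise_sd)
summary = V.summarize_field(records, condition="demo")

print(f"vesicles simulated     : {len(truth)}")
print(f"vesicles detected      : {len(rois)}")
print(f"mean influx (measured) : {summary.mean_influx:.3f} +- "
      f"{summary.sd_influx / np.sqrt(summary.n_vesicles):.3f}")
print(f"mean influx (true)     : {truth.true_influx.mean():.3f}")
# A measured mean within ~2 standard errors of the generating mean shows the
# detector + photometry + ratio chain is unbiased at this noise level.
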