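"""Simulate a measurement campaign with the synthetic sensor array.

Builds a desk-scale (256-sensor) version of the binary-mixture campaign:
five butanone/ethanol compositions, 41 measurements, first-order response
kinetics, 30% non-responding sensors and multiplicative read noise.
"""

import numpy as np

from enosekit import simulate

cfg = simulate.dataset1_config(seed=1, n_sensors=256)
recordings, labels = simulate.simulate_dataset(cfg, simulate.DATASET1_DESIGN)

rec = recordings[0]
print(f"campaign: {len(recordings)} measurements, labels {sorted(set(labels))}")
print(f"one recording: {rec.n_samples} samples x {rec.n_sensors} sensors "
      f"at {rec.sample_interval:.0f} Hz, stimulus {rec.stimulus_onset}"
      f"-{rec.stimulus_end} s, label {rec.label}")

# plateau response of a responding sensor vs a dead one
frac = rec.resistance[600] / rec.resistance[:100].mean(axis=0) - 1.0
print(f"plateau dR/R: median responding sensor "
      f"{np.median(frac[~cfg._dead]):.3f}, median dead sensor "
      f"{np.median(np.abs(frac[cfg._dead])):.5f}")
# A responding sensor swings a few percent to tens of percent of its
# baseline resistance; dead sensors show only read noise.
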