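"""Score EDA artifact epochs from accelerometer and temperature context.

Movement bursts contaminate the conductance channel; the epoch rule flags
exactly those 5-s epochs where high accelerometer variability coincides
with a steep EDA excursion.
"""

import numpy as np

from stresswear import SimConfig, detect_eda_artifacts, simulate_session

cfg = SimConfig(seed=3)
ch, truth = simulate_session(cfg, "contest", 600, np.random.default_rng(3))

mask = detect_eda_artifacts(ch.eda, ch.acc, ch.temp)
print(f"{len(mask)} epochs of {mask.epoch_len:.0f} s; {mask.n_flagged} flagged")

mids = mask.epoch_starts + mask.epoch_len / 2
true_flags = np.zeros(len(mask), bool)
for a0, a1 in truth.eda_artifact_windows:
    true_flags |= (mids >= a0) & (mids < a1)
tp = int((mask.flags & true_flags).sum())
print(f"injected contamination epochs: {int(true_flags.sum())}; "
      f"recall {tp / max(true_flags.sum(), 1):.2f}, "
      f"precision {tp / max(mask.n_flagged, 1):.2f}")
# Flagged epochs are excluded from EDA feature extraction downstream, so
# pressure/motion excursions never masquerade as skin conductance responses.
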