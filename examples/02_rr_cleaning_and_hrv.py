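"""Detect RR artifacts, clean the series both ways, and extract HRV features.

A simulated 5-minute recording with 2% multiplicative spike artifacts is
cleaned by the percentage-threshold detector; the feature battery is then
computed on the filtered series.
"""

import numpy as np

from stresswear import RRCleanConfig, SimConfig, clean_rr, detect_rr_artifacts, simulate_rr
from stresswear.hr import hrv_features_clean

cfg = SimConfig(seed=7)
rr, truth = simulate_rr(cfg, "lecture", 300, np.random.default_rng(7))
print(f"{len(rr)} beats, {truth.rr_artifact_indices.size} injected spike artifacts")

mask = detect_rr_artifacts(rr, RRCleanConfig(threshold_pct=20))
print(f"detector flagged {mask.n_flagged} beats "
      f"(every spike deviates ~50% from the causal local mean, far above 20%)")

for mode in ("filter", "interpolate"):
    c = RRCleanConfig(mode=mode)
    clean = clean_rr(rr, detect_rr_artifacts(rr, c), c)
    f = hrv_features_clean(clean)
    print(f"\n{mode} mode: fraction remaining {clean.fraction_remaining:.3f}")
    print(f"  mean HR {f['mean_hr']:.1f} bpm, SDNN {f['sdnn']*1000:.1f} ms, "
          f"RMSSD {f['rmssd']*1000:.1f} ms, pNN50 {f['pnn50']:.1f}%")
    print(f"  LF/HF (FFT) {f['lf_hf']:.2f}, LF/HF (Lomb-Scargle) {f['lomb_lf_hf']:.2f}")
# The two cleaning modes should agree closely: artifacts are sparse and
# both reconstructions recover the underlying rhythm.
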