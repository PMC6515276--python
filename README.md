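# stresswear

Stress-level detection from wrist-worn wearables: artifact handling and
feature extraction for inter-beat-interval (IBI), electrodermal (EDA),
accelerometer (ACC) and skin-temperature streams, windowed multimodal
feature fusion, and cross-validated three-level stress classification.

The package is aimed at affective-computing and physiological-signal
researchers working with Empatica-E4-style exports or generic
IBI-exporting smartwatches in *real-life* (unconstrained movement)
settings, where motion artifacts — not laboratory noise — dominate data
quality.

## What it computes

**Heart activity.** Beat `i` is an artifact when its interval deviates
from a causal local average by more than a percentage threshold
(default 20%):

```
|RR_i − L_i| / L_i > θ/100,   L_i = mean of the previous 5 accepted beats
```

Flagged beats are either removed (with minimum-run constraints on the
surviving segments) or repaired by shape-preserving cubic interpolation.
The HRV battery then yields mean HR, mean RR, SDNN, RMSSD, SDSD, pNN50,
the triangular index and TINN (1/128 s histogram), and VLF/LF/HF band
powers (0–0.04 / 0.04–0.15 / 0.15–0.4 Hz) with pLF/pHF and LF/HF — via
both a 4 Hz-resampled FFT periodogram and the Lomb–Scargle periodogram
evaluated directly on the irregular beat times.

**Electrodermal activity.** 5-s epochs are excluded when accelerometer
variability coincides with a steep conductance excursion (or the
temperature slew is implausible); the rule is a pluggable epoch
classifier. The signal is split as `y = tonic + phasic + residual` by a
convex program — sparse nonnegative SCR driver through a biexponential
kernel, B-spline tonic, quadratic residual — and seven features follow:
tonic mean, std, 20th/80th percentile, quartile deviation, and phasic
peak / strong-peak (> 1 µS) rates per 100 s of artifact-free signal.

**Accelerometer.** Per-axis means, mean magnitude, and DC-excluded FFT
energy of the magnitude (movement intensity independent of posture).

**Fusion & classification.** Features are extracted per aggregation
window (120 s default, sweepable to 20 min), averaged per session (or
kept per window), labelled by session context (free 0 / lecture 1 /
contest 2) or by binned 0–100 frustration reports (≤30 → 1, 35–75 → 2,
≥80 → 3), class-balanced, and evaluated with stratified 10-fold CV over
six classifiers (PCA+LDA, PCA+RBF-SVM, 1-NN, logistic, RF-100, MLP) in
either pooled-general or person-specific protocols.

A deterministic synthetic study generator produces all of the above with
ground truth (spike indices, SCR times, contamination windows, labels),
so every stage is testable against a known answer. See
`docs/methods.md` for models, parameters and limitations.

## Worked example

```bash
python examples/05_classification.py
```

```
304 window instances, 17 HRV features, classes [0, 1, 2] (0 free / 1 lecture / 2 contest)

general model  (RF-100, 10-fold): accuracy 97.7%  F1 97.7
person-specific mean accuracy   : 100.0%  (21 subjects)
permuted-label null             : 30.3%  (chance is 33.3%)
```

The simulated 21-subject study builds in strong class effects (stress
shortens RR, damps HRV, raises SCR rate), so the general model performs
far above the permutation floor; per-subject models absorb the
between-subject baseline heterogeneity and match or beat it. The other
examples walk through simulation (`01`), RR cleaning and the HRV battery
(`02`), EDA decomposition (`03`) and artifact-epoch scoring (`04`).

The same pipeline is scriptable from the shell:

```bash
stresswear simulate --subjects 4 --out study/
stresswear clean-rr study/S00_free_0/IBI.csv --threshold-pct 20
stresswear eda-clean study/S00_free_0 --out epochs.csv
stresswear features --out features.csv
stresswear evaluate --features features.csv --classifier rf100 --modality HR
```

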