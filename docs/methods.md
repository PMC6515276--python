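# Methods

This note documents the models and procedures implemented in `stresswear`,
the parameters that matter, what the synthetic study generator does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## Signal model and time conventions

All channels live on an absolute UNIX-seconds axis; windows are half-open
`[t0, t1)`. This makes joins across the 4 Hz (EDA, temperature), 32 Hz
(accelerometer) and irregular (inter-beat interval) streams unambiguous:
a sample or beat belongs to exactly one window of a contiguous tiling.
Aggregation windows tile each session from its start; the last partial
window is dropped rather than extrapolated.

An inter-beat interval (IBI, equivalently RR interval) series is stored as
`(beat_times, ibi)` with `ibi[i]` the interval *ending* at `beat_times[i]`.
Durations outside (0.2, 3.0) s are physiologically implausible; parsing
only warns about them because classifying them is the artifact stage's job.

## RR artifact detection and cleaning

A beat is flagged when its interval deviates from a local average by more
than `threshold_pct` percent (default 20, sweepable 10–25). The local
average is **causal and self-excluding**: the mean of the previous
`local_window_beats` (default 5) *accepted* beats, so an ectopic or
spurious beat never contaminates its own reference, and a burst of
artifacts cannot drag the reference toward itself. While the acceptance
buffer is filling, the raw leading beats seed it; the first beat has no
reference and is never flagged.

Two repair modes:

* **filter** — flagged beats are removed; the survivors split into
  contiguous runs at each removal, and runs with fewer than
  `min_consecutive_samples` beats (default 5) or a span below
  `min_consecutive_time` (default 10 s) are discarded. This implements
  the "minimum consecutive data" exclusion rules. `fraction_remaining`
  is kept beats / total beats; a duration-based variant is also reported.
* **interpolate** — flagged values are replaced by monotone
  (shape-preserving) piecewise-cubic interpolation over beat index against
  the unflagged neighbours. Beat count is preserved; on locally monotone
  data the repaired value cannot overshoot the flanking beats, and on
  linear data the interpolant is exact.

## HRV features

Time domain: mean HR (60/mean RR), mean RR, SDNN and SDSD as sample
(n−1) standard deviations (the dominant HRV convention), RMSSD, pNN50
(strictly greater than 50 ms), the triangular index (beat count divided
by the modal bin count of the RR histogram at the conventional 1/128 s
bin width — the width is exactly representable in binary, so binning is
reproducible), and TINN as the base width of the least-squares triangular
fit to that histogram. Degenerate histogram (single occupied bin) yields
TINN of one bin width. Diff-based statistics require three beats, the
rest two; anything below that propagates as NaN, never silently zero.

Frequency domain, over the standard VLF (0–0.04 Hz), LF (0.04–0.15 Hz)
and HF (0.15–0.40 Hz) bands, computed two ways:

* **FFT path** — the tachogram is resampled to a uniform 4 Hz grid by
  cubic-spline interpolation over beat times, mean-detrended, and a
  periodogram is integrated (trapezoid) over each band; pLF/pHF are the
  in-band argmax frequencies.
* **Lomb–Scargle path** — evaluated directly on the irregular beat times
  (no resampling), on a grid reaching 0.4 Hz with a step of at most
  0.002 Hz, scaled one-sided and integrated over the same bands.

Both paths require a 60 s span; below that the features are NaN.

In filter mode, distributional statistics pool all kept beats,
successive-difference statistics use within-segment differences only
(differences across a removal gap are meaningless), and **spectra are
computed on the pooled kept beats across segments**: the Lomb–Scargle
periodogram is defined for exactly this kind of gapped series, and the
FFT path's spline resampling bridges the gaps. An earlier per-segment
design was rejected because, at the default 120 s window, removals split
the data into runs almost always shorter than the 60 s spectral minimum,
leaving the frequency block undefined for most windows.

## EDA artifact exclusion

Electrodermal recordings from a wrist device are contaminated by motion
(electrode pressure, slippage) and temperature transients. The signal is
scored in consecutive 5 s epochs (the convention of epoch-based EDA
artifact tools); an epoch is excluded when

* the accelerometer-magnitude standard deviation exceeds 0.1 g **and**
  the maximum absolute EDA slope exceeds 0.4 µS/s, **or**
* the maximum absolute temperature slope exceeds 0.2 °C/s.

The conjunction matters: a genuine skin conductance response can be as
steep as an artifact, but it does not co-occur with a movement burst;
conversely wrist movement without an EDA excursion does not corrupt the
conductance channel. Thresholds were calibrated on the synthetic
generator so that each sits several noise standard deviations above the
clean-signal slope/variability distributions of its channel (the
temperature threshold in particular must clear the max-of-epoch-diffs
noise statistic, not the per-sample noise sd). All are configuration
keys, and the whole rule can be replaced by any epoch classifier
honouring the `feature-dict -> bool` contract — e.g. a trained SVM —
without touching downstream code. Excluded epochs contribute no samples
to feature extraction and are removed from the peak-rate denominator.

## Tonic/phasic decomposition

The conductance trace is modelled as `y = K q + B l + C d + e`:

* `q >= 0` — a sparse nonnegative SCR driver, one coefficient per sample;
* `K` — convolution with a biexponential SCR kernel
  `exp(-t/2.0) − exp(-t/0.75)` normalised to unit peak (so driver
  amplitudes are in µS), truncated at 10⁻³ of peak;
* `B l` — a cubic B-spline tonic level with knots every 10 s;
* `C d` — offset plus linear drift (unpenalised, so a constant input is
  represented exactly);
* `e` — Gaussian residual.

The decomposition solves the convex program
`min 0.5/n‖Kq+Bl+Cd−y‖² + (α/n)1ᵀq + 0.5(γ/n_l)‖l‖²` s.t. `q ≥ 0`,
with α = 8·10⁻⁴ (driver sparsity) and γ = 10⁻² (tonic stiffness), both
configuration keys. The solver is L-BFGS-B on sparse operators with an
analytic gradient: bounds keep the driver exactly nonnegative (hence the
phasic component is nonnegative, since the kernel is), the fixed
tolerance and iteration settings make the solution deterministic, and
the residual is defined as the remainder so
tonic + phasic + residual reconstructs the input to machine precision.
Inputs shorter than 10 s are rejected.

## EDA features

Seven per window: mean, standard deviation (population), 20th/80th
percentile and quartile deviation of the **tonic** component (phasic
excursions would otherwise inflate level statistics), and the rates of
phasic peaks and of *strong* peaks (amplitude > 1 µS) per 100 s of
artifact-free duration. Percentiles use the linear-interpolation
convention; the quartile deviation is the 75th-minus-25th-percentile
difference. Peaks are local maxima of the phasic component with
prominence at least 0.05 µS — the classic SCR minimum-amplitude
criterion; a threshold at the sensor-noise floor (0.01 µS) makes the
counts noise-dominated. Both thresholds are parameters.

## Accelerometer features

Per-axis means, mean magnitude, and the FFT energy of the mean-removed
magnitude, `(1/N)·Σ|X_k|²` with the DC term excluded — by Parseval this
equals the time-domain mean-removed sum of squares, so posture (gravity
orientation) contributes nothing and only oscillation registers.

## Fusion and labels

Features are computed per aggregation window (default 120 s; the sweep
grid is 120/300/600/1200 s) and averaged unweighted over windows with
valid values to give one instance per session, or kept per window when
window-level instances are requested (person-specific modelling needs
the larger instance count). Context labels enumerate free day 0,
lecture 1, contest 2. Perceived-stress labels bin the 0–100 NASA-TLX
frustration report: ≤ 30 → level 1, 35–75 → level 2, ≥ 80 → level 3
(scores 31–34 and 76–79 are unreachable at five-point increments but are
binned ≤ 30 → 1, < 80 → 2 for robustness, with a log entry). Devices
without an EDA sensor contribute a missing EDA block; datasets that
request EDA exclude those instances with a logged count.

## Classification protocol

Balancing resamples every class to the mean original class count —
minorities oversampled with replacement (exact duplicates), majorities
undersampled without. Evaluation is stratified 10-fold cross-validation
with predictions pooled over folds; metrics are accuracy and weighted
precision/recall/F1 on a 0–100 scale, plus the pooled confusion matrix.

Two protocol variants are provided because balance-then-fold leaks
duplicated minority rows across fold boundaries: the default
`within_fold` mode balances, standardises and fits PCA strictly inside
each training fold; `global` mode balances once before folding and is
retained for protocol-fidelity comparisons (on unlearnable data it
visibly inflates minority recall, which the test suite demonstrates).

The six classifiers: PCA(0.95 variance)+LDA, PCA+RBF-SVM (C = 1,
γ = 1/n_features), 1-NN, logistic regression, random forest with 100
trees, and an MLP with one hidden layer of ⌈(n_features+n_classes)/2⌉
units. Forest size and neighbour count are fixed by protocol; the open
hyperparameters are configuration keys. Standardisation precedes PCA and
all distance-based methods.

Person-specific evaluation repeats the CV inside each subject and
averages accuracies unweighted; subjects with fewer than
max(k, 2·n_classes) instances or fewer than two instances of any class
are excluded (logged), and the fold count shrinks to the smallest class
count when needed.

## Synthetic study generator

The generator emulates the statistical structure the analysis assumes,
with three session types modulating physiology per subject:

| parameter | free | lecture | contest |
|---|---|---|---|
| mean RR (s) | 0.90 | 0.80 | 0.70 |
| LF modulation amplitude (s) | 0.030 | 0.022 | 0.014 |
| HF modulation amplitude (s) | 0.030 | 0.018 | 0.008 |
| beat jitter sd (s) | 0.010 | 0.008 | 0.006 |
| SCR rate (/100 s) | 2 | 5 | 10 |
| frustration centre (0–100) | 20 | 50 | 85 |

RR series: class mean + 0.10 Hz and 0.25 Hz sinusoidal modulation +
Gaussian jitter, with multiplicative ×1.5 spikes at 2% of beats
(indices recorded). EDA: tonic baseline 2 µS with 0.001 µS/s drift,
Poisson SCR train convolved with the biexponential kernel (log-normal
amplitudes, median 0.4 µS), 0.01 µS sensor noise. Accelerometer:
gravity + 0.02 g noise, with movement bursts (0.5 g oscillation at 3 Hz,
5 s long, one per 100 s on average) snapped to the 5 s epoch grid so
each burst occupies whole detector epochs; every burst also receives a
2 µS triangular EDA contamination bump — the motion/EDA coupling the
artifact detector is premised on. Temperature: 33 °C with slow drift and
5 m°C noise. Subjects carry log-normal random effects on mean RR
(sd 0.05), HRV amplitudes (sd 0.20) and EDA baseline (sd 0.30);
frustration reports are Gaussian around the class centre (sd 10),
quantised to 5. The default study is 21 subjects × one session of each
type, 600 s per session, even-index subjects wearing the EDA-capable
device and odd-index subjects an IBI+ACC watch. Everything above is a
`SimConfig` field; effect sizes were chosen once as a strong, clearly
separable regime and are not tuned thereafter.

What the generator does **not** emulate: realistic beat-to-beat
autocorrelation beyond two sinusoids, respiratory sinus arrhythmia
coupling, circadian drift, missing-data dropouts, device clock skew, or
overlapping/asymmetric SCR shapes. Passing tests therefore demonstrate
correctness of the algorithms under their stated assumptions and the
recoverability of injected structure — not field performance on real
wrist recordings.

## Problem sizes and determinism

Tests and the acceptance script run on 600 s sessions and 21-subject
studies (property aggregates use 10–20 seeds), chosen so each stage is
exercised at realistic per-window sample counts while a full run stays
in the minutes range on one CPU. All randomness flows from
`numpy.random.default_rng` seeds; one master seed fans out to per-stage
seeds via SHA-256 (`config.derive_seed`), so stages are independently
reproducible and a fixed seed gives byte-identical simulator output,
feature tables and evaluation results across runs and platforms.

## Known limitations

* The epoch artifact rule is transparent but simplistic; the pluggable
  classifier contract exists precisely so a trained model can replace it.
* The causal local-average detector is sequential by construction
  (Python loop), fine at wearable beat rates.
* TINN's least-squares triangle search is exhaustive over bin pairs,
  O(bins²) per window — negligible at 1/128 s bins over physiological
  RR ranges.
* Lomb–Scargle band powers use a fixed-step grid, not an adaptive one;
  the LF/HF ratio is insensitive to the common scale factor.
* The decomposition's L-BFGS-B solve reaches the QP optimum to solver
  tolerance rather than an interior-point certificate; objective values
  are reproducible run to run, which is what downstream determinism
  requires.
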