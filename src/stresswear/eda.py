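"""Electrodermal activity: artifact exclusion, decomposition, features.

Artifact exclusion works on fixed-length epochs (5 s default) and is
driven by the accelerometer and temperature channels: skin-conductance
excursions that coincide with movement, or epochs with implausible
temperature slew, are excluded from feature extraction.  The default
detector is a transparent threshold rule; any epoch classifier honouring
the same contract (feature dict in, artifact flag out) can be plugged in.

Decomposition separates the signal into a slow tonic level (skin
conductance level) and a sparse event-driven phasic component (skin
conductance responses) by solving a convex quadratic program: the phasic
part is a nonnegative sparse driver convolved with a biexponential SCR
kernel, the tonic part a smooth cubic B-spline plus linear drift, and the
remainder Gaussian noise.  The program is solved with a projected
quasi-Newton method (L-BFGS-B) on sparse operators, which keeps the
driver exactly nonnegative and the solution deterministic.

Seven window features follow: mean, standard deviation, 20th/80th
percentile and quartile deviation of the tonic component, and the rates
of phasic peaks and of strong peaks (amplitude > 1 uS) per 100 s of
artifact-free signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import interpolate, optimize, signal, sparse

from .io_formats import ArtifactMask, UniformSeries
from .synthetic import scr_kernel_peak_delay

__all__ = [
    "EdaArtifactConfig",
    "EdaDecomposition",
    "detect_eda_artifacts",
    "decompose_eda",
    "eda_peaks",
    "eda_features",
    "EDA_KEYS",
]

EDA_KEYS = (
    "mean", "std", "peaks_per_100s", "strong_peaks_per_100s",
    "p20", "p80", "quartile_dev",
)


@dataclass(frozen=True)
class EdaArtifactConfig:
    """Epoch-based EDA artifact detector parameters.

    The default rule flags an epoch iff (accelerometer-magnitude standard
    deviation exceeds ``acc_std_threshold`` AND the maximum absolute EDA
    slope exceeds ``eda_slope_threshold``) OR the absolute temperature
    slope exceeds ``temp_slope_threshold``.  ``classifier`` may replace
    the rule: a callable mapping the epoch feature dict to True (artifact).
    """

    epoch_len: float = 5.0            # s
    acc_std_threshold: float = 0.1    # g
    eda_slope_threshold: float = 0.4  # uS/s
    temp_slope_threshold: float = 0.2  # degC/s
    classifier: Optional[Callable[[dict], bool]] = None

    def __post_init__(self) -> None:
        if self.epoch_len <= 0:
            raise ValueError("epoch_len must be positive")
        for v in (self.acc_std_threshold, self.eda_slope_threshold, self.temp_slope_threshold):
            if v <= 0:
                raise ValueError("thresholds must be positive")


def epoch_features(
    eda: UniformSeries,
    acc: Sequence[UniformSeries],
    temp: Optional[UniformSeries],
    t0: float,
    t1: float,
) -> dict:
    """Per-epoch summary features offered to the artifact classifier."""
    feats = {"t0": t0, "t1": t1}
    ax, ay, az = (a.slice(t0, t1).values for a in acc)
    n = min(ax.size, ay.size, az.size)
    mag = np.sqrt(ax[:n] ** 2 + ay[:n] ** 2 + az[:n] ** 2)
    feats["acc_std"] = float(np.std(mag)) if n else 0.0
    feats["acc_mean"] = float(np.mean(mag)) if n else 0.0
    e = eda.slice(t0, t1)
    if len(e) >= 2:
        feats["eda_slope_max"] = float(np.max(np.abs(np.diff(e.values))) * e.fs)
        feats["eda_mean"] = float(np.mean(e.values))
    else:
        feats["eda_slope_max"] = 0.0
        feats["eda_mean"] = float(e.values[0]) if len(e) else 0.0
    if temp is not None and len(tv := temp.slice(t0, t1)) >= 2:
        feats["temp_slope_max"] = float(np.max(np.abs(np.diff(tv.values))) * tv.fs)
    else:
        feats["temp_slope_max"] = 0.0
    return feats


def _default_rule(cfg: EdaArtifactConfig) -> Callable[[dict], bool]:
    def rule(f: dict) -> bool:
        motion = f["acc_std"] > cfg.acc_std_threshold and f["eda_slope_max"] > cfg.eda_slope_threshold
        return motion or f["temp_slope_max"] > cfg.temp_slope_threshold
    return rule


def detect_eda_artifacts(
    eda: UniformSeries,
    acc: Sequence[UniformSeries],
    temp: Optional[UniformSeries] = None,
    cfg: EdaArtifactConfig = EdaArtifactConfig(),
) -> ArtifactMask:
    """Classify consecutive epochs of the channel-overlap interval as clean
    or artifact.  The last partial epoch is not scored."""
    starts = [eda.start_epoch] + [a.start_epoch for a in acc]
    ends = [eda.t_end] + [a.t_end for a in acc]
    if temp is not None:
        starts.append(temp.start_epoch)
        ends.append(temp.t_end)
    lo, hi = max(starts), min(ends)
    if hi - lo < cfg.epoch_len:
        raise ValueError("channels do not overlap for at least one epoch")
    n_ep = int(np.floor((hi - lo) / cfg.epoch_len + 1e-9))
    classify = cfg.classifier if cfg.classifier is not None else _default_rule(cfg)
    flags = np.zeros(n_ep, dtype=bool)
    ep_starts = lo + cfg.epoch_len * np.arange(n_ep)
    for i, t0 in enumerate(ep_starts):
        flags[i] = bool(classify(epoch_features(eda, acc, temp, t0, t0 + cfg.epoch_len)))
    return ArtifactMask(
        flags, detector="acc_temp_rule" if cfg.classifier is None else "custom",
        epoch_starts=ep_starts, epoch_len=cfg.epoch_len,
    )


# ---------------------------------------------------------------------------
# Convex tonic/phasic decomposition
# ---------------------------------------------------------------------------

@dataclass
class EdaDecomposition:
    """Tonic + phasic + residual = input, exactly by construction."""

    tonic: UniformSeries
    phasic: UniformSeries
    residual: UniformSeries
    driver: np.ndarray
    status: str
    objective: float


def _scr_kernel(fs: float, rise: float, decay: float) -> np.ndarray:
    """Discretised biexponential SCR kernel, normalised to unit peak and
    truncated where it falls below 1e-3 of the peak."""
    tp = scr_kernel_peak_delay(rise, decay)
    peak = np.exp(-tp / decay) - np.exp(-tp / rise)
    t_max = decay * np.log(1e3 / peak) + tp
    t = np.arange(0.0, t_max, 1.0 / fs)
    h = (np.exp(-t / decay) - np.exp(-t / rise)) / peak
    return h[h >= 0]


def _spline_basis(n: int, fs: float, knot_spacing: float) -> sparse.csr_matrix:
    """Clamped cubic B-spline design matrix with knots every ``knot_spacing`` s."""
    dur = n / fs
    inner = np.arange(0.0, dur + knot_spacing, knot_spacing)
    if inner[-1] < dur:
        inner = np.append(inner, dur)
    knots = np.r_[[inner[0]] * 3, inner, [inner[-1]] * 3]
    x = np.minimum(np.arange(n) / fs, inner[-1] - 1e-9)
    B = interpolate.BSpline.design_matrix(x, knots, 3)
    return sparse.csr_matrix(B)


def decompose_eda(
    eda: UniformSeries,
    alpha: float = 8e-4,
    gamma: float = 1e-2,
    rise: float = 0.75,
    decay: float = 2.0,
    knot_spacing: float = 10.0,
    max_iter: int = 3000,
) -> EdaDecomposition:
    """Solve the convex decomposition program.

    minimise  0.5/n ||K q + B l + C d - y||^2 + (alpha/n) 1'q
              + 0.5 gamma/n_l ||l||^2      subject to  q >= 0

    where ``K`` convolves the nonnegative sparse driver ``q`` with the
    biexponential SCR kernel (unit peak, so driver amplitudes are in uS),
    ``B l`` is a smooth cubic-spline tonic and ``C d`` an offset + linear
    drift.  ``alpha`` sets driver sparsity, ``gamma`` tonic stiffness.
    """
    y = eda.values
    n = y.size
    fs = eda.fs
    if n / fs < 10.0:
        raise ValueError("need at least 10 s of signal to decompose")
    h = _scr_kernel(fs, rise, decay)
    K = sparse.diags(
        [np.full(n - k, h[k]) for k in range(min(h.size, n))],
        offsets=[-k for k in range(min(h.size, n))],
        format="csr",
    )
    B = _spline_basis(n, fs, knot_spacing)
    nl = B.shape[1]
    trel = np.arange(n) / fs
    C = sparse.csr_matrix(np.column_stack([np.ones(n), trel / trel[-1]]))
    M = sparse.hstack([K, B, C], format="csr")
    MT = M.T.tocsr()
    nvar = n + nl + 2
    reg = np.zeros(nvar)
    lin = np.zeros(nvar)
    lin[:n] = alpha / n
    reg[n:n + nl] = gamma / nl

    def fun(x):
        r = M @ x - y
        f = 0.5 * float(r @ r) / n + float(lin @ x) + 0.5 * float(reg @ (x * x))
        g = (MT @ r) / n + lin + reg * x
        return f, g

    bounds = [(0.0, None)] * n + [(None, None)] * (nl + 2)
    x0 = np.zeros(nvar)
    x0[n + nl] = float(np.min(y))  # start the offset at the signal floor
    res = optimize.minimize(
        fun, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_iter, "maxfun": 10 * max_iter, "ftol": 1e-14, "gtol": 1e-10},
    )
    if not res.success and "ABNORMAL" in str(res.message):
        raise RuntimeError(f"decomposition solver failed: {res.message}")
    q = res.x[:n]
    phasic_v = K @ q
    tonic_v = B @ res.x[n:n + nl] + C @ res.x[n + nl:]
    resid_v = y - phasic_v - tonic_v
    mk = lambda ch, v: UniformSeries(ch, eda.start_epoch, fs, v)
    return EdaDecomposition(
        tonic=mk("eda", tonic_v),
        phasic=mk("eda", phasic_v),
        residual=mk("eda", resid_v),
        driver=q,
        status=str(res.message),
        objective=float(res.fun),
    )


# ---------------------------------------------------------------------------
# Peaks and features
# ---------------------------------------------------------------------------

def eda_peaks(
    phasic: UniformSeries,
    min_amp: float = 0.05,
    strong_amp: float = 1.0,
):
    """Local maxima of the phasic component with prominence >= ``min_amp``.

    Returns ``(times, amplitudes, strong)`` where ``strong`` marks peaks
    whose amplitude exceeds ``strong_amp`` (1 uS by convention).
    """
    v = phasic.values
    idx, _ = signal.find_peaks(v, prominence=min_amp)
    times = phasic.start_epoch + idx / phasic.fs
    amps = v[idx]
    return times, amps, amps > strong_amp


def _kept_sample_mask(series: UniformSeries, mask: Optional[ArtifactMask]) -> np.ndarray:
    keep = np.ones(len(series), dtype=bool)
    if mask is None or mask.epoch_starts is None:
        return keep
    t = series.times
    for t0, bad in zip(mask.epoch_starts, mask.flags):
        if bad:
            keep &= ~((t >= t0) & (t < t0 + mask.epoch_len))
    return keep


def eda_features(
    decomp: EdaDecomposition,
    mask: Optional[ArtifactMask] = None,
    window: Optional[tuple] = None,
    min_amp: float = 0.05,
    strong_amp: float = 1.0,
) -> dict:
    """The seven EDA features on one window, artifact epochs excluded.

    Distribution features (mean, std, 20th/80th percentile, quartile
    deviation = 75th - 25th percentile) are computed on the tonic
    component; peak rates on the phasic component, normalised per 100 s of
    artifact-free duration.  Percentiles use linear interpolation.
    A fully excluded window yields NaN features.
    """
    tonic, phasic = decomp.tonic, decomp.phasic
    if window is not None:
        tonic, phasic = tonic.slice(*window), phasic.slice(*window)
    keep = _kept_sample_mask(tonic, mask)
    out = {k: float("nan") for k in EDA_KEYS}
    tv = tonic.values[keep]
    if tv.size == 0:
        return out
    out["mean"] = float(np.mean(tv))
    out["std"] = float(np.std(tv))
    out["p20"] = float(np.percentile(tv, 20))
    out["p80"] = float(np.percentile(tv, 80))
    out["quartile_dev"] = float(np.percentile(tv, 75) - np.percentile(tv, 25))
    times, amps, strong = eda_peaks(phasic, min_amp, strong_amp)
    kept_dur = keep.sum() / tonic.fs
    if kept_dur > 0:
        pk_keep = _kept_sample_mask(phasic, mask)
        sel = np.array(
            [pk_keep[int(round((t - phasic.start_epoch) * phasic.fs))] for t in times],
            dtype=bool,
        ) if times.size else np.zeros(0, dtype=bool)
        out["peaks_per_100s"] = 100.0 * float(np.sum(sel)) / kept_dur
        out["strong_peaks_per_100s"] = 100.0 * float(np.sum(sel & strong)) / kept_dur
    return out
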