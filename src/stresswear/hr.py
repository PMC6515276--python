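"""RR-interval artifact handling and heart-rate-variability features.

Artifact detection follows the percentage-threshold rule common in HRV
practice: a beat is an artifact when its interval deviates from a local
average by more than a configurable percentage (20% by default).  The
local average here is *causal* — the mean of the previous accepted beats —
so an artifact never contaminates its own reference.  Detected beats can
either be removed (with minimum-run constraints on the surviving segments)
or repaired by shape-preserving piecewise-cubic interpolation.

The feature battery covers the standard time-domain statistics (mean HR,
mean RR, SDNN, RMSSD, SDSD, pNN50, the triangular index and TINN on a
1/128 s histogram) and spectral band powers in the VLF (0-0.04 Hz),
LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz) bands, computed both from an
evenly resampled tachogram (FFT periodogram) and directly from the
irregular beat times (Lomb-Scargle).
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import interpolate, signal

from .io_formats import ArtifactMask, IBISeries

__all__ = [
    "RRCleanConfig",
    "CleanRR",
    "detect_rr_artifacts",
    "clean_rr",
    "hrv_time_features",
    "hrv_freq_features",
    "hrv_features",
    "HRV_TIME_KEYS",
    "HRV_FREQ_KEYS",
    "HRV_ALL_KEYS",
]

VLF_BAND = (0.0, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
HIST_BIN = 1.0 / 128.0  # s, conventional RR histogram bin width

HRV_TIME_KEYS = (
    "mean_hr", "mean_rr", "sdnn", "rmssd", "sdsd", "pnn50", "tri_index", "tinn",
)
HRV_FREQ_KEYS = (
    "vlf", "lf", "hf", "lf_hf", "plf", "phf", "lomb_lf", "lomb_hf", "lomb_lf_hf",
)
HRV_ALL_KEYS = HRV_TIME_KEYS + HRV_FREQ_KEYS


@dataclass(frozen=True)
class RRCleanConfig:
    """Parameters of the RR cleaning stage.

    threshold_pct        artifact threshold as % deviation from the local mean
    local_window_beats   length of the causal local mean, in accepted beats
    mode                 'filter' (remove + run constraints) or 'interpolate'
    min_consecutive_samples / min_consecutive_time
                         filter mode only: surviving runs with fewer beats or
                         a shorter time span are discarded
    """

    threshold_pct: float = 20.0
    local_window_beats: int = 5
    mode: str = "filter"
    min_consecutive_samples: int = 5
    min_consecutive_time: float = 10.0

    def __post_init__(self) -> None:
        if self.local_window_beats < 1:
            raise ValueError("local_window_beats must be >= 1")
        if self.mode not in ("filter", "interpolate"):
            raise ValueError("mode must be 'filter' or 'interpolate'")
        if self.threshold_pct <= 0:
            raise ValueError("threshold_pct must be positive")


@dataclass
class CleanRR:
    """Result of the cleaning stage.

    In filter mode ``segments`` holds the surviving contiguous runs; in
    interpolate mode ``repaired`` is a single series with the same beat
    count as the input.  ``fraction_remaining`` is kept beats / total
    beats (``fraction_remaining_time`` is the duration-based analogue).
    """

    segments: list
    mask: ArtifactMask
    fraction_remaining: float
    fraction_remaining_time: float
    repaired: Optional[IBISeries] = None

    @property
    def all_beats(self) -> IBISeries:
        """Kept beats pooled across segments (interpolate mode: the repaired
        series)."""
        if self.repaired is not None:
            return self.repaired
        if not self.segments:
            return IBISeries(np.empty(0), np.empty(0))
        bt = np.concatenate([s.beat_times for s in self.segments])
        rr = np.concatenate([s.ibi for s in self.segments])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return IBISeries(bt, rr)


def detect_rr_artifacts(rr: IBISeries, cfg: RRCleanConfig = RRCleanConfig()) -> ArtifactMask:
    """Flag beat ``i`` iff ``|rr_i - L_i| / L_i > threshold_pct/100`` where
    ``L_i`` is the mean of the previous ``local_window_beats`` accepted
    beats (fewer while the window fills; the very first beat has no
    reference and is never flagged).
    """
    n = len(rr)
    flags = np.zeros(n, dtype=bool)
    if n < cfg.local_window_beats + 1:
        warnings.warn(
            f"series of {n} beats shorter than local window "
            f"{cfg.local_window_beats}+1; nothing flagged",
            stacklevel=2,
        )
        return ArtifactMask(flags, detector="rr_pct_threshold")
    thr = cfg.threshold_pct / 100.0
    buf: deque = deque(maxlen=cfg.local_window_beats)
    vals = rr.ibi
    for i in range(n):
        if buf:
            ref = float(np.mean(buf))
            if abs(vals[i] - ref) / ref > thr:
                flags[i] = True
                continue
        buf.append(vals[i])
    return ArtifactMask(flags, detector="rr_pct_threshold")


def clean_rr(rr: IBISeries, mask: ArtifactMask, cfg: RRCleanConfig = RRCleanConfig()) -> CleanRR:
    """Remove or repair flagged beats.

    filter mode: flagged beats are removed; the surviving beats split into
    contiguous runs at each removal, and runs with fewer than
    ``min_consecutive_samples`` beats or spanning less than
    ``min_consecutive_time`` seconds are discarded.

    interpolate mode: flagged values are replaced by monotone (shape
    preserving) piecewise-cubic interpolation over beat index against the
    unflagged neighbours; beat count is preserved.
    """
    n = len(rr)
    flags = mask.flags
    if flags.shape != (n,):
        raise ValueError("mask does not align with series")
    total_time = float(np.sum(rr.ibi)) if n else 0.0

    if cfg.mode == "interpolate":
        good = ~flags
        if not np.any(good):
            return CleanRR([], mask, 0.0, 0.0)
        vals = rr.ibi.copy()
        if np.any(flags):
            idx = np.arange(n)
            if good.sum() >= 2:
                pchip = interpolate.PchipInterpolator(idx[good], vals[good], extrapolate=False)
                rep = pchip(idx[flags])
            else:
                rep = np.full(flags.sum(), np.nan)
            # edges beyond the outermost unflagged beats: hold nearest value
            rep = np.where(np.isnan(rep), np.interp(idx[flags], idx[good], vals[good]), rep)
            vals[flags] = rep
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            repaired = IBISeries(rr.beat_times, vals)
        frac = float(good.sum()) / n
        frac_t = float(np.sum(rr.ibi[good])) / total_time if total_time else 0.0
        return CleanRR([], mask, frac, frac_t, repaired=repaired)

    # filter mode
    segments = []
    kept_beats = 0
    kept_time = 0.0
    start = None
    for i in range(n + 1):
        if i < n and not flags[i]:
            if start is None:
                start = i
            continue
        if start is not None:
            bt, rrv = rr.beat_times[start:i], rr.ibi[start:i]
            span = float(bt[-1] - bt[0]) if bt.size > 1 else 0.0
            if bt.size >= cfg.min_consecutive_samples and span >= cfg.min_consecutive_time:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    segments.append(IBISeries(bt, rrv))
                kept_beats += bt.size
                kept_time += float(np.sum(rrv))
            start = None
    frac = kept_beats / n if n else 0.0
    frac_t = kept_time / total_time if total_time else 0.0
    return CleanRR(segments, mask, frac, frac_t)


# ---------------------------------------------------------------------------
# Time-domain features
# ---------------------------------------------------------------------------

def _nan_features(keys) -> dict:
    return {k: float("nan") for k in keys}


def hrv_time_features(rr: IBISeries) -> dict:
    """Standard time-domain HRV statistics; diff-based statistics need >= 3
    beats, the rest >= 2 (missing features are NaN)."""
    out = _nan_features(HRV_TIME_KEYS)
    vals = rr.ibi
    n = vals.size
    if n < 2:
        return out
    mean_rr = float(np.mean(vals))
    out["mean_rr"] = mean_rr
    out["mean_hr"] = 60.0 / mean_rr
    out["sdnn"] = float(np.std(vals, ddof=1))
    if n >= 3:
        d = np.diff(vals)
        out["rmssd"] = float(np.sqrt(np.mean(d ** 2)))
        out["sdsd"] = float(np.std(d, ddof=1))
        out["pnn50"] = 100.0 * float(np.sum(np.abs(d) > 0.050)) / d.size
    counts, _ = _rr_histogram(vals)
    out["tri_index"] = n / float(counts.max())
    out["tinn"] = _tinn(counts)
    return out


def _rr_histogram(vals: np.ndarray):
    """Histogram of RR intervals on the conventional 1/128 s grid."""
    lo = np.floor(vals.min() / HIST_BIN)
    hi = np.floor(vals.max() / HIST_BIN)
    edges = (np.arange(lo, hi + 2)) * HIST_BIN
    counts, _ = np.histogram(vals, bins=edges)
    return counts, edges


def _tinn(counts: np.ndarray) -> float:
    """Baseline width of the least-squares triangular fit to the RR histogram.

    The triangle is zero outside ``[N, M]``, rises linearly to the histogram
    peak and falls back to zero; ``N`` and ``M`` are searched over bin
    positions.  A single occupied bin degenerates to one bin width.
    """
    k = counts.size
    peak_idx = int(np.argmax(counts))
    y = float(counts[peak_idx])
    occupied = np.nonzero(counts)[0]
    if occupied.size <= 1:
        return HIST_BIN
    best = (np.inf, 1.0)
    x = np.arange(k, dtype=float)
    for n_i in range(-1, peak_idx + 1):          # left foot (bin index, may sit one bin out)
        for m_i in range(peak_idx, k + 1):       # right foot
            tri = np.zeros(k)
            if peak_idx > n_i:
                left = (x >= n_i) & (x <= peak_idx)
                tri[left] = y * (x[left] - n_i) / (peak_idx - n_i)
            if m_i > peak_idx:
                right = (x >= peak_idx) & (x <= m_i)
                tri[right] = y * (m_i - x[right]) / (m_i - peak_idx)
            tri[peak_idx] = y
            err = float(np.sum((counts - tri) ** 2))
            if err < best[0] - 1e-12:
                best = (err, (m_i - n_i) * HIST_BIN)
    return best[1]


# ---------------------------------------------------------------------------
# Frequency-domain features
# ---------------------------------------------------------------------------

RESAMPLE_FS = 4.0  # Hz, tachogram resampling rate for the FFT path
MIN_SPAN = 60.0    # s, shortest span the spectral bands are meaningful for


def _band_power(f: np.ndarray, p: np.ndarray, band) -> float:
    m = (f >= band[0]) & (f <= band[1])
    if m.sum() < 2:
        return 0.0
    return float(np.trapezoid(p[m], f[m]))


def _band_peak(f: np.ndarray, p: np.ndarray, band) -> float:
    m = (f >= band[0]) & (f <= band[1])
    if not np.any(m):
        return float("nan")
    return float(f[m][np.argmax(p[m])])


def hrv_freq_features(rr: IBISeries, method: str = "fft") -> dict:
    """Spectral band powers of the tachogram.

    ``fft``: the RR series is resampled to a uniform 4 Hz grid by cubic
    interpolation over beat times, mean-detrended, and a periodogram is
    integrated over the VLF/LF/HF bands; ``plf``/``phf`` are the dominant
    in-band frequencies.  ``lomb``: the Lomb-Scargle periodogram is
    evaluated directly on the irregular beat times (keys prefixed
    ``lomb_``).  Requires a span of at least 60 s.
    """
    if method not in ("fft", "lomb"):
        raise ValueError("method must be 'fft' or 'lomb'")
    keys = ("vlf", "lf", "hf", "lf_hf", "plf", "phf") if method == "fft" else (
        "lomb_lf", "lomb_hf", "lomb_lf_hf")
    out = _nan_features(keys)
    if len(rr) < 4 or rr.span < MIN_SPAN:
        return out
    t, x = rr.beat_times, rr.ibi
    if method == "fft":
        cs = interpolate.CubicSpline(t, x)
        tu = np.arange(t[0], t[-1], 1.0 / RESAMPLE_FS)
        xu = cs(tu)
        xu = xu - xu.mean()
        f, p = signal.periodogram(xu, fs=RESAMPLE_FS, detrend=False)
        out["vlf"] = _band_power(f, p, VLF_BAND)
        out["lf"] = _band_power(f, p, LF_BAND)
        out["hf"] = _band_power(f, p, HF_BAND)
        out["lf_hf"] = out["lf"] / out["hf"] if out["hf"] > 0 else float("nan")
        out["plf"] = _band_peak(f, p, LF_BAND)
        out["phf"] = _band_peak(f, p, HF_BAND)
        return out
    # Lomb-Scargle on the irregular beat times
    df = min(1.0 / (2.0 * rr.span), 0.002)
    f = np.arange(df, HF_BAND[1] + df, df)
    xm = x - x.mean()
    p = signal.lombscargle(t - t[0], xm, 2 * np.pi * f)
    # one-sided scale comparable across record lengths
    p = p * 2.0 / len(x)
    out["lomb_lf"] = _band_power(f, p, LF_BAND)
    out["lomb_hf"] = _band_power(f, p, HF_BAND)
    out["lomb_lf_hf"] = (
        out["lomb_lf"] / out["lomb_hf"] if out["lomb_hf"] > 0 else float("nan")
    )
    return out


def hrv_features(rr: IBISeries) -> dict:
    """Full HRV battery: time domain + FFT bands + Lomb-Scargle bands."""
    out = hrv_time_features(rr)
    out.update(hrv_freq_features(rr, "fft"))
    out.update(hrv_freq_features(rr, "lomb"))
    return out


def hrv_features_clean(clean: CleanRR) -> dict:
    """Feature battery on a cleaned series.

    Interpolate mode uses the single repaired series.  Filter mode pools
    within-segment statistics: means/SDNN over all kept beats, diff-based
    statistics from within-segment successive differences only, and
    spectral features computed per segment and averaged weighted by
    segment duration.
    """
    if clean.repaired is not None:
        return hrv_features(clean.repaired)
    segs = clean.segments
    out = _nan_features(HRV_ALL_KEYS)
    if not segs:
        return out
    pooled = clean.all_beats
    vals = pooled.ibi
    if vals.size >= 2:
        out["mean_rr"] = float(np.mean(vals))
        out["mean_hr"] = 60.0 / out["mean_rr"]
        out["sdnn"] = float(np.std(vals, ddof=1))
        counts, _ = _rr_histogram(vals)
        out["tri_index"] = vals.size / float(counts.max())
        out["tinn"] = _tinn(counts)
    diffs = [np.diff(s.ibi) for s in segs if len(s) >= 2]
    if diffs:
        d = np.concatenate(diffs)
        if d.size >= 2:
            out["rmssd"] = float(np.sqrt(np.mean(d ** 2)))
            out["sdsd"] = float(np.std(d, ddof=1))
            out["pnn50"] = 100.0 * float(np.sum(np.abs(d) > 0.050)) / d.size
    # spectral features on the pooled kept beats: the Lomb-Scargle
    # periodogram is defined on irregular (gapped) beat times, and the FFT
    # path's cubic resampling bridges the removal gaps
    if pooled.span >= MIN_SPAN:
        out.update(hrv_freq_features(pooled, "fft"))
        out.update(hrv_freq_features(pooled, "lomb"))
    return out
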