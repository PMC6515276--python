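"""Independent direct-formula oracles used by the acceptance checks.

Each function recomputes a published feature definition from scratch,
sharing no code with the package implementation.
"""

import numpy as np

BIN = 1.0 / 128.0


def time_features(rr: np.ndarray) -> dict:
    n = len(rr)
    d = rr[1:] - rr[:-1]
    mean_rr = rr.sum() / n
    counts = _hist(rr)
    return {
        "mean_rr": mean_rr,
        "mean_hr": 60.0 / mean_rr,
        "sdnn": np.sqrt(((rr - mean_rr) ** 2).sum() / (n - 1)),
        "rmssd": np.sqrt((d ** 2).sum() / len(d)),
        "sdsd": np.sqrt(((d - d.mean()) ** 2).sum() / (len(d) - 1)),
        "pnn50": 100.0 * (np.abs(d) > 0.050).sum() / len(d),
        "tri_index": n / counts.max(),
        "tinn": tinn(rr),
    }


def _hist(rr: np.ndarray) -> np.ndarray:
    ids = np.floor(rr / BIN).astype(int)
    lo = ids.min()
    counts = np.zeros(ids.max() - lo + 1)
    for i in ids:
        counts[i - lo] += 1
    return counts


def tinn(rr: np.ndarray) -> float:
    counts = _hist(rr)
    k = counts.size
    if (counts > 0).sum() <= 1:
        return BIN
    peak = int(np.argmax(counts))
    y = counts[peak]
    x = np.arange(k, dtype=float)
    best_err, best_w = np.inf, 1.0
    for n_i in range(-1, peak + 1):
        for m_i in range(peak, k + 1):
            up = np.clip((x - n_i) / (peak - n_i), 0, 1) if peak > n_i else (x >= peak) * 1.0
            down = np.clip((m_i - x) / (m_i - peak), 0, 1) if m_i > peak else (x <= peak) * 1.0
            tri = y * np.minimum(up, down)
            err = ((counts - tri) ** 2).sum()
            if err < best_err - 1e-12:
                best_err, best_w = err, (m_i - n_i) * BIN
    return best_w


def percentile_features(vals: np.ndarray) -> dict:
    """Linear-interpolation percentiles, computed by direct order statistics."""

    def pct(p):
        s = np.sort(vals)
        h = (len(s) - 1) * p / 100.0
        lo = int(np.floor(h))
        hi = min(lo + 1, len(s) - 1)
        return s[lo] + (h - lo) * (s[hi] - s[lo])

    return {
        "mean": vals.sum() / len(vals),
        "std": np.sqrt(((vals - vals.mean()) ** 2).sum() / len(vals)),
        "p20": pct(20),
        "p80": pct(80),
        "quartile_dev": pct(75) - pct(25),
    }


def acc_energy(x, y, z) -> float:
    mag = np.sqrt(x ** 2 + y ** 2 + z ** 2)
    return float(((mag - mag.mean()) ** 2).sum())
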