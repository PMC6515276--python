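"""Accelerometer window features: per-axis means, mean magnitude, and the
FFT energy of the mean-removed magnitude (posture-invariant movement
intensity)."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .io_formats import UniformSeries

__all__ = ["acc_window_features", "ACC_KEYS"]

ACC_KEYS = ("mean_x", "mean_y", "mean_z", "mean_magnitude", "fft_energy")


def acc_window_features(acc: Sequence[UniformSeries], window=None) -> dict:
    """Features of a three-axis accelerometer window.

    ``fft_energy = (1/N) * sum_k |X_k|^2`` of the magnitude signal with the
    DC component excluded, which by Parseval equals the time-domain
    mean-removed sum of squares — so a constant gravity vector carries zero
    energy and only oscillation contributes.  An empty window yields NaN
    features.
    """
    x, y, z = acc
    if window is not None:
        x, y, z = (s.slice(*window) for s in (x, y, z))
    n = min(len(x), len(y), len(z))
    out = {k: float("nan") for k in ACC_KEYS}
    if n == 0:
        return out
    xv, yv, zv = x.values[:n], y.values[:n], z.values[:n]
    out["mean_x"] = float(np.mean(xv))
    out["mean_y"] = float(np.mean(yv))
    out["mean_z"] = float(np.mean(zv))
    mag = np.sqrt(xv ** 2 + yv ** 2 + zv ** 2)
    out["mean_magnitude"] = float(np.mean(mag))
    spec = np.fft.rfft(mag - mag.mean())
    w = np.full(spec.size, 2.0)  # one-sided doubling, except DC/Nyquist
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    out["fft_energy"] = float(np.sum(w * np.abs(spec) ** 2) / n)
    return out
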