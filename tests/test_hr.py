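"""RR artifact detection/cleaning and the HRV feature battery.

Time-domain features are checked against an independent one-line-per-
formula oracle; spectra against analytically placed tones.
"""

import warnings
from collections import Counter

import numpy as np
import pytest

from stresswear.hr import (
    HIST_BIN,
    CleanRR,
    RRCleanConfig,
    clean_rr,
    detect_rr_artifacts,
    hrv_features_clean,
    hrv_freq_features,
    hrv_time_features,
)
from stresswear.io_formats import ArtifactMask, IBISeries
from stresswear.synthetic import simulate_rr


def series(rr_values, t0=0.0):
    rr = np.asarray(rr_values, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return IBISeries(t0 + np.cumsum(rr), rr)


# ---------------------------------------------------------------------------
# independent oracle (per-formula, no shared code with the implementation)
# ---------------------------------------------------------------------------

def oracle_time_features(rr: np.ndarray) -> dict:
    n = len(rr)
    d = rr[1:] - rr[:-1]
    bins = Counter(int(np.floor(v / HIST_BIN)) for v in rr)
    out = {
        "mean_rr": sum(rr) / n,
        "mean_hr": 60.0 / (sum(rr) / n),
        "sdnn": np.sqrt(sum((v - rr.mean()) ** 2 for v in rr) / (n - 1)),
        "rmssd": np.sqrt(sum(v * v for v in d) / len(d)),
        "sdsd": np.sqrt(sum((v - d.mean()) ** 2 for v in d) / (len(d) - 1)),
        "pnn50": 100.0 * sum(1 for v in d if abs(v) > 0.050) / len(d),
        "tri_index": n / max(bins.values()),
    }
    out["tinn"] = oracle_tinn(rr)
    return out


def oracle_tinn(rr: np.ndarray) -> float:
    lo = int(np.floor(rr.min() / HIST_BIN))
    hi = int(np.floor(rr.max() / HIST_BIN))
    k = hi - lo + 1
    counts = np.zeros(k)
    for v in rr:
        counts[int(np.floor(v / HIST_BIN)) - lo] += 1
    if (counts > 0).sum() <= 1:
        return HIST_BIN
    peak = int(np.argmax(counts))
    y = counts[peak]
    best_err, best_w = np.inf, 1.0
    for n_i in range(-1, peak + 1):
        for m_i in range(peak, k + 1):
            err = 0.0
            for j in range(k):
                if n_i <= j <= peak and peak > n_i:
                    tri = y * (j - n_i) / (peak - n_i)
                elif peak <= j <= m_i and m_i > peak:
                    tri = y * (m_i - j) / (m_i - peak)
                elif j == peak:
                    tri = y
                else:
                    tri = 0.0
                err += (counts[j] - tri) ** 2
            if err < best_err - 1e-12:
                best_err, best_w = err, (m_i - n_i) * HIST_BIN
    return best_w


# ---------------------------------------------------------------------------
# artifact detection
# ---------------------------------------------------------------------------

class TestDetect:
    def test_deviation_beyond_threshold_flagged(self):
        rr = series([0.8] * 5 + [1.0])  # deviation 25% from accepted mean 0.8
        mask = detect_rr_artifacts(rr, RRCleanConfig(threshold_pct=20))
        assert mask.flags.tolist() == [False] * 5 + [True]

    @pytest.mark.parametrize("thr", [10, 15, 20, 25])
    def test_constant_series_never_flagged(self, thr):
        mask = detect_rr_artifacts(series([0.8] * 50), RRCleanConfig(threshold_pct=thr))
        assert mask.n_flagged == 0

    def test_fifteen_percent_beat_threshold_direction(self):
        rr = series([0.8] * 5 + [0.92])  # 15% above local mean
        flagged_at_10 = detect_rr_artifacts(rr, RRCleanConfig(threshold_pct=10)).flags[-1]
        flagged_at_25 = detect_rr_artifacts(rr, RRCleanConfig(threshold_pct=25)).flags[-1]
        assert flagged_at_10 and not flagged_at_25

    def test_artifact_excluded_from_its_own_reference(self):
        # spike then normal beats: the spike must not drag the local mean up
        rr = series([0.8] * 5 + [1.4] + [0.8] * 3)
        mask = detect_rr_artifacts(rr)
        assert mask.flags.tolist() == [False] * 5 + [True] + [False] * 3

    def test_short_series_warns_all_unflagged(self):
        with pytest.warns(UserWarning, match="shorter"):
            mask = detect_rr_artifacts(series([0.8, 0.8, 0.8]))
        assert mask.n_flagged == 0

    def test_recall_and_fpr_on_simulated_spikes(self, default_cfg):
        rng = np.random.default_rng(11)
        rr, gt = simulate_rr(default_cfg, "lecture", 400, rng)
        mask = detect_rr_artifacts(rr)
        true = set(gt.rr_artifact_indices.tolist())
        det = set(np.flatnonzero(mask.flags).tolist())
        assert true <= det  # recall 1.0
        clean = len(rr) - len(true)
        assert len(det - true) / clean <= 0.01


class TestClean:
    def test_no_flags_single_segment_fraction_one(self):
        rr = series([0.8] * 30)
        mask = ArtifactMask(np.zeros(30, bool), "t")
        out = clean_rr(rr, mask, RRCleanConfig())
        assert len(out.segments) == 1 and out.fraction_remaining == 1.0
        np.testing.assert_array_equal(out.segments[0].ibi, rr.ibi)

    def test_short_run_discarded(self):
        flags = np.zeros(10, bool)
        flags[3] = True  # runs of 3 and 6 beats
        rr = series([0.8] * 10)
        out = clean_rr(rr, ArtifactMask(flags, "t"),
                       RRCleanConfig(min_consecutive_samples=5, min_consecutive_time=0.0))
        assert len(out.segments) == 1 and len(out.segments[0]) == 6
        assert out.fraction_remaining == pytest.approx(0.6)

    def test_all_flagged_empty_no_exception(self):
        rr = series([0.8] * 10)
        out = clean_rr(rr, ArtifactMask(np.ones(10, bool), "t"), RRCleanConfig())
        assert out.segments == [] and out.fraction_remaining == 0.0

    def test_interpolation_reproduces_linear_ramp(self):
        vals = np.linspace(0.7, 0.9, 11)
        rr = series(vals)
        flags = np.zeros(11, bool)
        flags[5] = True
        out = clean_rr(rr, ArtifactMask(flags, "t"), RRCleanConfig(mode="interpolate"))
        assert out.repaired is not None and len(out.repaired) == 11
        assert out.repaired.ibi[5] == pytest.approx((vals[4] + vals[6]) / 2, abs=1e-12)

    def test_interpolation_shape_preserving_bounds(self, rng):
        # monotone data: repaired values never leave the flanking interval
        vals = np.sort(rng.uniform(0.6, 1.0, 40))
        rr = series(vals)
        flags = np.zeros(40, bool)
        flags[[10, 11, 25]] = True
        out = clean_rr(rr, ArtifactMask(flags, "t"), RRCleanConfig(mode="interpolate"))
        for i in np.flatnonzero(flags):
            lo = vals[: i][~flags[: i]][-1]
            hi = vals[i + 1:][~flags[i + 1:]][0]
            assert lo - 1e-12 <= out.repaired.ibi[i] <= hi + 1e-12

    def test_fraction_remaining_monotone_in_threshold(self, default_cfg):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            for cls in ("free", "lecture", "contest"):
                rr, _ = simulate_rr(default_cfg, cls, 300, rng)
                fracs = []
                for thr in (10, 15, 20, 25):
                    cfg = RRCleanConfig(threshold_pct=thr)
                    out = clean_rr(rr, detect_rr_artifacts(rr, cfg), cfg)
                    fracs.append(out.fraction_remaining)
                assert all(a <= b + 1e-12 for a, b in zip(fracs, fracs[1:]))


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

class TestTimeFeatures:
    def test_constant_series(self):
        f = hrv_time_features(series([1.0] * 20))
        assert f["mean_hr"] == pytest.approx(60.0)
        assert f["sdnn"] == 0.0 and f["rmssd"] == 0.0 and f["pnn50"] == 0.0
        assert f["tri_index"] == pytest.approx(1.0)
        assert f["tinn"] == pytest.approx(HIST_BIN)

    def test_sixty_ms_swings(self):
        f = hrv_time_features(series([0.800, 0.860, 0.800]))
        assert f["pnn50"] == pytest.approx(100.0)
        assert f["rmssd"] == pytest.approx(0.060, abs=1e-12)

    def test_too_few_beats_missing(self):
        f = hrv_time_features(series([0.8]))
        assert all(np.isnan(v) for v in f.values())

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rr = np.clip(rng.normal(0.85, 0.05, 300), 0.4, 1.5)
        got = hrv_time_features(series(rr))
        want = oracle_time_features(rr)
        for k, v in want.items():
            assert got[k] == pytest.approx(v, abs=1e-9), k


class TestFreqFeatures:
    def test_single_lf_tone_dominates(self):
        t = np.cumsum(np.full(400, 0.8))
        rr = 0.8 + 0.05 * np.sin(2 * np.pi * 0.10 * t)
        f = hrv_freq_features(series(rr), "fft")
        grid_step = 4.0 / int(0.8 * 400 * 4)  # fs / n_samples
        assert f["plf"] == pytest.approx(0.10, abs=2 * grid_step)
        assert f["lf_hf"] > 10
        fl = hrv_freq_features(series(rr), "lomb")
        assert fl["lomb_lf_hf"] > 10

    def test_hf_tone_found_in_hf_band(self):
        t = np.cumsum(np.full(400, 0.8))
        rr = 0.8 + 0.03 * np.sin(2 * np.pi * 0.25 * t)
        f = hrv_freq_features(series(rr), "fft")
        assert f["phf"] == pytest.approx(0.25, abs=0.01)
        assert f["lf_hf"] < 0.5

    def test_constant_series_zero_power(self):
        f = hrv_freq_features(series([0.8] * 200), "fft")
        assert f["vlf"] < 1e-10 and f["lf"] < 1e-10 and f["hf"] < 1e-10

    def test_lf_hf_identity(self, default_cfg):
        rng = np.random.default_rng(3)
        rr, _ = simulate_rr(default_cfg, "free", 200, rng)
        f = hrv_freq_features(rr, "fft")
        assert f["lf_hf"] == pytest.approx(f["lf"] / f["hf"])

    def test_short_span_missing(self):
        f = hrv_freq_features(series([0.8] * 20), "fft")
        assert all(np.isnan(v) for v in f.values())


class TestCleanFeatures:
    def test_interpolate_mode_full_battery(self, default_cfg):
        rng = np.random.default_rng(5)
        rr, _ = simulate_rr(default_cfg, "lecture", 200, rng)
        cfg = RRCleanConfig(mode="interpolate")
        out = clean_rr(rr, detect_rr_artifacts(rr, cfg), cfg)
        f = hrv_features_clean(out)
        assert np.isfinite(f["rmssd"]) and np.isfinite(f["lf"]) and np.isfinite(f["lomb_lf"])

    def test_filter_mode_diffs_do_not_cross_gaps(self):
        # two runs separated by a removed beat: the jump between runs must
        # not enter the successive-difference statistics
        vals = [0.8] * 10 + [1.4] + [0.9] * 10
        rr = series(vals)
        flags = np.zeros(21, bool)
        flags[10] = True
        out = clean_rr(rr, ArtifactMask(flags, "t"),
                       RRCleanConfig(min_consecutive_samples=2, min_consecutive_time=0.0))
        f = hrv_features_clean(out)
        assert f["rmssd"] == 0.0  # constant within each run
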