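"""EDA artifact exclusion, convex decomposition and the seven features."""

from dataclasses import replace

import numpy as np
import pytest

from stresswear.eda import (
    EdaArtifactConfig,
    decompose_eda,
    detect_eda_artifacts,
    eda_features,
    eda_peaks,
)
from stresswear.io_formats import ArtifactMask, UniformSeries
from stresswear.synthetic import SimConfig, scr_train, simulate_session


def truth_epoch_flags(windows, epoch_starts, epoch_len):
    """An epoch is truly artifactual iff its midpoint lies in an injected
    contamination window."""
    mids = np.asarray(epoch_starts) + epoch_len / 2
    flags = np.zeros(mids.size, bool)
    for a0, a1 in windows:
        flags |= (mids >= a0) & (mids < a1)
    return flags


class TestArtifactDetection:
    def _session(self, seed, cls="contest", burst_rate=2.0):
        cfg = replace(SimConfig(seed=seed), burst_rate=burst_rate)
        rng = np.random.default_rng(seed)
        return simulate_session(cfg, cls, 600, rng), cfg

    def test_quiet_recording_no_artifacts(self, default_cfg):
        cfg = replace(default_cfg, burst_rate=0.0)
        rng = np.random.default_rng(0)
        ch, _ = simulate_session(cfg, "free", 300, rng)
        mask = detect_eda_artifacts(ch.eda, ch.acc, ch.temp)
        assert mask.n_flagged == 0

    def test_bursts_detected_with_high_recall_precision(self):
        tp = fp = fn = 0
        for seed in range(5):
            (ch, gt), _ = self._session(seed)
            mask = detect_eda_artifacts(ch.eda, ch.acc, ch.temp)
            truth = truth_epoch_flags(gt.eda_artifact_windows, mask.epoch_starts, mask.epoch_len)
            tp += int((mask.flags & truth).sum())
            fp += int((mask.flags & ~truth).sum())
            fn += int((~mask.flags & truth).sum())
        assert tp / (tp + fn) >= 0.9
        assert tp / (tp + fp) >= 0.9

    def test_no_overlap_raises(self, default_cfg):
        rng = np.random.default_rng(1)
        ch, _ = simulate_session(default_cfg, "free", 60, rng)
        late = UniformSeries("eda", 10_000.0, 4.0, np.full(240, 2.0))
        with pytest.raises(ValueError, match="overlap"):
            detect_eda_artifacts(late, ch.acc, ch.temp)

    def test_pluggable_classifier_replaces_rule(self, default_cfg):
        rng = np.random.default_rng(2)
        ch, _ = simulate_session(default_cfg, "free", 100, rng)
        cfg = EdaArtifactConfig(classifier=lambda f: True)
        mask = detect_eda_artifacts(ch.eda, ch.acc, ch.temp, cfg)
        assert mask.flags.all() and mask.detector == "custom"

    def test_flagged_epochs_contribute_no_samples(self):
        """Samples inside artifact epochs are excluded from the features."""
        from stresswear.eda import EdaDecomposition
        tonic = UniformSeries("eda", 0.0, 4.0, np.arange(80.0))
        zero = UniformSeries("eda", 0.0, 4.0, np.zeros(80))
        decomp = EdaDecomposition(tonic, zero, zero, np.zeros(80), "synthetic", 0.0)
        starts = np.arange(4) * 5.0  # four 5-s epochs covering [0, 20)
        mask = ArtifactMask(np.array([False, False, True, True]), "t",
                            epoch_starts=starts, epoch_len=5.0)
        f = eda_features(decomp, mask, window=(0.0, 20.0))
        f_all = eda_features(decomp, None, window=(0.0, 20.0))
        assert f["mean"] == pytest.approx(np.arange(40.0).mean())
        assert f_all["mean"] == pytest.approx(np.arange(80.0).mean())


class TestDecomposition:
    def test_constant_input_all_tonic(self):
        eda = UniformSeries("eda", 0.0, 4.0, np.full(200, 3.0))
        d = decompose_eda(eda)
        assert np.max(np.abs(d.tonic.values - 3.0)) < 0.01 * 3.0
        assert d.phasic.values.max() <= 1e-9 + 0.0

    def test_reconstruction_identity(self, default_cfg):
        rng = np.random.default_rng(4)
        eda, _ = scr_train(default_cfg, [10, 30, 50], [0.5, 1.2, 0.3], 100, rng=rng)
        d = decompose_eda(eda)
        recon = d.tonic.values + d.phasic.values + d.residual.values
        assert np.max(np.abs(recon - eda.values)) < 1e-6

    def test_phasic_nonnegative(self, default_cfg):
        rng = np.random.default_rng(5)
        eda, _ = scr_train(default_cfg, [20, 60], [0.8, 0.4], 120, rng=rng)
        d = decompose_eda(eda)
        assert d.phasic.values.min() >= -1e-9

    def test_scr_train_peaks_recovered(self, default_cfg):
        onsets = np.linspace(10, 160, 10)
        amps = np.full(10, 0.8)
        eda, gt = scr_train(default_cfg, onsets, amps, 200, rng=np.random.default_rng(6))
        d = decompose_eda(eda)
        times, _, _ = eda_peaks(d.phasic, min_amp=0.05)
        matched = sum(1 for a in gt.scr_apexes if times.size and np.min(np.abs(times - a)) <= 1.0)
        assert matched >= 9

    def test_objective_reproducible(self, default_cfg):
        eda, _ = scr_train(default_cfg, [15, 45], [0.6, 0.9], 80,
                           rng=np.random.default_rng(7))
        a = decompose_eda(eda)
        b = decompose_eda(eda)
        assert a.objective == b.objective
        np.testing.assert_array_equal(a.phasic.values, b.phasic.values)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            decompose_eda(UniformSeries("eda", 0, 4.0, np.full(20, 2.0)))


class TestPeaks:
    def test_flat_phasic_no_peaks(self):
        flat = UniformSeries("eda", 0, 4.0, np.zeros(100))
        times, amps, strong = eda_peaks(flat)
        assert times.size == 0

    def test_strong_peak_threshold(self, default_cfg):
        eda, _ = scr_train(default_cfg, [10, 40], [0.5, 1.5], 80, noise=0.0)
        phasic = UniformSeries("eda", 0, 4.0, eda.values - default_cfg.tonic_baseline)
        times, amps, strong = eda_peaks(phasic, min_amp=0.05)
        assert times.size == 2 and strong.sum() == 1

    def test_rate_normalisation(self, default_cfg):
        eda, _ = scr_train(default_cfg, [20, 70, 120, 170], [0.8] * 4, 200, noise=0.0)
        d = decompose_eda(eda)
        f = eda_features(d)
        assert f["peaks_per_100s"] == pytest.approx(2.0, abs=0.5)

    def test_peak_count_invariant_to_constant_offset(self, default_cfg):
        eda, _ = scr_train(default_cfg, [15, 50], [0.7, 0.9], 90, noise=0.0)
        shifted = UniformSeries("eda", 0, 4.0, eda.values + 5.0)
        f1 = eda_features(decompose_eda(eda))
        f2 = eda_features(decompose_eda(shifted))
        assert f1["peaks_per_100s"] == pytest.approx(f2["peaks_per_100s"])
        assert f2["mean"] == pytest.approx(f1["mean"] + 5.0, abs=0.05)


class TestFeatures:
    def _decomp_of(self, values):
        eda = UniformSeries("eda", 0.0, 4.0, np.asarray(values, float))
        from stresswear.eda import EdaDecomposition
        zero = UniformSeries("eda", 0.0, 4.0, np.zeros(len(values)))
        return EdaDecomposition(tonic=eda, phasic=zero, residual=zero,
                                driver=np.zeros(len(values)), status="synthetic", objective=0.0)

    def test_constant_tonic_no_peaks(self):
        f = eda_features(self._decomp_of(np.full(400, 2.5)))
        assert f["mean"] == 2.5 and f["std"] == 0.0
        assert f["p20"] == f["p80"] == 2.5 and f["quartile_dev"] == 0.0
        assert f["peaks_per_100s"] == 0.0 and f["strong_peaks_per_100s"] == 0.0

    def test_percentiles_linear_interpolation_oracle(self):
        vals = np.arange(1.0, 101.0)
        f = eda_features(self._decomp_of(vals))
        assert f["p20"] == pytest.approx(np.percentile(vals, 20)) == pytest.approx(20.8)
        assert f["p80"] == pytest.approx(np.percentile(vals, 80)) == pytest.approx(80.2)
        assert f["quartile_dev"] == pytest.approx(
            np.percentile(vals, 75) - np.percentile(vals, 25)) == pytest.approx(49.5)

    def test_excluding_half_window_halves_denominator(self, default_cfg):
        # 2 peaks in the kept 100 s of a 200 s window -> 2.0 per 100 s
        eda, _ = scr_train(default_cfg, [20, 60], [0.8, 0.8], 200, noise=0.0)
        d = decompose_eda(eda)
        starts = np.arange(0, 200, 5.0)
        flags = starts >= 100.0  # exclude the second half
        mask = ArtifactMask(flags, "t", epoch_starts=starts, epoch_len=5.0)
        f = eda_features(d, mask)
        assert f["peaks_per_100s"] == pytest.approx(2.0, abs=0.5)

    def test_fully_excluded_window_missing(self):
        d = self._decomp_of(np.full(80, 2.0))
        starts = np.arange(0, 20, 5.0)
        mask = ArtifactMask(np.ones(4, bool), "t", epoch_starts=starts, epoch_len=5.0)
        f = eda_features(d, mask)
        assert all(np.isnan(v) for v in f.values())


def test_scr_rate_feature_ordered_across_classes():
    """Mean SCR-rate feature strictly ordered contest > lecture > free over
    a 20-seed aggregate, matching the simulated rates."""
    rates = {c: [] for c in ("free", "lecture", "contest")}
    for seed in range(20):
        cfg = SimConfig(seed=seed)
        rng = np.random.default_rng(1000 + seed)
        for c in rates:
            from stresswear.synthetic import simulate_eda
            eda, _ = simulate_eda(cfg, c, 200, rng)
            d = decompose_eda(eda)
            rates[c].append(eda_features(d)["peaks_per_100s"])
    m = {c: np.mean(v) for c, v in rates.items()}
    assert m["contest"] > m["lecture"] > m["free"]
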