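"""Synthetic multimodal study generator with ground truth.

Emulates the statistical structure the analysis assumes: three session
types (free day, lecture, programming contest) that modulate cardiac and
electrodermal dynamics — stress shortens the mean RR interval, damps
beat-to-beat variability, and raises the skin-conductance-response rate —
plus controlled artifact injection (RR spikes, movement bursts that
contaminate the EDA channel), so that every preprocessing stage can be
scored against a known answer.

The generator is deterministic under a fixed seed.  All quantities that
shape the generated data are fields of :class:`SimConfig`; the defaults
are the package's reference study conditions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_formats import (
    IBISeries,
    SessionRecord,
    UniformSeries,
    write_e4_channel,
    write_e4_ibi,
    write_generic_ibi,
    write_sessions,
)

__all__ = [
    "ClassParams",
    "SimConfig",
    "GroundTruth",
    "SessionChannels",
    "Study",
    "scr_kernel_peak_delay",
    "simulate_rr",
    "simulate_eda",
    "scr_train",
    "simulate_acc_temp",
    "simulate_session",
    "simulate_study",
]

CLASS_NAMES = ("free", "lecture", "contest")


@dataclass(frozen=True)
class ClassParams:
    """Per-session-type physiological parameters.

    rr_mean       mean RR interval, s (stress shortens it)
    lf_amp        low-frequency (0.1 Hz) RR modulation amplitude, s
    hf_amp        high-frequency (0.25 Hz, respiratory) RR modulation, s
    rr_jitter     beat-to-beat Gaussian jitter sd, s
    scr_rate      skin conductance responses per 100 s (stress raises it)
    frustration_mean  centre of the reported 0-100 frustration scale
    """

    rr_mean: float
    lf_amp: float
    hf_amp: float
    rr_jitter: float
    scr_rate: float
    frustration_mean: float


def _default_classes() -> dict:
    # free day: long RR, high vagal (HF) modulation, few SCRs;
    # contest: short RR, damped HF, frequent SCRs.
    return {
        "free": ClassParams(0.90, 0.030, 0.030, 0.010, 2.0, 20.0),
        "lecture": ClassParams(0.80, 0.022, 0.018, 0.008, 5.0, 50.0),
        "contest": ClassParams(0.70, 0.014, 0.008, 0.006, 10.0, 85.0),
    }


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of the synthetic study."""

    seed: int = 0
    classes: dict = field(default_factory=_default_classes)
    lf_freq: float = 0.10          # Hz
    hf_freq: float = 0.25          # Hz
    # skin conductance
    scr_amp_mu: float = float(np.log(0.4))   # log-normal SCR amplitude, uS
    scr_amp_sigma: float = 0.5
    scr_rise: float = 0.75         # biexponential kernel rise, s
    scr_decay: float = 2.0         # biexponential kernel decay, s
    tonic_baseline: float = 2.0    # uS
    tonic_drift: float = 0.001     # uS/s
    eda_noise: float = 0.01        # uS
    eda_fs: float = 4.0
    # temperature
    temp_baseline: float = 33.0    # degC
    temp_drift: float = 0.0005     # degC/s
    temp_noise: float = 0.005
    temp_fs: float = 4.0
    # accelerometer
    acc_fs: float = 32.0
    acc_noise: float = 0.02        # g
    gravity: tuple = (0.0, 0.0, 1.0)
    # artifacts
    rr_spike_prob: float = 0.02
    rr_spike_factor: float = 1.5
    burst_rate: float = 1.0        # movement bursts per 100 s
    burst_duration: float = 5.0    # s; bursts snap to the epoch grid
    burst_amp: float = 0.5         # g oscillation amplitude
    burst_freq: float = 3.0        # Hz
    epoch_align: float = 5.0       # s grid bursts snap to (EDA epoch length)
    eda_artifact_amp: float = 2.0  # uS triangular contamination inside bursts
    # study layout
    session_length: float = 600.0  # s
    # between-subject heterogeneity (log-scale Gaussian sd)
    subject_sd_rr: float = 0.05
    subject_sd_hrv: float = 0.20
    subject_sd_eda: float = 0.30
    frustration_sd: float = 10.0

    def __post_init__(self) -> None:
        if set(self.classes) != set(CLASS_NAMES):
            raise ValueError(f"classes must be exactly {CLASS_NAMES}")
        for p in self.classes.values():
            if p.scr_rate < 0 or p.rr_jitter < 0:
                raise ValueError("rates and noise levels must be >= 0")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    label: Optional[int] = None
    rr_artifact_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    scr_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    scr_apexes: np.ndarray = field(default_factory=lambda: np.empty(0))
    scr_amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))
    acc_burst_windows: list = field(default_factory=list)
    eda_artifact_windows: list = field(default_factory=list)

    def to_jsonable(self) -> dict:
        return {
            "label": self.label,
            "rr_artifact_indices": [int(i) for i in self.rr_artifact_indices],
            "scr_onsets": [float(t) for t in self.scr_onsets],
            "scr_apexes": [float(t) for t in self.scr_apexes],
            "scr_amplitudes": [float(a) for a in self.scr_amplitudes],
            "acc_burst_windows": [[float(a), float(b)] for a, b in self.acc_burst_windows],
            "eda_artifact_windows": [[float(a), float(b)] for a, b in self.eda_artifact_windows],
        }


def scr_kernel_peak_delay(rise: float, decay: float) -> float:
    """Time from SCR driver onset to conductance apex for the biexponential
    kernel ``exp(-t/decay) - exp(-t/rise)``."""
    return float(np.log(decay / rise) * rise * decay / (decay - rise))


def _scr_kernel_peak_value(rise: float, decay: float) -> float:
    tp = scr_kernel_peak_delay(rise, decay)
    return float(np.exp(-tp / decay) - np.exp(-tp / rise))


# ---------------------------------------------------------------------------
# Channel simulators
# ---------------------------------------------------------------------------

def simulate_rr(
    cfg: SimConfig,
    session_class: str,
    duration: float,
    rng: Optional[np.random.Generator] = None,
    t0: float = 0.0,
    params: Optional[ClassParams] = None,
):
    """Simulate a stress-modulated RR series with multiplicative spike artifacts.

    Each interval is the class mean plus sinusoidal LF (sympathetic/baroreflex)
    and HF (respiratory) modulation plus Gaussian jitter; with probability
    ``rr_spike_prob`` a beat is corrupted by a multiplicative spike whose
    index is recorded in the returned :class:`GroundTruth`.
    """
    if duration < 10:
        raise ValueError("duration must be at least 10 s")
    rng = np.random.default_rng() if rng is None else rng
    p = params if params is not None else cfg.classes[session_class]
    beat_times, rrs, art = [], [], []
    t = t0
    i = 0
    while True:
        rel = t - t0
        rr = (
            p.rr_mean
            + p.lf_amp * np.sin(2 * np.pi * cfg.lf_freq * rel)
            + p.hf_amp * np.sin(2 * np.pi * cfg.hf_freq * rel)
            + rng.normal(0.0, p.rr_jitter)
        )
        rr = max(rr, 0.25)
        spiked = rng.random() < cfg.rr_spike_prob
        if spiked:
            rr *= cfg.rr_spike_factor
        t += rr
        if t - t0 > duration:
            break
        beat_times.append(t)
        rrs.append(rr)
        if spiked:
            art.append(i)
        i += 1
    gt = GroundTruth(rr_artifact_indices=np.asarray(art, dtype=int))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # spikes may exceed the plausibility window
        series = IBISeries(np.asarray(beat_times), np.asarray(rrs))
    return series, gt


def simulate_eda(
    cfg: SimConfig,
    session_class: str,
    duration: float,
    rng: Optional[np.random.Generator] = None,
    t0: float = 0.0,
    artifact_windows: Sequence = (),
    params: Optional[ClassParams] = None,
    baseline: Optional[float] = None,
):
    """Simulate skin conductance at 4 Hz.

    tonic = baseline + linear drift; phasic = Poisson event train (class
    SCR rate) convolved with a biexponential kernel normalised so that a
    unit-amplitude event produces a unit-height response; plus Gaussian
    sensor noise.  ``artifact_windows`` (absolute times) receive a
    triangular contamination bump of ``eda_artifact_amp`` uS, mimicking
    pressure/motion artifacts.
    """
    rng = np.random.default_rng() if rng is None else rng
    p = params if params is not None else cfg.classes[session_class]
    base = cfg.tonic_baseline if baseline is None else baseline
    n = int(round(duration * cfg.eda_fs))
    t = np.arange(n) / cfg.eda_fs  # relative time
    tonic = base + cfg.tonic_drift * t
    n_ev = rng.poisson(p.scr_rate * duration / 100.0)
    onsets = np.sort(rng.uniform(0.0, duration, n_ev))
    amps = rng.lognormal(cfg.scr_amp_mu, cfg.scr_amp_sigma, n_ev)
    peak = _scr_kernel_peak_value(cfg.scr_rise, cfg.scr_decay)
    phasic = np.zeros(n)
    for on, a in zip(onsets, amps):
        dt = t - on
        m = dt >= 0
        phasic[m] += (a / peak) * (
            np.exp(-dt[m] / cfg.scr_decay) - np.exp(-dt[m] / cfg.scr_rise)
        )
    bump = np.zeros(n)
    for a0, a1 in artifact_windows:
        r0, r1 = a0 - t0, a1 - t0
        mid, half = 0.5 * (r0 + r1), 0.5 * (r1 - r0)
        m = (t >= r0) & (t < r1)
        bump[m] += cfg.eda_artifact_amp * (1.0 - np.abs(t[m] - mid) / half)
    noise = rng.normal(0.0, cfg.eda_noise, n) if cfg.eda_noise > 0 else 0.0
    values = np.maximum(tonic + phasic + bump + noise, 0.0)
    gt = GroundTruth(
        scr_onsets=t0 + onsets,
        scr_apexes=t0 + onsets + scr_kernel_peak_delay(cfg.scr_rise, cfg.scr_decay),
        scr_amplitudes=amps,
        eda_artifact_windows=[(float(a), float(b)) for a, b in artifact_windows],
    )
    return UniformSeries("eda", t0, cfg.eda_fs, values), gt


def simulate_acc_temp(
    cfg: SimConfig,
    duration: float,
    rng: Optional[np.random.Generator] = None,
    t0: float = 0.0,
):
    """Simulate 3-axis acceleration (32 Hz) and wrist temperature (4 Hz).

    Baseline is the gravity vector plus sensor noise; movement bursts are
    high-amplitude oscillations lasting ``burst_duration`` s, snapped to
    the ``epoch_align`` grid so each burst occupies whole detector epochs.
    Every burst window is also recorded as an EDA-artifact window — the
    coupling the artifact detector is premised on.
    """
    rng = np.random.default_rng() if rng is None else rng
    n_burst = rng.poisson(cfg.burst_rate * duration / 100.0)
    slots = np.arange(0.0, duration - cfg.burst_duration + 1e-9, cfg.epoch_align)
    n_burst = min(n_burst, slots.size)
    starts = np.sort(rng.choice(slots, size=n_burst, replace=False)) if n_burst else np.empty(0)
    windows = [(t0 + s, t0 + s + cfg.burst_duration) for s in starts]

    na = int(round(duration * cfg.acc_fs))
    ta = np.arange(na) / cfg.acc_fs
    axes = []
    gx, gy, gz = cfg.gravity
    for gval in (gx, gy, gz):
        axes.append(gval + rng.normal(0.0, cfg.acc_noise, na))
    for (w0, w1) in windows:
        m = (ta >= w0 - t0) & (ta < w1 - t0)
        for vals in axes:
            phase = rng.uniform(0, 2 * np.pi)
            vals[m] += cfg.burst_amp * np.sin(2 * np.pi * cfg.burst_freq * ta[m] + phase)
    acc = tuple(
        UniformSeries(f"acc_{ax}", t0, cfg.acc_fs, vals)
        for ax, vals in zip("xyz", axes)
    )
    nt = int(round(duration * cfg.temp_fs))
    tt = np.arange(nt) / cfg.temp_fs
    temp_vals = cfg.temp_baseline + cfg.temp_drift * tt + rng.normal(0.0, cfg.temp_noise, nt)
    temp = UniformSeries("temp", t0, cfg.temp_fs, temp_vals)
    gt = GroundTruth(
        acc_burst_windows=[(float(a), float(b)) for a, b in windows],
        eda_artifact_windows=[(float(a), float(b)) for a, b in windows],
    )
    return acc, temp, gt


def scr_train(
    cfg: SimConfig,
    onsets: Sequence[float],
    amplitudes: Sequence[float],
    duration: float,
    t0: float = 0.0,
    noise: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
):
    """Deterministic skin-conductance trace with SCRs at given onsets and
    amplitudes (uS) on a flat tonic baseline — a known-answer input for the
    decomposition stage."""
    onsets = np.asarray(onsets, dtype=float)
    amps = np.asarray(amplitudes, dtype=float)
    n = int(round(duration * cfg.eda_fs))
    t = np.arange(n) / cfg.eda_fs
    peak = _scr_kernel_peak_value(cfg.scr_rise, cfg.scr_decay)
    phasic = np.zeros(n)
    for on, a in zip(onsets, amps):
        dt = t - on
        m = dt >= 0
        phasic[m] += (a / peak) * (
            np.exp(-dt[m] / cfg.scr_decay) - np.exp(-dt[m] / cfg.scr_rise)
        )
    sd = cfg.eda_noise if noise is None else noise
    eps = 0.0
    if sd > 0:
        rng = np.random.default_rng() if rng is None else rng
        eps = rng.normal(0.0, sd, n)
    values = cfg.tonic_baseline + phasic + eps
    gt = GroundTruth(
        scr_onsets=t0 + onsets,
        scr_apexes=t0 + onsets + scr_kernel_peak_delay(cfg.scr_rise, cfg.scr_decay),
        scr_amplitudes=amps,
    )
    return UniformSeries("eda", t0, cfg.eda_fs, values), gt


@dataclass
class SessionChannels:
    """In-memory channel bundle for one session (None where the device lacks it)."""

    ibi: Optional[IBISeries] = None
    eda: Optional[UniformSeries] = None
    temp: Optional[UniformSeries] = None
    acc: Optional[tuple] = None


def simulate_session(
    cfg: SimConfig,
    session_class: str,
    duration: float,
    rng: np.random.Generator,
    t0: float = 0.0,
    params: Optional[ClassParams] = None,
    eda_baseline: Optional[float] = None,
    with_eda: bool = True,
):
    """Simulate every channel of one session; EDA artifacts coincide with
    movement bursts."""
    acc, temp, gt_m = simulate_acc_temp(cfg, duration, rng, t0)
    eda = None
    gt = GroundTruth(
        acc_burst_windows=gt_m.acc_burst_windows,
        eda_artifact_windows=gt_m.eda_artifact_windows,
    )
    if with_eda:
        eda, gt_e = simulate_eda(
            cfg, session_class, duration, rng, t0,
            artifact_windows=gt_m.eda_artifact_windows,
            params=params, baseline=eda_baseline,
        )
        gt.scr_onsets = gt_e.scr_onsets
        gt.scr_apexes = gt_e.scr_apexes
        gt.scr_amplitudes = gt_e.scr_amplitudes
    rr, gt_r = simulate_rr(cfg, session_class, duration, rng, t0, params=params)
    gt.rr_artifact_indices = gt_r.rr_artifact_indices
    channels = SessionChannels(ibi=rr, eda=eda, temp=temp if with_eda else None, acc=acc)
    return channels, gt


# ---------------------------------------------------------------------------
# Whole-study simulation
# ---------------------------------------------------------------------------

CONTEXT_LABELS = {"free": 0, "lecture": 1, "contest": 2}


@dataclass
class Study:
    """A simulated multi-subject study held in memory."""

    config: SimConfig
    sessions: list
    channels: dict     # session key -> SessionChannels
    ground_truth: dict  # session key -> GroundTruth

    @staticmethod
    def session_key(record: SessionRecord) -> str:
        return f"{record.subject_id}_{record.session_type}_{int(record.t_start)}"


def _subject_params(cfg: SimConfig, rng: np.random.Generator):
    """Per-subject random effects: log-scale Gaussian on baselines so every
    scaled quantity stays positive."""
    f_rr = np.exp(rng.normal(0.0, cfg.subject_sd_rr))
    f_hrv = np.exp(rng.normal(0.0, cfg.subject_sd_hrv))
    f_eda = np.exp(rng.normal(0.0, cfg.subject_sd_eda))
    params = {
        name: replace(
            p,
            rr_mean=p.rr_mean * f_rr,
            lf_amp=p.lf_amp * f_hrv,
            hf_amp=p.hf_amp * f_hrv,
            rr_jitter=p.rr_jitter * f_hrv,
        )
        for name, p in cfg.classes.items()
    }
    return params, cfg.tonic_baseline * f_eda


def _frustration(cfg: SimConfig, p: ClassParams, rng: np.random.Generator) -> int:
    raw = rng.normal(p.frustration_mean, cfg.frustration_sd)
    return int(np.clip(5 * round(raw / 5.0), 0, 100))


def simulate_study(
    cfg: SimConfig,
    n_subjects: int = 21,
    sessions_per_subject: int = 3,
    out_dir=None,
) -> Study:
    """Simulate a full study: per-subject random effects, one session of each
    type per cycle of three, alternating device families (even-index subjects
    wear the EDA-capable reference device, odd-index subjects a watch that
    exports only inter-beat intervals and acceleration).

    When ``out_dir`` is given, all sessions are also written to disk in
    their device dialects together with ``sessions.csv`` and
    ``groundtruth.json``; identical seeds give byte-identical files.
    """
    rng = np.random.default_rng(cfg.seed)
    sessions, channels, gts = [], {}, {}
    for si in range(n_subjects):
        subject_id = f"S{si:02d}"
        params, eda_base = _subject_params(cfg, rng)
        if si % 2 == 0:
            family, device_id = "e4", f"E4-{si:02d}"
        else:
            family = "gear_s" if si % 4 == 1 else "gear_s2"
            device_id = f"GW-{si:02d}"
        for sj in range(sessions_per_subject):
            stype = CLASS_NAMES[sj % 3]
            t0 = si * 10_000_000.0 + sj * 100_000.0  # non-overlapping absolute axes
            ch, gt = simulate_session(
                cfg, stype, cfg.session_length, rng, t0,
                params=params[stype], eda_baseline=eda_base,
                with_eda=(family == "e4"),
            )
            rec = SessionRecord(
                subject_id=subject_id,
                device_id=device_id,
                device_family=family,
                session_type=stype,
                t_start=t0,
                t_end=t0 + cfg.session_length,
                frustration=_frustration(cfg, params[stype], rng),
            )
            gt.label = CONTEXT_LABELS[stype]
            key = Study.session_key(rec)
            sessions.append(rec)
            channels[key] = ch
            gts[key] = gt
    study = Study(config=cfg, sessions=sessions, channels=channels, ground_truth=gts)
    if out_dir is not None:
        _write_study(study, Path(out_dir))
    return study


def _write_study(study: Study, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_sessions(out_dir / "sessions.csv", study.sessions)
    gt_json = {k: v.to_jsonable() for k, v in sorted(study.ground_truth.items())}
    with open(out_dir / "groundtruth.json", "w") as fh:
        json.dump(gt_json, fh, indent=1, sort_keys=True)
    for rec in study.sessions:
        key = Study.session_key(rec)
        ch = study.channels[key]
        d = out_dir / key
        d.mkdir(exist_ok=True)
        write_e4_channel(d / "ACC.csv", ch.acc)
        if rec.device_family == "e4":
            write_e4_channel(d / "EDA.csv", ch.eda)
            write_e4_channel(d / "TEMP.csv", ch.temp)
            write_e4_ibi(d / "IBI.csv", ch.ibi)
        else:
            write_generic_ibi(d / "IBI_generic.csv", ch.ibi)
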