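"""Windowed feature aggregation, modality fusion and label assignment.

Features are extracted per aggregation window (windows tile each session
contiguously from its start; the last partial window is dropped) and
averaged over a session to form one instance per session, or kept per
window when window-level instances are requested.  Modalities can be
combined freely (HR, EDA, ACC); devices without an EDA sensor simply
contribute no EDA block.  Labels come either from the session context
(free day 0, lecture 1, contest 2) or from the 0-100 frustration report
binned into three perceived-stress levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .acc import ACC_KEYS, acc_window_features
from .eda import (
    EDA_KEYS,
    EdaArtifactConfig,
    decompose_eda,
    detect_eda_artifacts,
    eda_features,
)
from .hr import (
    HRV_ALL_KEYS,
    RRCleanConfig,
    clean_rr,
    detect_rr_artifacts,
    hrv_features_clean,
)
from .io_formats import SessionRecord
from .synthetic import SessionChannels, Study

log = logging.getLogger(__name__)

__all__ = [
    "AggregationConfig",
    "LabeledDataset",
    "assign_context_label",
    "bin_frustration",
    "extract_session_features",
    "extract_study_features",
    "assemble_dataset",
    "MODALITY_COLUMNS",
]

MODALITY_COLUMNS = {
    "HR": tuple(f"hr_{k}" for k in HRV_ALL_KEYS),
    "EDA": tuple(f"eda_{k}" for k in EDA_KEYS),
    "ACC": tuple(f"acc_{k}" for k in ACC_KEYS),
}

CONTEXT_MAP = {"free": 0, "lecture": 1, "contest": 2}


@dataclass(frozen=True)
class AggregationConfig:
    """window_len: aggregation window in seconds (the sweep grid is 120,
    300, 600, 1200); instance_unit: one instance per session (window
    features averaged) or per window; modality_set: subset of HR/EDA/ACC."""

    window_len: float = 120.0
    instance_unit: str = "session"
    modality_set: tuple = ("HR", "EDA", "ACC")

    def __post_init__(self) -> None:
        if self.window_len <= 0:
            raise ValueError("window_len must be positive")
        if self.instance_unit not in ("session", "window"):
            raise ValueError("instance_unit must be 'session' or 'window'")
        bad = set(self.modality_set) - set(MODALITY_COLUMNS)
        if bad:
            raise ValueError(f"unknown modalities {sorted(bad)}")


def assign_context_label(session_type: str) -> int:
    """Context ground truth: free day 0, lecture 1, contest 2."""
    return CONTEXT_MAP[session_type]


def bin_frustration(score: int) -> int:
    """Perceived-stress level from the 0-100 frustration report:
    0-30 -> 1, 35-75 -> 2, >= 80 -> 3.

    Scores 31-34 and 76-79 are unreachable with five-point increments but
    are still binned (<= 30 -> 1, < 80 -> 2) for robustness, with a log
    entry."""
    if not 0 <= score <= 100:
        raise ValueError(f"frustration score {score} outside 0-100")
    if score % 5 != 0:
        log.warning("nonstandard frustration score %s (not a multiple of 5)", score)
    if score <= 30:
        return 1
    if score < 80:
        return 2
    return 3


def _session_windows(rec: SessionRecord, window_len: float):
    n = int(np.floor(rec.duration / window_len + 1e-9))
    return [
        (rec.t_start + i * window_len, rec.t_start + (i + 1) * window_len)
        for i in range(n)
    ]


def _window_features(
    rec: SessionRecord,
    ch: SessionChannels,
    window,
    cfg: AggregationConfig,
    rr_cfg: RRCleanConfig,
    decomp,
    eda_mask,
) -> dict:
    feats: dict = {}
    if "HR" in cfg.modality_set and ch.ibi is not None:
        rr = ch.ibi.slice(*window)
        mask = detect_rr_artifacts(rr, rr_cfg)
        clean = clean_rr(rr, mask, rr_cfg)
        feats.update({f"hr_{k}": v for k, v in hrv_features_clean(clean).items()})
    if "EDA" in cfg.modality_set and decomp is not None:
        feats.update(
            {f"eda_{k}": v for k, v in eda_features(decomp, eda_mask, window).items()}
        )
    if "ACC" in cfg.modality_set and ch.acc is not None:
        feats.update({f"acc_{k}": v for k, v in acc_window_features(ch.acc, window).items()})
    return feats


def extract_session_features(
    rec: SessionRecord,
    ch: SessionChannels,
    cfg: AggregationConfig = AggregationConfig(),
    rr_cfg: RRCleanConfig = RRCleanConfig(),
    eda_cfg: EdaArtifactConfig = EdaArtifactConfig(),
) -> list[dict]:
    """Extract features for one session.

    Returns one dict per instance: a single window-averaged dict when
    ``instance_unit`` is 'session', otherwise one per window.  The EDA
    channel is decomposed once per session and its artifact epochs scored
    once; both are then windowed.  A modality with no usable window is a
    missing (NaN) block.
    """
    windows = _session_windows(rec, cfg.window_len)
    decomp = eda_mask = None
    if "EDA" in cfg.modality_set and ch.eda is not None and ch.acc is not None:
        decomp = decompose_eda(ch.eda)
        eda_mask = detect_eda_artifacts(ch.eda, ch.acc, ch.temp, eda_cfg)
    rows = [
        _window_features(rec, ch, w, cfg, rr_cfg, decomp, eda_mask) for w in windows
    ]
    if cfg.instance_unit == "window":
        return rows
    if not rows:
        return []
    keys = sorted({k for r in rows for k in r})
    merged = {}
    for k in keys:
        vals = np.array([r.get(k, np.nan) for r in rows], dtype=float)
        ok = np.isfinite(vals)
        merged[k] = float(np.mean(vals[ok])) if ok.any() else float("nan")
        if not ok.any():
            log.info("session %s: feature %s missing in every window", rec.subject_id, k)
    return [merged]


def extract_study_features(
    study: Study,
    cfg: AggregationConfig = AggregationConfig(),
    rr_cfg: RRCleanConfig = RRCleanConfig(),
    eda_cfg: EdaArtifactConfig = EdaArtifactConfig(),
) -> pd.DataFrame:
    """Feature table for a whole study: one row per instance with identifier
    columns (subject_id, device_family, session_key, session_type,
    frustration, window index) followed by feature columns."""
    rows = []
    for rec in study.sessions:
        key = Study.session_key(rec)
        feats = extract_session_features(rec, study.channels[key], cfg, rr_cfg, eda_cfg)
        for wi, f in enumerate(feats):
            row = {
                "subject_id": rec.subject_id,
                "device_family": rec.device_family,
                "session_key": key,
                "session_type": rec.session_type,
                "frustration": rec.frustration,
                "window_index": wi,
            }
            row.update(f)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class LabeledDataset:
    """Feature matrix + labels + grouping identifiers, ready for evaluation."""

    X: pd.DataFrame
    y: np.ndarray
    subject_ids: np.ndarray
    device_family: np.ndarray
    session_ids: np.ndarray
    label_source: str

    def __len__(self) -> int:
        return len(self.y)

    @property
    def n_classes(self) -> int:
        return np.unique(self.y).size

    def subset(self, idx) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(
            self.X.iloc[idx].reset_index(drop=True),
            self.y[idx],
            self.subject_ids[idx],
            self.device_family[idx],
            self.session_ids[idx],
            self.label_source,
        )


def assemble_dataset(
    features: pd.DataFrame,
    label_source: str = "context",
    modality_set: Sequence[str] = ("HR", "EDA", "ACC"),
    device_filter: str = "all",
) -> LabeledDataset:
    """Select modality columns, apply the device filter (e4 | samsung | all)
    and attach labels.

    Rows whose selected feature block is entirely missing (e.g. EDA
    requested on a device without an EDA sensor) are excluded with a
    logged count, as are rows with a missing label or residual missing
    values."""
    df = features
    if device_filter == "e4":
        df = df[df["device_family"] == "e4"]
    elif device_filter == "samsung":
        df = df[df["device_family"].isin(("gear_s", "gear_s2"))]
    elif device_filter != "all":
        raise ValueError("device_filter must be 'e4', 'samsung' or 'all'")
    cols = [c for m in modality_set for c in MODALITY_COLUMNS[m] if c in df.columns]
    missing_block = [
        m for m in modality_set
        if not any(c in df.columns for c in MODALITY_COLUMNS[m])
    ]
    if missing_block:
        raise ValueError(f"no columns at all for modalities {missing_block}")
    n0 = len(df)
    df = df.dropna(subset=cols, how="any")
    if len(df) < n0:
        log.info("dropped %d instances with missing feature values", n0 - len(df))
    if label_source == "context":
        y = df["session_type"].map(CONTEXT_MAP).to_numpy()
    elif label_source == "perceived":
        has = df["frustration"].notna()
        if (~has).any():
            log.info("dropped %d instances without frustration reports", int((~has).sum()))
        df = df[has]
        y = df["frustration"].astype(int).map(bin_frustration).to_numpy()
    else:
        raise ValueError("label_source must be 'context' or 'perceived'")
    X = df[cols].reset_index(drop=True)
    empty_cols = [c for c in X.columns if X[c].isna().all()]
    if empty_cols:
        raise ValueError(f"all-missing feature columns {empty_cols}")
    return LabeledDataset(
        X=X,
        y=y,
        subject_ids=df["subject_id"].to_numpy(),
        device_family=df["device_family"].to_numpy(),
        session_ids=df["session_key"].to_numpy(),
        label_source=label_source,
    )
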