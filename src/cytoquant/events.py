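"""Detection of sudden cytosolic siRNA release events in single-cell traces.

A frame is called when the median-filtered signal and the following
``persistence`` frames all exceed both a noise-adaptive threshold (trailing
mean plus a multiple of the trailing standard deviation) and a fixed-offset
threshold above the trailing mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DetectionConfig",
    "EventCall",
    "DetectionPerformance",
    "median_filter",
    "detect_events",
    "detect_events_table",
    "evaluate_detection",
]


@dataclass
class DetectionConfig:
    median_window: int = 5
    mean_lookback: int = 3
    sd_lookback: int = 10
    sd_multiplier: float = 3.0
    fixed_offset: float = 0.15
    persistence: int = 5

    def __post_init__(self) -> None:
        for name in ("median_window", "mean_lookback", "sd_lookback", "persistence"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be positive")
        if self.fixed_offset < 0:
            raise ValueError("fixed_offset must be non-negative")


@dataclass
class EventCall:
    track_id: int
    frame: int
    qc_status: str = "auto"  # auto | confirmed | rejected


@dataclass
class DetectionPerformance:
    tp: int
    fp: int
    tn: int
    fn: int
    match_window: int = 5

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return float("nan") if denom == 0 else self.tp / denom

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return float("nan") if denom == 0 else self.tn / denom


def median_filter(trace, window: int = 5) -> np.ndarray:
    """Centered moving median; edge windows shrink to the available frames."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    y = np.asarray(trace, dtype=float)
    if y.size == 0:
        return y.copy()
    if window == 1:
        return y.copy()
    half = window // 2
    out = np.empty_like(y)
    for i in range(y.size):
        out[i] = np.median(y[max(0, i - half): i + half + 1])
    return out


def detect_events(trace, config: DetectionConfig | None = None, track_id: int = 0) -> list[EventCall]:
    """Scan one trace for persistent upward signal shifts.

    The raw trace is median filtered first.  Frame ``t`` is called when the
    filtered values at ``t .. t+persistence`` all strictly exceed
    ``max(mu + sd_multiplier*sd, mu + fixed_offset)`` where ``mu`` is the mean
    of the ``mean_lookback`` preceding frames and ``sd`` the standard
    deviation of the ``sd_lookback`` preceding frames.  After a call the scan
    resumes after the persistence window, so multiple events per trace are
    supported.
    """
    cfg = config or DetectionConfig()
    y = np.asarray(trace, dtype=float)
    min_len = cfg.sd_lookback + cfg.persistence + 1
    if y.size < min_len:
        warnings.warn(
            f"trace too short for detection ({y.size} < {min_len} frames); no calls",
            stacklevel=2,
        )
        return []

    f = median_filter(y, cfg.median_window)
    calls: list[EventCall] = []
    t = max(cfg.sd_lookback, cfg.mean_lookback)
    last = y.size - cfg.persistence - 1
    while t <= last:
        mu = f[t - cfg.mean_lookback: t].mean()
        sd = f[t - cfg.sd_lookback: t].std(ddof=1)
        threshold = mu + max(cfg.sd_multiplier * sd, cfg.fixed_offset)
        if np.all(f[t: t + cfg.persistence + 1] > threshold):
            calls.append(EventCall(track_id=track_id, frame=t))
            t += cfg.persistence + 1
        else:
            t += 1
    return calls


def detect_events_table(
    traces: pd.DataFrame,
    config: DetectionConfig | None = None,
    value_column: str = "median_siRNA_cellmask",
) -> pd.DataFrame:
    """Run :func:`detect_events` per track of a long-format trace table.

    Returns a frame with columns ``track_id, frame, qc_status``.
    """
    rows = []
    for track_id, grp in traces.sort_values("frame").groupby("track_id"):
        y = grp[value_column].to_numpy(dtype=float)
        y = np.nan_to_num(y, nan=0.0)
        for call in detect_events(y, config, track_id=track_id):
            rows.append((track_id, int(grp["frame"].iloc[call.frame]), call.qc_status))
    return pd.DataFrame(rows, columns=["track_id", "frame", "qc_status"])


def apply_qc(calls: pd.DataFrame, qc: pd.DataFrame) -> pd.DataFrame:
    """Merge manual-QC flags (track_id, frame, qc_status) onto calls."""
    merged = calls.merge(
        qc[["track_id", "frame", "qc_status"]],
        on=["track_id", "frame"],
        how="left",
        suffixes=("", "_qc"),
    )
    merged["qc_status"] = merged.pop("qc_status_qc").fillna(merged["qc_status"])
    return merged


def evaluate_detection(
    calls,
    truth_events,
    n_cells_without_truth=None,
    match_window: int = 5,
) -> DetectionPerformance:
    """Score calls against ground-truth event times, one decision per cell.

    Each cell is evaluated up to its first call/truth event.  A cell with a
    truth event counts TP if any non-rejected call lies within
    ``match_window`` frames of the (first) truth frame, else FN.  A cell with
    calls but no truth is FP unless every call was QC-rejected, in which case
    it is reclassified TN.  Cells with neither calls nor truth count TN;
    their number can be supplied via ``n_cells_without_truth`` when they do
    not appear in either table.

    Parameters
    ----------
    calls:
        DataFrame with columns ``track_id, frame`` and optional ``qc_status``.
    truth_events:
        DataFrame with columns ``track_id, frame`` (first event per cell is
        used).
    """
    calls = pd.DataFrame(calls, columns=["track_id", "frame", "qc_status"]) if not isinstance(calls, pd.DataFrame) else calls.copy()
    truth = pd.DataFrame(truth_events, columns=["track_id", "frame"]) if not isinstance(truth_events, pd.DataFrame) else truth_events.copy()
    if "qc_status" not in calls.columns:
        calls["qc_status"] = "auto"

    first_truth = truth.sort_values("frame").groupby("track_id")["frame"].first()
    cells = set(calls["track_id"]).union(first_truth.index)

    tp = fp = tn = fn = 0
    for cell in cells:
        cell_calls = calls[calls["track_id"] == cell].sort_values("frame")
        accepted = cell_calls[cell_calls["qc_status"] != "rejected"]
        if cell in first_truth.index:
            t_true = first_truth.loc[cell]
            if (abs(accepted["frame"] - t_true) <= match_window).any():
                tp += 1
            else:
                fn += 1
        else:
            if len(accepted):
                fp += 1
            elif len(cell_calls):
                tn += 1  # all calls rejected by QC -> reclassified
    if n_cells_without_truth is not None:
        counted = len([c for c in cells if c not in first_truth.index])
        tn += max(0, int(n_cells_without_truth) - counted)
    return DetectionPerformance(tp=tp, fp=fp, tn=tn, fn=fn, match_window=match_window)
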