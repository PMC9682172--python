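"""Filtering, cue segmentation, onset detection and sliding-window extraction.

The pipeline mirrors standard offline sEMG conditioning: a 10-500 Hz 4th-order
Butterworth band-pass plus a 50 Hz 2nd-order Butterworth notch (both applied
zero-phase with ``sosfiltfilt``, which doubles the effective order), cue-based
trial segmentation with the preceding rest interval kept as baseline, a
threshold-based onset detector on the cross-channel rectified envelope,
100 ms transient trimming at both ends, and 512-sample windows with 128-sample
stride (250 ms / 62.5 ms at 2048 Hz, i.e. 384 samples overlap).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core_data import (Recording, ScheduleEntry, SplitSpec, WindowSet,
                        concat_window_sets)

log = logging.getLogger(__name__)


class NoActivityError(RuntimeError):
    """The trial envelope never exceeded the baseline-derived threshold."""


class TrialTooShortError(ValueError):
    pass


@dataclass(frozen=True)
class FilterConfig:
    bp_low: float = 10.0          # Hz
    bp_high: float = 500.0        # Hz
    bp_order: int = 4
    notch_freq: float = 50.0      # Hz
    notch_order: int = 2
    notch_halfwidth: float = 2.0  # Hz each side of notch_freq

    def validate(self, fs: float) -> None:
        nyq = fs / 2
        if not (0 < self.bp_low < self.bp_high < nyq):
            raise ValueError(
                f"band edges ({self.bp_low}, {self.bp_high}) must satisfy "
                f"0 < low < high < Nyquist ({nyq})")
        if not (self.bp_low < self.notch_freq < self.bp_high):
            raise ValueError("notch frequency must lie inside the pass band")


@dataclass(frozen=True)
class OnsetConfig:
    smooth_ms: float = 100.0   # moving-average width on the rectified signal
    k_sigma: float = 3.0       # threshold = baseline mean + k_sigma * baseline SD
    min_hold_ms: float = 50.0  # sustained exceedance required

    def __post_init__(self):
        if min(self.smooth_ms, self.k_sigma, self.min_hold_ms) <= 0:
            raise ValueError("onset parameters must be positive")


@dataclass(frozen=True)
class WindowingConfig:
    window_len: int = 512
    stride: int = 128
    trim_ms: float = 100.0

    def __post_init__(self):
        if not (0 < self.stride <= self.window_len):
            raise ValueError("require 0 < stride <= window_len")


@dataclass
class Trial:
    """A movement-phase signal slice with its preceding-rest baseline."""

    signal: np.ndarray          # (n_channels, n_samples)
    baseline: np.ndarray | None
    label: str
    repetition: int | None
    orientation: str | None
    fs: float


def apply_filters(rec: Recording, cfg: FilterConfig = FilterConfig(),
                  bandpass: bool = True, notch: bool = True) -> Recording:
    """Zero-phase band-pass + band-stop filtering; same shape out."""
    cfg.validate(rec.fs)
    x = rec.signal
    if bandpass:
        sos = sps.butter(cfg.bp_order, [cfg.bp_low, cfg.bp_high],
                         btype="bandpass", fs=rec.fs, output="sos")
        x = sps.sosfiltfilt(sos, x, axis=1)
    if notch:
        sos = sps.butter(cfg.notch_order,
                         [cfg.notch_freq - cfg.notch_halfwidth,
                          cfg.notch_freq + cfg.notch_halfwidth],
                         btype="bandstop", fs=rec.fs, output="sos")
        x = sps.sosfiltfilt(sos, x, axis=1)
    return Recording(signal=x, fs=rec.fs, schedule=list(rec.schedule),
                     subject_id=rec.subject_id, orientation=rec.orientation,
                     meta=dict(rec.meta))


def segment_by_cues(rec: Recording) -> list[Trial]:
    """One Trial per movement interval, keeping the preceding rest interval
    as its baseline reference (global pooled rest as fallback)."""
    rest_pool = [rec.signal[:, e.start:e.end] for e in rec.schedule if e.phase == "rest"]
    global_baseline = np.concatenate(rest_pool, axis=1) if rest_pool else None
    trials: list[Trial] = []
    last_rest: np.ndarray | None = None
    for e in rec.schedule:
        if e.phase == "rest":
            last_rest = rec.signal[:, e.start:e.end]
        elif e.phase == "movement":
            baseline = last_rest
            if baseline is None:
                log.warning("movement %r at sample %d has no preceding rest; "
                            "falling back to pooled rest baseline", e.label, e.start)
                baseline = global_baseline
            trials.append(Trial(signal=rec.signal[:, e.start:e.end],
                                baseline=baseline, label=e.label,
                                repetition=e.repetition,
                                orientation=e.orientation or rec.orientation,
                                fs=rec.fs))
            last_rest = None
    return trials


def _envelope(x: np.ndarray, fs: float, smooth_ms: float) -> np.ndarray:
    """Cross-channel mean of moving-average-smoothed rectified signal."""
    from scipy.ndimage import uniform_filter1d
    w = max(1, int(round(smooth_ms * fs / 1000)))
    sm = uniform_filter1d(np.abs(x), size=w, axis=1, mode="nearest")
    return sm.mean(axis=0)


def detect_active_interval(trial: Trial, cfg: OnsetConfig = OnsetConfig()
                           ) -> tuple[int, int]:
    """Threshold-based onset/offset detection against the rest baseline.

    Returns a half-open (onset, offset) interval covering the first through
    the last sustained threshold exceedance of the envelope.
    """
    if trial.baseline is None or trial.baseline.shape[1] == 0:
        raise ValueError("trial has no baseline reference")
    fs = trial.fs
    e = _envelope(trial.signal, fs, cfg.smooth_ms)
    eb = _envelope(trial.baseline, fs, cfg.smooth_ms)
    thresh = eb.mean() + cfg.k_sigma * eb.std()
    above = e > thresh
    hold = max(1, int(round(cfg.min_hold_ms * fs / 1000)))
    # sustained runs of >= hold samples
    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    keep = (ends - starts) >= hold
    if not keep.any():
        raise NoActivityError(
            f"envelope never exceeded threshold {thresh:.3g} for "
            f">= {cfg.min_hold_ms} ms in trial {trial.label!r}")
    onset = int(starts[keep][0])
    offset = int(ends[keep][-1])
    return onset, offset


def trim_transient(interval: tuple[int, int], fs: float,
                   trim_ms: float = 100.0) -> tuple[int, int]:
    """Remove floor(trim_ms*fs/1000) samples from each end of the interval."""
    on, off = interval
    trim = math.floor(trim_ms * fs / 1000)
    if off - on <= 2 * trim:
        raise TrialTooShortError(
            f"interval of {off - on} samples is too short for 2 x {trim} trim")
    return on + trim, off - trim


def slide_windows(trial: Trial, cfg: WindowingConfig = WindowingConfig(),
                  interval: tuple[int, int] | None = None,
                  subject_id: str = "S0") -> WindowSet:
    """Extract overlapping windows from (a sub-interval of) a trial.

    n_windows = floor((L - window_len)/stride) + 1 for L >= window_len,
    otherwise zero windows with a warning.
    """
    x = trial.signal if interval is None else trial.signal[:, interval[0]:interval[1]]
    n_ch, L = x.shape
    W, S = cfg.window_len, cfg.stride
    if L < W:
        log.warning("trial %r of %d samples is shorter than window %d; no windows",
                    trial.label, L, W)
        return WindowSet.empty(n_ch, W, S)
    n = (L - W) // S + 1
    idx = np.arange(n)[:, None] * S + np.arange(W)[None, :]
    windows = x[:, idx].transpose(1, 0, 2)          # (n, n_ch, W)
    rep = trial.repetition if trial.repetition is not None else -1
    return WindowSet(windows,
                     np.full(n, trial.label, dtype=object),
                     np.full(n, rep, dtype=np.int64),
                     np.full(n, trial.orientation, dtype=object),
                     np.full(n, subject_id, dtype=object),
                     W, S)


def windows_from_recording(rec: Recording,
                           filter_cfg: FilterConfig | None = FilterConfig(),
                           onset_cfg: OnsetConfig | None = OnsetConfig(),
                           window_cfg: WindowingConfig = WindowingConfig(),
                           ) -> WindowSet:
    """Full conditioning pipeline: filter -> segment -> onset -> trim -> window.

    ``filter_cfg=None`` skips filtering (pre-conditioned data styles);
    ``onset_cfg=None`` skips onset detection and trims the cue interval
    directly.  Trials with no detected activity are dropped with a log entry.
    """
    if filter_cfg is not None:
        rec = apply_filters(rec, filter_cfg)
    out: list[WindowSet] = []
    for trial in segment_by_cues(rec):
        try:
            if onset_cfg is not None:
                interval = detect_active_interval(trial, onset_cfg)
            else:
                interval = (0, trial.signal.shape[1])
            interval = trim_transient(interval, rec.fs, window_cfg.trim_ms)
        except (NoActivityError, TrialTooShortError) as exc:
            log.warning("dropping trial %r rep %s: %s", trial.label,
                        trial.repetition, exc)
            continue
        out.append(slide_windows(trial, window_cfg, interval,
                                 subject_id=rec.subject_id))
    if not out:
        return WindowSet.empty(rec.n_channels, window_cfg.window_len,
                               window_cfg.stride)
    return concat_window_sets(out)


def split_by_repetitions(ws: WindowSet, spec: SplitSpec
                         ) -> tuple[WindowSet, WindowSet]:
    """Partition windows into train/test by whole repetitions.

    nearlab_3of5: per (class, orientation), the first 3 of 5 repetitions in
    acquisition order go to train, the remaining 2 to test.
    ninapro_1346: repetitions {1,3,4,6} train, {2,5} test.
    custom: explicit (disjoint) repetition id sets.
    """
    n = ws.n_windows
    train_mask = np.zeros(n, dtype=bool)
    test_mask = np.zeros(n, dtype=bool)
    if spec.policy == "ninapro_1346":
        train_mask = np.isin(ws.repetition_ids, [1, 3, 4, 6])
        test_mask = np.isin(ws.repetition_ids, [2, 5])
    elif spec.policy == "custom":
        train_mask = np.isin(ws.repetition_ids, sorted(spec.train_repetitions))
        test_mask = np.isin(ws.repetition_ids, sorted(spec.test_repetitions))
    else:  # nearlab_3of5
        keys = list(zip(ws.labels, ws.orientations))
        for key in set(keys):
            sel = np.array([k == key for k in keys])
            reps = np.unique(ws.repetition_ids[sel])
            train_reps = set(reps[:3].tolist())
            train_mask |= sel & np.isin(ws.repetition_ids, sorted(train_reps))
            test_mask |= sel & ~np.isin(ws.repetition_ids, sorted(train_reps))
    if (train_mask & test_mask).any():
        raise ValueError("a repetition landed in both train and test")
    return ws.subset(train_mask), ws.subset(test_mask)
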