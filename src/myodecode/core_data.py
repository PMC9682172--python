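"""Domain types and file I/O for multichannel surface-EMG recordings.

A :class:`Recording` is a continuous (channels x samples) signal in microvolts
with a cue schedule; a :class:`WindowSet` is the stack of fixed-length labeled
windows every classifier consumes.  The label taxonomy distinguishes 8 basic
hand/wrist movements from 6 combined movements, each combined movement being
exactly one wrist rotation (pronation or supination) plus one hand function
(pinch, lateral pinch or grip).

Sample indices are 0-based and intervals half-open ``[start, end)``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

PHASES = ("rest", "preparation", "movement")
ORIENTATIONS = ("upward", "sideway", "downward")

ROTATIONS = ("pronation", "supination")
FUNCTIONS = ("pinch", "lateral_pinch", "grip")

COMBINED_SEPARATOR = "+"


class TaxonomyError(ValueError):
    pass


class FormatError(ValueError):
    pass


class IntegrityError(ValueError):
    pass


@dataclass(frozen=True)
class LabelTaxonomy:
    """8 basic movement classes and the 6 rotation+function compositions.

    Only 5 of the basic classes play a structural role (the two rotations and
    three hand functions); the remaining three are free tokens.  All transfer
    algorithms depend solely on the rotation/function index sets.
    """

    basic_classes: tuple[str, ...]
    combined_classes: tuple[str, ...]

    def __post_init__(self):
        if len(self.basic_classes) != 8:
            raise TaxonomyError(f"expected 8 basic classes, got {len(self.basic_classes)}")
        if len(self.combined_classes) != 6:
            raise TaxonomyError(f"expected 6 combined classes, got {len(self.combined_classes)}")
        for r in ROTATIONS:
            if r not in self.basic_classes:
                raise TaxonomyError(f"basic classes must include rotation {r!r}")
        for f in FUNCTIONS:
            if f not in self.basic_classes:
                raise TaxonomyError(f"basic classes must include function {f!r}")
        seen = set()
        for c in self.combined_classes:
            pair = self._parse(c)
            if pair in seen:
                raise TaxonomyError(f"duplicate decomposition for {c!r}")
            seen.add(pair)

    def _parse(self, label: str) -> tuple[str, str]:
        parts = label.split(COMBINED_SEPARATOR)
        if len(parts) != 2 or parts[0] not in ROTATIONS or parts[1] not in FUNCTIONS:
            raise TaxonomyError(f"combined class {label!r} must be '<rotation>+<function>'")
        return parts[0], parts[1]

    @property
    def rotation_indices(self) -> tuple[int, ...]:
        return tuple(self.basic_classes.index(r) for r in ROTATIONS)

    @property
    def function_indices(self) -> tuple[int, ...]:
        return tuple(self.basic_classes.index(f) for f in FUNCTIONS)

    @property
    def all_classes(self) -> tuple[str, ...]:
        return self.basic_classes + self.combined_classes

    def is_combined(self, label: str) -> bool:
        return label in self.combined_classes

    def validate_label(self, label: str) -> None:
        if label not in self.basic_classes and label not in self.combined_classes:
            raise TaxonomyError(f"unknown movement label {label!r}")


def default_taxonomy() -> LabelTaxonomy:
    """The 14-class taxonomy: 8 basic movements (three of them free placeholder
    tokens) and the 6 rotation+function combinations."""
    basic = ("pronation", "supination", "pinch", "lateral_pinch", "grip",
             "basic_6", "basic_7", "basic_8")
    combined = tuple(f"{r}{COMBINED_SEPARATOR}{f}" for r in ROTATIONS for f in FUNCTIONS)
    return LabelTaxonomy(basic, combined)


def decompose_combined(label: str, taxonomy: LabelTaxonomy) -> tuple[str, str]:
    """Split a combined class into its (rotation, function) components."""
    taxonomy.validate_label(label)
    if not taxonomy.is_combined(label):
        raise TaxonomyError(f"{label!r} is not a combined class")
    return taxonomy._parse(label)


def compose_combined(rotation: str, function: str, taxonomy: LabelTaxonomy) -> str:
    label = f"{rotation}{COMBINED_SEPARATOR}{function}"
    if label not in taxonomy.combined_classes:
        raise TaxonomyError(f"({rotation!r}, {function!r}) is not a known combination")
    return label


@dataclass
class ScheduleEntry:
    label: str            # movement class, or "" for rest/preparation
    phase: str            # rest | preparation | movement
    start: int            # sample index, inclusive
    end: int              # sample index, exclusive
    repetition: int | None = None
    orientation: str | None = None

    def __post_init__(self):
        if self.phase not in PHASES:
            raise FormatError(f"unknown phase {self.phase!r}")
        if not (0 <= self.start < self.end):
            raise FormatError(f"bad interval [{self.start}, {self.end})")


@dataclass
class Recording:
    """Continuous multichannel sEMG signal plus its cue schedule."""

    signal: np.ndarray          # (n_channels, n_samples), microvolts
    fs: float                   # Hz
    schedule: list[ScheduleEntry] = field(default_factory=list)
    subject_id: str = "S0"
    orientation: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise FormatError("signal must be (n_channels, n_samples)")
        self.validate()

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def validate(self, taxonomy: LabelTaxonomy | None = None) -> None:
        if self.fs <= 0:
            raise FormatError(f"sampling rate must be positive, got {self.fs}")
        prev_end = -1
        for i, e in enumerate(self.schedule):
            if e.end > self.n_samples:
                raise FormatError(
                    f"schedule interval {i} [{e.start},{e.end}) exceeds "
                    f"n_samples={self.n_samples}")
            if e.start < prev_end:
                raise FormatError(
                    f"schedule interval {i} [{e.start},{e.end}) overlaps previous "
                    f"interval ending at {prev_end}")
            prev_end = e.end
            if taxonomy is not None and e.phase == "movement":
                taxonomy.validate_label(e.label)


# ---------------------------------------------------------------------------
# Recording I/O: delimited text signal + JSON metadata

def write_recording(rec: Recording, signal_path: str | os.PathLike,
                    meta_path: str | os.PathLike) -> None:
    """One row per sample, one tab-separated column per channel; '%.17g'
    formatting round-trips float64 exactly."""
    np.savetxt(signal_path, rec.signal.T, fmt="%.17g", delimiter="\t")
    meta = {
        "fs": rec.fs,
        "n_channels": rec.n_channels,
        "subject_id": rec.subject_id,
        "orientation": rec.orientation,
        "meta": rec.meta,
        "schedule": [asdict(e) for e in rec.schedule],
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def read_recording(signal_path: str | os.PathLike,
                   meta_path: str | os.PathLike) -> Recording:
    with open(meta_path) as fh:
        meta = json.load(fh)
    fs = meta.get("fs")
    if fs is None or fs <= 0:
        raise FormatError(f"{meta_path}: metadata must declare fs > 0 (got {fs})")
    try:
        signal = np.loadtxt(signal_path, delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{signal_path}: ragged or non-numeric rows ({exc})") from exc
    n_declared = meta.get("n_channels")
    if n_declared is not None and signal.shape[1] != n_declared:
        raise FormatError(
            f"{signal_path}: {signal.shape[1]} columns but metadata declares "
            f"{n_declared} channels")
    schedule = [ScheduleEntry(**e) for e in meta.get("schedule", [])]
    return Recording(signal=signal.T, fs=fs, schedule=schedule,
                     subject_id=meta.get("subject_id", "S0"),
                     orientation=meta.get("orientation"),
                     meta=meta.get("meta", {}))


# ---------------------------------------------------------------------------
# WindowSet

@dataclass
class WindowSet:
    """A stack of fixed-length labeled windows (n x channels x window_len)."""

    windows: np.ndarray                     # (n, n_channels, window_len)
    labels: np.ndarray                      # (n,) str
    repetition_ids: np.ndarray              # (n,) int
    orientations: np.ndarray                # (n,) str
    subject_ids: np.ndarray                 # (n,) str
    window_len: int = 512
    stride: int = 128

    def __post_init__(self):
        self.windows = np.asarray(self.windows, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object)
        self.repetition_ids = np.asarray(self.repetition_ids, dtype=np.int64)
        self.orientations = np.asarray(self.orientations, dtype=object)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        n = len(self.windows)
        for name in ("labels", "repetition_ids", "orientations", "subject_ids"):
            if len(getattr(self, name)) != n:
                raise IntegrityError(f"{name} has {len(getattr(self, name))} entries "
                                     f"for {n} windows")
        if n and self.windows.shape[2] != self.window_len:
            raise IntegrityError(
                f"windows have length {self.windows.shape[2]} but window_len="
                f"{self.window_len}")

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def n_channels(self) -> int:
        return self.windows.shape[1] if self.n_windows else 0

    def subset(self, mask: np.ndarray) -> "WindowSet":
        return WindowSet(self.windows[mask], self.labels[mask],
                         self.repetition_ids[mask], self.orientations[mask],
                         self.subject_ids[mask], self.window_len, self.stride)

    @staticmethod
    def empty(n_channels: int, window_len: int = 512, stride: int = 128) -> "WindowSet":
        return WindowSet(np.empty((0, n_channels, window_len)),
                         np.empty(0, dtype=object), np.empty(0, dtype=np.int64),
                         np.empty(0, dtype=object), np.empty(0, dtype=object),
                         window_len, stride)


def concat_window_sets(sets: list[WindowSet]) -> WindowSet:
    sets = [s for s in sets]
    if not sets:
        raise ValueError("nothing to concatenate")
    wl, st = sets[0].window_len, sets[0].stride
    for s in sets:
        if (s.window_len, s.stride) != (wl, st):
            raise IntegrityError("window_len/stride differ between sets")
    nonempty = [s for s in sets if s.n_windows] or sets[:1]
    return WindowSet(
        np.concatenate([s.windows for s in nonempty]),
        np.concatenate([s.labels for s in nonempty]),
        np.concatenate([s.repetition_ids for s in nonempty]),
        np.concatenate([s.orientations for s in nonempty]),
        np.concatenate([s.subject_ids for s in nonempty]),
        wl, st)


def write_windows(ws: WindowSet, path: str | os.PathLike) -> None:
    """Lossless container: ``<path>.npy`` array + ``<path>.json`` sidecar."""
    base = os.fspath(path)
    np.save(base + ".npy", ws.windows)
    sidecar = {
        "shape": list(ws.windows.shape),
        "labels": ws.labels.tolist(),
        "repetition_ids": ws.repetition_ids.tolist(),
        "orientations": ws.orientations.tolist(),
        "subject_ids": ws.subject_ids.tolist(),
        "window_len": ws.window_len,
        "stride": ws.stride,
    }
    with open(base + ".json", "w") as fh:
        json.dump(sidecar, fh)


def read_windows(path: str | os.PathLike) -> WindowSet:
    base = os.fspath(path)
    try:
        windows = np.load(base + ".npy")
        with open(base + ".json") as fh:
            sc = json.load(fh)
    except (OSError, ValueError) as exc:
        raise IntegrityError(f"corrupt or missing window container at {base}: {exc}") from exc
    if list(windows.shape) != sc["shape"]:
        raise IntegrityError(f"{base}: array shape {windows.shape} != sidecar {sc['shape']}")
    if len(sc["labels"]) != windows.shape[0]:
        raise IntegrityError(
            f"{base}: sidecar has {len(sc['labels'])} labels for "
            f"{windows.shape[0]} windows")
    return WindowSet(windows, np.array(sc["labels"], dtype=object),
                     np.array(sc["repetition_ids"], dtype=np.int64),
                     np.array(sc["orientations"], dtype=object),
                     np.array(sc["subject_ids"], dtype=object),
                     sc["window_len"], sc["stride"])


@dataclass(frozen=True)
class SplitSpec:
    """Repetition-based train/test assignment."""

    policy: str = "nearlab_3of5"        # nearlab_3of5 | ninapro_1346 | custom
    train_repetitions: frozenset = frozenset()
    test_repetitions: frozenset = frozenset()

    def __post_init__(self):
        if self.policy not in ("nearlab_3of5", "ninapro_1346", "custom"):
            raise ValueError(f"unknown split policy {self.policy!r}")
        if self.train_repetitions & self.test_repetitions:
            raise ValueError("train and test repetitions overlap")
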