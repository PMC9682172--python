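"""Synergy-structured synthetic surface-EMG generator.

Emulates a multi-subject hand-gesture acquisition at desk scale: 10
differential channels sampled at 2048 Hz, 8 basic movement classes performed
in 3 hand orientations, and 6 combined movements realized as superpositions
of the activation patterns of their rotation and function components — the
muscle-synergy premise that makes the zero-shot task-transfer rule work.

The signal model per channel c during a movement of class k is

    x_c(t) = env(t) * g_subj,c * g_orient,c * G[k,c] * A * w_c(t)
             + B * b_c(t) + optional 50 Hz hum,

where ``env`` is a trapezoid (250 ms rise/fall by default), ``G`` a sparse
non-negative class-by-channel gain bank, ``w`` and ``b`` independent
band-limited (20-450 Hz) unit-RMS Gaussian processes, ``A`` the movement RMS
scale and ``B`` the baseline RMS.  Subject and orientation variability are
multiplicative log-normal channel gains.  Everything is reproducible
bit-exactly from the configured seed.

This is amplitude-modulated filtered noise, not a motor-unit simulation: it
reproduces the channel-pattern structure and schedule of real recordings but
none of their spectral nonstationarity or electrode-shift effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core_data import (LabelTaxonomy, ORIENTATIONS, Recording, ScheduleEntry,
                        decompose_combined)


@dataclass
class SynergyBank:
    """Class-by-channel activation gains; combined rows derive from basic rows."""

    gains: np.ndarray                 # (n_classes_total, n_channels)
    classes: tuple[str, ...]          # basic then combined, taxonomy order

    def row(self, label: str) -> np.ndarray:
        return self.gains[self.classes.index(label)]


@dataclass(frozen=True)
class SimulationConfig:
    fs: float = 2048.0
    n_channels: int = 10
    noise_band: tuple[float, float] = (20.0, 450.0)
    rise_ms: float = 250.0
    fall_ms: float = 250.0
    rest_s: float = 3.0
    prep_s: float = 2.0
    movement_s: float = 5.0
    movement_s_combined: float = 7.0
    baseline_rms: float = 8.0           # microvolts
    movement_rms_scale: float = 25.0    # microvolts per unit synergy gain
    line_hum_amp: float = 0.0           # 50 Hz amplitude, microvolts
    subject_gain_jitter_sd: float = 0.15
    orientation_gain_jitter_sd: float = 0.05
    trial_gain_jitter_sd: float = 0.15  # per-channel trial-to-trial variability
    trial_amplitude_jitter_sd: float = 0.4  # common-mode force-level variability
    seed: int = 0

    def __post_init__(self):
        if min(self.rest_s, self.prep_s, self.movement_s,
               self.movement_s_combined) <= 0:
            raise ValueError("durations must be positive")
        if min(self.subject_gain_jitter_sd, self.orientation_gain_jitter_sd,
               self.trial_gain_jitter_sd, self.trial_amplitude_jitter_sd) < 0:
            raise ValueError("jitter SDs must be non-negative")


def make_synergy_bank(taxonomy: LabelTaxonomy, n_channels: int = 10,
                      rng: np.random.Generator | None = None,
                      combine: str = "max",
                      max_correlation: float = 0.95) -> SynergyBank:
    """Draw sparse non-negative basic-class patterns; derive combined rows.

    Each basic class strongly activates 2-4 channels.  Basic rows are
    re-drawn until all pairwise correlations fall below ``max_correlation``.
    Combined rows are the per-channel maximum (or sum) of their rotation and
    function rows.
    """
    if n_channels < 4:
        raise ValueError("need at least 4 channels for distinct patterns")
    if combine not in ("max", "sum"):
        raise ValueError(f"unknown combine mode {combine!r}")
    rng = rng or np.random.default_rng(0)
    n_basic = len(taxonomy.basic_classes)
    for _ in range(200):
        rows = rng.uniform(0.0, 0.12, size=(n_basic, n_channels))
        for i in range(n_basic):
            k = rng.integers(2, 5)
            active = rng.choice(n_channels, size=k, replace=False)
            rows[i, active] = rng.uniform(0.7, 1.5, size=k)
        corr = np.corrcoef(rows)
        if np.abs(corr[np.triu_indices(n_basic, 1)]).max() < max_correlation:
            break
    else:  # pragma: no cover - extremely unlikely
        raise RuntimeError("could not draw sufficiently distinct synergy rows")
    combined_rows = []
    for c in taxonomy.combined_classes:
        rot, fun = decompose_combined(c, taxonomy)
        a = rows[taxonomy.basic_classes.index(rot)]
        b = rows[taxonomy.basic_classes.index(fun)]
        combined_rows.append(np.maximum(a, b) if combine == "max" else a + b)
    gains = np.vstack([rows, np.array(combined_rows)])
    return SynergyBank(gains=gains, classes=taxonomy.all_classes)


def _band_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                fs: float, band: tuple[float, float]) -> np.ndarray:
    """Independent band-limited unit-RMS Gaussian processes per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, white, axis=1)
    rms = np.sqrt(np.mean(x ** 2, axis=1, keepdims=True))
    return x / rms


def _trapezoid(n: int, fs: float, rise_ms: float, fall_ms: float) -> np.ndarray:
    rise = min(int(round(rise_ms * fs / 1000)), n // 2)
    fall = min(int(round(fall_ms * fs / 1000)), n - rise)
    env = np.ones(n)
    if rise:
        env[:rise] = np.linspace(0, 1, rise, endpoint=False)
    if fall:
        env[n - fall:] = np.linspace(1, 0, fall)
    return env


def _channel_jitter(rng: np.random.Generator, n_channels: int, sd: float
                    ) -> np.ndarray:
    if sd == 0:
        return np.ones(n_channels)
    return np.exp(rng.normal(0.0, sd, size=n_channels))


def subject_gains(cfg: SimulationConfig, subject_index: int
                  ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Deterministic per-subject and per-orientation channel gains."""
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 1000 + subject_index]))
    g_subj = _channel_jitter(rng, cfg.n_channels, cfg.subject_gain_jitter_sd)
    g_orient = {o: _channel_jitter(rng, cfg.n_channels,
                                   cfg.orientation_gain_jitter_sd)
                for o in ORIENTATIONS}
    return g_subj, g_orient


def simulate_recording(bank: SynergyBank, cfg: SimulationConfig,
                       subject_id: str,
                       schedule_items: list[tuple[str, str, int]],
                       taxonomy: LabelTaxonomy,
                       subject_index: int = 0,
                       stream_seed: int | None = None) -> Recording:
    """One continuous recording covering the given (class, orientation,
    repetition) items with rest/preparation/movement structure."""
    for label, _, _ in schedule_items:
        taxonomy.validate_label(label)
    fs = cfg.fs
    segs = []
    schedule: list[ScheduleEntry] = []
    cursor = 0

    def add(phase, dur_s, label="", rep=None, orient=None):
        nonlocal cursor
        n = int(round(dur_s * fs))
        schedule.append(ScheduleEntry(label=label, phase=phase, start=cursor,
                                      end=cursor + n, repetition=rep,
                                      orientation=orient))
        segs.append((phase, n, label, orient))
        cursor += n

    for label, orientation, rep in schedule_items:
        dur = (cfg.movement_s_combined if taxonomy.is_combined(label)
               else cfg.movement_s)
        add("rest", cfg.rest_s)
        add("preparation", cfg.prep_s)
        add("movement", dur, label, rep, orientation)

    n_total = cursor
    rng = np.random.default_rng(np.random.SeedSequence(
        [cfg.seed, 2000 + subject_index,
         stream_seed if stream_seed is not None else 0]))
    base = _band_noise(rng, cfg.n_channels, n_total, fs, cfg.noise_band)
    burst = _band_noise(rng, cfg.n_channels, n_total, fs, cfg.noise_band)
    g_subj, g_orient = subject_gains(cfg, subject_index)

    signal = cfg.baseline_rms * base
    pos = 0
    for phase, n, label, orient in segs:
        if phase == "movement":
            env = _trapezoid(n, fs, cfg.rise_ms, cfg.fall_ms)
            g_trial = _channel_jitter(rng, cfg.n_channels,
                                      cfg.trial_gain_jitter_sd)
            # common-mode contraction-force variability (scalar per trial)
            amp = (np.exp(rng.normal(0.0, cfg.trial_amplitude_jitter_sd))
                   if cfg.trial_amplitude_jitter_sd else 1.0)
            gains = (bank.row(label) * g_subj * g_trial * amp
                     * (g_orient[orient] if orient in g_orient else 1.0))
            signal[:, pos:pos + n] += (env[None, :]
                                       * gains[:, None]
                                       * cfg.movement_rms_scale
                                       * burst[:, pos:pos + n])
        pos += n
    if cfg.line_hum_amp:
        t = np.arange(n_total) / fs
        signal += cfg.line_hum_amp * np.sin(2 * np.pi * 50.0 * t)[None, :]
    return Recording(signal=signal, fs=fs, schedule=schedule,
                     subject_id=subject_id,
                     meta={"synthetic": True, "subject_index": subject_index})


def protocol_schedule(taxonomy: LabelTaxonomy, classes: list[str],
                      n_reps: int, orientations: list[str],
                      rng: np.random.Generator) -> list[tuple[str, str, int]]:
    """All (class, orientation, repetition) cells in randomized order.

    Repetitions are numbered 1..n_reps within each (class, orientation) cell,
    in the order the cells happen to occur (acquisition order).
    """
    cells = [(c, o) for o in orientations for c in classes for _ in range(n_reps)]
    order = rng.permutation(len(cells))
    counters: dict[tuple[str, str], int] = {}
    items = []
    for i in order:
        c, o = cells[i]
        counters[(c, o)] = counters.get((c, o), 0) + 1
        items.append((c, o, counters[(c, o)]))
    return items


def simulate_cohort(bank: SynergyBank, cfg: SimulationConfig,
                    n_subjects: int,
                    taxonomy: LabelTaxonomy,
                    classes: list[str] | None = None,
                    n_reps: int = 5,
                    orientations: list[str] | None = None) -> list[Recording]:
    """One randomized-protocol recording per subject, shared synergy bank."""
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    classes = list(classes if classes is not None else taxonomy.basic_classes)
    orientations = list(orientations or ORIENTATIONS)
    recs = []
    for s in range(n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3000 + s]))
        items = protocol_schedule(taxonomy, classes, n_reps, orientations, rng)
        recs.append(simulate_recording(bank, cfg, f"S{s}", items, taxonomy,
                                       subject_index=s))
    return recs
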