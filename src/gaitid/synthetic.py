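"""Synthetic dual-foot insole recordings with ground-truth gait cycles.

This module is the package's test harness, not a biomechanical gait model.
It emulates the statistical structure the identification method relies on:

* each subject has a stable template — per-sensor contact windows within
  the stance phase with a peak pressure level of 1 or 2, a 3-harmonic
  acceleration waveform per channel, and a preferred cycle duration;
* a gait cycle alternates a stance phase (about 60% of the cycle, at least
  one sensor loaded at every frame) and a swing phase during which every
  pressure sensor of that foot reads 0, so swing-onset segmentation is
  well defined; the two feet are offset by half a cycle;
* within-subject variability comes from cycle-length jitter (coefficient
  of variation ``cycle_cv``), per-step jitter of the contact windows
  (``press_jitter``), and additive Gaussian accelerometer noise.

Templates are drawn around a shared population prototype; ``separation``
scales the between-subject perturbations, so identification difficulty is
a dial: 0 makes all subjects identical (chance-level), larger values give
increasingly distinct gaits.

Ground truth uses the same convention as the segmenter — cycle i spans
[onset_i, onset_{i+1}) between successive swing onsets of the reference
(left) foot — so generator/segmenter comparisons are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import RecordingSession

STANCE_FRACTION = 0.6  # stance/swing split of one gait cycle

# Population prototype: per-sensor (onset, offset) contact window as a
# fraction of stance, and peak level, for the 8 sensors of one foot
# (3 forefoot-medial, 3 forefoot-lateral, 2 heel). Heel loads first, the
# forefoot rolls on later; sensors 7 (heel) and 0 (forefoot) are the
# "covering" pair that guarantees the stance phase is never all-zero.
_PROTO_WINDOWS = np.array(
    [
        (0.35, 1.00),  # forefoot medial 1 (covering: onset clipped <= 0.5)
        (0.40, 0.95),  # forefoot medial 2
        (0.45, 0.90),  # forefoot medial 3
        (0.38, 0.92),  # forefoot lateral 1
        (0.42, 0.88),  # forefoot lateral 2
        (0.50, 0.85),  # forefoot lateral 3
        (0.05, 0.55),  # heel 1
        (0.00, 0.60),  # heel 2 (covering: offset clipped >= 0.5)
    ]
)
_PROTO_PEAKS = np.array([2, 1, 1, 2, 1, 1, 2, 2])

# 3-harmonic acceleration prototype: amplitudes and phases per channel
# (left x,y,z then right x,y,z), arbitrary sensor units.
_PROTO_AMPS = np.array(
    [
        [1.0, 0.5, 0.2],
        [0.8, 0.4, 0.3],
        [1.2, 0.3, 0.15],
        [1.0, 0.5, 0.2],
        [0.8, 0.4, 0.3],
        [1.2, 0.3, 0.15],
    ]
)
_PROTO_PHASES = np.array(
    [
        [0.0, 0.7, 1.4],
        [0.5, 1.2, 0.3],
        [1.0, 0.2, 0.9],
        [0.0, 0.7, 1.4],
        [0.5, 1.2, 0.3],
        [1.0, 0.2, 0.9],
    ]
)
_PROTO_CYCLE_FRAMES = 115.0  # ~1.15 s per cycle at 100 Hz


@dataclass
class SubjectTemplate:
    """Generative parameters of one subject's gait."""

    subject_id: str
    windows: np.ndarray  # (2, 8, 2) per foot, per sensor: (onset, offset) in stance fractions
    peaks: np.ndarray  # (2, 8) peak pressure level in {1, 2}
    accel_amps: np.ndarray  # (6, 3) harmonic amplitudes
    accel_phases: np.ndarray  # (6, 3) harmonic phases (radians)
    mean_cycle_frames: float
    cycle_cv: float  # within-subject coefficient of variation of cycle length
    press_jitter: float  # per-step s.d. of window endpoints (stance fractions)
    accel_noise_sd: float

    def __post_init__(self) -> None:
        w = np.asarray(self.windows, dtype=float)
        if not ((0.0 <= w[..., 0]) & (w[..., 0] < w[..., 1]) & (w[..., 1] <= 1.0)).all():
            raise ValueError("every contact window needs 0 <= onset < offset <= 1")
        if self.mean_cycle_frames < 20:
            raise ValueError("mean_cycle_frames must be >= 20")
        if self.cycle_cv < 0:
            raise ValueError("cycle_cv must be >= 0")


@dataclass
class CohortSpec:
    """Cohort-level generation settings.

    ``separation`` scales between-subject template differences; the named
    presets are easy (1.0), moderate (0.5) and hard (0.15).
    """

    n_subjects: int = 14
    separation: float = 0.5
    steps_per_subject: int = 60
    cycle_cv: float = 0.05
    press_jitter: float = 0.02
    accel_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")


SEPARATION_PRESETS = {"easy": 1.0, "moderate": 0.5, "hard": 0.15}


def _clip_windows(windows: np.ndarray) -> np.ndarray:
    """Clip per-sensor windows to valid fractions and keep stance covered.

    Sensor 7 (a heel sensor) always has onset 0 and offset >= 0.5 and sensor
    0 (a forefoot sensor) always has offset 1 and onset <= 0.5, so the union
    of active windows covers the whole stance phase of each foot.
    """
    w = windows.copy()
    w[..., 0] = np.clip(w[..., 0], 0.0, 0.9)
    w[..., 1] = np.clip(w[..., 1], w[..., 0] + 0.05, 1.0)
    w[:, 7, 0] = 0.0
    w[:, 7, 1] = np.clip(w[:, 7, 1], 0.5, 1.0)
    w[:, 0, 1] = 1.0
    w[:, 0, 0] = np.clip(w[:, 0, 0], 0.0, 0.5)
    return w


def make_cohort(spec: CohortSpec) -> list[SubjectTemplate]:
    """Draw one template per subject around the population prototype."""
    rng = np.random.default_rng(spec.seed)
    sep = spec.separation
    templates = []
    for i in range(spec.n_subjects):
        windows = np.stack([_PROTO_WINDOWS, _PROTO_WINDOWS])  # (feet, sensor, 2)
        windows = windows + sep * rng.normal(0.0, 0.08, size=windows.shape)
        windows = _clip_windows(windows)
        peaks = np.stack([_PROTO_PEAKS, _PROTO_PEAKS])
        flip = rng.random(peaks.shape) < min(0.5, 0.25 * sep)
        peaks = np.where(flip, 3 - peaks, peaks)
        amps = np.abs(_PROTO_AMPS + sep * rng.normal(0.0, 0.3, size=_PROTO_AMPS.shape))
        phases = _PROTO_PHASES + sep * rng.normal(0.0, 0.5, size=_PROTO_PHASES.shape)
        mean_cycle = float(
            np.clip(_PROTO_CYCLE_FRAMES + sep * rng.normal(0.0, 12.0), 100.0, 130.0)
        )
        templates.append(
            SubjectTemplate(
                subject_id=f"S{i + 1:02d}",
                windows=windows,
                peaks=peaks,
                accel_amps=amps,
                accel_phases=phases,
                mean_cycle_frames=mean_cycle,
                cycle_cv=spec.cycle_cv,
                press_jitter=spec.press_jitter,
                accel_noise_sd=spec.accel_noise_sd,
            )
        )
    return templates


def _render_foot_pressure(
    template: SubjectTemplate, foot: int, stance: int, cycle: int, rng: np.random.Generator
) -> np.ndarray:
    """Pressure block (cycle, 8) for one foot: stance then all-zero swing."""
    block = np.zeros((cycle, 8), dtype=np.int64)
    frac = (np.arange(stance) + 0.5) / stance  # mid-frame stance fraction in (0, 1)
    jitter = rng.normal(0.0, template.press_jitter, size=(8, 2))
    windows = _clip_windows((template.windows[foot] + jitter)[None])[0]
    for s in range(8):
        onset, offset = windows[s]
        active = (frac >= onset) & (frac <= offset)
        block[:stance, s] = np.where(active, template.peaks[foot, s], 0)
    return block


def synth_session(
    template: SubjectTemplate, n_steps: int, rng: np.random.Generator | int
) -> tuple[RecordingSession, list[tuple[int, int]]]:
    """Render ``n_steps`` gait cycles and return the session with ground truth.

    The reference (left) foot starts each rendered cycle in stance, so its
    swing onsets occur at ``start + stance`` within each cycle; the returned
    boundaries are the ``n_steps - 1`` complete [onset, next onset) cycles
    the segmenter should recover. The right foot follows the same pattern
    shifted by half a cycle.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pressure_blocks, accel_blocks, onsets = [], [], []
    start = 0
    for _ in range(n_steps):
        mean = template.mean_cycle_frames
        cycle = int(max(20, round(rng.normal(mean, template.cycle_cv * mean))))
        stance = int(np.clip(round(STANCE_FRACTION * cycle), 1, cycle - 1))
        left = _render_foot_pressure(template, 0, stance, cycle, rng)
        right = _render_foot_pressure(template, 1, stance, cycle, rng)
        right = np.roll(right, cycle // 2, axis=0)  # half-cycle offset between feet
        phase = (np.arange(cycle) + 0.5) / cycle
        accel = np.empty((cycle, 6))
        harmonics = np.arange(1, 4)
        for ch in range(6):
            ph = phase + (0.5 if ch >= 3 else 0.0)  # right-foot channels lead by half a cycle
            wave = np.sum(
                template.accel_amps[ch]
                * np.sin(2.0 * np.pi * harmonics * ph[:, None] + template.accel_phases[ch]),
                axis=1,
            )
            accel[:, ch] = wave + rng.normal(0.0, template.accel_noise_sd, size=cycle)
        pressure_blocks.append(np.hstack([left, right]))
        accel_blocks.append(accel)
        onsets.append(start + stance)
        start += cycle
    session = RecordingSession(
        subject_id=template.subject_id,
        pressure=np.vstack(pressure_blocks),
        acceleration=np.vstack(accel_blocks),
    )
    boundaries = list(zip(onsets[:-1], onsets[1:]))
    return session, boundaries


def synth_cohort_sessions(
    spec: CohortSpec,
) -> tuple[list[RecordingSession], dict[str, list[tuple[int, int]]]]:
    """Generate one session per subject plus ground-truth cycle boundaries."""
    templates = make_cohort(spec)
    root = np.random.SeedSequence(spec.seed)
    sessions, truth = [], {}
    for template, child in zip(templates, root.spawn(len(templates))):
        session, boundaries = synth_session(
            template, spec.steps_per_subject + 1, np.random.default_rng(child)
        )
        sessions.append(session)
        truth[template.subject_id] = boundaries
    return sessions, truth
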