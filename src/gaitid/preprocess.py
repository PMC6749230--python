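"""Gait-cycle segmentation, length normalization, vectorization, regularization.

A gait cycle is delimited by successive swing-phase onsets of a reference
foot: the swing onset is the first frame at which *all* pressure sensors of
that foot read zero. Each cycle is resampled to a fixed length ``l`` (63
frames by default) so that walking-speed variation does not inflate
within-subject variability, flattened time-major into per-modality vectors
(l*16 pressure, l*6 acceleration), and regularized by adding uniform noise
on [0, 0.1) — the segmented vectors contain structurally zero entries
(every swing phase zeroes the reference foot), which would otherwise make
the scatter matrices rank deficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateStepError
from .io import N_ACCEL, N_PRESSURE, RecordingSession

DEFAULT_CYCLE_LENGTH = 63
DEFAULT_NOISE_HIGH = 0.1
DEFAULT_MIN_CYCLE_FRAMES = 10

LEFT_PRESSURE = slice(0, 8)
RIGHT_PRESSURE = slice(8, 16)


@dataclass
class StepSegment:
    """One gait cycle cut from a session, spanning frames [start, end)."""

    subject_id: str
    pressure: np.ndarray  # (T, 16) int
    acceleration: np.ndarray  # (T, 6) float
    start_frame: int
    end_frame: int

    @property
    def duration_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class NormalizedStep:
    """One gait cycle resampled to ``cycle_length`` frames.

    Matrices are real valued (linear interpolation de-quantizes pressure);
    vectors are the time-major (row-major) flattening of the matrices.
    """

    subject_id: str
    pressure_matrix: np.ndarray  # (l, 16)
    accel_matrix: np.ndarray  # (l, 6)
    cycle_length: int

    @property
    def pressure_vector(self) -> np.ndarray:
        return vectorize(self.pressure_matrix)

    @property
    def accel_vector(self) -> np.ndarray:
        return vectorize(self.accel_matrix)


@dataclass
class GaitSample:
    """Classifier input: ``k`` consecutive regularized steps, concatenated."""

    subject_id: str
    k: int
    feature_input_pressure: np.ndarray  # (k * l * 16,)
    feature_input_accel: np.ndarray  # (k * l * 6,)


def detect_swing_onsets(foot_pressure: np.ndarray) -> np.ndarray:
    """First frame index of every maximal all-zero run of one foot's sensors.

    Parameters
    ----------
    foot_pressure
        ``(n_frames, 8)`` pressure matrix for a single foot.

    Returns
    -------
    Increasing array of swing-phase onset frames (possibly empty).
    """
    foot_pressure = np.asarray(foot_pressure)
    airborne = np.all(foot_pressure == 0, axis=1)
    prev = np.concatenate([[False], airborne[:-1]])
    return np.flatnonzero(airborne & ~prev)


def segment_steps(
    session: RecordingSession,
    reference_foot: str = "left",
    min_cycle_frames: int = DEFAULT_MIN_CYCLE_FRAMES,
) -> list[StepSegment]:
    """Cut a session into complete gait cycles of the reference foot.

    Cycle ``i`` spans ``[onset_i, onset_{i+1})`` where onsets are the
    reference foot's swing-phase onsets; partial leading/trailing cycles are
    discarded, as are implausibly short segments (< ``min_cycle_frames``,
    treated as sensor glitches). Each segment carries all 16 pressure and 6
    acceleration channels over its span.
    """
    if reference_foot not in ("left", "right"):
        raise ValueError(f"reference_foot must be 'left' or 'right', got {reference_foot!r}")
    cols = LEFT_PRESSURE if reference_foot == "left" else RIGHT_PRESSURE
    onsets = detect_swing_onsets(session.pressure[:, cols])
    segments = []
    for start, end in zip(onsets[:-1], onsets[1:]):
        if end - start < max(min_cycle_frames, 2):
            continue
        segments.append(
            StepSegment(
                subject_id=session.subject_id,
                pressure=session.pressure[start:end],
                acceleration=session.acceleration[start:end],
                start_frame=int(start),
                end_frame=int(end),
            )
        )
    return segments


def resample_channels(matrix: np.ndarray, length: int) -> np.ndarray:
    """Resample each column from T rows to ``length`` rows by linear interpolation.

    The uniform grid maps [0, T-1] onto [0, length-1]; constants are
    preserved exactly and T == length returns the input values unchanged.
    """
    matrix = np.asarray(matrix, dtype=float)
    t = matrix.shape[0]
    if t < 2:
        raise DegenerateStepError(f"cannot resample a {t}-frame segment")
    grid = np.linspace(0.0, t - 1.0, length)
    source = np.arange(t, dtype=float)
    return np.column_stack([np.interp(grid, source, matrix[:, c]) for c in range(matrix.shape[1])])


def normalize_step(step: StepSegment, cycle_length: int = DEFAULT_CYCLE_LENGTH) -> NormalizedStep:
    """Resample one step to a fixed number of frames per cycle.

    Pressure becomes real valued after interpolation and is deliberately not
    re-quantized; all downstream math treats it as continuous.
    """
    if cycle_length < 2:
        raise ValueError("cycle_length must be >= 2")
    if step.duration_frames < 2:
        raise DegenerateStepError(
            f"step [{step.start_frame}, {step.end_frame}) has fewer than 2 frames"
        )
    return NormalizedStep(
        subject_id=step.subject_id,
        pressure_matrix=resample_channels(step.pressure, cycle_length),
        accel_matrix=resample_channels(step.acceleration, cycle_length),
        cycle_length=cycle_length,
    )


def vectorize(matrix: np.ndarray) -> np.ndarray:
    """Row-major (lexicographic, time-major) flattening: (t, ch) -> t*n_ch + ch."""
    return np.asarray(matrix, dtype=float).reshape(-1)


def unvectorize(vector: np.ndarray, n_channels: int) -> np.ndarray:
    """Inverse of :func:`vectorize` for a known channel count."""
    return np.asarray(vector, dtype=float).reshape(-1, n_channels)


def regularize(
    vector: np.ndarray, rng: np.random.Generator, high: float = DEFAULT_NOISE_HIGH
) -> np.ndarray:
    """Add i.i.d. uniform noise on [0, high) to every element.

    Structural zeros (the swing phase zeroes whole blocks of the pressure
    vector in every sample) otherwise make the total scatter rank deficient.
    """
    vector = np.asarray(vector, dtype=float)
    return vector + rng.uniform(0.0, high, size=vector.shape)


def group_steps(
    steps: list[NormalizedStep],
    k: int,
    rng: np.random.Generator,
    noise_high: float = DEFAULT_NOISE_HIGH,
) -> list[GaitSample]:
    """Group consecutive steps of one subject into k-step samples.

    Windows are non-overlapping and in time order; the final ``n mod k``
    leftover steps are discarded. Regularization noise is drawn fresh per
    step here, so each grouping (one per experiment repeat) sees its own
    noise realization.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    samples = []
    for i in range(0, len(steps) - k + 1, k):
        window = steps[i : i + k]
        pressure = np.concatenate([regularize(s.pressure_vector, rng, noise_high) for s in window])
        accel = np.concatenate([regularize(s.accel_vector, rng, noise_high) for s in window])
        samples.append(
            GaitSample(
                subject_id=window[0].subject_id,
                k=k,
                feature_input_pressure=pressure,
                feature_input_accel=accel,
            )
        )
    return samples


def session_to_steps(
    session: RecordingSession,
    cycle_length: int = DEFAULT_CYCLE_LENGTH,
    reference_foot: str = "left",
    min_cycle_frames: int = DEFAULT_MIN_CYCLE_FRAMES,
) -> list[NormalizedStep]:
    """Segment and length-normalize a whole session."""
    return [
        normalize_step(step, cycle_length)
        for step in segment_steps(session, reference_foot, min_cycle_frames)
    ]
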