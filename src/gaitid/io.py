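"""Recording data model and on-disk session format.

A recording session holds the synchronous output of a dual smart insole:
16 plantar-pressure channels (8 per foot, quantized to {0, 1, 2}) and 6
acceleration channels (triaxial per foot), sampled at 100 Hz.

On disk a session is a single CSV file. The first line is a comment of the
form ``# subject_id=<label> sample_rate=<hz>``, followed by a header row
``t,Lp1..Lp8,Rp1..Rp8,Lax,Lay,Laz,Rax,Ray,Raz`` and one row per frame.
A cohort is a directory laid out as ``<cohort>/<subject_id>/<session>.csv``.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

PRESSURE_COLUMNS = [f"{foot}p{i}" for foot in ("L", "R") for i in range(1, 9)]
ACCEL_COLUMNS = [f"{foot}a{axis}" for foot in ("L", "R") for axis in ("x", "y", "z")]
ALL_COLUMNS = ["t"] + PRESSURE_COLUMNS + ACCEL_COLUMNS

N_PRESSURE = 16
N_ACCEL = 6
DEFAULT_SAMPLE_RATE = 100.0

#: admissible plantar-pressure quantization levels (0 = foot off the ground)
PRESSURE_LEVELS = (0, 1, 2)


@dataclass
class RecordingSession:
    """One labeled dual-foot insole recording.

    Parameters
    ----------
    subject_id
        Identity label of the walker.
    pressure
        ``(n_frames, 16)`` integer matrix; columns are left-foot sensors 1-8
        followed by right-foot sensors 1-8. Values must lie in {0, 1, 2}.
    acceleration
        ``(n_frames, 6)`` real matrix; columns are left (x, y, z) then
        right (x, y, z), in raw sensor units.
    sample_rate
        Frames per second (the hardware samples at 100 Hz).
    """

    subject_id: str
    pressure: np.ndarray
    acceleration: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure)
        self.acceleration = np.asarray(self.acceleration, dtype=float)
        self.validate()
        self.pressure = self.pressure.astype(np.int64)

    @property
    def n_frames(self) -> int:
        return self.pressure.shape[0]

    def validate(self) -> None:
        """Raise :class:`ValidationError` if any model invariant is violated."""
        p, a = self.pressure, self.acceleration
        if p.ndim != 2 or p.shape[1] != N_PRESSURE:
            raise ValidationError(f"pressure must be (n_frames, {N_PRESSURE}), got {p.shape}")
        if a.ndim != 2 or a.shape[1] != N_ACCEL:
            raise ValidationError(f"acceleration must be (n_frames, {N_ACCEL}), got {a.shape}")
        if p.shape[0] != a.shape[0]:
            raise ValidationError(
                f"pressure ({p.shape[0]} frames) and acceleration ({a.shape[0]} frames) "
                "must have identical frame counts"
            )
        if p.shape[0] < 1:
            raise ValidationError("session must contain at least one frame")
        bad = ~np.isin(p, PRESSURE_LEVELS)
        if bad.any():
            t, ch = np.argwhere(bad)[0]
            raise ValidationError(
                f"pressure value {p[t, ch]} at frame {t}, channel {PRESSURE_COLUMNS[ch]} "
                f"is outside {set(PRESSURE_LEVELS)}"
            )
        if not np.isfinite(a).all():
            raise ValidationError("acceleration contains non-finite values")
        if not self.sample_rate > 0:
            raise ValidationError("sample_rate must be positive")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RecordingSession):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.sample_rate == other.sample_rate
            and np.array_equal(self.pressure, other.pressure)
            and np.array_equal(self.acceleration, other.acceleration)
        )


def _parse_metadata(line: str, path: Path) -> dict:
    if not line.startswith("#"):
        raise FormatError(f"{path}: line 1 must be a '# subject_id=... sample_rate=...' comment")
    meta = {}
    for token in line.lstrip("#").split():
        if "=" not in token:
            raise FormatError(f"{path}: malformed metadata token {token!r} on line 1")
        key, value = token.split("=", 1)
        meta[key] = value
    if "subject_id" not in meta:
        raise FormatError(f"{path}: metadata line is missing subject_id")
    return meta


def read_session(path: str | Path) -> RecordingSession:
    """Read and validate one session CSV.

    Raises
    ------
    FormatError
        If the file is empty, the metadata/header lines are malformed, or a
        data row has the wrong column count (the error names the line).
    ValidationError
        If a parsed value violates a :class:`RecordingSession` invariant
        (the error names the channel and line).
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValidationError(f"{path}: empty session file")
    lines = text.splitlines()
    meta = _parse_metadata(lines[0], path)
    if len(lines) < 3:
        raise ValidationError(f"{path}: no data rows")
    header = lines[1].split(",")
    if header != ALL_COLUMNS:
        raise FormatError(f"{path}: line 2 header does not match {','.join(ALL_COLUMNS)}")
    n_cols = len(ALL_COLUMNS)
    for i, line in enumerate(lines[2:], start=3):
        if line.count(",") != n_cols - 1:
            raise FormatError(f"{path}: line {i} has {line.count(',') + 1} columns, expected {n_cols}")
    try:
        frame = pd.read_csv(_io.StringIO("\n".join(lines[1:])), float_precision="round_trip")
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc

    pressure = frame[PRESSURE_COLUMNS].to_numpy()
    bad = ~np.isin(pressure, PRESSURE_LEVELS)
    if bad.any():
        t, ch = np.argwhere(bad)[0]
        raise ValidationError(
            f"{path}: line {t + 3}: pressure value {pressure[t, ch]} in channel "
            f"{PRESSURE_COLUMNS[ch]} is outside {set(PRESSURE_LEVELS)}"
        )
    return RecordingSession(
        subject_id=meta["subject_id"],
        pressure=pressure,
        acceleration=frame[ACCEL_COLUMNS].to_numpy(dtype=float),
        sample_rate=float(meta.get("sample_rate", DEFAULT_SAMPLE_RATE)),
    )


def write_session(session: RecordingSession, path: str | Path) -> None:
    """Write a session to ``path`` in the CSV dialect read by :func:`read_session`.

    Writing is deterministic: the same session always yields byte-identical
    files, and floats use the shortest round-tripping decimal representation.
    """
    path = Path(path)
    session.validate()
    sr = session.sample_rate
    sr_text = repr(int(sr)) if float(sr).is_integer() else repr(sr)
    with open(path, "w", newline="") as fh:
        fh.write(f"# subject_id={session.subject_id} sample_rate={sr_text}\n")
        fh.write(",".join(ALL_COLUMNS) + "\n")
        for t in range(session.n_frames):
            cells = [str(t)]
            cells += [str(int(v)) for v in session.pressure[t]]
            # repr of a Python float is the shortest exactly round-tripping form
            cells += [repr(float(v)) for v in session.acceleration[t]]
            fh.write(",".join(cells) + "\n")


def read_cohort(root: str | Path) -> list[RecordingSession]:
    """Read every ``<root>/<subject_id>/*.csv`` session, sorted for determinism."""
    root = Path(root)
    paths = sorted(root.glob("*/*.csv"))
    if not paths:
        raise FormatError(f"{root}: no session files found under <subject_id>/*.csv")
    return [read_session(p) for p in paths]


def write_cohort(sessions: list[RecordingSession], root: str | Path) -> list[Path]:
    """Write sessions into the ``<root>/<subject_id>/<session>.csv`` layout."""
    root = Path(root)
    counter: dict[str, int] = {}
    written = []
    for session in sessions:
        counter[session.subject_id] = counter.get(session.subject_id, 0) + 1
        directory = root / str(session.subject_id)
        directory.mkdir(parents=True, exist_ok=True)
        path = directory / f"session{counter[session.subject_id]:02d}.csv"
        write_session(session, path)
        written.append(path)
    return written
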