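"""Frame schedules, time-activity curves, blood samples, and their file formats.

Everything downstream of image reconstruction works at the level of
time-activity curves (TACs): per-frame activity concentrations (kBq/cc) on an
acquisition frame schedule, with time in minutes post injection.  This module
owns those containers, the delimited-text formats they travel in, and the
frame-average operator that links continuous model curves to frame data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .expsum import ExpPolySum, frame_average_numeric

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "BloodSampleSeries",
    "build_frame_schedule",
    "frame_average",
    "read_tac",
    "write_tac",
    "read_samples",
    "write_samples",
    "peak_of_tac",
]

TAC_COLUMNS = ("frame_start_min", "frame_end_min", "activity_kBq_cc")
SAMPLE_COLUMNS = ("time_min", "activity_kBq_cc")

#: The 23-bin, 60-minute acquisition used throughout: 11 x 8 s, 1 x 12 s,
#: 2 x 60 s, 1 x 180 s, 8 x 400 s.
DEFAULT_FRAMING: tuple[tuple[int, float], ...] = ((11, 8), (1, 12), (2, 60), (1, 180), (8, 400))


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered, non-overlapping acquisition frames in minutes."""

    frames: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        frames = tuple((float(b), float(e)) for b, e in self.frames)
        if not frames:
            raise ValueError("schedule must contain at least one frame")
        if frames[0][0] < 0:
            raise ValueError("first frame must start at t >= 0")
        for i, (b, e) in enumerate(frames):
            if b >= e:
                raise ValueError(f"frame {i}: start {b} >= end {e}")
            if i and b < frames[i - 1][1] - 1e-12:
                raise ValueError(f"frame {i} overlaps frame {i - 1}")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def starts(self) -> np.ndarray:
        return np.array([b for b, _ in self.frames])

    @property
    def ends(self) -> np.ndarray:
        return np.array([e for _, e in self.frames])

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) / 2.0

    @property
    def durations(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def total_minutes(self) -> float:
        return float(self.ends[-1] - self.starts[0])


@dataclass(frozen=True)
class TimeActivityCurve:
    """Per-frame activity concentration (kBq/cc) for one region."""

    schedule: FrameSchedule
    values: np.ndarray
    label: str = ""
    allow_negative: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.schedule),):
            raise ValueError(
                f"TAC '{self.label}': {values.size} values for {len(self.schedule)} frames"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError(f"TAC '{self.label}': non-finite activity values")
        if not self.allow_negative and np.any(values < 0):
            raise ValueError(
                f"TAC '{self.label}': negative activity; pass allow_negative=True for noisy data"
            )
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class BloodSampleSeries:
    """Discrete arterial blood samples: times (min) and activities (kBq/cc)."""

    times: np.ndarray
    activities: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        acts = np.asarray(self.activities, dtype=float)
        if times.ndim != 1 or times.shape != acts.shape:
            raise ValueError("times and activities must be 1-D and the same length")
        if np.any(times < 0) or np.any(np.diff(times) <= 0):
            raise ValueError("sample times must be >= 0 and strictly ascending")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "activities", acts)
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != times.shape:
                raise ValueError("weights must match sample count")
            object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.times)


def build_frame_schedule(spec: Sequence[tuple[int, float]]) -> FrameSchedule:
    """Build contiguous frames from ``(count, duration_seconds)`` groups.

    Frames start at t = 0 and are converted to minutes, e.g. the standard
    23-bin 60-min protocol is ``[(11, 8), (1, 12), (2, 60), (1, 180), (8, 400)]``.
    """
    if not spec:
        raise ValueError("empty framing specification")
    frames: list[tuple[float, float]] = []
    t = 0.0
    for count, dur_s in spec:
        if count < 1 or dur_s <= 0:
            raise ValueError(f"invalid framing entry ({count}, {dur_s})")
        for _ in range(int(count)):
            frames.append((t, t + dur_s / 60.0))
            t += dur_s / 60.0
    return FrameSchedule(tuple(frames))


def frame_average(
    f: Callable[[float], float] | ExpPolySum, frame: tuple[float, float], tol: float = 1e-8
) -> float:
    """Mean of a continuous curve over one frame: ``int f / (t_e - t_b)``.

    Uses the exact antiderivative for :class:`~mcifkit.expsum.ExpPolySum`
    curves and adaptive quadrature (absolute tolerance ``tol``) otherwise.
    """
    t_b, t_e = frame
    if t_b >= t_e:
        raise ValueError(f"invalid frame: t_b={t_b} >= t_e={t_e}")
    if isinstance(f, ExpPolySum):
        return float(f.definite_integral(t_b, t_e)) / (t_e - t_b)
    return frame_average_numeric(f, t_b, t_e, tol=tol)


def peak_of_tac(
    tac: TimeActivityCurve, window: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Maximum frame value within a time window -> (midpoint_min, value).

    A frame belongs to the window when its midpoint does; ties take the
    earliest frame.  Peak values are per-frame (already frame-averaged)
    activities, matching the resolution of reconstructed dynamic images.
    """
    mids = tac.schedule.midpoints
    if window is None:
        mask = np.ones(len(mids), dtype=bool)
    else:
        t_min, t_max = window
        mask = (mids >= t_min) & (mids <= t_max)
    if not mask.any():
        raise ValueError(f"window {window} contains no frame midpoints")
    idx = np.flatnonzero(mask)
    best = idx[int(np.argmax(tac.values[idx]))]  # argmax takes first of ties
    return float(mids[best]), float(tac.values[best])


# -- file I/O ---------------------------------------------------------------


def _read_table(path: str | Path, columns: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    unit_scale = 1.0
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#"):
        if "units=" in first:
            unit = first.split("units=")[1].strip()
            if unit in ("kBq/cc", "kBq_cc"):
                unit_scale = 1.0
            elif unit in ("Bq/cc", "Bq_cc"):
                unit_scale = 1e-3
            else:
                raise ValueError(f"{path}: unsupported units '{unit}'")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df[columns[-1]] = df[columns[-1]] * unit_scale
    return df


def read_tac(path: str | Path, label: str = "", allow_negative: bool = False) -> TimeActivityCurve:
    """Read a TAC CSV (columns ``frame_start_min,frame_end_min,activity_kBq_cc``).

    An optional leading comment line ``# units=Bq/cc`` rescales activities to
    kBq/cc on ingest.  Schedule invariants are enforced; violations name the
    offending row.
    """
    df = _read_table(path, TAC_COLUMNS)
    starts = df[TAC_COLUMNS[0]].to_numpy(float)
    ends = df[TAC_COLUMNS[1]].to_numpy(float)
    for i in range(len(df)):
        if starts[i] >= ends[i]:
            raise ValueError(f"{path}: row {i}: frame start >= end")
        if i and starts[i] < ends[i - 1] - 1e-12:
            raise ValueError(f"{path}: row {i}: overlapping/non-ascending frames")
    schedule = FrameSchedule(tuple(zip(starts, ends)))
    return TimeActivityCurve(
        schedule,
        df[TAC_COLUMNS[2]].to_numpy(float),
        label=label or Path(path).stem,
        allow_negative=allow_negative,
    )


def write_tac(tac: TimeActivityCurve, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# units=kBq/cc\n")
        pd.DataFrame(
            {
                TAC_COLUMNS[0]: tac.schedule.starts,
                TAC_COLUMNS[1]: tac.schedule.ends,
                TAC_COLUMNS[2]: tac.values,
            }
        ).to_csv(fh, index=False, float_format="%.12g")


def read_samples(path: str | Path) -> BloodSampleSeries:
    """Read arterial samples CSV (columns ``time_min,activity_kBq_cc``)."""
    df = _read_table(path, SAMPLE_COLUMNS)
    return BloodSampleSeries(
        df[SAMPLE_COLUMNS[0]].to_numpy(float), df[SAMPLE_COLUMNS[1]].to_numpy(float)
    )


def write_samples(samples: BloodSampleSeries, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# units=kBq/cc\n")
        pd.DataFrame(
            {SAMPLE_COLUMNS[0]: samples.times, SAMPLE_COLUMNS[1]: samples.activities}
        ).to_csv(fh, index=False, float_format="%.12g")
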