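"""Dynamic PET frame schedules.

A frame schedule is the sequence of contiguous acquisition windows of a
dynamic scan.  The two protocols bundled here are the short ketone-tracer
scan (10 min) and the standard FDG scan (60 min)::

    acac : 12 x 10 s, 8 x 30 s, 1 x 4 min          -> 21 frames, 10 min
    fdg  : 12 x 10 s, 8 x 30 s, 6 x 4 min, 6 x 5 min -> 32 frames, 60 min

All times are minutes post injection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrameSchedule", "acac_schedule", "fdg_schedule", "schedule_from_durations"]


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping acquisition frames of a dynamic scan.

    Parameters
    ----------
    frames : tuple of (start_min, end_min)
        Frame windows in minutes; the first frame starts at 0 and each
        frame starts where the previous one ended.
    """

    frames: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ValueError("schedule needs at least one frame")
        starts = np.array([f[0] for f in self.frames], dtype=float)
        ends = np.array([f[1] for f in self.frames], dtype=float)
        if starts[0] != 0.0:
            raise ValueError("first frame must start at t=0")
        if np.any(ends <= starts):
            raise ValueError("frame end times must exceed start times")
        if np.any(np.diff(ends) <= 0):
            raise ValueError("frame end times must be strictly increasing")
        if not np.allclose(starts[1:], ends[:-1], atol=1e-9):
            raise ValueError("frames must be contiguous")
        object.__setattr__(self, "frames", tuple((float(s), float(e)) for s, e in self.frames))

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def starts(self) -> np.ndarray:
        return np.array([f[0] for f in self.frames])

    @property
    def ends(self) -> np.ndarray:
        return np.array([f[1] for f in self.frames])

    @property
    def midpoints(self) -> np.ndarray:
        """Arithmetic frame midpoints (min) — the evaluation times used for
        frame-averaged data."""
        return 0.5 * (self.starts + self.ends)

    @property
    def durations(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def total_duration(self) -> float:
        return float(self.frames[-1][1])


def schedule_from_durations(durations_min: list[float]) -> FrameSchedule:
    """Build a schedule from an ordered list of frame durations (min)."""
    ends = np.cumsum(np.asarray(durations_min, dtype=float))
    starts = np.concatenate([[0.0], ends[:-1]])
    return FrameSchedule(tuple(zip(starts, ends)))


def acac_schedule() -> FrameSchedule:
    """10-min ketone-tracer protocol: 12 x 10 s, 8 x 30 s, 1 x 4 min."""
    return schedule_from_durations([10 / 60] * 12 + [30 / 60] * 8 + [4.0])


def fdg_schedule() -> FrameSchedule:
    """60-min FDG protocol: 12 x 10 s, 8 x 30 s, 6 x 4 min, 6 x 5 min."""
    return schedule_from_durations([10 / 60] * 12 + [30 / 60] * 8 + [4.0] * 6 + [5.0] * 6)
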