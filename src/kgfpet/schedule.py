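"""Dynamic-scan frame schedules.

A dynamic PET acquisition is divided into N contiguous time frames; early
frames are short (to resolve the fast tracer kinetics after injection) and
later frames are long (to accumulate counts once the uptake has saturated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrameSchedule", "fdg_24frame_schedule"]


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, ordered frame timing of a dynamic scan (seconds)."""

    frame_start: np.ndarray
    frame_duration: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start, dtype=float)
        dur = np.asarray(self.frame_duration, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_duration", dur)
        if start.ndim != 1 or dur.shape != start.shape:
            raise ValueError("frame_start and frame_duration must be 1-D and equal length")
        if start.size < 2:
            raise ValueError("a dynamic schedule needs at least 2 frames")
        if np.any(dur <= 0):
            raise ValueError("frame durations must be positive")
        if not np.allclose(start[1:], start[:-1] + dur[:-1]):
            raise ValueError("frames must be contiguous and ordered")

    @property
    def n_frames(self) -> int:
        return int(self.frame_start.size)

    @property
    def frame_end(self) -> np.ndarray:
        return self.frame_start + self.frame_duration

    @property
    def frame_mid(self) -> np.ndarray:
        return self.frame_start + 0.5 * self.frame_duration

    @property
    def total_duration(self) -> float:
        return float(self.frame_end[-1] - self.frame_start[0])

    @classmethod
    def from_durations(cls, durations, t0: float = 0.0) -> "FrameSchedule":
        dur = np.asarray(durations, dtype=float)
        start = t0 + np.concatenate([[0.0], np.cumsum(dur[:-1])])
        return cls(start, dur)


def fdg_24frame_schedule() -> FrameSchedule:
    """The 24-frame, 60-minute FDG schedule: 4x20 s, 4x40 s, 4x60 s, 4x180 s, 8x300 s."""
    durations = [20.0] * 4 + [40.0] * 4 + [60.0] * 4 + [180.0] * 4 + [300.0] * 8
    return FrameSchedule.from_durations(durations)
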