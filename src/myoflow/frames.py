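"""Acquisition frame schedules and framed time-activity curves (TACs).

Dynamic cardiac SPECT list-mode data are re-binned into a short sequence of
frames; every curve in this package (arterial input function, whole-LV or
per-territory myocardium) is a vector of frame-averaged activity
concentrations (kBq/ml) attached to a :class:`FrameSchedule`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrameSchedule",
    "SampledCurve",
    "default_frame_schedule",
    "VALID_REGIONS",
]

#: Region labels used throughout: the arterial input function, the whole-LV
#: ("global") myocardium, and the three coronary vessel territories.
VALID_REGIONS = ("input", "global", "LAD", "LCx", "RCA")


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered, contiguous acquisition frames.

    Parameters
    ----------
    frames
        Sequence of ``(start_s, duration_s)`` pairs, in seconds from
        acquisition start.  Frames must be sorted, non-overlapping and
        contiguous, with strictly positive durations.
    pre_injection_offset_s
        Time between acquisition start and tracer injection (the camera
        starts before the bolus), in seconds.
    """

    frames: tuple[tuple[float, float], ...]
    pre_injection_offset_s: float = 10.0

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ValueError("schedule needs at least one frame")
        frames = tuple((float(s), float(d)) for s, d in self.frames)
        object.__setattr__(self, "frames", frames)
        prev_end = frames[0][0]
        for start, dur in frames:
            if dur <= 0:
                raise ValueError(f"frame duration must be > 0, got {dur}")
            if not np.isclose(start, prev_end, atol=1e-9):
                raise ValueError(
                    "frames must be contiguous and sorted: "
                    f"frame starting at {start} does not follow end {prev_end}"
                )
            prev_end = start + dur

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def starts(self) -> np.ndarray:
        return np.array([s for s, _ in self.frames])

    @property
    def durations(self) -> np.ndarray:
        return np.array([d for _, d in self.frames])

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.durations

    @property
    def mid_times(self) -> np.ndarray:
        return self.starts + 0.5 * self.durations

    @property
    def total_time_s(self) -> float:
        return float(self.ends[-1] - self.starts[0])

    def injection_times(self) -> np.ndarray:
        """Frame start times measured from the injection instant."""
        return self.starts - self.pre_injection_offset_s


def default_frame_schedule(
    n_short: int = 12,
    short_s: float = 10.0,
    n_long: int = 8,
    long_s: float = 30.0,
    pre_injection_offset_s: float = 10.0,
) -> FrameSchedule:
    """Clinical default re-binning: 12 frames of 10 s then 8 frames of 30 s.

    The camera starts 10 s before the bolus injection, so frame times are
    relative to acquisition start with the injection at
    ``+pre_injection_offset_s``.  The default covers the first 360 s of the
    acquisition; pass different frame counts for longer schedules.
    """
    frames: list[tuple[float, float]] = []
    t = 0.0
    for _ in range(n_short):
        frames.append((t, short_s))
        t += short_s
    for _ in range(n_long):
        frames.append((t, long_s))
        t += long_s
    return FrameSchedule(tuple(frames), pre_injection_offset_s)


@dataclass
class SampledCurve:
    """Frame-averaged activity concentration for one region.

    ``values[i]`` is the mean activity concentration (kBq/ml) over frame
    ``i`` of ``schedule``.  Negative or non-finite values are rejected at
    construction: reconstructed concentrations may be noisy but are clipped
    non-negative upstream.
    """

    schedule: FrameSchedule
    values: np.ndarray
    region_label: str = "global"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != self.schedule.n_frames:
            raise ValueError(
                f"expected {self.schedule.n_frames} frame values, "
                f"got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve values must be finite")
        if np.any(self.values < 0):
            raise ValueError("negative activity concentrations rejected")
        if self.region_label not in VALID_REGIONS:
            raise ValueError(
                f"unknown region {self.region_label!r}; expected one of {VALID_REGIONS}"
            )

    def same_schedule(self, other: "SampledCurve") -> bool:
        return self.schedule.frames == other.schedule.frames
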