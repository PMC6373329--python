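"""Acquisition frame schedules, frame binning and 30-min static windows.

A dynamic PET acquisition is reconstructed into contiguous time frames; every
region-level time-activity curve (TAC) lives on such a :class:`FrameSchedule`.
Frames are half-open intervals ``[start, end)`` in seconds, 0-based; the math
downstream works in minutes, conversion happens at this boundary.

The clinical protocol emulated throughout the package is a 120-min scan binned
as ``6x30,3x60,2x120,22x300`` (33 frames), from which 30-min static windows
starting at 30, 40, 50 and 60 min post-injection are assembled.  Windows must
coincide exactly with frame boundaries — there is never silent interpolation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

#: frame schedule of the emulated acquisition protocol
PAPER_SCHEDULE_SPEC = "6x30,3x60,2x120,22x300"

_SPEC_TOKEN = re.compile(r"^\s*(\d+)\s*x\s*(\d+(?:\.\d+)?)\s*$")


class ScheduleError(ValueError):
    """Malformed frame-schedule specification."""


class AlignmentError(ValueError):
    """A requested time point or window does not coincide with frame boundaries."""


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered, contiguous, non-overlapping acquisition frames in seconds."""

    starts_s: tuple[float, ...]
    ends_s: tuple[float, ...]

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts_s, dtype=float)
        ends = np.asarray(self.ends_s, dtype=float)
        if starts.size == 0 or starts.size != ends.size:
            raise ScheduleError("schedule needs matching, non-empty start/end lists")
        if starts[0] != 0.0:
            raise ScheduleError("first frame must start at 0 s")
        if np.any(ends <= starts):
            raise ScheduleError("all frame durations must be positive")
        if starts.size > 1 and not np.allclose(ends[:-1], starts[1:], rtol=0, atol=1e-9):
            raise ScheduleError("frames must be contiguous (end_i == start_{i+1})")

    @classmethod
    def from_spec(cls, spec: str) -> "FrameSchedule":
        """Parse a ``count x duration_s`` comma list, e.g. ``"6x30,3x60"``."""
        durations: list[float] = []
        for token in str(spec).split(","):
            m = _SPEC_TOKEN.match(token)
            if m is None:
                raise ScheduleError(f"cannot parse schedule token {token!r}")
            count, dur = int(m.group(1)), float(m.group(2))
            if count < 1 or dur <= 0:
                raise ScheduleError(f"zero count or duration in token {token!r}")
            durations.extend([dur] * count)
        ends = np.cumsum(durations)
        starts = np.concatenate([[0.0], ends[:-1]])
        return cls(tuple(starts), tuple(ends))

    def to_spec(self) -> str:
        """Run-length-encoded spec string (inverse of :meth:`from_spec`)."""
        durs = self.durations_s
        parts: list[tuple[int, float]] = []
        for d in durs:
            if parts and parts[-1][1] == d:
                parts[-1] = (parts[-1][0] + 1, d)
            else:
                parts.append((1, d))
        return ",".join(f"{c}x{d:g}" for c, d in parts)

    # -- geometry -----------------------------------------------------------

    @property
    def n_frames(self) -> int:
        return len(self.starts_s)

    @property
    def durations_s(self) -> np.ndarray:
        return np.asarray(self.ends_s) - np.asarray(self.starts_s)

    @property
    def durations_min(self) -> np.ndarray:
        return self.durations_s / 60.0

    @property
    def mid_times_s(self) -> np.ndarray:
        return (np.asarray(self.starts_s) + np.asarray(self.ends_s)) / 2.0

    @property
    def mid_times_min(self) -> np.ndarray:
        return self.mid_times_s / 60.0

    @property
    def total_duration_s(self) -> float:
        return float(self.ends_s[-1])

    @property
    def total_duration_min(self) -> float:
        return self.total_duration_s / 60.0

    @property
    def boundaries_s(self) -> np.ndarray:
        return np.concatenate([np.asarray(self.starts_s), [self.ends_s[-1]]])

    def boundary_index(self, t_min: float) -> int:
        """Index of the frame boundary at ``t_min`` minutes; AlignmentError if none."""
        t_s = t_min * 60.0
        bounds = self.boundaries_s
        hits = np.nonzero(np.isclose(bounds, t_s, rtol=0, atol=1e-6))[0]
        if hits.size == 0:
            raise AlignmentError(
                f"{t_min} min is not a frame boundary of schedule {self.to_spec()!r}"
            )
        return int(hits[0])

    def frames_between(self, start_min: float, end_min: float) -> np.ndarray:
        """Indices of the consecutive frames exactly covering [start, end) min."""
        i0 = self.boundary_index(start_min)
        i1 = self.boundary_index(end_min)
        if i1 <= i0:
            raise AlignmentError("window end must come after window start")
        return np.arange(i0, i1)


@dataclass(frozen=True)
class TimeActivityCurve:
    """Frame-averaged activity concentrations (kBq/mL) for one region."""

    region: str
    schedule: FrameSchedule
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size != self.schedule.n_frames:
            raise ValueError(
                f"TAC {self.region!r}: {vals.size} values for "
                f"{self.schedule.n_frames} frames"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"TAC {self.region!r} contains non-finite values")

    @property
    def mid_times_min(self) -> np.ndarray:
        return self.schedule.mid_times_min

    def truncated(self, t_end_min: float) -> "TimeActivityCurve":
        """Drop frames at or beyond ``t_end_min`` (must be a frame boundary)."""
        i = self.schedule.boundary_index(t_end_min)
        if i == 0:
            raise AlignmentError("truncation would leave no frames")
        sched = FrameSchedule(self.schedule.starts_s[:i], self.schedule.ends_s[:i])
        return TimeActivityCurve(self.region, sched, self.values[:i])


@dataclass(frozen=True)
class StaticWindow:
    """One 30-min (by default) static acquisition assembled from whole frames."""

    start_min: float
    end_min: float
    frame_indices: tuple[int, ...]
    means: dict[str, float]  # region -> duration-weighted mean concentration


def build_schedule(spec: str) -> FrameSchedule:
    """Build a :class:`FrameSchedule` from a ``count x duration_s`` spec string."""
    return FrameSchedule.from_spec(spec)


def _piecewise_linear_integral(t: np.ndarray, c: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Integral of the piecewise-linear curve (t, c) from t[0] to each x (exact)."""
    F = np.concatenate([[0.0], cumulative_trapezoid(c, t)])
    i = np.clip(np.searchsorted(t, x, side="right") - 1, 0, t.size - 2)
    cx = np.interp(x, t, c)
    return F[i] + (x - t[i]) * (c[i] + cx) / 2.0


def bin_to_frames(
    t_min: np.ndarray, curve: np.ndarray, schedule: FrameSchedule, region: str = ""
) -> TimeActivityCurve:
    """Average a continuous curve over each frame (trapezoidal, exact for
    piecewise-linear curves sampled on ``t_min``)."""
    t = np.asarray(t_min, dtype=float)
    c = np.asarray(curve, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing with >= 2 points")
    if t[0] > 0.0 or t[-1] < schedule.total_duration_min - 1e-9:
        raise ValueError("fine grid must span the full schedule")
    bounds_min = schedule.boundaries_s / 60.0
    I = _piecewise_linear_integral(t, c, bounds_min)
    vals = np.diff(I) / schedule.durations_min
    return TimeActivityCurve(region, schedule, vals)


def extract_window(
    tacs: dict[str, TimeActivityCurve], start_min: float, duration_min: float = 30.0
) -> StaticWindow:
    """Duration-weighted mean concentration per region over one static window.

    The window must start and end exactly on frame boundaries of the shared
    schedule; otherwise an :class:`AlignmentError` is raised.
    """
    if not tacs:
        raise ValueError("no TACs supplied")
    first = next(iter(tacs.values())).schedule
    for tac in tacs.values():
        if tac.schedule.starts_s != first.starts_s or tac.schedule.ends_s != first.ends_s:
            raise ValueError("all TACs must share one schedule")
    end_min = start_min + duration_min
    idx = first.frames_between(start_min, end_min)
    w = first.durations_s[idx]
    w = w / w.sum()
    means = {name: float(np.dot(w, tac.values[idx])) for name, tac in tacs.items()}
    return StaticWindow(float(start_min), float(end_min), tuple(int(i) for i in idx), means)


def truncate_to(
    tacs: dict[str, TimeActivityCurve], t_end_min: float
) -> dict[str, TimeActivityCurve]:
    """Truncate every TAC to [0, t_end_min); t_end must be a frame boundary."""
    return {name: tac.truncated(t_end_min) for name, tac in tacs.items()}
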