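"""Shift calendar: clinical working hours vs continuous laboratory operation.

Simulation time is measured in fractional *days*; durations are in *hours*.
Day 0 is a Monday (fixed), so a weekly pattern is fully determined by the
time-of-week.  Internally the calendar works in hours-of-week on a 168 h
cycle with a precomputed sorted list of open intervals, so every query is
O(number of weekly windows) arithmetic with no date objects involved.

Atomic tasks must fit entirely inside one open window and are deferred to
the next window that can hold them; non-atomic tasks start at the next open
instant and accrue service only while the calendar is open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

HOURS_PER_WEEK = 168.0

#: weekday indices, Monday = 0 (simulation day 0 is a Monday)
WEEKDAYS = frozenset(range(5))
ALL_DAYS = frozenset(range(7))


@dataclass(frozen=True)
class ShiftPattern:
    """Weekly availability pattern for a resource pool.

    Parameters
    ----------
    schedule_class:
        ``"clinical_shift"`` or ``"continuous"``.
    daily_windows:
        Open intervals ``(start_hour, end_hour)`` within a 24 h day,
        non-overlapping, ``0 <= start < end <= 24``.
    working_days:
        Weekday indices (Monday = 0) on which the windows apply.
    """

    schedule_class: str = "clinical_shift"
    daily_windows: tuple = ((8.0, 17.0),)
    working_days: frozenset = field(default_factory=lambda: WEEKDAYS)

    # derived, populated in __post_init__
    _week_intervals: tuple = field(init=False, repr=False, compare=False)
    _cum_open: tuple = field(init=False, repr=False, compare=False)
    _weekly_open: float = field(init=False, repr=False, compare=False)
    _max_window: float = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        windows = sorted(tuple(map(float, w)) for w in self.daily_windows)
        prev_end = -1.0
        for s, e in windows:
            if not (0.0 <= s < e <= 24.0):
                raise ValueError(f"invalid daily window ({s}, {e})")
            if s < prev_end:
                raise ValueError("overlapping daily windows")
            prev_end = e
        days = sorted(self.working_days)
        if any(d not in range(7) for d in days):
            raise ValueError("working_days must be weekday indices 0-6")
        intervals = tuple(
            (24.0 * d + s, 24.0 * d + e) for d in days for (s, e) in windows
        )
        cum = [0.0]
        for a, b in intervals:
            cum.append(cum[-1] + (b - a))
        object.__setattr__(self, "daily_windows", tuple(windows))
        object.__setattr__(self, "working_days", frozenset(days))
        object.__setattr__(self, "_week_intervals", intervals)
        object.__setattr__(self, "_cum_open", tuple(cum))
        object.__setattr__(self, "_weekly_open", cum[-1])
        object.__setattr__(
            self, "_max_window", max((b - a for a, b in intervals), default=0.0)
        )

    # -- constructors ----------------------------------------------------

    @staticmethod
    def continuous() -> "ShiftPattern":
        """24/7 operation (single (0, 24) window, all seven days)."""
        return ShiftPattern("continuous", ((0.0, 24.0),), ALL_DAYS)

    @staticmethod
    def clinical(start: float = 8.0, end: float = 17.0) -> "ShiftPattern":
        """Standard clinical shift, Monday-Friday."""
        return ShiftPattern("clinical_shift", ((start, end),), WEEKDAYS)

    # -- core queries (hours-of-week domain) -----------------------------

    @property
    def is_continuous(self) -> bool:
        return self._weekly_open == HOURS_PER_WEEK

    @property
    def max_window_hours(self) -> float:
        """Length of the longest single open window (caps atomic tasks)."""
        return self._max_window

    def _open_before(self, o: float) -> float:
        """Open hours in [0, o) of the week cycle."""
        total = 0.0
        for (a, b), c in zip(self._week_intervals, self._cum_open):
            if o <= a:
                return c
            if o < b:
                return c + (o - a)
        return self._weekly_open

    def open_hours_until(self, t_days: float) -> float:
        """Cumulative open hours from time 0 to ``t_days``."""
        h = t_days * 24.0
        weeks, o = divmod(h, HOURS_PER_WEEK)
        return weeks * self._weekly_open + self._open_before(o)

    def available_hours(self, t0: float, t1: float) -> float:
        """Scheduled open hours in the interval ``[t0, t1)`` (days in)."""
        if t1 < t0:
            raise ValueError("t0 must not exceed t1")
        return self.open_hours_until(t1) - self.open_hours_until(t0)

    def next_open(self, t_days: float) -> float:
        """Earliest open instant >= ``t_days``."""
        if self.is_continuous:
            return t_days
        h = t_days * 24.0
        weeks, o = divmod(h, HOURS_PER_WEEK)
        for a, b in self._week_intervals:
            if o < b:
                return (weeks * HOURS_PER_WEEK + max(o, a)) / 24.0
        # wrap to next week's first window
        a0 = self._week_intervals[0][0]
        return ((weeks + 1) * HOURS_PER_WEEK + a0) / 24.0

    def add_open_hours(self, t_days: float, hours: float) -> float:
        """Time at which ``hours`` of open time have accrued from ``t_days``.

        Used for non-atomic tasks, which pause while the calendar is closed.
        """
        if hours < 0:
            raise ValueError("hours must be non-negative")
        if self.is_continuous:
            return t_days + hours / 24.0
        if self._weekly_open <= 0:
            raise ValueError("pattern has no open time")
        h = t_days * 24.0
        weeks, o = divmod(h, HOURS_PER_WEEK)
        remaining = hours + self._open_before(o)
        full_weeks, remaining = divmod(remaining, self._weekly_open)
        # locate instant where cumulative open time within the week = remaining
        for (a, b), c in zip(self._week_intervals, self._cum_open):
            if remaining <= (b - a) + c:
                end_o = a + (remaining - c)
                return ((weeks + full_weeks) * HOURS_PER_WEEK + end_o) / 24.0
        # remaining == weekly_open exactly: end of last window
        end_o = self._week_intervals[-1][1]
        return ((weeks + full_weeks) * HOURS_PER_WEEK + end_o) / 24.0

    def fit_atomic(self, t_days: float, hours: float) -> float:
        """Earliest start >= ``t_days`` so that ``hours`` fits in one window."""
        if hours > self._max_window + 1e-12:
            raise ValueError(
                f"atomic task of {hours} h exceeds longest window "
                f"({self._max_window} h)"
            )
        h = t_days * 24.0
        weeks, o = divmod(h, HOURS_PER_WEEK)
        for a, b in self._week_intervals:
            start = max(o, a)
            if start + hours <= b + 1e-12:
                return (weeks * HOURS_PER_WEEK + start) / 24.0
        a0 = self._week_intervals[0][0]
        return ((weeks + 1) * HOURS_PER_WEEK + a0) / 24.0


def available_hours(pattern: ShiftPattern, t0: float, t1: float) -> float:
    """Total scheduled open hours of ``pattern`` in ``[t0, t1)`` (days)."""
    return pattern.available_hours(t0, t1)


def task_start_time(
    now: float, duration_hours: float, pattern: ShiftPattern, atomic: bool
) -> float:
    """Earliest feasible service start for a task arriving at ``now``.

    Atomic tasks are deferred until ``[start, start + duration]`` fits inside
    a single open window (no fragmentation across shift boundaries);
    non-atomic tasks start at the next open instant and simply pause while
    the calendar is closed.
    """
    if duration_hours <= 0:
        raise ValueError("duration must be positive")
    if atomic:
        return pattern.fit_atomic(now, duration_hours)
    return pattern.next_open(now)


def service_end_time(
    start: float, duration_hours: float, pattern: ShiftPattern, atomic: bool
) -> float:
    """Completion time of a task that begins service at ``start``."""
    if atomic or pattern.is_continuous:
        return start + duration_hours / 24.0
    return pattern.add_open_hours(start, duration_hours)
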