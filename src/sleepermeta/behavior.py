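"""Sleep metrics from per-minute Drosophila activity traces.

Sleep is the standard fly definition: any maximal run of >= 5 consecutive
minutes with zero beam crossings. From the resulting per-minute sleep state
this module derives interval totals, deprivation efficiency, activation /
rebound deltas against the matched interval 24 h earlier, nested cumulative
sleep-history windows (1..12 h before sampling) and matched-baseline rebound
windows (1..12 h after sampling minus the same clock interval a day before).

All intervals are half-open ``[start, end)`` in minutes of experiment time
(minute 0 = lights-on of the first recorded day); ZT of minute t is
``t % 1440``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

MINUTES_PER_DAY = 1440
DEFAULT_MIN_BOUT = 5
MAX_WINDOW_HOURS = 12

BEFORE = "before_sampling"
AFTER = "after_sampling"


@dataclass
class ActivityTrace:
    """One fly's per-minute beam-crossing counts.

    ``t0`` is the experiment-time minute of the first bin (equals the ZT of
    the first bin for recordings starting on day 0). The recording must span
    whole 24 h cycles in 1-minute bins.
    """

    fly_id: str
    condition_id: str
    counts: np.ndarray
    t0: int = 0
    bin_minutes: int = 1
    temperature_c: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.bin_minutes != 1:
            raise ValueError("only 1-minute bins are supported")
        self.counts = np.asarray(self.counts)
        if self.counts.size == 0:
            raise ValueError(f"fly {self.fly_id}: empty trace")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError(f"fly {self.fly_id}: non-integer activity counts")
            self.counts = as_int
        if (self.counts < 0).any():
            raise ValueError(f"fly {self.fly_id}: negative activity counts")

    @property
    def days(self) -> int:
        """Whole recorded 24 h cycles (partial trailing days are allowed)."""
        return self.counts.size // MINUTES_PER_DAY

    @property
    def t_end(self) -> int:
        return self.t0 + self.counts.size


@dataclass
class SleepSeries:
    """Per-minute sleep state and the sleep bouts it decomposes into.

    ``bouts`` is a list of ``(start_minute, duration)`` in experiment time;
    bouts are disjoint maximal zero-activity runs of at least the minimum
    bout length.
    """

    fly_id: str
    condition_id: str
    asleep: np.ndarray
    bouts: list[tuple[int, int]]
    t0: int = 0

    @property
    def total_minutes(self) -> int:
        return int(self.asleep.sum())

    @property
    def t_end(self) -> int:
        return self.t0 + self.asleep.size


@dataclass
class SleepWindows:
    """Mean cumulative sleep in nested 1..12 h windows anchored at sampling."""

    condition_id: str
    direction: str  # before_sampling | after_sampling
    window_hours: np.ndarray
    minutes_asleep: np.ndarray
    n_flies: np.ndarray = field(default=None)  # flies entering each window mean


@dataclass
class ReboundWindows:
    """Post-sampling cumulative sleep minus matched-ZT baseline, per window."""

    condition_id: str
    window_hours: np.ndarray
    rebound_minutes: np.ndarray


def _zero_runs(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Starts and (exclusive) ends of maximal zero-count runs, as indices."""
    zero = np.concatenate(([0], (counts == 0).astype(np.int8), [0]))
    edges = np.flatnonzero(np.diff(zero))
    return edges[0::2], edges[1::2]


def call_sleep(trace: ActivityTrace, min_bout_minutes: int = DEFAULT_MIN_BOUT) -> SleepSeries:
    """Call per-minute sleep state from an activity trace.

    A minute is asleep iff it lies inside a maximal run of zero-count minutes
    of length >= ``min_bout_minutes`` (default 5, the standard fly criterion).
    The full maximal run is one bout; runs are never partitioned.
    """
    if min_bout_minutes < 1:
        raise ValueError("min_bout_minutes must be >= 1")
    starts, ends = _zero_runs(trace.counts)
    keep = (ends - starts) >= min_bout_minutes
    asleep = np.zeros(trace.counts.size, dtype=bool)
    bouts: list[tuple[int, int]] = []
    for s, e in zip(starts[keep], ends[keep]):
        asleep[s:e] = True
        bouts.append((int(s) + trace.t0, int(e - s)))
    return SleepSeries(
        fly_id=trace.fly_id,
        condition_id=trace.condition_id,
        asleep=asleep,
        bouts=bouts,
        t0=trace.t0,
    )


def total_sleep(series: SleepSeries, t_start: int, t_end: int) -> int:
    """Minutes asleep in the half-open experiment-time interval [t_start, t_end)."""
    if t_start >= t_end:
        raise ValueError("interval start must precede end")
    i0 = t_start - series.t0
    i1 = t_end - series.t0
    if i0 < 0 or i1 > series.asleep.size:
        raise ValueError(
            f"interval [{t_start}, {t_end}) outside recording "
            f"[{series.t0}, {series.t_end})"
        )
    return int(series.asleep[i0:i1].sum())


def sd_efficiency(
    series: SleepSeries,
    baseline: SleepSeries,
    interval: tuple[int, int],
) -> float:
    """Fraction of matched-baseline sleep abolished during a deprivation interval.

    Returns ``1 - sleep(interval) / sleep(interval 24 h earlier)``. Flies pass
    the deprivation filter iff the fraction is strictly greater than 0.90.
    With zero baseline sleep the efficiency is 1.0 if the fly also slept zero
    minutes during deprivation, otherwise 0.0 (the fly cannot demonstrate
    deprivation against an empty baseline and fails the filter).
    """
    t_start, t_end = interval
    sd_sleep = total_sleep(series, t_start, t_end)
    base_sleep = total_sleep(baseline, t_start - MINUTES_PER_DAY, t_end - MINUTES_PER_DAY)
    if base_sleep == 0:
        return 1.0 if sd_sleep == 0 else 0.0
    return 1.0 - sd_sleep / base_sleep


def passes_sd_filter(efficiency: float, threshold: float = 0.90) -> bool:
    """Strict ">90% of baseline sleep deprived" inclusion rule."""
    return efficiency > threshold


def sleep_change(series: SleepSeries, interval: tuple[int, int]) -> int:
    """Sleep during an interval minus sleep in the matched interval 24 h earlier.

    Used both for activation deltas (sleep during a manipulation vs the same
    clock interval the previous day) and rebound deltas.
    """
    t_start, t_end = interval
    if t_start - MINUTES_PER_DAY < series.t0:
        raise ValueError("recording does not cover the matched interval 24 h earlier")
    now = total_sleep(series, t_start, t_end)
    before = total_sleep(series, t_start - MINUTES_PER_DAY, t_end - MINUTES_PER_DAY)
    return now - before


def cumulative_windows(
    series_per_fly: list[SleepSeries],
    t_sample: int,
    direction: str = "before",
    condition_id: str | None = None,
    max_hours: int = MAX_WINDOW_HOURS,
) -> SleepWindows:
    """Mean cumulative sleep over nested 1..max_hours windows at ``t_sample``.

    For k = 1..12 the window is the k full hours immediately before (or after)
    the sampling minute — nested totals, not rolling bins. Means are taken
    over flies; a fly whose recording does not fully cover a window is
    excluded from that window's mean rather than truncated or imputed.
    """
    if direction in ("before", BEFORE):
        dir_label = BEFORE
    elif direction in ("after", AFTER):
        dir_label = AFTER
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if not series_per_fly:
        raise ValueError("at least one fly is required")
    if condition_id is None:
        condition_id = series_per_fly[0].condition_id
    hours = np.arange(1, max_hours + 1)
    means = np.empty(max_hours, dtype=float)
    n_flies = np.empty(max_hours, dtype=int)
    for i, k in enumerate(hours):
        if dir_label == BEFORE:
            lo, hi = t_sample - 60 * int(k), t_sample
        else:
            lo, hi = t_sample, t_sample + 60 * int(k)
        vals = [
            total_sleep(s, lo, hi)
            for s in series_per_fly
            if s.t0 <= lo and hi <= s.t_end
        ]
        if not vals:
            raise ValueError(
                f"{condition_id}: no fly covers the {k} h window at t={t_sample}"
            )
        means[i] = float(np.mean(vals))
        n_flies[i] = len(vals)
    return SleepWindows(condition_id, dir_label, hours, means, n_flies)


def rebound_windows(post: SleepWindows, baseline: SleepWindows) -> ReboundWindows:
    """Sleep rebound per window: post-sampling cumulative sleep minus the
    matched-ZT baseline cumulative sleep (computed 24 h earlier)."""
    if post.direction != AFTER:
        raise ValueError("post windows must be after_sampling")
    if post.window_hours.size != baseline.window_hours.size:
        raise ValueError("window vectors differ in length")
    return ReboundWindows(
        condition_id=post.condition_id,
        window_hours=post.window_hours.copy(),
        rebound_minutes=post.minutes_asleep - baseline.minutes_asleep,
    )


def exclude_dead(
    traces: list[ActivityTrace], min_quiet_hours: int = 12
) -> tuple[list[ActivityTrace], list[str]]:
    """Drop flies that look dead: no activity over a trailing span of at least
    ``min_quiet_hours`` while at least one other fly is active in that span.

    Returns (kept traces, dropped fly ids). Mirrors the standard behavioural
    inspection used before averaging or collecting flies.
    """
    if len(traces) < 2:
        return list(traces), []
    quiet_min = min_quiet_hours * 60
    trailing = []
    for tr in traces:
        nz = np.flatnonzero(tr.counts)
        trailing.append(tr.counts.size if nz.size == 0 else tr.counts.size - 1 - nz[-1])
    kept, dropped = [], []
    for i, tr in enumerate(traces):
        tz = trailing[i]
        if tz < quiet_min:
            kept.append(tr)
            continue
        span_start = tr.t_end - tz
        others_active = any(
            other.counts[max(0, span_start - other.t0): tr.t_end - other.t0].sum() > 0
            for j, other in enumerate(traces)
            if j != i and other.t_end > span_start
        )
        if others_active:
            dropped.append(tr.fly_id)
        else:
            kept.append(tr)
    if dropped:
        warnings.warn(f"excluded {len(dropped)} dead flies: {sorted(dropped)}")
    return kept, dropped
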