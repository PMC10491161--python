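"""Sleep scoring and sleep metrics for per-minute DAM activity counts.

Sleep is scored with the field's standard rule: a fly is asleep during any
maximal run of zero-count minutes lasting at least 5 minutes.  On top of the
minute-level score this module extracts sleep bouts, the latency of sleep
onset after dusk (lights-off), windowed sleep amounts, baseline-vs-manipulation
sleep changes, and binned cohort sleep profiles.

Onset after dusk uses a "re-score from dusk" rule: the night segment from
dusk onward is scored on its own, so a quiescence run that began before dusk
and continues past it yields an onset of exactly dusk.  This bounds onset
below by ZT12 and matches the floor effect dusk imposes on the metric; the
alternative (exclude straddling bouts and take the first bout starting after
dusk) is available via ``straddle="exclude"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dam import MINUTES_PER_DAY, FlySeries

DEFAULT_SLEEP_THRESHOLD_MIN = 5


@dataclass(frozen=True)
class WindowSpec:
    """Half-open ZT window [start, end); ZT0-6/ZT6-12 then partition the day."""

    start_zt_hr: float
    end_zt_hr: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start_zt_hr < self.end_zt_hr <= 24):
            raise ValueError(f"window must satisfy 0 <= start < end <= 24, got {self}")

    @property
    def start_min(self) -> int:
        return int(round(self.start_zt_hr * 60))

    @property
    def end_min(self) -> int:
        return int(round(self.end_zt_hr * 60))


MORNING = WindowSpec(0, 6, "morning")
AFTERNOON = WindowSpec(6, 12, "afternoon")
NIGHT = WindowSpec(12, 24, "night")


@dataclass
class Bout:
    """One sleep bout within a protocol day, in ZT minutes from that day's ZT0."""

    start_min: int
    end_min: int  # exclusive
    day: int = 0
    continues_from_prev_day: bool = False
    continues_into_next_day: bool = False

    @property
    def duration_min(self) -> int:
        return self.end_min - self.start_min


@dataclass
class SleepBoutSet:
    fly_id: str
    bouts: list[Bout] = field(default_factory=list)

    def for_day(self, day: int) -> list[Bout]:
        return [b for b in self.bouts if b.day == day]

    def total_sleep_min(self) -> int:
        return sum(b.duration_min for b in self.bouts)


def _zero_runs(is_zero: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, end) index pairs."""
    if len(is_zero) == 0:
        return []
    padded = np.concatenate(([False], is_zero, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return list(zip(starts.tolist(), ends.tolist()))


def score_sleep(
    minutes: np.ndarray,
    threshold_min: int = DEFAULT_SLEEP_THRESHOLD_MIN,
    flagged: np.ndarray | None = None,
) -> np.ndarray:
    """Minute-level sleep indicator via the inactivity-run rule.

    A minute is sleep iff it lies in a maximal run of zero-count, unflagged
    minutes of length >= ``threshold_min``.  Flagged minutes (bad monitor
    status) break runs and are never scored as sleep.
    """
    minutes = np.asarray(minutes)
    if threshold_min < 1:
        raise ValueError("threshold_min must be >= 1")
    if np.any(minutes < 0):
        raise ValueError("counts must be non-negative")
    quiescent = minutes == 0
    if flagged is not None:
        quiescent &= ~np.asarray(flagged, dtype=bool)
    asleep = np.zeros(len(minutes), dtype=bool)
    for start, end in _zero_runs(quiescent):
        if end - start >= threshold_min:
            asleep[start:end] = True
    return asleep


def extract_bouts(
    indicator: np.ndarray,
    fly_id: str = "",
    day_minutes: int = MINUTES_PER_DAY,
) -> SleepBoutSet:
    """Turn a sleep indicator into bouts, splitting runs at day boundaries.

    A run crossing a boundary becomes two bouts with the linkage recorded on
    both fragments, so per-day sums and whole-series sums agree.
    """
    indicator = np.asarray(indicator, dtype=bool)
    bouts: list[Bout] = []
    for start, end in _zero_runs(indicator):
        first_day, last_day = start // day_minutes, (end - 1) // day_minutes
        for day in range(first_day, last_day + 1):
            lo = max(start, day * day_minutes)
            hi = min(end, (day + 1) * day_minutes)
            bouts.append(
                Bout(
                    start_min=lo - day * day_minutes,
                    end_min=hi - day * day_minutes,
                    day=day,
                    continues_from_prev_day=(day > first_day),
                    continues_into_next_day=(day < last_day),
                )
            )
    return SleepBoutSet(fly_id=fly_id, bouts=bouts)


def sleep_onset_after_dusk(
    minutes: np.ndarray,
    dusk_zt_hr: float = 12.0,
    threshold_min: int = DEFAULT_SLEEP_THRESHOLD_MIN,
    flagged: np.ndarray | None = None,
    straddle: str = "dusk",
) -> float | None:
    """ZT (hours) of the first qualifying sleep bout at or after dusk.

    ``minutes`` is one protocol day (1440 values).  With ``straddle="dusk"``
    (default) the segment from dusk to the end of the day is re-scored, so a
    quiescence run straddling dusk gives onset exactly at dusk.  With
    ``straddle="exclude"`` only runs beginning strictly after dusk qualify.
    Returns ``None`` when the fly never sleeps after dusk.
    """
    if not 0 <= dusk_zt_hr < 24:
        raise ValueError(f"dusk_zt_hr must lie in [0, 24), got {dusk_zt_hr}")
    if straddle not in ("dusk", "exclude"):
        raise ValueError(f"straddle must be 'dusk' or 'exclude', got {straddle!r}")
    minutes = np.asarray(minutes)
    dusk_min = int(round(dusk_zt_hr * 60))
    if straddle == "dusk":
        seg = minutes[dusk_min:]
        seg_flag = None if flagged is None else np.asarray(flagged)[dusk_min:]
        ind = score_sleep(seg, threshold_min, seg_flag)
        runs = _zero_runs(ind)
        if not runs:
            return None
        return (dusk_min + runs[0][0]) / 60.0
    ind = score_sleep(minutes, threshold_min, flagged)
    for start, end in _zero_runs(ind):
        if start > dusk_min:
            return start / 60.0
    return None


def sleep_amount(indicator: np.ndarray, window: WindowSpec) -> int:
    """Minutes of sleep within one ZT window of a single scored day."""
    indicator = np.asarray(indicator, dtype=bool)
    return int(indicator[window.start_min : window.end_min].sum())


def sleep_change(
    manipulation_day: np.ndarray,
    baseline_day: np.ndarray,
    window: WindowSpec,
) -> int:
    """Change in windowed sleep, manipulation minus baseline (negative = loss)."""
    return sleep_amount(manipulation_day, window) - sleep_amount(baseline_day, window)


def sleep_profile(
    indicators: np.ndarray,
    bin_minutes: int = 30,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cohort sleep profile: minutes asleep per bin, averaged over flies.

    ``indicators`` has shape (n_flies, n_minutes) with n_minutes a multiple of
    ``bin_minutes``.  Returns ``(bin_start_zt_hr, mean_per_bin, per_fly)``
    where ``per_fly`` has shape (n_flies, n_bins) in minutes per bin.
    """
    indicators = np.atleast_2d(np.asarray(indicators, dtype=float))
    if indicators.shape[0] < 1:
        raise ValueError("need at least one fly")
    n_min = indicators.shape[1]
    if n_min % bin_minutes != 0:
        raise ValueError("series length must be a multiple of bin_minutes")
    nbins = n_min // bin_minutes
    per_fly = indicators.reshape(indicators.shape[0], nbins, bin_minutes).sum(axis=2)
    starts = (np.arange(nbins) * bin_minutes % MINUTES_PER_DAY) / 60.0
    return starts, per_fly.mean(axis=0), per_fly


def is_dead(series: FlySeries, final_hours: float = 12.0) -> bool:
    """Dead-fly filter: no beam breaks over the final stretch of the protocol."""
    n = int(round(final_hours * 60))
    return bool(series.counts[-n:].sum() == 0)


def score_series(series: FlySeries, threshold_min: int = DEFAULT_SLEEP_THRESHOLD_MIN) -> np.ndarray:
    """Score a whole FlySeries, honoring its flagged-minute mask."""
    return score_sleep(series.counts, threshold_min, series.flagged)
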