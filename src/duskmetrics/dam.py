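"""Reading, writing and zeitgeber alignment of Trikinetics DAM monitor files.

The Drosophila Activity Monitor (DAM) writes one tab-separated line per
minute per monitor: a reading index, a date (``"9 Sep 25"``), a time
(``"08:00:00"``), a status code, six extended-status fields, and 32 beam-break
counts (one per fly tube).  This module parses that DAM2 dialect into
:class:`MonitorData`, writes it back verbatim, and converts a single channel
into a :class:`FlySeries` of whole protocol days indexed by zeitgeber time
(ZT; hours since lights-on, so ZT0 = dawn and ZT12 = dusk in 12:12 LD).

Timestamps are treated as local, monotone, 1-minute-resolution wall-clock
times; daylight-saving transitions are out of scope.  In constant darkness
(DD) the same mapping yields circadian time (CT) projected from the prior
entrained phase, because lights-on stays declared in the schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

N_CHANNELS = 32
N_EXTENDED = 6
N_COLUMNS = 4 + N_EXTENDED + N_CHANNELS  # index, date, time, status, ext x6, counts x32
MINUTES_PER_DAY = 1440
OK_STATUS = 1

_DATE_FMT = "%d %b %y"


class DAMFormatError(ValueError):
    """A DAM2 line could not be parsed; message names line and column."""


class ScheduleCoverageError(ValueError):
    """The declared light schedule does not cover the data's time span."""


@dataclass
class ParseReport:
    """Bookkeeping produced while reading a monitor file."""

    n_rows: int = 0
    flagged_rows: list[int] = field(default_factory=list)  # 0-based rows, status != 1
    timestamp_gaps: list[int] = field(default_factory=list)  # rows preceded by a gap > 60 s


@dataclass
class MonitorData:
    """Per-minute beam-break counts for the 32 channels of one monitor."""

    reading_index: np.ndarray  # (n,) int
    timestamps: pd.DatetimeIndex  # (n,) 1-min resolution, strictly increasing
    status: np.ndarray  # (n,) int, recorded verbatim
    extended: np.ndarray  # (n, 6) int extended-status fields
    counts: np.ndarray  # (n, 32) non-negative int
    report: ParseReport = field(default_factory=ParseReport)

    channel_ids = tuple(range(1, N_CHANNELS + 1))

    def __post_init__(self) -> None:
        if self.counts.ndim != 2 or self.counts.shape[1] != N_CHANNELS:
            raise ValueError(f"counts must be (n, {N_CHANNELS})")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def flagged(self) -> np.ndarray:
        """Boolean mask of rows whose status code is not the OK value (1)."""
        return self.status != OK_STATUS


@dataclass
class DaySpec:
    """One protocol day: light regime, temperature epoch and analysis tag."""

    regime: str = "LD"  # "LD" or "DD"
    temperature_c: float = 22.0
    tag: str = "baseline"  # "baseline" | "manipulation" | "discard"

    def __post_init__(self) -> None:
        if self.regime not in ("LD", "DD"):
            raise ValueError(f"regime must be LD or DD, got {self.regime!r}")


@dataclass
class LightSchedule:
    """Lights-on time, photoperiod and the per-day protocol structure.

    ``lights_on_hr`` is the wall-clock hour of lights-on (ZT0).  In DD days the
    ZT/CT mapping continues unchanged from the entrained phase.
    """

    lights_on_hr: float = 8.0
    photoperiod_hr: float = 12.0
    days: list[DaySpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 < self.photoperiod_hr < 24:
            raise ValueError("photoperiod must lie in (0, 24)")

    def zt_hours(self, timestamps: pd.DatetimeIndex) -> np.ndarray:
        """Map wall-clock timestamps to ZT in [0, 24)."""
        clock_hr = (
            timestamps.hour + timestamps.minute / 60.0 + timestamps.second / 3600.0
        )
        return np.asarray((clock_hr - self.lights_on_hr) % 24.0)

    def day_spec(self, day_index: int) -> DaySpec:
        if not self.days:
            return DaySpec()
        if day_index >= len(self.days):
            raise ScheduleCoverageError(
                f"schedule declares {len(self.days)} days but day {day_index} requested"
            )
        return self.days[day_index]


@dataclass
class FlySeries:
    """Whole protocol days of per-minute counts for one fly, ZT-indexed.

    ``counts`` has one entry per minute over ``n_days`` consecutive days;
    minute ``i`` is at ZT ``(i % 1440) / 60`` hours.  ``flagged`` marks minutes
    whose monitor status was not OK; metrics exclude them.
    """

    fly_id: str
    counts: np.ndarray  # (n_days * 1440,) int
    day_tags: list[str]
    regimes: list[str]
    flagged: np.ndarray | None = None
    dropped_leading_min: int = 0
    dropped_trailing_min: int = 0

    def __post_init__(self) -> None:
        if len(self.counts) % MINUTES_PER_DAY != 0:
            raise ValueError("series length must be a multiple of 1440 minutes")
        if self.flagged is None:
            self.flagged = np.zeros(len(self.counts), dtype=bool)

    @property
    def n_days(self) -> int:
        return len(self.counts) // MINUTES_PER_DAY

    @property
    def zt_hours(self) -> np.ndarray:
        return (np.arange(len(self.counts)) % MINUTES_PER_DAY) / 60.0

    def day(self, i: int) -> np.ndarray:
        return self.counts[i * MINUTES_PER_DAY : (i + 1) * MINUTES_PER_DAY]

    def day_flagged(self, i: int) -> np.ndarray:
        return self.flagged[i * MINUTES_PER_DAY : (i + 1) * MINUTES_PER_DAY]


def read_dam_monitor(path, dialect: str = "DAM2") -> MonitorData:
    """Parse a DAM2 monitor file into :class:`MonitorData`.

    Malformed lines raise :class:`DAMFormatError` naming the line (1-based)
    and column; rows with a status code other than 1 are kept and flagged in
    ``data.report``.
    """
    if dialect != "DAM2":
        raise ValueError(f"unsupported dialect {dialect!r}")
    idx, stamps, status, extended, counts = [], [], [], [], []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < N_COLUMNS:
                raise DAMFormatError(
                    f"line {line_no}: expected {N_COLUMNS} columns "
                    f"(fewer than 32 count channels), got {len(parts)}"
                )
            try:
                idx.append(int(parts[0]))
            except ValueError:
                raise DAMFormatError(f"line {line_no}, column 1: bad reading index {parts[0]!r}")
            try:
                stamps.append(datetime.strptime(f"{parts[1]} {parts[2]}", f"{_DATE_FMT} %H:%M:%S"))
            except ValueError:
                raise DAMFormatError(
                    f"line {line_no}, columns 2-3: bad timestamp {parts[1]!r} {parts[2]!r}"
                )
            row_ints = []
            for col, tok in enumerate(parts[3:N_COLUMNS], start=4):
                try:
                    row_ints.append(int(tok))
                except ValueError:
                    raise DAMFormatError(
                        f"line {line_no}, column {col}: non-integer value {tok!r}"
                    )
            status.append(row_ints[0])
            extended.append(row_ints[1 : 1 + N_EXTENDED])
            row_counts = row_ints[1 + N_EXTENDED :]
            if any(c < 0 for c in row_counts):
                bad = next(i for i, c in enumerate(row_counts) if c < 0)
                raise DAMFormatError(
                    f"line {line_no}, column {4 + N_EXTENDED + bad}: negative count"
                )
            counts.append(row_counts)

    data = MonitorData(
        reading_index=np.asarray(idx, dtype=np.int64),
        timestamps=pd.DatetimeIndex(stamps),
        status=np.asarray(status, dtype=np.int64),
        extended=np.asarray(extended, dtype=np.int64).reshape(-1, N_EXTENDED),
        counts=np.asarray(counts, dtype=np.int64).reshape(-1, N_CHANNELS),
    )
    report = data.report
    report.n_rows = len(data)
    report.flagged_rows = list(np.nonzero(data.flagged)[0])
    if len(data) > 1:
        deltas = np.diff(data.timestamps.asi8) / 1e9
        report.timestamp_gaps = list(np.nonzero(deltas > 60.0)[0] + 1)
    return data


def _format_date(ts: pd.Timestamp) -> str:
    # DAM files write the day of month without zero padding
    return f"{ts.day} {ts.strftime('%b %y')}"


def write_dam_monitor(data: MonitorData, path) -> str:
    """Write :class:`MonitorData` as DAM2 tab-delimited text (no header)."""
    with open(path, "w") as fh:
        for i in range(len(data)):
            ts = data.timestamps[i]
            fields = [
                str(int(data.reading_index[i])),
                _format_date(ts),
                ts.strftime("%H:%M:%S"),
                str(int(data.status[i])),
                *(str(int(v)) for v in data.extended[i]),
                *(str(int(v)) for v in data.counts[i]),
            ]
            fh.write("\t".join(fields) + "\n")
    return str(path)


def monitor_from_counts(
    counts: np.ndarray,
    start: datetime | None = None,
    status: np.ndarray | None = None,
) -> MonitorData:
    """Build a MonitorData from an (n_minutes, <=32) count matrix.

    Unused channels are zero-filled (they read as dead flies downstream).
    """
    counts = np.asarray(counts, dtype=np.int64)
    n = counts.shape[0]
    full = np.zeros((n, N_CHANNELS), dtype=np.int64)
    full[:, : counts.shape[1]] = counts
    if start is None:
        start = datetime(2025, 9, 1, 8, 0, 0)
    stamps = pd.DatetimeIndex([start + timedelta(minutes=i) for i in range(n)])
    if status is None:
        status = np.full(n, OK_STATUS, dtype=np.int64)
    return MonitorData(
        reading_index=np.arange(1, n + 1, dtype=np.int64),
        timestamps=stamps,
        status=np.asarray(status, dtype=np.int64),
        extended=np.zeros((n, N_EXTENDED), dtype=np.int64),
        counts=full,
    )


def to_fly_series(
    data: MonitorData,
    schedule: LightSchedule,
    channel: int,
    fly_id: str | None = None,
) -> FlySeries:
    """Extract one channel as whole ZT-aligned protocol days.

    Minutes before the first ZT0 and after the last complete day are dropped
    (and their totals recorded on the result).  Day tags and regimes come from
    the schedule, indexed from the first retained day.
    """
    if channel not in data.channel_ids:
        raise KeyError(f"channel {channel} not in 1..{N_CHANNELS}")
    zt = schedule.zt_hours(data.timestamps)
    zt_min = np.rint(zt * 60).astype(int) % MINUTES_PER_DAY
    starts = np.nonzero(zt_min == 0)[0]
    if len(starts) == 0:
        raise ScheduleCoverageError("data never reaches ZT0; no whole day available")
    first = starts[0]
    n_days = (len(data) - first) // MINUTES_PER_DAY
    if n_days == 0:
        raise ScheduleCoverageError("no complete protocol day in the data span")
    last = first + n_days * MINUTES_PER_DAY
    col = data.counts[:, channel - 1]
    specs = [schedule.day_spec(d) for d in range(n_days)]
    return FlySeries(
        fly_id=fly_id if fly_id is not None else f"ch{channel:02d}",
        counts=col[first:last].copy(),
        day_tags=[s.tag for s in specs],
        regimes=[s.regime for s in specs],
        flagged=data.flagged[first:last].copy(),
        dropped_leading_min=int(first),
        dropped_trailing_min=int(len(data) - last),
    )


def bin_series(series: FlySeries, bin_minutes: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """Bin per-minute counts to mean counts/min per bin, day by day.

    Returns ``(bin_start_zt_hr, values)`` where ``values`` has shape
    ``(n_days, 1440 // bin_minutes)``.  Total counts are conserved:
    ``values.sum() * bin_minutes == series.counts.sum()``.
    """
    if bin_minutes <= 0 or MINUTES_PER_DAY % bin_minutes != 0:
        raise ValueError(f"bin_minutes must divide 1440, got {bin_minutes}")
    nbins = MINUTES_PER_DAY // bin_minutes
    values = series.counts.reshape(series.n_days, nbins, bin_minutes).mean(axis=2)
    starts = np.arange(nbins) * bin_minutes / 60.0
    return starts, values
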