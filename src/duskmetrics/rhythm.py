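"""Evening anticipation slope and evening peak phase from binned activity.

Evening anticipation is the clock-driven ramp of locomotor activity in the
hours before lights-off.  It is quantified here as the ordinary least-squares
slope of binned mean activity (counts/min) against bin-start time over a
window ending at the transition (default the 3 h before dusk, ZT9-12),
computed per day and averaged across analysis days.

Evening peak phase is the ZT of maximal activity in a search window spanning
dusk (default ZT6-14), after smoothing the binned profile with a centered
moving average.  Phase is reported at the bin center; ties take the earliest
bin; per-day phases are averaged arithmetically (all phases are constrained
to the search window, so no circular averaging is needed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dam import FlySeries, bin_series
from .sleep import WindowSpec

EVENING_SEARCH = WindowSpec(6, 14, "evening-peak search")


@dataclass
class AnticipationResult:
    fly_id: str
    slope: float  # counts/min per hour
    window_hr: float
    transition_zt_hr: float
    days_used: list[int]
    per_day_slope: list[float]


@dataclass
class PhaseResult:
    fly_id: str
    evening_peak_zt: float | None  # None when the profile is flat in the window
    smooth_hr: float
    search: WindowSpec
    days_used: list[int]
    per_day_phase: list[float | None]


def _analysis_days(series: FlySeries, days: list[int] | None) -> list[int]:
    if days is not None:
        return list(days)
    return [d for d in range(series.n_days) if series.day_tags[d] != "discard"]


def anticipation_slope(
    series: FlySeries,
    transition_zt_hr: float = 12.0,
    window_hr: float = 3.0,
    bin_minutes: int = 30,
    days: list[int] | None = None,
    exclude_transition_bin: bool = True,
) -> AnticipationResult:
    """OLS slope of binned activity over the pre-transition window.

    The bin containing the light transition itself is excluded when
    ``exclude_transition_bin`` is set, masking the lights-off startle
    artifact (with the default window ending at the transition this bin is
    outside the fit anyway).
    """
    starts, values = bin_series(series, bin_minutes)
    lo, hi = transition_zt_hr - window_hr, transition_zt_hr
    sel = (starts >= lo) & (starts < hi)
    if exclude_transition_bin:
        sel &= ~((starts <= transition_zt_hr) & (starts + bin_minutes / 60.0 > transition_zt_hr))
    if sel.sum() < 2:
        raise ValueError("anticipation window must contain at least 2 bins")
    x = starts[sel]
    use = _analysis_days(series, days)
    slopes = [float(np.polyfit(x, values[d, sel], 1)[0]) for d in use]
    return AnticipationResult(
        fly_id=series.fly_id,
        slope=float(np.mean(slopes)),
        window_hr=window_hr,
        transition_zt_hr=transition_zt_hr,
        days_used=use,
        per_day_slope=slopes,
    )


def _centered_moving_average(values: np.ndarray, width_bins: float) -> np.ndarray:
    """Circular centered moving average; even widths get half-weight ends."""
    w = int(round(width_bins))
    if w <= 1:
        return values.astype(float)
    if w % 2 == 0:
        kernel = np.concatenate(([0.5], np.ones(w - 1), [0.5])) / w
    else:
        kernel = np.ones(w) / w
    half = len(kernel) // 2
    padded = np.concatenate([values[-half:], values, values[:half]])
    return np.convolve(padded, kernel, mode="valid")


def evening_peak_phase(
    series: FlySeries,
    search: WindowSpec = EVENING_SEARCH,
    smooth_hr: float = 2.0,
    bin_minutes: int = 30,
    days: list[int] | None = None,
) -> PhaseResult:
    """Bin-center ZT of the smoothed activity maximum in the search window."""
    starts, values = bin_series(series, bin_minutes)
    centers = starts + bin_minutes / 120.0
    sel = (centers >= search.start_zt_hr) & (centers < search.end_zt_hr)
    if not np.any(sel):
        raise ValueError("search window contains no bins")
    width = smooth_hr * 60.0 / bin_minutes
    use = _analysis_days(series, days)
    phases: list[float | None] = []
    for d in use:
        smoothed = _centered_moving_average(values[d], width)
        win = smoothed[sel]
        if np.ptp(win) == 0:  # flat profile: phase undefined
            phases.append(None)
            continue
        phases.append(float(centers[sel][np.argmax(win)]))
    defined = [p for p in phases if p is not None]
    return PhaseResult(
        fly_id=series.fly_id,
        evening_peak_zt=float(np.mean(defined)) if defined else None,
        smooth_hr=smooth_hr,
        search=search,
        days_used=use,
        per_day_phase=phases,
    )
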