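"""Synthetic DAM behavior and Voltron-like voltage traces with ground truth.

The behavior generator emulates crepuscular fly locomotion in a DAM monitor:
a morning activity peak after lights-on, a midday siesta, a gradual evening
anticipatory ramp toward dusk, a brief startle at light transitions, rapid
sleep onset after dusk and consolidated night sleep.  Wake/sleep is a
two-state semi-Markov process (sleep bouts with state-dependent durations;
the first post-dusk bout starts at dusk plus a drawn latency); wake minutes
emit Poisson counts from a time-of-day rate template; sleep minutes emit
zeros.  This is an emulation of the phenomenology, not a mechanistic clock
model.

Three phenotype injections mirror the experimental manipulations analysed
downstream: ``delta_onset_min`` (conditional silencing delays sleep onset),
``afternoon_wake_promotion`` (thermogenetic activation suppresses afternoon
sleep on manipulation days), and ``phase_advance_hr`` (a short-period clock
advances the evening activity peak).

All generated sleep bouts are at least 5 min long, bouts are flanked by
nonzero wake minutes, and accidental zero-count wake runs are broken before
they reach 5 min, so the generator's recorded sleep state coincides exactly
with what the 5-min inactivity rule scores on the emitted counts (whenever
the wake rate is positive).  Identical params + seed give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime

import numpy as np

from .dam import (
    MINUTES_PER_DAY,
    N_CHANNELS,
    DaySpec,
    LightSchedule,
    MonitorData,
    monitor_from_counts,
)
from .voltage import DEFAULT_RATE_HZ, VoltageTrace

SLEEP_MIN_BOUT = 5  # matches the scoring threshold by construction


@dataclass
class BehaviorParams:
    """Rate-template, sleep-process and phenotype parameters for one cohort."""

    n_flies: int = 32
    days: list[DaySpec] = field(default_factory=lambda: [DaySpec(), DaySpec()])
    lights_on_hr: float = 8.0
    # wake-rate template (counts/min)
    baseline_rate: float = 1.5
    morning_peak_amp: float = 3.0
    morning_peak_width_hr: float = 1.0
    evening_ramp_slope: float = 2.0  # counts/min per hour
    evening_ramp_start_zt: float = 9.0
    evening_peak_zt: float = 12.0
    post_peak_fall_hr: float = 0.75
    startle_amp: float = 8.0
    startle_minutes: int = 2
    post_dusk_rate: float = 1.5  # extra wake drive between dusk and sleep onset
    # sleep process
    n_siesta_bouts: int = 3
    siesta_window: tuple[float, float] = (4.0, 9.0)
    siesta_bout_mean_min: float = 60.0
    night_bout_mean_min: float = 120.0
    night_gap_min: int = 2
    onset_latency_mean_min: float = 20.0
    onset_latency_shape: float = 4.0
    # phenotype injections
    delta_onset_min: float = 0.0  # applied every analysis day (silencing)
    afternoon_wake_promotion: float = 0.0  # bout-drop prob, manipulation days only
    phase_advance_hr: float = 0.0  # advances ramp + peak (short-period clock)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.onset_latency_mean_min < 0:
            raise ValueError("rates and latencies must be non-negative")
        if not 0.0 <= self.afternoon_wake_promotion <= 1.0:
            raise ValueError("afternoon_wake_promotion must be a probability")


@dataclass
class BehaviorTruth:
    """Exact per-fly ground truth recorded during generation."""

    sleep_state: np.ndarray  # (n_flies, n_days*1440) bool
    onset_latency_min: np.ndarray  # (n_flies, n_days) float, NaN = no night sleep
    ramp_slope: float  # counts/min per hour injected into the template
    peak_phase_zt: float  # template peak ZT after any phase advance


@dataclass
class GenResult:
    monitors: list[MonitorData]
    schedule: LightSchedule
    truth: BehaviorTruth
    params: BehaviorParams
    fly_channels: list[tuple[int, int]]  # (monitor index, channel id) per fly

    @property
    def counts(self) -> np.ndarray:
        """(n_flies, n_minutes) count matrix across monitors."""
        return np.stack(
            [self.monitors[m].counts[:, ch - 1] for m, ch in self.fly_channels]
        )


def _wake_rate_template(p: BehaviorParams, day: DaySpec) -> np.ndarray:
    """Expected wake counts/min at each of the 1440 ZT minutes."""
    zt = (np.arange(MINUTES_PER_DAY) + 0.5) / 60.0
    lam = np.full(MINUTES_PER_DAY, p.baseline_rate)
    # morning peak at ZT0 (circular distance)
    d = np.minimum(zt, 24.0 - zt)
    if p.morning_peak_amp > 0 and p.morning_peak_width_hr > 0:
        lam += p.morning_peak_amp * np.exp(-0.5 * (d / p.morning_peak_width_hr) ** 2)
    # evening anticipatory ramp ending at the (possibly advanced) peak
    peak = p.evening_peak_zt - p.phase_advance_hr
    ramp_len = p.evening_peak_zt - p.evening_ramp_start_zt
    lo = peak - ramp_len
    in_ramp = (zt >= lo) & (zt < peak)
    lam[in_ramp] += p.evening_ramp_slope * (zt[in_ramp] - lo)
    peak_amp = p.evening_ramp_slope * ramp_len
    in_fall = (zt >= peak) & (zt < peak + p.post_peak_fall_hr)
    lam[in_fall] += peak_amp * (1.0 - (zt[in_fall] - peak) / p.post_peak_fall_hr)
    # post-dusk activity burst before sleep onset (nightfall reaction)
    dusk = 12.0
    in_post = (zt >= dusk) & (zt < dusk + 1.0)
    lam[in_post] += p.post_dusk_rate
    if day.regime == "LD" and p.startle_amp > 0:
        lam[: p.startle_minutes] += p.startle_amp
        lam[720 : 720 + p.startle_minutes] += p.startle_amp
    return lam


def _bout_duration(rng: np.random.Generator, mean_min: float, shape: float = 2.0) -> int:
    return max(SLEEP_MIN_BOUT, int(round(rng.gamma(shape, mean_min / shape))))


def _simulate_day_state(
    rng: np.random.Generator,
    p: BehaviorParams,
    day: DaySpec,
) -> tuple[np.ndarray, float]:
    """One day's sleep state (1440 bool) and the drawn onset latency (min)."""
    asleep = np.zeros(MINUTES_PER_DAY, dtype=bool)
    # siesta bouts in disjoint segments of the siesta window
    lo_hr, hi_hr = p.siesta_window
    if p.n_siesta_bouts > 0 and hi_hr > lo_hr:
        edges = np.linspace(lo_hr * 60, hi_hr * 60, p.n_siesta_bouts + 1)
        suppress = (
            day.tag == "manipulation" and p.afternoon_wake_promotion > 0
        )
        for b in range(p.n_siesta_bouts):
            if suppress and rng.random() < p.afternoon_wake_promotion:
                continue
            seg_lo, seg_hi = int(edges[b]), int(edges[b + 1])
            max_dur = seg_hi - seg_lo - 2  # leave wake margin between bouts
            if max_dur < SLEEP_MIN_BOUT:
                continue
            dur = min(_bout_duration(rng, p.siesta_bout_mean_min, shape=3.0), max_dur)
            start = seg_lo + 1 + int(rng.integers(0, seg_hi - seg_lo - dur - 1))
            asleep[start : start + dur] = True
    # night: first bout at dusk + latency, then consolidated bouts with brief gaps
    if p.onset_latency_mean_min > 0:
        latency = rng.gamma(
            p.onset_latency_shape, p.onset_latency_mean_min / p.onset_latency_shape
        )
    else:
        latency = 0.0
    latency += p.delta_onset_min
    t = 720 + int(round(latency))
    onset_recorded = np.nan
    while t < MINUTES_PER_DAY - SLEEP_MIN_BOUT:
        dur = _bout_duration(rng, p.night_bout_mean_min)
        end = min(t + dur, MINUTES_PER_DAY)
        asleep[t:end] = True
        if np.isnan(onset_recorded):
            onset_recorded = t - 720.0
        t = end + max(0, p.night_gap_min)
    return asleep, onset_recorded


def _emit_counts(
    rng: np.random.Generator,
    asleep: np.ndarray,
    lam: np.ndarray,
) -> np.ndarray:
    """Poisson wake counts with guards keeping scoring identical to the state.

    Wake minutes flanking a sleep bout are forced to >= 1 count, and any
    accidental zero-count wake run is broken before reaching the 5-min
    threshold.  Guards only act where the wake rate is positive, so a
    zero-rate template still yields an all-quiescent day.
    """
    counts = np.where(asleep, 0, rng.poisson(lam)).astype(np.int64)
    active_rate = lam > 0
    wake = ~asleep
    # flank guard
    edges = np.diff(asleep.astype(np.int8))
    for i in np.nonzero(edges == 1)[0]:  # minute before bout start
        if wake[i] and active_rate[i]:
            counts[i] = max(1, counts[i])
    for i in np.nonzero(edges == -1)[0] + 1:  # minute after bout end
        if i < len(counts) and wake[i] and active_rate[i]:
            counts[i] = max(1, counts[i])
    # zero-run guard
    risky = wake & (counts == 0) & active_rate
    padded = np.concatenate(([False], risky, [False]))
    d = np.diff(padded.astype(np.int8))
    for start, end in zip(np.nonzero(d == 1)[0], np.nonzero(d == -1)[0]):
        if end - start >= SLEEP_MIN_BOUT:
            counts[start + SLEEP_MIN_BOUT - 1 : end : SLEEP_MIN_BOUT - 1] = 1
    return counts


def generate_behavior(params: BehaviorParams) -> GenResult:
    """Generate DAM-format monitor data plus exact ground truth for one cohort."""
    p = params
    if not p.days:
        raise ValueError("at least one protocol day required")
    n_days = len(p.days)
    templates = [_wake_rate_template(p, day) for day in p.days]
    rng = np.random.default_rng(np.random.SeedSequence(p.seed))
    all_counts = np.zeros((p.n_flies, n_days * MINUTES_PER_DAY), dtype=np.int64)
    state = np.zeros_like(all_counts, dtype=bool)
    onset = np.full((p.n_flies, n_days), np.nan)
    for f in range(p.n_flies):
        day_states = []
        for d, day in enumerate(p.days):
            s, lat = _simulate_day_state(rng, p, day)
            day_states.append(s)
            onset[f, d] = lat
        asleep = np.concatenate(day_states)
        lam = np.concatenate(templates)
        all_counts[f] = _emit_counts(rng, asleep, lam)
        state[f] = asleep
    schedule = LightSchedule(lights_on_hr=p.lights_on_hr, days=list(p.days))
    monitors, fly_channels = [], []
    start = datetime(2025, 9, 1, int(p.lights_on_hr), int(round((p.lights_on_hr % 1) * 60)), 0)
    for block in range(0, p.n_flies, N_CHANNELS):
        chunk = all_counts[block : block + N_CHANNELS].T
        monitors.append(monitor_from_counts(chunk, start=start))
        for ch in range(chunk.shape[1]):
            fly_channels.append((len(monitors) - 1, ch + 1))
    truth = BehaviorTruth(
        sleep_state=state,
        onset_latency_min=onset,
        ramp_slope=p.evening_ramp_slope,
        peak_phase_zt=p.evening_peak_zt - p.phase_advance_hr,
    )
    return GenResult(monitors, schedule, truth, p, fly_channels)


# ---------------------------------------------------------------------------
# voltage traces and movies


@dataclass
class TraceParams:
    duration_s: float = 60.0
    rate_hz: float = DEFAULT_RATE_HZ
    bleach_amp: float = 100.0
    bleach_tau_s: float = 60.0
    bleach_offset: float = 500.0
    subthreshold_amp: float = 3.0
    subthreshold_hz: float = 2.0
    subthreshold_phase: float = 0.0
    spike_rate_hz: float = 1.0
    spike_depth_sd: float = 6.0  # in units of the noise sigma
    spike_tau_ms: float = 3.0
    refractory_ms: float = 20.0
    noise_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spike_depth_sd < 0 or self.noise_sigma < 0:
            raise ValueError("spike depth and noise sigma must be non-negative")
        if self.rate_hz <= 2 * self.subthreshold_hz:
            raise ValueError("sampling rate must exceed twice the subthreshold frequency")


@dataclass
class TraceResult:
    trace: VoltageTrace
    spike_times_s: np.ndarray
    bleach: np.ndarray  # bleach-only component (shared by background pixels)


def _refractory_poisson(
    rng: np.random.Generator, rate_hz: float, refractory_s: float, duration_s: float
) -> np.ndarray:
    """Event times of a dead-time-corrected Poisson process at mean rate ``rate_hz``."""
    if rate_hz <= 0:
        return np.empty(0)
    if rate_hz * refractory_s >= 1.0:
        raise ValueError("rate incompatible with refractory period")
    lam = rate_hz / (1.0 - rate_hz * refractory_s)  # dead-time correction
    times, t = [], 0.0
    while True:
        gap = rng.exponential(1.0 / lam)
        t += gap if not times else gap + refractory_s
        if t >= duration_s:
            break
        times.append(t)
    return np.asarray(times)


def generate_trace(params: TraceParams) -> TraceResult:
    """Voltron-like trace: bleach decay + slow oscillation - spikes + noise."""
    p = params
    rng = np.random.default_rng(np.random.SeedSequence(p.seed))
    n = int(round(p.duration_s * p.rate_hz))
    t = np.arange(n) / p.rate_hz
    bleach = p.bleach_offset + p.bleach_amp * np.exp(-t / p.bleach_tau_s)
    f = bleach + p.subthreshold_amp * np.sin(
        2 * np.pi * p.subthreshold_hz * t + p.subthreshold_phase
    )
    spike_times = _refractory_poisson(rng, p.spike_rate_hz, p.refractory_ms / 1e3, p.duration_s)
    tau = p.spike_tau_ms / 1e3
    depth = p.spike_depth_sd * p.noise_sigma
    if depth > 0 and tau > 0:
        kernel_len = int(round(8 * tau * p.rate_hz)) + 1
        kernel = depth * np.exp(-np.arange(kernel_len) / (tau * p.rate_hz))
        for ts in spike_times:
            i = int(round(ts * p.rate_hz))
            if i >= n:
                continue
            j = min(n, i + kernel_len)
            f[i:j] -= kernel[: j - i]
    if p.noise_sigma > 0:
        f = f + rng.normal(0.0, p.noise_sigma, size=n)
    meta = f"synthetic {p.duration_s:g}s @ {p.rate_hz:g} Hz"
    return TraceResult(VoltageTrace(f, p.rate_hz, meta), spike_times, bleach)


@dataclass
class MovieResult:
    movie: np.ndarray  # (n_pixels, n_time)
    signal_mask: np.ndarray  # (n_pixels,) bool ground truth
    source: TraceResult


def generate_movie(
    params: TraceParams,
    n_signal_pixels: int = 16,
    n_background_pixels: int = 48,
    pixel_noise_sigma: float | None = None,
) -> MovieResult:
    """Pixel x time movie: signal pixels share one trace, background is bleach."""
    if n_signal_pixels < 1:
        raise ValueError("need at least one signal pixel")
    if n_background_pixels < 0:
        raise ValueError("background pixel count must be non-negative")
    src = generate_trace(params)
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 1)))
    sigma = params.noise_sigma if pixel_noise_sigma is None else pixel_noise_sigma
    n_t = len(src.trace.samples)
    n_pix = n_signal_pixels + n_background_pixels
    movie = np.empty((n_pix, n_t))
    for i in range(n_signal_pixels):
        movie[i] = src.trace.samples + rng.normal(0.0, sigma, n_t)
    for i in range(n_signal_pixels, n_pix):
        movie[i] = src.bleach + rng.normal(0.0, sigma, n_t)
    mask = np.zeros(n_pix, dtype=bool)
    mask[:n_signal_pixels] = True
    perm = rng.permutation(n_pix)  # shuffle so clustering cannot rely on order
    return MovieResult(movie[perm], mask[perm], src)


# ---------------------------------------------------------------------------
# multi-genotype experiments


SCENARIOS = (
    "null",
    "E1_silencing",
    "E1_activation_LD",
    "E1_activation_DD",
    "E2_clock_phase_advance",
)

EXPERIMENTAL_LABEL = "GAL4>UAS"
CONTROL_LABELS = ("GAL4/+", "UAS/+")


@dataclass
class Experiment:
    scenario: str
    cohorts: dict[str, GenResult]
    roles: dict[str, str]  # label -> "experimental" | "control"


def _scenario_days(scenario: str) -> list[DaySpec]:
    if scenario == "E1_activation_LD":
        return [DaySpec("LD", 22.0, "baseline"), DaySpec("LD", 28.0, "manipulation")]
    if scenario == "E1_activation_DD":
        return [DaySpec("DD", 22.0, "baseline"), DaySpec("DD", 28.0, "manipulation")]
    if scenario == "E1_silencing":
        return [DaySpec("LD", 22.0, "manipulation"), DaySpec("LD", 22.0, "manipulation")]
    return [DaySpec("LD", 22.0, "baseline"), DaySpec("LD", 22.0, "baseline")]


def build_experiment(
    scenario: str,
    n_per_group: int = 32,
    seed: int = 0,
    base_params: BehaviorParams | None = None,
    delta_onset_min: float = 45.0,
    afternoon_wake_promotion: float = 0.6,
    phase_advance_hr: float = 1.0,
) -> Experiment:
    """One experimental cohort plus two genetic controls for a named scenario.

    The phenotype is injected only into the experimental cohort: silencing
    delays sleep onset on every day, LD activation suppresses afternoon sleep
    on the heated (manipulation) day only, DD activation injects no effect,
    and the clock phase advance shifts the evening activity peak.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    days = _scenario_days(scenario)
    base = base_params or BehaviorParams()
    injections = {
        "null": {},
        "E1_silencing": {"delta_onset_min": delta_onset_min},
        "E1_activation_LD": {"afternoon_wake_promotion": afternoon_wake_promotion},
        "E1_activation_DD": {},
        "E2_clock_phase_advance": {"phase_advance_hr": phase_advance_hr},
    }[scenario]
    seeds = np.random.SeedSequence(seed).generate_state(3) % (2**31)
    cohorts, roles = {}, {}
    labels = (EXPERIMENTAL_LABEL, *CONTROL_LABELS)
    for label, cohort_seed in zip(labels, seeds):
        kwargs = dict(n_flies=n_per_group, days=days, seed=int(cohort_seed))
        if label == EXPERIMENTAL_LABEL:
            kwargs.update(injections)
        cohorts[label] = generate_behavior(replace(base, **kwargs))
        roles[label] = "experimental" if label == EXPERIMENTAL_LABEL else "control"
    return Experiment(scenario, cohorts, roles)
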