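# Methods

This note documents the models, rules and numerical choices behind
`duskmetrics`, what its synthetic-data generators do and do not emulate, and
the known limitations of each stage.

## Sleep scoring and onset latency

Sleep is the standard DAM inactivity criterion: a minute is asleep iff it
lies in a maximal run of zero-count minutes of length ≥ `threshold_min`
(default 5). Minutes whose monitor status code is not 1 are flagged; flagged
minutes break runs, are never scored as sleep, and are excluded from
metrics. Runs crossing a protocol-day boundary are split into per-day bouts
with the linkage recorded, so per-day bout sums and whole-series sleep
minutes always agree.

Sleep onset after dusk re-scores the segment from dusk (default ZT12) to the
end of the day on its own. Consequences: a quiescence run straddling dusk
yields onset exactly ZT12, and onset is bounded below by dusk — the floor
that motivates always treating onset as non-normally distributed. The
alternative rule (ignore straddling runs; take the first run starting
strictly after dusk) is available via `straddle="exclude"`. Flies with no
qualifying post-dusk run return a missing onset and are excluded from onset
statistics rather than scored as zero; the analysis records how many flies
were excluded. A dead-fly filter removes flies with zero counts over the
final 12 h of the protocol (threshold configurable).

Windows are half-open `[start, end)` so ZT0–6 / ZT6–12 / ZT12–24 partition
the day and windowed amounts are additive.

## Evening anticipation and peak phase

Anticipation slope: per day, activity is binned to mean counts/min in
30-min bins; the OLS slope of bin value against bin-start time (hours) is
fit over the 3 h ending at the light transition (`[ZT9, ZT12)` by default)
and per-day slopes are averaged. Three hours isolates the anticipatory ramp
from the siesta trough; the window, bin width and a 6-h sensitivity variant
are all parameters. The bin containing the transition itself can carry a
lights-off startle artifact and is excluded from fits when the window is
configured to include it.

Evening peak phase: the binned day is smoothed with a centered circular
moving average of width 2 h (even widths use half-weight end bins so the
kernel stays centered), and the phase is the bin-center ZT of the maximum
within a ZT6–14 search window — wide enough to catch phase-advanced peaks.
Ties take the earliest bin; a flat profile yields an explicitly undefined
phase. Per-day phases are averaged arithmetically; because all phases are
constrained to the search window, circular averaging is unnecessary. This
smooth-then-argmax definition is a re-specification of "peak evening
activity", not a reproduction of any particular tool's internals.

Note that the ZT9–12 slope is only meaningful for cohorts whose ramp
actually occupies that window: a phase-advanced clock moves the ramp
earlier, and the standard-window slope drops — peak phase is the readout for
period manipulations.

## Voltage-trace pipeline

Stages, in order, for traces sampled near 849 Hz:

1. **ROI selection** — pixels are detrended (cubic polynomial), z-scored and
   clustered with seeded k-means (k = 2 default; k is configurable since the
   right value depends on the field of view). The signal cluster is the one
   whose mean trace has the greatest variance after detrending; the ROI
   trace is the mean over its pixels. An all-constant movie is flagged
   degenerate rather than clustered.
2. **Photobleach detrend** — least-squares polynomial (degree 3 default,
   configurable) over the whole trace, subtracted; the fit uses a scaled
   abscissa for conditioning. Output mean is numerically zero.
3. **Low-pass filter** — order-2 Butterworth, cutoff expressed as a fraction
   of Nyquist (0.5 → ≈ 212 Hz at 849 Hz), applied forward-backward
   (`sosfiltfilt`) so spike timing is unbiased. The two passes square the
   magnitude response, so the amplitude ratio at the cutoff is 0.5.
4. **Moving baseline** — zero-phase 1–8 Hz band-pass (order 2 per edge),
   which keeps the slow subthreshold oscillation and rejects both DC and
   spike-timescale content.
5. **Spike detection** — candidates are strict local minima of
   (filtered − baseline) lying more than `n_sd` residual standard deviations
   below the baseline (spikes are negative-going in inverted-fluorescence
   convention). σ is the SD of the residual over the whole recording, chosen
   for determinism; a running-window σ is available. Candidates closer than
   5 ms keep only the deepest; the first and last 250 ms are excluded to
   avoid filter transients.
6. **Rate** — spike count divided by recording length.

### Detection threshold

`detect_spikes` defaults to `n_sd = 2`: a permissive candidate pass of the
kind that is normally followed by manual curation of the detections. The
automated `process_trace` pipeline instead uses `n_sd = 4.5`, set where the
expected number of false calls on noise falls below one per minute-long
recording: discrete low-passed noise has a strict local minimum roughly
every third sample (~1.7 × 10⁴ per minute at 849 Hz), and minima are a few
times likelier than arbitrary samples to lie in the lower tail, so < 1
expected false call requires a Gaussian tail probability below ~10⁻⁵, i.e.
about 4.5 SD. At 2 SD several hundred noise minima per minute qualify, which
no automated rate estimate survives. At the synthetic study conditions
(spike depth 6 × noise SD, 1 Hz rate, 2 Hz subthreshold, exponential
bleach, 60 s) the automated pipeline measures precision ≥ 0.98 and recall
≥ 0.95 across seeds.

Because any noise-scaled threshold has a nonzero false-call probability on
pure noise, a spike-free *noisy* trace can yield up to ~1 call/min; a
spike-free noiseless trace yields exactly zero.

## Statistics

Planned comparisons only: each experimental group against each of its
controls, never all pairs. The parametric branch is one-way ANOVA with
pairwise t statistics built from the ANOVA residual mean square and its
N − k degrees of freedom (the classic Bonferroni multiple-comparison test;
a Welch variant can be obtained by comparing pairs directly). The
non-parametric branch is Kruskal–Wallis with tie correction and Dunn's z
using pooled rank variance N(N+1)/12 − Σ(t³−t)/(12(N−1)). Both branches
adjust raw p values by p_adj = min(1, m·p) with m = number of planned
comparisons.

The normality gate is Shapiro–Wilk per group at α = 0.05 — any rejection,
any group with n < 3, or any zero-variance group routes to the
non-parametric branch — and every decision is recorded in a trail on the
report so the gate can be audited. Sleep onset is forced non-parametric
regardless of the data. With two groups, Dunn's raw p equals the two-sided
Mann–Whitney normal approximation without continuity correction.

The verdict rule mirrors the genetic-controls logic: a phenotype is called
only when the experimental group differs from **both** controls at adjusted
p < α with the same sign of effect.

Degenerate inputs are defined, not errors: all-identical data give F = 0 or
H = 0 with p = 1.

## Synthetic behavior generator

Wake/sleep is a two-state semi-Markov process — the simplest structure that
makes every metric recoverable; it is an emulation of crepuscular
phenomenology, not a mechanistic clock model. Per protocol day:

- **Siesta**: 3 sleep bouts (gamma-distributed durations, mean 60 min,
  minimum 5 min) placed in disjoint segments of ZT4–9, giving ≈ 110 min of
  afternoon (ZT6–12) sleep, in line with published male DAM sleep profiles.
  The window deliberately ends before ZT9 so the anticipation-slope window
  is wake by construction.
- **Night**: the first bout starts at dusk plus a gamma latency (shape 4,
  mean 20 min); consolidated bouts (mean 120 min) follow, separated by
  2-min active gaps, until the day ends.
- **Wake counts** are Poisson from a rate template (counts/min): baseline
  1.5, Gaussian morning peak (amp 3, width 1 h) at ZT0, a linear evening
  ramp of 2.0 counts/min per hour over the 3 h before the evening peak
  (ZT12 by default), a 0.75-h post-peak fall, a 1-h post-dusk activity
  burst, and a 2-min startle of amp 8 at both light transitions on LD days
  (dropped in DD, where the template phase continues from entrainment).

Three guards make the generator's recorded sleep state coincide *exactly*
with what the 5-min rule scores on the emitted counts whenever the wake
rate is positive: all generated bouts are ≥ 5 min, the wake minutes
flanking each bout are forced to ≥ 1 count, and accidental zero-count wake
runs are broken before reaching 5 min. This exactness is what lets tests
compare measured metrics against recorded truth with no slack from the
scorer itself.

Phenotype injections: `delta_onset_min` adds to the latency draw on every
day (conditional silencing); `afternoon_wake_promotion` drops each siesta
bout with that probability on manipulation days only (thermogenetic
activation); `phase_advance_hr` rigidly advances the evening ramp and peak
(short-period clock). `build_experiment` wires these into five scenarios
(null, silencing, LD activation, DD activation with no injected effect, and
clock phase advance), always as one experimental plus two control cohorts
with per-cohort seeds spawned from one experiment seed.

What the generator does **not** emulate: temperature physiology of the
effectors, light input pathways, free-running period drift in extended DD,
inter-fly correlation, and day-to-day within-fly stability (each day is
drawn independently, which makes change-score variances conservative).
Passing tests therefore show the *analysis* recovers what the generator
encodes under realistic rates and noise — not that real flies behave like
the generator.

The trace generator builds F(t) = offset + bleach·e^(−t/τ_b) +
A_sub·sin(2π f_sub t + φ) − Σᵢ depth·σ·e^(−(t−tᵢ)/τ_s)·[t ≥ tᵢ] + N(0, σ)
with spike times from a dead-time-corrected Poisson process (refractory
20 ms; the underlying rate is inflated by 1/(1 − r·d) so the realized mean
rate equals the nominal r). Defaults: 60 s at 849 Hz, bleach 100 a.u. over
τ_b = 60 s on a 500 a.u. offset, subthreshold amp 3σ at 2 Hz, spikes 1 Hz at
depth 6σ with τ_s = 3 ms, σ = 1. Movies share one generated trace across
signal pixels plus independent pixel noise; background pixels carry only
bleach and noise; pixel order is shuffled so clustering cannot exploit
layout.

## Problem sizes and determinism

All simulations are seeded (NumPy `SeedSequence`); identical params + seed
give identical monitor files, traces and CSVs. The test suite and
`scripts/acceptance.py` use the study design sizes throughout: n = 32 flies
per genotype and 2 protocol days for behavioral experiments (20 seeds for
the silencing recovery, 100 for the null false-positive calibration), 60-s
traces at 849 Hz for spike metrics (5–8 seeds), 500 replicates at n = 7 per
group for the equal-rate t-test calibration, and 2000 replicates for the
family-wise error calibrations of the post-hoc schemes.

## Other numerical choices

- DAM2 dialect is fixed at 42 tab-separated columns (reading index, date,
  time, status, six extended-status fields, 32 counts); timestamps are
  local, monotone, 1-min resolution; daylight-saving handling is out of
  scope. Lights-on time is always declared by the user in the schedule —
  monitor files do not reliably encode it.
- Partial leading/trailing days are dropped (and counted) when aligning to
  ZT; day discard policy (e.g. loading-day recovery) is configuration via
  day tags, not hard-coded.
- Binning requires widths that divide 1440 min and conserves total counts
  exactly.
- Phase is reported at bin centers; with 30-min bins phases land on
  :15/:45 half-hours.
- t/F/H p-values come from scipy; Dunn's test is implemented here (no
  installed package provides it) and is cross-checked in the tests against
  brute-force rank arithmetic.

## Limitations

- The onset straddle rule and the slope/phase window and smoothing choices
  are re-specifications of tool-dependent metrics; absolute values are only
  comparable within a fixed configuration.
- The automated spike pipeline trades a little recall (deep threshold) for
  precision; very shallow or very fast spikes (≲ 2 samples) are attenuated
  by the 0.5-Nyquist low-pass and can be missed.
- Kruskal–Wallis/Dunn p-values use the large-sample normal/χ² forms; very
  small groups (n < 5) get conservative but approximate p-values.
- The generator's Poisson wake counts have no overdispersion; real beam
  crossings are burstier, so real-data metric variances will exceed the
  synthetic calibrations.
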