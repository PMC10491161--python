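# duskmetrics

Quantitative analysis of *Drosophila* behavior and neural activity around
dusk: sleep and locomotor metrics from Drosophila Activity Monitor (DAM)
beam-break data, the planned-comparison statistics used for multi-genotype
fly experiments, and a spike-detection pipeline for fluorescence
voltage-imaging traces — plus ground-truthed synthetic-data generators so
every stage can be validated without raw recordings.

It is written for chronobiology and sleep labs that run DAM experiments
comparing experimental genotypes (GAL4>UAS) against their genetic controls
(GAL4/+, UAS/+), and for groups doing in vivo voltage imaging of clock
neurons with Voltron-class indicators.

## What it computes

**Sleep.** A fly is asleep during any maximal run of zero-count minutes of
length ≥ 5 (the field's standard inactivity criterion). From the minute-level
score the package derives sleep bouts, windowed sleep amounts over half-open
ZT windows (morning ZT0–6, afternoon ZT6–12, night ZT12–24),
baseline-vs-manipulation sleep changes (negative = sleep loss), binned cohort
sleep profiles, and **sleep onset latency after dusk**: the night segment
from ZT12 is re-scored on its own, and the onset is the ZT of the first
qualifying inactivity run, so a bout straddling dusk gives onset exactly
ZT12 (the floor dusk imposes on this metric).

**Circadian activity.** Evening anticipation slope — the OLS slope of
30-min-binned activity (counts/min) against time over the 3 h before
lights-off, per day, averaged across days — and evening peak phase, the
bin-center ZT of maximal activity in a ZT6–14 search window after a centered
2-h moving average.

**Statistics.** Each experimental group is compared only against its own
controls. Normally distributed metrics (Shapiro–Wilk per group, α = 0.05) use
one-way ANOVA with Bonferroni-adjusted pooled-variance post-hoc t tests;
non-normal metrics use Kruskal–Wallis with tie-corrected Dunn's z tests,
Bonferroni-adjusted over the planned pairs. Sleep onset is always routed to
the non-parametric branch. A phenotype verdict requires adjusted p < α
against **both** controls with agreeing directions. Two-condition firing
rates use a two-tailed pooled-variance Student's t test.

**Voltage imaging.** For traces sampled at 849 Hz: k-means ROI selection on
pixel time courses, photobleach removal by polynomial subtraction, zero-phase
order-2 Butterworth low-pass (cutoff 0.5 × Nyquist), moving-baseline
estimation with a zero-phase 1–8 Hz band-pass, spike calling at strict local
minima of the baseline-subtracted trace below an SD threshold (negative-going
spikes), and rate = spikes / recording length.

**Synthetic data.** `duskmetrics.synthetic` generates DAM monitor files from
a two-state wake/sleep process with a crepuscular rate template (morning
peak, midday siesta, evening anticipatory ramp, light-transition startle,
rapid post-dusk sleep onset, consolidated night sleep) and Voltron-like
traces (bleach decay, slow subthreshold oscillation, refractory-Poisson
negative spikes, Gaussian noise), with exact ground truth and injectable
phenotypes: onset delay (silencing), afternoon sleep suppression
(activation), and evening phase advance (short-period clock).

## Worked example

`examples/05_full_experiment.py` builds a silencing experiment (45-min
injected onset delay, n = 32 per genotype) and runs the whole pipeline:

```
median sleep onset (ZT) per genotype:
  GAL4>UAS    13.07
  GAL4/+      12.38
  UAS/+       12.30

Kruskal-Wallis: H = 64.9, p = 8e-15
GAL4>UAS vs GAL4/+: *** (adj. P = 7.09e-10)
GAL4>UAS vs UAS/+: *** (adj. P = 1.13e-13)

significant vs BOTH controls: True
```

The experimental median is delayed ~0.73 h (≈ 44 min, recovering the 45-min
injection); Dunn's test is significant against both controls, so the verdict
is a genuine onset phenotype. The other scripts in `examples/` demonstrate
DAM I/O and binning, sleep metrics, anticipation slope and peak phase, and
the voltage spike pipeline, each printing what the numbers mean.

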