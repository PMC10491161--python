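"""Voltage-trace pipeline: ROI, detrend, filters, spike detection, rates."""

import numpy as np
import pytest
from scipy import special

from duskmetrics.synthetic import TraceParams, generate_movie, generate_trace
from duskmetrics.voltage import (
    PipelineParams,
    VoltageTrace,
    compare_conditions,
    detect_spikes,
    detrend_photobleach,
    estimate_baseline,
    filter_trace,
    process_trace,
    select_roi_kmeans,
    spike_rate,
)

FS = 849.0


def match_counts(detected, true, tol_s=0.005):
    """Greedy one-to-one matching of detected to true spike times."""
    true = np.sort(np.asarray(true))
    used = np.zeros(len(true), dtype=bool)
    tp = 0
    for t in detected:
        d = np.abs(true - t)
        d[used] = np.inf
        if len(d) and d.min() <= tol_s:
            used[np.argmin(d)] = True
            tp += 1
    return tp


# --- ROI selection -------------------------------------------------------


def test_roi_recovers_planted_mask():
    mv = generate_movie(TraceParams(seed=11), n_signal_pixels=12, n_background_pixels=52)
    roi = select_roi_kmeans(mv.movie, k=2)
    assert np.array_equal(roi.mask, mv.signal_mask)
    assert not roi.flagged_degenerate


def test_roi_single_signal_pixel_lands_in_signal_cluster():
    mv = generate_movie(
        TraceParams(seed=12, subthreshold_amp=6.0), n_signal_pixels=1, n_background_pixels=63
    )
    roi = select_roi_kmeans(mv.movie, k=2)
    assert roi.mask[np.nonzero(mv.signal_mask)[0][0]]


def test_roi_k1_is_global_mean():
    mv = generate_movie(TraceParams(seed=13), 4, 4)
    roi = select_roi_kmeans(mv.movie, k=1)
    assert roi.mask.all()
    assert np.allclose(roi.trace.samples, mv.movie.mean(axis=0))


def test_roi_identical_populations_symmetric():
    """Two identical pixel populations: either labeling gives the same trace."""
    t = np.arange(2000) / FS
    row = np.sin(2 * np.pi * 3 * t)
    movie = np.tile(row, (8, 1))
    movie[:, 0] += 1e-9 * np.arange(8)  # break exact degeneracy without structure
    roi = select_roi_kmeans(movie, k=2)
    assert np.allclose(roi.trace.samples, row, atol=1e-6)


def test_roi_degenerate_movie_flagged():
    roi = select_roi_kmeans(np.full((6, 1000), 7.0), k=2)
    assert roi.flagged_degenerate and roi.trace is None


def test_roi_argument_errors():
    with pytest.raises(ValueError):
        select_roi_kmeans(np.zeros((3, 100)), k=5)


# --- detrending ----------------------------------------------------------


def test_detrend_removes_cubic_exactly():
    t = np.linspace(0, 30, int(30 * FS))
    poly = 5.0 + 2.0 * t - 0.3 * t**2 + 0.01 * t**3
    out = detrend_photobleach(VoltageTrace(poly, FS))
    assert np.max(np.abs(out.samples)) < 1e-9 * np.max(np.abs(poly))
    const = detrend_photobleach(VoltageTrace(np.full(1000, 42.0), FS))
    assert np.allclose(const.samples, 0.0, atol=1e-10)


def test_detrend_leaves_sinusoid():
    t = np.linspace(0, 30, int(30 * FS))
    poly = 100.0 - 3.0 * t + 0.05 * t**2
    sine = 4.0 * np.sin(2 * np.pi * 4.0 * t)
    out = detrend_photobleach(VoltageTrace(poly + sine, FS))
    rms_err = np.sqrt(np.mean((out.samples - sine) ** 2))
    assert rms_err < 0.01 * 4.0
    assert abs(out.samples.mean()) < 1e-8


def test_detrend_validation():
    with pytest.raises(ValueError):
        detrend_photobleach(VoltageTrace(np.ones(100), FS), degree=-1)
    with pytest.raises(ValueError):
        detrend_photobleach(VoltageTrace(np.ones(3), FS), degree=3)


# --- filtering -----------------------------------------------------------


def test_lowpass_dc_gain_unity():
    out = filter_trace(VoltageTrace(np.full(5000, 3.5), FS))
    assert np.allclose(out.samples, 3.5, atol=1e-9)


def test_lowpass_linearity(rng):
    a = rng.normal(size=4000)
    b = rng.normal(size=4000)
    fa = filter_trace(VoltageTrace(a, FS)).samples
    fb = filter_trace(VoltageTrace(b, FS)).samples
    fab = filter_trace(VoltageTrace(a + b, FS)).samples
    assert np.allclose(fab, fa + fb, atol=1e-9)


def test_lowpass_cutoff_amplitude_half():
    """At the cutoff, forward-backward order-2 Butterworth gives ratio 0.5."""
    fc = 0.5 * FS / 2
    t = np.arange(int(10 * FS)) / FS
    out = filter_trace(VoltageTrace(np.sin(2 * np.pi * fc * t), FS))
    amp = np.abs(out.samples[2000:-2000]).max()
    assert amp == pytest.approx(0.5, rel=0.02)


def test_lowpass_cutoff_validation():
    with pytest.raises(ValueError):
        filter_trace(VoltageTrace(np.ones(100), FS), normalized_cutoff=1.5)


# --- baseline ------------------------------------------------------------


def test_baseline_passes_4hz():
    t = np.arange(int(10 * FS)) / FS
    base = estimate_baseline(VoltageTrace(np.sin(2 * np.pi * 4 * t), FS))
    assert np.abs(base[2000:-2000]).max() > 0.9


def test_baseline_rejects_dc():
    base = estimate_baseline(VoltageTrace(np.full(int(10 * FS), 100.0), FS))
    assert abs(base.mean()) < 1.0
    assert np.abs(base).max() < 1.0


def test_baseline_separates_slow_from_fast():
    t = np.arange(int(10 * FS)) / FS
    slow = 5.0 * np.sin(2 * np.pi * 2 * t)
    fast = 5.0 * np.sin(2 * np.pi * 100 * t)
    base = estimate_baseline(VoltageTrace(slow + fast, FS))
    core = slice(2000, -2000)
    rms = np.sqrt(np.mean((base[core] - slow[core]) ** 2))
    assert rms < 0.1 * 5.0


def test_baseline_validation():
    with pytest.raises(ValueError):
        estimate_baseline(VoltageTrace(np.ones(100), FS), band_hz=(8.0, 1.0))
    with pytest.raises(ValueError):
        estimate_baseline(VoltageTrace(np.ones(100), 10.0), band_hz=(1.0, 8.0))


# --- spike detection -----------------------------------------------------


def _planted_trace(depths, times_s, duration_s=20.0, tau_s=0.003):
    n = int(duration_s * FS)
    f = np.zeros(n)
    for d, ts in zip(depths, times_s):
        i = int(round(ts * FS))
        k = int(8 * tau_s * FS) + 1
        f[i : i + k] -= d * np.exp(-np.arange(min(k, n - i)) / (tau_s * FS))
    return VoltageTrace(f, FS)


def test_flat_trace_no_spikes_flagged():
    tr = VoltageTrace(np.zeros(int(5 * FS)), FS)
    train = detect_spikes(filter_trace(tr), np.zeros(len(tr.samples)))
    assert train.n_spikes == 0 and train.flagged_degenerate


def test_planted_spikes_detected_exactly():
    """10 noiseless spikes, separation > 100 ms: all found within 2 samples."""
    times = np.linspace(1, 19, 10)
    tr = _planted_trace([5.0] * 10, times)
    fil = filter_trace(tr)
    train = detect_spikes(fil, estimate_baseline(fil), n_sd=2.0)
    assert train.n_spikes == 10
    assert np.all(np.abs(train.spike_times_s - times) <= 2 / FS)


def test_doublet_keeps_deeper():
    """Two spikes 2 ms apart merge to the deeper one under the 5 ms rule."""
    tr = _planted_trace([3.0, 6.0], [5.0, 5.002])
    train = detect_spikes(tr, np.zeros(len(tr.samples)), n_sd=2.0)
    assert train.n_spikes == 1
    assert abs(train.spike_times_s[0] - 5.002) <= 2 / FS


def test_spike_rate_trivials():
    from duskmetrics.voltage import SpikeTrain

    assert spike_rate(SpikeTrain(np.linspace(0, 19, 10), 20.0)) == 0.5
    assert spike_rate(SpikeTrain(np.empty(0), 20.0)) == 0.0
    with pytest.raises(ValueError):
        spike_rate(SpikeTrain(np.empty(0), 0.0))


def test_poisson_rate_estimate_within_sampling_error():
    r, dur = 1.0, 60.0
    rates = []
    for seed in range(40):
        res = generate_trace(TraceParams(seed=seed, duration_s=dur, spike_rate_hz=r))
        rates.append(len(res.spike_times_s) / dur)
    assert abs(np.mean(rates) - r) < 3 * np.sqrt(r / dur / 40)


# --- full pipeline -------------------------------------------------------


def test_pipeline_recall_precision_on_study_conditions():
    res = generate_trace(TraceParams(seed=101))
    out = process_trace(res.trace)
    core = (res.spike_times_s > 0.3) & (res.spike_times_s < res.trace.duration_s - 0.3)
    true = res.spike_times_s[core]
    tp = match_counts(out.spikes.spike_times_s, true)
    assert tp / max(1, out.spikes.n_spikes) >= 0.95
    assert tp / len(true) >= 0.95


def test_pipeline_zero_spike_trace_rate_zero():
    """Bleach + subthreshold with no spikes and no noise -> rate exactly 0."""
    res = generate_trace(TraceParams(seed=5, spike_rate_hz=0.0, noise_sigma=0.0))
    out = process_trace(res.trace)
    assert out.rate_hz_spikes == 0.0


def test_pipeline_noisy_zero_spike_trace_near_zero():
    """On pure noise the automated threshold admits at most ~1 false call/min."""
    rates = []
    for seed in range(5):
        res = generate_trace(TraceParams(seed=200 + seed, spike_rate_hz=0.0))
        rates.append(process_trace(res.trace).rate_hz_spikes)
    assert np.mean(rates) <= 1.0 / 60.0


def test_pipeline_deterministic():
    res = generate_trace(TraceParams(seed=7))
    a = process_trace(res.trace)
    b = process_trace(res.trace)
    assert np.array_equal(a.spikes.spike_times_s, b.spikes.spike_times_s)
    assert np.array_equal(a.filtered.samples, b.filtered.samples)


def test_pipeline_invariant_to_constant_and_cubic_drift():
    res = generate_trace(TraceParams(seed=9))
    base_out = process_trace(res.trace)
    t = res.trace.times_s
    drift = 50.0 + 3.0 * t - 0.2 * t**2 + 0.004 * t**3
    shifted = VoltageTrace(res.trace.samples + drift, res.trace.rate_hz)
    drift_out = process_trace(shifted)
    # spike times unchanged up to edge effects
    a = base_out.spikes.spike_times_s
    b = drift_out.spikes.spike_times_s
    core_a = a[(a > 0.5) & (a < 59.5)]
    core_b = b[(b > 0.5) & (b < 59.5)]
    assert np.allclose(core_a, core_b, atol=2 / FS)


def test_spike_count_non_increasing_in_threshold():
    res = generate_trace(TraceParams(seed=21))
    counts = []
    for n_sd in (2.0, 3.0, 4.0, 5.0, 6.0):
        out = process_trace(res.trace, PipelineParams(n_sd=n_sd))
        counts.append(out.spikes.n_spikes)
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_f1_degrades_with_shrinking_depth():
    """F1 on a 3-point SNR ladder decreases as spike depth shrinks."""
    f1s = []
    for depth in (6.0, 3.0, 1.5):
        res = generate_trace(TraceParams(seed=31, spike_depth_sd=depth))
        out = process_trace(res.trace)
        true = res.spike_times_s[(res.spike_times_s > 0.3) & (res.spike_times_s < 59.7)]
        tp = match_counts(out.spikes.spike_times_s, true)
        prec = tp / max(1, out.spikes.n_spikes)
        rec = tp / len(true)
        f1s.append(0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec))
    assert f1s[0] >= f1s[1] >= f1s[2]


# --- condition comparison ------------------------------------------------


def test_compare_identical_groups():
    res = compare_conditions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.t == 0.0 and res.p == pytest.approx(1.0)
    assert res.direction == 0


def test_compare_closed_form():
    """{1,2,3} vs {4,5,6}: pooled t and p match hand computation."""
    res = compare_conditions([1, 2, 3], [4, 5, 6])
    # pooled s^2 = (2 + 2) / 4 = 1; se = sqrt(2/3); t = -3/se
    t_expected = -3.0 / np.sqrt(2.0 / 3.0)
    assert res.t == pytest.approx(t_expected, abs=1e-12)
    df = 4
    p_expected = special.betainc(df / 2.0, 0.5, df / (df + t_expected**2))
    assert res.p == pytest.approx(p_expected, abs=1e-12)
    assert res.df == 4 and res.direction == -1


def test_compare_requires_two_per_group():
    with pytest.raises(ValueError):
        compare_conditions([1.0], [2.0, 3.0])
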