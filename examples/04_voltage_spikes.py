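"""Voltage-imaging spike detection and a dawn-vs-dusk rate comparison.

A Voltron-like trace (849 Hz) is detrended of photobleach, low-pass
filtered, baselined with a 1-8 Hz band-pass, and spikes are called at
negative-going local minima.  Firing rates of two conditions are compared
with a two-tailed pooled-variance t test.
"""

import numpy as np

from duskmetrics import compare_conditions, process_trace, select_roi_kmeans
from duskmetrics.synthetic import TraceParams, generate_movie, generate_trace

res = generate_trace(TraceParams(seed=1))
out = process_trace(res.trace)
print(f"60-s trace: {len(res.spike_times_s)} true spikes, "
      f"{out.spikes.n_spikes} detected, rate {out.rate_hz_spikes:.2f} Hz")

mv = generate_movie(TraceParams(seed=2), n_signal_pixels=12, n_background_pixels=52)
roi = select_roi_kmeans(mv.movie, k=2)
acc = (roi.mask == mv.signal_mask).mean()
print(f"k-means ROI: {roi.mask.sum()} signal pixels selected, "
      f"{acc:.0%} agreement with the planted mask")

rng = np.random.default_rng(0)
dawn = [process_trace(generate_trace(TraceParams(seed=int(s))).trace).rate_hz_spikes
        for s in rng.integers(0, 2**31, 6)]
dusk = [process_trace(generate_trace(TraceParams(seed=int(s))).trace).rate_hz_spikes
        for s in rng.integers(0, 2**31, 6)]
t = compare_conditions(dawn, dusk)
print(f"dawn {np.mean(dawn):.2f} Hz vs dusk {np.mean(dusk):.2f} Hz: "
      f"t({t.df}) = {t.t:.2f}, p = {t.p:.2f}")
# Equal true rates at both times of day give a non-significant t test --
# the expected outcome when a neuron's firing does not cycle with time.
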