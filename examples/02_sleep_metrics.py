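"""Score sleep with the 5-min inactivity rule and measure onset after dusk.

Sleep in DAM data is any run of >= 5 zero-count minutes.  Sleep onset
latency is the time from dusk (ZT12, lights-off) to the start of the first
qualifying sleep bout of the night.
"""

import numpy as np

from duskmetrics import score_sleep, sleep_amount, sleep_onset_after_dusk, sleep_profile
from duskmetrics.sleep import AFTERNOON, NIGHT, extract_bouts
from duskmetrics.synthetic import BehaviorParams, generate_behavior

res = generate_behavior(BehaviorParams(n_flies=16, seed=7))
onsets, night_sleep, afternoon_sleep = [], [], []
for f in range(16):
    day = res.counts[f, :1440]
    ind = score_sleep(day)
    onset = sleep_onset_after_dusk(day)
    if onset is not None:
        onsets.append((onset - 12.0) * 60.0)
    night_sleep.append(sleep_amount(ind, NIGHT))
    afternoon_sleep.append(sleep_amount(ind, AFTERNOON))

print(f"n = 16 flies, day 1")
print(f"median sleep-onset latency after dusk : {np.median(onsets):5.1f} min")
print(f"mean night (ZT12-24) sleep            : {np.mean(night_sleep):5.0f} min")
print(f"mean afternoon (ZT6-12) sleep (siesta): {np.mean(afternoon_sleep):5.0f} min")

bouts = extract_bouts(score_sleep(res.counts[0]))
durs = [b.duration_min for b in bouts.bouts]
print(f"fly 0: {len(durs)} sleep bouts, median duration {np.median(durs):.0f} min")
# Latency near the generator's 20-min draw and long consolidated night bouts
# reflect the rapid wake-to-sleep transition flies make after nightfall.
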