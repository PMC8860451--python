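"""Compare dF/F baseline methods and quantify the distortion each introduces.

When baseline fluorescence covaries with behavior (here: higher baseline on
trials with earlier licks), normalizing each trial to its own pre-trial
baseline erases that structure and distorts the trace.  The Distortion Index
compares min-max-normalized raw vs corrected traces over paired early/
rewarded trial windows.
"""

import numpy as np

import ramptime as rt
from ramptime import preprocess as pp

cfg = rt.TaskConfig(iti_end=9.0, sampling_rate=100.0)
session = rt.make_session(rt.GenerativeParams(n_trials=150), cfg, seed=7)
raw = session.channels["gcamp"]
fs = cfg.sampling_rate

pairs = pp.find_trial_pairs(session.trials, fs, len(raw))
print(f"paired ER/RE comparisons found: {len(pairs)}")

timing = slice(int(20.0 * fs), int(23.3 * fs))  # trial-n timing interval
for method in ("normalized_baseline", "multiple_baseline", "moving_average"):
    dff = pp.compute_dff(raw, fs, method, session.trials)
    di = pp.distortion_index(raw, dff, pairs, smooth=0)
    print(f"  {method:20s} mean DI over the timing interval = {np.nanmean(di[timing]):.4f}")
print("baseline normalization shows the largest distortion because it removes")
print("the behaviorally meaningful baseline differences between paired trials.")
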