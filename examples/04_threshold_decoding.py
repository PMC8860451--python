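"""Decode first-lick time from single-trial threshold crossings.

For ramps rising to a common endpoint, the regression slope of crossing time
on first-lick time grows with the threshold level (approaching 1 at the
endpoint); a discrete step would cross every level at the same moment, so
its slope profile is flat.  The nested decoder then shows how much variance
the crossing time explains beyond trial history and baseline signals.
"""

import numpy as np

import ramptime as rt
from ramptime import decode_time as dt
from ramptime import preprocess as pp

cfg = rt.TaskConfig(iti_end=9.0, sampling_rate=100.0)
session = rt.make_session(rt.GenerativeParams(n_trials=300), cfg, seed=13)
fs = cfg.sampling_rate
dff = pp.compute_dff(session.channels["gcamp"], fs, "moving_average", session.trials)
ctrl = pp.compute_dff(session.channels["control"], fs, "moving_average", session.trials)

fl = session.trials["first_lick_time"].to_numpy()
segs, ids = dt.ramping_intervals(session, dff)
res = dt.threshold_slope_analysis(segs, fl[ids])
print("crossing-time vs first-lick-time regression per threshold level:")
print(res[["level_name", "slope", "slope_ci_low", "slope_ci_high", "r2", "n"]]
      .to_string(index=False))
print("rising slopes across low/mid/high levels are the ramp signature.\n")

dec = dt.fit_timelick_decoder(session, dff, ctrl, seed=0)
print("nested decoder of log(first-lick time), held-out R^2 per nest:")
for name, r2 in zip(dec["nests"], dec["r2_cv"]):
    print(f"  {name:18s} {r2:6.3f}")
print("the jump at the baseline/crossing nests shows where the predictive")
print("information lives; crossing time absorbs baseline-explained variance.")
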