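"""Fit the nested encoding GLM and read the loss-improvement ledger.

Nests 0-3 carry timing-independent inputs (offset, control channel, cue and
lick kernels, nuisance movements); nests 4-5 add the timing-dependent
baseline offset and the 500-predictor interval "stretch".  On the signal
channel, the timing-dependent nests cut held-out loss; on the control
channel they do not - the model's way of saying the ramp is real signal,
not artifact.
"""

import ramptime as rt
from ramptime import encoding as enc
from ramptime import preprocess as pp

cfg = rt.TaskConfig(iti_end=9.0, sampling_rate=100.0)
session = rt.make_session(rt.GenerativeParams(n_trials=200), cfg, seed=11)
fs = cfg.sampling_rate
dff = pp.compute_dff(session.channels["gcamp"], fs, "moving_average", session.trials)
ctrl = pp.compute_dff(session.channels["control"], fs, "moving_average", session.trials)

for label, target, other in (("signal", dff, ctrl), ("control", ctrl, dff)):
    fit = enc.fit_nested_ridge(session, target, other, seed=0)
    print(f"\n{label} channel: relative held-out loss improvement per nest")
    print(fit.improvements[["input", "cv_mse", "rel_improvement"]].to_string(index=False))
print("\npositive improvements at 'baseline_offset' and 'stretch' on the signal")
print("channel (and none on the control) indicate timing-dependent structure.")
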