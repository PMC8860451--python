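"""End-to-end pipeline: simulate -> preprocess -> behavior -> encode ->
decode-time -> dynamics -> decode-state -> opto, with per-stage provenance
hashes so identical config + seed yields an identical report."""

from __future__ import annotations

import hashlib
import logging
import time

import numpy as np

from . import behavior, decode_state, decode_time, dynamics, encoding, optostats, preprocess
from .session_io import RunConfig
from .synth import make_session

log = logging.getLogger("ramptime")

STAGES = ["simulate", "preprocess", "behavior", "encode", "decode-time",
          "dynamics", "decode-state", "opto"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _hash(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(np.asarray(a, dtype=float)).tobytes())
    return h.hexdigest()[:16]


def run_pipeline(
    config: RunConfig | None = None,
    seed: int = 0,
    only: list[str] | None = None,
    classify_max_trials: int = 50,
) -> dict:
    """Run the full analysis on one synthetic session.

    ``only`` restricts execution to a stage subset (simulate always runs,
    since later stages need the session).  ``classify_max_trials`` caps the
    per-trial ramp-vs-step classification, the most expensive stage.
    Returns a report with per-stage outputs and provenance hashes.
    """
    config = config or RunConfig()
    wanted = set(only) if only else set(STAGES)
    report: dict = {"seed": seed, "config_hash": config.config_hash(), "stages": {}}

    def stage(name):
        return name in wanted

    t0 = time.time()
    session = make_session(config.generator, config.task, seed=seed)
    report["stages"]["simulate"] = {
        "hash": _hash(session.channels["gcamp"], session.trials["cue_time"].to_numpy()),
        "n_trials": len(session.trials),
        "seconds": round(time.time() - t0, 2),
    }

    dff = control = None
    if wanted & {"preprocess", "behavior", "encode", "decode-time", "dynamics", "decode-state"}:
        t0 = time.time()
        try:
            dff = preprocess.compute_dff(
                session.channels["gcamp"], session.sampling_rate,
                config.dff_method, session.trials, window=config.dff_window,
            )
            control = preprocess.compute_dff(
                session.channels["control"], session.sampling_rate,
                config.dff_method, session.trials, window=config.dff_window,
            )
        except Exception as e:  # noqa: BLE001
            raise StageError("preprocess", e) from e
        report["stages"]["preprocess"] = {
            "hash": _hash(dff.values), "method": dff.method,
            "seconds": round(time.time() - t0, 2),
        }

    fl = session.trials["first_lick_time"].to_numpy()
    if stage("behavior"):
        t0 = time.time()
        try:
            hist = behavior.timing_histogram(fl, config.hazard_bin)
            curve = behavior.hazard_function(hist)
            corr = behavior.baseline_timing_correlation(dff, session.trials, "baseline")
        except Exception as e:  # noqa: BLE001
            raise StageError("behavior", e) from e
        report["stages"]["behavior"] = {
            "hash": _hash(curve.hazard[np.isfinite(curve.hazard)]),
            "baseline_r": corr["r"],
            "seconds": round(time.time() - t0, 2),
        }

    if stage("encode"):
        t0 = time.time()
        try:
            fit = encoding.fit_nested_ridge(session, dff, control, folds=config.folds, seed=seed)
        except Exception as e:  # noqa: BLE001
            raise StageError("encode", e) from e
        report["stages"]["encode"] = {
            "hash": _hash(fit.cv_mse),
            "cv_mse": list(np.round(fit.cv_mse, 8)),
            "improvements": fit.improvements.to_dict("records"),
            "seconds": round(time.time() - t0, 2),
        }

    segs = ids = None
    if wanted & {"decode-time", "dynamics"}:
        segs, ids = decode_time.ramping_intervals(session, dff)

    if stage("decode-time"):
        t0 = time.time()
        try:
            dec = decode_time.fit_timelick_decoder(session, dff, control,
                                                   folds=config.folds, seed=seed)
            slopes = decode_time.threshold_slope_analysis(segs, fl[ids])
        except Exception as e:  # noqa: BLE001
            raise StageError("decode-time", e) from e
        report["stages"]["decode-time"] = {
            "hash": _hash(dec["r2_cv"]),
            "r2_cv": list(np.round(dec["r2_cv"], 6)),
            "slopes": slopes.to_dict("records"),
            "seconds": round(time.time() - t0, 2),
        }

    if stage("dynamics"):
        t0 = time.time()
        try:
            rng = np.random.default_rng(seed)
            pick = rng.choice(len(segs), size=min(classify_max_trials, len(segs)), replace=False)
            p_ramp = [
                dynamics.classify_trial(
                    segs[i], session.sampling_rate,
                    config.n_traces, config.n_rounds, seed=seed + int(i),
                ).p_ramp
                for i in pick
            ]
        except Exception as e:  # noqa: BLE001
            raise StageError("dynamics", e) from e
        report["stages"]["dynamics"] = {
            "hash": _hash(p_ramp),
            "median_p_ramp": float(np.median(p_ramp)),
            "n_classified": len(p_ramp),
            "seconds": round(time.time() - t0, 2),
        }

    if stage("decode-state"):
        t0 = time.time()
        try:
            series = decode_state.build_state_series(session, dff, fs=config.state_fs)
            sfit = decode_state.fit_state_model(series, n_boot=20, seed=seed)
            hz = decode_state.fitted_hazard(sfit, series, fl[np.isfinite(fl)])
        except Exception as e:  # noqa: BLE001
            raise StageError("decode-state", e) from e
        report["stages"]["decode-state"] = {
            "hash": _hash(sfit.coef[-1]),
            "hazard_r2": hz["r2"],
            "seconds": round(time.time() - t0, 2),
        }

    if stage("opto") and session.trials["opto_on"].any():
        t0 = time.time()
        try:
            cmp_ = optostats.compare_opto_session(
                session.trials, n_boot=min(config.n_boot, 100_000),
                n_perm=config.n_perm, seed=seed,
            )
        except Exception as e:  # noqa: BLE001
            raise StageError("opto", e) from e
        report["stages"]["opto"] = {
            "hash": _hash([cmp_.ks_d, cmp_.delta_median, cmp_.dauc]),
            "ks_d": cmp_.ks_d, "ks_p": cmp_.ks_p,
            "delta_median": cmp_.delta_median, "dauc": cmp_.dauc,
            "seconds": round(time.time() - t0, 2),
        }

    return report
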