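"""Session store: HDF5 round trip, CSV trial-table export, run configuration.

Schema (version 1):
  /channels/<name>   float series; attrs: rate (Hz), units
  /events/<name>     sorted event times (s)
  /trials/<column>   per-trial columns (outcome stored as UTF-8 strings)
  /derived/<stage>/  stage outputs (free-form datasets)
  /meta              attrs: schema_version, seed, config_yaml, config_hash
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .config import GenerativeParams, KernelParams, OptoParams, TaskConfig
from .synth import SessionTimeline

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """Raised when a session file does not match the expected schema."""


def _to_plain(obj):
    if is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class RunConfig:
    """Every pipeline stage's parameters, serializable to YAML.

    Defaults carry the study's printed constants: 250 ms hazard bins, 200 s
    moving-average dF/F window, 0.7/0.6 s ramping-interval buffers, 100
    candidate thresholds, 20 traces x 50 refinement rounds, 100 Hz state
    model, 10^4 permutations and 10^6 bootstrap draws.
    """

    task: TaskConfig = field(default_factory=TaskConfig)
    generator: GenerativeParams = field(default_factory=GenerativeParams)
    dff_method: str = "moving_average"
    dff_window: float = 200.0
    hazard_bin: float = 0.25
    cue_buffer: float = 0.7
    lick_buffer: float = 0.6
    n_thresholds: int = 100
    n_traces: int = 20
    n_rounds: int = 50
    state_fs: float = 100.0
    n_boot: int = 1_000_000
    n_perm: int = 10_000
    folds: int = 5

    def to_dict(self) -> dict:
        return _to_plain(self)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = yaml.safe_load(text) or {}
        task = TaskConfig(**d.pop("task", {}))
        gd = d.pop("generator", {})
        for kname in ("cue_kernel", "lick_kernel", "reward_kernel"):
            if kname in gd and isinstance(gd[kname], dict):
                gd[kname] = KernelParams(**gd[kname])
        if gd.get("opto") is not None and isinstance(gd.get("opto"), dict):
            gd["opto"] = OptoParams(**gd["opto"])
        gen = GenerativeParams(**gd)
        return cls(task=task, generator=gen, **d)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def write_session(session: SessionTimeline, path: str | Path, config: RunConfig | None = None) -> None:
    """Write a session to the HDF5 store (lossless for channels/events/trials)."""
    with h5py.File(path, "w") as f:
        ch = f.create_group("channels")
        for name, values in session.channels.items():
            d = ch.create_dataset(name, data=np.asarray(values, dtype=float))
            d.attrs["rate"] = session.sampling_rate
            d.attrs["units"] = "Hz"
        ev = f.create_group("events")
        for name, times in session.events.items():
            d = ev.create_dataset(name, data=np.asarray(times, dtype=float))
            d.attrs["units"] = "seconds"
        tg = f.create_group("trials")
        for col in session.trials.columns:
            v = session.trials[col]
            if v.dtype == object or str(v.dtype) == "category":
                tg.create_dataset(col, data=v.astype(str).to_numpy().astype("S"))
            else:
                tg.create_dataset(col, data=v.to_numpy())
        f.create_group("derived")
        meta = f.create_group("meta")
        meta.attrs["schema_version"] = SCHEMA_VERSION
        meta.attrs["seed"] = int(session.meta.get("seed", -1))
        if config is not None:
            meta.attrs["config_yaml"] = config.to_yaml()
            meta.attrs["config_hash"] = config.config_hash()


def read_session(path: str | Path) -> SessionTimeline:
    """Read a session store, checking the schema version and required groups."""
    with h5py.File(path, "r") as f:
        if "meta" not in f or f["meta"].attrs.get("schema_version") != SCHEMA_VERSION:
            raise SchemaError(
                f"schema version mismatch (expected {SCHEMA_VERSION}); migrate the file"
            )
        for group in ("channels", "events", "trials"):
            if group not in f:
                raise SchemaError(f"missing required group '/{group}'")
        channels = {}
        rate = None
        for name, d in f["channels"].items():
            channels[name] = d[...]
            rate = float(d.attrs["rate"])
        events = {name: d[...] for name, d in f["events"].items()}
        cols = {}
        for name, d in f["trials"].items():
            v = d[...]
            cols[name] = v.astype(str) if v.dtype.kind == "S" else v
        trials = pd.DataFrame(cols)
        if "outcome" in trials:
            trials["outcome"] = pd.Categorical(
                trials["outcome"],
                categories=["reaction", "early", "reward", "iti_lick", "no_lick"],
            )
        meta = {"seed": int(f["meta"].attrs.get("seed", -1))}
        if "config_yaml" in f["meta"].attrs:
            meta["config_yaml"] = str(f["meta"].attrs["config_yaml"])
    order = [c for c in ["trial", "lampoff_time", "cue_time", "first_lick_time",
                         "outcome", "opto_on", "gt_baseline_offset", "gt_ramp_slope",
                         "gt_step_time"] if c in trials.columns]
    trials = trials[order + [c for c in trials.columns if c not in order]]
    return SessionTimeline(channels=channels, events=events, trials=trials,
                           sampling_rate=rate, meta=meta)


def write_derived(path: str | Path, stage: str, arrays: dict) -> None:
    """Store stage outputs under /derived/<stage>, replacing earlier runs."""
    with h5py.File(path, "a") as f:
        g = f.require_group("derived")
        if stage in g:
            del g[stage]
        sg = g.create_group(stage)
        for name, v in arrays.items():
            sg.create_dataset(name, data=np.asarray(v))


def export_trials_csv(session: SessionTimeline, path: str | Path) -> None:
    session.trials.to_csv(path, index=False)


def import_trials_csv(path: str | Path) -> pd.DataFrame:
    trials = pd.read_csv(path)
    trials["outcome"] = pd.Categorical(
        trials["outcome"], categories=["reaction", "early", "reward", "iti_lick", "no_lick"]
    )
    return trials
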