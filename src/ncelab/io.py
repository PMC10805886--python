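"""Session container I/O.

One HDF5 file per session:

```
/                      attrs: schema_version, session_id, subject_id,
                              subjects, meta (JSON)
/trials/<field>        columnar event times (float64, NaN = absent) and
                       condition labels (fixed-width bytes)
/units/<unit_id>/spike_times    flat float64 ms, cue-onset referenced
/units/<unit_id>/trial_offsets  int64, len n_trials + 1 (ragged index)
                       attrs: channel, optional selection results
```

All times are milliseconds as 64-bit floats, so a write/read round trip is
bit exact.  Unknown schema versions are rejected loudly.
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import List

import h5py
import numpy as np

from .datamodel import SelectionResult, SessionData, UnitSpikes
from .task import TaskTimeline, Trial, TrialCondition

__all__ = [
    "SCHEMA_VERSION",
    "SessionIOError",
    "SchemaVersionError",
    "SessionFormatError",
    "SessionValidationError",
    "UnsupportedDepositLayoutError",
    "write_session",
    "read_session",
    "export_condition_table",
    "import_zenodo",
]

SCHEMA_VERSION = "ncelab-session-1"

_TIME_FIELDS = ("fixation_onset", "rule_cue_onset", "rule_cue_offset",
                "stimuli_onset", "cue_onset", "cue_offset",
                "distractor_dim_onset", "target_dim_onset", "response_time",
                "trial_end")
_LABEL_FIELDS = ("rule", "congruency", "target_side", "cue_side",
                 "cue_color", "outcome")
_SELECTION_KEYS = ("statistic", "p", "passed", "untestable", "note")


class SessionIOError(Exception):
    """Base class for session-container errors."""


class SchemaVersionError(SessionIOError):
    """The file declares an unknown or missing schema version."""


class SessionFormatError(SessionIOError):
    """Required groups or datasets are missing or malformed."""


class SessionValidationError(SessionIOError):
    """The stored data violate session invariants (e.g. unsorted spikes)."""


class UnsupportedDepositLayoutError(SessionIOError):
    """A deposit directory does not match any layout the adapter knows."""


def write_session(session: SessionData, path: str) -> None:
    """Write a validated session; invariant violations abort before writing."""
    try:
        session.validate()
    except ValueError as exc:
        raise SessionValidationError(str(exc)) from exc
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["session_id"] = session.session_id
        f.attrs["subject_id"] = session.subject_id
        f.attrs["subjects"] = json.dumps(list(session.subjects))
        f.attrs["meta"] = json.dumps(session.meta, default=str)
        g = f.create_group("trials")
        n = session.n_trials
        for name in _TIME_FIELDS:
            vals = np.array(
                [np.nan if getattr(t.timeline, name) is None
                 else float(getattr(t.timeline, name)) for t in session.trials],
                dtype=np.float64)
            g.create_dataset(name, data=vals)
        for name in _LABEL_FIELDS:
            vals = np.array([getattr(t.condition, name) for t in session.trials],
                            dtype="S16")
            g.create_dataset(name, data=vals)
        ug = f.create_group("units")
        for u in session.units:
            uu = ug.create_group(u.unit_id)
            offsets = np.zeros(n + 1, dtype=np.int64)
            for i, st in enumerate(u.spikes):
                offsets[i + 1] = offsets[i] + len(st)
            flat = (np.concatenate([np.asarray(s, dtype=np.float64)
                                    for s in u.spikes])
                    if offsets[-1] else np.empty(0, dtype=np.float64))
            uu.create_dataset("spike_times", data=flat)
            uu.create_dataset("trial_offsets", data=offsets)
            uu.attrs["channel"] = int(u.channel)
            for test_name, res in u.selection.items():
                uu.attrs[f"selection/{test_name}"] = json.dumps({
                    "statistic": res.statistic, "p": res.p,
                    "passed": bool(res.passed),
                    "untestable": bool(res.untestable), "note": res.note})


def read_session(path: str) -> SessionData:
    """Read and re-validate a session container."""
    if not os.path.exists(path):
        raise SessionIOError(f"no such file: {path}")
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version is None:
            raise SchemaVersionError(f"{path}: missing schema_version")
        if version != SCHEMA_VERSION:
            raise SchemaVersionError(
                f"{path}: unsupported schema version {version!r} "
                f"(expected {SCHEMA_VERSION!r})")
        if "trials" not in f or "units" not in f:
            raise SessionFormatError(f"{path}: missing /trials or /units group")
        g = f["trials"]
        for name in _TIME_FIELDS + _LABEL_FIELDS:
            if name not in g:
                raise SessionFormatError(f"{path}: missing /trials/{name}")
        times = {name: np.asarray(g[name], dtype=float) for name in _TIME_FIELDS}
        labels = {name: [v.decode() for v in g[name][()]]
                  for name in _LABEL_FIELDS}
        n = len(times["cue_onset"])
        trials: List[Trial] = []
        for i in range(n):
            kw = {}
            for name in _TIME_FIELDS:
                v = times[name][i]
                kw[name] = None if np.isnan(v) else float(v)
            tl = TaskTimeline(**kw)
            cond = TrialCondition(**{name: labels[name][i]
                                     for name in _LABEL_FIELDS})
            trials.append(Trial(timeline=tl, condition=cond))
        units: List[UnitSpikes] = []
        for unit_id in f["units"]:
            uu = f["units"][unit_id]
            if "spike_times" not in uu or "trial_offsets" not in uu:
                raise SessionFormatError(
                    f"{path}: unit {unit_id} missing spike_times/trial_offsets")
            flat = np.asarray(uu["spike_times"], dtype=np.float64)
            offsets = np.asarray(uu["trial_offsets"], dtype=np.int64)
            if offsets.size != n + 1 or offsets[0] != 0 or offsets[-1] != flat.size:
                raise SessionFormatError(
                    f"{path}: unit {unit_id} has inconsistent trial offsets")
            spikes = [flat[offsets[i]:offsets[i + 1]].copy() for i in range(n)]
            sel = {}
            for key in uu.attrs:
                if key.startswith("selection/"):
                    d = json.loads(uu.attrs[key])
                    sel[key.split("/", 1)[1]] = SelectionResult(
                        statistic=d["statistic"], p=d["p"], passed=d["passed"],
                        untestable=d["untestable"], note=d["note"])
            units.append(UnitSpikes(unit_id=unit_id,
                                    channel=int(uu.attrs.get("channel", -1)),
                                    spikes=spikes, selection=sel))
        meta = json.loads(f.attrs.get("meta", "{}"))
        subjects = tuple(json.loads(f.attrs.get("subjects", '["S", "R"]')))
        session = SessionData(session_id=str(f.attrs["session_id"]),
                              subject_id=str(f.attrs["subject_id"]),
                              trials=trials, units=units, subjects=subjects,
                              meta=meta)
    try:
        session.validate()
    except ValueError as exc:
        raise SessionValidationError(f"{path}: {exc}") from exc
    return session


def export_condition_table(session: SessionData, path: str) -> None:
    """Write the per-trial condition table as CSV.

    Columns: trial index, rule, congruency, target_side, cue_side,
    cue_color, outcome, and the jittered event times (ms, cue-referenced;
    empty = absent).
    """
    session.condition_table().to_csv(path, index=False)


def import_zenodo(path: str) -> List[SessionData]:
    """Adapt a local copy of a data deposit into SessionData objects.

    The adapter accepts a directory containing one or more session
    containers in this package's HDF5 layout (any ``*.h5``/``*.hdf5``
    files).  Any other layout raises
    :class:`UnsupportedDepositLayoutError` with an inventory of the files
    seen, so unmapped content is surfaced rather than silently dropped.
    """
    if not os.path.exists(path):
        raise SessionIOError(f"deposit path does not exist: {path}")
    if os.path.isfile(path):
        candidates = [path]
        inventory = [os.path.basename(path)]
    else:
        inventory = sorted(os.listdir(path))
        candidates = [os.path.join(path, name) for name in inventory
                      if name.endswith((".h5", ".hdf5"))]
    if not candidates:
        raise UnsupportedDepositLayoutError(
            "unsupported deposit layout: no session containers found; "
            f"files seen: {inventory}")
    sessions = []
    errors = []
    for c in sorted(candidates):
        try:
            sessions.append(read_session(c))
        except SessionIOError as exc:
            errors.append(f"{os.path.basename(c)}: {exc}")
    if not sessions:
        raise UnsupportedDepositLayoutError(
            "unsupported deposit layout: no readable session containers; "
            f"files seen: {inventory}; errors: {errors}")
    return sessions
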