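"""Readers/writers for the pipeline's on-disk artifacts.

Events travel as BIDS-events-dialect TSV (times in seconds, RT in ms,
0-based run/block indices, documented in a JSON sidecar); patterns as an
HDF5 container keyed subject/ROI; configs as JSON or YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

EVENTS_COLUMNS = ["onset", "duration", "subject", "run", "block", "trial",
                  "context", "trial_type", "task", "accuracy", "rt_ms",
                  "post_error"]

EVENTS_SIDECAR = {
    "onset": {"Description": "event onset within run", "Units": "s"},
    "duration": {"Description": "stimulus duration", "Units": "s"},
    "subject": {"Description": "0-based subject index"},
    "run": {"Description": "0-based run index"},
    "block": {"Description": "0-based block index within run"},
    "trial": {"Description": "0-based trial index within block; -1 marks "
                             "room-onset events"},
    "context": {"Description": "0-based spatial context (room) id"},
    "trial_type": {"Levels": {"context_onset": "room interior onset",
                              "trial_cue": "task-cue onset"}},
    "task": {"Levels": {"0": "face", "1": "object"},
             "Description": "-1 for room-onset events"},
    "accuracy": {"Levels": {"0": "incorrect", "1": "correct"}},
    "rt_ms": {"Description": "response time", "Units": "ms"},
    "post_error": {"Description": "trial immediately follows an error "
                                  "within the same block"},
}


def write_events_tsv(trials_by_subject: dict, path) -> None:
    """Write all subjects' trial tables as one events TSV + JSON sidecar."""
    path = Path(path)
    frames = []
    for subject, trials in trials_by_subject.items():
        df = trials.copy()
        df["subject"] = subject
        df["onset"] = df["cue_onset"]
        df["duration"] = 0.25
        df["trial_type"] = "trial_cue"
        frames.append(df[EVENTS_COLUMNS])
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
    path.with_suffix(".json").write_text(
        json.dumps(EVENTS_SIDECAR, indent=2) + "\n")


def read_events_tsv(path) -> dict:
    """Read an events TSV back into {subject: trial table}."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for subject, grp in df.groupby("subject"):
        trials = grp.rename(columns={"onset": "cue_onset"}).drop(
            columns=["duration", "subject", "trial_type"])
        trials["congruent"] = np.nan  # restored by the caller from the design
        out[int(subject)] = trials.reset_index(drop=True)
    return out


def write_patterns_h5(patterns_by_subject: dict, path) -> None:
    """Patterns to HDF5: /sub-<i>/<roi>/{data,events-as-columns}."""
    with h5py.File(path, "w") as f:
        for subject, rois in patterns_by_subject.items():
            g_sub = f.create_group(f"sub-{subject}")
            for name, pset in rois.items():
                g = g_sub.create_group(name)
                g.create_dataset("data", data=pset.data)
                ev = g.create_group("events")
                for col in pset.events.columns:
                    vals = pset.events[col].to_numpy()
                    if vals.dtype == object:
                        vals = vals.astype("S")
                    ev.create_dataset(col, data=vals)


def read_patterns_h5(path) -> dict:
    from .glm import PatternSet

    out: dict = {}
    with h5py.File(path, "r") as f:
        for sub_key in f:
            subject = int(sub_key.split("-")[1])
            out[subject] = {}
            for name in f[sub_key]:
                g = f[sub_key][name]
                cols = {}
                for col in g["events"]:
                    vals = g["events"][col][()]
                    if vals.dtype.kind == "S":
                        vals = vals.astype(str)
                    cols[col] = vals
                events = pd.DataFrame(cols)
                out[subject][name] = PatternSet(
                    roi=name, data=g["data"][()], events=events)
    return out


def load_config_file(path) -> dict:
    """JSON or YAML config to a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml
        return yaml.safe_load(text)
    return json.loads(text)
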