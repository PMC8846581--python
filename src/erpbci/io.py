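"""File formats: BIDS-style events TSV, the continuous-EEG array
container with a JSON sidecar, classifier serialization and run
manifests.

The EEG container is a ``.npy`` array (channels x samples, float32
microvolts) next to a ``<stem>.json`` sidecar holding the sampling rate,
channel names and markers, so every recording round-trips losslessly up
to float32 quantization without binary container dependencies.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .decoder import LDAClassifier
from .paradigm import Role, StimulusEvent
from .simulate import ContinuousEEG

__all__ = [
    "EVENT_COLUMNS",
    "read_events",
    "write_events",
    "read_eeg",
    "write_eeg",
    "save_classifier",
    "load_classifier",
    "RunManifest",
]

EVENT_COLUMNS = (
    "onset",
    "duration",
    "trial_type",
    "word_id",
    "direction",
    "trial_id",
    "run_id",
)


def write_events(path, events: list[StimulusEvent]) -> None:
    """Write stimulus events as a tab-separated BIDS-style events file."""
    df = pd.DataFrame(
        {
            "onset": [e.onset_s for e in events],
            "duration": [e.duration_s for e in events],
            "trial_type": [Role(e.role).value for e in events],
            "word_id": [e.word_id for e in events],
            "direction": [e.direction for e in events],
            "trial_id": [e.trial_id for e in events],
            "run_id": [e.run_id for e in events],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_events(path) -> list[StimulusEvent]:
    """Read an events TSV (columns located by header, any order)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"events file {path} missing columns: {sorted(missing)}")
    bad = pd.to_numeric(df["onset"], errors="coerce").isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise ValueError(f"malformed onset value at line {line} of {path}")
    return [
        StimulusEvent(
            onset_s=float(r.onset),
            word_id=int(r.word_id),
            role=Role(r.trial_type),
            direction=int(r.direction),
            trial_id=int(r.trial_id),
            run_id=int(r.run_id),
            duration_s=float(r.duration),
        )
        for r in df.itertuples()
    ]


def write_eeg(path, eeg: ContinuousEEG) -> None:
    """Write the array container + JSON sidecar (see module docstring)."""
    path = Path(path)
    if path.suffix != ".npy":
        path = path.with_suffix(".npy")
    np.save(path, eeg.data.astype(np.float32))
    sidecar = {
        "fs_hz": eeg.fs_hz,
        "channel_names": list(eeg.channel_names),
        "markers": [
            {"sample": int(idx), **_event_dict(ev)} for idx, ev in eeg.markers
        ],
        "n_samples": int(eeg.data.shape[1]),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_eeg(path) -> ContinuousEEG:
    path = Path(path)
    if path.suffix != ".npy":
        path = path.with_suffix(".npy")
    data = np.load(path).astype(float)
    if data.size == 0:
        raise ValueError(f"empty recording in {path}")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    names = tuple(sidecar["channel_names"])
    if data.shape[0] != len(names):
        raise ValueError(
            f"channel count mismatch: data has {data.shape[0]}, sidecar lists {len(names)}"
        )
    markers = [
        (int(m["sample"]), _event_from_dict(m)) for m in sidecar["markers"]
    ]
    return ContinuousEEG(
        data=data, fs_hz=float(sidecar["fs_hz"]), channel_names=names, markers=markers
    )


def _event_dict(ev: StimulusEvent) -> dict:
    return {
        "onset_s": ev.onset_s,
        "word_id": ev.word_id,
        "role": Role(ev.role).value,
        "direction": ev.direction,
        "trial_id": ev.trial_id,
        "run_id": ev.run_id,
        "duration_s": ev.duration_s,
    }


def _event_from_dict(d: dict) -> StimulusEvent:
    return StimulusEvent(
        onset_s=float(d["onset_s"]),
        word_id=int(d["word_id"]),
        role=Role(d["role"]),
        direction=int(d["direction"]),
        trial_id=int(d["trial_id"]),
        run_id=int(d["run_id"]),
        duration_s=float(d.get("duration_s", 0.3)),
    )


def save_classifier(path, clf: LDAClassifier, history: list[dict] | None = None) -> None:
    """Serialize classifier state (w, b, means, sigma, gamma) for
    session-to-session transfer; arrays go to an .npz, scalars and the
    adaptation history to a JSON sidecar."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    np.savez(
        path,
        w=clf.w,
        mu_target=clf.mu_target,
        mu_nontarget=clf.mu_nontarget,
        sigma=clf.sigma,
    )
    meta = {"b": clf.b, "gamma": clf.gamma, "history": history or []}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_classifier(path) -> LDAClassifier:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    arrays = np.load(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return LDAClassifier(
        w=arrays["w"],
        b=float(meta["b"]),
        mu_target=arrays["mu_target"],
        mu_nontarget=arrays["mu_nontarget"],
        sigma=arrays["sigma"],
        gamma=float(meta["gamma"]),
    )


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline invocation."""

    command: str
    config: dict
    seed: int | None
    outputs: list[str] = field(default_factory=list)
    log: list[dict] = field(default_factory=list)

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def log_stage(self, stage: str, **info) -> None:
        self.log.append({"stage": stage, "time": time.time(), **info})

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))
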