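"""File formats: signals, schedules, score tables and decoder models.

Signals are stored as delimited text (one row per sample, one column per
channel, mV) with a JSON sidecar carrying the metadata (sample rate,
channel count, units, subject/limb ids, generator seed when synthetic).
Plain text is deliberately chosen over a binary container: inspectable,
diffable, and adequate at desk scale.  Round trips are lossless to
1e-9 mV.

Schedules are CSV ``class_id,onset_s,duration_s``; session scores are CSV
with one row per (limb, set, session); trained decoders are a single JSON
document.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .classify import LDAModel
from .core import CueEntry, CueSchedule, EMGRecording, MotionSet, SessionScore

__all__ = [
    "SignalFormatError",
    "write_signal",
    "read_signal",
    "write_schedule",
    "read_schedule",
    "write_scores",
    "read_scores",
    "write_model",
    "read_model",
    "write_motion_set",
    "read_motion_set",
]


class SignalFormatError(ValueError):
    """Data file and sidecar metadata disagree, or the file is malformed."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_signal(
    path: str | Path,
    rec: EMGRecording,
    subject_id: str = "",
    limb_id: str = "",
    seed: int | None = None,
) -> None:
    """Write a recording as samples-by-channels CSV plus a JSON sidecar."""
    path = Path(path)
    header = ",".join(f"ch{c}" for c in range(rec.n_channels))
    np.savetxt(path, rec.samples.T, fmt="%.12g", delimiter=",", header=header, comments="")
    meta = {
        "sample_rate": rec.sample_rate,
        "channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "units": "mV",
        "start_time": rec.start_time,
        "subject_id": subject_id,
        "limb_id": limb_id,
    }
    if seed is not None:
        meta["seed"] = seed
    _sidecar_path(path).write_text(json.dumps(meta, indent=2) + "\n")


def read_signal(path: str | Path) -> tuple[EMGRecording, dict]:
    """Read a signal file and its sidecar, validating shape against metadata."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise SignalFormatError(f"missing sidecar metadata file {sidecar}")
    meta = json.loads(sidecar.read_text())
    try:
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    except ValueError as exc:
        raise SignalFormatError(f"malformed signal data in {path}: {exc}") from exc
    n_samples, n_channels = data.shape
    if n_channels != meta["channels"]:
        raise SignalFormatError(
            f"{path}: data has {n_channels} columns but metadata declares "
            f"{meta['channels']} channels"
        )
    if "n_samples" in meta and n_samples != meta["n_samples"]:
        raise SignalFormatError(
            f"{path}: data has {n_samples} rows but metadata declares "
            f"{meta['n_samples']} samples"
        )
    rec = EMGRecording(
        data.T, meta["sample_rate"], meta.get("start_time", 0.0)
    )
    return rec, meta


def write_schedule(path: str | Path, schedule: CueSchedule) -> None:
    df = pd.DataFrame(
        [
            {"class_id": e.class_id, "onset_s": e.onset_s, "duration_s": e.duration_s}
            for e in schedule
        ],
        columns=["class_id", "onset_s", "duration_s"],
    )
    df.to_csv(path, index=False)


def read_schedule(path: str | Path) -> CueSchedule:
    df = pd.read_csv(path)
    entries = [
        CueEntry(int(r.class_id), float(r.onset_s), float(r.duration_s))
        for r in df.itertuples()
    ]
    return CueSchedule(entries)


def write_scores(path: str | Path, scores: Iterable[SessionScore]) -> None:
    from .stats import scores_to_frame

    scores_to_frame(scores).to_csv(path, index=False)


def read_scores(path: str | Path) -> list[SessionScore]:
    df = pd.read_csv(path)
    return [
        SessionScore(
            subject_id=str(r.subject_id),
            limb_id=str(r.limb_id),
            session_index=int(r.session_index),
            day_offset=float(r.day_offset),
            motion_set=str(r.motion_set),
            mean_accuracy=float(r.mean_accuracy),
        )
        for r in df.itertuples()
    ]


def write_model(
    path: str | Path, model: LDAModel, vocabulary: MotionSet | None = None,
    feature_fingerprint: str = "",
) -> None:
    """Serialize a trained decoder (means, covariance, priors, vocabulary)."""
    doc = {
        "class_ids": model.class_ids.tolist(),
        "means": model.means.tolist(),
        "pooled_covariance": model.pooled_covariance.tolist(),
        "priors": model.priors.tolist(),
        "shrinkage_lambda": model.shrinkage_lambda,
        "feature_fingerprint": feature_fingerprint,
    }
    if vocabulary is not None:
        doc["vocabulary"] = {
            "name": vocabulary.name,
            "classes": [{"id": c.id, "name": c.name} for c in vocabulary],
        }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_model(path: str | Path) -> tuple[LDAModel, MotionSet | None]:
    doc = json.loads(Path(path).read_text())
    model = LDAModel(
        class_ids=np.array(doc["class_ids"]),
        means=np.array(doc["means"]),
        pooled_covariance=np.array(doc["pooled_covariance"]),
        priors=np.array(doc["priors"]),
        shrinkage_lambda=doc["shrinkage_lambda"],
    )
    vocab = None
    if "vocabulary" in doc:
        from .core import MotionClass

        v = doc["vocabulary"]
        vocab = MotionSet(
            v["name"], tuple(MotionClass(c["id"], c["name"]) for c in v["classes"])
        )
    return model, vocab


def write_motion_set(path: str | Path, motion_set: MotionSet) -> None:
    doc = {
        "name": motion_set.name,
        "classes": [{"id": c.id, "name": c.name} for c in motion_set],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_motion_set(path: str | Path) -> MotionSet:
    from .core import MotionClass

    doc = json.loads(Path(path).read_text())
    return MotionSet(
        doc["name"], tuple(MotionClass(c["id"], c["name"]) for c in doc["classes"])
    )
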