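"""Domain vocabulary and recording/session data model.

Motion classes are purely categorical labels; there is no kinematic model
behind them.  The four canonical vocabularies mirror the training curricula
of a virtual prosthetic-training platform:

* ``PASSIVE11`` — the 11-motion passive (avatar-following) curriculum,
* ``BASIC`` — 6 wrist/hand motions,
* ``ADVANCED`` — the Basic set plus three complex grasps (9 motions),
* ``DIGIT`` — individual finger control plus hand open (6 motions).

Recordings are multi-channel surface EMG (sEMG): a circumferential array of
electrodes around the residual limb, sampled at 1 kHz, amplitudes in mV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MotionClass",
    "MotionSet",
    "EMGRecording",
    "CueSchedule",
    "LabelStream",
    "SessionScore",
    "build_standard_sets",
    "union_class_count",
    "UNLABELED",
]

#: Label value meaning "no cue / rest / unlabeled".
UNLABELED: int = -1


@dataclass(frozen=True)
class MotionClass:
    """A discrete intended movement (e.g. ``wrist flexion``)."""

    id: int
    name: str

    def __post_init__(self) -> None:
        if self.id < 0:
            raise ValueError(f"motion class id must be non-negative, got {self.id}")
        if not self.name:
            raise ValueError("motion class name must be non-empty")


@dataclass(frozen=True)
class MotionSet:
    """An ordered, duplicate-free vocabulary of motion classes.

    Class ids are assigned by list order, 0-based, so a vocabulary
    serializes deterministically.
    """

    name: str
    classes: tuple[MotionClass, ...]

    def __post_init__(self) -> None:
        ids = [c.id for c in self.classes]
        names = [c.name for c in self.classes]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate class ids in motion set {self.name!r}")
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate class names in motion set {self.name!r}")

    def __len__(self) -> int:
        return len(self.classes)

    def __iter__(self):
        return iter(self.classes)

    @property
    def ids(self) -> list[int]:
        return [c.id for c in self.classes]

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.classes]

    def id_of(self, name: str) -> int:
        for c in self.classes:
            if c.name == name:
                return c.id
        raise KeyError(f"no class named {name!r} in motion set {self.name!r}")

    def name_of(self, class_id: int) -> str:
        for c in self.classes:
            if c.id == class_id:
                return c.name
        raise KeyError(f"no class id {class_id} in motion set {self.name!r}")

    @classmethod
    def from_names(cls, name: str, class_names: Sequence[str]) -> "MotionSet":
        return cls(name, tuple(MotionClass(i, n) for i, n in enumerate(class_names)))


# The passive curriculum names five motions explicitly (wrist flexion,
# extension, pronation, supination, hand open); the remaining six are grasp
# patterns and wrist motions drawn from the active curricula.  Their exact
# identities carry no algorithmic weight — they are labels only — and the
# vocabulary is user-configurable via MotionSet.from_names.
_PASSIVE11_NAMES = (
    "wrist flexion",
    "wrist extension",
    "wrist pronation",
    "wrist supination",
    "hand open",
    "cylindrical grasp",
    "lateral grasp",
    "spherical grasp",
    "pointer grasp",
    "wrist radial deviation",
    "wrist ulnar deviation",
)

_BASIC_NAMES = (
    "wrist rotation in",
    "wrist rotation out",
    "wrist flexion",
    "wrist extension",
    "cylindrical grasp",
    "hand open",
)

_ADVANCED_NAMES = _BASIC_NAMES + (
    "lateral grasp",
    "spherical grasp",
    "pointer grasp",
)

_DIGIT_NAMES = (
    "thumb",
    "index finger",
    "middle finger",
    "ring finger",
    "little finger",
    "hand open",
)


def build_standard_sets() -> dict[str, MotionSet]:
    """Return the four canonical motion vocabularies.

    ``BASIC`` (6) is a strict subset of ``ADVANCED`` (9, adding the lateral,
    spherical and pointer grasps); ``DIGIT`` (6) covers the five fingers plus
    hand open, which is the single class it shares with ``BASIC``;
    ``PASSIVE11`` (11) is the passive-training curriculum.
    """
    return {
        "PASSIVE11": MotionSet.from_names("PASSIVE11", _PASSIVE11_NAMES),
        "BASIC": MotionSet.from_names("BASIC", _BASIC_NAMES),
        "ADVANCED": MotionSet.from_names("ADVANCED", _ADVANCED_NAMES),
        "DIGIT": MotionSet.from_names("DIGIT", _DIGIT_NAMES),
    }


def union_class_count(sets: Iterable[MotionSet]) -> int:
    """Number of distinct class names across the given motion sets.

    Order-invariant and idempotent; e.g. Basic ∪ Advanced ∪ Digit spans
    14 distinct motions.
    """
    sets = list(sets)
    if not sets:
        raise ValueError("union_class_count requires at least one motion set")
    names: set[str] = set()
    for s in sets:
        names.update(s.names)
    return len(names)


@dataclass
class EMGRecording:
    """A multi-channel sEMG recording.

    Parameters
    ----------
    samples
        ``channels x T`` array of amplitudes in mV.
    sample_rate
        Sampling rate in Hz (default 1000).
    start_time
        Offset of the first sample, in seconds.
    """

    samples: np.ndarray
    sample_rate: float = 1000.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError(
                f"samples must be a 2-D channels x T array, got ndim={self.samples.ndim}"
            )
        if self.samples.shape[1] < 1:
            raise ValueError("recording must contain at least one sample")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass(frozen=True)
class CueEntry:
    class_id: int
    onset_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"cue duration must be positive, got {self.duration_s}")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class CueSchedule:
    """A time-sorted, non-overlapping sequence of motion cues.

    Cue intervals are half-open: ``[onset, onset + duration)``.
    """

    entries: list[CueEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        for prev, cur in zip(self.entries, self.entries[1:]):
            if cur.onset_s < prev.onset_s:
                raise ValueError("cue schedule entries must be time-sorted")
            if cur.onset_s < prev.end_s - 1e-12:
                raise ValueError(
                    f"overlapping cues: [{prev.onset_s}, {prev.end_s}) and "
                    f"[{cur.onset_s}, {cur.end_s})"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def end_s(self) -> float:
        return max((e.end_s for e in self.entries), default=0.0)

    def label_at(self, t: float) -> int:
        """Class id of the cue covering time ``t``, or ``UNLABELED``."""
        for e in self.entries:
            if e.onset_s <= t < e.end_s:
                return e.class_id
        return UNLABELED

    def class_ids(self) -> list[int]:
        return sorted({e.class_id for e in self.entries})


@dataclass
class LabelStream:
    """Per-sample or per-window motion labels aligned to a recording.

    ``UNLABELED`` (−1) marks rest / uncued stretches.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")

    def __len__(self) -> int:
        return len(self.labels)

    def validate_vocabulary(self, valid_ids: Iterable[int]) -> None:
        allowed = set(valid_ids) | {UNLABELED}
        bad = set(np.unique(self.labels)) - allowed
        if bad:
            raise ValueError(f"labels outside vocabulary: {sorted(bad)}")


@dataclass(frozen=True)
class SessionScore:
    """One session's mean classification accuracy for one limb and motion set."""

    subject_id: str
    limb_id: str
    session_index: int
    day_offset: float
    motion_set: str
    mean_accuracy: float

    def __post_init__(self) -> None:
        if self.session_index < 1:
            raise ValueError("session_index must be >= 1")
        if not 0.0 <= self.mean_accuracy <= 100.0:
            raise ValueError(
                f"mean_accuracy must lie in [0, 100], got {self.mean_accuracy}"
            )
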