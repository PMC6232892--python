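"""Training protocols: passive cue scheduling and offline scoring, and
active training schedules.

Passive training presents each of the 11 motions in 2-minute blocks — one
fixed-order pass first, then seeded randomized-order blocks — while the
user mirrors a virtual avatar and labeled sEMG is recorded.  There is no
feedback loop; the session is scored afterwards by cross-validated
classification accuracy over the cue-labeled windows.

Active training presents each motion of the chosen set (Basic, Advanced or
Digit) for 2 s, twice, to collect labeled data for decoder training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classify import classification_accuracy, fit_lda, predict_batch
from .core import CueEntry, CueSchedule, EMGRecording, LabelStream, MotionSet
from .signal import FeatureConfig, FeatureMatrix, extract_features

__all__ = [
    "PassiveConfig",
    "build_passive_schedule",
    "score_passive_session",
    "score_feature_matrix",
    "build_active_training",
]


@dataclass(frozen=True)
class PassiveConfig:
    """Passive-block parameters: 120 s blocks, fixed first pass, seeded order."""

    block_duration_s: float = 120.0
    fixed_prefix: bool = True
    n_random_passes: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_duration_s <= 0:
            raise ValueError("block_duration_s must be positive")
        if self.n_random_passes < 0:
            raise ValueError("n_random_passes must be >= 0")


def build_passive_schedule(
    motion_set: MotionSet, cfg: PassiveConfig | None = None
) -> CueSchedule:
    """One fixed-order pass through the set, then randomized-order passes.

    Every block lasts ``block_duration_s`` (120 s by default); blocks are
    back-to-back.  The random passes are reproducible under ``seed``.
    """
    if cfg is None:
        cfg = PassiveConfig()
    rng = np.random.default_rng(cfg.seed)
    ids = list(motion_set.ids)
    order: list[int] = []
    if cfg.fixed_prefix:
        order.extend(ids)
    for _ in range(cfg.n_random_passes):
        order.extend(rng.permutation(ids).tolist())
    entries = [
        CueEntry(cid, i * cfg.block_duration_s, cfg.block_duration_s)
        for i, cid in enumerate(order)
    ]
    return CueSchedule(entries)


def score_feature_matrix(
    feats: FeatureMatrix,
    shrinkage: float = 1e-3,
    folds: int = 5,
    fold_seed: int = 0,
    resubstitution: bool = False,
) -> float:
    """Mean classification accuracy (percent) over labeled windows.

    Default is stratified k-fold cross-validation: train the decoder on
    k−1 folds, score the held-out fold, average the fold accuracies.
    ``resubstitution=True`` instead trains and scores on all windows
    (optimistic; provided for comparison with training-set accuracy).
    """
    labeled = feats.labeled()
    if len(labeled) == 0:
        raise ValueError("no cue-labeled windows to score")
    if resubstitution:
        model = fit_lda(labeled, shrinkage=shrinkage)
        return classification_accuracy(model, labeled)
    y = labeled.labels.labels
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"every class needs >= {folds} windows for {folds}-fold CV; "
            f"smallest class has {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=fold_seed)
    accs = []
    X = labeled.values
    for train_idx, test_idx in skf.split(X, y):
        model = fit_lda((X[train_idx], y[train_idx]), shrinkage=shrinkage)
        pred = predict_batch(model, X[test_idx])
        accs.append(100.0 * float(np.mean(pred == y[test_idx])))
    return float(np.mean(accs))


def score_passive_session(
    rec: EMGRecording,
    schedule: CueSchedule | LabelStream,
    featcfg: FeatureConfig | None = None,
    shrinkage: float = 1e-3,
    folds: int = 5,
    fold_seed: int = 0,
    resubstitution: bool = False,
    prefiltered: bool = False,
) -> float:
    """Offline accuracy score of a passive session, in percent.

    The recording is high-pass filtered (unless ``prefiltered``), windowed
    into features labeled by the cue schedule, and scored by stratified
    k-fold cross-validated LDA accuracy over the labeled windows.
    """
    from .signal import apply_filter

    if featcfg is None:
        featcfg = FeatureConfig()
    if not prefiltered:
        rec = apply_filter(rec)
    feats = extract_features(rec, schedule, featcfg)
    return score_feature_matrix(
        feats,
        shrinkage=shrinkage,
        folds=folds,
        fold_seed=fold_seed,
        resubstitution=resubstitution,
    )


def build_active_training(
    motion_set: MotionSet, reps: int = 2, duration_s: float = 2.0
) -> CueSchedule:
    """Active-training schedule: the set cycled ``reps`` times, back to
    back, at ``duration_s`` per cue (defaults: two sets of 2 s per motion)."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    entries = []
    t = 0.0
    for _ in range(reps):
        for c in motion_set:
            entries.append(CueEntry(c.id, t, duration_s))
            t += duration_s
    return CueSchedule(entries)
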