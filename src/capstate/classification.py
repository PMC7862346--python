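"""Supervised discrimination of TG vs WT animals from CAP features.

Two schemes are provided:

* **All-subject scheme** — CAPs are extracted from the full cohort and
  either temporal (duration + occurrence of each retained matched pair),
  spatial (subject mean BOLD at the union of the pair's significant
  voxels) or voxel-variance control features feed an L2-regularized
  logistic-regression classifier over repeated random 80/20
  train/validation splits.

* **Training-set-only (unbiased) scheme** — per trial, group-level CAPs
  are extracted from the training subjects only; every subject (train or
  validation) is then represented by WT-like and TG-like CAPs built by
  correlating each group CAP with the subject's frames, averaging the
  local correlation peaks into a seed centroid, and running a
  two-cluster correlation-distance k-means seeded with it.  This mimics
  diagnosing a new animal whose data never influenced CAP extraction.

Chance level comes from label-shuffled surrogate trials preserving the
8/10 group sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.linear_model import LogisticRegression

from .config import Group
from .extraction import (
    CAPMap,
    GroupImageSeries,
    TMap,
    cluster_frames,
    compute_cap_maps,
    compute_tmap,
    normalize_frames,
)
from .matching import MatchResult
from .metrics import mean_durations, occurrence_fractions
from .synthetic import SubjectRecording

log = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "ClassificationReport",
    "build_temporal_features",
    "build_spatial_features",
    "build_variance_features",
    "train_mlr",
    "cross_validate",
    "chance_level",
    "subject_projected_caps",
    "run_unbiased_scheme",
]

_LABEL_TO_INT = {Group.WT: 0, Group.TG: 1}


@dataclass
class FeatureMatrix:
    """Subjects x named features, with bookkeeping flags."""

    values: np.ndarray  # (n_subjects, n_features)
    feature_names: List[str]
    subject_ids: List[str]
    kind: str  # temporal | spatial | variance
    zscored: bool = False
    imputed: np.ndarray = field(default_factory=lambda: np.zeros((0, 0), bool))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature name count != column count")


@dataclass
class ClassificationReport:
    accuracies: np.ndarray  # per trial
    mean_accuracy: float
    confusion: np.ndarray  # rows: true (WT, TG); cols: predicted (WT, TG)
    scheme: str
    n_trials: int
    seed: int
    chance_accuracies: Optional[np.ndarray] = None
    p_value: Optional[float] = None


def build_temporal_features(
    metrics_wt: Sequence[Dict[str, np.ndarray]],
    metrics_tg: Sequence[Dict[str, np.ndarray]],
    match: MatchResult,
    subject_ids_wt: Sequence[str],
    subject_ids_tg: Sequence[str],
) -> FeatureMatrix:
    """Duration + occurrence of every retained matched pair, per subject.

    WT subjects contribute the WT-side CAP's metrics, TG subjects the
    matched TG-side CAP's.  A CAP a subject never visits has no duration;
    it is imputed as 0 and flagged.
    """
    pairs = match.retained_pairs()
    if not pairs:
        raise ValueError("no retained CAP pairs: no temporal features to build")
    rows, names, imputed = [], [], []
    for p_idx, (i, j) in enumerate(pairs):
        names += [f"pair{p_idx}_occurrence", f"pair{p_idx}_duration"]
    all_metrics = [(m, 0) for m in metrics_wt] + [(m, 1) for m in metrics_tg]
    for m, side in all_metrics:
        row, imp = [], []
        for (i, j) in pairs:
            cap = i if side == 0 else j
            occ = m["occurrence"][cap]
            dur = m["duration"][cap]
            row.append(occ)
            imp.append(False)
            if np.isnan(dur):
                row.append(0.0)
                imp.append(True)
            else:
                row.append(dur)
                imp.append(False)
        rows.append(row)
        imputed.append(imp)
    if np.any(imputed):
        log.info("imputed %d absent durations as 0", int(np.sum(imputed)))
    return FeatureMatrix(
        values=np.array(rows),
        feature_names=names,
        subject_ids=list(subject_ids_wt) + list(subject_ids_tg),
        kind="temporal",
        imputed=np.array(imputed),
    )


def build_spatial_features(
    recordings: Sequence[SubjectRecording],
    label_sequences: Sequence[np.ndarray],
    tmaps_wt: Sequence[TMap],
    tmaps_tg: Sequence[TMap],
    match: MatchResult,
) -> FeatureMatrix:
    """Mean subject BOLD at the significant-voxel union of each retained pair.

    Each subject's own group decides
    which side of the pair labels its frames.  For every retained pair
    (i, j) the voxel set is the union of significant (either sign)
    voxels of WT CAP i and TG CAP j; the feature vector is the subject's
    mean BOLD across its frames assigned to that CAP at those voxels.
    Subjects never visiting the CAP get zeros (flagged).
    """
    pairs = match.retained_pairs()
    if not pairs:
        raise ValueError("no retained CAP pairs: no spatial features to build")
    unions = []
    for (i, j) in pairs:
        u = (
            tmaps_wt[i].sig_pos
            | tmaps_wt[i].sig_neg
            | tmaps_tg[j].sig_pos
            | tmaps_tg[j].sig_neg
        )
        unions.append(np.flatnonzero(u))
    names = [
        f"pair{p}_vox{v}" for p, vox in enumerate(unions) for v in vox
    ]
    rows, imputed = [], []
    for rec, labels in zip(recordings, label_sequences):
        row, imp = [], []
        for (i, j), vox in zip(pairs, unions):
            cap = i if rec.group == Group.WT else j
            sel = np.asarray(labels) == cap
            if sel.any():
                mean_map = rec.frames[sel].mean(axis=0)
                row.extend(mean_map[vox])
                imp.extend([False] * vox.size)
            else:
                row.extend(np.zeros(vox.size))
                imp.extend([True] * vox.size)
        rows.append(row)
        imputed.append(imp)
    return FeatureMatrix(
        values=np.array(rows),
        feature_names=names,
        subject_ids=[r.subject_id for r in recordings],
        kind="spatial",
        imputed=np.array(imputed),
    )


def build_variance_features(recordings: Sequence[SubjectRecording]) -> FeatureMatrix:
    """Temporal variance of every in-mask voxel (control feature set).

    Intended for series conditioned *without* the unit-variance step;
    on normalized input all features are 1 and a warning is emitted.
    """
    values = np.vstack([r.frames.var(axis=0, ddof=0) for r in recordings])
    if np.allclose(values, 1.0, atol=1e-6):
        log.warning("variance features computed on unit-variance input: all ~1")
    return FeatureMatrix(
        values=values,
        feature_names=[f"vox{v}_var" for v in range(values.shape[1])],
        subject_ids=[r.subject_id for r in recordings],
        kind="variance",
    )


def train_mlr(
    features: np.ndarray, labels: Sequence[int], reg: float = 10.0,
    reg_is_penalty: bool = False,
) -> LogisticRegression:
    """L2-penalized logistic regression (binary reduction of multinomial MLR).

    ``reg`` is the inverse regularization strength (sklearn's C) by
    default; with ``reg_is_penalty`` it is read as the penalty weight
    (C = 1/reg).
    """
    y = np.asarray(labels, dtype=int)
    if min(np.bincount(y, minlength=2)) < 2:
        raise ValueError("need >= 2 training subjects per class")
    C = 1.0 / reg if reg_is_penalty else reg
    model = LogisticRegression(C=C, solver="lbfgs", max_iter=2000)
    model.fit(np.asarray(features, dtype=float), y)
    return model


def _predict(model: LogisticRegression, X: np.ndarray) -> np.ndarray:
    """Max-posterior decision; exact ties go to TG (majority class)."""
    p_tg = model.predict_proba(X)[:, list(model.classes_).index(1)]
    return (p_tg >= 0.5).astype(int)


def _zscore_train_apply(train: np.ndarray, other: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (other - mu) / sd


def _split(n: int, n_val: int, rng) -> Tuple[np.ndarray, np.ndarray]:
    perm = rng.permutation(n)
    return perm[n_val:], perm[:n_val]


def _one_trial(X, y, train_idx, val_idx, reg, reg_is_penalty):
    Xtr, Xva = _zscore_train_apply(X[train_idx], X[val_idx])
    model = train_mlr(Xtr, y[train_idx], reg=reg, reg_is_penalty=reg_is_penalty)
    pred = _predict(model, Xva)
    return pred, y[val_idx]


def cross_validate(
    features: FeatureMatrix,
    labels: Sequence[Group],
    train_frac: float = 0.8,
    n_trials: int = 100,
    seed: int = 0,
    reg: float = 10.0,
    reg_is_penalty: bool = False,
    scheme: str = "all-subject",
) -> ClassificationReport:
    """Repeated random-split validation with per-trial z-scoring.

    Split sizes follow rounding of ``train_frac`` (18 subjects -> 14/4);
    z-scoring parameters are fit on the training rows only each trial;
    the confusion matrix pools validation predictions over all trials.
    """
    X = features.values
    y = np.array([_LABEL_TO_INT[Group(g)] for g in labels])
    n = X.shape[0]
    n_val = n - int(round(train_frac * n))
    if n_val < 1:
        raise ValueError("validation set empty at this train fraction")
    rng = np.random.default_rng(int(seed))
    accs = np.empty(n_trials)
    confusion = np.zeros((2, 2), dtype=int)
    for t in range(n_trials):
        train_idx, val_idx = _split(n, n_val, rng)
        pred, truth = _one_trial(X, y, train_idx, val_idx, reg, reg_is_penalty)
        accs[t] = np.mean(pred == truth)
        for tr, pr in zip(truth, pred):
            confusion[tr, pr] += 1
    return ClassificationReport(
        accuracies=accs,
        mean_accuracy=float(accs.mean()),
        confusion=confusion,
        scheme=scheme,
        n_trials=n_trials,
        seed=seed,
    )


def chance_level(
    features: FeatureMatrix,
    labels: Sequence[Group],
    n_surrogates: int = 100,
    train_frac: float = 0.8,
    seed: int = 0,
    reg: float = 10.0,
    reg_is_penalty: bool = False,
) -> np.ndarray:
    """Validation accuracies under shuffled subject labels (sizes preserved)."""
    if n_surrogates < 1:
        raise ValueError("need at least one surrogate")
    X = features.values
    y = np.array([_LABEL_TO_INT[Group(g)] for g in labels])
    n = X.shape[0]
    n_val = n - int(round(train_frac * n))
    rng = np.random.default_rng(int(seed))
    accs = np.empty(n_surrogates)
    for s in range(n_surrogates):
        y_shuf = y[rng.permutation(n)]
        train_idx, val_idx = _split(n, n_val, rng)
        pred, truth = _one_trial(X, y_shuf, train_idx, val_idx, reg, reg_is_penalty)
        accs[s] = np.mean(pred == truth)
    return accs


def accuracy_p_value(report: ClassificationReport, chance: np.ndarray) -> float:
    """Fraction of surrogate accuracies at least as high as the true mean."""
    return float(np.mean(chance >= report.mean_accuracy))


def subject_projected_caps(
    group_cap: CAPMap, frames: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Project one group-level CAP into a subject's scan.

    The group CAP is correlated with every frame; strict local maxima of
    the correlation series with r > 0 are voxel-averaged into the first
    initial centroid (the mean of the remaining frames is the second),
    and all frames are 2-clustered under correlation distance from that
    seeding.  Frames of the first cluster are voxel-averaged into the
    subject's CAP-like map.

    Returns (cap_like_map, other_map, labels, fallback_used): labels are
    0 for the CAP-like cluster; ``fallback_used`` marks subjects without
    a positive local peak, where the single best-correlated frame seeds
    centroid 1 instead.
    """
    X = np.asarray(frames, dtype=float)
    Xn = normalize_frames(X)
    g = np.asarray(group_cap.mean_map, dtype=float)
    g = g - g.mean()
    gn = np.linalg.norm(g)
    if gn == 0:
        raise ValueError("group CAP map is constant")
    r = Xn @ (g / gn)
    interior = np.zeros(r.size, dtype=bool)
    if r.size >= 3:
        interior[1:-1] = (r[1:-1] > r[:-2]) & (r[1:-1] > r[2:])
    peaks = np.flatnonzero(interior & (r > 0))
    fallback = peaks.size == 0
    if fallback:
        peaks = np.array([int(np.argmax(r))])
        log.info("no positive correlation peak; falling back to best frame")
    c1 = X[peaks].mean(axis=0)
    rest = np.setdiff1d(np.arange(X.shape[0]), peaks)
    c2 = X[rest].mean(axis=0) if rest.size else X.mean(axis=0)
    series = GroupImageSeries(
        frames=X, subject_offsets=[0], subject_ids=["subject"], group="subject"
    )
    part = cluster_frames(series, 2, init_centroids=np.vstack([c1, c2]))
    cap_like = X[part.labels == 0].mean(axis=0)
    other = (
        X[part.labels == 1].mean(axis=0) if (part.labels == 1).any() else np.zeros_like(cap_like)
    )
    return cap_like, other, part.labels, fallback


def subject_projected_cap_set(
    group_caps: Sequence[CAPMap], frames: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, List[bool]]:
    """Project a whole group-level CAP set into one subject's scan.

    Every group CAP is correlated with the subject's frames; the
    positive local peaks of each correlation series are voxel-averaged
    into one initial centroid per CAP, and a single k-means of all
    frames (k = number of group CAPs, correlation distance) is seeded
    with those centroids.  Cluster j's frames are voxel-averaged into
    the subject's CAP-j-like map.  Seeding every cluster at once keeps
    cluster composition aligned with the group CAPs; a lone two-way
    split cannot isolate one pattern among many.

    Returns (k x V cap-like maps, per-frame labels, fallback flags).
    """
    X = np.asarray(frames, dtype=float)
    Xn = normalize_frames(X)
    inits, fallbacks = [], []
    for cap in group_caps:
        g = np.asarray(cap.mean_map, dtype=float)
        g = g - g.mean()
        gn = np.linalg.norm(g)
        if gn == 0:
            raise ValueError("group CAP map is constant")
        r = Xn @ (g / gn)
        interior = np.zeros(r.size, dtype=bool)
        if r.size >= 3:
            interior[1:-1] = (r[1:-1] > r[:-2]) & (r[1:-1] > r[2:])
        peaks = np.flatnonzero(interior & (r > 0))
        fb = peaks.size == 0
        if fb:
            peaks = np.array([int(np.argmax(r))])
        fallbacks.append(fb)
        inits.append(X[peaks].mean(axis=0))
    series = GroupImageSeries(
        frames=X, subject_offsets=[0], subject_ids=["subject"], group="subject"
    )
    part = cluster_frames(series, len(group_caps), init_centroids=np.vstack(inits))
    cap_like = np.vstack(
        [X[part.labels == j].mean(axis=0) for j in range(len(group_caps))]
    )
    return cap_like, part.labels, fallbacks


def _group_caps_and_masks(
    recordings: Sequence[SubjectRecording],
    k: int,
    seed: int,
    n_restarts: int,
    alpha: float,
) -> Tuple[List[CAPMap], List[TMap]]:
    series = GroupImageSeries.from_recordings(recordings, group=recordings[0].group.value)
    part = cluster_frames(series, k, seed=seed, n_restarts=n_restarts)
    caps = compute_cap_maps(series, part)
    tmaps = [
        compute_tmap(series.frames[part.labels == j], alpha=alpha) for j in range(k)
    ]
    return caps, tmaps


def run_unbiased_scheme(
    cohort: Sequence[SubjectRecording],
    k: int,
    feature_kind: str = "spatial",
    n_trials: int = 50,
    train_frac: float = 0.8,
    seed: int = 0,
    reg: float = 10.0,
    n_restarts: int = 3,
    alpha: float = 0.01,
) -> ClassificationReport:
    """Training-set-only CAP extraction with subject-projected features.

    Per trial: subjects are split; WT and TG group CAPs are extracted
    from the *training* subjects only; every subject is represented by
    the projections of all 2k group CAPs (spatial features: the
    subject's CAP-like map at the group CAP's significant voxels;
    temporal features: occurrence fraction and mean duration of the
    CAP-like cluster); the classifier is trained on training rows and
    scored on the held-out subjects.  Validation subjects' frames never
    enter CAP extraction or z-scoring parameters.
    """
    if feature_kind not in ("spatial", "temporal"):
        raise ValueError("feature_kind must be 'spatial' or 'temporal'")
    y = np.array([_LABEL_TO_INT[r.group] for r in cohort])
    n = len(cohort)
    n_val = n - int(round(train_frac * n))
    rng = np.random.default_rng(int(seed))
    accs = np.empty(n_trials)
    confusion = np.zeros((2, 2), dtype=int)
    for t in range(n_trials):
        train_idx, val_idx = _split(n, n_val, rng)
        train_set = set(train_idx.tolist())
        assert train_set.isdisjoint(val_idx.tolist())
        wt_train = [cohort[i] for i in train_idx if cohort[i].group == Group.WT]
        tg_train = [cohort[i] for i in train_idx if cohort[i].group == Group.TG]
        trial_seed = int(rng.integers(2**31 - 1))
        caps_wt, tmaps_wt = _group_caps_and_masks(
            wt_train, k, trial_seed, n_restarts, alpha
        )
        caps_tg, tmaps_tg = _group_caps_and_masks(
            tg_train, k, trial_seed + 1, n_restarts, alpha
        )
        rows = []
        for rec in cohort:
            row = []
            for caps, tmaps in ((caps_wt, tmaps_wt), (caps_tg, tmaps_tg)):
                cap_like, labels_k, _ = subject_projected_cap_set(caps, rec.frames)
                if feature_kind == "spatial":
                    for j, tmap in enumerate(tmaps):
                        vox = np.flatnonzero(tmap.sig_pos | tmap.sig_neg)
                        row.extend(cap_like[j, vox])
                else:
                    occ = occurrence_fractions(labels_k, k)
                    dur = mean_durations(labels_k, k)
                    dur = np.where(np.isnan(dur), 0.0, dur)
                    row.extend(np.column_stack([occ, dur]).ravel())
            rows.append(row)
        X = np.array(rows)
        pred, truth = _one_trial(X, y, train_idx, val_idx, reg, False)
        accs[t] = np.mean(pred == truth)
        for tr, pr in zip(truth, pred):
            confusion[tr, pr] += 1
    return ClassificationReport(
        accuracies=accs,
        mean_accuracy=float(accs.mean()),
        confusion=confusion,
        scheme=f"unbiased-{feature_kind}",
        n_trials=n_trials,
        seed=seed,
    )
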