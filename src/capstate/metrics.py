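"""Subject-level temporal and spatial CAP statistics.

Per subject and CAP: occurrence fraction (share of frames carrying the
CAP's label), mean duration (mean maximal-run length in frames),
hemispheric laterality of significantly co-activated / co-deactivated
voxels of the subject-level T-map, and the incidence of each CAP inside
externally supplied quasi-periodic-pattern (QPP) occurrence windows.

The laterality index LI = (mean_T_left - mean_T_right) / mean_T_brain is
computed over Bonferroni-significant voxels of one sign only, each mean
taken per significant voxel of that hemisphere (an empty hemisphere
contributes 0).  LI is +1 for a fully left-lateralized pattern, -1 for
fully right-lateralized, 0 for a mirror-symmetric one.  For the negative
sign the index uses |T| so the left/right semantics match the positive
case.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .extraction import TMap, compute_tmap

__all__ = [
    "occurrence_fractions",
    "mean_durations",
    "run_lengths",
    "subject_tmap",
    "hemisphere_masks",
    "laterality_index",
    "qpp_cap_incidence",
    "average_caps_incidence",
]


def occurrence_fractions(label_sequence: np.ndarray, k: int) -> np.ndarray:
    """Per-CAP share of a subject's frames; absent CAPs give 0; sums to 1."""
    labels = np.asarray(label_sequence, dtype=int)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError("labels outside 0..k-1")
    return np.bincount(labels, minlength=k) / labels.size


def run_lengths(label_sequence: np.ndarray, k: int) -> List[List[int]]:
    """Lengths of maximal constant runs, per CAP, in order of occurrence."""
    labels = np.asarray(label_sequence, dtype=int)
    runs: List[List[int]] = [[] for _ in range(k)]
    if labels.size == 0:
        return runs
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [labels.size]])
    for s, e in zip(starts, ends):
        runs[labels[s]].append(int(e - s))
    return runs


def mean_durations(label_sequence: np.ndarray, k: int) -> np.ndarray:
    """Mean run length per CAP in frames; NaN where the CAP never occurs."""
    out = np.full(k, np.nan)
    for j, r in enumerate(run_lengths(label_sequence, k)):
        if r:
            out[j] = float(np.mean(r))
    return out


def subject_tmap(
    subject_frames: np.ndarray,
    label_sequence: np.ndarray,
    cap_id: int,
    alpha: float = 0.01,
    n_tests: Optional[int] = None,
) -> Optional[TMap]:
    """One-sample T-map over the subject's frames assigned to one CAP.

    Returns None (metric unavailable) when the CAP occupies fewer than
    two of the subject's frames.
    """
    sel = np.asarray(label_sequence) == cap_id
    if sel.sum() < 2:
        return None
    return compute_tmap(subject_frames[sel], alpha=alpha, n_tests=n_tests)


def hemisphere_masks(
    mask: np.ndarray, flip: bool = False
) -> Tuple[np.ndarray, np.ndarray]:
    """Boolean left/right indicators for in-mask voxels (row-major order).

    Columns strictly left of the grid midline are "left"; with an even
    column count no voxel sits on the midline.  ``flip`` swaps the
    convention for radiological-order data.
    """
    rows, cols = mask.shape
    col_idx = np.tile(np.arange(cols), (rows, 1))
    left2d = col_idx < cols // 2
    left = left2d[mask]
    if flip:
        left = ~left
    return left, ~left


def laterality_index(
    tmap: TMap, left: np.ndarray, right: np.ndarray, sign: str = "positive"
) -> Optional[float]:
    """Hemispheric laterality of one sign's significant voxels; None if none."""
    if sign == "positive":
        sig = tmap.sig_pos
        vals = tmap.t_stat
    elif sign == "negative":
        sig = tmap.sig_neg
        vals = np.abs(tmap.t_stat)
    else:
        raise ValueError("sign must be 'positive' or 'negative'")
    if not sig.any():
        return None
    v = vals[sig]
    finite = np.isfinite(v)
    if not finite.all():
        # +/-inf sentinels (zero-variance voxels) carry no graded magnitude;
        # replace with the largest finite |T| present, or 1 if none.
        cap = np.max(v[finite]) if finite.any() else 1.0
        v = np.where(finite, v, cap)
    lsel = left[sig]
    mean_left = float(v[lsel].mean()) if lsel.any() else 0.0
    mean_right = float(v[~lsel].mean()) if (~lsel).any() else 0.0
    mean_brain = float(v.mean())
    return (mean_left - mean_right) / mean_brain


def qpp_cap_incidence(
    label_sequence: np.ndarray,
    qpp_windows: Sequence[Tuple[int, int]],
    k: int,
    normalization: str = "per_qpp_frames",
) -> np.ndarray:
    """Percentage of QPP-window frames carrying each CAP's label.

    ``per_qpp_frames`` normalizes by the total number of window frames
    (values sum to 100% across CAPs); ``per_total_frames`` normalizes by
    the subject's full frame count, measuring overall prevalence.
    """
    labels = np.asarray(label_sequence, dtype=int)
    T = labels.size
    counts = np.zeros(k)
    total_window_frames = 0
    for start, length in qpp_windows:
        if start < 0 or start + length > T:
            raise ValueError(f"window ({start}, {length}) outside 0..{T}")
        seg = labels[start : start + length]
        counts += np.bincount(seg, minlength=k)
        total_window_frames += length
    if normalization == "per_qpp_frames":
        if total_window_frames == 0:
            raise ValueError("no QPP window frames to normalize by")
        return 100.0 * counts / total_window_frames
    if normalization == "per_total_frames":
        return 100.0 * counts / T
    raise ValueError("normalization must be 'per_qpp_frames' or 'per_total_frames'")


def average_caps_incidence(
    values: np.ndarray, cap_ids: Sequence[int]
) -> float:
    """Arithmetic mean of a per-CAP incidence vector over a CAP subset."""
    cap_ids = list(cap_ids)
    if not cap_ids:
        raise ValueError("CAP subset must be non-empty")
    values = np.asarray(values, dtype=float)
    return float(values[cap_ids].mean())


def subject_metric_table(
    frames: np.ndarray,
    label_sequence: np.ndarray,
    k: int,
    left: np.ndarray,
    right: np.ndarray,
    alpha: float = 0.01,
) -> Dict[str, np.ndarray]:
    """All per-CAP metrics for one subject (NaN where unavailable)."""
    occ = occurrence_fractions(label_sequence, k)
    dur = mean_durations(label_sequence, k)
    lat_pos = np.full(k, np.nan)
    lat_neg = np.full(k, np.nan)
    for j in range(k):
        tm = subject_tmap(frames, label_sequence, j, alpha=alpha)
        if tm is None:
            continue
        lp = laterality_index(tm, left, right, "positive")
        ln = laterality_index(tm, left, right, "negative")
        if lp is not None:
            lat_pos[j] = lp
        if ln is not None:
            lat_neg[j] = ln
    return {
        "occurrence": occ,
        "duration": dur,
        "laterality_pos": lat_pos,
        "laterality_neg": lat_neg,
    }
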