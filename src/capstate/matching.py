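"""Between-group CAP matching and the shuffle-based chance threshold.

CAPs from two equal-k partitions are paired by the Hungarian method with
1 - Pearson's r between mean maps as the assignment cost.  The spatial
similarity of each matched pair is then compared against a surrogate
null: frame labels are shuffled within each group (preserving cluster
sizes), surrogate CAPs recomputed, and the correlations of the *fixed*
original pairing pooled over shuffles; the empirical upper quantile at
the configured p is the chance threshold below which pairs are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from .extraction import CAPMap

log = logging.getLogger(__name__)

__all__ = ["MatchResult", "match_caps", "surrogate_null", "filter_matches"]


def _pearson_maps(a: np.ndarray, b: np.ndarray) -> Tuple[float, bool]:
    """Pearson r of two maps; constant maps give (0, degenerate=True)."""
    a = np.asarray(a, float) - np.mean(a)
    b = np.asarray(b, float) - np.mean(b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0, True
    return float(a @ b / (na * nb)), False


@dataclass
class MatchResult:
    """A perfect matching between two CAP sets with per-pair correlations."""

    pairs: List[Tuple[int, int]]  # (cap id in A, cap id in B)
    pair_correlations: np.ndarray
    total_distance: float
    null_threshold: Optional[float] = None
    retained: Optional[np.ndarray] = None  # bool per pair
    degenerate_pairs: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))

    def retained_pairs(self) -> List[Tuple[int, int]]:
        if self.retained is None:
            return list(self.pairs)
        return [p for p, keep in zip(self.pairs, self.retained) if keep]


def match_caps(caps_a: Sequence[CAPMap], caps_b: Sequence[CAPMap]) -> MatchResult:
    """Hungarian assignment minimizing total (1 - r) over all pairings.

    Both sets must contain the same number of CAPs defined on the same
    voxel set.  scipy's linear_sum_assignment resolves cost ties
    deterministically in favour of the lowest A-index.
    """
    if len(caps_a) != len(caps_b):
        raise ValueError(
            f"cannot match {len(caps_a)} CAPs against {len(caps_b)}: counts differ"
        )
    k = len(caps_a)
    R = np.empty((k, k))
    for i, ca in enumerate(caps_a):
        for j, cb in enumerate(caps_b):
            R[i, j], _ = _pearson_maps(ca.mean_map, cb.mean_map)
    cost = 1.0 - R
    rows, cols = linear_sum_assignment(cost)
    pairs = list(zip(rows.tolist(), cols.tolist()))
    r_vals = R[rows, cols]
    return MatchResult(
        pairs=pairs,
        pair_correlations=r_vals,
        total_distance=float(cost[rows, cols].sum()),
        degenerate_pairs=np.zeros(k, bool),
    )


def surrogate_null(
    labels_a: np.ndarray,
    frames_a: np.ndarray,
    labels_b: np.ndarray,
    frames_b: np.ndarray,
    pairs: Sequence[Tuple[int, int]],
    n_shuffles: int = 10_000,
    p: float = 1e-4,
    seed: int = 0,
) -> float:
    """Chance threshold for matched-CAP correlations by label shuffling.

    Each shuffle independently permutes the frame labels of both groups
    (cluster sizes preserved), recomputes surrogate CAP means, and
    evaluates Pearson's r for every pair of the fixed original matching.
    All values are pooled and the empirical (1 - p) upper quantile
    returned.  Degenerate surrogate correlations (constant maps) enter
    the pool as 0.
    """
    if n_shuffles < 1.0 / p:
        raise ValueError(
            f"{n_shuffles} shuffles cannot resolve the p={p} quantile "
            f"(need >= {int(np.ceil(1/p))})"
        )
    rng = np.random.default_rng(int(seed))
    pooled = np.empty((n_shuffles, len(pairs)))
    means = [_shuffled_means_setup(labels_a, frames_a), _shuffled_means_setup(labels_b, frames_b)]
    for s in range(n_shuffles):
        mean_a = _shuffled_means(*means[0], rng)
        mean_b = _shuffled_means(*means[1], rng)
        for q, (i, j) in enumerate(pairs):
            r, degen = _pearson_maps(mean_a[i], mean_b[j])
            pooled[s, q] = 0.0 if degen else r
    return float(np.quantile(pooled.ravel(), 1.0 - p, method="higher"))


def _shuffled_means_setup(labels: np.ndarray, frames: np.ndarray):
    labels = np.asarray(labels)
    k = int(labels.max()) + 1
    sizes = np.bincount(labels, minlength=k)
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    return frames, sizes, offsets


def _shuffled_means(frames, sizes, offsets, rng) -> np.ndarray:
    """Cluster means after a uniformly random relabeling of the frames."""
    perm = rng.permutation(frames.shape[0])
    sums = np.add.reduceat(frames[perm], offsets, axis=0)
    return sums / sizes[:, None]


def filter_matches(
    match: MatchResult,
    threshold: Optional[float] = None,
    r_min: Optional[float] = None,
) -> MatchResult:
    """Flag pairs whose correlation clears the chance threshold (and r_min)."""
    cut = -np.inf
    if threshold is not None:
        cut = max(cut, threshold)
    if r_min is not None:
        cut = max(cut, r_min)
    retained = match.pair_correlations >= cut
    if not retained.any():
        log.warning("no matched CAP pair clears the similarity threshold %.3f", cut)
    log.info("%d/%d matched pairs retained", int(retained.sum()), len(match.pairs))
    return MatchResult(
        pairs=match.pairs,
        pair_correlations=match.pair_correlations,
        total_distance=match.total_distance,
        null_threshold=threshold if threshold is not None else match.null_threshold,
        retained=retained,
        degenerate_pairs=match.degenerate_pairs,
    )
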