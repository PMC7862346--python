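"""Frame-wise CAP extraction: correlation-distance k-means, explained
variance, elbow selection, mean CAP maps and one-sample T-statistic maps.

Every time frame z_j (one V-voxel image) is treated as an observation and
all frames of a group-level (concatenated) image-series are clustered
with k-means++ under correlation distance d = 1 - Pearson's r.  The
partition count is selected where the fractional gain in explained
variance

    V_W = (1/N) sum_k sum_{j in k} d^2(z_j, c_k)
    V_B = (1/N) sum_k n_k d^2(c_k, c),  c = sum_k (n_k/N) c_k
    EV  = V_B / (V_W + V_B)

first drops below 10% in every group.  Frames in each cluster are then
voxel-wise averaged into CAP maps and tested voxel-wise against zero
(two-tailed one-sample T, Bonferroni-corrected over in-mask voxels).

Correlation-distance k-means is realized by centering each frame at its
spatial mean and scaling to unit norm; on such rows squared Euclidean
distance equals twice the correlation distance, so Lloyd iterations with
renormalized mean centroids descend the summed correlation distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.cluster import kmeans_plusplus

from .config import DegenerateInputError
from .synthetic import SubjectRecording

log = logging.getLogger(__name__)

__all__ = [
    "GroupImageSeries",
    "Partition",
    "VarianceDecomposition",
    "CAPMap",
    "TMap",
    "ElbowResult",
    "normalize_frames",
    "cluster_frames",
    "explained_variance",
    "ev_curve",
    "detect_elbow",
    "compute_cap_maps",
    "compute_tmap",
]


@dataclass
class GroupImageSeries:
    """Concatenated frames of one group (or of both, for combined analysis)."""

    frames: np.ndarray  # (N, V)
    subject_offsets: np.ndarray  # start index of each subject's block
    subject_ids: List[str]
    group: str  # "WT" | "TG" | "combined"
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.subject_offsets = np.asarray(self.subject_offsets, dtype=int)
        if self.subject_offsets[0] != 0 or np.any(np.diff(self.subject_offsets) <= 0):
            raise ValueError("subject_offsets must start at 0 and strictly increase")
        if len(self.subject_ids) != len(self.subject_offsets):
            raise ValueError("one offset per subject required")

    @classmethod
    def from_recordings(
        cls, recordings: Sequence[SubjectRecording], group: str = "combined"
    ) -> "GroupImageSeries":
        offsets = np.cumsum([0] + [r.n_frames for r in recordings[:-1]])
        return cls(
            frames=np.vstack([r.frames for r in recordings]),
            subject_offsets=offsets,
            subject_ids=[r.subject_id for r in recordings],
            group=group,
            mask=recordings[0].mask,
        )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def subject_slices(self) -> List[Tuple[str, slice]]:
        bounds = list(self.subject_offsets) + [self.n_frames]
        return [
            (sid, slice(bounds[i], bounds[i + 1]))
            for i, sid in enumerate(self.subject_ids)
        ]


@dataclass
class Partition:
    """A k-clustering of the frames of one image-series."""

    k: int
    labels: np.ndarray  # (N,) 0-based cluster ids
    centroids: np.ndarray  # (k, V) unit-norm, zero-mean rows
    cluster_sizes: np.ndarray  # (k,)
    inertia: float  # summed correlation distance to assigned centroid
    n_empty_repairs: int = 0

    def __post_init__(self):
        if (self.cluster_sizes == 0).any():
            raise ValueError("partition contains an empty cluster")
        if int(self.cluster_sizes.sum()) != self.labels.size:
            raise ValueError("cluster sizes do not sum to N")


@dataclass
class VarianceDecomposition:
    k: int
    v_within: float
    v_between: float
    explained: float
    global_centroid: np.ndarray
    degenerate: bool = False


@dataclass
class CAPMap:
    """Voxel-wise mean BOLD over the frames of one cluster."""

    cap_id: int
    mean_map: np.ndarray  # (V,)
    n_frames: int


@dataclass
class TMap:
    """Voxel-wise one-sample T statistics with Bonferroni significance masks."""

    t_stat: np.ndarray
    p_two_tailed: np.ndarray
    dof: int
    alpha: float
    sig_pos: np.ndarray
    sig_neg: np.ndarray


@dataclass
class ElbowResult:
    k: int
    found: bool
    gains: List[np.ndarray] = field(default_factory=list)


def normalize_frames(X: np.ndarray) -> np.ndarray:
    """Center each row at its spatial mean and scale to unit norm.

    Rows that are spatially constant (zero variance) are mapped to zero
    vectors; their correlation with anything is undefined and treated as
    0 (distance 1).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 3:
        raise DegenerateInputError(
            "correlation distance undefined for frames with < 3 voxels"
        )
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    flat = norms[:, 0] == 0
    norms[flat] = 1.0
    Xn = Xc / norms
    Xn[flat] = 0.0
    return Xn


def corr_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - Pearson correlation of two maps (0 if either is constant)."""
    u = np.asarray(u, float) - np.mean(u)
    v = np.asarray(v, float) - np.mean(v)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 1.0
    return float(1.0 - u @ v / (nu * nv))


def _renorm_rows(C: np.ndarray) -> np.ndarray:
    C = C - C.mean(axis=1, keepdims=True)
    n = np.linalg.norm(C, axis=1, keepdims=True)
    n[n[:, 0] == 0] = 1.0
    return C / n


def _lloyd(Xn: np.ndarray, init: np.ndarray, max_iter: int = 100):
    """Lloyd iterations under correlation distance on normalized rows.

    Returns (labels, centroids, inertia, n_empty_repairs).  Empty
    clusters are repaired by splitting the largest cluster: its farthest
    member becomes the empty cluster's new centroid.
    """
    N = Xn.shape[0]
    C = _renorm_rows(init.copy())
    k = C.shape[0]
    labels = np.full(N, -1)
    repairs = 0
    for _ in range(max_iter):
        sim = Xn @ C.T  # (N, k) Pearson r to each centroid
        new_labels = np.argmax(sim, axis=1)
        # empty-cluster repair
        counts = np.bincount(new_labels, minlength=k)
        while (counts == 0).any():
            empty = int(np.argmin(counts))
            big = int(np.argmax(counts))
            members = np.flatnonzero(new_labels == big)
            far = members[np.argmin(sim[members, big])]
            new_labels[far] = empty
            C[empty] = Xn[far]
            counts = np.bincount(new_labels, minlength=k)
            repairs += 1
            log.info("repaired empty cluster %d by splitting cluster %d", empty, big)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            C[j] = Xn[labels == j].mean(axis=0)
        C = _renorm_rows(C)
    sim = Xn @ C.T
    inertia = float(np.sum(1.0 - sim[np.arange(N), labels]))
    return labels, C, inertia, repairs


def cluster_frames(
    series: GroupImageSeries,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    init_centroids: Optional[np.ndarray] = None,
    max_iter: int = 100,
) -> Partition:
    """K-means++ clustering of all frames under correlation distance.

    Without ``init_centroids`` the best of ``n_restarts`` k-means++
    seeded runs (by summed correlation distance) is kept; with them a
    single deterministic Lloyd descent from the given centroids is run.
    k = 1 degenerates to a single cluster at the global (normalized)
    mean.
    """
    N = series.n_frames
    if k < 1 or k > N:
        raise ValueError(f"k={k} must lie in 1..N={N}")
    Xn = normalize_frames(series.frames)
    if k == 1:
        C = _renorm_rows(Xn.mean(axis=0, keepdims=True))
        labels = np.zeros(N, dtype=int)
        inertia = float(np.sum(1.0 - Xn @ C[0]))
        return Partition(1, labels, C, np.array([N]), inertia)

    if init_centroids is not None:
        init = np.asarray(init_centroids, dtype=float)
        if init.shape != (k, series.frames.shape[1]):
            raise ValueError("init_centroids must be k x V")
        labels, C, inertia, rep = _lloyd(Xn, init, max_iter)
        return Partition(k, labels, C, np.bincount(labels, minlength=k), inertia, rep)

    rng = np.random.default_rng(int(seed))
    best = None
    for _ in range(max(1, n_restarts)):
        sub_seed = int(rng.integers(2**31 - 1))
        init, _ = kmeans_plusplus(Xn, n_clusters=k, random_state=sub_seed)
        labels, C, inertia, rep = _lloyd(Xn, init, max_iter)
        if best is None or inertia < best[2]:
            best = (labels, C, inertia, rep)
    labels, C, inertia, rep = best
    return Partition(k, labels, C, np.bincount(labels, minlength=k), inertia, rep)


def explained_variance(
    series: GroupImageSeries, partition: Partition
) -> VarianceDecomposition:
    """Within/between-cluster variance decomposition of the frame series.

    Computed in the correlation geometry the clustering itself uses:
    each frame is spatially normalized (zero mean, unit norm), so that
    squared Euclidean distance between two normalized maps equals twice
    their correlation distance.  With c_k the plain cluster means of the
    normalized frames and c their size-weighted grand mean,

        V_W = (1/N) sum_k sum_{j in k} d^2(z_j, c_k)
        V_B = sum_k (n_k/N) d^2(c_k, c)

    satisfy V_W + V_B = total variance exactly (the classical ANOVA
    identity), so EV = V_B / (V_W + V_B) rises from ~0 and saturates
    once the real cluster structure is captured — the behaviour the
    explained-variance elbow rule relies on.  Evaluating d as
    1 - Pearson's r between frames and *renormalized* centroids instead
    breaks the identity and makes the curve start high and flat.
    """
    if partition.labels.size != series.n_frames:
        raise ValueError("partition does not match series")
    Xn = normalize_frames(series.frames)
    N = series.n_frames
    k = partition.k
    means = np.vstack(
        [Xn[partition.labels == j].mean(axis=0) for j in range(k)]
    )
    weights = partition.cluster_sizes / N
    c_global = weights @ means
    v_within = float(
        np.sum((Xn - means[partition.labels]) ** 2) / N
    )
    v_between = float(weights @ np.sum((means - c_global) ** 2, axis=1))
    tot = v_within + v_between
    if tot < 1e-15:  # all frames identical up to scale: no variance to explain
        return VarianceDecomposition(k, 0.0, 0.0, 0.0, c_global, True)
    return VarianceDecomposition(k, v_within, v_between, v_between / tot, c_global)


def ev_curve(
    series: GroupImageSeries,
    k_min: int = 2,
    k_max: int = 20,
    seed: int = 0,
    n_restarts: int = 10,
) -> List[VarianceDecomposition]:
    """Explained variance for every partition size in [k_min, k_max]."""
    if not (2 <= k_min <= k_max):
        raise ValueError("need 2 <= k_min <= k_max")
    out = []
    for k in range(k_min, k_max + 1):
        part = cluster_frames(series, k, seed=seed + k, n_restarts=n_restarts)
        out.append(explained_variance(series, part))
    return out


def detect_elbow(
    curves: Sequence[Sequence], gain_threshold: float = 0.10, k_min: int = 2
) -> ElbowResult:
    """Smallest k >= 3 whose fractional EV gain is below threshold in all groups.

    ``curves`` is one EV sequence per group, aligned on the same k grid
    starting at ``k_min`` (=2).  The gain at k is
    (EV(k) - EV(k-1)) / EV(k-1); EV(k-1) = 0 makes the gain +inf.  If no
    k qualifies simultaneously in every group, k_max is returned with
    ``found=False``.
    """
    evs = []
    for curve in curves:
        evs.append(
            np.array([c.explained if hasattr(c, "explained") else c for c in curve])
        )
    if len({len(e) for e in evs}) != 1:
        raise ValueError("all groups must share the same k range")
    gains = []
    for e in evs:
        prev = e[:-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.where(prev > 0, (e[1:] - prev) / np.where(prev > 0, prev, 1.0), np.inf)
        gains.append(g)
    k_values = np.arange(k_min + 1, k_min + 1 + len(gains[0]))
    ok = np.all([g < gain_threshold for g in gains], axis=0)
    ok &= k_values >= 3
    hits = np.flatnonzero(ok)
    if hits.size:
        return ElbowResult(int(k_values[hits[0]]), True, gains)
    log.warning("no elbow below gain threshold %.2f; returning k_max", gain_threshold)
    return ElbowResult(int(k_min + len(evs[0]) - 1), False, gains)


def compute_cap_maps(series: GroupImageSeries, partition: Partition) -> List[CAPMap]:
    """Voxel-wise mean BOLD across each cluster's frames (the CAPs)."""
    return [
        CAPMap(
            cap_id=j,
            mean_map=series.frames[partition.labels == j].mean(axis=0),
            n_frames=int(partition.cluster_sizes[j]),
        )
        for j in range(partition.k)
    ]


def compute_tmap(
    frames_of_cluster: np.ndarray, alpha: float = 0.01, n_tests: Optional[int] = None
) -> TMap:
    """Two-tailed one-sample T-test of each voxel's mean against zero.

    Significance is decided at the Bonferroni-corrected level
    alpha / n_tests (n_tests defaults to the voxel count).  Voxels with
    zero sample variance get a +/-inf T sentinel when their mean is
    nonzero (p = 0) and T = 0, p = 1 when the series is identically zero.
    """
    X = np.asarray(frames_of_cluster, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("t-statistic undefined for clusters with < 2 frames")
    V = X.shape[1]
    n_tests = V if n_tests is None else int(n_tests)
    m = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    dof = n - 1
    t = np.empty(V)
    p = np.empty(V)
    flat = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t[~flat] = m[~flat] / (sd[~flat] / np.sqrt(n))
    p[~flat] = 2.0 * stats.t.sf(np.abs(t[~flat]), dof)
    t[flat] = np.where(m[flat] > 0, np.inf, np.where(m[flat] < 0, -np.inf, 0.0))
    p[flat] = np.where(m[flat] == 0, 1.0, 0.0)
    sig = p < alpha / n_tests
    return TMap(
        t_stat=t,
        p_two_tailed=p,
        dof=dof,
        alpha=alpha,
        sig_pos=sig & (t > 0),
        sig_neg=sig & (t < 0),
    )
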