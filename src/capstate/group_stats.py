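"""Between-group comparisons of matched-CAP metrics and prototype grouping.

For every retained matched CAP pair within one partition, the subject
medians of occurrence, duration and positive/negative laterality are
compared between groups with a two-sample rank-sum (Wilcoxon /
Mann-Whitney) test; p-values are Benjamini-Hochberg FDR-adjusted per
metric within the partition (never across partitions — the hypotheses
tested across partitions are not independent).  Significant CAPs from
multiple partitions can then be grouped into spatial prototypes by
greedy correlation agglomeration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .matching import MatchResult, _pearson_maps

log = logging.getLogger(__name__)

__all__ = [
    "GroupComparison",
    "PrototypeGroup",
    "ranksum_compare",
    "bh_fdr",
    "compare_partition",
    "compare_qpp_incidence",
    "find_prototypes",
    "METRIC_NAMES",
]

METRIC_NAMES = ("occurrence", "duration", "laterality_pos", "laterality_neg")


@dataclass
class GroupComparison:
    k: int
    pair: Tuple[int, int]  # (WT cap id, TG cap id)
    metric: str
    statistic: float  # rank-sum W of the first sample
    p_raw: float
    p_adjusted: float = np.nan
    significant: bool = False
    median_wt: float = np.nan
    median_tg: float = np.nan
    n_wt: int = 0
    n_tg: int = 0


@dataclass
class PrototypeGroup:
    """Spatially similar significant CAPs recurring across partitions."""

    members: List[Tuple[int, int]]  # (partition k, cap id)
    representative: np.ndarray
    n_partitions: int


def ranksum_compare(values_a: Sequence[float], values_b: Sequence[float]):
    """Two-sided rank-sum test; exact null for small tie-free samples.

    Returns (W, p) where W is the rank-sum of the first sample.  The
    exact permutation null is used when the combined sample is <= 20 and
    tie-free; otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(values_a, dtype=float)
    y = np.asarray(values_b, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two finite values per group")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(res.statistic + x.size * (x.size + 1) / 2.0)  # U -> rank-sum W
    return w, float(res.pvalue)


def bh_fdr(p_values: Sequence[float], q: float = 0.05):
    """Benjamini-Hochberg step-up: (adjusted p, reject flags)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def compare_partition(
    metrics_wt: Sequence[Dict[str, np.ndarray]],
    metrics_tg: Sequence[Dict[str, np.ndarray]],
    match: MatchResult,
    k: int,
    q: float = 0.05,
    metric_names: Sequence[str] = METRIC_NAMES,
) -> List[GroupComparison]:
    """Rank-sum + per-metric BH-FDR over the retained matched pairs.

    ``metrics_wt``/``metrics_tg`` hold one per-subject dict (metric name
    -> length-k vector, NaN = unavailable) per subject.  Subjects with an
    unavailable metric are excluded from that comparison (counts kept).
    """
    comparisons: List[GroupComparison] = []
    pairs = match.retained_pairs()
    if not pairs:
        return comparisons
    for metric in metric_names:
        batch = []
        for (i, j) in pairs:
            vals_wt = np.array([m[metric][i] for m in metrics_wt])
            vals_tg = np.array([m[metric][j] for m in metrics_tg])
            vals_wt = vals_wt[np.isfinite(vals_wt)]
            vals_tg = vals_tg[np.isfinite(vals_tg)]
            if vals_wt.size < 2 or vals_tg.size < 2:
                log.info(
                    "skipping %s for pair (%d,%d): too few finite values", metric, i, j
                )
                continue
            w, p = ranksum_compare(vals_wt, vals_tg)
            batch.append(
                GroupComparison(
                    k=k,
                    pair=(i, j),
                    metric=metric,
                    statistic=w,
                    p_raw=p,
                    median_wt=float(np.median(vals_wt)),
                    median_tg=float(np.median(vals_tg)),
                    n_wt=int(vals_wt.size),
                    n_tg=int(vals_tg.size),
                )
            )
        if batch:
            p_adj, reject = bh_fdr([c.p_raw for c in batch], q=q)
            for c, pa, rej in zip(batch, p_adj, reject):
                c.p_adjusted = float(pa)
                c.significant = bool(rej)
        comparisons.extend(batch)
    return comparisons


def compare_qpp_incidence(values_wt, values_tg):
    """Unpaired two-sample T-test for QPP-window CAP incidences.

    This is the one metric compared with an unpaired T-test instead of
    the rank-sum used everywhere else (per-subject incidence
    percentages of the QPP-dominant CAP).  Returns (t, p, flag) where
    the flag names the test so downstream tables can mark the
    exception.
    """
    x = np.asarray(values_wt, dtype=float)
    y = np.asarray(values_tg, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two finite values per group")
    res = sps.ttest_ind(x, y)
    return float(res.statistic), float(res.pvalue), "unpaired-t"


def find_prototypes(
    significant_caps: Sequence[Tuple[int, int, np.ndarray]],
    r_min: float = 0.7,
) -> List[PrototypeGroup]:
    """Greedy agglomeration of significant CAPs into spatial prototypes.

    ``significant_caps`` is a list of (partition k, cap id, mean map).
    Repeatedly: seed with the candidate whose r >= r_min neighbourhood
    spans the most distinct partitions (ties -> first listed), absorb the
    best-correlated candidate from each other partition, remove them,
    and continue.  Each CAP belongs to at most one prototype.
    """
    remaining = list(range(len(significant_caps)))
    maps = [np.asarray(m, dtype=float) for _, _, m in significant_caps]
    parts = [kk for kk, _, _ in significant_caps]
    groups: List[PrototypeGroup] = []
    while remaining:
        best_seed, best_cover = None, -1
        for idx in remaining:
            cover = {parts[idx]}
            for other in remaining:
                if other == idx:
                    continue
                r, _ = _pearson_maps(maps[idx], maps[other])
                if r >= r_min:
                    cover.add(parts[other])
            if len(cover) > best_cover:
                best_seed, best_cover = idx, len(cover)
        members = [best_seed]
        # best-correlated absorbable candidate per other partition
        by_part: Dict[int, Tuple[float, int]] = {}
        for other in remaining:
            if other == best_seed or parts[other] == parts[best_seed]:
                continue
            r, _ = _pearson_maps(maps[best_seed], maps[other])
            if r >= r_min and (parts[other] not in by_part or r > by_part[parts[other]][0]):
                by_part[parts[other]] = (r, other)
        members.extend(idx for _, idx in by_part.values())
        groups.append(
            PrototypeGroup(
                members=[(parts[i], significant_caps[i][1]) for i in members],
                representative=maps[best_seed],
                n_partitions=len({parts[i] for i in members}),
            )
        )
        remaining = [i for i in remaining if i not in set(members)]
    return groups
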