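"""End-to-end study recipes on synthetic cohorts.

These functions bundle the pipeline stages into the named analyses the
package is validated with: laterality endpoint checks, elbow-recovery
across seeds, classifier power under a strong planted effect, and null
cohorts with no group difference.  The desk-scale problem sizes used
here (32x16 grid, 600 frames per subject, elbow scans to k_max = 10-12,
3-5 k-means restarts inside classification trials) are the package's
analysis scale; docs/methods.md discusses them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .classification import (
    ClassificationReport,
    build_spatial_features,
    chance_level,
    cross_validate,
    run_unbiased_scheme,
)
from .config import Group, PreprocessConfig, SimulationConfig
from .extraction import (
    GroupImageSeries,
    cluster_frames,
    compute_cap_maps,
    compute_tmap,
    detect_elbow,
    ev_curve,
)
from .matching import filter_matches, match_caps
from .metrics import hemisphere_masks, laterality_index, subject_metric_table
from .preprocess import preprocess_recording
from .synthetic import SubjectRecording, simulate_cohort

__all__ = [
    "desk_preprocess_config",
    "prepare_cohort",
    "split_groups",
    "elbow_recovery_study",
    "extract_matched_caps",
    "all_subject_classification_study",
    "unbiased_classification_study",
    "null_comparison_study",
]


def desk_preprocess_config() -> PreprocessConfig:
    """Conditioning parameters for the 32x16 desk grid.

    The smoothing kernel is scaled with the grid (0.5 px here vs 2 px on
    a 128x64 slice); trims are 20 frames each end.
    """
    return PreprocessConfig(smoothing_sigma_pixels=0.5)


def prepare_cohort(
    config: SimulationConfig, preprocess: Optional[PreprocessConfig] = None
) -> List[SubjectRecording]:
    """Simulate and condition a cohort with the fixed preprocessing chain."""
    pp = preprocess or desk_preprocess_config()
    return [preprocess_recording(rec, pp) for rec in simulate_cohort(config)]


def split_groups(
    cohort: Sequence[SubjectRecording],
) -> Tuple[List[SubjectRecording], List[SubjectRecording]]:
    wt = [r for r in cohort if r.group == Group.WT]
    tg = [r for r in cohort if r.group == Group.TG]
    return wt, tg


def elbow_recovery_study(
    n_seeds: int = 10,
    base_seed: int = 0,
    k_max: int = 10,
    n_restarts: int = 3,
    config_overrides: Optional[dict] = None,
) -> Dict[str, object]:
    """Elbow detection across seeds on the default 7-state cohort.

    For each seed a fresh cohort is simulated and conditioned, per-group
    EV curves computed for k = 2..k_max, and the two-group elbow rule
    (fractional gain < 10% in both groups) applied.  Returns the chosen
    k per seed and the recovery count.
    """
    overrides = config_overrides or {}
    chosen: List[int] = []
    ss = np.random.SeedSequence([int(base_seed), 77])
    seeds = ss.generate_state(n_seeds) % (2**31)
    n_states = overrides.get("n_states", SimulationConfig().n_states)
    for s in seeds:
        config = SimulationConfig(seed=int(s), **overrides)
        cohort = prepare_cohort(config)
        wt, tg = split_groups(cohort)
        curves = []
        for group_recs, tag in ((wt, "WT"), (tg, "TG")):
            series = GroupImageSeries.from_recordings(group_recs, group=tag)
            curves.append(
                ev_curve(series, 2, k_max, seed=int(s), n_restarts=n_restarts)
            )
        chosen.append(detect_elbow(curves).k)
    chosen_arr = np.array(chosen)
    return {
        "chosen_k": chosen_arr,
        "n_recovered": int(np.sum(chosen_arr == n_states)),
        "n_seeds": n_seeds,
        "true_k": n_states,
    }


def laterality_endpoint_values(grid_rows: int = 8, grid_cols: int = 8) -> Dict[str, float]:
    """Analytic laterality-index endpoints on a hand-built T-map.

    Three constructions on a full rectangular mask: significant positive
    voxels only in the left hemisphere (T values 2 and 4), only in the
    right (mirror image), and a perfectly mirror-symmetric pattern.
    Expected indices are +1, -1 and 0 by the definition of the index.
    """
    from .extraction import TMap
    from .metrics import hemisphere_masks, laterality_index

    mask = np.ones((grid_rows, grid_cols), dtype=bool)
    left, right = hemisphere_masks(mask)
    V = mask.sum()

    def tmap_with(sig: np.ndarray, t: np.ndarray) -> TMap:
        return TMap(
            t_stat=t,
            p_two_tailed=np.where(sig, 0.0, 1.0),
            dof=9,
            alpha=0.01,
            sig_pos=sig & (t > 0),
            sig_neg=sig & (t < 0),
        )

    t_left = np.zeros(V)
    sig_left = np.zeros(V, dtype=bool)
    idx_left = np.flatnonzero(left)[:2]
    t_left[idx_left] = [2.0, 4.0]
    sig_left[idx_left] = True

    t_right = np.zeros(V)
    sig_right = np.zeros(V, dtype=bool)
    idx_right = np.flatnonzero(right)[:2]
    t_right[idx_right] = [2.0, 4.0]
    sig_right[idx_right] = True

    t_sym = np.zeros(V)
    sig_sym = np.zeros(V, dtype=bool)
    t_sym[idx_left] = [2.0, 4.0]
    # mirror the same rows/columns across the midline
    grid = t_sym.reshape(grid_rows, grid_cols)
    grid += grid[:, ::-1].copy()
    t_sym = grid.ravel()
    sig_sym = t_sym > 0

    return {
        "all_left": laterality_index(tmap_with(sig_left, t_left), left, right),
        "all_right": laterality_index(tmap_with(sig_right, t_right), left, right),
        "mirror_symmetric": laterality_index(tmap_with(sig_sym, t_sym), left, right),
    }


@dataclass
class MatchedExtraction:
    """Everything downstream stages need from a two-group extraction."""

    series_wt: GroupImageSeries
    series_tg: GroupImageSeries
    partition_wt: object
    partition_tg: object
    caps_wt: list
    caps_tg: list
    tmaps_wt: list
    tmaps_tg: list
    match: object
    labels_by_subject: Dict[str, np.ndarray]


def extract_matched_caps(
    cohort: Sequence[SubjectRecording],
    k: int,
    seed: int = 0,
    n_restarts: int = 5,
    alpha: float = 0.01,
    r_min: float = 0.5,
) -> MatchedExtraction:
    """Group-level extraction at k, Hungarian matching, r >= r_min filter."""
    wt, tg = split_groups(cohort)
    series_wt = GroupImageSeries.from_recordings(wt, group="WT")
    series_tg = GroupImageSeries.from_recordings(tg, group="TG")
    part_wt = cluster_frames(series_wt, k, seed=seed, n_restarts=n_restarts)
    part_tg = cluster_frames(series_tg, k, seed=seed + 1, n_restarts=n_restarts)
    caps_wt = compute_cap_maps(series_wt, part_wt)
    caps_tg = compute_cap_maps(series_tg, part_tg)
    tmaps_wt = [
        compute_tmap(series_wt.frames[part_wt.labels == j], alpha=alpha)
        for j in range(k)
    ]
    tmaps_tg = [
        compute_tmap(series_tg.frames[part_tg.labels == j], alpha=alpha)
        for j in range(k)
    ]
    match = filter_matches(match_caps(caps_wt, caps_tg), r_min=r_min)
    labels_by_subject: Dict[str, np.ndarray] = {}
    for series, part in ((series_wt, part_wt), (series_tg, part_tg)):
        for sid, sl in series.subject_slices():
            labels_by_subject[sid] = part.labels[sl]
    return MatchedExtraction(
        series_wt,
        series_tg,
        part_wt,
        part_tg,
        caps_wt,
        caps_tg,
        tmaps_wt,
        tmaps_tg,
        match,
        labels_by_subject,
    )


def cohort_metric_tables(
    cohort: Sequence[SubjectRecording],
    extraction: MatchedExtraction,
    k: int,
    alpha: float = 0.01,
) -> Tuple[list, list]:
    """Per-subject metric dicts for the WT and TG groups."""
    left, right = hemisphere_masks(cohort[0].mask)
    wt, tg = split_groups(cohort)
    tables_wt = [
        subject_metric_table(
            r.frames, extraction.labels_by_subject[r.subject_id], k, left, right, alpha
        )
        for r in wt
    ]
    tables_tg = [
        subject_metric_table(
            r.frames, extraction.labels_by_subject[r.subject_id], k, left, right, alpha
        )
        for r in tg
    ]
    return tables_wt, tables_tg


def _spatial_features(cohort, extraction):
    return build_spatial_features(
        recordings=list(cohort),
        label_sequences=[
            extraction.labels_by_subject[r.subject_id] for r in cohort
        ],
        tmaps_wt=extraction.tmaps_wt,
        tmaps_tg=extraction.tmaps_tg,
        match=extraction.match,
    )


def all_subject_classification_study(
    seed: int = 0,
    n_trials: int = 100,
    k: Optional[int] = None,
    k_max: int = 10,
    n_restarts: int = 5,
    with_chance: bool = True,
    config: Optional[SimulationConfig] = None,
) -> Dict[str, object]:
    """Strong-effect cohort, all-subject CAP extraction, spatial features.

    When ``k`` is None the elbow K of the cohort's own two-group EV
    curves (k = 2..k_max) is used, as in the full pipeline.

    The study cohort keeps the modelled study's 2400 frames per
    subject: subject-level CAP estimates (and especially the projected
    CAPs of the training-only scheme) need that scan length; short
    scans visibly degrade the training-only scheme.
    """
    config = config or SimulationConfig.strong_effect(
        seed=int(seed), n_frames_per_subject=2400
    )
    cohort = prepare_cohort(config)
    wt, tg = split_groups(cohort)
    if k is None:
        curves = [
            ev_curve(
                GroupImageSeries.from_recordings(g, group=t),
                2,
                k_max,
                seed=int(seed),
                n_restarts=n_restarts,
            )
            for g, t in ((wt, "WT"), (tg, "TG"))
        ]
        k = detect_elbow(curves).k
    extraction = extract_matched_caps(cohort, k, seed=int(seed), n_restarts=n_restarts)
    features = _spatial_features(cohort, extraction)
    labels = [r.group for r in cohort]
    report = cross_validate(
        features, labels, n_trials=n_trials, seed=int(seed) + 1
    )
    chance = (
        chance_level(features, labels, n_surrogates=100, seed=int(seed) + 2)
        if with_chance
        else None
    )
    report.chance_accuracies = chance
    return {"report": report, "k": k, "features": features, "extraction": extraction}


def unbiased_classification_study(
    seed: int = 0,
    n_trials: int = 50,
    k: int = 7,
    n_restarts: int = 3,
    config: Optional[SimulationConfig] = None,
) -> ClassificationReport:
    """Strong-effect cohort under the training-set-only projection scheme.

    Same cohort family as the all-subject study (2400 frames/subject).
    """
    config = config or SimulationConfig.strong_effect(
        seed=int(seed), n_frames_per_subject=2400
    )
    cohort = prepare_cohort(config)
    return run_unbiased_scheme(
        cohort,
        k=k,
        feature_kind="spatial",
        n_trials=n_trials,
        seed=int(seed) + 1,
        n_restarts=n_restarts,
    )


def null_comparison_study(
    seed: int = 0, k: int = 7, n_trials: int = 50, q: float = 0.05
) -> Dict[str, object]:
    """Cohort with zero planted group effect: statistics and classifier.

    Returns the fraction of metric comparisons flagged significant at
    FDR level q, and the training-set-only classification report.  The
    leakage-free scheme is the right null check: the all-subject scheme
    builds each subject's features with its own group's partition and
    therefore carries a group signature even when the groups are
    statistically identical (the selection bias the training-set-only
    scheme exists to avoid); ``all_subject_report`` exposes that bias.
    """
    from .group_stats import compare_partition

    config = SimulationConfig.null_effect(seed=int(seed))
    cohort = prepare_cohort(config)
    extraction = extract_matched_caps(cohort, k, seed=int(seed))
    tables_wt, tables_tg = cohort_metric_tables(cohort, extraction, k)
    comparisons = compare_partition(tables_wt, tables_tg, extraction.match, k, q=q)
    n_sig = sum(c.significant for c in comparisons)
    features = _spatial_features(cohort, extraction)
    labels = [r.group for r in cohort]
    all_subject_report = cross_validate(
        features, labels, n_trials=n_trials, seed=int(seed) + 1
    )
    report = run_unbiased_scheme(
        cohort, k=k, feature_kind="spatial", n_trials=n_trials, seed=int(seed) + 2
    )
    return {
        "comparisons": comparisons,
        "n_significant": n_sig,
        "n_comparisons": len(comparisons),
        "false_positive_rate": n_sig / len(comparisons) if comparisons else 0.0,
        "report": report,
        "all_subject_report": all_subject_report,
    }
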