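"""One-command end-to-end pipeline driver with per-stage logs and resume.

Stage order mirrors the analysis: simulate -> preprocess -> extract (per
group) -> match -> metrics -> stats -> classify.  Every stage writes its
outputs plus a JSON log (parameters, seeds, config hash) into the output
directory; a rerun with the same config resumes past stages whose
outputs already exist.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as capio
from .classification import chance_level, cross_validate
from .config import Group, PreprocessConfig, SimulationConfig, config_hash
from .extraction import GroupImageSeries, detect_elbow, ev_curve
from .group_stats import compare_partition
from .matching import surrogate_null, filter_matches
from .preprocess import preprocess_recording
from .studies import (
    _spatial_features,
    cohort_metric_tables,
    extract_matched_caps,
    split_groups,
)
from .synthetic import simulate_cohort

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Whole-run configuration: stage configs plus pipeline knobs."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(
        default_factory=lambda: PreprocessConfig(smoothing_sigma_pixels=0.5)
    )
    k: Optional[int] = None  # None -> elbow selection
    k_min: int = 2
    k_max: int = 12
    n_restarts: int = 5
    alpha: float = 0.01
    r_min: float = 0.5
    n_shuffles: int = 10_000
    null_p: float = 1e-4
    n_trials: int = 100
    seed: int = 0
    verbosity: int = 1

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulation" in d:
            d["simulation"] = SimulationConfig(**d["simulation"])
        if "preprocess" in d:
            d["preprocess"] = PreprocessConfig(**d["preprocess"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _stage_log(out: Path, stage: str, payload: dict, cfg_hash: str) -> None:
    payload = dict(payload)
    payload["stage"] = stage
    payload["config_hash"] = cfg_hash
    (out / f"log_{stage}.json").write_text(json.dumps(payload, indent=2, default=str))


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Run (or resume) the full synthetic-cohort pipeline; returns out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config_hash(config.simulation, config.preprocess, config.seed)

    # --- simulate ---------------------------------------------------------
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        log.info("resume: simulate outputs present")
        manifest = capio.read_manifest(manifest_path)
        if manifest["config_hash"] != cfg_hash:
            raise RuntimeError(
                "existing outputs were produced with a different config; "
                "use a fresh output directory"
            )
    cohort = simulate_cohort(config.simulation)
    mask = cohort[0].mask
    if not manifest_path.exists():
        capio.write_mask(mask, out / "mask.nii.gz")
        from .metrics import run_lengths

        run_length_table = {}
        for rec in cohort:
            capio.write_series(rec, out / f"{rec.subject_id}.nii.gz")
            capio.write_motion_tsv(
                rec.motion_regressors, out / f"{rec.subject_id}_motion.tsv"
            )
            run_length_table[rec.subject_id] = run_lengths(
                rec.true_state_sequence, config.simulation.n_states
            )
        capio.write_manifest(
            {
                "subjects": [r.subject_id for r in cohort],
                "groups": [r.group.value for r in cohort],
                "seed": config.seed,
                "config_hash": cfg_hash,
                "true_state_run_lengths": run_length_table,
            },
            manifest_path,
        )
        _stage_log(out, "simulate", {"n_subjects": len(cohort)}, cfg_hash)

    # --- preprocess -------------------------------------------------------
    cohort = [preprocess_recording(r, config.preprocess) for r in cohort]
    _stage_log(
        out,
        "preprocess",
        {"config": dataclasses.asdict(config.preprocess)},
        cfg_hash,
    )

    # --- extract ----------------------------------------------------------
    wt, tg = split_groups(cohort)
    k = config.k
    if k is None:
        curves = []
        ev_rows = []
        for recs, tag in ((wt, "WT"), (tg, "TG")):
            series = GroupImageSeries.from_recordings(recs, group=tag)
            curve = ev_curve(
                series, config.k_min, config.k_max,
                seed=config.seed, n_restarts=config.n_restarts,
            )
            curves.append(curve)
            ev_rows += [
                {"group": tag, "k": c.k, "explained_variance": c.explained}
                for c in curve
            ]
        pd.DataFrame(ev_rows).to_csv(out / "ev_curve.tsv", sep="\t", index=False)
        elbow = detect_elbow(curves)
        k = elbow.k
        _stage_log(out, "elbow", {"k": k, "found": elbow.found}, cfg_hash)
    extraction = extract_matched_caps(
        cohort, k, seed=config.seed,
        n_restarts=config.n_restarts, alpha=config.alpha, r_min=config.r_min,
    )
    for tag, series, part in (
        ("WT", extraction.series_wt, extraction.partition_wt),
        ("TG", extraction.series_tg, extraction.partition_tg),
    ):
        subject_of_frame = np.empty(series.n_frames, dtype=object)
        for sid, sl in series.subject_slices():
            subject_of_frame[sl] = sid
        capio.write_labels_tsv(part.labels, subject_of_frame, out / f"labels_{tag}.tsv")
    for j, cap in enumerate(extraction.caps_wt):
        capio.write_map(cap.mean_map, mask, out / f"cap_WT_{j+1}.nii.gz")
    for j, cap in enumerate(extraction.caps_tg):
        capio.write_map(cap.mean_map, mask, out / f"cap_TG_{j+1}.nii.gz")
    _stage_log(out, "extract", {"k": k}, cfg_hash)

    # --- match ------------------------------------------------------------
    threshold = surrogate_null(
        extraction.partition_wt.labels,
        extraction.series_wt.frames,
        extraction.partition_tg.labels,
        extraction.series_tg.frames,
        extraction.match.pairs,
        n_shuffles=config.n_shuffles,
        p=config.null_p,
        seed=config.seed + 11,
    )
    match = filter_matches(extraction.match, threshold=threshold, r_min=config.r_min)
    extraction.match = match
    (out / "match.json").write_text(
        json.dumps(
            {
                "pairs_1based": [[i + 1, j + 1] for i, j in match.pairs],
                "pearson_r": match.pair_correlations.tolist(),
                "null_threshold": threshold,
                "retained": match.retained.tolist(),
            },
            indent=2,
        )
    )
    _stage_log(out, "match", {"threshold": threshold}, cfg_hash)

    # --- metrics ----------------------------------------------------------
    tables_wt, tables_tg = cohort_metric_tables(cohort, extraction, k, config.alpha)
    rows = []
    for recs, tables in ((wt, tables_wt), (tg, tables_tg)):
        for rec, table in zip(recs, tables):
            for metric, vals in table.items():
                for j, v in enumerate(vals):
                    rows.append(
                        {
                            "subject": rec.subject_id,
                            "group": rec.group.value,
                            "cap": j + 1,  # 1-based
                            "metric": metric,
                            "value": v,
                        }
                    )
    pd.DataFrame(rows).to_csv(out / "metrics.tsv", sep="\t", index=False)
    _stage_log(out, "metrics", {"n_rows": len(rows)}, cfg_hash)

    # --- stats ------------------------------------------------------------
    comparisons = compare_partition(tables_wt, tables_tg, match, k)
    pd.DataFrame(
        [
            {
                "k": c.k,
                "cap_wt": c.pair[0] + 1,
                "cap_tg": c.pair[1] + 1,
                "metric": c.metric,
                "median_wt": c.median_wt,
                "median_tg": c.median_tg,
                "p_raw": c.p_raw,
                "p_adj": c.p_adjusted,
                "significant": c.significant,
            }
            for c in comparisons
        ]
    ).to_csv(out / "stats.tsv", sep="\t", index=False)
    _stage_log(out, "stats", {"n_comparisons": len(comparisons)}, cfg_hash)

    # --- classify ---------------------------------------------------------
    if not match.retained.any():
        (out / "classification.json").write_text(
            json.dumps({"skipped": "no matched CAP pair above threshold"}, indent=2)
        )
        _stage_log(out, "classify", {"skipped": True}, cfg_hash)
        return out
    features = _spatial_features(cohort, extraction)
    labels = [r.group for r in cohort]
    report = cross_validate(
        features, labels, n_trials=config.n_trials, seed=config.seed + 21
    )
    chance = chance_level(features, labels, n_surrogates=100, seed=config.seed + 22)
    (out / "classification.json").write_text(
        json.dumps(
            {
                "scheme": report.scheme,
                "mean_accuracy": report.mean_accuracy,
                "chance_mean": float(chance.mean()),
                "confusion": report.confusion.tolist(),
                "n_trials": report.n_trials,
            },
            indent=2,
        )
    )
    _stage_log(out, "classify", {"mean_accuracy": report.mean_accuracy}, cfg_hash)
    return out
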