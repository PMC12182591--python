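"""End-to-end orchestration: per-subject segmentation and cohort analysis.

``run_subject`` executes the fixed stage order
denoise -> motion-correct -> average -> ROI transfer -> reference stats ->
threshold segmentation -> volume, logging each stage, and returns a
:class:`~nmseg.segmentation.SegmentationResult` plus a flat CSV-ready row.
``run_cohort`` aggregates subject rows (or a simulated cohort table), runs the
statistical layer and population maps, and writes a reproducibility manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .image import ImageVolume, RoiMask
from .popmaps import population_mean
from .preprocess import MeasurementStack, average_stack, denoise_stack, motion_correct
from .segmentation import (DEFAULT_K, DEFAULT_PROB_THRESHOLD, build_search_roi,
                           mtc_map, reference_stats, segment_snc)
from .spatial import TransformChain
from .stats import ancova, normality_check

__all__ = ["PipelineConfig", "SubjectInputs", "run_subject", "run_cohort"]

logger = logging.getLogger(__name__)

STAGE_ORDER = ("denoise", "motion_correct", "average")


@dataclass
class PipelineConfig:
    """Tunable parameters of the whole pipeline; defaults follow the method."""

    k: float = DEFAULT_K
    atlas_prob_threshold: float = DEFAULT_PROB_THRESHOLD
    dilation_radius_voxels: int = 1
    denoise_method: str = "patch_pca"
    denoise_params: dict = field(default_factory=dict)
    mask_interpolation: str = "nearest"
    sd_ddof: int = 0
    stage_order: tuple = STAGE_ORDER
    allow_reordered_stages: bool = False
    covariates: tuple = ("sex", "age", "total_brain_volume", "site")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if not 0.0 < self.atlas_prob_threshold < 1.0:
            raise ValueError("atlas_prob_threshold must lie in (0, 1)")
        if self.dilation_radius_voxels < 0:
            raise ValueError("dilation_radius_voxels must be >= 0")
        if tuple(self.stage_order) != STAGE_ORDER and not self.allow_reordered_stages:
            raise ValueError(
                f"preprocessing stages must run in order {STAGE_ORDER}; "
                "set allow_reordered_stages=True to override")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stage_order"] = list(self.stage_order)
        d["covariates"] = list(self.covariates)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class SubjectInputs:
    subject_id: str
    stack: MeasurementStack
    atlas: ImageVolume            # probabilistic SNc atlas, template space
    cp_mask: RoiMask              # cerebral-peduncle reference ROI, template space
    template_to_gre: TransformChain
    group: str | None = None
    covariate_row: dict = field(default_factory=dict)


def run_subject(config: PipelineConfig, inputs: SubjectInputs):
    """Run the per-subject pipeline; returns (SegmentationResult, row dict)."""
    sid = inputs.subject_id
    logger.info("[%s] denoise method=%s", sid, config.denoise_method)
    stack = denoise_stack(inputs.stack, config.denoise_method, config.denoise_params)
    logger.info("[%s] motion correction over %d measurements", sid, len(stack))
    stack, transforms = motion_correct(stack) if len(stack) > 1 else (stack, [])
    logger.info("[%s] averaging", sid)
    avg = average_stack(stack)

    logger.info("[%s] ROI transfer (single composed resample)", sid)
    search_roi = build_search_roi(inputs.atlas, inputs.template_to_gre, avg,
                                  prob_threshold=config.atlas_prob_threshold,
                                  dilation_radius_voxels=config.dilation_radius_voxels)
    from .spatial import compose_and_resample
    cp_native = compose_and_resample(inputs.cp_mask, inputs.template_to_gre, avg, order=0)
    ref = reference_stats(avg, cp_native, ddof=config.sd_ddof)
    logger.info("[%s] mu_ref=%.3f sigma_ref=%.3f over %d voxels",
                sid, ref.mu_ref, ref.sigma_ref, ref.n_voxels)

    result = segment_snc(avg, search_roi, ref, k=config.k)
    if result.voxel_count == 0:
        logger.warning("[%s] empty SNc mask at k=%.3g (threshold %.3f)",
                       sid, config.k, result.threshold)
    row = {
        "subject_id": sid,
        "group": inputs.group,
        **inputs.covariate_row,
        "mu_ref": ref.mu_ref,
        "sigma_ref": ref.sigma_ref,
        "threshold": result.threshold,
        "voxel_count": result.voxel_count,
        "snc_volume": result.volume_mm3,
    }
    return result, row


def run_cohort(config: PipelineConfig, subjects, out_dir, template_grid=None,
               chains_to_template=None, cohort_table: pd.DataFrame | None = None):
    """Segment all subjects (or take a precomputed table), then run statistics.

    ``subjects`` is an iterable of :class:`SubjectInputs`; alternatively pass a
    ready ``cohort_table``. Writes the cohort CSV, a text report, optional
    population maps and a reproducibility manifest; failed subjects are
    recorded and the batch continues.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs, failures, rows, results = [], [], [], {}

    for inputs in (subjects or []):
        try:
            result, row = run_subject(config, inputs)
            rows.append(row)
            results[inputs.subject_id] = result
        except Exception as exc:  # noqa: BLE001 - batch must continue
            logger.error("[%s] failed: %s", inputs.subject_id, exc)
            failures.append({"subject_id": inputs.subject_id, "error": str(exc)})

    table = cohort_table if cohort_table is not None else pd.DataFrame(rows)
    csv_path = out_dir / "cohort.csv"
    table.to_csv(csv_path, index=False)
    outputs.append(csv_path.name)

    report_lines = [f"nmseg cohort report (config {config.digest()})",
                    f"subjects: {len(table)}  failures: {len(failures)}"]
    stats_payload = {}
    groups = table["group"].dropna().unique() if "group" in table else []
    counts = table["group"].value_counts() if "group" in table else pd.Series(dtype=int)
    if len(groups) >= 2 and (counts >= 2).all():
        covars = []
        for c in config.covariates:
            if c not in table.columns:
                continue
            if table[c].dropna().nunique() < 2:
                logger.info("covariate %r is constant in this cohort; dropped", c)
                continue
            covars.append(c)
        try:
            res = ancova(table, outcome="snc_volume", group="group", covariates=covars)
            sw = normality_check(table)
        except ValueError as exc:
            logger.error("statistics stage failed: %s", exc)
            report_lines.append(f"statistics failed: {exc}")
        else:
            report_lines.append(f"ANCOVA group effect: F={res.F:.3f}, p={res.p:.4g} "
                                f"(df {res.df_effect}, {res.df_residual})")
            for g, (m, se) in res.marginal_means.items():
                report_lines.append(f"  marginal mean {g}: {m:.1f} mm^3 (SE {se:.1f})")
            stats_payload = {
                "ancova": {"F": res.F, "p": res.p,
                           "marginal_means": {g: list(v)
                                              for g, v in res.marginal_means.items()},
                           "covariates": {c: list(v)
                                          for c, v in res.covariate_tests.items()},
                           "posthoc": {f"{a}|{b}": p
                                       for (a, b), p in res.posthoc.items()}},
                "shapiro_wilk": sw,
            }
    else:
        report_lines.append("statistics skipped: need >= 2 groups with n >= 2 each")

    if template_grid is not None and chains_to_template and results:
        per_group: dict = {}
        for inputs_id, chain in chains_to_template.items():
            if inputs_id in results:
                res = results[inputs_id]
                grp = table.loc[table.subject_id == inputs_id, "group"]
                label = str(grp.iloc[0]) if len(grp) else "all"
                per_group.setdefault(label, []).append((res.snc_mask, chain))
        for label, items in per_group.items():
            pmap = population_mean(items, template_grid, group_label=label,
                                   mask_interpolation="trilinear"
                                   if config.mask_interpolation == "nearest"
                                   else config.mask_interpolation)
            path = out_dir / f"popmap_{label}.nii.gz"
            pmap.mean_map.to_nifti(path)
            outputs.append(path.name)

    report_path = out_dir / "report.txt"
    report_path.write_text("\n".join(report_lines) + "\n")
    outputs.append(report_path.name)
    if stats_payload:
        stats_path = out_dir / "stats.json"
        stats_path.write_text(json.dumps(stats_payload, indent=2))
        outputs.append(stats_path.name)

    manifest = {
        "software": {"name": "nmseg", "version": __version__},
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_subjects": int(len(table)),
        "failures": failures,
        "outputs": sorted(outputs + ["manifest.json"]),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return table, manifest
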