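"""End-to-end orchestration: simulate -> connectome -> GLM -> train/predict
-> define regions -> evaluate.

Every stage is deterministic given (config, seed); `run_pipeline` records
per-stage wall time and sha256 checksums of everything it writes in a run
manifest so reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .connectome import FrameMask, build_feature_matrix, censor_frames, compute_connectome
from .evaluation import (
    AnovaResult,
    MethodComparison,
    anova_selectivity,
    compare_methods,
    selectivity_table,
)
from .froi import FROI, define_froi, overlap_metrics
from .glm import (
    BetaMap,
    ContrastMap,
    HRFParams,
    build_glm_design,
    compute_contrast,
    contrast_for_category,
    fit_glm,
    flag_motion_frames,
)
from .io import sha256_of, write_cohort, write_model
from .model import CVReport, RidgeModel, fit_final_model, lambda_grid, loso_predict
from .synth.atlas import ATLAS_MODES, make_group_atlas
from .synth.cohort import Cohort, generate_cohort

__all__ = ["PipelineResult", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "connectome", "glm", "train", "froi", "evaluate")

EVAL_METHODS = ("connectivity", "localizer-run1", "ground-truth",
                "atlas-union", "atlas-dilated", "atlas-shifted")


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: Cohort
    masks: dict[str, FrameMask] = field(default_factory=dict)
    features: dict[str, dict] = field(default_factory=dict)          # froi -> sid -> FeatureMatrix
    betamaps: dict[str, dict[int, BetaMap]] = field(default_factory=dict)
    contrasts: dict[str, dict[int, dict[str, ContrastMap]]] = field(default_factory=dict)
    cv_reports: dict[str, CVReport] = field(default_factory=dict)
    final_models: dict[str, RidgeModel] = field(default_factory=dict)
    frois: dict[tuple[str, float], dict[tuple[str, str], FROI]] = field(default_factory=dict)
    atlases: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    overlap: pd.DataFrame | None = None
    selectivity: pd.DataFrame | None = None
    comparison: MethodComparison | None = None
    anova: AnovaResult | None = None
    manifest: dict = field(default_factory=dict)

    def froi_sets(self, method: str, fraction: float) -> dict[tuple[str, str], np.ndarray]:
        """(subject, froi) -> vertex array for one method/fraction."""
        return {
            key: np.asarray(f.vertices)
            for key, f in self.frois.get((method, fraction), {}).items()
        }


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(
    config: PipelineConfig,
    *,
    cohort: Cohort | None = None,
    froi_subset: "list[str] | None" = None,
    until: str = "evaluate",
) -> PipelineResult:
    """Run the pipeline through ``until`` (one of ``STAGES``).

    A pre-generated cohort may be supplied (e.g. loaded from disk); the
    configured seed is otherwise used to simulate one.
    """
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}")
    stop = STAGES.index(until)
    cfg_hash = _config_hash(config)
    log = logging.LoggerAdapter(logger, {"seed": config.seed, "config": cfg_hash})
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": cfg_hash,
        "config": dataclasses.asdict(config),
        "stages": {},
        "checksums": {},
    }
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def _stage_done(name: str, t0: float) -> None:
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
        log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)

    # --- simulate -----------------------------------------------------
    t0 = time.perf_counter()
    if cohort is None:
        cohort = generate_cohort(config.cohort.with_(seed=config.seed))
    if out_dir:
        write_cohort(cohort, out_dir / "cohort")
    result = PipelineResult(config=config, cohort=cohort, manifest=manifest)
    _stage_done("simulate", t0)
    if stop == 0:
        return _finalize(result, out_dir)

    registry = cohort.registry
    froi_ids = froi_subset or registry.froi_ids
    hrf = HRFParams(config.hrf_delay, config.hrf_dispersion, config.hrf_exponent)

    # --- connectome ---------------------------------------------------
    t0 = time.perf_counter()
    for subj in cohort.subjects:
        result.masks[subj.subject_id] = censor_frames(subj.rest, config.fd_threshold_mm)
    for fid in froi_ids:
        result.features[fid] = {}
        for subj in cohort.subjects:
            conn = compute_connectome(subj.rest, result.masks[subj.subject_id],
                                      cohort.surface, fid)
            result.features[fid][subj.subject_id] = build_feature_matrix(conn, cohort.surface)
    _stage_done("connectome", t0)
    if stop == 1:
        return _finalize(result, out_dir)

    # --- glm ----------------------------------------------------------
    t0 = time.perf_counter()
    categories = sorted({registry[fid].category for fid in froi_ids})
    for subj in cohort.subjects:
        result.betamaps[subj.subject_id] = {}
        result.contrasts[subj.subject_id] = {}
        for i, run in enumerate(subj.task_runs, start=1):
            spikes = flag_motion_frames(run, config.motion_threshold_mm)
            design = build_glm_design(run.design, hrf, run.motion, spikes)
            bm = fit_glm(run, design)
            result.betamaps[subj.subject_id][i] = bm
            result.contrasts[subj.subject_id][i] = {
                cat: compute_contrast(bm, contrast_for_category(cat)) for cat in categories
            }
    _stage_done("glm", t0)
    if stop == 2:
        return _finalize(result, out_dir)

    # --- train / predict ---------------------------------------------
    t0 = time.perf_counter()
    grid = lambda_grid(config.lambda_count, config.lambda_lo, config.lambda_hi)
    for fid in froi_ids:
        category = registry[fid].category
        data = {}
        columns = None
        for subj in cohort.subjects:
            feats = result.features[fid][subj.subject_id]
            columns = feats.columns
            target = result.contrasts[subj.subject_id][1][category].effect_for(feats.vertex_ids)
            data[subj.subject_id] = (feats.values, target)
        result.cv_reports[fid] = loso_predict(
            data, grid, columns=columns, froi_id=fid, inner_mse=config.inner_mse,
            keep_models=True,
        )
        if config.compute_final_models:
            result.final_models[fid] = fit_final_model(
                data, grid, columns=columns, froi_id=fid, inner_mse=config.inner_mse
            )
    _stage_done("train", t0)
    if stop == 3:
        return _finalize(result, out_dir)

    # --- define regions ----------------------------------------------
    t0 = time.perf_counter()
    for mode in ATLAS_MODES:
        result.atlases[f"atlas-{mode.split('-')[0]}"] = make_group_atlas(
            cohort, mode, q=config.atlas_q,
            dilate_radius=config.atlas_dilate_radius, shift=config.atlas_shift,
        )
    primary_f = config.fractions[0]
    overlap_rows = []
    for f in config.fractions:
        for method in ("connectivity", "localizer-run1", "localizer-run2"):
            result.frois[(method, f)] = {}
        for subj in cohort.subjects:
            sid = subj.subject_id
            for fid in froi_ids:
                feats = result.features[fid][sid]
                verts = feats.vertex_ids
                category = registry[fid].category
                maps = {
                    "connectivity": result.cv_reports[fid].predictions[sid],
                    "localizer-run1": result.contrasts[sid][1][category].effect_for(verts),
                    "localizer-run2": result.contrasts[sid][2][category].effect_for(verts),
                }
                for method, values in maps.items():
                    result.frois[(method, f)][(sid, fid)] = define_froi(
                        values, verts, froi_id=fid, method=method, fraction=f,
                        source=f"{sid}:{method}",
                    )
                ov = overlap_metrics(
                    result.frois[("connectivity", f)][(sid, fid)],
                    result.frois[("localizer-run1", f)][(sid, fid)],
                    result.frois[("localizer-run2", f)][(sid, fid)],
                )
                overlap_rows.append(
                    {
                        "subject": sid, "froi": fid, "fraction": f,
                        "dice_pred_actual": ov.dice_pred_actual,
                        "dice_actual_actual": ov.dice_actual_actual,
                        "explainable_ratio": ov.explainable_ratio,
                        "chance_adjusted": ov.chance_adjusted,
                    }
                )
    # fixed vertex-set methods recorded at the primary fraction
    gt_sets: dict[tuple[str, str], FROI] = {}
    for subj in cohort.subjects:
        for fid in froi_ids:
            gv = subj.ground_truth.froi_vertices[fid]
            gt_sets[(subj.subject_id, fid)] = FROI(
                froi_id=fid, method="ground-truth",
                vertices=tuple(int(v) for v in gv),
                fraction=cohort.config.froi_fraction, source=subj.subject_id,
            )
    result.frois[("ground-truth", primary_f)] = gt_sets
    for name, sets in result.atlases.items():
        result.frois[(name, primary_f)] = {
            (subj.subject_id, fid): FROI(
                froi_id=fid, method=name,
                vertices=tuple(int(v) for v in sets[fid]),
                fraction=primary_f, source=name,
            )
            for subj in cohort.subjects
            for fid in froi_ids
        }
    result.overlap = pd.DataFrame(overlap_rows)
    _stage_done("froi", t0)
    if stop == 4:
        return _finalize(result, out_dir)

    # --- evaluate -----------------------------------------------------
    t0 = time.perf_counter()
    eval_run = config.evaluation_run
    eval_betamaps = {sid: runs[eval_run] for sid, runs in result.betamaps.items()}
    frois_by_method = {
        m: result.froi_sets(m, primary_f) for m in EVAL_METHODS
        if (m, primary_f) in result.frois
    }
    result.selectivity = selectivity_table(registry, frois_by_method, eval_betamaps)
    conn = result.selectivity[result.selectivity["method"] == "connectivity"]
    if len(froi_ids) == len(registry):
        result.anova = anova_selectivity(conn, denominators=config.anova_denominators)
    result.comparison = compare_methods(result.selectivity, reference="connectivity")
    _stage_done("evaluate", t0)
    return _finalize(result, out_dir)


def _finalize(result: PipelineResult, out_dir: Path | None) -> PipelineResult:
    if out_dir is None:
        return result
    cfg = result.config

    if result.cv_reports:
        folds = pd.concat(
            [rep.folds.assign(froi=fid) for fid, rep in result.cv_reports.items()],
            ignore_index=True,
        )
        folds.to_csv(out_dir / "cv_report.tsv", sep="\t", index=False)
        pred_rows = []
        for fid, rep in result.cv_reports.items():
            verts = next(iter(result.features[fid].values())).vertex_ids
            for sid, pred in rep.predictions.items():
                pred_rows.append(
                    pd.DataFrame({"subject": sid, "froi": fid, "vertex": verts, "predicted": pred})
                )
        pd.concat(pred_rows, ignore_index=True).to_csv(
            out_dir / "predicted_maps.tsv", sep="\t", index=False
        )
    if result.final_models:
        mdir = out_dir / "final_models"
        mdir.mkdir(exist_ok=True)
        for fid, model in result.final_models.items():
            write_model(model, mdir / f"{fid}.json")
    if result.frois:
        rows = []
        for (method, f), sets in result.frois.items():
            for (sid, fid), froi in sets.items():
                for v in froi.vertices:
                    rows.append((method, f, sid, fid, v))
        pd.DataFrame(
            rows, columns=["method", "fraction", "subject", "froi", "vertex"]
        ).to_csv(out_dir / "frois.tsv", sep="\t", index=False)
    if result.overlap is not None:
        result.overlap.to_csv(out_dir / "overlap.tsv", sep="\t", index=False)
    if result.selectivity is not None:
        result.selectivity.to_csv(out_dir / "selectivity.tsv", sep="\t", index=False)
    if result.comparison is not None:
        result.comparison.selectivity_tests.to_csv(out_dir / "tests.tsv", sep="\t", index=False)
        result.comparison.pairwise.to_csv(out_dir / "pairwise_tests.tsv", sep="\t", index=False)
        result.comparison.summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    if result.anova is not None:
        tab = result.anova.table.reset_index().rename(
            columns={"index": "Predictor", "ss": "SumSq", "df": "df", "ms": "MeanSq"}
        )
        tab.to_csv(out_dir / "anova.tsv", sep="\t", index=False)

    for path in sorted(out_dir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            result.manifest["checksums"][str(path.relative_to(out_dir))] = sha256_of(path)
    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=1, default=str))
    return result
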