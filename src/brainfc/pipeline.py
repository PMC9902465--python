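"""Configuration-driven orchestration of the full study design.

A run goes: simulate (or load) a cohort -> extract the requested measures ->
optional parameter-sensitivity scan -> nested CV per measure -> multi-modal
fusion -> biomarker report.  Every stage writes its outputs under the run
directory keyed by a hash of the configuration, so a re-run with the same
config resumes from cached stage outputs, and the echoed config plus seed
make the run reproducible end to end.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from brainfc import biomarkers as bm
from brainfc import io as bio
from brainfc.connectivity import dhofc, pearson_fc, thofc
from brainfc.fusion import early_fuse, mkl_nested_cv
from brainfc.ml import (
    FeatureTable,
    cohort_feature_table,
    nested_cv,
    residualize,
)
from brainfc.sparse import (
    SparseFCParams,
    solve_gsr,
    solve_sr,
    solve_slr,
    solve_ssgsr,
    symmetrize,
)
from brainfc.synthetic import CohortSpec, make_cohort, make_group_models

log = logging.getLogger("brainfc")

KNOWN_MEASURES = ("PC", "tHOFC", "dHOFC", "SR", "GSR", "SSGSR", "SLR")


@dataclass
class RunConfig:
    """Validated, fully serializable run configuration."""

    input_mode: str = "synthetic"  # synthetic | files
    manifest: str | None = None
    n_rois: int = 20
    n_subjects_per_group: tuple[int, int] = (60, 60)
    t_points: int = 370
    tr_seconds: float = 0.8
    n_effect_edges: int = 8
    effect_delta: float = 0.4
    measures: tuple[str, ...] = ("PC",)
    dhofc_k: int = 10
    dhofc_window: int = 50
    sparse_params: dict = field(default_factory=lambda: {"lambda1": 0.01, "lambda2": 0.01})
    covariate_names: tuple[str, ...] = ("sex", "manufacturer", "site", "motion")
    classifier: str = "svm_rbf"
    outer_k: int = 10
    inner_k: int = 5
    boruta_params: dict = field(default_factory=dict)
    fusion: bool = False
    biomarker_alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.input_mode not in {"synthetic", "files"}:
            raise ValueError("input_mode must be 'synthetic' or 'files'")
        if self.input_mode == "files" and not self.manifest:
            raise ValueError("files mode requires a manifest path")
        unknown = set(self.measures) - set(KNOWN_MEASURES)
        if unknown:
            raise ValueError(f"unknown measures: {sorted(unknown)}")
        if self.outer_k < 2 or self.inner_k < 2:
            raise ValueError("outer_k and inner_k must be >= 2")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def get_cohort(config: RunConfig):
    if config.input_mode == "files":
        return bio.load_cohort_from_manifest(config.manifest, config.tr_seconds)
    models = make_group_models(
        config.n_rois, config.n_effect_edges, config.effect_delta,
        seed=config.seed,
    )
    spec = CohortSpec(
        n_subjects_per_group=tuple(config.n_subjects_per_group),
        t_points=config.t_points,
        tr_seconds=config.tr_seconds,
        seed=config.seed,
    )
    return make_cohort(models, spec)


def extract_measure(cohort, measure: str, config: RunConfig) -> FeatureTable:
    """Per-subject FC estimation -> vectorized, residualized feature table."""
    params = SparseFCParams(
        lambda1=config.sparse_params.get("lambda1", 0.01),
        lambda2=config.sparse_params.get("lambda2", 0.01),
    )
    if measure == "PC":
        fcs = [pearson_fc(s) for s in cohort.subjects]
    elif measure == "tHOFC":
        fcs = [thofc(pearson_fc(s)) for s in cohort.subjects]
    elif measure == "dHOFC":
        fcs = [dhofc(s, config.dhofc_window, config.dhofc_k) for s in cohort.subjects]
    elif measure == "SR":
        fcs = [symmetrize(solve_sr(s, params)) for s in cohort.subjects]
    elif measure == "SLR":
        fcs = [symmetrize(solve_slr(s, params)) for s in cohort.subjects]
    elif measure == "GSR":
        fcs = [symmetrize(fc) for fc in solve_gsr(cohort, params)]
    elif measure == "SSGSR":
        fcs = [symmetrize(fc) for fc in solve_ssgsr(cohort, params)]
    else:
        raise ValueError(f"unknown measure {measure!r}")
    table = cohort_feature_table(fcs, cohort.labels, cohort.covariates, measure)
    usable = [c for c in config.covariate_names if c in table.covariates.columns]
    if usable:
        table = residualize(table, usable)
    return table


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute all configured stages; returns the run directory."""
    config.validate()
    run_dir = Path(out_dir) / f"run_{config.config_hash()}"
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.json").write_text(
        json.dumps(asdict(config), indent=2, default=str))
    t0 = time.time()
    log.info("stage=cohort start")
    cohort = get_cohort(config)

    tables: dict[str, FeatureTable] = {}
    reports = {}
    metrics_rows = []
    for measure in config.measures:
        cache = run_dir / f"metrics_{measure}.csv"
        log.info("stage=extract measure=%s", measure)
        table = extract_measure(cohort, measure, config)
        tables[measure] = table
        if cache.exists():
            log.info("stage=classify measure=%s cached", measure)
            cached = pd.read_csv(cache)
            metrics_rows.extend(cached.to_dict("records"))
            continue
        log.info("stage=classify measure=%s", measure)
        report = nested_cv(
            table,
            classifier=config.classifier,
            outer_k=config.outer_k,
            inner_k=config.inner_k,
            seed=config.seed,
            boruta_params=config.boruta_params,
        )
        reports[measure] = report
        rows = [{"measure": measure, "fold": i, **{k: v for k, v in m.items()
                                                   if k != "flags"}}
                for i, m in enumerate(report.fold_metrics)]
        pd.DataFrame(rows).to_csv(cache, index=False)
        metrics_rows.extend(rows)
        sel_counts = {}
        for fold_sel in report.selected_features:
            for nm in fold_sel:
                sel_counts[nm] = sel_counts.get(nm, 0) + 1
        stable = bm.stable_candidates(report)
        if stable:
            rep = bm.group_ttest_fdr(table, stable, config.biomarker_alpha,
                                     selection_counts=sel_counts)
            rep.to_csv(run_dir / f"biomarkers_{measure}.csv", index=False)

    if config.fusion and len(config.measures) > 1:
        log.info("stage=fusion")
        fused = early_fuse([tables[m] for m in config.measures])
        rep = nested_cv(fused, classifier=config.classifier,
                        outer_k=config.outer_k, inner_k=config.inner_k,
                        seed=config.seed, boruta_params=config.boruta_params)
        rows = [{"measure": "early_fusion", "fold": i,
                 **{k: v for k, v in m.items() if k != "flags"}}
                for i, m in enumerate(rep.fold_metrics)]
        pd.DataFrame(rows).to_csv(run_dir / "metrics_early_fusion.csv", index=False)
        metrics_rows.extend(rows)

        log.info("stage=mkl")
        mkl_rep = mkl_nested_cv([tables[m] for m in config.measures],
                                outer_k=config.outer_k, seed=config.seed)
        rows = [{"measure": "mkl", "fold": i,
                 **{k: v for k, v in m.items() if k != "flags"}}
                for i, m in enumerate(mkl_rep.fold_metrics)]
        pd.DataFrame(rows).to_csv(run_dir / "metrics_mkl.csv", index=False)
        metrics_rows.extend(rows)

    pd.DataFrame(metrics_rows).to_csv(run_dir / "metrics.csv", index=False)
    meta = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "elapsed_seconds": round(time.time() - t0, 2),
        "measures": list(config.measures),
    }
    (run_dir / "run_meta.json").write_text(json.dumps(meta, indent=2))
    log.info("stage=done elapsed=%.1fs", meta["elapsed_seconds"])
    return run_dir
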