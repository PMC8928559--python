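"""End-to-end orchestration from a single configuration.

``run_pipeline`` executes variable selection -> ELC map -> aridity/soil
indices -> the three environmental filters -> calibration -> overlap
report, writing each stage's outputs and a manifest (config, seed, row
counts) into a run directory so any output is reproducible from the
manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import calibration, elc, filtering, indices, io, selectvar
from .types import COMPONENTS, EnvironmentalStack

log = logging.getLogger("predchar")

#: Default thresholds and sizes of the study design, in one auditable block.
STUDY_DEFAULTS: dict[str, Any] = {
    "top_n_variables": 15,
    "r_threshold": 0.5,
    "alpha": 0.05,
    "max_k": 6,
    "drought_aridity_cutoff": 15.0,
    "waterlogging_aridity_cutoff": 25.0,
    "salinity_primary_ec": 4.0,
    "salinity_fallback_low": 2.0,
    "binarize_quantile": 0.10,
    "n_runs": 100,
    "train_frac": 0.75,
    "subset_cap": 30,
    "top_n_projection": 30,
    "n_perm": 100,
}


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    out_dir: str
    stack_dir: str | None = None
    occurrences: str | None = None
    evaluations: str | None = None
    seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "selectvar": True,
            "elcmap": True,
            "indices": True,
            "filter": True,
            "calibrate": True,
            "overlaps": True,
        }
    )
    params: dict[str, Any] = field(default_factory=lambda: dict(STUDY_DEFAULTS))
    column_map: dict[str, str] = field(default_factory=dict)
    monthly_precip_cols: list[str] = field(default_factory=list)
    monthly_temp_cols: list[str] = field(default_factory=list)
    trait: str = "rust"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        params = dict(STUDY_DEFAULTS)
        params.update(raw.pop("params", {}))
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        cfg.params = params
        return cfg

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def run_pipeline(
    config: RunConfig,
    stack: EnvironmentalStack | None = None,
    occurrences: pd.DataFrame | None = None,
    evaluations: pd.DataFrame | None = None,
) -> dict[str, Any]:
    """Run the configured stages; returns a results dict and writes the run dir.

    Inputs may be passed in memory (as the simulate stage produces them) or
    read from the configured paths.  A stage failure halts the run with the
    stage name while preserving completed outputs.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    t0 = time.time()
    p = config.params
    results: dict[str, Any] = {}
    manifest: dict[str, Any] = {"seed": config.seed, "stages": {}, "params": dict(p)}

    def stage_done(name: str, **info):
        manifest["stages"][name] = info
        log.info("stage %s done: %s", name, json.dumps(info, default=str))

    if occurrences is None and config.occurrences:
        occurrences = io.read_occurrences(config.occurrences, column_map=config.column_map)
    if stack is None and config.stack_dir:
        with open(os.path.join(config.stack_dir, "components.json")) as fh:
            comps = json.load(fh)
        stack = io.read_stack(config.stack_dir, comps)
    if evaluations is None and config.evaluations:
        evaluations = io.read_evaluations(config.evaluations, column_map=config.column_map)
    if occurrences is None or stack is None:
        raise ValueError("pipeline needs an occurrence table and an environmental stack")

    occ = occurrences
    variables = None
    try:
        if config.stages.get("selectvar", True):
            ranking = selectvar.rank_variables(occ, stack, seed=config.seed)
            ranking = selectvar.prune_correlated(
                ranking, occ, top_n=p["top_n_variables"],
                r_threshold=p["r_threshold"], alpha=p["alpha"],
            )
            ranking.table.to_csv(os.path.join(config.out_dir, "ranking.csv"), index=False)
            retained_layers = [v for v in ranking.retained() if v in stack.layers]
            variables = {
                c: [v for v in retained_layers if stack.component[v] == c] or stack.names(c)
                for c in COMPONENTS
            }
            results["ranking"] = ranking
            stage_done("selectvar", retained=ranking.retained())

        if config.stages.get("elcmap", True):
            elc_map = elc.build_elc_map(
                stack, variables=variables, max_k=p["max_k"], seed=config.seed
            )
            io.write_raster(
                elc_map.category_grid, stack.grid, os.path.join(config.out_dir, "elc.asc")
            )
            elc_map.legend_table().to_csv(os.path.join(config.out_dir, "legend.csv"), index=False)
            occ = elc.assign_category(elc_map, occ)
            results["elc_map"] = elc_map
            stage_done(
                "elcmap",
                k=elc_map.k,
                n_categories=elc_map.n_categories,
                n_assigned=int(occ["elc_category"].notna().sum()),
            )

        if config.stages.get("indices", True):
            occ = indices.annotate_indices(
                occ,
                monthly_precip_cols=config.monthly_precip_cols or _monthly_cols(occ, "precip"),
                monthly_temp_cols=config.monthly_temp_cols or _monthly_cols(occ, "temp"),
            )
            occ.to_csv(os.path.join(config.out_dir, "indexed.csv"), index=False)
            stage_done("indices", n_rows=len(occ))

        selections: list[filtering.SubsetSelection] = []
        if config.stages.get("filter", True):
            cap = p["subset_cap"]
            selections = [
                filtering.select_drought(occ, threshold=p["drought_aridity_cutoff"], cap=cap),
                filtering.select_salinity(
                    occ, primary_ec=p["salinity_primary_ec"],
                    fallback_low=p["salinity_fallback_low"], cap=cap,
                ),
                filtering.select_waterlogging(
                    occ, aridity_threshold=p["waterlogging_aridity_cutoff"], cap=cap
                ),
            ]
            for sel in selections:
                sel.members.to_csv(
                    os.path.join(config.out_dir, f"subset_{sel.trait}.csv"), index=False
                )
            results["selections"] = selections
            stage_done("filter", sizes={s.trait: len(s) for s in selections})

        calib_ids: list[str] | None = None
        if config.stages.get("calibrate", True) and evaluations is not None:
            labeled = calibration.binarize_dsr(evaluations, quantile=p["binarize_quantile"])
            predictors = [
                v for v in (variables and sum(variables.values(), []) or stack.names())
                if v in labeled.columns and v in occ.columns
            ]
            if len(predictors) < 2:
                # fall back to every shared environmental column
                predictors = [v for v in stack.names() if v in labeled.columns and v in occ.columns]
            runs, summaries = calibration.train_suite(
                labeled,
                predictors,
                n_runs=p["n_runs"],
                train_frac=p["train_frac"],
                seed=config.seed,
            )
            eval_X = labeled.dropna(subset=predictors)[predictors].to_numpy(dtype=float)
            result = calibration.select_and_project(
                summaries,
                occ[~occ.get("elc_excluded", pd.Series(False, index=occ.index)).astype(bool)],
                predictors,
                eval_X,
                trait=config.trait,
                top_n=p["top_n_projection"],
                n_perm=p["n_perm"],
                seed=config.seed,
            )
            result.summary_table().to_csv(os.path.join(config.out_dir, "summary.csv"), index=False)
            pd.DataFrame(
                [
                    {"algorithm": r.algorithm, "run": r.run, "tss": r.tss, "failed": r.failed}
                    for r in runs
                ]
            ).to_csv(os.path.join(config.out_dir, "runs.csv"), index=False)
            if not result.unmodelable:
                result.projections.to_csv(
                    os.path.join(config.out_dir, "projections.csv"), index=False
                )
                result.top_subset.to_csv(os.path.join(config.out_dir, "subset_calibration.csv"), index=False)
                calib_ids = result.top_subset["pop_id"].tolist()
            results["calibration"] = result
            stage_done(
                "calibrate",
                unmodelable=result.unmodelable,
                chosen=result.chosen_algorithm,
                mean_tss={a: s.mean_tss for a, s in summaries.items()},
            )

        if config.stages.get("overlaps", True) and selections:
            report = filtering.summarize_overlaps(selections, calib_ids, config.trait)
            report.to_csv(os.path.join(config.out_dir, "overlaps.csv"), index=False)
            results["overlaps"] = report
            stage_done("overlaps", pairwise={f"{a}&{b}": v for (a, b), v in report.attrs["pairwise"].items()})
    except Exception as exc:
        failed_stage = next(
            (s for s in config.stages if config.stages[s] and s not in manifest["stages"]), "?"
        )
        raise RuntimeError(f"pipeline halted in stage {failed_stage!r}: {exc}") from exc

    manifest["elapsed_s"] = round(time.time() - t0, 2)
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["params"], sort_keys=True).encode()
    ).hexdigest()[:16]
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    results["manifest"] = manifest
    results["occurrences"] = occ
    return results


def _monthly_cols(df: pd.DataFrame, kind: str) -> list[str]:
    cols = [f"{kind}_m{m:02d}" for m in range(1, 13)]
    return cols if all(c in df.columns for c in cols) else []
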