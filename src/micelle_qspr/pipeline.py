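"""End-to-end orchestration of the QSPR model-building workflow.

Stage order mirrors the study design: descriptor pre-reduction → ln
transform of LC → Mean/SD standardization → Duplex train/test split →
(optional) subset-size sweep → GFA model search → validation battery for the
top models → applicability domain of the best model → (optional) monomer
interpretation.  One seed drives every stochastic stage, and a manifest
records every parameter, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_io import (
    DescriptorTable,
    ln_transform_response,
    prereduce,
    read_descriptor_table,
    standardize,
)
from .domain import williams_report
from .duplex import duplex_split
from .gfa import GfaConfig, evolve, sweep_subset_size
from .mlr import coefficient_stats, fit_mlr
from .synthetic import SyntheticSpec, generate
from .validation import validate_model

__all__ = ["PipelineConfig", "run_all"]

log = logging.getLogger("micelle_qspr")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one full run needs; seed propagates to every stage."""

    input_csv: str | None = None          # CSV with descriptors + LC column
    synthetic: SyntheticSpec | None = None  # used when input_csv is None
    response_column: str = "LC"
    corr_threshold: float = 0.99
    n_test: int = 8
    gfa: GfaConfig = field(default_factory=GfaConfig)
    sweep_sizes: tuple | None = None      # e.g. (1, 2, 3, 4, 5, 6)
    n_validate: int = 10
    y_rand_iterations: int = 500
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, obj: dict) -> "PipelineConfig":
        obj = dict(obj)
        if "gfa" in obj and isinstance(obj["gfa"], dict):
            obj["gfa"] = GfaConfig(**obj["gfa"])
        if "synthetic" in obj and isinstance(obj["synthetic"], dict):
            obj["synthetic"] = SyntheticSpec(**obj["synthetic"])
        if "sweep_sizes" in obj and obj["sweep_sizes"] is not None:
            obj["sweep_sizes"] = tuple(obj["sweep_sizes"])
        return cls(**obj)


def _load_input(config: PipelineConfig) -> DescriptorTable:
    if config.input_csv is not None:
        path = Path(config.input_csv)
        if not path.exists():
            raise FileNotFoundError(f"input file not found: {path}")
        return read_descriptor_table(path, config.response_column)
    spec = config.synthetic or SyntheticSpec(seed=config.seed)
    return generate(spec)


def run_all(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns (and optionally writes) the bundle."""
    stage = "load"
    try:
        table = _load_input(config)
        log.info("loaded %d samples x %d descriptors", table.n_samples,
                 table.n_descriptors)

        stage = "prereduce"
        reduced, prelog = prereduce(table, corr_threshold=config.corr_threshold)

        stage = "ln_transform"
        reduced = ln_transform_response(reduced)

        stage = "standardize"
        reduced, std_params = standardize(reduced)

        stage = "duplex_split"
        split = duplex_split(reduced, n_test=config.n_test,
                             standardize_first=False)  # already standardized
        train = reduced.select_samples(split.training_ids)
        test = reduced.select_samples(split.test_ids)

        gfa_cfg = dataclasses.replace(config.gfa, seed=config.seed)
        sweep_df = recommended = None
        if config.sweep_sizes:
            stage = "sweep_subset_size"
            sweep_df, recommended = sweep_subset_size(train, config.sweep_sizes,
                                                      gfa_cfg)
            gfa_cfg = dataclasses.replace(gfa_cfg, subset_size=recommended)
            log.info("recommended subset size: %d", recommended)

        stage = "gfa"
        result = evolve(train, gfa_cfg)
        log.info("GFA evaluated %d distinct subsets; best LOF %.6f",
                 result.evaluation_count, result.lof_values[0])

        stage = "validate"
        reports = []
        for model in result.models[: config.n_validate]:
            reports.append(
                validate_model(train, test, model.descriptor_subset,
                               y_rand_iterations=config.y_rand_iterations,
                               seed=config.seed)
            )
        ranking = pd.DataFrame([r.to_row() for r in reports],
                               index=range(1, len(reports) + 1))
        # flag the model that is best on each criterion instead of
        # hard-coding a single winner
        best_on = {
            "R2": int(ranking["R2"].idxmax()),
            "R2cv": int(ranking["R2cv"].idxmax()),
            "F": int(ranking["F"].idxmax()),
            "RMSE(a)": int(ranking["RMSE(a)"].idxmin()),
            "R2pred": int(ranking["R2pred"].idxmax()),
            "RMSE(b)": int(ranking["RMSE(b)"].idxmin()),
        }

        stage = "coefficients"
        best_model = result.models[0]
        coef = coefficient_stats(best_model, train)

        stage = "applicability_domain"
        ad = williams_report(train, test, best_model.descriptor_subset, best_model)

        bundle = {
            "manifest": {
                "version": __version__,
                "seed": config.seed,
                "config": _config_dict(config),
                "n_samples": table.n_samples,
                "n_descriptors_input": table.n_descriptors,
                "n_descriptors_after_prereduction": reduced.n_descriptors,
            },
            "prereduction": json.loads(prelog.to_json()),
            "split": json.loads(split.to_json()),
            "sweep": None if sweep_df is None else {
                "table": sweep_df.to_dict(orient="records"),
                "recommended_size": recommended,
            },
            "models": [
                {
                    "rank": i + 1,
                    "descriptors": list(m.descriptor_subset),
                    "coefficients": m.coefficients.tolist(),
                    "intercept": m.intercept,
                    "lof": result.lof_values[i],
                }
                for i, m in enumerate(result.models)
            ],
            "ranking": ranking.reset_index(names="model").to_dict(orient="records"),
            "best_on_each_criterion": best_on,
            "best_model_coefficients": coef.to_dataframe().reset_index()
            .to_dict(orient="records"),
            "applicability_domain": json.loads(ad.to_json()),
        }
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "bundle.json").write_text(json.dumps(bundle, indent=2, default=float))
        ranking.to_csv(out / "model_ranking.csv", index_label="model")
        ad.to_dataframe().to_csv(out / "williams.csv", index=False)
    return bundle


def _config_dict(config: PipelineConfig) -> dict:
    obj = dataclasses.asdict(config)
    return obj
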