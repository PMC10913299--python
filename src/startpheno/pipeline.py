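"""Stage-chaining pipeline: simulate -> extract -> stats -> classify.

A pipeline config is a plain dict (typically loaded from a JSON file):

    {
      "stages": ["simulate", "extract", "stats", "classify"],
      "seed": 7,
      "out_dir": "results",
      "n_per_group": [40, 48, 43],
      "cv": {"folds": 5, "repeats": 20, "classifier": "gradient_boosting"}
    }

Identical config + seed gives identical output files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import classify as _classify
from .features import ExtractionConfig, extract_cohort
from .io import feature_frame, read_cohort, write_cohort, write_feature_table
from .simulate import SimulationConfig, default_profiles, simulate_cohort
from .stats import group_table

logger = logging.getLogger("startpheno")

STAGES = ("simulate", "extract", "stats", "classify")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _load_config(config: Union[dict, str, Path, None]) -> dict:
    if config is None:
        return {}
    if isinstance(config, (str, Path)):
        return json.loads(Path(config).read_text())
    return dict(config)


def run_pipeline(config: Union[dict, str, Path, None] = None) -> dict:
    """Execute the configured stages in order; returns a report bundle.

    Artifacts written under ``out_dir``: cohort.jsonl, features.csv,
    filters.csv, group_table.csv, classification.csv.
    """
    cfg = _load_config(config)
    stages = cfg.get("stages", list(STAGES))
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stage {unknown[0]!r}")
    seed = int(cfg.get("seed", 0))
    out_dir = Path(cfg.get("out_dir", "startpheno_out"))
    out_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out_dir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("pipeline start: stages=%s seed=%d", stages, seed)

    bundle: dict = {"out_dir": str(out_dir), "seed": seed}
    try:
        _run_stages(stages, cfg, seed, out_dir, bundle)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return bundle


def _run_stages(stages, cfg, seed, out_dir, bundle) -> None:
    cohort = None
    features_df: Optional[pd.DataFrame] = None
    for stage in stages:
        logger.info("stage %s", stage)
        try:
            if stage == "simulate":
                sim = SimulationConfig(
                    seed=seed,
                    n_per_group=tuple(cfg.get("n_per_group", (40, 48, 43))),
                )
                cohort = simulate_cohort(sim, default_profiles())
                write_cohort(cohort, out_dir / "cohort.jsonl")
                bundle["cohort_file"] = str(out_dir / "cohort.jsonl")
            elif stage == "extract":
                if cohort is None:
                    src = cfg.get("cohort_file", out_dir / "cohort.jsonl")
                    cohort = read_cohort(src)
                ex = ExtractionConfig(pci_seed=seed)
                vectors, outcomes = extract_cohort(cohort, ex)
                write_feature_table(vectors, out_dir / "features.csv")
                pd.DataFrame(
                    [
                        {
                            "child_id": cid,
                            "task": o.task_name,
                            "included": o.included,
                            "reason": o.reason.value,
                        }
                        for cid, o in outcomes
                    ]
                ).to_csv(out_dir / "filters.csv", index=False)
                features_df = feature_frame(vectors)
                bundle["features_file"] = str(out_dir / "features.csv")
            elif stage == "stats":
                if features_df is None:
                    features_df = pd.read_csv(cfg.get("features_file", out_dir / "features.csv"))
                table = group_table(features_df)
                table.to_csv(out_dir / "group_table.csv", index=False)
                bundle["group_table"] = table
            elif stage == "classify":
                if features_df is None:
                    features_df = pd.read_csv(cfg.get("features_file", out_dir / "features.csv"))
                cv_kwargs = dict(cfg.get("cv", {}))
                cv = _classify.CVConfig(seed=seed, **cv_kwargs)
                rows = []
                reports = []
                for block in _classify.FEATURE_BLOCKS:
                    X, y, _, _cols = _classify.assemble_matrix(features_df, [block])
                    reports.append(_classify.evaluate_blocks(X, y, [block], cv))
                X, y, _, _cols = _classify.assemble_matrix(
                    features_df, _classify.BEST_COMBINATION
                )
                reports.append(
                    _classify.evaluate_blocks(X, y, _classify.BEST_COMBINATION, cv)
                )
                for rep in reports:
                    rows.append(
                        {
                            "blocks": "+".join(rep.blocks),
                            "overall_accuracy": rep.overall_accuracy,
                            "binary_td_vs_ndd": _classify.collapse_binary(rep),
                            **{
                                f"recall_{k}": v
                                for k, v in rep.per_class_accuracy.items()
                            },
                        }
                    )
                pd.DataFrame(rows).to_csv(out_dir / "classification.csv", index=False)
                bundle["classification"] = pd.DataFrame(rows)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
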