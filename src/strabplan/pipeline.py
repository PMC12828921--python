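"""Reproducible end-to-end runs.

simulate -> (optional tune) -> multilabel-stratified CV -> calibrate ->
threshold -> evaluate -> report.  Every artefact in the run directory names
the seed and config hash that produced it; the emitted fold indices are
sufficient to replay the run.
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

from .crossval import run_cv
from .evaluation import (
    full_report,
    report_to_json,
    report_to_markdown,
)
from .model import config_to_yaml
from .nn import ModelConfig
from .simulate import (
    GeneratorConfig,
    LABEL_COLUMNS,
    read_cohort_csv,
    simulate_cohort,
    write_cohort_csv,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """End-to-end run settings."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    cohort_csv: str | None = None  # use an existing cohort instead of simulating
    k_folds: int = 10
    bootstrap_b: int = 1000
    seed: int = 0
    tolerance_pp: float = 2.0
    output_dir: str = "run"
    overwrite: bool = False
    make_plots: bool = False

    @classmethod
    def demo(cls, output_dir: str = "demo_run", seed: int = 0) -> "RunConfig":
        """Small profile sized to finish in a couple of minutes on one CPU."""
        gen = GeneratorConfig(n_patients=200, seed=seed)
        model = ModelConfig(seed=seed)
        return cls(
            generator=gen,
            model=model,
            k_folds=5,
            bootstrap_b=200,
            seed=seed,
            output_dir=output_dir,
        )


def _config_hash(run_config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(run_config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(run_config: RunConfig) -> dict:
    """Execute the full pipeline and write all artefacts.

    Returns the MetricsReport dict.  Refuses to touch an output directory
    containing a previous run unless ``overwrite`` is set.
    """
    out = Path(run_config.output_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not run_config.overwrite:
        raise FileExistsError(
            f"{out} already holds a run (manifest.json present); "
            "pass overwrite to replace it"
        )
    out.mkdir(parents=True, exist_ok=True)

    if run_config.cohort_csv:
        cohort = read_cohort_csv(run_config.cohort_csv)
        log.info("loaded cohort of %d patients from %s", len(cohort), run_config.cohort_csv)
    else:
        gen = dataclasses.replace(run_config.generator, seed=run_config.seed)
        cohort = simulate_cohort(gen)
        gen.to_yaml(out / "generator_config.yaml")
    write_cohort_csv(cohort, out / "cohort.csv")

    prevalences = cohort[LABEL_COLUMNS].mean()
    log.info("label prevalences:\n%s", prevalences.round(3).to_string())

    config_to_yaml(run_config.model, out / "model_config.yaml")

    cv = run_cv(
        cohort,
        model_config=run_config.model,
        k=run_config.k_folds,
        seed=run_config.seed,
        tolerance=run_config.tolerance_pp,
    )
    cv.foldspec.to_frame().to_csv(out / "folds.csv", index=False)
    cv.oof.to_csv(out / "oof_predictions.csv", index=False)
    for f, res in enumerate(cv.fold_results):
        res.save(out / f"checkpoint_fold{f}.json")

    report = full_report(
        cv.oof, cohort, bootstrap_b=run_config.bootstrap_b, seed=run_config.seed
    )
    report["fold_certificate_max_pp"] = cv.foldspec.max_deviation
    report["fold_certificate_within_tolerance"] = cv.foldspec.within_tolerance
    report_to_json(report, out / "metrics.json")
    (out / "report.md").write_text(report_to_markdown(report))
    pd.DataFrame(report["decision_curve"]).to_csv(out / "decision_curve.csv", index=False)
    pd.DataFrame(report["reliability"]).to_csv(out / "reliability.csv", index=False)

    if run_config.make_plots:
        from . import plots

        plots.save_standard_plots(cv.oof, report, out)

    manifest = {
        "seed": run_config.seed,
        "config_hash": _config_hash(run_config),
        "n_patients": int(len(cohort)),
        "k_folds": run_config.k_folds,
        "bootstrap_b": run_config.bootstrap_b,
        "fold_certificate_max_pp": cv.foldspec.max_deviation,
        "n_model_params": cv.fold_results[0].n_params,
        "artefacts": sorted(p.name for p in out.iterdir()),
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)

    log.info("run complete: %s", out)
    return report
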