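"""End-to-end orchestration: simulate/load -> %FCR -> normalize -> classify
-> significance, as one reproducible run.

All randomness flows through named seeds in :class:`RunConfig`; re-running
an identical config yields byte-identical outputs.  Every comparison
produces a report table with one row per repeat (selected features,
accuracy, sensitivity, specificity, MCC and the confusion counts), a
consensus-feature set, per-repeat binomial p-values and a shuffle-null
summary, written as CSV plus a JSON summary document.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .chromatic import (
    FeatureMatrix,
    aggregate_plate,
    normalize_to_controls,
    standardize_across_plates,
)
from .classify import run_repeated_experiment
from .plate_model import Plate, ReactomicsError, read_plates
from .significance import accuracy_significance, run_shuffle_null
from .synthetic import ConfigError, SyntheticConfig, generate_cohort

logger = logging.getLogger("reactomics")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``synthetic`` (a generator configuration) or
    ``plates_path`` (an existing plate CSV) supplies the input cohort.
    ``comparisons`` lists (positive_group, negative_group) pairs; the
    positive class is conventionally the cancer group in cancer-vs-control
    comparisons.  Seeds are explicit — no wall-clock entropy.
    """

    comparisons: list[tuple[str, str]]
    synthetic: SyntheticConfig | None = None
    plates_path: str | None = None
    partition_seeds: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5])
    shuffle_seeds: list[int] = field(default_factory=list)
    shuffle_comparison: tuple[str, str] | None = None
    sizing: str = "balanced-25"
    c_param: float = 1.0
    control_group: str = "control"

    def validate(self) -> None:
        if (self.synthetic is None) == (self.plates_path is None):
            raise ConfigError("provide exactly one of synthetic config or plates_path")
        if not self.comparisons:
            raise ConfigError("no comparisons configured")
        if self.synthetic is not None:
            known = set(self.synthetic.groups)
            for pos, neg in self.comparisons:
                for g in (pos, neg):
                    if g not in known:
                        raise ConfigError(
                            f"comparison group {g!r} not among cohort groups {sorted(known)}"
                        )
            if self.control_group not in known:
                raise ConfigError(f"control group {self.control_group!r} unknown")


def build_features(
    plates: list[Plate], control_group: str = "control"
) -> FeatureMatrix:
    """Aggregate, standardize and normalize a plate cohort into features."""
    tables = [aggregate_plate(p) for p in plates]
    tables = standardize_across_plates(tables)
    return normalize_to_controls(tables, control_group=control_group)


def run_all(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute the staged pipeline for every configured comparison.

    Returns the run report as a dict; when ``outdir`` is given, also writes
    one ``<pos>_vs_<neg>.csv`` report per comparison plus ``summary.json``.
    """
    config.validate()
    if config.synthetic is not None:
        logger.info("generating synthetic cohort (seed=%d)", config.synthetic.seed)
        plates = generate_cohort(config.synthetic)
    else:
        plates = read_plates(config.plates_path)
    matrix = build_features(plates, control_group=config.control_group)
    known = set(matrix.groups.unique())
    for pos, neg in config.comparisons:
        if pos not in known or neg not in known:
            raise ConfigError(f"comparison ({pos}, {neg}) not in cohort groups {known}")

    summary: dict = {"comparisons": {}}
    frames: dict[str, pd.DataFrame] = {}
    for pos, neg in config.comparisons:
        name = f"{pos}_vs_{neg}"
        logger.info("comparison %s: %d repeats", name, len(config.partition_seeds))
        report = run_repeated_experiment(
            matrix, pos, neg,
            seeds=config.partition_seeds,
            sizing=config.sizing,
            c_param=config.c_param,
        )
        frame = report.to_frame()
        frame["p_binomial"] = [
            accuracy_significance(r.test_cm).p_value for r in report.results
        ]
        frames[name] = frame
        summary["comparisons"][name] = {
            "positive_group": pos,
            "negative_group": neg,
            "mean_test_accuracy": float(frame["accuracy"].mean()),
            "mean_test_mcc": float(frame["mcc"].mean()),
            "consensus_features": list(report.consensus_features),
            "repeats": frame.drop(columns=["tp", "fp", "tn", "fn"]).to_dict("records"),
        }

    if config.shuffle_seeds:
        pos, neg = config.shuffle_comparison or config.comparisons[0]
        logger.info("shuffle null: %d shuffles on %s vs %s",
                    len(config.shuffle_seeds), pos, neg)
        shuffle = run_shuffle_null(
            matrix, pos, neg,
            seeds=config.shuffle_seeds,
            sizing=config.sizing,
            c_param=config.c_param,
        )
        summary["shuffle_null"] = {
            "comparison": [pos, neg],
            "n_shuffles": shuffle.n_shuffles,
            "mean_mcc": shuffle.mean_mcc,
            "sd_mcc": shuffle.sd_mcc,
        }

    summary["n_samples"] = int(len(matrix))
    summary["features"] = matrix.feature_names
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, frame in frames.items():
            frame.to_csv(outdir / f"{name}.csv", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
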