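"""End-to-end analysis orchestration behind a config file.

A run configuration names the input (a rating CSV or a synthetic-generator
config), the analysis stages to execute, and the decoding settings (folds,
hyperparameter grid, permutation count, seeds). ``run`` executes the stages
in dependency order, writes a JSON report plus CSV side-products to the
output directory, and returns the report. Everything is deterministically
seeded: the same (config, seed) yields byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .vocab import Vocabulary, DEFAULT_VOCABULARY
from .data import (
    RatingDataset, load_dataset, write_dataset,
    colour_feature_table, country_feature_table,
)
from .synthetic import GeneratorConfig, generate
from .decoder import HyperParams, DEFAULT_GRID, cross_validate
from .metrics import chance_level, permutation_test
from .transfer import transfer_matrix, advantage_matrix
from .similarity import estimate_similarity, similarity_report

__all__ = ["RunConfig", "ConfigError", "validate_config", "run"]

logger = logging.getLogger(__name__)

VALID_TASKS = ("colour", "country", "permtest", "transfer", "similarity")


class ConfigError(ValueError):
    """A run configuration violated the schema."""


@dataclass
class RunConfig:
    """Validated analysis configuration."""

    seed: int
    input_path: str | None = None
    simulate: GeneratorConfig | None = None
    tasks: tuple[str, ...] = ("colour", "country", "permtest", "transfer", "similarity")
    k: int = 10
    inner_k: int = 5
    grid: tuple[HyperParams, ...] = DEFAULT_GRID
    n_perm: int = 10
    output_dir: str = "results"
    smoothing: float = 0.5
    vocabulary: Vocabulary = field(default_factory=lambda: DEFAULT_VOCABULARY)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed: required (no wall-clock seeding)")
        if self.k < 2:
            raise ConfigError("k: must be >= 2")
        if self.inner_k < 2:
            raise ConfigError("inner_k: must be >= 2")
        if self.n_perm < 1:
            raise ConfigError("n_perm: must be >= 1")
        if (self.input_path is None) == (self.simulate is None):
            raise ConfigError("exactly one of input_path / simulate is required")
        unknown = set(self.tasks) - set(VALID_TASKS)
        if unknown:
            raise ConfigError(f"tasks: unknown {sorted(unknown)}")
        if not self.grid:
            raise ConfigError("grid: must not be empty")

    def config_hash(self) -> str:
        payload = {
            "seed": self.seed,
            "input_path": self.input_path,
            "simulate": self.simulate.to_dict() if self.simulate else None,
            "tasks": list(self.tasks),
            "k": self.k,
            "inner_k": self.inner_k,
            "grid": [[p.C, p.kernel_width] for p in self.grid],
            "n_perm": self.n_perm,
            "smoothing": self.smoothing,
            "vocabulary": self.vocabulary.to_dict(),
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def validate_config(path: str | Path) -> RunConfig:
    """Parse, default and schema-validate a YAML/JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    if "seed" not in raw:
        raise ConfigError("seed: required")

    vocab = DEFAULT_VOCABULARY
    if "vocabulary" in raw:
        v = raw["vocabulary"]
        vocab = Vocabulary.from_file(v) if isinstance(v, str) else Vocabulary.from_dict(v)

    sim = None
    if "simulate" in raw and raw["simulate"] is not None:
        sim_raw = dict(raw["simulate"])
        sim_raw.setdefault("seed", raw["seed"])
        sim_raw["vocabulary"] = vocab
        try:
            sim = GeneratorConfig.from_dict(sim_raw)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"simulate: {exc}") from exc

    grid = DEFAULT_GRID
    if "grid" in raw and raw["grid"] is not None:
        try:
            grid = tuple(
                HyperParams(C=float(g["C"]), kernel_width=float(g["kernel_width"]))
                for g in raw["grid"]
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"grid: {exc}") from exc

    try:
        return RunConfig(
            seed=int(raw["seed"]),
            input_path=raw.get("input"),
            simulate=sim,
            tasks=tuple(raw.get("tasks", VALID_TASKS)),
            k=int(raw.get("k", 10)),
            inner_k=int(raw.get("inner_k", 5)),
            grid=grid,
            n_perm=int(raw.get("n_perm", 10)),
            output_dir=str(raw.get("output_dir", "results")),
            smoothing=float(raw.get("smoothing", 0.5)),
            vocabulary=vocab,
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc


def _cv_block(result, n_classes: int) -> dict:
    return {
        "accuracy": result.accuracy,
        "chance_level": chance_level(n_classes),
        "auc_weighted": result.auc_weighted,
        "auc_macro": result.auc_macro,
        "per_fold_accuracy": list(result.per_fold_accuracy),
        "confusion_counts": result.confusion.counts.tolist(),
        "confusion_classes": list(result.classes),
    }


def run(config: RunConfig) -> dict:
    """Execute the configured stages and write the analysis report.

    Stage order is fixed (simulate/load, colour, permtest, country, transfer,
    similarity); a stage failure aborts with a stage-labelled error.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "package_version": __version__,
        }
    }
    grid = list(config.grid)

    def _stage(name, fn):
        t0 = time.perf_counter()
        logger.info("stage %s: start (seed=%d)", name, config.seed)
        try:
            value = fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        logger.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
        return value

    if config.simulate is not None:
        dataset = _stage("simulate", lambda: generate(config.simulate))
        write_dataset(dataset, out_dir / "simulated_ratings.csv")
        report["dataset"] = {"source": "simulated", "n_participants": dataset.n_participants}
    else:
        dataset = _stage(
            "load", lambda: load_dataset(config.input_path, config.vocabulary)
        )
        report["dataset"] = {
            "source": str(config.input_path),
            "n_participants": dataset.n_participants,
        }

    colour_cv = None
    if {"colour", "permtest", "similarity"} & set(config.tasks):
        table = colour_feature_table(dataset)
        colour_cv = _stage(
            "colour",
            lambda: cross_validate(
                table, k=config.k, grid=grid, seed=config.seed,
                inner_k=config.inner_k,
            ),
        )
        if "colour" in config.tasks:
            report["colour"] = _cv_block(colour_cv, len(table.classes))
            colour_cv.confusion.to_frame().to_csv(out_dir / "colour_confusion.csv")

    if "permtest" in config.tasks:
        table = colour_feature_table(dataset)
        perm = _stage(
            "permtest",
            lambda: permutation_test(
                table, k=config.k, grid=grid, n_perm=config.n_perm,
                seed=config.seed, observed=colour_cv,
            ),
        )
        report["permtest"] = {
            "observed_auc": perm.observed_auc,
            "observed_accuracy": perm.observed_accuracy,
            "null_auc": list(perm.null_auc),
            "null_accuracy": list(perm.null_accuracy),
            "n_perm": perm.n_perm,
            "p_value_auc": perm.p_value_auc,
            "p_value_accuracy": perm.p_value_accuracy,
            "p_value_auc_ttest": perm.p_value_auc_ttest,
        }

    if "country" in config.tasks:
        table = country_feature_table(dataset)
        present = dataset.countries_present()
        res = _stage(
            "country",
            lambda: cross_validate(
                table, k=config.k, grid=grid, seed=config.seed,
                inner_k=config.inner_k,
            ),
        )
        report["country"] = _cv_block(res, len(present))
        res.confusion.to_frame().to_csv(out_dir / "country_confusion.csv")

    if "transfer" in config.tasks:
        tm = _stage(
            "transfer",
            lambda: transfer_matrix(
                dataset, k=config.k, grid=grid, seed=config.seed,
                inner_k=config.inner_k,
            ),
        )
        adv = advantage_matrix(tm)
        report["transfer"] = {
            "countries": list(tm.countries),
            "accuracy_matrix": tm.accuracies.tolist(),
            "advantage_matrix": [
                [None if np.isnan(v) else v for v in row] for row in adv.advantage
            ],
            "advantage_mean": adv.mean,
            "advantage_sd": adv.sd,
            "advantage_min": adv.min,
            "advantage_max": adv.max,
        }
        tm.to_frame().to_csv(out_dir / "transfer_accuracy.csv")
        adv.to_frame().to_csv(out_dir / "transfer_advantage.csv")

    if "similarity" in config.tasks:
        sm = _stage(
            "similarity",
            lambda: estimate_similarity(colour_cv.confusion, config.smoothing),
        )
        report["similarity"] = {
            "classes": list(sm.classes),
            "eta": sm.eta.tolist(),
            "bias": sm.bias.tolist(),
            "n_clipped": sm.n_clipped,
            "top_pairs": [
                {"pair": [a, b], "similarity": v}
                for a, b, v in similarity_report(sm, top_n=10)
            ],
        }
        sm.to_frame(upper_only=True).to_csv(out_dir / "colour_similarity.csv")

    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
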