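"""Experiment orchestration: replicated runs, sweeps and aggregate tables.

One *experiment* trains ``n_replicates`` networks of a single architecture
on one space-coding task, reads each one out linearly, and runs the
sparseness and gain-field analyses on every replicate that passes the 3-deg
read-out criterion.  Replicates that fail the criterion are kept in the
read-out table but excluded from the gain-field aggregates.

Datasets are generated once per (task, dataset seed, sizes) and cached in
memory, mirroring the study design of reusing one dataset per task across
architectures.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import analyze_gain_fields, sparseness_report
from .autoencoder import SparseAutoencoder
from .ffnet import FeedForwardNetwork
from .rbm import RBM
from .readout import LinearReadout, evaluate_readout
from .stimuli import Dataset, SpaceConfig, generate_dataset

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment",
           "run_sweep", "combined_table", "TASK_ALIASES"]

logger = logging.getLogger(__name__)

#: Short task labels used throughout the study's figures.
TASK_ALIASES = {"A": "no_transformation", "B": "with_transformation",
                "C": "supervised"}

ARCHITECTURES = ("rbm", "autoencoder", "ffnet")


@dataclass(frozen=True)
class ExperimentConfig:
    """One cell of the study design.

    ``task`` accepts the study's letter labels (A: unsupervised without the
    motor program, B: unsupervised with it, C: supervised mapping) or the
    long names.  ``extra`` carries architecture hyperparameter overrides
    (e.g. scaled-down epoch counts); dataset sizes default to the full
    20,000 / 8,861 split.
    """

    architecture: str
    task: str = "A"
    hidden_size: int = 400
    sparsity_target: float | None = 0.05
    n_replicates: int = 10
    base_seed: int = 0
    train_size: int = 20000
    test_size: int | None = None
    patterns_per_target: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.task_name not in TASK_ALIASES.values():
            raise ValueError(f"unknown task {self.task!r}")
        if self.architecture == "ffnet" and self.task_name != "supervised":
            raise ValueError("the feed-forward baseline is defined only for "
                             "the supervised task (C)")
        if self.architecture != "ffnet" and self.task_name == "supervised":
            raise ValueError("unsupervised encoders train on task A or B")
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be positive")

    @property
    def task_name(self) -> str:
        return TASK_ALIASES.get(self.task, self.task)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class ExperimentReport:
    """Per-replicate rows plus aggregate mean/sd for one experiment."""

    config: ExperimentConfig
    replicates: pd.DataFrame

    @property
    def aggregate(self) -> pd.Series:
        rows = self.replicates
        numeric = rows.select_dtypes("number")
        out = {}
        for col in numeric.columns:
            vals = numeric[col]
            if col.startswith("frac_") or col in ("n_visual",):
                vals = vals[rows["success"]]  # gain-field stats: passers only
            out[f"{col}_mean"] = float(vals.mean())
            out[f"{col}_sd"] = float(vals.std(ddof=0))
        out["n_success"] = int(rows["success"].sum())
        out["n_replicates"] = len(rows)
        return pd.Series(out)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stem = self.config.digest()
        rows = self.replicates.copy()
        rows.insert(0, "config_hash", stem)
        rows.insert(1, "package_version", __version__)
        rows.to_csv(outdir / f"replicates_{stem}.csv", index=False)
        manifest = {"config": asdict(self.config),
                    "config_hash": stem,
                    "package_version": __version__,
                    "aggregate": self.aggregate.to_dict()}
        (outdir / f"experiment_{stem}.json").write_text(
            json.dumps(manifest, indent=2, default=str))


_DATASET_CACHE: dict[tuple, Dataset] = {}


def get_dataset(task_name: str, seed: int, train_size: int,
                test_size: int | None, patterns_per_target: int | None,
                cfg: SpaceConfig | None = None) -> Dataset:
    """Cached balanced dataset for one task and seed."""
    cfg = cfg or SpaceConfig()
    key = (cfg.digest(), task_name, seed, train_size, test_size,
           patterns_per_target)
    if key not in _DATASET_CACHE:
        logger.info("generating %s dataset (seed %d)", task_name, seed)
        _DATASET_CACHE[key] = generate_dataset(
            cfg, task=task_name, seed=seed, train_size=train_size,
            test_size=test_size, patterns_per_target=patterns_per_target)
    return _DATASET_CACHE[key]


def build_estimator(config: ExperimentConfig, seed: int):
    """Instantiate the configured architecture with its default hypers."""
    extra = dict(config.extra)
    if config.architecture == "rbm":
        return RBM(n_hidden=config.hidden_size,
                   sparsity_target=config.sparsity_target,
                   random_state=seed, **extra)
    if config.architecture == "autoencoder":
        if config.sparsity_target is None:
            extra.setdefault("sparsity_weight", 0.0)
            return SparseAutoencoder(n_hidden=config.hidden_size,
                                     random_state=seed, **extra)
        return SparseAutoencoder(n_hidden=config.hidden_size,
                                 sparsity_target=config.sparsity_target,
                                 random_state=seed, **extra)
    return FeedForwardNetwork(n_hidden=config.hidden_size,
                              random_state=seed, **extra)


def run_replicate(config: ExperimentConfig, dataset: Dataset, seed: int,
                  readout_epochs: int = 250, analyze: bool = True) -> dict:
    """Train one network end-to-end and return its metrics row."""
    est = build_estimator(config, seed)
    if config.architecture == "ffnet":
        est.fit(dataset.sensory("train"), dataset.motor("train"))
    else:
        est.fit(dataset.inputs("train"))
    hidden_train = est.transform(dataset.probe_inputs("train"))
    hidden_test = est.transform(dataset.probe_inputs("test"))
    ro = LinearReadout(n_epochs=readout_epochs, random_state=seed).fit(
        hidden_train, dataset.motor("train"))
    report = evaluate_readout(ro, hidden_test, dataset.motor("test"),
                              dataset.target_positions("test"),
                              dataset.config)
    row = {"seed": seed, **report.as_dict()}
    sp = sparseness_report(hidden_test)
    row["single_neuron_sparseness"] = sp.single_neuron
    row["population_sparseness"] = sp.population
    row["n_silent_neurons"] = sp.n_silent_neurons
    row["mean_hidden_activation"] = float(hidden_test.mean())
    if config.sparsity_target is not None and config.architecture != "ffnet":
        row["sparsity_satisfied"] = bool(
            row["mean_hidden_activation"] <= config.sparsity_target + 0.01)
    if analyze and report.success:
        ga = analyze_gain_fields(est, dataset.config, task=dataset.task)
        row.update(ga.distribution.as_dict())
    return row


def run_experiment(config: ExperimentConfig,
                   dataset: Dataset | None = None,
                   cfg: SpaceConfig | None = None,
                   outdir=None, analyze: bool = True) -> ExperimentReport:
    """Run all replicates of one experiment cell.

    A failing stage in one replicate is recorded (``error`` column) and
    the experiment continues with the remaining replicates.
    """
    if dataset is None:
        dataset = get_dataset(config.task_name, config.base_seed,
                              config.train_size, config.test_size,
                              config.patterns_per_target, cfg)
    rows = []
    for rep in range(config.n_replicates):
        seed = (config.base_seed + 1000 * (rep + 1)) % (2 ** 31)
        try:
            rows.append(run_replicate(config, dataset, seed,
                                      analyze=analyze))
        except Exception as exc:  # keep going; record the failure
            logger.exception("replicate %d failed", rep)
            rows.append({"seed": seed, "success": False, "error": str(exc)})
    report = ExperimentReport(config=config,
                              replicates=pd.DataFrame(rows))
    if outdir is not None:
        report.save(outdir)
    return report


def run_sweep(configs, outdir=None, cfg: SpaceConfig | None = None,
              analyze: bool = True) -> list[ExperimentReport]:
    """Run a list of experiment cells, skipping already-completed ones.

    When ``outdir`` is given, a cell whose manifest already exists on disk
    is reloaded instead of re-run, so an interrupted sweep resumes where it
    stopped.
    """
    reports = []
    for config in configs:
        if outdir is not None:
            stem = Path(outdir) / f"replicates_{config.digest()}.csv"
            if stem.exists():
                logger.info("skipping completed cell %s", config.digest())
                rows = pd.read_csv(stem).drop(
                    columns=["config_hash", "package_version"])
                reports.append(ExperimentReport(config=config,
                                                replicates=rows))
                continue
        reports.append(run_experiment(config, cfg=cfg, outdir=outdir,
                                      analyze=analyze))
    if outdir is not None and reports:
        combined_table(reports).to_csv(
            Path(outdir) / "readout_table.csv", index=False)
    return reports


def combined_table(reports) -> pd.DataFrame:
    """Read-out error table (task x size x architecture), mean (sd)."""
    rows = []
    for rep in reports:
        agg = rep.aggregate
        rows.append({
            "task": rep.config.task,
            "architecture": rep.config.architecture,
            "hidden_size": rep.config.hidden_size,
            "sparsity_target": rep.config.sparsity_target,
            "com_error_mean": agg["com_error_mean_mean"],
            "com_error_sd": agg["com_error_mean_sd"],
            "n_success": agg["n_success"],
            "n_replicates": agg["n_replicates"],
        })
    return pd.DataFrame(rows).sort_values(
        ["task", "hidden_size", "architecture"]).reset_index(drop=True)
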