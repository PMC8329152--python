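"""End-to-end experiment runner: config, logging, persistence, plots.

`run_all` executes a requested subset of the five-experiment grid on a
synthetic or loaded cohort, writes a tidy summary CSV (experiment × model ×
supervision -> mean AUC), per-repeat AUC samples, mean-ROC and AUC-violin
plots, and a machine-readable manifest (config + seed + versions) from
which the identical summary can be replayed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import platform
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .cnn import ArchitectureSpec, TrainConfig
from .data import NoduleRecord, load_cohort
from .evaluate import ExperimentResult, results_table, run_experiment
from .exceptions import ConfigurationError
from .pseudolabel import DEFAULT_K
from .synthetic import GeneratorConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce one full run."""

    experiments: tuple[int, ...] = (1,)
    modes: tuple[str, ...] = ("full", "semi")
    n_repeats: dict[int, int] = field(default_factory=dict)  # per-experiment override
    best_k: int = DEFAULT_K
    ratio: float = 0.8
    rf_trees: int = 100
    seed: int = 0
    cohort_dir: str | None = None  # load instead of generating
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    arch_divisor: int = 1  # >1 selects a narrow CNN for smoke runs
    cnn_mode: str = "shared"
    out_dir: str = "nodulefuse_out"
    log_level: str = "INFO"
    make_plots: bool = True

    def __post_init__(self) -> None:
        if not self.experiments:
            raise ConfigurationError("at least one experiment must be requested")
        if not self.modes:
            raise ConfigurationError("at least one supervision mode must be requested")
        bad = [e for e in self.experiments if e not in (1, 2, 3, 4, 5)]
        if bad:
            raise ConfigurationError(f"unknown experiments {bad}")
        bad = [m for m in self.modes if m not in ("full", "semi")]
        if bad:
            raise ConfigurationError(f"unknown modes {bad}")

    def to_manifest(self) -> dict:
        raw = dataclasses.asdict(self)
        raw["package_version"] = __version__
        raw["numpy_version"] = np.__version__
        raw["python_version"] = platform.python_version()
        return raw


def _load_records(config: RunConfig) -> list[NoduleRecord]:
    if config.cohort_dir is not None:
        logger.info("loading cohort from %s", config.cohort_dir)
        return load_cohort(config.cohort_dir)
    gen = dataclasses.replace(config.generator, seed=config.seed)
    logger.info("generating synthetic cohort (n=%d)", gen.n_nodules)
    return generate_cohort(gen)


def _plot_results(results: list[ExperimentResult], out_dir: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    by_exp: dict[int, list[ExperimentResult]] = {}
    for r in results:
        by_exp.setdefault(r.experiment_id, []).append(r)
    for exp, rs in by_exp.items():
        fig, ax = plt.subplots(figsize=(5, 5))
        for r in rs:
            style = "-" if r.supervision == "semi" else "--"
            ax.plot(
                r.mean_roc.fpr, r.mean_roc.tpr, style,
                label=f"{r.model_name} ({r.supervision}) AUC={r.mean_auc:.3f}",
            )
        ax.plot([0, 1], [0, 1], ":", color="grey", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"Experiment {exp}: mean ROC")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(os.path.join(out_dir, f"roc_experiment{exp}.png"), dpi=120)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(5, 4))
        data = [r.auc_samples for r in rs]
        names = [f"{r.model_name}\n{r.supervision}" for r in rs]
        ax.violinplot(data, showmeans=True)
        ax.set_xticks(range(1, len(names) + 1), names, fontsize=8)
        ax.set_ylabel("AUC")
        ax.set_title(f"Experiment {exp}: AUC over repeats")
        fig.tight_layout()
        fig.savefig(os.path.join(out_dir, f"auc_violin_experiment{exp}.png"), dpi=120)
        plt.close(fig)


def run_all(config: RunConfig) -> pd.DataFrame:
    """Execute the requested grid; returns (and writes) the tidy summary."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    os.makedirs(config.out_dir, exist_ok=True)
    records = _load_records(config)
    arch = ArchitectureSpec()
    if config.arch_divisor > 1:
        arch = arch.scaled(config.arch_divisor)

    all_results: list[ExperimentResult] = []
    per_repeat_rows = []
    for exp in config.experiments:
        for mode in config.modes:
            logger.info("experiment %d, %s supervision", exp, mode)
            out = run_experiment(
                records,
                exp,
                supervision=mode,
                n_repeats=config.n_repeats.get(exp),
                seed=config.seed,
                ratio=config.ratio,
                best_k=config.best_k,
                rf_trees=config.rf_trees,
                arch=arch,
                train_config=config.train,
                cnn_mode=config.cnn_mode,
            )
            for res in out.values():
                all_results.append(res)
                for i, auc in enumerate(res.auc_samples):
                    per_repeat_rows.append(
                        {
                            "experiment": exp,
                            "model": res.model_name,
                            "supervision": mode,
                            "repeat": i,
                            "auc": round(float(auc), 6),
                        }
                    )

    summary = results_table(all_results)
    summary.to_csv(os.path.join(config.out_dir, "summary.csv"), index=False)
    pd.DataFrame(per_repeat_rows).to_csv(
        os.path.join(config.out_dir, "auc_samples.csv"), index=False
    )
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(config.to_manifest(), fh, indent=2, default=str)
    if config.make_plots:
        _plot_results(all_results, config.out_dir)
    logger.info("wrote summary to %s", os.path.join(config.out_dir, "summary.csv"))
    return summary
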