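"""End-to-end experiment sweeps: simulate -> train -> evaluate -> interpret -> match.

A sweep trains a set of CNN variants on one shared synthetic dataset (the
benchmark trains every model on the same data; trial seeds vary only
initialisation and shuffling), quantifies classification (AU-ROC/AU-PR),
distils the designated convolutional layers into filter PPMs, matches them
against the ground-truth motif pool, and collects everything into a
Table-1-style results table.

Two scale presets exist: ``full`` is the complete benchmark protocol
(25,000 sequences, 100 epochs at learning rate 3e-4 — hours of CPU) and
``reduced`` is the desk-scale profile used throughout the test suite and
the acceptance script (see ``docs/methods.md`` for the rationale behind
its settings).
"""

from __future__ import annotations

import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .architectures import (TrainConfig, build_model, evaluate, make_variant,
                            train)
from .interpret import build_ppm, export_meme, scan_activations
from .match import report
from .motifs import MotifPool, load_default_pool
from .simulate import SyntheticDataset, generate_dataset

logger = logging.getLogger(__name__)

#: which conv layers are alignment-visualisable, per variant (no pooling
#: before them); every variant gets layer 1, CNN-1 adds layer 2 and the
#: three-conv variant adds layers 2 and 3
EXTRA_INTERPRET_LAYERS = {"CNN-1": [2], "CNN-1-1-100": [2, 3]}


@dataclass
class ScalePreset:
    n_sequences: int
    max_epochs: int
    learning_rate: float


SCALES = {
    # the complete benchmark protocol
    "full": ScalePreset(25000, 100, 3e-4),
    # desk-scale profile: same dataset geometry, shorter schedule with the
    # learning rate raised to compensate (constant-lr Adam; see methods)
    "reduced": ScalePreset(10000, 60, 2.5e-3),
}


@dataclass
class ExperimentConfig:
    variants: list[str]
    n_trials: int = 1
    data_seed: int = 0
    train_seeds: list[int] = field(default_factory=lambda: [1])
    scale: str = "reduced"
    output_dir: str | Path | None = None
    n_sequences: int | None = None      # override the preset
    max_epochs: int | None = None
    learning_rate: float | None = None
    n_filters1: int = 30
    n_shuffles: int = 1000
    e_cutoff: float = 0.1
    match_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1 or len(self.train_seeds) != self.n_trials:
            raise ValueError("need one train seed per trial")
        preset = SCALES[self.scale]
        self.n_sequences = self.n_sequences or preset.n_sequences
        self.max_epochs = self.max_epochs or preset.max_epochs
        self.learning_rate = self.learning_rate or preset.learning_rate


@dataclass
class ResultsTable:
    """Per-(variant, trial) metrics plus mean +/- std aggregates."""

    rows: pd.DataFrame
    errors: list[dict] = field(default_factory=list)

    def aggregate(self) -> pd.DataFrame:
        num = self.rows.drop(columns=["trial"]).groupby("variant", sort=False)
        agg = num.agg(["mean", "std"])
        agg.columns = ["_".join(c) for c in agg.columns]
        return agg.reset_index()


def run_variant(name: str, dataset: SyntheticDataset, pool: MotifPool,
                config: ExperimentConfig, train_seed: int,
                output_dir: Path | None = None) -> dict:
    """Train one variant once and measure everything; returns a result row."""
    spec = make_variant(name, n_filters1=config.n_filters1)
    model = build_model(spec, dataset.length, seed=train_seed)
    trained = train(model, dataset,
                    TrainConfig(max_epochs=config.max_epochs,
                                learning_rate=config.learning_rate,
                                seed=train_seed))
    metrics = evaluate(trained, dataset, "test")
    row = {
        "variant": name, "trial": train_seed,
        "mean_auroc": metrics["mean_auroc"],
        "mean_aupr": metrics["mean_aupr"],
        "best_epoch": trained.best_epoch,
    }
    Xte, _ = dataset.subset("test")
    for layer in [1] + EXTRA_INTERPRET_LAYERS.get(name, []):
        scan = scan_activations(trained, layer, Xte)
        ppms = build_ppm(scan, Xte)
        rep = report(ppms, pool, pool, e_cutoff=config.e_cutoff,
                     n_shuffles=config.n_shuffles, seed=config.match_seed)
        suffix = "" if layer == 1 else f"_layer{layer}"
        row[f"frac_relevant{suffix}"] = rep.frac_relevant
        row[f"n_empty{suffix}"] = sum(p.empty for p in ppms)
        if output_dir is not None:
            try:
                export_meme(ppms, output_dir /
                            f"{name}_seed{train_seed}_layer{layer}.meme")
            except ValueError:
                logger.info("%s layer %d: all PPMs empty, MEME skipped",
                            name, layer)
    if output_dir is not None:
        hist = {"spec": spec.to_dict(), "history": trained.history,
                "best_epoch": trained.best_epoch,
                "metrics": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                            for k, v in metrics.items()}}
        (output_dir / f"{name}_seed{train_seed}.json").write_text(
            json.dumps(hist, indent=1))
    return row


def run_sweep(config: ExperimentConfig,
              dataset: SyntheticDataset | None = None,
              pool: MotifPool | None = None) -> ResultsTable:
    """Run every variant x trial on one shared dataset; failures are recorded
    per run without aborting the sweep."""
    pool = pool or load_default_pool()
    if dataset is None:
        dataset = generate_dataset(pool, n_sequences=config.n_sequences,
                                   seed=config.data_seed)
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    rows, errors = [], []
    for name in config.variants:
        for seed in config.train_seeds:
            try:
                rows.append(run_variant(name, dataset, pool, config, seed,
                                        out_dir))
            except Exception as exc:  # noqa: BLE001 — sweep must continue
                logger.error("variant %s seed %d failed: %s", name, seed, exc)
                errors.append({"variant": name, "seed": seed,
                               "error": repr(exc),
                               "traceback": traceback.format_exc()})
    table = ResultsTable(pd.DataFrame(rows), errors)
    if out_dir is not None:
        table.rows.to_csv(out_dir / "results.tsv", sep="\t", index=False)
        manifest = {
            "config": {k: (str(v) if isinstance(v, Path) else v)
                       for k, v in vars(config).items()},
            "n_sequences": dataset.n_sequences,
            "data_seed": dataset.seed,
            "errors": errors,
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return table


def filter_count_sweep(counts: list[int], config: ExperimentConfig,
                       base_variant: str = "CNN-25",
                       dataset: SyntheticDataset | None = None,
                       pool: MotifPool | None = None) -> ResultsTable:
    """Widen the first conv layer of ``base_variant`` over ``counts`` filters."""
    pool = pool or load_default_pool()
    if dataset is None:
        dataset = generate_dataset(pool, n_sequences=config.n_sequences,
                                   seed=config.data_seed)
    frames, errors = [], []
    for n in counts:
        cfg = ExperimentConfig(
            variants=[base_variant], n_trials=config.n_trials,
            data_seed=config.data_seed, train_seeds=config.train_seeds,
            scale=config.scale, output_dir=config.output_dir,
            n_sequences=config.n_sequences, max_epochs=config.max_epochs,
            learning_rate=config.learning_rate, n_filters1=n,
            n_shuffles=config.n_shuffles, e_cutoff=config.e_cutoff,
            match_seed=config.match_seed)
        t = run_sweep(cfg, dataset=dataset, pool=pool)
        t.rows["variant"] = f"{base_variant} ({n})"
        frames.append(t.rows)
        errors.extend(t.errors)
    return ResultsTable(pd.concat(frames, ignore_index=True), errors)
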