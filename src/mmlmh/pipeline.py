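"""Training pipeline: splits, the train entry point, ablation suite, reports.

Thin orchestration over :class:`mmlmh.model.MultimodalHealthModel`; the
functions here are what the command-line interface calls.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ABLATION_FLAGS, TrainConfig
from .data import MultimodalDataset
from .model import HealthFitResults, MultimodalHealthModel, TrainHistory

__all__ = [
    "stratified_split",
    "train",
    "run_ablation_suite",
    "evaluate_cli",
    "history_to_json",
]


def stratified_split(
    dataset: MultimodalDataset,
    fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
    seed: int = 0,
):
    """70/15/15 train/validation/test split, stratified by label.

    Classification stratifies by class; regression by score quartile.
    Deterministic under the seed.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    labels = dataset.labels
    if dataset.task == "classification":
        strata = labels.astype(int)
    else:
        strata = np.searchsorted(np.quantile(labels, [0.25, 0.5, 0.75]), labels)
    train_idx, val_idx, test_idx = [], [], []
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        rng.shuffle(idx)
        n = len(idx)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        train_idx.append(idx[:n_train])
        val_idx.append(idx[n_train : n_train + n_val])
        test_idx.append(idx[n_train + n_val :])
    order = lambda parts: np.sort(np.concatenate(parts))
    return (
        dataset.subset(order(train_idx)),
        dataset.subset(order(val_idx)),
        dataset.subset(order(test_idx)),
    )


def train(
    config: TrainConfig,
    train_set: MultimodalDataset,
    validation_set: MultimodalDataset | None = None,
    epochs: int | None = None,
    record_diagnostics: bool = False,
    verbose: bool = False,
) -> tuple[HealthFitResults, TrainHistory]:
    """Fit the full model (or the configured ablation) and return results."""
    model = MultimodalHealthModel(train_set, config, validation=validation_set)
    results = model.fit(epochs=epochs, record_diagnostics=record_diagnostics, verbose=verbose)
    return results, results.history


def run_ablation_suite(
    config: TrainConfig,
    dataset: MultimodalDataset,
    epochs: int | None = None,
    split_seed: int = 0,
) -> pd.DataFrame:
    """Train the full model and all six single-component ablations.

    Identical splits and seeds across rows; the returned table has one row
    per variant with the validation metrics and the (zeroed) removed term.
    """
    train_set, val_set, _ = stratified_split(dataset, seed=split_seed)
    rows = []
    for variant in ("full", *ABLATION_FLAGS):
        cfg = config if variant == "full" else config.replace(**{variant: True})
        results, history = train(cfg, train_set, val_set, epochs=epochs)
        report = results.val_report.as_dict() if results.val_report else {}
        last_losses = history.epochs[-1]["losses"] if history.epochs else {}
        rows.append(
            {
                "variant": variant,
                "seed": cfg.seed,
                "epochs_run": len(history.epochs),
                **{k: v for k, v in report.items() if k != "confusion_matrix"},
                **{f"loss_{k}": v for k, v in last_losses.items()},
            }
        )
    frame = pd.DataFrame(rows)
    frame.attrs["seed"] = config.seed
    frame.attrs["config_hash"] = config.hash()
    return frame


def evaluate_cli(results: HealthFitResults, dataset: MultimodalDataset, report_path) -> dict:
    """Deterministic evaluation pass; writes the metric report as JSON."""
    if len(dataset) == 0:
        raise ValueError("cannot evaluate an empty dataset")
    report = results.evaluate(dataset)
    report.to_json(report_path)
    return report.as_dict()


def history_to_json(history: TrainHistory, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "seed": history.seed,
                "config_hash": history.config_hash,
                "best_epoch": history.best_epoch,
                "wall_time_s": history.wall_time_s,
                "epochs": history.epochs,
            },
            indent=2,
            default=float,
        )
    )
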