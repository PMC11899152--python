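"""The multimodal health-assessment model and its fitted results object.

`MultimodalHealthModel` is constructed from a training dataset, a
`TrainConfig` and an optional validation dataset; `fit()` optimises the
composite objective

    L = L_task + beta1 * L_intra + beta2 * L_inter + beta3 * L_recon

with AdamW and early stopping, and returns a `HealthFitResults` carrying the
trained network, the per-epoch history, validation metrics, diagnostics
accessors and a `summary()` table. Ablation switches in the config remove
individual components; a disabled component contributes exactly zero to the
objective and its parameters receive no gradient.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._tensor import Tensor
from .cmd_metrics import CmdConfig
from .config import TrainConfig
from .data import MODALITIES, MultimodalDataset
from .fusion import FusionModule, FusionState
from .nn import AdamW, Module, softmax
from .prediction import (
    MetricReport,
    PredictionHead,
    PredictionOutput,
    classification_loss,
    evaluate,
    regression_loss,
)
from .representation import (
    LossBreakdown,
    RepresentationModule,
    RepresentationSet,
    inter_loss_batch,
    intra_diff_loss,
    intra_sim_loss,
    recon_loss,
)
from .synthetic import padded_contrastive_indices

__all__ = [
    "MMLMHNetwork",
    "MultimodalHealthModel",
    "HealthFitResults",
    "TrainHistory",
    "TrainingDivergedError",
    "compute_losses",
    "mean_shared_specific_cosine",
    "save_checkpoint",
    "load_checkpoint",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


class MMLMHNetwork(Module):
    """Representation, fusion and prediction stages wired together."""

    def __init__(
        self,
        widths: Mapping[str, int],
        d_environment: int,
        config: TrainConfig,
        rng: np.random.Generator,
        n_classes: int | None = None,
    ):
        super().__init__()
        self.config = config
        self.widths = dict(widths)
        self.d_environment = d_environment
        self.n_classes = n_classes
        self.rep = RepresentationModule(
            widths, config.d_utterance, config.d_shared, config.hidden, config.dropout, rng
        )
        self.fusion = FusionModule(
            config.d_shared,
            config.d_fused,
            d_environment,
            rng,
            calibration_hidden=config.calibration_hidden,
            dropout=config.dropout,
        )
        self.head = PredictionHead(
            config.d_fused, config.hidden, config.task, n_classes, rng, config.dropout
        )

    def forward(self, batch: Mapping, compute_recon: bool = True):
        """Full pass; returns (head output, feature dicts, fusion state)."""
        cfg = self.config
        omega = {m: self.rep.encode_modality(batch["tokens"][m], m) for m in MODALITIES}
        shared = {m: self.rep.shared_encode(omega[m]) for m in MODALITIES}
        specific = {m: self.rep.specific_encode(omega[m], m) for m in MODALITIES}
        recon = (
            {m: self.rep.decode(shared[m], specific[m]) for m in MODALITIES}
            if compute_recon
            else None
        )
        xi_final, state = self.fusion.forward(
            shared,
            specific,
            batch["flags"],
            batch["environment"],
            adaptive=not cfg.no_adaptive_fusion,
            calibration=not cfg.no_calibration,
            use_environment=not cfg.no_environment,
        )
        out = self.head(xi_final)
        return out, {"omega": omega, "shared": shared, "specific": specific, "recon": recon}, state


def compute_losses(
    net: MMLMHNetwork,
    batch: Mapping,
    contrast_rng: np.random.Generator,
    collect_state: bool = True,
):
    """Objective for one batch: (total Tensor, LossBreakdown, FusionState).

    Disabled components are skipped entirely (their term is exactly zero and
    their parameters receive no gradient).
    """
    cfg = net.config
    sample_cmd = CmdConfig(cfg.cmd_order, cfg.cmd_range_width, "samples")
    vector_cmd_cfg = CmdConfig(cfg.cmd_order, cfg.cmd_range_width, "coordinates")
    out, feats, state = net.forward(batch, compute_recon=not cfg.no_recon)

    if cfg.task == "classification":
        probs = softmax(out, axis=-1)
        l_task = classification_loss(probs, batch["labels"])
    else:
        l_task = regression_loss(out, batch["labels"])
    total = l_task

    bd = LossBreakdown(beta1=cfg.beta1, beta2=cfg.beta2, beta3=cfg.beta3)
    bd.l_task = float(l_task.data)

    if not cfg.no_intra:
        l_sim = intra_sim_loss(feats["shared"], sample_cmd)
        l_diff = intra_diff_loss(feats["shared"], feats["specific"])
        bd.l_intra_sim = float(l_sim.data)
        bd.l_intra_diff = float(l_diff.data)
        total = total + cfg.beta1 * l_sim + cfg.beta1 * l_diff

    if not cfg.no_inter:
        pos_idx, pos_mask, neg_idx, neg_mask, anchor_mask = padded_contrastive_indices(
            batch["labels"], cfg.n_positives, cfg.n_negatives, contrast_rng, cfg.task,
            cfg.positive_window,
        )
        features = {}
        for m in MODALITIES:
            features[("shared", m)] = feats["shared"][m]
            features[("specific", m)] = feats["specific"][m]
        l_inter = inter_loss_batch(
            features, pos_idx, pos_mask, neg_idx, neg_mask, anchor_mask,
            margin=cfg.margin, cfg=vector_cmd_cfg,
        )
        bd.l_inter = float(l_inter.data)
        total = total + cfg.beta2 * l_inter

    if not cfg.no_recon:
        l_recon = recon_loss(feats["omega"], feats["recon"])
        bd.l_recon = float(l_recon.data)
        total = total + cfg.beta3 * l_recon

    return total, bd, (state if collect_state else None)


@dataclass
class TrainHistory:
    """Per-epoch loss breakdowns and validation metrics of one fit."""

    epochs: list[dict] = field(default_factory=list)
    seed: int = 0
    config_hash: str = ""
    wall_time_s: float = 0.0
    best_epoch: int = -1
    diagnostics: list[dict] = field(default_factory=list)

    def loss_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e["losses"] for e in self.epochs])


class MultimodalHealthModel:
    """Model object: dataset + config in, `fit()` out.

    Parameters
    ----------
    train_data : MultimodalDataset
        Training split; dimensions configure the network.
    config : TrainConfig, optional
        Architecture/optimisation settings; defaults to `TrainConfig()` with
        the task taken from the data.
    validation : MultimodalDataset, optional
        Held-out split monitored for early stopping.
    """

    def __init__(
        self,
        train_data: MultimodalDataset,
        config: TrainConfig | None = None,
        validation: MultimodalDataset | None = None,
    ):
        if config is None:
            config = TrainConfig(task=train_data.task)
        if config.task != train_data.task:
            raise ValueError(f"config task {config.task!r} != dataset task {train_data.task!r}")
        if validation is not None and (
            validation.dims != train_data.dims
            or validation.d_environment != train_data.d_environment
        ):
            raise ValueError("validation dimensions differ from training dimensions")
        n_classes = config.n_classes or train_data.n_classes
        self.config = config.replace(n_classes=n_classes)
        self.train_data = train_data
        self.validation = validation

    @classmethod
    def from_dataset(cls, dataset, config=None, validation=None):
        return cls(dataset, config, validation)

    # -- construction -----------------------------------------------------
    def _seed_streams(self):
        ss = np.random.SeedSequence(self.config.seed)
        return [np.random.default_rng(s) for s in ss.spawn(3)]

    def build_network(self) -> MMLMHNetwork:
        """Deterministically initialised network (same draw as `fit`)."""
        rng_init, _, _ = self._seed_streams()
        widths = {m: self.train_data.dims[m][1] for m in MODALITIES}
        return MMLMHNetwork(
            widths,
            self.train_data.d_environment,
            self.config,
            rng_init,
            n_classes=self.config.n_classes,
        )

    @staticmethod
    def _batch(ds: MultimodalDataset, idx: np.ndarray) -> dict:
        return {
            "tokens": {m: ds.modality(m)[idx] for m in MODALITIES},
            "labels": ds.labels[idx],
            "flags": ds.synthetic_flags[idx],
            "environment": ds.environment[idx],
        }

    # -- fitting ----------------------------------------------------------
    def fit(
        self,
        epochs: int | None = None,
        record_diagnostics: bool = False,
        verbose: bool = False,
    ) -> "HealthFitResults":
        cfg = self.config
        epochs = epochs if epochs is not None else cfg.epochs
        rng_init, rng_shuffle, rng_contrast = self._seed_streams()
        widths = {m: self.train_data.dims[m][1] for m in MODALITIES}
        net = MMLMHNetwork(
            widths, self.train_data.d_environment, cfg, rng_init, n_classes=cfg.n_classes
        )
        opt = AdamW(net.parameters(), lr=cfg.learning_rate, weight_decay=cfg.l2)
        n = len(self.train_data)
        history = TrainHistory(seed=cfg.seed, config_hash=cfg.hash())
        best_monitor = np.inf
        best_params: dict[str, np.ndarray] | None = None
        bad_epochs = 0
        t0 = time.perf_counter()

        for epoch in range(1, epochs + 1):
            net.train()
            perm = rng_shuffle.permutation(n)
            sums: dict[str, float] = {}
            n_batches = 0
            for start in range(0, n, cfg.batch_size):
                idx = perm[start : start + cfg.batch_size]
                if len(idx) < 2:
                    continue  # batch-level moments need >= 2 rows
                batch = self._batch(self.train_data, idx)
                total, bd, state = compute_losses(
                    net, batch, rng_contrast, collect_state=record_diagnostics
                )
                if not np.isfinite(total.data):
                    bad = {k: v for k, v in bd.as_dict().items() if not np.isfinite(v)}
                    raise TrainingDivergedError(
                        f"non-finite loss at epoch {epoch}: offending terms {bad or 'composite'}"
                    )
                opt.zero_grad()
                total.backward()
                opt.step()
                for k, v in bd.as_dict().items():
                    sums[k] = sums.get(k, 0.0) + v
                n_batches += 1
                if record_diagnostics and state is not None:
                    history.diagnostics.append(_step_diagnostics(epoch, state))
            losses = {k: v / max(n_batches, 1) for k, v in sums.items()}

            val_report, val_task = None, None
            if self.validation is not None:
                val_report, val_task = self._validate(net, self.validation)
            history.epochs.append(
                {
                    "epoch": epoch,
                    "losses": losses,
                    "val_task_loss": val_task,
                    "val_metrics": val_report.as_dict() if val_report else None,
                    "wall_time_s": time.perf_counter() - t0,
                }
            )
            if verbose:  # pragma: no cover - console convenience
                msg = f"epoch {epoch:3d} loss {losses.get('l_total', np.nan):.4f}"
                if val_task is not None:
                    msg += f" val_task {val_task:.4f}"
                print(msg)

            monitor = val_task if val_task is not None else losses.get("l_total", np.inf)
            if monitor < best_monitor - 1e-12:
                best_monitor = monitor
                best_params = {k: p.data.copy() for k, p in net.named_parameters().items()}
                history.best_epoch = epoch
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs > cfg.patience:
                    break

        if best_params is not None:
            named = net.named_parameters()
            for k, v in best_params.items():
                named[k].data = v
        history.wall_time_s = time.perf_counter() - t0
        net.eval()
        final_val = None
        if self.validation is not None:
            final_val, _ = self._validate(net, self.validation)
        return HealthFitResults(self, net, history, final_val)

    def _validate(self, net: MMLMHNetwork, ds: MultimodalDataset):
        was_training = net.training
        net.eval()
        preds, task_losses = [], []
        for start in range(0, len(ds), 256):
            idx = np.arange(start, min(start + 256, len(ds)))
            batch = self._batch(ds, idx)
            out, _, _ = net.forward(batch, compute_recon=False)
            if net.config.task == "classification":
                probs = softmax(out, axis=-1).data
                task_losses.append(classification_loss(probs, batch["labels"]) * len(idx))
                preds.append(probs)
            else:
                task_losses.append(regression_loss(out.data, batch["labels"]) * len(idx))
                preds.append(out.data)
            net.train(was_training)
        preds = np.concatenate(preds, axis=0)
        report = evaluate(preds, ds.labels, task=net.config.task)
        return report, float(np.sum(task_losses) / len(ds))


def _step_diagnostics(epoch: int, state: FusionState) -> dict:
    """Compact per-step contract checks: attention row sums, gate ranges."""
    row_dev = max(
        float(np.abs(am.weights.sum(axis=-1) - 1.0).max())
        for am in state.attention_maps.values()
    )
    gate_vals = np.concatenate([np.atleast_1d(g) for g in state.gates.values()])
    calib_vals = np.concatenate([np.atleast_1d(c) for c in state.calibrations.values()])
    return {
        "epoch": epoch,
        "attention_rowsum_maxdev": row_dev,
        "gate_min": float(gate_vals.min()),
        "gate_max": float(gate_vals.max()),
        "calibration_min": float(calib_vals.min()),
        "calibration_max": float(calib_vals.max()),
    }


class HealthFitResults:
    """Fitted-model results: estimates, history, diagnostics, summary."""

    def __init__(
        self,
        model: MultimodalHealthModel,
        network: MMLMHNetwork,
        history: TrainHistory,
        val_report: MetricReport | None,
    ):
        self.model = model
        self.network = network
        self.history = history
        self.val_report = val_report
        self.config = model.config

    # -- inference --------------------------------------------------------
    def predict(self, dataset: MultimodalDataset, batch_size: int = 256) -> PredictionOutput:
        if len(dataset) == 0:
            raise ValueError("cannot predict on an empty dataset")
        net = self.network
        net.eval()
        probs, logits, scores = [], [], []
        for start in range(0, len(dataset), batch_size):
            idx = np.arange(start, min(start + batch_size, len(dataset)))
            batch = MultimodalHealthModel._batch(dataset, idx)
            out, _, _ = net.forward(batch, compute_recon=False)
            if self.config.task == "classification":
                probs.append(softmax(out, axis=-1).data)
                logits.append(out.data)
            else:
                scores.append(out.data)
        if self.config.task == "classification":
            return PredictionOutput(
                probabilities=np.concatenate(probs), logits=np.concatenate(logits)
            )
        return PredictionOutput(scores=np.concatenate(scores))

    def evaluate(self, dataset: MultimodalDataset) -> MetricReport:
        pred = self.predict(dataset)
        values = pred.probabilities if self.config.task == "classification" else pred.scores
        return evaluate(values, dataset.labels, task=self.config.task)

    def representations(self, dataset: MultimodalDataset, batch_size: int = 256) -> RepresentationSet:
        net = self.network
        net.eval()
        acc = {k: {m: [] for m in MODALITIES} for k in ("omega", "shared", "specific", "recon")}
        for start in range(0, len(dataset), batch_size):
            idx = np.arange(start, min(start + batch_size, len(dataset)))
            batch = MultimodalHealthModel._batch(dataset, idx)
            _, feats, _ = net.forward(batch, compute_recon=True)
            for k in acc:
                for m in MODALITIES:
                    acc[k][m].append(feats[k][m].data)
        join = lambda d: {m: np.concatenate(v) for m, v in d.items()}
        return RepresentationSet(
            omega=join(acc["omega"]),
            shared=join(acc["shared"]),
            specific=join(acc["specific"]),
            reconstructed=join(acc["recon"]),
        )

    def fusion_diagnostics(self, dataset: MultimodalDataset, batch_size: int = 256) -> pd.DataFrame:
        """Per-sample gates, adjusted gates and calibrations (CSV-friendly)."""
        net = self.network
        net.eval()
        rows = []
        for start in range(0, len(dataset), batch_size):
            idx = np.arange(start, min(start + batch_size, len(dataset)))
            batch = MultimodalHealthModel._batch(dataset, idx)
            _, _, state = net.forward(batch, compute_recon=False)
            frame = pd.DataFrame(
                {
                    "sample": idx,
                    "w_audio": state.gates["audio"],
                    "w_visual": state.gates["visual"],
                    "c_text": state.calibrations["text"],
                    "c_audio": state.calibrations["audio"],
                    "c_visual": state.calibrations["visual"],
                    "w_adj_audio": state.adjusted_gates["audio"],
                    "w_adj_visual": state.adjusted_gates["visual"],
                    "flag_text": batch["flags"][:, 0],
                    "flag_audio": batch["flags"][:, 1],
                    "flag_visual": batch["flags"][:, 2],
                }
            )
            rows.append(frame)
        return pd.concat(rows, ignore_index=True)

    def export_fusion_diagnostics(self, dataset: MultimodalDataset, path) -> None:
        self.fusion_diagnostics(dataset).to_csv(path, index=False)

    def loss_breakdown(self, dataset: MultimodalDataset, idx=None, seed: int = 0) -> LossBreakdown:
        """Eval-mode loss terms on one batch (defaults to the first 32 rows)."""
        net = self.network
        net.eval()
        if idx is None:
            idx = np.arange(min(32, len(dataset)))
        batch = MultimodalHealthModel._batch(dataset, np.asarray(idx))
        _, bd, _ = compute_losses(net, batch, np.random.default_rng(seed), collect_state=False)
        return bd

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Multimodal health-assessment model — fit results",
            "=" * 52,
            f"task                 {cfg.task}"
            + (f" ({cfg.n_classes} classes)" if cfg.task == "classification" else ""),
            f"n train / val        {len(self.model.train_data)} / "
            + (str(len(self.model.validation)) if self.model.validation is not None else "-"),
            f"parameters           {self.network.n_parameters()}",
            f"epochs run (best)    {len(self.history.epochs)} ({self.history.best_epoch})",
            f"config hash / seed   {self.history.config_hash} / {cfg.seed}",
            f"wall time            {self.history.wall_time_s:.1f} s",
        ]
        if self.history.epochs:
            last = self.history.epochs[-1]["losses"]
            lines.append("final training losses:")
            for k in ("l_task", "l_intra", "l_inter", "l_recon", "l_total"):
                if k in last:
                    lines.append(f"  {k:<12} {last[k]:.4f}")
        if self.val_report is not None:
            lines.append("validation metrics:")
            for k, v in self.val_report.as_dict().items():
                if k != "confusion_matrix" and v is not None:
                    lines.append(f"  {k:<12} {v:.4f}" if isinstance(v, float) else f"  {k:<12} {v}")
        return "\n".join(lines)

    def save(self, path) -> None:
        save_checkpoint(self.network, path)


def mean_shared_specific_cosine(
    network: MMLMHNetwork, dataset: MultimodalDataset, batch_size: int = 256
) -> float:
    """Mean |cos(specific, shared)| over samples and modalities (eval mode)."""
    network.eval()
    vals = []
    for start in range(0, len(dataset), batch_size):
        idx = np.arange(start, min(start + batch_size, len(dataset)))
        batch = MultimodalHealthModel._batch(dataset, idx)
        _, feats, _ = network.forward(batch, compute_recon=False)
        for m in MODALITIES:
            u = feats["specific"][m].data
            s = feats["shared"][m].data
            num = np.abs((u * s).sum(axis=-1))
            den = np.maximum(np.linalg.norm(u, axis=-1) * np.linalg.norm(s, axis=-1), 1e-12)
            vals.append(num / den)
    return float(np.concatenate(vals).mean())


def save_checkpoint(network: MMLMHNetwork, path) -> None:
    """Single-file archive: all parameter groups plus the config snapshot."""
    import json

    arrays = {f"param:{k}": p.data for k, p in network.named_parameters().items()}
    meta = {
        "config": network.config.to_dict(),
        "widths": network.widths,
        "d_environment": network.d_environment,
        "n_classes": network.n_classes,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> MMLMHNetwork:
    """Rebuild a network from an archive; validates dimension compatibility."""
    import json

    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        config = TrainConfig.from_dict(meta["config"])
        net = MMLMHNetwork(
            meta["widths"],
            meta["d_environment"],
            config,
            np.random.default_rng(0),
            n_classes=meta["n_classes"],
        )
        named = net.named_parameters()
        stored = {k[len("param:"):] for k in archive.files if k.startswith("param:")}
        if stored != set(named):
            raise ValueError("checkpoint parameter groups do not match the architecture")
        for k, p in named.items():
            data = archive[f"param:{k}"]
            if data.shape != p.data.shape:
                raise ValueError(f"dimension mismatch for {k}: {data.shape} vs {p.data.shape}")
            p.data = data.copy()
    net.eval()
    return net
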