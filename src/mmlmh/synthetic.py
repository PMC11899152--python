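"""Seed-deterministic generator of synthetic multimodal consultation data.

The generator realises the statistical structure the representation and
fusion machinery assumes, in a transparent latent-factor form:

* a shared latent ``z`` carries the health signal: for classification it is
  drawn about class means placed at regular-simplex vertices scaled by the
  separation ``delta``; for regression a real score is a fixed linear read-out
  of ``z`` plus label noise, clipped to [-3, 3];
* each modality adds a private latent ``u_m``, squashes ``A_m z + B_m u_m``
  through tanh, adds per-token Gaussian noise plus a consultation-level
  channel noise (coherent across tokens, independent across modalities, so
  no single channel is fully reliable and fusing channels genuinely helps)
  and lifts the result to the modality's feature width by a fixed random
  projection — so all informative modalities express the same shared factor
  while keeping private structure;
* a per-modality Bernoulli(rho) flag marks "synthetically generated" data;
  a flagged channel expresses the shared state at fidelity ``1/kappa``,
  mixed with an amplitude-matched plausible decoy (for classification, a
  randomly chosen wrong condition) — generative-model content that looks
  statistically like real data but is only partly faithful to the patient,
  which the flag-conditioned calibration gate is meant to discover; an
  optional constant feature bias models systematic generator offset;
* the environment vector is weakly label-associated: class- (or score-)
  dependent mean scaled by ``env_effect`` plus noise.

A modality with ``informative=False`` omits the ``A_m z`` term entirely and
is therefore statistically independent of the label — the probe used to test
whether the gated fusion learns to down-weight uninformative channels.

All draws come from one ``numpy`` Generator seeded by the spec, so an
identical spec yields a bit-identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .data import MODALITIES, MultimodalDataset

__all__ = [
    "ModalitySpec",
    "SyntheticDatasetSpec",
    "generate",
    "make_contrastive_batch",
    "simplex_vertices",
]

#: regression positives are batch-mates with |score difference| below this
REGRESSION_POSITIVE_WINDOW = 0.5


@dataclass(frozen=True)
class ModalitySpec:
    """Per-modality generation settings."""

    seq_len: int = 8
    width: int = 32
    noise: float = 0.1
    informative: bool = True


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Full generative recipe; identical spec (incl. seed) => identical data.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 600 samples, 3 classes, shared latent dimension 8, separation 3,
    modality widths 32/16/48 at sequence length 8, a 20% synthetic fraction
    at halved fidelity, and a weakly informative 6-dimensional environment
    vector.
    """

    n_samples: int = 600
    task: str = "classification"
    n_classes: int = 3
    d_z: int = 8
    delta: float = 3.0
    sigma_z: float = 1.0
    private_strength: float = 1.0
    text: ModalitySpec = field(default_factory=lambda: ModalitySpec(8, 32, 0.1, True))
    audio: ModalitySpec = field(default_factory=lambda: ModalitySpec(8, 16, 0.1, True))
    visual: ModalitySpec = field(default_factory=lambda: ModalitySpec(8, 48, 0.1, True))
    sigma_consult: float = 0.3
    synthetic_fraction: float = 0.2
    synthetic_noise_multiplier: float = 2.0
    synthetic_bias: float = 0.0
    d_environment: int = 6
    env_effect: float = 0.5
    sigma_env: float = 1.0
    sigma_label: float = 0.2
    seed: int = 0

    def modality(self, m: str) -> ModalitySpec:
        return getattr(self, m)

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"invalid n_samples: {self.n_samples}")
        if self.task not in ("classification", "regression"):
            raise ValueError(f"invalid task: {self.task!r}")
        if self.task == "classification":
            if self.n_classes < 2:
                raise ValueError(f"invalid n_classes: {self.n_classes}")
            if self.d_z < self.n_classes - 1:
                raise ValueError(f"invalid d_z: need >= n_classes-1, got {self.d_z}")
        if self.d_z < 1:
            raise ValueError(f"invalid d_z: {self.d_z}")
        if not 0.0 <= self.synthetic_fraction <= 1.0:
            raise ValueError(f"invalid synthetic_fraction: {self.synthetic_fraction}")
        for name in ("delta", "sigma_z", "private_strength", "sigma_consult",
                     "synthetic_noise_multiplier", "sigma_env", "sigma_label", "env_effect"):
            if getattr(self, name) < 0:
                raise ValueError(f"invalid {name}: {getattr(self, name)}")
        if self.d_environment < 1:
            raise ValueError(f"invalid d_environment: {self.d_environment}")
        for m in MODALITIES:
            ms = self.modality(m)
            if ms.seq_len < 1:
                raise ValueError(f"invalid {m}.seq_len: {ms.seq_len}")
            if ms.width < 1:
                raise ValueError(f"invalid {m}.width: {ms.width}")
            if ms.noise < 0:
                raise ValueError(f"invalid {m}.noise: {ms.noise}")

    def to_dict(self) -> dict:
        return asdict(self)


def simplex_vertices(c: int, dim: int) -> np.ndarray:
    """`c` unit vectors at regular-simplex vertices, embedded in R^dim.

    Pairwise distances are equal; requires dim >= c - 1.
    """
    if dim < c - 1:
        raise ValueError(f"need dim >= c-1 to embed a {c}-simplex, got {dim}")
    centered = np.eye(c) - 1.0 / c
    # the rows span a (c-1)-dim subspace; take coordinates in that subspace
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    coords = (u * s)[:, : c - 1]
    coords /= np.linalg.norm(coords, axis=1, keepdims=True)
    out = np.zeros((c, dim))
    out[:, : c - 1] = coords
    return out


def generate(spec: SyntheticDatasetSpec) -> MultimodalDataset:
    """Draw a dataset according to ``spec`` (deterministic in the seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, d_z = spec.n_samples, spec.d_z

    if spec.task == "classification":
        y = rng.integers(0, spec.n_classes, size=n)
        mu = simplex_vertices(spec.n_classes, d_z) * spec.delta
        z = mu[y] + rng.normal(0.0, spec.sigma_z, size=(n, d_z))
        labels = y.astype(np.int64)
    else:
        z = rng.normal(0.0, spec.sigma_z, size=(n, d_z))
        w_z = rng.normal(size=d_z)
        w_z /= np.linalg.norm(w_z)
        score = z @ w_z + rng.normal(0.0, spec.sigma_label, size=n)
        labels = np.clip(score, -3.0, 3.0)

    flags = (rng.random(size=(n, 3)) < spec.synthetic_fraction).astype(np.uint8)

    # synthetic-flagged channels express the shared state at reduced
    # fidelity 1/kappa, mixed with a plausible decoy of matched amplitude: a
    # generative model renders content that is statistically indistinguishable
    # from real data but only partly faithful to the patient — which is
    # exactly why the fusion stage needs the flag to calibrate reliability
    fidelity = 1.0 / max(spec.synthetic_noise_multiplier, 1.0)
    token_arrays: dict[str, np.ndarray] = {}
    for j, m in enumerate(MODALITIES):
        ms = spec.modality(m)
        a_m = rng.normal(size=(d_z, d_z)) / np.sqrt(d_z)
        b_m = rng.normal(size=(d_z, d_z)) / np.sqrt(d_z)
        p_m = rng.normal(size=(d_z, ms.width)) / np.sqrt(d_z)
        u_m = rng.normal(size=(n, d_z))
        # consultation-level channel perturbation: drawn once per sample in
        # latent space, so every token of a channel expresses a coherently
        # shifted shared state (per-token noise alone would average out
        # under the encoder's mean pooling, leaving channels redundant)
        eta = rng.normal(size=(n, d_z)) * spec.sigma_consult
        if spec.task == "classification":
            decoy = mu[rng.integers(0, spec.n_classes, size=n)] + rng.normal(
                0.0, spec.sigma_z, size=(n, d_z)
            )
        else:
            decoy = rng.normal(0.0, spec.sigma_z, size=(n, d_z))
        fl = flags[:, j : j + 1].astype(float)
        z_eff = (1 - fl) * z + fl * (
            fidelity * z + np.sqrt(1.0 - fidelity**2) * decoy
        )
        drive = spec.private_strength * (u_m @ b_m)
        if ms.informative:
            drive = drive + (z_eff + eta) @ a_m
        core = np.tanh(drive)  # (n, d_z), identical across the token axis
        eps = rng.normal(size=(n, ms.seq_len, d_z)) * ms.noise
        tokens = (core[:, None, :] + eps) @ p_m
        tokens += (flags[:, j] * spec.synthetic_bias)[:, None, None]
        token_arrays[m] = tokens

    h = rng.normal(size=(spec.n_classes if spec.task == "classification" else 1,
                         spec.d_environment))
    if spec.task == "classification":
        env_mean = spec.env_effect * h[labels.astype(int)]
    else:
        env_mean = spec.env_effect * labels[:, None] * h[0]
    environment = env_mean + rng.normal(0.0, spec.sigma_env, size=(n, spec.d_environment))

    return MultimodalDataset(
        text=token_arrays["text"],
        audio=token_arrays["audio"],
        visual=token_arrays["visual"],
        labels=labels,
        synthetic_flags=flags,
        environment=environment,
        task=spec.task,
        n_classes=spec.n_classes if spec.task == "classification" else None,
        spec=spec.to_dict(),
    )


def _same_condition(labels: np.ndarray, task: str, a: int, window: float) -> np.ndarray:
    """Boolean mask of samples sharing anchor `a`'s health condition."""
    if task == "classification":
        return labels == labels[a]
    return np.abs(labels - labels[a]) < window


def make_contrastive_batch(
    dataset_or_labels,
    anchor_indices: Sequence[int],
    n_pos: int,
    n_neg: int,
    seed: int | np.random.Generator,
    task: str | None = None,
    positive_window: float = REGRESSION_POSITIVE_WINDOW,
) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """Per anchor, sample positive (same condition) and negative index sets.

    Positives share the anchor's class (regression: score within
    ``positive_window``); negatives differ. Sampling is without replacement
    where the pool allows, the anchor itself is never a positive, and the
    result is deterministic under the seed. Anchors short of candidates get
    all that exist (possibly fewer than requested).
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    if isinstance(dataset_or_labels, MultimodalDataset):
        labels = dataset_or_labels.labels
        task = dataset_or_labels.task
    else:
        labels = np.asarray(dataset_or_labels)
        if task is None:
            task = "classification" if np.issubdtype(labels.dtype, np.integer) else "regression"
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    all_idx = np.arange(len(labels))
    for a in anchor_indices:
        same = _same_condition(labels, task, a, positive_window)
        pos_pool = all_idx[same & (all_idx != a)]
        neg_pool = all_idx[~same]
        pos = rng.choice(pos_pool, size=min(n_pos, len(pos_pool)), replace=False)
        neg = rng.choice(neg_pool, size=min(n_neg, len(neg_pool)), replace=False)
        out.append((int(a), pos, neg))
    return out


def padded_contrastive_indices(
    labels: np.ndarray,
    n_pos: int,
    n_neg: int,
    rng: np.random.Generator,
    task: str,
    positive_window: float = REGRESSION_POSITIVE_WINDOW,
):
    """Fixed-shape contrastive index/mask arrays for vectorised batch losses.

    Returns ``(pos_idx, pos_mask, neg_idx, neg_mask, anchor_mask)`` where the
    index arrays are (B, N) / (B, M), masks are 1.0 on valid entries, and
    ``anchor_mask`` marks anchors with at least one positive and one
    negative (others are excluded from the loss average).
    """
    b = len(labels)
    pos_idx = np.zeros((b, n_pos), dtype=np.int64)
    neg_idx = np.zeros((b, n_neg), dtype=np.int64)
    pos_mask = np.zeros((b, n_pos))
    neg_mask = np.zeros((b, n_neg))
    anchor_mask = np.zeros(b)
    for a, pos, neg in make_contrastive_batch(
        labels, np.arange(b), n_pos, n_neg, rng, task, positive_window
    ):
        if len(pos) == 0 or len(neg) == 0:
            continue
        anchor_mask[a] = 1.0
        pos_idx[a, : len(pos)] = pos
        pos_mask[a, : len(pos)] = 1.0
        neg_idx[a, : len(neg)] = neg
        neg_mask[a, : len(neg)] = 1.0
    return pos_idx, pos_mask, neg_idx, neg_mask, anchor_mask
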