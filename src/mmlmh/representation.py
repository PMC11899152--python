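"""Per-modality encoding and collaborative shared/specific representation.

Each modality's token sequence is L2-normalised per token, projected to the
model width, passed through a small single-head self-attention encoder block
and mean-pooled into an utterance vector ``omega_m``. One *shared* encoder
(a single parameter set applied to all three modalities) maps utterances to
modality-invariant features ``gamma_m^s``; three *specific* encoders produce
modality-private features ``gamma_m^u`` of the same width. A decoder
reconstructs the utterance vector from the concatenated pair.

Four losses shape this space:

* intra-sample similarity — mean pairwise CMD between the batch
  distributions of the three shared-feature sets (consistency);
* intra-sample distinctiveness — mean absolute cosine between shared and
  specific features within a modality and between specific features across
  modalities (orthogonality; the absolute value makes orthogonality, not
  anti-alignment, the minimum);
* inter-sample contrast — a hinged contrastive term pulling same-condition
  samples together and pushing different-condition samples apart under the
  per-vector (coordinate-axis) CMD;
* reconstruction — mean squared error of the decoded utterance vectors.

The composite representation objective weights these three groups by
``beta1``/``beta2``/``beta3``; training adds the task loss on top.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from ._tensor import Tensor, absolute, cat, sqrt
from .cmd_metrics import CmdConfig, batch_cmd, batched_vector_cmd, vector_cmd
from .data import MODALITIES
from .nn import FeedForward, Linear, Module, SelfAttention

__all__ = [
    "RepresentationSet",
    "LossBreakdown",
    "ModalityEncoder",
    "RepresentationModule",
    "intra_sim_loss",
    "intra_diff_loss",
    "inter_loss",
    "recon_loss",
    "total_representation_loss",
]

_PAIRS = (("text", "audio"), ("text", "visual"), ("audio", "visual"))
#: coordinate-axis CMD used by the per-vector contrastive terms
VECTOR_CMD = CmdConfig(max_order=5, range_width=1.0, axis="coordinates")


@dataclass
class RepresentationSet:
    """Per-modality utterance, shared, specific and reconstructed vectors."""

    omega: dict[str, np.ndarray]
    shared: dict[str, np.ndarray]
    specific: dict[str, np.ndarray]
    reconstructed: dict[str, np.ndarray]


@dataclass
class LossBreakdown:
    """Every term of the training objective, with its weight.

    ``l_total`` composes as ``l_task + beta1*l_intra + beta2*l_inter +
    beta3*l_recon`` where ``l_intra = l_intra_sim + l_intra_diff``.
    """

    l_intra_sim: float = 0.0
    l_intra_diff: float = 0.0
    l_inter: float = 0.0
    l_recon: float = 0.0
    l_task: float = 0.0
    beta1: float = 0.7
    beta2: float = 0.8
    beta3: float = 0.5
    lam: float = 0.0

    @property
    def l_intra(self) -> float:
        return self.l_intra_sim + self.l_intra_diff

    @property
    def l_total(self) -> float:
        # composed strictly left-to-right so the reported value is bitwise
        # reproducible from the reported terms
        return (
            self.l_task
            + self.beta1 * self.l_intra
            + self.beta2 * self.l_inter
            + self.beta3 * self.l_recon
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "l_intra_sim": self.l_intra_sim,
            "l_intra_diff": self.l_intra_diff,
            "l_intra": self.l_intra,
            "l_inter": self.l_inter,
            "l_recon": self.l_recon,
            "l_task": self.l_task,
            "l_total": self.l_total,
        }


class ModalityEncoder(Module):
    """Token sequence -> utterance vector.

    L2-normalise each token, project to the model width, apply one
    single-head self-attention block with a residual feed-forward, and
    mean-pool over the sequence.
    """

    def __init__(self, width: int, d_out: int, hidden: int, dropout: float, rng):
        super().__init__()
        self.width = width
        self.proj = Linear(width, d_out, rng)
        self.attn = SelfAttention(d_out, d_out, rng)
        self.ffn = FeedForward(d_out, hidden, d_out, rng, dropout=dropout)

    def __call__(self, tokens: np.ndarray | Tensor) -> Tensor:
        if isinstance(tokens, np.ndarray):
            if tokens.ndim == 2:
                tokens = tokens[None, ...]
            if tokens.shape[-1] != self.width:
                raise ValueError(
                    f"token width {tokens.shape[-1]} != configured width {self.width}"
                )
            norms = np.linalg.norm(tokens, axis=-1, keepdims=True)
            tokens = Tensor(tokens / np.maximum(norms, 1e-12))
        h = self.proj(tokens)
        h = h + self.attn(h)
        h = h + self.ffn(h)
        return h.mean(axis=1)


class RepresentationModule(Module):
    """Shared/specific encoders and the reconstruction decoder.

    The shared encoder is one parameter set applied to every modality's
    utterance vector; the three specific encoders share nothing.
    """

    def __init__(
        self,
        widths: Mapping[str, int],
        d_utterance: int,
        d_shared: int,
        hidden: int,
        dropout: float,
        rng: np.random.Generator,
    ):
        super().__init__()
        self.d_utterance = d_utterance
        self.d_shared = d_shared  # specific width equals shared width
        self.encoders = {
            m: ModalityEncoder(widths[m], d_utterance, hidden, dropout, rng)
            for m in MODALITIES
        }
        self.shared_encoder = FeedForward(d_utterance, hidden, d_shared, rng, dropout)
        self.specific_encoders = {
            m: FeedForward(d_utterance, hidden, d_shared, rng, dropout) for m in MODALITIES
        }
        self.decoder = FeedForward(2 * d_shared, hidden, d_utterance, rng, dropout)

    def encode_modality(self, tokens, modality: str) -> Tensor:
        if modality not in MODALITIES:
            raise ValueError(f"unknown modality {modality!r}")
        return self.encoders[modality](tokens)

    def shared_encode(self, omega: Tensor) -> Tensor:
        return self.shared_encoder(omega)

    def specific_encode(self, omega: Tensor, modality: str) -> Tensor:
        if modality not in MODALITIES:
            raise ValueError(f"unknown modality {modality!r}")
        return self.specific_encoders[modality](omega)

    def decode(self, gamma_s: Tensor, gamma_u: Tensor) -> Tensor:
        return self.decoder(cat([gamma_s, gamma_u], axis=-1))

    def decoder_param_norm_sq(self) -> Tensor:
        total = None
        for p in self.decoder.parameters():
            term = (p.reshape(p.size) ** 2).sum()
            total = term if total is None else total + term
        return total

    def forward(self, batch_tokens: Mapping[str, np.ndarray]):
        """Full representation pass; returns per-modality feature dicts."""
        omega = {m: self.encode_modality(batch_tokens[m], m) for m in MODALITIES}
        shared = {m: self.shared_encode(omega[m]) for m in MODALITIES}
        specific = {m: self.specific_encode(omega[m], m) for m in MODALITIES}
        recon = {m: self.decode(shared[m], specific[m]) for m in MODALITIES}
        return omega, shared, specific, recon


# ---------------------------------------------------------------------------
# losses (accept plain arrays or autodiff tensors)
# ---------------------------------------------------------------------------


def intra_sim_loss(shared: Mapping[str, "np.ndarray | Tensor"], cfg: CmdConfig):
    """Mean pairwise sample-axis CMD between the three shared-feature batches."""
    for m in MODALITIES:
        x = shared[m]
        n = x.shape[0]
        if n < 2:
            raise ValueError("intra_sim_loss needs batch size >= 2")
    total = None
    for m1, m2 in _PAIRS:
        term = batch_cmd(shared[m1], shared[m2], cfg)
        total = term if total is None else total + term
    return total * (1.0 / 3.0)


def _abs_cosine(u, v):
    """Per-row |cos| with zero-norm rows mapped to 0."""
    dot = (u * v).sum(axis=-1)
    nu = sqrt((u**2).sum(axis=-1))
    nv = sqrt((v**2).sum(axis=-1))
    denom = nu * nv
    if isinstance(denom, Tensor):
        if np.any(denom.data < 1e-12):
            warnings.warn("zero-norm vector in cosine term; treating cosine as 0")
        denom = denom.clip_min(1e-12)
    else:
        if np.any(denom < 1e-12):
            warnings.warn("zero-norm vector in cosine term; treating cosine as 0")
        denom = np.maximum(denom, 1e-12)
    return absolute(dot / denom)


def intra_diff_loss(shared: Mapping, specific: Mapping):
    """Orthogonality penalty in [0, 1].

    Per sample: the mean of six absolute cosines — shared vs specific within
    each modality, and specific vs specific across the three modality pairs —
    then averaged over the batch.
    """
    total = None
    for m in MODALITIES:
        term = _abs_cosine(specific[m], shared[m])
        total = term if total is None else total + term
    for m1, m2 in _PAIRS:
        total = total + _abs_cosine(specific[m1], specific[m2])
    return (total * (1.0 / 6.0)).mean()


def inter_loss(
    anchor: Mapping,
    positives: Mapping,
    negatives: Mapping,
    margin: float = 0.2,
    cfg: CmdConfig = VECTOR_CMD,
) -> float:
    """Hinged contrastive loss for a single anchor.

    ``anchor`` maps the six (feature type, modality) keys to vectors;
    ``positives``/``negatives`` map the same keys to (N, d) / (M, d) arrays
    of same-condition / different-condition neighbours. Each key contributes
    ``max(0, margin + mean CMD to positives - mean CMD to negatives)`` and
    the six terms are averaged.
    """
    keys = list(anchor.keys())
    if len(keys) != 6:
        raise ValueError("expected features for 2 feature types x 3 modalities")
    total = 0.0
    for key in keys:
        a = np.asarray(anchor[key], dtype=float)
        pos = np.asarray(positives[key], dtype=float)
        neg = np.asarray(negatives[key], dtype=float)
        if pos.shape[0] < 1 or neg.shape[0] < 1:
            raise ValueError("need at least one positive and one negative")
        d_pos = np.mean([vector_cmd(a, p, cfg) for p in pos])
        d_neg = np.mean([vector_cmd(a, q, cfg) for q in neg])
        total += max(0.0, margin + d_pos - d_neg)
    return total / 6.0


def inter_loss_batch(
    features: Mapping[tuple[str, str], Tensor],
    pos_idx: np.ndarray,
    pos_mask: np.ndarray,
    neg_idx: np.ndarray,
    neg_mask: np.ndarray,
    anchor_mask: np.ndarray,
    margin: float = 0.2,
    cfg: CmdConfig = VECTOR_CMD,
):
    """Vectorised differentiable contrastive loss over an in-batch selection.

    ``features`` maps the six (feature type, modality) keys to (B, d)
    tensors; index/mask arrays come from
    :func:`mmlmh.synthetic.padded_contrastive_indices`. Anchors without both
    a positive and a negative are excluded from the average; if none remain
    the loss is 0 (with a warning).
    """
    n_valid = float(anchor_mask.sum())
    if n_valid == 0:
        warnings.warn("no anchors with both positives and negatives; inter loss = 0")
        return Tensor(0.0)
    b, n_pos = pos_idx.shape
    n_neg = neg_idx.shape[1]
    pos_cnt = np.maximum(pos_mask.sum(axis=1), 1.0)
    neg_cnt = np.maximum(neg_mask.sum(axis=1), 1.0)
    total = None
    for key, feat in features.items():
        anchors = feat.reshape(b, 1, feat.shape[-1])
        pos = feat.take(pos_idx.ravel()).reshape(b, n_pos, feat.shape[-1])
        neg = feat.take(neg_idx.ravel()).reshape(b, n_neg, feat.shape[-1])
        d_pos = (batched_vector_cmd(pos, anchors, cfg) * pos_mask).sum(axis=1) / pos_cnt
        d_neg = (batched_vector_cmd(neg, anchors, cfg) * neg_mask).sum(axis=1) / neg_cnt
        hinge = (d_pos - d_neg + margin).relu()
        total = hinge if total is None else total + hinge
    per_anchor = total * (1.0 / 6.0)
    return (per_anchor * anchor_mask).sum() * (1.0 / n_valid)


def recon_loss(
    omega: Mapping[str, "np.ndarray | Tensor"],
    reconstructed: Mapping[str, "np.ndarray | Tensor"],
    lam: float = 0.0,
    decoder_param_norm_sq=None,
):
    """Batch-mean reconstruction MSE plus the decoder L2 regulariser.

    Per sample: (1/3) sum over modalities of the squared L2 reconstruction
    error; plus ``lam/2`` times the squared decoder parameter norm.
    """
    total = None
    for m in MODALITIES:
        err = ((omega[m] - reconstructed[m]) ** 2).sum(axis=-1)
        total = err if total is None else total + err
    out = (total * (1.0 / 3.0)).mean()
    if lam != 0.0:
        if decoder_param_norm_sq is None:
            raise ValueError("lam != 0 requires the decoder parameter norm")
        out = out + (lam / 2.0) * decoder_param_norm_sq
    return out


def total_representation_loss(parts: LossBreakdown):
    """Weighted composite: beta1*L_intra + beta2*L_inter + beta3*L_recon."""
    if parts.beta1 < 0 or parts.beta2 < 0 or parts.beta3 < 0:
        raise ValueError("loss weights must be non-negative")
    return (
        parts.beta1 * (parts.l_intra_sim + parts.l_intra_diff)
        + parts.beta2 * parts.l_inter
        + parts.beta3 * parts.l_recon
    )
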