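"""Two-stage adaptive fusion of shared and specific modality features.

Stage one works within a modality: the shared and specific feature vectors
are concatenated, read as a two-token sequence, passed through single-head
self-attention and mean-pooled into a fused modality vector ``xi_m``.

Stage two is text-anchored: cross-attention uses the text vector as query
against each non-text modality (with a single key the softmax weight is
exactly 1, so the output reduces to the value projection of the attended
modality — documented, and asserted in tests). A gated network turns each
cross-attention output into a scalar weight ``w_m`` in (0, 1); a calibration
network conditioned on the modality's synthetic/real flag produces
``c_m`` in (0, 1), and the adjusted weights ``w'_m = w_m * c_m`` down-weight
modalities whose synthetic provenance makes them unreliable. The final
fused vector adds a learned projection of the environment context vector
scaled by a learned scalar weight:

    xi_final = xi_text + w'_audio * xi_audio + w'_visual * xi_visual
               + w_env * P_env(e)

Calibration factors are computed for all three modalities but applied only
to the audio and visual weights (text is the anchor and carries weight 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor, cat
from .data import MODALITIES
from .nn import FeedForward, Linear, Module, Parameter, SelfAttention, softmax

__all__ = ["AttentionMap", "FusionState", "FusionModule", "concat_features"]

NON_TEXT = ("audio", "visual")


@dataclass
class AttentionMap:
    """Row-stochastic attention weights and their 1/sqrt(d_k) scale."""

    weights: np.ndarray
    scale: float

    def validate(self, tol: float = 1e-6) -> None:
        sums = self.weights.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=tol):
            raise ValueError("attention rows must sum to 1")
        if self.weights.min() < 0 or self.weights.max() > 1 + tol:
            raise ValueError("attention weights must lie in [0, 1]")


@dataclass
class FusionState:
    """Everything the fusion stage produced for one batch (numpy views)."""

    xi: dict[str, np.ndarray]  # per-modality fused vectors
    cross_attention: dict[str, np.ndarray]
    gates: dict[str, float | np.ndarray]  # w_audio, w_visual
    calibrations: dict[str, np.ndarray]  # c_text, c_audio, c_visual
    adjusted_gates: dict[str, np.ndarray]  # w'_audio, w'_visual
    attention_maps: dict[str, AttentionMap]
    xi_intermediate: np.ndarray
    xi_final: np.ndarray


def concat_features(gamma_s, gamma_u):
    """Ordered concatenation [shared; specific] along the feature axis."""
    if gamma_s is None or gamma_u is None:
        raise ValueError("both shared and specific features are required")
    if isinstance(gamma_s, Tensor) or isinstance(gamma_u, Tensor):
        return cat([gamma_s, gamma_u], axis=-1)
    return np.concatenate([np.asarray(gamma_s), np.asarray(gamma_u)], axis=-1)


class FusionModule(Module):
    """Within-modality self-attention plus adaptive cross-modal gating."""

    def __init__(
        self,
        d_shared: int,
        d_fused: int,
        d_environment: int,
        rng: np.random.Generator,
        calibration_hidden: int = 64,
        dropout: float = 0.2,
    ):
        super().__init__()
        self.d_shared = d_shared
        self.d_fused = d_fused
        # stage one: per-modality self-attention over the 2-token sequence
        self.self_attn = {m: SelfAttention(d_shared, d_fused, rng) for m in MODALITIES}
        # stage two: one cross-attention parameter set, text as anchor query
        self.cross_q = Linear(d_fused, d_fused, rng, bias=False)
        self.cross_k = Linear(d_fused, d_fused, rng, bias=False)
        self.cross_v = Linear(d_fused, d_fused, rng, bias=False)
        self.gate_net = Linear(d_fused, 1, rng)
        # the calibration head carries a weak, slowly accumulating gradient
        # (it only matters on flagged samples); dropout there would drown it
        self.calib_net = FeedForward(d_fused + 1, calibration_hidden, 1, rng, dropout=0.0)
        self.env_proj = Linear(d_environment, d_fused, rng)
        self.env_weight = Parameter(np.asarray(0.1))

    # -- stage one --------------------------------------------------------
    def self_attend(self, omega_m: Tensor, modality: str) -> Tensor:
        """Fused modality vector from the concatenated [shared; specific] pair.

        ``omega_m`` has width 2*d_shared and is read as a two-token
        sequence; attended tokens are mean-pooled to width d_fused.
        """
        b = omega_m.shape[0]
        tokens = omega_m.reshape(b, 2, self.d_shared)
        attended = self.self_attn[modality](tokens)
        return attended.mean(axis=1)

    # -- stage two --------------------------------------------------------
    def cross_attend(self, xi_text: Tensor, xi_m: Tensor, modality: str) -> Tensor:
        """Text-query attention over a single non-text key/value token."""
        if modality == "text":
            raise ValueError("text is the anchor modality; cross-attend to audio/visual")
        if modality not in NON_TEXT:
            raise ValueError(f"unknown modality {modality!r}")
        b = xi_text.shape[0]
        q = self.cross_q(xi_text).reshape(b, 1, self.d_fused)
        k = self.cross_k(xi_m).reshape(b, 1, self.d_fused)
        v = self.cross_v(xi_m).reshape(b, 1, self.d_fused)
        logits = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.d_fused))
        att = softmax(logits, axis=-1)  # single key: weight exactly 1
        self._last_cross_attention = att.data.copy()
        return (att @ v).reshape(b, self.d_fused)

    def gate(self, ca_out: Tensor) -> Tensor:
        """Scalar fusion weight in (0, 1) from a cross-attention output."""
        return self.gate_net(ca_out).sigmoid().reshape(ca_out.shape[0])

    def calibrate(self, xi_m: Tensor, s_m: np.ndarray) -> Tensor:
        """Synthetic-data calibration factor in (0, 1).

        ``s_m`` is the per-sample binary synthetic/real flag for the
        modality, appended to the fused vector as an input feature.
        """
        s_m = np.asarray(s_m)
        if not np.all(np.isin(s_m, (0, 1))):
            raise ValueError("synthetic flag must be binary")
        inp = cat([xi_m, Tensor(s_m.reshape(-1, 1).astype(float))], axis=-1)
        return self.calib_net(inp).sigmoid().reshape(xi_m.shape[0])

    def forward(
        self,
        shared: dict[str, Tensor],
        specific: dict[str, Tensor],
        flags: np.ndarray,
        environment: np.ndarray,
        adaptive: bool = True,
        calibration: bool = True,
        use_environment: bool = True,
    ) -> tuple[Tensor, FusionState]:
        """Run both fusion stages for a batch; returns (xi_final, state).

        Ablations: ``adaptive=False`` fixes all gates at 1;
        ``calibration=False`` fixes all calibration factors at 1;
        ``use_environment=False`` drops the environment term.
        """
        xi: dict[str, Tensor] = {}
        att_maps: dict[str, AttentionMap] = {}
        for m in MODALITIES:
            omega_m = concat_features(shared[m], specific[m])
            xi[m] = self.self_attend(omega_m, m)
            att_maps[m] = AttentionMap(
                weights=self.self_attn[m].last_attention, scale=1.0 / np.sqrt(self.d_fused)
            )

        ca: dict[str, Tensor] = {}
        gates: dict[str, Tensor] = {}
        b = xi["text"].shape[0]
        for j, m in enumerate(NON_TEXT):
            ca[m] = self.cross_attend(xi["text"], xi[m], m)
            att_maps[f"cross_{m}"] = AttentionMap(
                weights=self._last_cross_attention, scale=1.0 / np.sqrt(self.d_fused)
            )
            gates[m] = self.gate(ca[m]) if adaptive else Tensor(np.ones(b))

        calib: dict[str, Tensor] = {}
        for j, m in enumerate(MODALITIES):
            if calibration:
                calib[m] = self.calibrate(xi[m], flags[:, j])
            else:
                calib[m] = Tensor(np.ones(b))

        adjusted = {m: gates[m] * calib[m] for m in NON_TEXT}

        def weighted(w: Tensor, v: Tensor) -> Tensor:
            return v * w.reshape(w.shape[0], 1)

        xi_mid = xi["text"] + weighted(gates["audio"], xi["audio"]) + weighted(
            gates["visual"], xi["visual"]
        )
        xi_final = xi["text"] + weighted(adjusted["audio"], xi["audio"]) + weighted(
            adjusted["visual"], xi["visual"]
        )
        if use_environment:
            env = self.env_proj(Tensor(np.asarray(environment, dtype=float)))
            xi_final = xi_final + env * self.env_weight

        state = FusionState(
            xi={m: xi[m].data.copy() for m in MODALITIES},
            cross_attention={m: ca[m].data.copy() for m in NON_TEXT},
            gates={m: gates[m].data.copy() for m in NON_TEXT},
            calibrations={m: calib[m].data.copy() for m in MODALITIES},
            adjusted_gates={m: adjusted[m].data.copy() for m in NON_TEXT},
            attention_maps=att_maps,
            xi_intermediate=xi_mid.data.copy(),
            xi_final=xi_final.data.copy(),
        )
        return xi_final, state
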