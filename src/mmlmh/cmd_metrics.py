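"""Central moment discrepancy (CMD) between empirical feature distributions.

CMD_K compares two empirical distributions through their first K moments:

    CMD_K(X, Y) = (1/|b-a|) ||m1(X) - m1(Y)||_2
                  + sum_{k=2..K} (1/|b-a|^k) ||C_k(X) - C_k(Y)||_2

where m1 is the per-dimension mean and C_k the per-dimension order-k central
moment (divisor n). It is symmetric, non-negative, zero iff the first K
moment profiles coincide, and with K=1 and unit range width it reduces to
the Euclidean distance between mean vectors.

Two axis conventions are supported and matter for how the losses use it:

* ``axis="samples"``: rows of a matrix are observations, columns are feature
  dimensions — the batch-level usage in the shared-feature similarity loss.
* ``axis="coordinates"``: a single vector's coordinates are treated as scalar
  observations of a one-dimensional distribution — the per-sample usage in
  the contrastive inter-sample loss, where a lone vector has no sample axis.

The representation space here is unbounded, so the normalising range width
|b - a| defaults to 1 (plain central-moment differences); it is configurable
for bounded feature spaces.

The arithmetic is written against a minimal dispatching surface so the same
code runs on plain numpy arrays (exact, used by the public API and tests)
and on autodiff tensors (used inside the training losses).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tensor import Tensor, absolute, sqrt

__all__ = [
    "MomentProfile",
    "CmdConfig",
    "central_moments",
    "cmd",
    "vector_cmd",
    "batched_vector_cmd",
    "batch_cmd",
    "cmd_brute_force",
]


@dataclass(frozen=True)
class MomentProfile:
    """Per-dimension moment vector of one empirical distribution.

    `values[j]` is the mean (order 1) or the order-k central moment
    (order >= 2, computed about the empirical mean, divisor n) of feature
    dimension j.
    """

    order: int
    values: np.ndarray

    def __post_init__(self):
        if self.order < 1:
            raise ValueError(f"moment order must be >= 1, got {self.order}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("moment values must be finite")


@dataclass(frozen=True)
class CmdConfig:
    """CMD settings: highest order K, range width |b-a|, observation axis."""

    max_order: int = 5
    range_width: float = 1.0
    axis: str = "samples"

    def __post_init__(self):
        if self.max_order < 1:
            raise ValueError(f"max_order must be >= 1, got {self.max_order}")
        if self.range_width <= 0:
            raise ValueError(f"range_width must be > 0, got {self.range_width}")
        if self.axis not in ("samples", "coordinates"):
            raise ValueError(f"axis must be 'samples' or 'coordinates', got {self.axis!r}")


DEFAULT_CMD = CmdConfig()


def _validate_matrix(X: np.ndarray, name: str) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError(f"{name} must be 2-D (observations x dimensions), got ndim={X.ndim}")
    if X.shape[0] < 1 or X.shape[1] < 1:
        raise ValueError(f"{name} must be non-empty, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError(f"{name} contains non-finite entries")
    return X


def central_moments(X: np.ndarray, order: int) -> MomentProfile:
    """Per-dimension empirical moments of the rows of ``X``.

    Order 1 is the mean; order k >= 2 is the mean of (x - mean)^k with
    divisor n (plain population moments).
    """
    X = _validate_matrix(X, "X")
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    if order == 1:
        values = X.mean(axis=0)
    else:
        centered = X - X.mean(axis=0, keepdims=True)
        values = (centered**order).mean(axis=0)
    return MomentProfile(order=order, values=values)


def _cmd_core(X, Y, K: int, range_width: float, obs_axis: int, reduce_all: bool = True):
    """CMD over `obs_axis`; runs on ndarrays and autodiff Tensors alike.

    With ``reduce_all`` the moment-profile norm sums over every remaining
    axis (the matrix case: one scalar out). Without it only the collapsed
    observation axis is reduced, so batched single-vector usage (shapes like
    (B, N, d) against (B, 1, d) with ``obs_axis=-1``) vectorises into one
    CMD value per leading index.
    """
    mx = X.mean(axis=obs_axis, keepdims=True)
    my = Y.mean(axis=obs_axis, keepdims=True)

    def profile_norm(diff):
        # `diff` keeps the observation axis with size 1
        sq = diff**2
        return sqrt(sq.sum(axis=None) if reduce_all else sq.sum(axis=obs_axis))

    total = profile_norm(mx - my) * (1.0 / range_width)
    if K >= 2:
        cx = X - mx
        cy = Y - my
        px, py = cx, cy
        for k in range(2, K + 1):
            px = px * cx
            py = py * cy
            diff = px.mean(axis=obs_axis, keepdims=True) - py.mean(axis=obs_axis, keepdims=True)
            total = total + profile_norm(diff) * (range_width**-k)
    return total


def cmd(X: np.ndarray, Y: np.ndarray, cfg: CmdConfig = DEFAULT_CMD) -> float:
    """CMD_K between the empirical distributions of two matrices.

    With ``cfg.axis == "samples"`` rows are observations and the moment
    profiles live in feature space; ``"coordinates"`` transposes that
    reading (each column treated as an observation of the row index).
    """
    X = _validate_matrix(X, "X")
    Y = _validate_matrix(Y, "Y")
    ax = 0 if cfg.axis == "samples" else 1
    other = 1 - ax
    if X.shape[other] != Y.shape[other]:
        raise ValueError(
            f"dimension mismatch on compared axis: {X.shape} vs {Y.shape} (axis={cfg.axis})"
        )
    return float(_cmd_core(X, Y, cfg.max_order, cfg.range_width, ax))


def vector_cmd(u: np.ndarray, v: np.ndarray, cfg: CmdConfig = DEFAULT_CMD) -> float:
    """CMD between two single vectors read as 1-D empirical distributions.

    Each vector's coordinates are scalar observations; higher central
    moments therefore need length >= 2.
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.ndim != 1 or v.ndim != 1:
        raise ValueError("vector_cmd expects 1-D vectors")
    if u.shape[0] < 2 or v.shape[0] < 2:
        raise ValueError("vectors must have length >= 2 (higher moments undefined)")
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
        raise ValueError("inputs contain non-finite entries")
    return float(_cmd_core(u[None, :], v[None, :], cfg.max_order, cfg.range_width, 1))


def batched_vector_cmd(U, V, cfg: CmdConfig = DEFAULT_CMD):
    """Vectorised/differentiable `vector_cmd` over leading batch axes.

    ``U`` and ``V`` are arrays or Tensors broadcastable against each other
    with vector coordinates on the last axis; returns one CMD value per
    broadcast leading index (the last axis is reduced away).
    """
    return _cmd_core(U, V, cfg.max_order, cfg.range_width, -1, reduce_all=False)


def batch_cmd(X, Y, cfg: CmdConfig = DEFAULT_CMD):
    """Differentiable sample-axis CMD between two (n x d) batches."""
    return _cmd_core(X, Y, cfg.max_order, cfg.range_width, 0 if cfg.axis == "samples" else 1)


def cmd_brute_force(X: np.ndarray, Y: np.ndarray, cfg: CmdConfig = DEFAULT_CMD) -> float:
    """Independent loop-based CMD oracle (no vectorisation), for testing.

    Walks dimensions and orders with explicit Python loops; kept free of any
    code shared with :func:`cmd`.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if cfg.axis == "coordinates":
        X, Y = X.T, Y.T
    n_x, d = X.shape
    n_y, d_y = Y.shape
    if d != d_y:
        raise ValueError("dimension mismatch")

    def moment(M, n_rows, j, k):
        mean = 0.0
        for i in range(n_rows):
            mean += M[i, j]
        mean /= n_rows
        if k == 1:
            return mean
        acc = 0.0
        for i in range(n_rows):
            acc += (M[i, j] - mean) ** k
        return acc / n_rows

    total = 0.0
    for k in range(1, cfg.max_order + 1):
        sq = 0.0
        for j in range(d):
            diff = moment(X, n_x, j, k) - moment(Y, n_y, j, k)
            sq += diff * diff
        total += np.sqrt(sq) / cfg.range_width**k
    return float(total)
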