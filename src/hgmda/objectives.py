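"""Training objectives: NT-Xent contrastive loss, L1/L2/Huber, and their sum.

The model is trained with an integrated objective: a robust reconstruction
loss (Huber by default) on the sampled microbe-disease pairs, plus a
temperature-scaled contrastive term that pulls each node's two graph-view
embeddings (KNN view vs K-means view) together while pushing apart the
embeddings of other nodes.  All losses are differentiable through the
package's autodiff tensors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, as_tensor, concat, where

__all__ = [
    "LossConfig",
    "cosine_similarity",
    "contrastive_loss",
    "l1_loss",
    "l2_loss",
    "huber_loss",
    "reconstruction_loss",
    "combined_loss",
]


@dataclass
class LossConfig:
    """Which reconstruction loss to use and how the terms are weighted.

    ``delta`` is the Huber threshold separating the quadratic and linear
    regimes; ``temperature`` the NT-Xent temperature C (smaller = sharper
    discrimination); ``lambda_cl`` the weight of the contrastive term.
    """

    loss_kind: str = "huber"
    delta: float = 1.0
    temperature: float = 0.1
    lambda_cl: float = 1.0
    include_self: bool = False  # keep the anchor in the NT-Xent denominator

    def __post_init__(self):
        if self.loss_kind not in ("l1", "l2", "huber"):
            raise ValueError(f"loss_kind must be l1|l2|huber, got {self.loss_kind!r}")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.lambda_cl < 0:
            raise ValueError("lambda_cl must be nonnegative")


def cosine_similarity(z_i, z_j) -> float:
    """Normalized dot product z_i . z_j / (||z_i|| ||z_j||), in [-1, 1]."""
    z_i = np.asarray(z_i, dtype=float).ravel()
    z_j = np.asarray(z_j, dtype=float).ravel()
    ni, nj = np.linalg.norm(z_i), np.linalg.norm(z_j)
    if ni == 0.0 or nj == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(z_i @ z_j / (ni * nj))


def _row_normalize(Z: Tensor, eps: float = 1e-12) -> Tensor:
    # eps inside the sqrt keeps the gradient finite at exact-zero rows
    norms = ((Z * Z).sum(axis=1, keepdims=True) + eps).sqrt()
    return Z / norms


def contrastive_loss(Z1, Z2, temperature: float = 0.1,
                     include_self: bool = False) -> Tensor:
    """NT-Xent loss between two views of the same N nodes.

    Row i of ``Z1`` and row i of ``Z2`` form a positive pair in a batch of
    2N embeddings.  For every anchor, the cross-entropy of its positive
    against all other batch members (cosine similarities scaled by the
    temperature) is computed; the loss is symmetrised over both directions
    and averaged over all 2N anchors.  By SimCLR convention the anchor itself
    is excluded from the denominator; ``include_self=True`` keeps it.
    """
    Z1, Z2 = as_tensor(Z1), as_tensor(Z2)
    if Z1.shape != Z2.shape:
        raise ValueError(f"view shapes differ: {Z1.shape} vs {Z2.shape}")
    N = Z1.shape[0]
    if N < 2:
        raise ValueError("contrastive loss needs a batch of at least 2 nodes")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    # zero rows (e.g. a dead ReLU unit row early in training) are mapped to
    # the zero vector by the eps-guarded normalisation: similarity 0 to all
    Z = _row_normalize(concat([Z1, Z2], axis=0))
    sim = (Z @ Z.T) * (1.0 / temperature)  # (2N, 2N) cosine / C
    if not include_self:
        # push the anchor's own term far below the batch range before LSE
        mask = np.eye(2 * N, dtype=bool)
        sim = where(mask, sim - 1e9, sim)
    denom = sim.logsumexp(axis=1)  # (2N,)
    idx = np.arange(2 * N)
    partner = np.concatenate([idx[N:], idx[:N]])
    pos = sim[idx, partner]
    return (denom - pos).mean()


def l1_loss(y, yhat) -> Tensor:
    """Mean absolute error."""
    y, yhat = as_tensor(y), as_tensor(yhat)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    return (y - yhat).abs().mean()


def l2_loss(y, yhat) -> Tensor:
    """Mean squared error."""
    y, yhat = as_tensor(y), as_tensor(yhat)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    return ((y - yhat) ** 2.0).mean()


def huber_loss(y, yhat, delta: float = 1.0) -> Tensor:
    """Mean Huber loss: 0.5 a^2 for |a| <= delta, delta(|a| - delta/2) beyond."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    y, yhat = as_tensor(y), as_tensor(yhat)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    a = y - yhat
    abs_a = a.abs()
    quad = (a * a) * 0.5
    lin = (abs_a - 0.5 * delta) * delta
    return where(np.abs(np.asarray(a)) <= delta, quad, lin).mean()


def reconstruction_loss(y, yhat, config: LossConfig) -> Tensor:
    if config.loss_kind == "l1":
        return l1_loss(y, yhat)
    if config.loss_kind == "l2":
        return l2_loss(y, yhat)
    return huber_loss(y, yhat, config.delta)


def combined_loss(scores, labels, Z1_micro, Z2_micro, Z1_dis, Z2_dis,
                  config: LossConfig) -> Tensor:
    """Integrated objective: reconstruction + lambda_cl * (CL_micro + CL_dis).

    ``scores`` are the predictions at the sampled pairs, ``labels`` their 0/1
    targets; the contrastive terms act on the two view embeddings of each
    entity type.  With ``lambda_cl == 0`` this is exactly the reconstruction
    loss (the contrastive-ablation path).
    """
    total = reconstruction_loss(as_tensor(labels), as_tensor(scores), config)
    if config.lambda_cl > 0:
        cl = contrastive_loss(Z1_micro, Z2_micro, config.temperature, config.include_self) \
            + contrastive_loss(Z1_dis, Z2_dis, config.temperature, config.include_self)
        total = total + config.lambda_cl * cl
    return total
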