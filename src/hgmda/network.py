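"""Forward model: hypergraph convolution, channel attention, Transformer,
projection, and pair scoring.

Per entity type (microbes, diseases) the model runs two hypergraph
convolution branches — one on the KNN-neighbourhood view, one on the K-means
cluster view — producing two embeddings of each node.  A squeeze-and-
excitation style channel attention block weighs the two views, the gated
embeddings are concatenated and refined by a Transformer encoder (each node a
token, no positional encoding since nodes are unordered), and a fully
connected layer projects into the shared embedding space.  The association
score of a (microbe, disease) pair is the sigmoid of the inner product of
their embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ._autodiff import Tensor, as_tensor, concat, glorot_uniform
from .graphs import HypergraphView

__all__ = [
    "ModelParams",
    "ModelDims",
    "init_model",
    "hgcn_layer",
    "channel_attention",
    "transformer_encode",
    "project",
    "score_pairs",
    "forward",
]

_VIEWS = ("knn", "kmeans")
_ENTITIES = ("microbe", "disease")


@dataclass
class ModelDims:
    """Layer widths.  ``d_view`` is each branch's output width; the
    Transformer operates at ``2 * d_view`` (the two views concatenated)."""

    d_in_microbe: int
    d_in_disease: int
    d_hidden: int = 64
    d_view: int = 32
    d_embed: int = 64
    d_attn_hidden: int = 8

    @property
    def d_model(self) -> int:
        return 2 * self.d_view


@dataclass
class ModelParams:
    """All learnable tensors plus the hyperparameter record that built them."""

    hgcn_weights: dict[str, dict[str, list[Tensor]]]
    attn_mlp: dict[str, tuple[Tensor, Tensor, Tensor, Tensor]]
    transformer: dict[str, list[dict[str, Tensor]]]
    projector: dict[str, tuple[Tensor, Tensor]]
    dims: ModelDims
    hyperparams: dict[str, Any] = field(default_factory=dict)

    def all_tensors(self) -> list[Tensor]:
        out: list[Tensor] = []
        for ent in _ENTITIES:
            for view in _VIEWS:
                out.extend(self.hgcn_weights[ent][view])
            out.extend(self.attn_mlp[ent])
            for layer in self.transformer[ent]:
                out.extend(layer.values())
            out.extend(self.projector[ent])
        return out


def _zeros(*shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def _ones(*shape) -> Tensor:
    return Tensor(np.ones(shape), requires_grad=True)


def init_model(dims: ModelDims, n_head: int = 8, nlayer: int = 2,
               seed: int = 0, hyperparams: dict | None = None,
               proj_gain: float = 0.1) -> ModelParams:
    """Glorot-uniform initialisation of every weight under a fixed seed."""
    if dims.d_model % n_head != 0:
        raise ValueError(f"d_model={dims.d_model} not divisible by n_head={n_head}")
    rng = np.random.default_rng(seed)
    hgcn: dict[str, dict[str, list[Tensor]]] = {}
    attn: dict[str, tuple] = {}
    trans: dict[str, list[dict[str, Tensor]]] = {}
    proj: dict[str, tuple] = {}
    d_in = {"microbe": dims.d_in_microbe, "disease": dims.d_in_disease}
    dm = dims.d_model
    for ent in _ENTITIES:
        hgcn[ent] = {
            view: [
                glorot_uniform(rng, d_in[ent], dims.d_hidden),
                glorot_uniform(rng, dims.d_hidden, dims.d_view),
            ]
            for view in _VIEWS
        }
        attn[ent] = (
            glorot_uniform(rng, dims.d_attn_hidden, 2),  # W1
            _zeros(dims.d_attn_hidden),                  # b1
            glorot_uniform(rng, 2, dims.d_attn_hidden),  # W2
            _zeros(2),                                   # b2
        )
        layers = []
        for _ in range(nlayer):
            layers.append({
                "ln1_g": _ones(dm), "ln1_b": _zeros(dm),
                "Wq": glorot_uniform(rng, dm, dm), "bq": _zeros(dm),
                "Wk": glorot_uniform(rng, dm, dm), "bk": _zeros(dm),
                "Wv": glorot_uniform(rng, dm, dm), "bv": _zeros(dm),
                "Wo": glorot_uniform(rng, dm, dm), "bo": _zeros(dm),
                "ln2_g": _ones(dm), "ln2_b": _zeros(dm),
                "Wf1": glorot_uniform(rng, dm, 4 * dm), "bf1": _zeros(4 * dm),
                "Wf2": glorot_uniform(rng, 4 * dm, dm), "bf2": _zeros(dm),
            })
        trans[ent] = layers
        # Small-gain head: the pair score is a sigmoid of a d_embed-dim inner
        # product, so a full-scale Glorot head starts deep in saturation.
        # Scaling the projection weights keeps initial scores near 0.5.
        Wp = glorot_uniform(rng, dm, dims.d_embed)
        Wp.data *= proj_gain
        proj[ent] = (Wp, _zeros(dims.d_embed))
    hp = dict(hyperparams or {})
    hp.setdefault("n_head", n_head)
    hp.setdefault("nlayer", nlayer)
    return ModelParams(hgcn, attn, trans, proj, dims, hp)


def hgcn_layer(L, X, W_theta) -> Tensor:
    """One hypergraph convolution: ReLU(L X W_theta)."""
    L, X, W_theta = as_tensor(L), as_tensor(X), as_tensor(W_theta)
    if L.shape[1] != X.shape[0] or X.shape[1] != W_theta.shape[0]:
        raise ValueError(
            f"non-conformable shapes: L{L.shape} X{X.shape} W{W_theta.shape}"
        )
    return (L @ X @ W_theta).relu()


def channel_attention(X1, X2, attn_mlp) -> tuple[Tensor, Tensor, Tensor]:
    """Squeeze-and-excitation over the two view embeddings.

    Each view is one channel: squeeze to its global mean, pass the 2-vector
    through a two-layer MLP (ReLU then sigmoid), and rescale each view by its
    gate.  Returns the two gated views and the gate vector s in (0, 1)^2.
    """
    X1, X2 = as_tensor(X1), as_tensor(X2)
    if X1.shape != X2.shape:
        raise ValueError(f"view shapes differ: {X1.shape} vs {X2.shape}")
    W1, b1, W2, b2 = (as_tensor(p) for p in attn_mlp)
    z = concat([X1.mean().reshape(1), X2.mean().reshape(1)], axis=0)  # (2,)
    h = (W1 @ z + b1).relu()
    s = (W2 @ h + b2).sigmoid()
    return X1 * s[0], X2 * s[1], s


def _attention_head(Q: Tensor, K: Tensor, V: Tensor) -> Tensor:
    dk = Q.shape[1]
    scores = (Q @ K.T) * (1.0 / np.sqrt(dk))
    return scores.softmax(axis=1) @ V


def transformer_encode(X, layers: list[dict[str, Tensor]], n_head: int,
                       dropout: float = 0.0,
                       rng: np.random.Generator | None = None,
                       training: bool = False) -> Tensor:
    """Pre-norm Transformer encoder; every node is a token, no positional
    encoding (node order is arbitrary, so the map is permutation-equivariant).
    """
    X = as_tensor(X)
    dm = X.shape[1]
    if dm % n_head != 0:
        raise ValueError(f"model width {dm} not divisible by n_head={n_head}")
    dk = dm // n_head
    if training and dropout > 0 and rng is None:
        raise ValueError("training-mode dropout requires an rng")

    def drop(t: Tensor) -> Tensor:
        return t.dropout(dropout, rng, training)

    for p in layers:
        Xn = X.layer_norm(p["ln1_g"], p["ln1_b"])
        Q = Xn @ p["Wq"] + p["bq"]
        K = Xn @ p["Wk"] + p["bk"]
        V = Xn @ p["Wv"] + p["bv"]
        heads = [
            _attention_head(Q[:, h * dk:(h + 1) * dk],
                            K[:, h * dk:(h + 1) * dk],
                            V[:, h * dk:(h + 1) * dk])
            for h in range(n_head)
        ]
        attn_out = concat(heads, axis=1) @ p["Wo"] + p["bo"]
        X = X + drop(attn_out)
        Xn = X.layer_norm(p["ln2_g"], p["ln2_b"])
        ff = ((Xn @ p["Wf1"] + p["bf1"]).relu()) @ p["Wf2"] + p["bf2"]
        X = X + drop(ff)
    return X


def project(X, projector) -> Tensor:
    """Affine projection into the shared embedding space (no activation)."""
    Wp, bp = (as_tensor(p) for p in projector)
    X = as_tensor(X)
    if X.shape[1] != Wp.shape[0]:
        raise ValueError(f"cannot project {X.shape} with {Wp.shape}")
    return X @ Wp + bp


def score_pairs(Z_micro, Z_dis) -> Tensor:
    """sigmoid(Z_micro @ Z_dis^T): association score for every pair."""
    Z_micro, Z_dis = as_tensor(Z_micro), as_tensor(Z_dis)
    if Z_micro.shape[1] != Z_dis.shape[1]:
        raise ValueError(
            f"embedding widths differ: {Z_micro.shape[1]} vs {Z_dis.shape[1]}"
        )
    return (Z_micro @ Z_dis.T).sigmoid()


def forward(
    features: dict[str, np.ndarray],
    views: dict[str, tuple[HypergraphView, HypergraphView]],
    params: ModelParams,
    mode: str = "eval",
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
    use_attention: bool = True,
) -> tuple[Tensor, dict[str, tuple[Tensor, Tensor]]]:
    """Full pipeline for both entity types.

    ``features[ent]`` is the fused node-feature matrix; ``views[ent]`` the
    (KNN, K-means) hypergraph views.  Returns the score matrix and, per
    entity, the two pre-attention view embeddings (the contrastive-loss
    inputs).  Dropout fires only in train mode.  With ``use_attention=False``
    the gating is skipped and the raw view embeddings are concatenated (the
    attention-ablation path).
    """
    if mode not in ("train", "eval"):
        raise ValueError(f"mode must be train|eval, got {mode!r}")
    training = mode == "train"
    embeddings: dict[str, Tensor] = {}
    view_pairs: dict[str, tuple[Tensor, Tensor]] = {}
    for ent in _ENTITIES:
        X = as_tensor(features[ent])
        branch: list[Tensor] = []
        for view_tag, view in zip(_VIEWS, views[ent]):
            L = Tensor(view.L)
            h = X
            weights = params.hgcn_weights[ent][view_tag]
            for li, W in enumerate(weights):
                h = hgcn_layer(L, h, W)
                if training and dropout > 0 and li < len(weights) - 1:
                    h = h.dropout(dropout, rng, training)
            branch.append(h)
        Z1, Z2 = branch
        view_pairs[ent] = (Z1, Z2)
        if use_attention:
            G1, G2, _ = channel_attention(Z1, Z2, params.attn_mlp[ent])
        else:
            G1, G2 = Z1, Z2
        joint = concat([G1, G2], axis=1)
        encoded = transformer_encode(
            joint, params.transformer[ent], params.hyperparams["n_head"],
            dropout=dropout, rng=rng, training=training,
        )
        embeddings[ent] = project(encoded, params.projector[ent])
    scores = score_pairs(embeddings["microbe"], embeddings["disease"])
    return scores, view_pairs
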