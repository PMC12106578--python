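"""CE-GCN forward computation.

Per age snapshot, a graph convolution propagates one-hot structural features
through the symmetric-normalized adjacency D̃^{-1/2}(A+I)D̃^{-1/2}; across the
age axis, each layer's weight matrix is the hidden state of a matrix-valued
GRU whose input is a top-k-pooled summary of that layer's node embeddings.
A two-layer MLP scores unordered node pairs (symmetrized over the two
concatenation orders), trained with class-weighted binary cross-entropy on
logits.

Because node embeddings are n×d_l while the recurrent state W_l is
d_l×d_{l+1}, the embedding matrix is pooled down to k = d_{l+1} rows with a
learned scoring vector and a tanh gate, then transposed, so the GRU's gate
equations are conformable — the standard construction for evolving GCN
weights with node-feature input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .cohort import GraphSnapshot
from .features import _check_binary_symmetric

_ACTIVATIONS = {
    "relu": ad.relu,
    "tanh": ad.tanh,
    "identity": lambda t: t,
}


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    dims[0] is the one-hot feature width d (vocabulary size); subsequent
    entries are GCN layer widths.  The final GCN layer uses the identity
    activation so raw embeddings feed the pair scorer.
    """

    dims: list[int]
    activation: str = "relu"
    mlp_hidden: int = 32
    pos_weight: float = 10.0
    evolve_layers: str = "all"  # "all" | "first" | "none"
    seed: int = 0

    @property
    def n_layers(self) -> int:
        return len(self.dims) - 1

    def layer_evolves(self, layer: int) -> bool:
        if self.evolve_layers == "all":
            return True
        if self.evolve_layers == "first":
            return layer == 0
        return False

    def layer_activation(self, layer: int):
        name = self.activation if layer < self.n_layers - 1 else "identity"
        return _ACTIVATIONS[name]


def normalize_adjacency(snapshot: GraphSnapshot | np.ndarray) -> np.ndarray:
    """Symmetric normalization D̃^{-1/2} (A+I) D̃^{-1/2} of a binary adjacency.

    Self-loops guarantee every degree >= 1, so isolated nodes are safe; the
    result is symmetric with spectrum contained in [-1, 1].
    """
    adj = snapshot.adjacency if isinstance(snapshot, GraphSnapshot) else np.asarray(snapshot)
    _check_binary_symmetric(adj)
    a_tilde = adj.astype(np.float64) + np.eye(adj.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a_tilde.sum(axis=1))
    return a_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_parameters(config: ModelConfig) -> dict[str, Tensor]:
    """Glorot-uniform initial GCN weights, GRU cells, pooling vectors, MLP."""
    rng = np.random.default_rng(config.seed)
    params: dict[str, Tensor] = {}
    dims = config.dims
    for l in range(config.n_layers):
        d_in, d_out = dims[l], dims[l + 1]
        params[f"W0_{l}"] = ad.parameter(_glorot(rng, d_in, d_out))
        if config.layer_evolves(l):
            params[f"pool_p_{l}"] = ad.parameter(
                rng.uniform(-1, 1, size=(d_in, 1)) / np.sqrt(d_in))
            for gate in ("Z", "R", "W"):
                params[f"gru{l}_U{gate}"] = ad.parameter(_glorot(rng, d_in, d_in))
                params[f"gru{l}_C{gate}"] = ad.parameter(_glorot(rng, d_in, d_in))
                # Update-gate bias starts negative so the weight trajectory
                # begins close to the static W0 and learns when to evolve
                # (the recurrent analogue of LSTM forget-bias initialization).
                bias0 = -3.0 if gate == "Z" else 0.0
                params[f"gru{l}_B{gate}"] = ad.parameter(np.full((d_in, 1), bias0))
    h = dims[-1]
    params["mlp_W1"] = ad.parameter(_glorot(rng, 2 * h, config.mlp_hidden))
    params["mlp_b1"] = ad.parameter(np.zeros((1, config.mlp_hidden)))
    params["mlp_W2"] = ad.parameter(_glorot(rng, config.mlp_hidden, 1))
    params["mlp_b2"] = ad.parameter(np.zeros((1, 1)))
    return params


def gcn_forward(norm_adj, embeddings, weight, activation=ad.relu) -> Tensor:
    """One propagation step: activation(Â · H · W)."""
    norm_adj = norm_adj if isinstance(norm_adj, Tensor) else ad.constant(norm_adj)
    embeddings = embeddings if isinstance(embeddings, Tensor) else ad.constant(embeddings)
    weight = weight if isinstance(weight, Tensor) else ad.constant(weight)
    if norm_adj.shape[1] != embeddings.shape[0] or embeddings.shape[1] != weight.shape[0]:
        raise ValueError(
            f"shape mismatch: adj {norm_adj.shape}, H {embeddings.shape}, W {weight.shape}")
    return activation(norm_adj @ embeddings @ weight)


def summarize_embeddings(embeddings, pool_vector, k: int) -> Tensor:
    """Deterministic learned top-k pooling of an n×d embedding matrix.

    Each row is scored by y = H p / ||p||; the k highest-scoring rows (ties
    broken by ascending row index) are kept, each scaled by tanh(y).  If
    n < k, the result is zero-padded to k rows.  Gradients flow through both
    the retained rows and the scoring vector; the selection itself is
    treated as constant.
    """
    embeddings = embeddings if isinstance(embeddings, Tensor) else ad.constant(embeddings)
    pool_vector = pool_vector if isinstance(pool_vector, Tensor) else ad.constant(pool_vector)
    norm = ad.sqrt((pool_vector * pool_vector).sum()) + 1e-12
    y = (embeddings @ pool_vector) / norm            # n×1
    gated = embeddings * ad.tanh(y)                  # broadcast over columns
    order = np.argsort(-y.value.ravel(), kind="stable")
    n = embeddings.shape[0]
    if n >= k:
        return ad.take_rows(gated, order[:k])
    return ad.pad_rows(ad.take_rows(gated, order), k)


def gru_weight_update(summary, prev_weight, params: dict[str, Tensor],
                      layer: int) -> tuple[Tensor, dict[str, Tensor]]:
    """Matrix GRU step: evolve a GCN weight matrix from the pooled summary.

    Z = σ(U_Z X + C_Z W_prev + B_Z)         (update gate)
    R = σ(U_R X + C_R W_prev + B_R)         (reset gate)
    W̃ = tanh(U_W X + C_W (R ∘ W_prev) + B_W)
    W = (1 − Z) ∘ W_prev + Z ∘ W̃

    Every entry of the result lies between the corresponding entries of
    W_prev and W̃ (elementwise convex combination).
    """
    summary = summary if isinstance(summary, Tensor) else ad.constant(summary)
    prev_weight = prev_weight if isinstance(prev_weight, Tensor) else ad.constant(prev_weight)
    p = {g: (params[f"gru{layer}_U{g}"], params[f"gru{layer}_C{g}"],
             params[f"gru{layer}_B{g}"]) for g in ("Z", "R", "W")}
    uz, cz, bz = p["Z"]
    ur, cr, br = p["R"]
    uw, cw, bw = p["W"]
    update = ad.sigmoid(uz @ summary + cz @ prev_weight + bz)
    reset = ad.sigmoid(ur @ summary + cr @ prev_weight + br)
    candidate = ad.tanh(uw @ summary + cw @ (reset * prev_weight) + bw)
    new_weight = (1.0 - update) * prev_weight + update * candidate
    if not np.isfinite(new_weight.value).all():
        raise FloatingPointError(f"non-finite GRU update at layer {layer}")
    gates = {"update": update, "reset": reset, "candidate": candidate}
    return new_weight, gates


def forward_sequence(norm_adjs: list[np.ndarray], feature_mats: list[np.ndarray],
                     params: dict[str, Tensor], config: ModelConfig,
                     n_steps: int | None = None) -> list[Tensor]:
    """Run the recurrent forward pass, returning final-layer embeddings per age.

    The weight trajectory starts at W0_l; at each age every evolving layer
    first updates its weight from the summary of its *input* embeddings,
    then applies the graph convolution.  ``n_steps`` truncates the pass (no
    later snapshot is ever touched before its turn).
    """
    if len(norm_adjs) != len(feature_mats):
        raise ValueError("adjacency and feature lists must have equal length")
    n_steps = len(norm_adjs) if n_steps is None else n_steps
    weights = {l: params[f"W0_{l}"] for l in range(config.n_layers)}
    outputs: list[Tensor] = []
    for t in range(n_steps):
        h = ad.constant(feature_mats[t])
        adj = ad.constant(norm_adjs[t])
        for l in range(config.n_layers):
            if config.layer_evolves(l):
                k = config.dims[l + 1]
                summary = summarize_embeddings(h, params[f"pool_p_{l}"], k).T
                weights[l], _ = gru_weight_update(summary, weights[l], params, l)
            h = gcn_forward(adj, h, weights[l], config.layer_activation(l))
        outputs.append(h)
    return outputs


def score_pairs(embeddings, pairs, params: dict[str, Tensor]) -> Tensor:
    """Symmetrized MLP logits for unordered node pairs.

    score(i, j) = mean of the MLP applied to [h_i ‖ h_j] and [h_j ‖ h_i],
    which makes score(i, j) = score(j, i) exactly.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no pairs to score")
    i_idx = np.fromiter((i for i, _ in pairs), dtype=np.intp, count=len(pairs))
    j_idx = np.fromiter((j for _, j in pairs), dtype=np.intp, count=len(pairs))
    if np.any(i_idx == j_idx):
        raise ValueError("self-pairs are not scorable")
    embeddings = embeddings if isinstance(embeddings, Tensor) else ad.constant(embeddings)
    hi = ad.take_rows(embeddings, i_idx)
    hj = ad.take_rows(embeddings, j_idx)

    def mlp(rep):
        hidden = ad.relu(rep @ params["mlp_W1"] + params["mlp_b1"])
        return hidden @ params["mlp_W2"] + params["mlp_b2"]

    logits = 0.5 * (mlp(ad.concat([hi, hj])) + mlp(ad.concat([hj, hi])))
    return logits.reshape((len(pairs),))


def link_loss(logits, labels, pos_weight: float = 1.0) -> Tensor:
    """Mean class-weighted cross-entropy on logits.

    Positive pairs contribute pos_weight · softplus(−z), negatives
    softplus(z); with zero logits and pos_weight 1 the loss is ln 2.
    """
    labels = np.asarray(labels, dtype=np.float64)
    if labels.size == 0:
        raise ValueError("link_loss needs at least one pair")
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ValueError("labels must be binary")
    logits = logits if isinstance(logits, Tensor) else ad.constant(logits)
    pos = ad.constant(labels * pos_weight)
    neg = ad.constant(1.0 - labels)
    return (pos * ad.softplus(-logits) + neg * ad.softplus(logits)).mean()
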