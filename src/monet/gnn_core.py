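"""Graph layers and the full model forward pass.

Two embeddings are learned for every gene from the same PPI graph and input
features: a spectral graph-convolution stack (symmetrically normalized
adjacency with self-loops, D̃^{-1/2}(A+I)D̃^{-1/2}) and a multi-head
graph-attention stack (per-edge softmax attention over each node's
neighbourhood, self-edge included). The two 16-dimensional embeddings are
concatenated into a 32-dimensional "graph-enhanced" feature per gene and
classified by a small MLP with a logistic output.

All forward computations are pure functions of explicit weights; training
wraps them in :class:`MonetModel`, whose parameters are autodiff tensors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import sparse as sp

from . import autodiff as ad
from .autodiff import Tensor
from .data_io import AttributedGraphDataset, GeneNetwork

__all__ = [
    "NormalizedAdjacency", "normalize_adjacency", "gcn_layer_forward",
    "gat_attention_weights", "gat_layer_forward", "concat_embeddings",
    "monet_forward", "MonetModel", "self_loop_edge_index",
    "ACTIVATIONS",
]

# activation registry: name -> Tensor -> Tensor
ACTIVATIONS: dict[str, Callable[[Tensor], Tensor]] = {
    "relu": ad.relu,
    "elu": ad.elu,
    "identity": lambda t: t,
    "leaky_relu": ad.leaky_relu,
    "sigmoid": ad.sigmoid,
}


def _resolve_sigma(sigma) -> Callable[[Tensor], Tensor]:
    if callable(sigma):
        return sigma
    try:
        return ACTIVATIONS[sigma]
    except KeyError:
        raise ValueError(f"unknown activation {sigma!r}; "
                         f"known: {sorted(ACTIVATIONS)}") from None


@dataclass(frozen=True)
class NormalizedAdjacency:
    """D̃^{-1/2} (A + I) D̃^{-1/2} as a symmetric sparse matrix."""

    matrix: sp.csr_matrix

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


def normalize_adjacency(network: GeneNetwork | sp.spmatrix) -> NormalizedAdjacency:
    """Symmetric renormalized adjacency with self-loops.

    Adds the identity (every node gains a self-loop, so all degrees are >= 1)
    and scales by inverse square-root degrees on both sides.
    """
    adj = network.adjacency() if isinstance(network, GeneNetwork) else sp.csr_matrix(network)
    n = adj.shape[0]
    a_tilde = adj + sp.identity(n, format="csr")
    deg = np.asarray(a_tilde.sum(axis=1)).ravel()
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
    return NormalizedAdjacency(sp.csr_matrix(d_inv_sqrt @ a_tilde @ d_inv_sqrt))


def gcn_layer_forward(adj_norm: NormalizedAdjacency, H, W,
                      sigma="relu"):
    """One graph-convolution layer: sigma(adj_norm @ H @ W).

    ``H`` and ``W`` may be ndarrays (returns an ndarray) or autodiff tensors
    (returns a tensor on the same graph); the math is identical either way.
    """
    sigma_fn = _resolve_sigma(sigma)
    H_t, W_t = ad.as_tensor(H), ad.as_tensor(W)
    if H_t.data.shape[0] != adj_norm.n_nodes:
        raise ValueError(f"H has {H_t.data.shape[0]} rows but the graph has "
                         f"{adj_norm.n_nodes} nodes")
    if H_t.data.shape[1] != W_t.data.shape[0]:
        raise ValueError("H and W dimensions are incompatible")
    out = sigma_fn(ad.spmm(adj_norm.matrix, ad.matmul(H_t, W_t)))
    if isinstance(H, Tensor) or isinstance(W, Tensor):
        return out
    return out.data


def self_loop_edge_index(network: GeneNetwork | sp.spmatrix) -> tuple[np.ndarray, np.ndarray]:
    """Directed edge index (dst, src) covering both edge directions plus a
    self-edge per node, so every neighbourhood N_i contains i itself."""
    adj = network.adjacency() if isinstance(network, GeneNetwork) else sp.csr_matrix(network)
    n = adj.shape[0]
    coo = (adj + sp.identity(n, format="csr")).tocoo()
    order = np.lexsort((coo.col, coo.row))
    return coo.row[order], coo.col[order]


def gat_attention_weights(h: np.ndarray, W: np.ndarray, a: np.ndarray,
                          neighborhoods: dict[int, Sequence[int]],
                          negative_slope: float = 0.2) -> dict[tuple[int, int], float]:
    """Per-edge attention coefficients alpha_ij for one head.

    The logit for edge (i, j) is LeakyReLU(a^T [W h_i || W h_j]); weights are
    softmax-normalized over each node's neighbourhood, which must include the
    node itself. Returns a dict keyed by (i, j).
    """
    Wh = np.asarray(h, dtype=float) @ np.asarray(W, dtype=float)
    a = np.asarray(a, dtype=float).ravel()
    f_out = Wh.shape[1]
    if a.shape[0] != 2 * f_out:
        raise ValueError(f"attention vector length {a.shape[0]} != 2*{f_out}")
    a_dst, a_src = a[:f_out], a[f_out:]
    s_dst, s_src = Wh @ a_dst, Wh @ a_src
    out: dict[tuple[int, int], float] = {}
    for i, nbrs in neighborhoods.items():
        nbrs = list(nbrs)
        if not nbrs:
            raise ValueError(f"node {i} has an empty neighbourhood "
                             f"(self-inclusion is required)")
        e = s_dst[i] + s_src[nbrs]
        e = np.where(e > 0, e, negative_slope * e)
        e -= e.max()
        w = np.exp(e)
        w /= w.sum()
        for j, alpha in zip(nbrs, w):
            out[(i, j)] = float(alpha)
    return out


def _gat_head(h_t: Tensor, W_t: Tensor, a_dst_t: Tensor, a_src_t: Tensor,
              dst: np.ndarray, src: np.ndarray, n: int,
              negative_slope: float) -> Tensor:
    """One attention head over the directed edge index (dst <- src)."""
    Wh = ad.matmul(h_t, W_t)
    s_dst = ad.matmul(Wh, a_dst_t)  # (N, 1)
    s_src = ad.matmul(Wh, a_src_t)
    e = ad.leaky_relu(ad.add(ad.gather_rows(s_dst, dst),
                             ad.gather_rows(s_src, src)),
                      negative_slope=negative_slope)
    alpha = ad.segment_softmax(e, dst, n)
    msg = ad.mul(alpha, ad.gather_rows(Wh, src))
    return ad.scatter_add_rows(msg, dst, n)


def gat_layer_forward(h, heads, edge_index: tuple[np.ndarray, np.ndarray],
                      aggregation: str = "mean", sigma="identity",
                      negative_slope: float = 0.2):
    """One multi-head attention layer.

    ``heads`` is a sequence of (W, a) pairs, each ``a`` of length twice the
    head output dimension. ``edge_index = (dst, src)`` must include a
    self-edge for every node. ``aggregation`` is ``"concat"`` (hidden-layer
    convention: head outputs stacked column-wise) or ``"mean"`` (output-layer
    convention: average over heads). The nonlinearity is applied after
    aggregation.
    """
    if not heads:
        raise ValueError("heads must be non-empty")
    if aggregation not in ("concat", "mean"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    sigma_fn = _resolve_sigma(sigma)
    dst, src = edge_index
    h_t = ad.as_tensor(h)
    n = h_t.data.shape[0]
    outs = []
    dims = set()
    for head in heads:
        if len(head) == 3:
            W, a_dst, a_src = head
            W_t, ad_t, as_t = ad.as_tensor(W), ad.as_tensor(a_dst), ad.as_tensor(a_src)
        else:
            W, a = head
            W_t = ad.as_tensor(W)
            a_arr = np.asarray(a.data if isinstance(a, Tensor) else a,
                               dtype=float).reshape(-1, 1)
            f_out = W_t.data.shape[1]
            if a_arr.shape[0] != 2 * f_out:
                raise ValueError("attention vector length mismatch")
            ad_t, as_t = Tensor(a_arr[:f_out]), Tensor(a_arr[f_out:])
        if ad_t.data.ndim == 1:
            ad_t = ad.as_tensor(ad_t.data.reshape(-1, 1))
        if as_t.data.ndim == 1:
            as_t = ad.as_tensor(as_t.data.reshape(-1, 1))
        out = _gat_head(h_t, W_t, ad_t, as_t, dst, src, n, negative_slope)
        dims.add(out.data.shape[1])
        outs.append(out)
    if aggregation == "mean":
        if len(dims) != 1:
            raise ValueError("mean aggregation requires equal per-head "
                             "output dimensions")
        acc = outs[0]
        for o in outs[1:]:
            acc = ad.add(acc, o)
        agg = ad.mul(acc, Tensor(np.array(1.0 / len(outs))))
    else:
        agg = outs[0] if len(outs) == 1 else ad.concat(outs, axis=1)
    result = sigma_fn(agg)
    if isinstance(h, Tensor) or any(isinstance(x, Tensor)
                                    for head in heads for x in head):
        return result
    return result.data


def concat_embeddings(gcn_out, gat_out):
    """Column-wise concatenation, GCN block first."""
    g_t, a_t = ad.as_tensor(gcn_out), ad.as_tensor(gat_out)
    if g_t.data.shape[0] != a_t.data.shape[0]:
        raise ValueError("row counts differ between the two embeddings")
    out = ad.concat([g_t, a_t], axis=1)
    if isinstance(gcn_out, Tensor) or isinstance(gat_out, Tensor):
        return out
    return out.data


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


@dataclass
class MonetModel:
    """The full model with trainable parameters as autodiff tensors.

    Branches: a 3-layer GCN (d_in -> 300 -> 100 -> 16, ReLU hidden, linear
    output), a 2-layer GAT (5 concatenated heads of width 100, ELU; then one
    16-dimensional output head, linear), and an MLP head (32 -> 16 -> 1,
    ReLU hidden, logistic output). ``branch`` selects "both" (concatenated),
    "gcn" or "gat" (single-branch ablations; the MLP input shrinks to 16).
    Dropout is applied to the input of every learned layer during training.
    """

    d_in: int
    gcn_dims: tuple[int, ...] = (300, 100, 16)
    gat_hidden_dim: int = 100
    gat_heads_hidden: int = 5
    gat_out_dim: int = 16
    mlp_hidden: int = 16
    dropout: float = 0.5
    negative_slope: float = 0.2
    branch: str = "both"
    seed: int = 0

    gcn_weights: list[Tensor] = field(default_factory=list, repr=False)
    gat_hidden_heads: list[tuple[Tensor, Tensor, Tensor]] = field(
        default_factory=list, repr=False)
    gat_out_head: tuple[Tensor, Tensor, Tensor] | None = field(
        default=None, repr=False)
    mlp_w1: Tensor = field(default=None, repr=False)  # type: ignore[assignment]
    mlp_b1: Tensor = field(default=None, repr=False)  # type: ignore[assignment]
    mlp_w2: Tensor = field(default=None, repr=False)  # type: ignore[assignment]
    mlp_b2: Tensor = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        if self.branch not in ("both", "gcn", "gat"):
            raise ValueError(f"unknown branch {self.branch!r}")
        if not self.gcn_weights:
            self._init_params(np.random.default_rng(self.seed))

    def _init_params(self, rng: np.random.Generator) -> None:
        def param(fan_in, fan_out, shape=None):
            return Tensor(glorot_uniform(rng, fan_in, fan_out, shape),
                          requires_grad=True)

        dims = (self.d_in,) + tuple(self.gcn_dims)
        self.gcn_weights = [param(dims[i], dims[i + 1])
                            for i in range(len(dims) - 1)]
        f = self.gat_hidden_dim
        for _ in range(self.gat_heads_hidden):
            self.gat_hidden_heads.append((
                param(self.d_in, f),
                param(2 * f, 1, shape=(f, 1)),
                param(2 * f, 1, shape=(f, 1)),
            ))
        gat_hidden_out = self.gat_hidden_dim * self.gat_heads_hidden
        g = self.gat_out_dim
        self.gat_out_head = (
            param(gat_hidden_out, g),
            param(2 * g, 1, shape=(g, 1)),
            param(2 * g, 1, shape=(g, 1)),
        )
        mlp_in = {"both": self.gcn_dims[-1] + self.gat_out_dim,
                  "gcn": self.gcn_dims[-1],
                  "gat": self.gat_out_dim}[self.branch]
        self.mlp_w1 = param(mlp_in, self.mlp_hidden)
        self.mlp_b1 = Tensor(np.zeros((1, self.mlp_hidden)), requires_grad=True)
        self.mlp_w2 = param(self.mlp_hidden, 1)
        self.mlp_b2 = Tensor(np.zeros((1, 1)), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        ps = list(self.gcn_weights)
        for head in self.gat_hidden_heads:
            ps.extend(head)
        ps.extend(self.gat_out_head)
        ps += [self.mlp_w1, self.mlp_b1, self.mlp_w2, self.mlp_b2]
        return ps

    def _drop(self, t: Tensor, rng: np.random.Generator | None) -> Tensor:
        if rng is None or self.dropout <= 0:
            return t
        keep = 1.0 - self.dropout
        mask = (rng.random(t.data.shape) < keep) / keep
        return ad.mul(t, Tensor(mask))

    def forward_logits(self, features: np.ndarray,
                       adj_norm: NormalizedAdjacency,
                       edge_index: tuple[np.ndarray, np.ndarray],
                       dropout_rng: np.random.Generator | None = None) -> Tensor:
        """Logit per node; pass a generator to enable training-mode dropout."""
        x = Tensor(features)
        blocks = []
        if self.branch in ("both", "gcn"):
            h = x
            last = len(self.gcn_weights) - 1
            for i, W in enumerate(self.gcn_weights):
                sigma = "relu" if i < last else "identity"
                h = gcn_layer_forward(adj_norm, self._drop(h, dropout_rng),
                                      W, sigma)
            blocks.append(h)
        if self.branch in ("both", "gat"):
            h = gat_layer_forward(self._drop(x, dropout_rng),
                                  self.gat_hidden_heads, edge_index,
                                  aggregation="concat", sigma="elu",
                                  negative_slope=self.negative_slope)
            h = gat_layer_forward(self._drop(h, dropout_rng),
                                  [self.gat_out_head], edge_index,
                                  aggregation="mean", sigma="identity",
                                  negative_slope=self.negative_slope)
            blocks.append(h)
        z = blocks[0] if len(blocks) == 1 else concat_embeddings(*blocks)
        hid = ad.relu(ad.add(ad.matmul(self._drop(z, dropout_rng), self.mlp_w1),
                             self.mlp_b1))
        return ad.add(ad.matmul(self._drop(hid, dropout_rng), self.mlp_w2),
                      self.mlp_b2)

    def predict_proba(self, dataset: AttributedGraphDataset) -> np.ndarray:
        """Deterministic inference probabilities for every node."""
        adj_norm = normalize_adjacency(dataset.network)
        edge_index = self_loop_edge_index(dataset.network)
        logits = self.forward_logits(dataset.features, adj_norm, edge_index)
        return ad.sigmoid(logits).data.ravel()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = state[f"p{i}"].copy()

    def save(self, path) -> None:
        """Single-file checkpoint: every weight plus the architecture config."""
        np.savez_compressed(path, **self.state_dict(), __meta_d_in=self.d_in,
                            __meta_seed=self.seed,
                            __meta_branch=np.array(self.branch))

    @classmethod
    def load(cls, path, **config) -> "MonetModel":
        with np.load(path, allow_pickle=True) as z:
            model = cls(d_in=int(z["__meta_d_in"]),
                        seed=int(z["__meta_seed"]),
                        branch=str(z["__meta_branch"]), **config)
            model.load_state_dict({k: z[k] for k in z.files
                                   if not k.startswith("__meta")})
        return model


def monet_forward(dataset: AttributedGraphDataset, model: MonetModel,
                  dropout_rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-node driver probabilities; deterministic when ``dropout_rng`` is None."""
    if dropout_rng is None:
        return model.predict_proba(dataset)
    adj_norm = normalize_adjacency(dataset.network)
    edge_index = self_loop_edge_index(dataset.network)
    logits = model.forward_logits(dataset.features, adj_norm, edge_index,
                                  dropout_rng=dropout_rng)
    return ad.sigmoid(logits).data.ravel()
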