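"""2-D topological encoder: shared-parameter GAT trunk with hierarchical
self-attention-pooling readouts.

Node features are LayerNorm-ed, projected to width d = heads × head_dim, and
passed through four graph-attention layers (one shared parameter set by
default), each followed by LayerNorm and ELU.  Bond features enter the
attention score as an additive edge term.  Three readout branches summarise
the molecule at increasingly coarse levels:

* atom level — mean of the first layer's node states,
* functional-group level — self-attention pooling at ratio 0.5, then mean,
* scaffold level — self-attention pooling at ratio 0.25, then mean,

and a perceptron fuses the three into the graph summary.  Molecules are
batched as one disjoint union with per-atom graph ids, so a whole drug
library is encoded in a single set of array operations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .chemio import EDGE_FEATURE_DIM, NODE_FEATURE_DIM, MolecularGraph
from .nn import LayerNorm, Linear, Module, Parameter, fan_in_uniform


@dataclass
class Topo2DConfig:
    n_layers: int = 4
    heads: int = 2
    head_dim: int = 32
    share_parameters: bool = True
    pool_ratios: tuple[float, float] = (0.5, 0.25)

    @property
    def d(self) -> int:
        return self.heads * self.head_dim


@dataclass
class GraphBatch:
    """Disjoint union of molecular graphs, atoms stacked along one axis."""

    node_features: np.ndarray  # [sum N, 55]
    edges: np.ndarray          # [sum E, 2], indices offset per graph
    edge_features: np.ndarray  # [sum E, 6]
    graph_ids: np.ndarray      # [sum N]
    n_graphs: int
    sizes: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.sizes is None:
            self.sizes = np.bincount(self.graph_ids, minlength=self.n_graphs)


def batch_graphs(graphs: list[MolecularGraph]) -> GraphBatch:
    if not graphs:
        raise ValueError("empty graph list")
    nodes, edges, efeats, gids = [], [], [], []
    offset = 0
    for gi, g in enumerate(graphs):
        nodes.append(g.node_features)
        if g.edges.size:
            edges.append(g.edges + offset)
            efeats.append(g.edge_features)
        gids.append(np.full(g.n_atoms, gi, dtype=np.intp))
        offset += g.n_atoms
    return GraphBatch(
        node_features=np.concatenate(nodes, axis=0),
        edges=(np.concatenate(edges, axis=0) if edges
               else np.zeros((0, 2), dtype=np.intp)),
        edge_features=(np.concatenate(efeats, axis=0) if efeats
                       else np.zeros((0, EDGE_FEATURE_DIM))),
        graph_ids=np.concatenate(gids),
        n_graphs=len(graphs),
    )


@dataclass
class TopoEmbeddings:
    H2D: Tensor                 # [sum N, d]
    level_summaries: tuple      # three Tensors [G, d]: atom / group / scaffold
    graph_summary: Tensor       # [G, d]


class GATLayer(Module):
    """Multi-head graph attention with additive edge-feature score terms."""

    def __init__(self, in_dim: int, heads: int, head_dim: int,
                 rng: np.random.Generator, leaky_slope: float = 0.2):
        super().__init__()
        self.heads, self.head_dim = heads, head_dim
        self.leaky_slope = leaky_slope
        for h in range(heads):
            setattr(self, f"W{h}", Parameter(
                fan_in_uniform(rng, (in_dim, head_dim), in_dim)))
            setattr(self, f"We{h}", Parameter(
                fan_in_uniform(rng, (EDGE_FEATURE_DIM, head_dim),
                               EDGE_FEATURE_DIM)))
            setattr(self, f"a_src{h}", Parameter(
                fan_in_uniform(rng, (head_dim, 1), head_dim)))
            setattr(self, f"a_dst{h}", Parameter(
                fan_in_uniform(rng, (head_dim, 1), head_dim)))
            setattr(self, f"a_edge{h}", Parameter(
                fan_in_uniform(rng, (head_dim, 1), head_dim)))

    def edge_logits(self, h, edges: np.ndarray, efeat: np.ndarray,
                    head: int) -> tuple[Tensor, Tensor]:
        """Unnormalized attention logits and projected sources for one head."""
        z = ad.matmul(h, getattr(self, f"W{head}"))
        s_src = ad.reshape(ad.matmul(z, getattr(self, f"a_src{head}")), (-1,))
        s_dst = ad.reshape(ad.matmul(z, getattr(self, f"a_dst{head}")), (-1,))
        src, dst = edges[:, 0], edges[:, 1]
        logits = ad.add(ad.gather(ad.reshape(s_src, (-1, 1)), src),
                        ad.gather(ad.reshape(s_dst, (-1, 1)), dst))
        if efeat.size:
            ze = ad.matmul(Tensor(efeat), getattr(self, f"We{head}"))
            logits = ad.add(logits, ad.matmul(ze, getattr(self, f"a_edge{head}")))
        logits = ad.leaky_relu(ad.reshape(logits, (-1,)), self.leaky_slope)
        return logits, z

    def __call__(self, h, edges: np.ndarray, efeat: np.ndarray,
                 n_nodes: int) -> Tensor:
        outs = []
        for head in range(self.heads):
            if edges.shape[0] == 0:
                outs.append(Tensor(np.zeros((n_nodes, self.head_dim))))
                continue
            logits, z = self.edge_logits(h, edges, efeat, head)
            alpha = ad.segment_softmax(logits, edges[:, 1], n_nodes)
            msg = ad.mul(ad.gather(z, edges[:, 0]), ad.reshape(alpha, (-1, 1)))
            outs.append(ad.segment_sum(msg, edges[:, 1], n_nodes))
        return ad.concat(outs, axis=1)


def attention_coefficients(layer: GATLayer, h, edges: np.ndarray,
                           efeat: np.ndarray, n_nodes: int
                           ) -> list[np.ndarray]:
    """Per-edge attention weights for every head (softmax over incoming edges
    of each destination node; weights sum to 1 per destination)."""
    weights = []
    for head in range(layer.heads):
        logits, _ = layer.edge_logits(ad.astensor(h), edges, efeat, head)
        alpha = ad.segment_softmax(logits, edges[:, 1], n_nodes)
        weights.append(alpha.data.copy())
    return weights


class SAGPool(Module):
    """Self-attention graph pooling: keep the top `ratio` of nodes per graph,
    scored by a light graph convolution, gated by tanh(score)."""

    def __init__(self, dim: int, ratio: float, rng: np.random.Generator):
        super().__init__()
        self.ratio = ratio
        self.w_self = Parameter(fan_in_uniform(rng, (dim, 1), dim))
        self.w_neigh = Parameter(fan_in_uniform(rng, (dim, 1), dim))
        self.bias = Parameter(np.zeros(1))

    def scores(self, h, edges: np.ndarray, n_nodes: int) -> Tensor:
        s = ad.add(ad.matmul(h, self.w_self), self.bias)
        if edges.shape[0]:
            zn = ad.matmul(h, self.w_neigh)
            indeg = np.bincount(edges[:, 1], minlength=n_nodes).astype(float)
            neigh = ad.segment_sum(ad.gather(zn, edges[:, 0]), edges[:, 1],
                                   n_nodes)
            s = ad.add(s, ad.mul(neigh, (1.0 / np.maximum(indeg, 1.0))[:, None]))
        return ad.reshape(s, (-1,))

    def __call__(self, h, edges: np.ndarray, graph_ids: np.ndarray,
                 n_graphs: int) -> Tensor:
        """Pooled per-graph mean vectors, [n_graphs, d]."""
        n_nodes = h.shape[0]
        score = self.scores(h, edges, n_nodes)
        # top-k selection per graph on detached scores (argsort is not
        # differentiable; gradient flows through the kept rows and gates)
        keep: list[np.ndarray] = []
        for g in range(n_graphs):
            idx = np.flatnonzero(graph_ids == g)
            k = max(1, math.ceil(self.ratio * idx.size)) if idx.size else 0
            if not k:
                continue
            order = np.argsort(-score.data[idx], kind="stable")[:k]
            keep.append(idx[order])
        keep_idx = np.concatenate(keep) if keep else np.zeros(0, dtype=np.intp)
        gated = ad.mul(ad.gather(h, keep_idx),
                       ad.reshape(ad.tanh(ad.gather(
                           ad.reshape(score, (-1, 1)), keep_idx)), (-1, 1)))
        return ad.segment_mean(gated, graph_ids[keep_idx], n_graphs)


class Topo2DEncoder(Module):
    def __init__(self, config: Topo2DConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        d = config.d
        self.input_norm = LayerNorm(NODE_FEATURE_DIM)
        self.input_proj = Linear(NODE_FEATURE_DIM, d, rng)
        n_param_sets = 1 if config.share_parameters else config.n_layers
        for i in range(n_param_sets):
            setattr(self, f"gat{i}", GATLayer(d, config.heads, config.head_dim, rng))
            setattr(self, f"norm{i}", LayerNorm(d))
        self.pool_group = SAGPool(d, config.pool_ratios[0], rng)
        self.pool_scaffold = SAGPool(d, config.pool_ratios[1], rng)
        self.fuse1 = Linear(3 * d, d, rng)
        self.fuse2 = Linear(d, d, rng)

    def _layer(self, i: int) -> tuple[GATLayer, LayerNorm]:
        j = 0 if self.config.share_parameters else i
        return getattr(self, f"gat{j}"), getattr(self, f"norm{j}")

    def forward(self, batch: GraphBatch,
                with_summaries: bool = True) -> TopoEmbeddings:
        if batch.node_features.shape[0] == 0:
            raise ValueError("empty graph batch")
        n_nodes = batch.node_features.shape[0]
        h = self.input_proj(self.input_norm(Tensor(batch.node_features)))
        h_first = None
        for i in range(self.config.n_layers):
            gat, norm = self._layer(i)
            h = ad.elu(norm(gat(h, batch.edges, batch.edge_features, n_nodes)))
            if h_first is None:
                h_first = h
        if not with_summaries:
            return TopoEmbeddings(H2D=h, level_summaries=(), graph_summary=None)
        atom_level = ad.segment_mean(h_first, batch.graph_ids, batch.n_graphs)
        group_level = self.pool_group(h, batch.edges, batch.graph_ids,
                                      batch.n_graphs)
        scaffold_level = self.pool_scaffold(h, batch.edges, batch.graph_ids,
                                            batch.n_graphs)
        fused = self.fuse2(ad.relu(self.fuse1(
            ad.concat([atom_level, group_level, scaffold_level], axis=1))))
        return TopoEmbeddings(H2D=h,
                              level_summaries=(atom_level, group_level,
                                               scaffold_level),
                              graph_summary=fused)

    __call__ = forward


def encode_topology(graph: MolecularGraph,
                    encoder: Topo2DEncoder) -> TopoEmbeddings:
    """Encode one molecule (single-graph convenience wrapper)."""
    return encoder.forward(batch_graphs([graph]))
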