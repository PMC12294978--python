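"""The full DDI network: 2-D trunk, 3-D pathway, DFE fusion, RESCAL scoring.

This module wires the per-component modules into one trainable whole and
owns the ablation switches:

* ``use_3d=False``   — the 3-D pathway is skipped and v3D is a zero vector;
* ``use_dfe=False``  — cross-attention exchange is bypassed and the raw
  modality features are pooled directly;
* ``use_contrast=False`` — handled by the training loop (no second view,
  zero contrastive weight).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .contrastive import ContrastiveConfig, ContrastiveState
from .fusion_dfe import DFEParameters, batched_dfe, pooled_without_dfe
from .nn import Module
from .predictor import DrugFusion, RelationTensor, batched_rescal_scores
from .spatial3d import Spatial3DConfig, Spatial3DLayer
from .topo2d import GraphBatch, Topo2DConfig, Topo2DEncoder


@dataclass
class NetworkConfig:
    d: int = 64
    topo: Topo2DConfig = field(default_factory=Topo2DConfig)
    spatial: Spatial3DConfig = field(default_factory=Spatial3DConfig)
    contrastive: ContrastiveConfig = field(default_factory=ContrastiveConfig)
    use_3d: bool = True
    use_dfe: bool = True
    use_contrast: bool = True
    score_mode: str = "fused"  # or "cross_modal"
    gamma_dfe_init: float = 0.1

    def __post_init__(self):
        if self.score_mode not in {"fused", "cross_modal"}:
            raise ValueError(f"unknown score_mode: {self.score_mode}")
        if self.topo.d != self.d or self.spatial.d != self.d:
            raise ValueError("2D and 3D embedding widths must both equal d")


@dataclass
class DrugEmbeddings:
    """Batch-level drug representations (rows aligned with the drug order)."""

    v2d: Tensor  # [G, d]
    v3d: Tensor  # [G, d]
    g: Tensor    # [G, d] fused drug vectors


class LSADDINetwork(Module):
    def __init__(self, config: NetworkConfig, relation_ids: list[int],
                 rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.topo = Topo2DEncoder(config.topo, rng)
        self.spatial = Spatial3DLayer(config.spatial, rng)
        self.dfe = DFEParameters(config.d, rng, config.gamma_dfe_init)
        self.fusion = DrugFusion(config.d, rng)
        self.relations = RelationTensor(relation_ids, config.d, rng)
        self.contrast = ContrastiveState(config.contrastive)

    def encode(self, batch: GraphBatch, coords: np.ndarray | None,
               rng: np.random.Generator | None = None) -> DrugEmbeddings:
        """Encode a disjoint-union batch of drugs into pooled vectors.

        `coords` stacks every atom's 3-D coordinates in batch order; pass
        ``None`` (or configure ``use_3d=False``) to run the 2-D-only path.
        """
        # hierarchical readout summaries are a 2-D diagnostic output; the
        # scoring path pools the exchanged node states instead
        topo_out = self.topo.forward(batch, with_summaries=False)
        h2d = topo_out.H2D
        use_3d = self.config.use_3d and coords is not None
        if use_3d:
            spatial_out = self.spatial.forward(coords, batch.graph_ids,
                                               batch.n_graphs, rng)
            h3d = spatial_out.s
            if self.config.use_dfe:
                _, _, v2d, v3d = batched_dfe(h2d, h3d, self.dfe,
                                             batch.graph_ids, batch.n_graphs)
            else:
                v2d, v3d = pooled_without_dfe(h2d, h3d, batch.graph_ids,
                                              batch.n_graphs)
        else:
            v2d = ad.segment_mean(h2d, batch.graph_ids, batch.n_graphs)
            v3d = Tensor(np.zeros((batch.n_graphs, self.config.d)))
        g = self.fusion(v2d, v3d)
        return DrugEmbeddings(v2d=v2d, v3d=v3d, g=g)

    def score(self, emb: DrugEmbeddings, idx_a: np.ndarray,
              idx_b: np.ndarray, relations: np.ndarray) -> Tensor:
        """RESCAL scores for triples given row indices into the batch."""
        if self.config.score_mode == "fused":
            return batched_rescal_scores(ad.gather(emb.g, idx_a),
                                         ad.gather(emb.g, idx_b),
                                         relations, self.relations)
        s1 = batched_rescal_scores(ad.gather(emb.v2d, idx_a),
                                   ad.gather(emb.v3d, idx_b),
                                   relations, self.relations)
        s2 = batched_rescal_scores(ad.gather(emb.v3d, idx_a),
                                   ad.gather(emb.v2d, idx_b),
                                   relations, self.relations)
        return ad.add(s1, s2)
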