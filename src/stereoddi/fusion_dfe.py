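"""Dynamic Feature Exchange (DFE): bidirectional cross-attention between a
drug's 2-D topological and 3-D spatial node features.

Queries come from the 2-D side and keys from the 3-D side,

    alpha = row_softmax( (H2D W_Q)(H3D W_K)^T / sqrt(d) ),

and the other modality's value projection is injected residually with a
learnable scale gamma (initialised at 0.1 to keep early fusion gentle):

    H2D~ = H2D + gamma * alpha   (H3D W_V)
    H3D~ = H3D + gamma * alpha^T (H2D W_V)

Attention is strictly intra-drug (the two modalities describe the same atoms
in the same order); the two drugs of a pair pass through DFE independently
with shared parameters.  Global average pooling then yields the per-modality
drug vectors v2D and v3D.
"""

from __future__ import annotations

import math

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Module, Parameter, fan_in_uniform


class DFEParameters(Module):
    def __init__(self, d: int, rng: np.random.Generator,
                 gamma_init: float = 0.1):
        super().__init__()
        self.d = d
        self.W_Q = Parameter(fan_in_uniform(rng, (d, d), d))
        self.W_K = Parameter(fan_in_uniform(rng, (d, d), d))
        self.W_V = Parameter(fan_in_uniform(rng, (d, d), d))
        self.gamma = Parameter(np.array([gamma_init]))


def cross_attention(H2D, H3D, params: DFEParameters) -> Tensor:
    """Row-stochastic attention of each 2-D atom over all 3-D atoms, [N, N]."""
    H2D, H3D = ad.astensor(H2D), ad.astensor(H3D)
    if H2D.shape[0] != H3D.shape[0]:
        raise ValueError("DFE requires both modalities of the same molecule "
                         f"(got {H2D.shape[0]} vs {H3D.shape[0]} atoms)")
    q = ad.matmul(H2D, params.W_Q)
    k = ad.matmul(H3D, params.W_K)
    logits = ad.mul(ad.matmul(q, ad.transpose(k)), 1.0 / math.sqrt(params.d))
    return ad.row_softmax(logits)


def exchange(H2D, H3D, alpha, params: DFEParameters
             ) -> tuple[Tensor, Tensor]:
    """Gated bidirectional injection; exact identity when gamma = 0."""
    H2D, H3D, alpha = ad.astensor(H2D), ad.astensor(H3D), ad.astensor(alpha)
    v3 = ad.matmul(H3D, params.W_V)
    v2 = ad.matmul(H2D, params.W_V)
    h2_tilde = ad.add(H2D, ad.mul(ad.matmul(alpha, v3), params.gamma))
    h3_tilde = ad.add(H3D, ad.mul(ad.matmul(ad.transpose(alpha), v2),
                                  params.gamma))
    return h2_tilde, h3_tilde


def pool_modalities(H2D_tilde, H3D_tilde) -> tuple[Tensor, Tensor]:
    """Global average pooling over atoms for each modality."""
    return (ad.tmean(ad.astensor(H2D_tilde), axis=0),
            ad.tmean(ad.astensor(H3D_tilde), axis=0))


def dfe_forward(H2D, H3D, params: DFEParameters
                ) -> tuple[Tensor, Tensor, Tensor, Tensor, Tensor]:
    """Full single-molecule DFE pass: (alpha, H2D~, H3D~, v2D, v3D)."""
    alpha = cross_attention(H2D, H3D, params)
    h2t, h3t = exchange(H2D, H3D, alpha, params)
    v2d, v3d = pool_modalities(h2t, h3t)
    return alpha, h2t, h3t, v2d, v3d


def _padding_layout(graph_ids: np.ndarray, n_graphs: int
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Indices mapping a disjoint-union batch to a [B, Nmax] padded layout.

    Returns (pad_idx, valid_mask, flat_positions, n_max): `pad_idx` points
    padded slots at their source atom row (or at an appended zero row),
    `flat_positions` recovers each atom's slot in the flattened padding.
    """
    sizes = np.bincount(graph_ids, minlength=n_graphs)
    n_max = int(sizes.max())
    n = graph_ids.shape[0]
    pad_idx = np.full((n_graphs, n_max), n, dtype=np.intp)  # n -> zero row
    valid = np.zeros((n_graphs, n_max), dtype=bool)
    offsets = np.concatenate(([0], np.cumsum(sizes)))[:-1]
    within = np.arange(n) - offsets[graph_ids]
    pad_idx[graph_ids, within] = np.arange(n)
    valid[graph_ids, within] = True
    flat_positions = graph_ids * n_max + within
    return pad_idx.ravel(), valid, flat_positions, n_max


def batched_dfe(H2D, H3D, params: DFEParameters, graph_ids: np.ndarray,
                n_graphs: int) -> tuple[Tensor, Tensor, Tensor, Tensor]:
    """DFE over a disjoint-union batch: returns (H2D~, H3D~, v2D, v3D).

    Attention is block-diagonal by molecule; molecules are padded to a
    common atom count and handled with one batched dense attention, which is
    equivalent to the per-molecule computation (padded keys are masked out
    of the softmax and padded queries zeroed before the transposed pass).
    """
    H2D, H3D = ad.astensor(H2D), ad.astensor(H3D)
    graph_ids = np.asarray(graph_ids, dtype=np.intp)
    d = params.d
    pad_idx, valid, flat_pos, n_max = _padding_layout(graph_ids, n_graphs)

    def pad(x: Tensor) -> Tensor:
        ext = ad.concat([x, Tensor(np.zeros((1, d)))], axis=0)
        return ad.reshape(ad.gather(ext, pad_idx), (n_graphs, n_max, d))

    q = pad(ad.matmul(H2D, params.W_Q))
    k = pad(ad.matmul(H3D, params.W_K))
    v3 = pad(ad.matmul(H3D, params.W_V))
    v2 = pad(ad.matmul(H2D, params.W_V))
    key_mask = np.where(valid, 0.0, -1e30)[:, None, :]   # [B, 1, Nmax]
    query_mask = valid.astype(float)[:, :, None]         # [B, Nmax, 1]
    logits = ad.add(ad.mul(ad.bmm(q, ad.swapaxes_last(k)), 1.0 / math.sqrt(d)),
                    Tensor(key_mask))
    alpha = ad.mul(ad.row_softmax(logits), Tensor(query_mask))
    inj2 = ad.reshape(ad.bmm(alpha, v3), (n_graphs * n_max, d))
    inj3 = ad.reshape(ad.bmm(ad.swapaxes_last(alpha), v2),
                      (n_graphs * n_max, d))
    h2t = ad.add(H2D, ad.mul(ad.gather(inj2, flat_pos), params.gamma))
    h3t = ad.add(H3D, ad.mul(ad.gather(inj3, flat_pos), params.gamma))
    v2d = ad.segment_mean(h2t, graph_ids, n_graphs)
    v3d = ad.segment_mean(h3t, graph_ids, n_graphs)
    return h2t, h3t, v2d, v3d


def pooled_without_dfe(H2D, H3D, graph_ids: np.ndarray, n_graphs: int
                       ) -> tuple[Tensor, Tensor]:
    """Ablation path (wo_DFE): pool the raw modality features directly."""
    return (ad.segment_mean(ad.astensor(H2D), graph_ids, n_graphs),
            ad.segment_mean(ad.astensor(H3D), graph_ids, n_graphs))
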