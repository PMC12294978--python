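"""Multiscale InfoNCE contrastive learning with annealed weighting.

Pair representations (concatenated fused drug embeddings, width 2d) and
their 3-D-reaugmented counterparts form positive pairs; other pairs in the
batch are negatives.  Each representation is average-pooled along the
feature axis at scales {1, 2, 4} (atom / functional-group / scaffold
levels), L2-normalized, and scored by temperature-scaled cosine similarity.
Per-scale InfoNCE losses are combined with softmax weights over three
learnable logits, and the combined loss enters the total objective with a
linearly annealed coefficient

    gamma(t) = gamma0 * (1 - t / T),   gamma0 = 0.1, T = 500 epochs,

clamped at zero beyond T.  The temperature is a learnable scalar hard-bounded
to [0.1, 2.0] by a logistic reparameterization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Module, Parameter

logger = logging.getLogger(__name__)


@dataclass
class ContrastiveConfig:
    scales: tuple[int, ...] = (1, 2, 4)
    tau_bounds: tuple[float, float] = (0.1, 2.0)
    gamma0: float = 0.1
    T: int = 500

    def __post_init__(self):
        lo, hi = self.tau_bounds
        if not (0.0 < lo < hi):
            raise ValueError("tau bounds must satisfy 0 < lower < upper")


class ContrastiveState(Module):
    """Learnable temperature (bounded) and per-scale weight logits."""

    def __init__(self, config: ContrastiveConfig):
        super().__init__()
        self.config = config
        self.tau_raw = Parameter(np.zeros(1))
        self.scale_logits = Parameter(np.zeros(len(config.scales)))

    def tau(self) -> Tensor:
        """tau = lo + (hi - lo) * sigmoid(tau_raw): always inside its bounds."""
        lo, hi = self.config.tau_bounds
        return ad.add(ad.mul(ad.sigmoid(self.tau_raw), hi - lo), lo)

    def weights(self) -> Tensor:
        return scale_weights(self.scale_logits)


def scale_pool(f, s: int) -> Tensor:
    """Non-overlapping window means (window = stride = s) along features."""
    f = ad.astensor(f)
    dim = f.shape[-1]
    if dim % s:
        raise ValueError(f"scale {s} does not divide feature width {dim}")
    if s == 1:
        return f
    if f.ndim == 1:
        return ad.tmean(ad.reshape(f, (dim // s, s)), axis=1)
    return ad.tmean(ad.reshape(f, (f.shape[0], dim // s, s)), axis=2)


def l2_normalize(f) -> Tensor:
    """Unit-norm rows; exact zero rows pass through unchanged (warned)."""
    f = ad.astensor(f)
    axis = f.ndim - 1
    sq = ad.tsum(ad.power(f, 2.0), axis=axis, keepdims=True)
    norms = np.sqrt(sq.data)
    if np.any(norms == 0.0):
        logger.warning("l2_normalize received zero vectors; left unchanged")
    return ad.mul(f, ad.power(ad.add(sq, (norms == 0.0).astype(float)), -0.5))


def similarity_matrix(f1, f2, tau) -> Tensor:
    """S = F1 F2^T / tau for row-normalized inputs."""
    f1, f2 = ad.astensor(f1), ad.astensor(f2)
    return ad.mul(ad.matmul(f1, ad.transpose(f2)),
                  ad.power(ad.astensor(tau), -1.0))


def infonce_scale_loss(view1, view2, tau, s: int) -> Tensor:
    """InfoNCE at scale s between a batch of pair representations and their
    reaugmented counterparts.

    For anchor i the positive is its counterpart i'; the denominator holds
    the positive plus the 2(N-1) in-batch negatives {f_j}_{j != i} (same
    view) and {f_j'}_{j != i} (other view).  N = 1 gives exactly zero.
    """
    f1 = l2_normalize(scale_pool(view1, s))
    f2 = l2_normalize(scale_pool(view2, s))
    n = f1.shape[0]
    cross = similarity_matrix(f1, f2, tau)        # cross[i, j] = sim(f_i, f_j')
    within = similarity_matrix(f1, f1, tau)       # within[i, j] = sim(f_i, f_j)
    eye = np.eye(n)
    pos = ad.tsum(ad.mul(cross, eye), axis=1)     # sim(f_i, f_i') / tau
    # mask the i = j term of the same-view matrix out of the negatives
    masked_within = ad.add(within, Tensor(-1e30 * eye))
    logits = ad.concat([cross, masked_within], axis=1)
    lse = ad.logsumexp_rows(logits)
    return ad.tmean(ad.add(lse, ad.mul(pos, -1.0)))


def scale_weights(scale_logits) -> Tensor:
    """Softmax over the scale logits: nonnegative, summing to one."""
    logits = ad.astensor(scale_logits)
    return ad.reshape(ad.row_softmax(ad.reshape(logits, (1, -1))), (-1,))


def multiscale_loss(per_scale_losses: list, weights) -> Tensor:
    """L_total = sum_s w_s L_contrast^s."""
    weights = ad.astensor(weights)
    stacked = ad.concat([ad.reshape(ad.astensor(l), (1,))
                         for l in per_scale_losses], axis=0)
    return ad.tsum(ad.mul(stacked, weights))


def contrastive_weight(t: float, gamma0: float = 0.1, T: int = 500) -> float:
    """Linearly annealed coefficient gamma(t) = gamma0 (1 - t/T), floored at 0."""
    if t < 0:
        raise ValueError("epoch index must be nonnegative")
    return max(gamma0 * (1.0 - t / T), 0.0)


def multiscale_contrastive_loss(view1, view2, state: ContrastiveState
                                ) -> tuple[Tensor, list[Tensor], Tensor]:
    """Assemble L_total across the configured scales.

    Returns (L_total, per-scale losses, weights).
    """
    tau = state.tau()
    losses = [infonce_scale_loss(view1, view2, tau, s)
              for s in state.config.scales]
    w = state.weights()
    return multiscale_loss(losses, w), losses, w


def total_loss(l_main, l_contrast_total, t: float,
               gamma0: float = 0.1, T: int = 500) -> Tensor:
    """L = L_main + gamma(t) * L_total."""
    g = contrastive_weight(t, gamma0, T)
    return ad.add(ad.astensor(l_main), ad.mul(ad.astensor(l_contrast_total), g))
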