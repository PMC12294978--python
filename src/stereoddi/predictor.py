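"""Pair scoring: per-drug embedding fusion and RESCAL bilinear relation
scoring.

Each drug's pooled modality vectors are fused into one 64-dimensional
embedding g = linear([v2D ; v3D]); a triple (x, y, r) is scored by the
bilinear form

    score = g_x^T W_rel^(r) g_y,        probability = sigmoid(score),

with one learnable 64 x 64 matrix per interaction type.  An alternative
`cross_modal` scoring mode couples modalities across the pair instead:
score = v2D_x^T W_r v3D_y + v3D_x^T W_r v2D_y.

Training negatives are generated by uniform corruption of one drug slot of
each positive triple, rejecting known positives, and the main task loss is
mean binary cross-entropy of the logistic scores against 1/0 labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .chemio import DDITriple
from .nn import Linear, Module, Parameter, fan_in_uniform


class RelationTensor(Module):
    """Stack of per-relation bilinear matrices W_rel^(r), each [d x d]."""

    def __init__(self, relation_ids: list[int], d: int,
                 rng: np.random.Generator):
        super().__init__()
        self.d = d
        self.relation_ids = list(relation_ids)
        self._index = {r: i for i, r in enumerate(self.relation_ids)}
        for i in range(len(self.relation_ids)):
            setattr(self, f"W{i}", Parameter(fan_in_uniform(rng, (d, d), d)))

    def matrix(self, relation: int) -> Parameter:
        if relation not in self._index:
            raise KeyError(f"unknown relation id: {relation}")
        return getattr(self, f"W{self._index[relation]}")


class DrugFusion(Module):
    """g = linear([v2D ; v3D]), mapping 2d -> d."""

    def __init__(self, d: int, rng: np.random.Generator):
        super().__init__()
        self.linear = Linear(2 * d, d, rng)

    def __call__(self, v2d, v3d) -> Tensor:
        v2d, v3d = ad.astensor(v2d), ad.astensor(v3d)
        axis = 1 if v2d.ndim == 2 else 0
        return self.linear(ad.concat([v2d, v3d], axis=axis))


def fuse_drug_embedding(v2d, v3d, fusion: DrugFusion) -> Tensor:
    return fusion(v2d, v3d)


def rescal_score(g_x, g_y, relation: int,
                 relation_tensor: RelationTensor) -> Tensor:
    """Bilinear score g_x^T W_r g_y (scalar for vectors, [B] for row-batches)."""
    g_x, g_y = ad.astensor(g_x), ad.astensor(g_y)
    w = relation_tensor.matrix(relation)
    if g_x.ndim == 1:
        return ad.tsum(ad.mul(ad.matmul(ad.reshape(g_x, (1, -1)), w),
                              ad.reshape(g_y, (1, -1))))
    return ad.tsum(ad.mul(ad.matmul(g_x, w), g_y), axis=1)


def batched_rescal_scores(g_x, g_y, relations: np.ndarray,
                          relation_tensor: RelationTensor) -> Tensor:
    """Scores for a batch of triples, grouped by relation for efficiency.

    `g_x`, `g_y` are [B, d] row-aligned with `relations` [B].
    """
    relations = np.asarray(relations)
    b = relations.shape[0]
    pieces, orders = [], []
    for r in np.unique(relations):
        sel = np.flatnonzero(relations == r)
        pieces.append(rescal_score(ad.gather(ad.astensor(g_x), sel),
                                   ad.gather(ad.astensor(g_y), sel),
                                   int(r), relation_tensor))
        orders.append(sel)
    order = np.concatenate(orders)
    scores = ad.concat(pieces, axis=0)
    inverse = np.empty(b, dtype=np.intp)
    inverse[order] = np.arange(b)
    return ad.gather(scores, inverse)


@dataclass
class PairScore:
    score: float
    probability: float

    @classmethod
    def from_score(cls, score: float) -> "PairScore":
        return cls(score=float(score),
                   probability=1.0 / (1.0 + math.exp(-float(score))))


def sample_negatives(positives: list[DDITriple], drug_set: list[str],
                     rng: np.random.Generator,
                     known_positives: set | None = None,
                     max_resample: int = 20) -> list[DDITriple]:
    """One corrupted triple per positive (uniform one-slot replacement).

    With probability 0.5 the first drug is replaced, otherwise the second,
    drawing uniformly from `drug_set`; candidates that collide with a known
    positive are rejected and redrawn up to `max_resample` times, after which
    the collision is accepted (labelled via identical fields).
    """
    if not drug_set:
        raise ValueError("drug_set must be nonempty")
    if known_positives is None:
        known_positives = {(t.drug_a, t.drug_b, t.itype) for t in positives}
    drug_arr = list(drug_set)
    negatives = []
    for t in positives:
        neg = t
        for _ in range(max_resample + 1):
            replacement = drug_arr[rng.integers(len(drug_arr))]
            if rng.random() < 0.5:
                cand = replace(t, drug_a=replacement, label=0)
            else:
                cand = replace(t, drug_b=replacement, label=0)
            neg = cand
            if (cand.drug_a, cand.drug_b, cand.itype) not in known_positives:
                break
        negatives.append(neg)
    return negatives


def main_loss(pos_scores, neg_scores) -> Tensor:
    """Mean binary cross-entropy of logistic(score) against 1 / 0 labels."""
    pos, neg = ad.astensor(pos_scores), ad.astensor(neg_scores)
    n_pos = pos.data.size
    n_neg = neg.data.size
    if n_pos == 0 or n_neg == 0:
        raise ValueError("main_loss requires nonempty positive and negative batches")
    total = ad.add(ad.tsum(ad.softplus(ad.mul(pos, -1.0))),
                   ad.tsum(ad.softplus(neg)))
    return ad.mul(total, 1.0 / (n_pos + n_neg))


def labeled_bce_loss(scores, labels: np.ndarray) -> Tensor:
    """Mean BCE for explicitly labelled pairs: softplus(-s) + (1 - y) * s."""
    scores = ad.astensor(scores)
    y = np.asarray(labels, dtype=np.float64)
    per = ad.add(ad.softplus(ad.mul(scores, -1.0)), ad.mul(scores, 1.0 - y))
    return ad.tmean(per)
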