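"""Dataset splitting, the training loop, evaluation metrics, and ablations.

Cold-start splits partition the *drugs* into seen (G_old) and unseen (G_new)
sets, then route triples: both drugs seen -> Dtrain; both unseen -> S1;
exactly one unseen -> S2.  Warm-start splits are triple-level 70/10/20.

Training follows the published recipe: AdamW (weight decay 1e-3), batch size
512, initial learning rate 5e-3 with cosine annealing over the epoch budget,
binary cross-entropy on positives plus 1:1 corrupted negatives, and the
annealed multiscale contrastive term.  All stochastic draws (shuffling,
rotations, corruption) come from one seeded generator, so identical seeds
give identical histories.

Evaluation scores positives plus equally many corrupted negatives (fixed
evaluation seed) and reports ACC / AUROC / AP / F1; accuracy and F1 use the
0.5 probability threshold.  Tables with an explicit ``label`` column are
scored against those labels instead of sampling negatives.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd
from sklearn.metrics import (accuracy_score, average_precision_score,
                             f1_score, roc_auc_score)

from . import autodiff as ad
from .chemio import (Conformer, DDITriple, MolecularGraph, build_graph,
                     conformer_seed, generate_conformer, sample_rotation,
                     rotate_coordinates)
from .contrastive import contrastive_weight, multiscale_contrastive_loss
from .network import DrugEmbeddings, LSADDINetwork, NetworkConfig
from .nn import AdamW, clip_grad_norm, cosine_lr
from .predictor import labeled_bce_loss, main_loss, sample_negatives
from .topo2d import batch_graphs

logger = logging.getLogger(__name__)


class SplitMode(str, Enum):
    warm = "warm"
    cold = "cold"


@dataclass
class SplitSpec:
    mode: SplitMode
    seed: int
    new_drug_fraction: float | None = None
    g_new: set[str] = field(default_factory=set)
    g_old: set[str] = field(default_factory=set)
    partitions: dict[str, list[DDITriple]] = field(default_factory=dict)


def cold_start_split(triples: list[DDITriple], registry: dict[str, str],
                     fraction: float = 0.2, seed: int = 0) -> SplitSpec:
    """Drug-level split into Dtrain / S1 (both new) / S2 (one new)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    drugs = sorted(registry)
    if len(drugs) < 2:
        raise ValueError("need at least 2 drugs to split")
    rng = np.random.default_rng(seed)
    n_new = int(round(fraction * len(drugs)))
    new = set(rng.choice(drugs, size=n_new, replace=False).tolist())
    old = set(drugs) - new
    dtrain, s1, s2 = [], [], []
    for t in triples:
        a_new, b_new = t.drug_a in new, t.drug_b in new
        if a_new and b_new:
            s1.append(t)
        elif a_new or b_new:
            s2.append(t)
        else:
            dtrain.append(t)
    if not s1:
        logger.warning("cold-start routing left the S1 partition empty")
    return SplitSpec(mode=SplitMode.cold, seed=seed, new_drug_fraction=fraction,
                     g_new=new, g_old=old,
                     partitions={"train": dtrain, "S1": s1, "S2": s2})


def warm_split(triples: list[DDITriple], seed: int = 0,
               ratios: tuple[float, float, float] = (0.7, 0.1, 0.2)
               ) -> SplitSpec:
    """Triple-level random split into train / valid / test."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(triples))
    n_train = int(round(ratios[0] * len(triples)))
    n_valid = int(round(ratios[1] * len(triples)))
    idx = {"train": order[:n_train],
           "valid": order[n_train:n_train + n_valid],
           "test": order[n_train + n_valid:]}
    return SplitSpec(mode=SplitMode.warm, seed=seed,
                     partitions={k: [triples[i] for i in v]
                                 for k, v in idx.items()})


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 512
    lr: float = 5e-3
    weight_decay: float = 1e-3
    seed: int = 0
    use_3d: bool = True
    use_dfe: bool = True
    use_contrast: bool = True
    scales: tuple[int, ...] = (1, 2, 4)
    gamma0: float = 0.1
    annealing_T: int = 500
    d: int = 64
    dropout: float = 0.1
    share_parameters: bool = True
    pool_ratios: tuple[float, float] = (0.5, 0.25)
    score_mode: str = "fused"
    warmup_epochs: int = 5
    max_grad_norm: float = 5.0
    optimize_conformers: bool = False
    eval_every: int = 1

    def network_config(self) -> NetworkConfig:
        from .contrastive import ContrastiveConfig
        from .spatial3d import Spatial3DConfig
        from .topo2d import Topo2DConfig
        return NetworkConfig(
            d=self.d,
            topo=Topo2DConfig(share_parameters=self.share_parameters,
                              pool_ratios=self.pool_ratios),
            spatial=Spatial3DConfig(d=self.d, dropout_rate=self.dropout),
            contrastive=ContrastiveConfig(scales=self.scales,
                                          gamma0=self.gamma0,
                                          T=self.annealing_T),
            use_3d=self.use_3d, use_dfe=self.use_dfe,
            use_contrast=self.use_contrast, score_mode=self.score_mode)


@dataclass
class Metrics:
    acc: float
    auroc: float
    ap: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {"ACC": self.acc, "AUROC": self.auroc, "AP": self.ap,
                "F1": self.f1}


class DDIDataset:
    """Registry + triples with cached graphs and conformers."""

    def __init__(self, registry: dict[str, str], triples: list[DDITriple]):
        unknown = sorted({d for t in triples for d in (t.drug_a, t.drug_b)}
                         - set(registry))
        if unknown:
            raise ValueError(f"triples reference unknown drug ids: {unknown}")
        self.registry = dict(registry)
        self.triples = list(triples)
        self.drug_ids = sorted(registry)
        self.relation_ids = sorted({t.itype for t in triples})
        self.known_positives = {(t.drug_a, t.drug_b, t.itype) for t in triples}
        self.labeled = any(t.label is not None for t in triples)
        self.graphs: dict[str, MolecularGraph] = {}
        self.conformers: dict[str, Conformer] = {}
        self._prepared_seed: int | None = None

    def prepare(self, run_seed: int,
                optimize_conformers: bool = False) -> None:
        """Build graphs and embed conformers (idempotent per run seed)."""
        if self._prepared_seed == run_seed and self.graphs:
            return
        self.graphs = {d: build_graph(self.registry[d], d)
                       for d in self.drug_ids}
        self.conformers = {
            d: generate_conformer(self.registry[d],
                                  conformer_seed(d, run_seed), drug_id=d,
                                  optimize=optimize_conformers)
            for d in self.drug_ids}
        self._prepared_seed = run_seed


def _stack_rotated(dataset: DDIDataset, drug_ids: list[str],
                   rng: np.random.Generator | None) -> np.ndarray:
    """Per-drug randomly rotated (or canonical) coordinates, stacked."""
    pieces = []
    for d in drug_ids:
        coords = dataset.conformers[d].coordinates
        if rng is not None:
            coords = rotate_coordinates(coords, sample_rotation(rng))
        pieces.append(coords)
    return np.concatenate(pieces, axis=0)


def _encode_drugs(network: LSADDINetwork, dataset: DDIDataset,
                  drug_ids: list[str], rng: np.random.Generator | None,
                  rotate: bool, dropout_rng: np.random.Generator | None = None
                  ) -> DrugEmbeddings:
    batch = batch_graphs([dataset.graphs[d] for d in drug_ids])
    coords = None
    if network.config.use_3d:
        coords = _stack_rotated(dataset, drug_ids, rng if rotate else None)
    return network.encode(batch, coords, dropout_rng)


def _triple_scores(network: LSADDINetwork, emb: DrugEmbeddings,
                   row_of: dict[str, int], triples: list[DDITriple]):
    idx_a = np.array([row_of[t.drug_a] for t in triples], dtype=np.intp)
    idx_b = np.array([row_of[t.drug_b] for t in triples], dtype=np.intp)
    rels = np.array([t.itype for t in triples])
    return network.score(emb, idx_a, idx_b, rels)


def train(config: TrainConfig, dataset: DDIDataset,
          val_triples: list[DDITriple] | None = None,
          eval_seed: int = 12345
          ) -> tuple[LSADDINetwork, pd.DataFrame]:
    """Train the network on `dataset.triples`; returns (network, history).

    `history` has one row per epoch with the loss components, the annealing
    weight gamma(t), the temperature tau, the learning rate, and validation
    metrics when `val_triples` is given.
    """
    dataset.prepare(config.seed, config.optimize_conformers)
    init_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    run_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    network = LSADDINetwork(config.network_config(), dataset.relation_ids,
                            init_rng)
    optimizer = AdamW(network.parameters(), lr=config.lr,
                      weight_decay=config.weight_decay)
    triples = dataset.triples
    history_rows = []
    t0 = time.perf_counter()
    for epoch in range(config.epochs):
        network.train()
        optimizer.lr = cosine_lr(config.lr, epoch, config.epochs,
                                 min(config.warmup_epochs, config.epochs // 5))
        gamma = contrastive_weight(epoch, config.gamma0, config.annealing_T)
        order = run_rng.permutation(len(triples))
        epoch_main, epoch_contrast, n_batches = 0.0, 0.0, 0
        tau_value = float(network.contrast.tau().data[0])
        for start in range(0, len(order), config.batch_size):
            batch_triples = [triples[i] for i in order[start:start +
                                                       config.batch_size]]
            if dataset.labeled:
                pos = batch_triples
                neg = []
                scored = batch_triples
            else:
                pos = batch_triples
                neg = sample_negatives(pos, dataset.drug_ids, run_rng,
                                       dataset.known_positives)
                scored = pos + neg
            drug_ids = sorted({d for t in scored
                               for d in (t.drug_a, t.drug_b)})
            row_of = {d: i for i, d in enumerate(drug_ids)}
            emb = _encode_drugs(network, dataset, drug_ids, run_rng,
                                rotate=True, dropout_rng=run_rng)
            if dataset.labeled:
                scores = _triple_scores(network, emb, row_of, pos)
                labels = np.array([t.label for t in pos], dtype=float)
                l_main = labeled_bce_loss(scores, labels)
            else:
                pos_scores = _triple_scores(network, emb, row_of, pos)
                neg_scores = _triple_scores(network, emb, row_of, neg)
                l_main = main_loss(pos_scores, neg_scores)
            loss = l_main
            l_contrast_val = 0.0
            if config.use_contrast and len(pos) > 0:
                emb2 = _encode_drugs(network, dataset, drug_ids, run_rng,
                                     rotate=True, dropout_rng=run_rng)
                idx_a = np.array([row_of[t.drug_a] for t in pos], dtype=np.intp)
                idx_b = np.array([row_of[t.drug_b] for t in pos], dtype=np.intp)
                f1 = ad.concat([ad.gather(emb.g, idx_a),
                                ad.gather(emb.g, idx_b)], axis=1)
                f2 = ad.concat([ad.gather(emb2.g, idx_a),
                                ad.gather(emb2.g, idx_b)], axis=1)
                l_total, _, _ = multiscale_contrastive_loss(
                    f1, f2, network.contrast)
                l_contrast_val = float(l_total.data)
                loss = ad.add(l_main, ad.mul(l_total, gamma))
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss.data!r}, "
                    f"lr={optimizer.lr:.2e}, gamma={gamma:.4f}")
            optimizer.zero_grad()
            loss.backward()
            clip_grad_norm(network.parameters(), config.max_grad_norm)
            optimizer.step()
            epoch_main += float(l_main.data)
            epoch_contrast += l_contrast_val
            n_batches += 1
        row = {
            "epoch": epoch,
            "lr": optimizer.lr,
            "loss_main": epoch_main / max(n_batches, 1),
            "loss_contrast": epoch_contrast / max(n_batches, 1),
            "gamma": gamma,
            "tau": tau_value,
            "seconds": time.perf_counter() - t0,
        }
        if val_triples is not None and (epoch % config.eval_every == 0
                                        or epoch == config.epochs - 1):
            val = evaluate(network, val_triples, dataset, seed=eval_seed)
            row.update({f"val_{k.lower()}": v for k, v in
                        val.as_dict().items()})
        history_rows.append(row)
    return network, pd.DataFrame(history_rows)


def score_triples(network: LSADDINetwork, triples: list[DDITriple],
                  dataset: DDIDataset) -> np.ndarray:
    """Deterministic scores for arbitrary triples (canonical conformers,
    evaluation mode)."""
    network.eval()
    drug_ids = sorted({d for t in triples for d in (t.drug_a, t.drug_b)})
    row_of = {d: i for i, d in enumerate(drug_ids)}
    emb = _encode_drugs(network, dataset, drug_ids, None, rotate=False)
    return _triple_scores(network, emb, row_of, triples).data.copy()


def evaluate(network: LSADDINetwork, triples: list[DDITriple],
             dataset: DDIDataset, seed: int = 12345,
             drug_set: list[str] | None = None) -> Metrics:
    """ACC / AUROC / AP / F1 on positives plus 1:1 corrupted negatives.

    Triples carrying explicit labels are scored against those labels
    directly (no corruption).
    """
    if not triples:
        raise ValueError("cannot evaluate on an empty triple list")
    labeled = any(t.label is not None for t in triples)
    if labeled:
        scored = triples
        labels = np.array([t.label for t in triples], dtype=int)
    else:
        rng = np.random.default_rng(seed)
        negs = sample_negatives(triples, drug_set or dataset.drug_ids, rng,
                                dataset.known_positives)
        scored = list(triples) + negs
        labels = np.array([1] * len(triples) + [0] * len(negs))
    if len(np.unique(labels)) < 2:
        raise ValueError("evaluation requires both classes present")
    scores = score_triples(network, scored, dataset)
    probs = 1.0 / (1.0 + np.exp(-scores))
    preds = (probs >= 0.5).astype(int)
    return Metrics(acc=float(accuracy_score(labels, preds)),
                   auroc=float(roc_auc_score(labels, scores)),
                   ap=float(average_precision_score(labels, scores)),
                   f1=float(f1_score(labels, preds, zero_division=0)))


ABLATION_VARIANTS = {
    "full": {},
    "wo_3d": {"use_3d": False},
    "wo_DFE": {"use_dfe": False},
    "wo_contrast": {"use_contrast": False},
    "wo_3d_contrast": {"use_3d": False, "use_contrast": False},
    "scale_4": {"scales": (4,)},
    "scale_1_2": {"scales": (1, 2)},
}


def run_ablation_suite(config: TrainConfig, dataset: DDIDataset,
                       train_triples: list[DDITriple],
                       test_triples: list[DDITriple],
                       variants: list[str] | None = None,
                       eval_seed: int = 12345) -> pd.DataFrame:
    """Train and evaluate the requested variants on identical splits/seeds."""
    names = variants or list(ABLATION_VARIANTS)
    rows = []
    for name in names:
        overrides = ABLATION_VARIANTS[name]
        cfg = replace(config, **overrides)
        subset = DDIDataset(dataset.registry, train_triples)
        subset.known_positives = dataset.known_positives
        subset.graphs = dataset.graphs
        subset.conformers = dataset.conformers
        subset._prepared_seed = dataset._prepared_seed
        net, _ = train(cfg, subset)
        metrics = evaluate(net, test_triples, subset, seed=eval_seed)
        rows.append({"variant": name, **metrics.as_dict()})
    return pd.DataFrame(rows).set_index("variant")
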