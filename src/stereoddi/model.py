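"""User-facing modelling surface: :class:`DDIModel` and :class:`DDIResults`.

Follows the familiar two-object pattern: a model is constructed from data
(a drug registry and a triple table), ``fit()`` trains it and returns a
results object carrying the trained network, the per-epoch history, final
metrics and a ``summary()`` table, plus ``predict`` / ``evaluate`` /
``save`` conveniences.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .chemio import (DDITriple, build_graph, conformer_seed,
                     generate_conformer, read_ddi_table,
                     read_smiles_registry)
from .network import LSADDINetwork
from .predictor import PairScore
from .synthbench import SynthSpec, make_dataset
from .traineval import (DDIDataset, Metrics, TrainConfig, evaluate,
                        score_triples, train)


class DDIModel:
    """Drug–drug interaction model over a registry and a triple table."""

    def __init__(self, registry: dict[str, str], triples: list[DDITriple],
                 config: TrainConfig | None = None):
        self.config = config or TrainConfig()
        self.dataset = DDIDataset(registry, triples)

    @classmethod
    def from_files(cls, registry_path, triples_path,
                   config: TrainConfig | None = None) -> "DDIModel":
        registry = read_smiles_registry(registry_path)
        triples = read_ddi_table(triples_path, registry)
        return cls(registry, triples, config)

    @classmethod
    def from_synthetic(cls, spec: SynthSpec | None = None,
                       config: TrainConfig | None = None) -> "DDIModel":
        registry, triples = make_dataset(spec or SynthSpec())
        return cls(registry, triples, config)

    def fit(self, val_triples: list[DDITriple] | None = None,
            eval_seed: int = 12345) -> "DDIResults":
        network, history = train(self.config, self.dataset,
                                 val_triples=val_triples,
                                 eval_seed=eval_seed)
        return DDIResults(self, network, history)


class DDIResults:
    def __init__(self, model: DDIModel, network: LSADDINetwork,
                 history: pd.DataFrame):
        self.model = model
        self.network = network
        self.history = history
        self.config = model.config
        self.dataset = model.dataset

    # -- inference ------------------------------------------------------------
    def predict(self, smiles_a: str, smiles_b: str, itype: int) -> PairScore:
        """Score one interaction query from raw SMILES."""
        tmp = DDIDataset({"a": smiles_a, "b": smiles_b},
                         [DDITriple("a", "b", itype)])
        tmp.graphs = {d: build_graph(s, d) for d, s in tmp.registry.items()}
        tmp.conformers = {
            d: generate_conformer(s, conformer_seed(d, self.config.seed),
                                  drug_id=d)
            for d, s in tmp.registry.items()}
        tmp._prepared_seed = self.config.seed
        score = score_triples(self.network, tmp.triples, tmp)[0]
        return PairScore.from_score(score)

    def evaluate(self, triples: list[DDITriple],
                 seed: int = 12345) -> Metrics:
        return evaluate(self.network, triples, self.dataset, seed=seed)

    # -- reporting ------------------------------------------------------------
    def summary(self) -> str:
        n_params = sum(p.data.size for p in self.network.parameters())
        last = self.history.iloc[-1] if len(self.history) else None
        buf = io.StringIO()
        line = "=" * 62
        buf.write(line + "\n")
        buf.write("Stereochemistry-aware DDI model\n")
        buf.write(line + "\n")
        rows = [
            ("Drugs", len(self.dataset.drug_ids)),
            ("Triples", len(self.dataset.triples)),
            ("Interaction types", len(self.dataset.relation_ids)),
            ("Parameters", n_params),
            ("Epochs", self.config.epochs),
            ("Batch size", self.config.batch_size),
            ("Initial lr", self.config.lr),
            ("Weight decay", self.config.weight_decay),
            ("3D pathway", self.config.use_3d),
            ("DFE fusion", self.config.use_dfe),
            ("Contrastive", self.config.use_contrast),
            ("Scales", self.config.scales),
            ("Score mode", self.config.score_mode),
        ]
        if last is not None:
            rows += [("Final main loss", f"{last['loss_main']:.4f}"),
                     ("Final gamma(t)", f"{last['gamma']:.4f}"),
                     ("Final tau", f"{last['tau']:.4f}")]
            for key in ("val_acc", "val_auroc", "val_ap", "val_f1"):
                if key in last and np.isfinite(last[key]):
                    rows.append((key.replace("val_", "Validation ").upper(),
                                 f"{last[key]:.4f}"))
        width = max(len(k) for k, _ in rows)
        for k, v in rows:
            buf.write(f"{k:<{width}}  {v}\n")
        buf.write(line + "\n")
        return buf.getvalue()

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint: parameters + config + relation vocabulary (.npz)."""
        meta = {
            "config": asdict(self.config),
            "relation_ids": self.dataset.relation_ids,
            "registry": self.dataset.registry,
        }
        state = self.network.state_dict()
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode("utf8"), dtype=np.uint8), **state)

    @staticmethod
    def load(path) -> tuple[LSADDINetwork, TrainConfig, dict[str, str]]:
        """Restore (network, config, registry) from a checkpoint."""
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode("utf8"))
            state = {k: data[k] for k in data.files if k != "__meta__"}
        cfg_dict = meta["config"]
        for key in ("scales", "pool_ratios"):
            cfg_dict[key] = tuple(cfg_dict[key])
        config = TrainConfig(**cfg_dict)
        rng = np.random.default_rng(0)  # shapes only; weights overwritten
        network = LSADDINetwork(config.network_config(),
                                [int(r) for r in meta["relation_ids"]], rng)
        network.load_state_dict(state)
        network.eval()
        return network, config, meta["registry"]
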