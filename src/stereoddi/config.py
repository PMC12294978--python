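"""YAML run-configuration loading.

A configuration file holds flat sections mirroring the config dataclasses::

    train:
      epochs: 50
      batch_size: 512
      lr: 5.0e-3
      seed: 7
    model:
      use_3d: true
      use_dfe: true
      use_contrast: true
      score_mode: fused
    spatial3d:
      d: 64
      dropout: 0.1
    topo2d:
      share_parameters: true
      pool_ratios: [0.5, 0.25]
    contrastive:
      scales: [1, 2, 4]
      gamma0: 0.1
      T: 500

Every key is optional; omitted keys keep the published defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .traineval import TrainConfig

_KEYMAP = {
    ("train", "epochs"): "epochs",
    ("train", "batch_size"): "batch_size",
    ("train", "lr"): "lr",
    ("train", "weight_decay"): "weight_decay",
    ("train", "seed"): "seed",
    ("train", "eval_every"): "eval_every",
    ("model", "use_3d"): "use_3d",
    ("model", "use_dfe"): "use_dfe",
    ("model", "use_contrast"): "use_contrast",
    ("model", "score_mode"): "score_mode",
    ("spatial3d", "d"): "d",
    ("spatial3d", "dropout"): "dropout",
    ("topo2d", "share_parameters"): "share_parameters",
    ("topo2d", "pool_ratios"): "pool_ratios",
    ("contrastive", "scales"): "scales",
    ("contrastive", "gamma0"): "gamma0",
    ("contrastive", "T"): "annealing_T",
    ("chemio", "optimize_conformers"): "optimize_conformers",
}


def load_train_config(path) -> TrainConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for section, entries in raw.items():
        if not isinstance(entries, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        for key, value in entries.items():
            field = _KEYMAP.get((section, key))
            if field is None:
                raise ValueError(f"unknown config key: {section}.{key}")
            if field in ("scales", "pool_ratios"):
                value = tuple(value)
            kwargs[field] = value
    return TrainConfig(**kwargs)
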