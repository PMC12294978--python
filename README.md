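# stereoddi

Stereochemistry-aware drug–drug interaction (DDI) prediction from molecular
structure alone.

Most graph-based DDI predictors see only the 2-D molecular graph, so two
drugs that differ purely in double-bond geometry — *cis*/*trans* (Z/E)
isomers — are literally indistinguishable to them, even though such
conformation-dependent differences can change how a drug pair interacts.
`stereoddi` fuses the 2-D topology with 3-D conformer geometry so that this
information survives all the way into the pair score. It is aimed at
computational chemists and ML-for-drug-discovery practitioners who want a
CPU-friendly, fully deterministic, desk-scale implementation whose every
component is unit-testable against closed forms and brute-force oracles.

## The model

For a drug pair (x, y) and an interaction type r the model learns
f : G × G × I → [0, 1], the probability that the pair exhibits interaction
type r.

**2-D pathway.** Atoms carry a 55-dimensional descriptor vector (44-slot
element one-hot, degree, implicit valence, formal charge, radical electrons,
5-slot hybridization one-hot, aromaticity, total hydrogens) and bonds a
6-dimensional one (type one-hot, conjugation, ring flag). A 4-layer
graph-attention trunk with shared parameters (2 heads × 32 dims,
LayerNorm + ELU, bond features as additive attention terms) produces node
states H₂D; self-attention pooling readouts summarise the molecule at atom /
functional-group / scaffold levels.

**3-D pathway.** A conformer is embedded from SMILES by distance geometry
and randomly rotated each epoch (Euler angles ~ U(0, 2π), composed Z·Y·X):

    X_aug = R_θ · X_init

Three encoders act per atom: a coordinate encoder (3 → d), a distance
encoder on centroid distances dᵢ = ‖Xᵢ − c‖₂ (1 → d/2, rotation- and
translation-invariant), and an angle encoder on the unit directions
(Xᵢ − c)/‖Xᵢ − c‖₂ (3 → d/2). Concatenation (width 2d) is fused back to
d = 64.

**Dynamic feature exchange (DFE).** Bidirectional cross-attention aligns
the modalities per molecule:

    α = softmax(H₂D W_Q (H₃D W_K)ᵀ / √d)
    H̃₂D = H₂D + γ · α  (H₃D W_V),   H̃₃D = H₃D + γ · αᵀ (H₂D W_V)

with a learnable gate γ (initial 0.1). Global average pooling gives v₂D,
v₃D; a linear map fuses them into the drug embedding g.

**Scoring.** Each interaction type owns a 64 × 64 bilinear matrix
(RESCAL): score = g_xᵀ W_r g_y, probability = σ(score). Training uses
binary cross-entropy against 1:1 uniformly corrupted negatives.

**Multiscale contrastive regulariser.** Pair representations [g_x ; g_y]
and their independently re-rotated counterparts are average-pooled along
features at scales {1, 2, 4}, L2-normalized, and contrasted with an InfoNCE
loss (learnable temperature τ hard-bounded to [0.1, 2.0]); per-scale losses
are softmax-weighted and annealed into the objective with
γ(t) = 0.1·(1 − t/500):

    L = L_main + γ(t) · Σ_s w_s L_contrast^s

**Optimization.** AdamW (weight decay 10⁻³), batch size 512, initial
learning rate 5·10⁻³ with linear warmup and cosine annealing, global
gradient-norm clipping. Everything is NumPy/float64 on a small reverse-mode
autodiff core, so runs are bitwise reproducible per seed.

## Worked example

```python
from stereoddi import DDIModel, TrainConfig, SynthSpec, warm_split
from stereoddi.traineval import DDIDataset
from stereoddi.synthbench import make_dataset

# synthetic DrugBank-shaped benchmark: 200 drugs (30% as E/Z isomer pairs),
# 3 rule-generated interaction types, 5% label noise
registry, triples = make_dataset(SynthSpec(n_drugs=200, stereo_fraction=0.3,
                                           label_noise=0.05, seed=1))
split = warm_split(triples, seed=1)

model = DDIModel(registry, split.partitions["train"],
                 TrainConfig(epochs=50, seed=1, eval_every=5))
results = model.fit(val_triples=split.partitions["valid"])
print(results.summary())
test = results.evaluate(split.partitions["test"])
print(f"test AUROC = {test.auroc:.3f}")
```

prints (abridged):

```
==============================================================
Stereochemistry-aware DDI model
==============================================================
Drugs              200
Triples            2398
Interaction types  3
Parameters         73461
...
Final main loss    0.2521
Final tau          0.6650
VALIDATION AUROC   0.9282
==============================================================
test AUROC = 0.941
```

The validation AUROC ≈ 0.93 says the model recovered the functional-group
interaction rules from structure despite 5% label noise. On the dedicated
stereochemistry task — probes paired with either the *cis* or the *trans*
member of an isomer pair, where both classes present bit-identical 2-D
graphs — the full model reaches AUROC ≈ 0.99 while the `wo_3d` ablation is
pinned at exactly 0.5, because without the 3-D pathway the two classes are
the same input:

```python
from stereoddi.benchmarks import run_stereo_sensitivity
r = run_stereo_sensitivity(seed=1)
print(r["full_auroc"], r["wo_3d_auroc"])   # 0.991, 0.500
```

A command-line interface mirrors the library
(`stereo-ddi synth|split|train|eval|predict`), e.g.:

```bash
stereo-ddi synth --n-drugs 200 --stereo-fraction 0.3 --seed 1 --out data/
stereo-ddi split --mode cold --fraction 0.2 --seed 7 \
    --registry data/registry.csv --triples data/triples.tsv --out splits/
stereo-ddi train --registry data/registry.csv --triples splits/train.tsv \
    --epochs 50 --seed 1 --out ckpt.npz
stereo-ddi predict --model ckpt.npz --smiles-a 'CCO' \
    --smiles-b 'CCC(=O)O' --type 2
```

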