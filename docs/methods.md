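# Methods

This note records the model as implemented, the defaults and why they hold,
the numerical choices, and what the synthetic benchmarks can and cannot
demonstrate.

## Problem setting and model

The task is relation-typed link prediction over drug pairs: given drugs
x, y (as SMILES) and an interaction type r, output a probability that the
pair exhibits that interaction. The model has four stages:

1. **2-D topological encoder.** Heavy-atom graphs with 55-wide atom and
   6-wide bond descriptors (the atom vector deliberately carries *no*
   stereo flag). The trunk is 4 graph-attention layers sharing one
   parameter set (2 heads × 32 dims concatenated to d = 64), each followed
   by LayerNorm and ELU; the input is LayerNorm-ed and linearly projected
   55 → 64 before the trunk. Bond features enter attention scoring as an
   additive per-edge term — the mechanism is unconstrained by the
   architecture we follow, and an additive term keeps the score linear in
   the bond descriptor. No self-loops are added; an isolated atom
   aggregates to zero and is handled by the following LayerNorm. Three
   readout branches summarise the molecule at atom level (mean of layer-1
   states), functional-group level (self-attention pooling, keep ratio 0.5,
   then mean) and scaffold level (ratio 0.25, then mean), fused by a small
   perceptron. The coarser branches are defined purely by pooling ratio;
   no chemistry-rule scaffold extraction (e.g. Murcko) is attempted.
2. **3-D spatial encoder.** One conformer per drug, embedded with RDKit
   distance geometry (ETKDGv3) on the hydrogen-saturated molecule and
   stripped back to heavy atoms so both modalities index the same atoms.
   Hydrogens do not participate beyond embedding; keeping heavy atoms only
   keeps N identical across modalities. The per-molecule embedding seed is
   CRC32(drug_id) XOR run-seed, so libraries are reproducible across runs
   and machines. No force-field relaxation by default (an optional flag
   exists); raw distance-geometry conformers already separate E/Z
   geometry, which is all the benchmarks require. Per epoch the conformer
   is rigidly rotated by Euler angles drawn uniformly from [0, 2π),
   composed in the fixed order Z·Y·X. Three two-layer perceptron pathways
   (the smallest "multilayer" choice) encode coordinates (3 → d, with
   dropout 0.1 — the only place dropout is applied), centroid distances
   (1 → d/2) and unit direction cosines (3 → d/2); atoms that sit at the
   centroid (any single-atom molecule) emit a zero direction vector under
   an epsilon rule (1e-8). A linear + ReLU + LayerNorm fusion maps the
   2d-wide concatenation back to d.
3. **Dynamic feature exchange.** Single-head cross-attention per molecule
   (queries from 2-D states, keys from 3-D states, scaled by 1/√d) with a
   residual, gate-scaled value injection in both directions; the gate γ is
   a free learnable scalar initialised at 0.1 so early fusion is gentle.
   The exchange is strictly intra-drug: the two drugs of a pair are
   encoded independently with shared weights, and no cross-drug attention
   exists. Note this gate is a different quantity from the annealed
   contrastive weight; they share a symbol in some notations but are kept
   apart here (`gamma_dfe` vs `gamma(t)`).
4. **Scoring.** Modality vectors are pooled by global averaging and fused
   per drug by one linear map of their concatenation (2d → 64); a
   per-relation 64 × 64 bilinear matrix scores the pair. An alternative
   `cross_modal` mode (v2D of one drug against v3D of the other,
   symmetrised) is exposed because the bilinear form is also readable that
   way; `fused` is the default as the more conventional entity-embedding
   reading.

## Training objective

Positives are the observed triples; negatives are generated 1:1 by
replacing one uniformly chosen drug slot with a uniform draw over the drug
set, rejecting known positives up to 20 redraws. The main loss is mean
binary cross-entropy on the logistic scores. Tables that carry an explicit
0/1 `label` column (the stereo task) are scored against those labels
directly.

The contrastive term treats a pair representation [g_x ; g_y] (width 128)
and its recomputation from independently re-rotated conformers as the
positive pair; in-batch others (both views) are negatives. Representations
are average-pooled along the feature axis at scales {1, 2, 4}, L2-normalized
(exact zero vectors pass through, with a warning), and compared by
temperature-scaled cosine similarity. The temperature is reparameterized as
τ = 0.1 + 1.9·σ(τ_raw) so the [0.1, 2.0] range is a hard constraint rather
than a clamp; scale weights are a softmax over three learnable logits. The
combined contrastive loss enters the objective with γ(t) = 0.1·(1 − t/500),
clamped at zero — the annealing clock counts epochs and keeps T = 500
regardless of the actual epoch budget, so short desk-scale runs sit on the
early (strong-regularisation) part of the schedule by design. With a batch
of one pair the InfoNCE loss is exactly zero (no negatives).

Optimization: AdamW, weight decay 1e-3, batch size 512, initial learning
rate 5e-3, cosine annealing to zero over the epoch budget. Two loop-level
stabilisers are package choices: a linear learning-rate warmup over the
first 5 epochs (capped at a fifth of the budget) and global gradient-norm
clipping at 5.0. Without them the 5e-3 start occasionally throws small-data
runs into a flat region they cannot leave within a 50-epoch budget; with
them all tested seeds converge. A non-finite loss aborts with diagnostics.

All stochastic draws — shuffling, rotations, corruption, dropout — come
from a single seeded generator, and the numerics are float64 single-thread
NumPy (on a small reverse-mode autodiff core in `stereoddi.autodiff`), so
identical seeds give bitwise-identical histories. Evaluation uses the
canonical (unrotated) conformer and disables dropout, hence is
deterministic; rotation only augments training views. Metrics (ACC, AUROC,
AP, F1) are computed on positives plus 1:1 corrupted negatives under a
fixed evaluation seed, thresholding probabilities at 0.5 for ACC/F1.

## Splits

Warm start: triple-level 70/10/20 random split. Cold start: the drug set is
partitioned into seen/unseen at a configurable fraction (default 1/5);
triples route to Dtrain (both seen), S1 (both unseen) or S2 (exactly one
unseen). The routing identities (disjoint union, membership rules) are
property-tested over random datasets and hold exactly for every seed and
fraction.

## Synthetic benchmarks — what they emulate and what they do not

`synthbench` produces DrugBank-*shaped* data: a registry of valid SMILES
plus a positives-only triple table over a small type vocabulary. Drugs are
template-assembled (alkyl/branched/aromatic backbones decorated with
carboxylic acid, primary amine, hydroxyl and halide groups); a configurable
fraction is emitted as E/Z isomer pairs around a C=C. Labels follow a fixed
rule book (acid+acid → type 1; acid+amine → type 2; *cis* isomer + hydroxyl
partner → type 3), with a label-noise rate flipping to a random other type.
*Cis* membership is detected from the registry itself (a Z-configured
double bond plus a registered stereo-stripped twin), not from generation
metadata. Defaults — 200 drugs, 3 types, 5% noise, 30% stereo fraction —
are the benchmark conditions used throughout.

E/Z (cis/trans) isomerism carries the stereo signal rather than
enantiomerism: centroid distances provably differ between E and Z isomers
while being rotation-invariant, whereas whether the per-atom
coordinate/distance/angle feature set can separate enantiomers at all is
unsettled (the pooled representation may be effectively achiral); that
question is left as an experimental flag, not a tested claim.

The stereo task pairs a hydroxyl probe with *both* members of an isomer
pair, labelling the *cis* partner 1 and the *trans* partner 0, so the two
classes present bit-identical multisets of 2-D inputs and a 2-D-only model
is chance level *by construction* — the sharpest possible ablation test.

What passing these benchmarks does **not** show: real pharmacology. The
rules are simple, molecules are small (≤ ~15 heavy atoms), there is a
single conformer per drug, no tautomers or charge states, and interaction
labels have no biological content. The benchmarks decide *learnability and
attribution direction* (does the 3-D pathway carry usable, rotation-robust
stereo information through fusion into the score?), not benchmark-level
accuracy on real DDI databases.

## Benchmark protocols and problem sizes

* Learnability: 200-drug functional-group dataset, warm split, full model,
  50 epochs, batch 512; tracked by best validation AUROC (evaluated every
  5 epochs). Typical result ≈ 0.93.
* Stereo sensitivity: 200 examples, 50 epochs, batch 32 — at this dataset
  size an epoch at batch 512 would be a single optimizer step, so the batch
  is matched to the data; trained and scored on the task's examples (the
  wo_3d chance level is input-forced, resubstitution cannot rescue it).
  Typical result: full ≈ 0.96, wo_3d = 0.50.
* Ablation direction: variants trained on the Dtrain partition of a
  drug-level cold-start split (new-drug fraction 0.2) with matched seeds
  and compared on AUROC over the pooled unseen-drug triples (S1 ∪ S2) —
  the setting in which component attribution is meaningful. Removing the
  3-D pathway costs several AUROC points; the exchange and contrastive
  components move the score by less than the seed-to-seed noise floor
  (≈ ±0.003) at this scale, so their attribution direction is at the edge
  of resolution — an expected property of a saturated desk-scale task with
  an annealed regulariser weight of at most 0.1, not of the components'
  large-data behaviour.

These sizes are the package's chosen desk-scale study conditions; the
synthetic generator and the experiment functions in
`stereoddi.benchmarks` pin them so the test suite and the reproduction
script run identical protocols.

## Numerical choices and degenerate inputs

* float64 throughout; segment reductions use a sorted fast path
  (`np.add.reduceat`) with an exact unsorted fallback.
* Softmax/log-sum-exp are computed with detached max-shifts (exactness
  preserved; softmax is shift-invariant).
* Attention over a node with no incoming edges returns a zero aggregate;
  pooling a 1-node graph keeps that node; SAGPool top-k uses stable
  argsort, so ties break by index.
* Batched DFE pads molecules to a common atom count; padded keys are
  masked out of the softmax (−1e30 logits) and padded query rows zeroed
  before the transposed pass — verified equal to the per-molecule dense
  computation to 1e-10.
* Embedding failures retry with seed+1 … seed+5, then fall back to the
  planar 2-D layout with z = 0 (flagged `fallback_2d`, logged).
* Out-of-vocabulary atoms map to the final "other" one-hot slot rather
  than erroring.

## Known limitations

* Single conformer per drug; conformational ensembles are out of scope.
* The 2-D hierarchical readout summaries are produced and tested for their
  invariances but do not feed the pair score; the scored pathway pools the
  exchanged node states, and the contrastive scales supply the multiscale
  structure instead.
* Cold-start metrics at desk scale are not meaningful estimates of
  real-database cold-start performance; the split machinery is exact, the
  numbers are small-sample.
* The autodiff core implements exactly the operator set the model needs;
  it is not a general-purpose framework.
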