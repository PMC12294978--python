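"""Synthetic DrugBank-shaped benchmarks with known label rules.

The generator assembles a drug library from small-molecule templates (alkyl,
branched and aromatic backbones decorated with carboxylic acid, primary
amine, hydroxyl and halide groups) plus a configurable fraction of E/Z
isomer pairs around a C=C double bond.  Isomer pairs share a bit-identical
2-D graph (the featurization carries no stereo descriptor) but different
conformer geometry — which makes stereochemistry sensitivity of a model a
decidable, rule-level property.

Interaction labels follow a fixed rule book over three types:

* type 1 — both drugs carry a carboxylic acid;
* type 2 — one drug carries an acid, the other a primary amine;
* type 3 — one drug is the *cis* (Z) member of an isomer pair and the other
  carries a hydroxyl group.

Pairs matching no rule are omitted (positives-only table, as DrugBank-style
triple tables are shaped).  A label-noise rate flips labels to a random
other type.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .chemio import DDITriple, parse_smiles

N_TYPES = 3

ACID_SMARTS = Chem.MolFromSmarts("C(=O)[OX2H1]")
PRIMARY_AMINE_SMARTS = Chem.MolFromSmarts("[NX3;H2;!$(NC=O)]")
HYDROXYL_SMARTS = Chem.MolFromSmarts("[OX2H;!$(OC=O)]")

# substituent fragments flanking a C=C: prefix (left) and suffix (right) forms
_STEREO_SUBS = ["F", "Cl", "Br", "I", "C", "CC", "CCC", "CO", "CCO", "C(C)C"]

_BACKBONES = ["CC", "CCC", "CCCC", "CCCCC", "CCCCCC", "CC(C)C", "CC(C)CC",
              "C1CCCC1", "C1CCCCC1", "c1ccccc1", "Cc1ccccc1", "CCc1ccccc1"]
_SUFFIX_GROUPS = ["C(=O)O", "N", "O", "Cl", "Br", "F", ""]
_PREFIX_GROUPS = ["", "OC", "NC"]


@dataclass
class SynthSpec:
    n_drugs: int = 200
    n_types: int = N_TYPES
    label_noise: float = 0.05
    stereo_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_drugs < 4:
            raise ValueError("need n_drugs >= 4")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        if not 0.0 <= self.stereo_fraction <= 1.0:
            raise ValueError("stereo_fraction must lie in [0, 1]")
        if self.n_types != N_TYPES:
            raise ValueError("the rule book defines exactly 3 interaction types")


def _canonical(smiles: str) -> str:
    return Chem.MolToSmiles(parse_smiles(smiles))


def _skeleton(smiles: str) -> str:
    """Canonical SMILES with stereo stripped (the shared 2-D constitution)."""
    mol = parse_smiles(smiles)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def stereo_pair_templates() -> list[tuple[str, str]]:
    """(cis, trans) SMILES pairs around a C=C, from substituent combos."""
    pairs = []
    seen = set()
    for a, b in itertools.combinations_with_replacement(_STEREO_SUBS, 2):
        cis = f"{a}/C=C\\{b}"
        trans = f"{a}/C=C/{b}"
        try:
            c_cis, c_trans = _canonical(cis), _canonical(trans)
        except Exception:  # pragma: no cover - all templates parse
            continue
        if c_cis == c_trans or c_cis in seen or c_trans in seen:
            continue  # stereo centre degenerate for this combo
        seen.update((c_cis, c_trans))
        pairs.append((cis, trans))
    return pairs


def plain_templates() -> list[str]:
    """Achiral decorated-backbone SMILES (deduplicated, all parseable)."""
    out, seen = [], set()
    for pre, backbone, suf in itertools.product(_PREFIX_GROUPS, _BACKBONES,
                                                _SUFFIX_GROUPS):
        smi = f"{pre}{backbone}{suf}"
        try:
            canon = _canonical(smi)
        except Exception:
            continue
        if canon in seen:
            continue
        seen.add(canon)
        out.append(smi)
    return out


def generate_drug_library(spec: SynthSpec) -> dict[str, str]:
    """Deterministic registry of `n_drugs` valid, unique SMILES."""
    rng = np.random.default_rng(spec.seed)
    n_pairs = int(round(spec.stereo_fraction * spec.n_drugs / 2))
    stereo = stereo_pair_templates()
    if n_pairs > len(stereo):
        raise ValueError(f"only {len(stereo)} stereo pair templates available, "
                         f"{n_pairs} requested")
    rng.shuffle(stereo)
    chosen_pairs = stereo[:n_pairs]
    stereo_smiles = [s for pair in chosen_pairs for s in pair]
    plain = plain_templates()
    stereo_skeletons = {_skeleton(s) for s in stereo_smiles}
    plain = [s for s in plain if _skeleton(s) not in stereo_skeletons]
    n_plain = spec.n_drugs - len(stereo_smiles)
    if n_plain > len(plain):
        raise ValueError(f"only {len(plain)} plain templates available, "
                         f"{n_plain} requested")
    rng.shuffle(plain)
    smiles_list = stereo_smiles + plain[:n_plain]
    width = max(4, len(str(spec.n_drugs)))
    return {f"D{i:0{width}d}": smi for i, smi in enumerate(smiles_list)}


def _group_flags(smiles: str) -> dict[str, bool]:
    mol = parse_smiles(smiles)
    return {
        "acid": mol.HasSubstructMatch(ACID_SMARTS),
        "amine": mol.HasSubstructMatch(PRIMARY_AMINE_SMARTS),
        "hydroxyl": mol.HasSubstructMatch(HYDROXYL_SMARTS),
    }


def _has_z_double_bond(smiles: str) -> bool:
    mol = parse_smiles(smiles)
    return any(b.GetStereo() == Chem.rdchem.BondStereo.STEREOZ
               for b in mol.GetBonds())


def cis_members(registry: dict[str, str]) -> set[str]:
    """Drugs that are the Z (cis) member of an isomer pair in the registry.

    A drug qualifies if it carries a Z-configured double bond and the
    registry also contains a drug with the same stereo-stripped constitution
    but a different stereo SMILES (its E twin).
    """
    by_skeleton: dict[str, list[str]] = {}
    for drug_id, smi in registry.items():
        by_skeleton.setdefault(_skeleton(smi), []).append(drug_id)
    out = set()
    for ids in by_skeleton.values():
        if len(ids) < 2:
            continue
        for drug_id in ids:
            if _has_z_double_bond(registry[drug_id]):
                out.add(drug_id)
    return out


def rule_label(flags_a: dict, flags_b: dict, a_cis: bool, b_cis: bool
               ) -> int | None:
    """Apply the rule book to one unordered pair; None when no rule fires."""
    if flags_a["acid"] and flags_b["acid"]:
        return 1
    if (flags_a["acid"] and flags_b["amine"]) or \
            (flags_b["acid"] and flags_a["amine"]):
        return 2
    if (a_cis and flags_b["hydroxyl"]) or (b_cis and flags_a["hydroxyl"]):
        return 3
    return None


def generate_ddi_labels(registry: dict[str, str],
                        spec: SynthSpec) -> list[DDITriple]:
    """Rule-generated triple table over all unordered drug pairs."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    ids = sorted(registry)
    flags = {d: _group_flags(registry[d]) for d in ids}
    cis = cis_members(registry)
    triples = []
    for a, b in itertools.combinations(ids, 2):
        label = rule_label(flags[a], flags[b], a in cis, b in cis)
        if label is None:
            continue
        if spec.label_noise > 0 and rng.random() < spec.label_noise:
            others = [t for t in range(1, spec.n_types + 1) if t != label]
            label = others[rng.integers(len(others))]
        triples.append(DDITriple(a, b, label))
    if not triples:
        raise ValueError("registry contains no rule-eligible drug pair")
    return triples


def make_dataset(spec: SynthSpec) -> tuple[dict[str, str], list[DDITriple]]:
    registry = generate_drug_library(spec)
    return registry, generate_ddi_labels(registry, spec)


# probe alcohols for the stereochemistry task
_PROBES = ["CCO", "CCCO", "CCCCO", "CC(C)O", "CC(C)CO", "OCC1CCCCC1",
           "OC1CCCCC1", "OCc1ccccc1", "CCC(C)O", "OCCO"]


def make_stereo_task(n_examples: int = 200, seed: int = 0
                     ) -> tuple[dict[str, str], list[DDITriple]]:
    """Balanced binary task separable only through 3-D geometry.

    Each duo pairs one hydroxyl probe with *both* members of an E/Z isomer
    pair: (probe, cis) is labelled 1 and (probe, trans) 0, so the two
    classes present bit-identical multisets of 2-D graphs and any 2-D-only
    model is chance level by construction.
    """
    if n_examples % 2:
        raise ValueError("n_examples must be even (cis/trans duos)")
    rng = np.random.default_rng(seed)
    pairs = stereo_pair_templates()
    rng.shuffle(pairs)
    registry: dict[str, str] = {}
    for i, smi in enumerate(_PROBES):
        registry[f"P{i:03d}"] = smi
    pair_ids = []
    for i, (cis, trans) in enumerate(pairs):
        registry[f"Z{i:03d}"] = cis
        registry[f"E{i:03d}"] = trans
        pair_ids.append((f"Z{i:03d}", f"E{i:03d}"))
    triples = []
    for _ in range(n_examples // 2):
        probe = f"P{rng.integers(len(_PROBES)):03d}"
        cis_id, trans_id = pair_ids[rng.integers(len(pair_ids))]
        triples.append(DDITriple(probe, cis_id, 3, label=1))
        triples.append(DDITriple(probe, trans_id, 3, label=0))
    used = {d for t in triples for d in (t.drug_a, t.drug_b)}
    registry = {k: v for k, v in registry.items() if k in used}
    return registry, triples
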