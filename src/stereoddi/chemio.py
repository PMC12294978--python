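"""Molecule parsing, featurization, conformer generation, and file I/O.

Drugs enter the model as heavy-atom graphs built from SMILES with RDKit.
Each atom carries a 55-wide descriptor vector and each directed bond a
6-wide one:

===================================  =====
atomic symbol (one-hot, fixed list)     44
degree                                   1
implicit valence                         1
formal charge                            1
radical electrons                        1
hybridization (one-hot)                  5
aromatic flag                            1
total hydrogens                          1
-----------------------------------  -----
node subtotal                           55
===================================  =====

bond type one-hot {single, double, triple, aromatic} (4) + conjugation (1)
+ in-ring (1) = 6.  Note the node vector carries **no stereo descriptor**:
E/Z isomers produce bit-identical graphs, and only the 3-D pathway can tell
them apart — the property the stereochemistry benchmark exploits.

3-D conformers are embedded with RDKit distance geometry (ETKDG) on the
hydrogen-saturated molecule and then stripped back to the heavy atoms, so
coordinates and graph share one atom ordering.
"""

from __future__ import annotations

import csv
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

NODE_FEATURE_DIM = 55
EDGE_FEATURE_DIM = 6

# Fixed atomic-symbol vocabulary (44 slots, last = out-of-vocabulary "other").
ATOM_SYMBOLS = [
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb", "other",
]

HYBRIDIZATIONS = [
    Chem.rdchem.HybridizationType.SP,
    Chem.rdchem.HybridizationType.SP2,
    Chem.rdchem.HybridizationType.SP3,
    Chem.rdchem.HybridizationType.SP3D,
    Chem.rdchem.HybridizationType.SP3D2,
]

BOND_TYPES = [
    Chem.rdchem.BondType.SINGLE,
    Chem.rdchem.BondType.DOUBLE,
    Chem.rdchem.BondType.TRIPLE,
    Chem.rdchem.BondType.AROMATIC,
]


class InputError(ValueError):
    """Raised for malformed user inputs (bad SMILES, broken tables)."""


@dataclass
class MolecularGraph:
    """Heavy-atom 2-D topology of one drug."""

    drug_id: str
    n_atoms: int
    node_features: np.ndarray  # [N, 55]
    edges: np.ndarray          # [E, 2] directed pairs, both directions present
    edge_features: np.ndarray  # [E, 6]

    def __post_init__(self):
        assert self.node_features.shape == (self.n_atoms, NODE_FEATURE_DIM)
        if self.edges.size:
            assert self.edge_features.shape == (self.edges.shape[0],
                                                EDGE_FEATURE_DIM)


@dataclass
class Conformer:
    """Heavy-atom 3-D coordinates (Å) aligned with the MolecularGraph order."""

    drug_id: str
    coordinates: np.ndarray  # [N, 3]
    provenance: str = "embedded"  # or "fallback_2d"

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError(f"non-finite coordinates for {self.drug_id}")


@dataclass
class Rotation:
    """A proper rotation, stored both as Euler angles and as a matrix."""

    euler_angles: tuple[float, float, float]
    matrix: np.ndarray = field(init=False)

    def __post_init__(self):
        self.matrix = euler_to_matrix(*self.euler_angles)


def parse_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparseable SMILES: {smiles!r}")
    return mol


def featurize_atoms(mol: Chem.Mol) -> np.ndarray:
    """Per-atom 55-wide descriptor rows for the heavy atoms of `mol`."""
    rows = np.zeros((mol.GetNumAtoms(), NODE_FEATURE_DIM))
    for i, atom in enumerate(mol.GetAtoms()):
        sym = atom.GetSymbol()
        j = ATOM_SYMBOLS.index(sym) if sym in ATOM_SYMBOLS else len(ATOM_SYMBOLS) - 1
        rows[i, j] = 1.0
        rows[i, 44] = atom.GetDegree()
        rows[i, 45] = atom.GetImplicitValence()
        rows[i, 46] = atom.GetFormalCharge()
        rows[i, 47] = atom.GetNumRadicalElectrons()
        hyb = atom.GetHybridization()
        if hyb in HYBRIDIZATIONS:
            rows[i, 48 + HYBRIDIZATIONS.index(hyb)] = 1.0
        rows[i, 53] = float(atom.GetIsAromatic())
        rows[i, 54] = atom.GetTotalNumHs()
    return rows


def featurize_bonds(mol: Chem.Mol) -> tuple[np.ndarray, np.ndarray]:
    """Directed edge list and 6-wide bond descriptors (each bond twice)."""
    edges, feats = [], []
    for bond in mol.GetBonds():
        row = np.zeros(EDGE_FEATURE_DIM)
        bt = bond.GetBondType()
        if bt in BOND_TYPES:
            row[BOND_TYPES.index(bt)] = 1.0
        row[4] = float(bond.GetIsConjugated())
        row[5] = float(bond.IsInRing())
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.append((i, j))
        feats.append(row)
        edges.append((j, i))
        feats.append(row.copy())
    if not edges:
        return (np.zeros((0, 2), dtype=np.intp),
                np.zeros((0, EDGE_FEATURE_DIM)))
    edge_arr = np.asarray(edges, dtype=np.intp)
    feat_arr = np.asarray(feats)
    # stable sort by destination: batched scatter ops take their fast path
    order = np.argsort(edge_arr[:, 1], kind="stable")
    return edge_arr[order], feat_arr[order]


def build_graph(smiles: str, drug_id: str = "") -> MolecularGraph:
    mol = parse_smiles(smiles)
    nodes = featurize_atoms(mol)
    edges, efeat = featurize_bonds(mol)
    return MolecularGraph(drug_id=drug_id, n_atoms=mol.GetNumAtoms(),
                          node_features=nodes, edges=edges,
                          edge_features=efeat)


def conformer_seed(drug_id: str, run_seed: int) -> int:
    """Stable per-drug embedding seed: CRC32(drug_id) XOR run seed, < 2^31."""
    return (zlib.crc32(drug_id.encode("utf8")) ^ (run_seed & 0x7FFFFFFF)) & 0x7FFFFFFF


def generate_conformer(smiles: str, seed: int, drug_id: str = "",
                       max_retries: int = 5,
                       optimize: bool = False) -> Conformer:
    """Embed a 3-D conformer with distance geometry, deterministically.

    Hydrogens are added for the embedding and stripped afterwards so the
    coordinate rows align with the heavy-atom graph.  On repeated embedding
    failure the planar 2-D layout (z = 0) is used and flagged as
    ``fallback_2d``.
    """
    mol = parse_smiles(smiles)
    n_heavy = mol.GetNumAtoms()
    molh = Chem.AddHs(mol)
    conf_id = -1
    for attempt in range(max_retries + 1):
        params = AllChem.ETKDGv3()
        params.randomSeed = int((seed + attempt) & 0x7FFFFFFF)
        conf_id = AllChem.EmbedMolecule(molh, params)
        if conf_id >= 0:
            break
    if conf_id >= 0:
        if optimize:
            AllChem.MMFFOptimizeMolecule(molh, confId=conf_id)
        pos = molh.GetConformer(conf_id).GetPositions()
        coords = np.asarray(pos[:n_heavy], dtype=np.float64)
        return Conformer(drug_id=drug_id, coordinates=coords,
                         provenance="embedded")
    logger.warning("3D embedding failed for %r; using planar 2D fallback",
                   smiles)
    AllChem.Compute2DCoords(mol)
    pos = mol.GetConformer().GetPositions()
    coords = np.asarray(pos, dtype=np.float64)
    coords[:, 2] = 0.0
    return Conformer(drug_id=drug_id, coordinates=coords,
                     provenance="fallback_2d")


def euler_to_matrix(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Proper rotation matrix R = Rz(alpha) · Ry(beta) · Rx(gamma)."""
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    cg, sg = np.cos(gamma), np.sin(gamma)
    rz = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    ry = np.array([[cb, 0.0, sb], [0.0, 1.0, 0.0], [-sb, 0.0, cb]])
    rx = np.array([[1.0, 0.0, 0.0], [0.0, cg, -sg], [0.0, sg, cg]])
    return rz @ ry @ rx


def sample_rotation(rng: np.random.Generator) -> Rotation:
    """Three Euler angles each drawn uniformly from [0, 2π)."""
    angles = tuple(rng.uniform(0.0, 2.0 * np.pi, size=3))
    return Rotation(euler_angles=angles)


def rotate_coordinates(coords: np.ndarray, rotation: Rotation) -> np.ndarray:
    return coords @ rotation.matrix.T


def random_rotation(conformer: Conformer,
                    rng: np.random.Generator) -> Conformer:
    """Rigid random rotation X_aug = R·X applied row-wise."""
    rot = sample_rotation(rng)
    return Conformer(drug_id=conformer.drug_id,
                     coordinates=rotate_coordinates(conformer.coordinates, rot),
                     provenance=conformer.provenance)


# ---------------------------------------------------------------------------
# registry / triple-table I/O
# ---------------------------------------------------------------------------

def _sniff_delimiter(path: Path) -> str:
    head = path.read_text().splitlines()[0]
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_smiles_registry(path) -> dict[str, str]:
    """Read a drug registry (columns ``id``, ``smiles``; CSV/TSV or .smi).

    ``.smi`` files are whitespace-delimited ``SMILES id`` lines without a
    header, as the format is conventionally written.
    """
    path = Path(path)
    registry: dict[str, str] = {}
    if path.suffix == ".smi":
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise InputError(f"bad .smi line: {line!r}")
            smiles, drug_id = parts[0], parts[1]
            if drug_id in registry:
                raise InputError(f"duplicate drug id: {drug_id}")
            registry[drug_id] = smiles
        return registry
    delim = _sniff_delimiter(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        cols = set(reader.fieldnames or ())
        if not {"id", "smiles"} <= cols:
            raise InputError(f"registry needs columns id,smiles; got {sorted(cols)}")
        for row in reader:
            drug_id = row["id"].strip()
            if drug_id in registry:
                raise InputError(f"duplicate drug id: {drug_id}")
            registry[drug_id] = row["smiles"].strip()
    for drug_id, smi in registry.items():
        parse_smiles(smi)  # fail fast with the offending string
    return registry


def write_smiles_registry(registry: dict[str, str], path) -> None:
    path = Path(path)
    if path.suffix == ".smi":  # headerless "SMILES id" lines
        path.write_text("".join(f"{smi} {drug_id}\n"
                                for drug_id, smi in registry.items()))
        return
    delim = "\t" if path.suffix == ".tsv" else ","
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(["id", "smiles"])
        for drug_id, smi in registry.items():
            writer.writerow([drug_id, smi])


@dataclass(frozen=True)
class DDITriple:
    drug_a: str
    drug_b: str
    itype: int
    label: int | None = None  # optional explicit 0/1 label


def read_ddi_table(path, registry: dict[str, str] | None = None
                   ) -> list[DDITriple]:
    """Read a triple table (columns drug_a, drug_b, type[, label])."""
    path = Path(path)
    delim = _sniff_delimiter(path)
    triples: list[DDITriple] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        cols = set(reader.fieldnames or ())
        if not {"drug_a", "drug_b", "type"} <= cols:
            raise InputError(
                f"triple table needs columns drug_a,drug_b,type; got {sorted(cols)}")
        has_label = "label" in cols
        for row in reader:
            label = int(row["label"]) if has_label and row["label"] != "" else None
            triples.append(DDITriple(row["drug_a"].strip(), row["drug_b"].strip(),
                                     int(row["type"]), label))
    if registry is not None:
        unknown = sorted({d for t in triples for d in (t.drug_a, t.drug_b)}
                         - set(registry))
        if unknown:
            raise InputError(f"triples reference unknown drug ids: {unknown}")
    return triples


def write_ddi_table(triples: Iterable[DDITriple], path) -> None:
    path = Path(path)
    delim = "\t" if path.suffix == ".tsv" else ","
    has_label = any(t.label is not None for t in triples)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        header = ["drug_a", "drug_b", "type"] + (["label"] if has_label else [])
        writer.writerow(header)
        for t in triples:
            row = [t.drug_a, t.drug_b, t.itype]
            if has_label:
                row.append("" if t.label is None else t.label)
            writer.writerow(row)


def export_sdf(conformers: Iterable[Conformer], registry: dict[str, str],
               path) -> None:
    """Write conformers to an SDF file (heavy atoms only)."""
    writer = Chem.SDWriter(str(path))
    try:
        for conf in conformers:
            mol = parse_smiles(registry[conf.drug_id])
            rd_conf = Chem.Conformer(mol.GetNumAtoms())
            for i, (x, y, z) in enumerate(conf.coordinates):
                rd_conf.SetAtomPosition(i, (float(x), float(y), float(z)))
            mol.AddConformer(rd_conf)
            mol.SetProp("_Name", conf.drug_id)
            mol.SetProp("provenance", conf.provenance)
            writer.write(mol)
    finally:
        writer.close()
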