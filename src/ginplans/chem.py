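"""SMILES parsing, extended-connectivity fingerprints and molecular graphs.

All chemistry goes through RDKit.  Molecules that RDKit cannot load are
rejected explicitly; callers drop such records and log them.

Graphs are heavy-atom only (hydrogens implicit).  Node features are a
fixed-length concatenation of one-hot blocks — atom type, degree, formal
charge, hybridization, aromaticity flag, chirality tag — each with an
overflow bucket so the encoding length never depends on the molecule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from rdkit import Chem
from rdkit import RDLogger
from rdkit.Chem import rdFingerprintGenerator

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.error")  # parse failures are reported by us, not stderr


class SmilesParseError(ValueError):
    """Raised when RDKit cannot load a SMILES string."""


def parse_smiles(smiles: str) -> Chem.Mol:
    """Parse and sanitize a SMILES string; raises SmilesParseError on failure."""
    mol = Chem.MolFromSmiles(smiles) if isinstance(smiles, str) else None
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    return mol


def try_parse_smiles(smiles: str) -> Chem.Mol | None:
    try:
        return parse_smiles(smiles)
    except SmilesParseError:
        return None


# ---------------------------------------------------------------------------
# ECFP


def compute_ecfp(mol: Chem.Mol, radius: int = 4, n_bits: int = 2048,
                 use_chirality: bool = False) -> np.ndarray:
    """Binary Morgan/ECFP vector of length ``n_bits`` (folded).

    Defaults follow the reference setup: radius 4, 2048 bits, chirality
    flags off (configurable).
    """
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=n_bits, includeChirality=use_chirality
    )
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def ecfp_matrix(smiles_list, radius: int = 4, n_bits: int = 2048,
                use_chirality: bool = False):
    """Fingerprint each loadable SMILES; returns (matrix, dropped indices)."""
    rows, dropped = [], []
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=n_bits, includeChirality=use_chirality
    )
    for i, smi in enumerate(smiles_list):
        mol = try_parse_smiles(smi)
        if mol is None:
            dropped.append(i)
            continue
        arr = np.zeros(n_bits, dtype=np.uint8)
        for bit in gen.GetFingerprint(mol).GetOnBits():
            arr[bit] = 1
        rows.append(arr)
    if dropped:
        logger.info("dropped %d unloadable SMILES at indices %s", len(dropped), dropped)
    mat = np.vstack(rows) if rows else np.zeros((0, n_bits), dtype=np.uint8)
    return mat, dropped


# ---------------------------------------------------------------------------
# Molecular graphs

_ATOM_TYPES = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P")
_DEGREES = (0, 1, 2, 3, 4, 5)
_FORMAL_CHARGES = (-2, -1, 0, 1, 2)
_HYBRIDIZATIONS = (
    Chem.HybridizationType.S,
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
)
_CHIRAL_TAGS = (
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
)

#: fixed node-feature length (each block gets an overflow bucket; +1 aromatic)
NODE_FEATURE_DIM = (
    len(_ATOM_TYPES) + 1 + len(_DEGREES) + 1 + len(_FORMAL_CHARGES) + 1
    + len(_HYBRIDIZATIONS) + 1 + 1 + len(_CHIRAL_TAGS) + 1
)

# offsets of the one-hot blocks inside the feature vector
_OFF_TYPE = 0
_OFF_DEGREE = _OFF_TYPE + len(_ATOM_TYPES) + 1
_OFF_CHARGE = _OFF_DEGREE + len(_DEGREES) + 1
_OFF_HYB = _OFF_CHARGE + len(_FORMAL_CHARGES) + 1
_OFF_AROMATIC = _OFF_HYB + len(_HYBRIDIZATIONS) + 1
_OFF_CHIRAL = _OFF_AROMATIC + 1


def _one_hot_index(value, choices) -> int:
    try:
        return choices.index(value)
    except ValueError:
        return len(choices)  # overflow bucket


def _atom_features(atom: Chem.Atom) -> np.ndarray:
    f = np.zeros(NODE_FEATURE_DIM, dtype=np.float32)
    f[_OFF_TYPE + _one_hot_index(atom.GetSymbol(), list(_ATOM_TYPES))] = 1.0
    f[_OFF_DEGREE + _one_hot_index(atom.GetDegree(), list(_DEGREES))] = 1.0
    f[_OFF_CHARGE + _one_hot_index(atom.GetFormalCharge(), list(_FORMAL_CHARGES))] = 1.0
    f[_OFF_HYB + _one_hot_index(atom.GetHybridization(), list(_HYBRIDIZATIONS))] = 1.0
    f[_OFF_AROMATIC] = 1.0 if atom.GetIsAromatic() else 0.0
    f[_OFF_CHIRAL + _one_hot_index(atom.GetChiralTag(), list(_CHIRAL_TAGS))] = 1.0
    return f


def degree_from_features(feature_row: np.ndarray) -> int:
    """Degree encoded in a node-feature row (index of the one-hot block)."""
    block = feature_row[_OFF_DEGREE:_OFF_DEGREE + len(_DEGREES) + 1]
    return int(np.argmax(block))


@dataclass
class MolecularGraph:
    """Heavy-atom graph: featurized nodes, one undirected edge per bond."""

    node_features: np.ndarray  # (n_nodes, NODE_FEATURE_DIM) float32
    edges: np.ndarray          # (n_edges, 2) int64, i < j, each bond once
    n_nodes: int

    def __post_init__(self):
        self.node_features = np.asarray(self.node_features, dtype=np.float32)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if self.node_features.shape[0] != self.n_nodes:
            raise ValueError("node_features row count != n_nodes")
        if self.edges.size:
            if self.edges.min() < 0 or self.edges.max() >= self.n_nodes:
                raise ValueError("edge index out of range")
            if (self.edges[:, 0] == self.edges[:, 1]).any():
                raise ValueError("self-loops are not allowed")

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric 0/1 adjacency matrix (csr)."""
        if self.n_edges == 0:
            return sparse.csr_matrix((self.n_nodes, self.n_nodes), dtype=np.float32)
        i, j = self.edges[:, 0], self.edges[:, 1]
        rows = np.concatenate([i, j])
        cols = np.concatenate([j, i])
        data = np.ones(rows.size, dtype=np.float32)
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(self.n_nodes, self.n_nodes)
        )

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def permute(self, perm) -> "MolecularGraph":
        """Relabel nodes: node i of the new graph is node perm[i] of this one."""
        perm = np.asarray(perm, dtype=np.int64)
        if sorted(perm.tolist()) != list(range(self.n_nodes)):
            raise ValueError("perm must be a permutation of node indices")
        inv = np.empty_like(perm)
        inv[perm] = np.arange(self.n_nodes)
        new_edges = inv[self.edges] if self.edges.size else self.edges
        new_edges = np.sort(new_edges, axis=1) if new_edges.size else new_edges
        return MolecularGraph(self.node_features[perm], new_edges, self.n_nodes)


def build_graph(mol: Chem.Mol) -> MolecularGraph:
    """Featurized heavy-atom graph of a parsed molecule."""
    feats = np.vstack([_atom_features(a) for a in mol.GetAtoms()])
    edges = [
        (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
         max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        for b in mol.GetBonds()
    ]
    edges = np.array(edges, dtype=np.int64).reshape(-1, 2)
    return MolecularGraph(feats, edges, mol.GetNumAtoms())


def graphs_from_smiles(smiles_list):
    """Build graphs for loadable SMILES; returns (graphs, dropped indices)."""
    graphs, dropped = [], []
    for i, smi in enumerate(smiles_list):
        mol = try_parse_smiles(smi)
        if mol is None:
            dropped.append(i)
            continue
        graphs.append(build_graph(mol))
    if dropped:
        logger.info("dropped %d unloadable SMILES at indices %s", len(dropped), dropped)
    return graphs, dropped


def read_smiles_file(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
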