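"""Synthetic drug-like molecules with planted substructure labels.

The generator assembles molecules from a curated vocabulary of valid
fragments (alkyl chains, aromatic rings, common heteroatom substituents)
joined by single bonds, so every output is a sanitizable, valence-
respecting SMILES.  Activity against each target is planted as a
substructure rule — the molecule is active iff it contains that target's
motif — then optionally corrupted by label noise, masked cell-wise at
random (partially labeled pool), or stripped entirely (unlabeled pool).

Motif-bearing fragments are rare in the vocabulary, so the all-negative
profile dominates the class distribution, mirroring the imbalance of
real enzyme-panel datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem import parse_smiles
from .labels import MISSING

# (SMILES, sampling weight); motif carriers are deliberately down-weighted
FRAGMENT_VOCABULARY: tuple[tuple[str, float], ...] = (
    ("C", 3.0),
    ("CC", 3.0),
    ("CCC", 2.0),
    ("CC(C)C", 1.5),
    ("c1ccccc1", 3.0),
    ("C1CCCCC1", 1.5),
    ("O", 2.0),
    ("OC", 1.5),
    ("N", 1.5),
    ("CCO", 1.0),
    ("F", 1.0),
    ("c1ccncc1", 0.8),
    ("C(=O)O", 0.8),
    ("Cl", 0.8),
    ("CS", 0.8),
    ("C(=O)N", 0.8),
)

#: default planted activity rules, one per target
DEFAULT_MOTIFS: tuple[str, ...] = (
    "c1ccncc1",   # pyridine ring
    "C(=O)O",     # carboxyl / ester
    "[Cl]",       # chlorine
    "[#16]",      # any sulfur
    "C(=O)N",     # amide
)


#: fragments that carry one of the default motifs
MOTIF_FRAGMENTS: frozenset[str] = frozenset(
    {"c1ccncc1", "C(=O)O", "Cl", "CS", "C(=O)N"})


def vocabulary_with_motif_weight(weight: float) -> tuple[tuple[str, float], ...]:
    """Copy of the built-in vocabulary with motif-carrier weights replaced.

    Raising the weight lifts per-target positive rates (less imbalance);
    the default vocabulary keeps motifs rare so the all-negative class
    dominates.
    """
    return tuple(
        (s, weight if s in MOTIF_FRAGMENTS else w) for s, w in FRAGMENT_VOCABULARY
    )


class MotifError(ValueError):
    """Raised when a motif is not a valid substructure query."""


@dataclass
class SyntheticConfig:
    n_molecules: int
    n_targets: int = 5
    motif_smarts: tuple[str, ...] = DEFAULT_MOTIFS
    label_noise: float = 0.0
    missing_rate: float = 0.0
    unlabeled_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.n_targets != len(self.motif_smarts):
            raise ValueError(
                f"n_targets={self.n_targets} but {len(self.motif_smarts)} motifs given"
            )
        if not 0.0 <= self.label_noise < 1.0:
            raise ValueError(f"label_noise must lie in [0, 1); got {self.label_noise}")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"missing_rate must lie in [0, 1]; got {self.missing_rate}")
        if not 0.0 <= self.unlabeled_fraction < 1.0:
            raise ValueError(
                f"unlabeled_fraction must lie in [0, 1); got {self.unlabeled_fraction}")


@dataclass
class SyntheticDataset:
    smiles: list[str]
    ground_truth: np.ndarray                     # (n, t) complete labels
    fully_labeled: list[tuple[str, np.ndarray]]
    partially_labeled: list[tuple[str, np.ndarray]]
    unlabeled: list[str]
    fully_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    partial_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    unlabeled_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))


def _attachable_atoms(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() >= 1]


def generate_molecules(n: int, seed: int, min_fragments: int = 2,
                       max_fragments: int = 5, max_retries: int = 50,
                       vocabulary: tuple[tuple[str, float], ...] = FRAGMENT_VOCABULARY,
                       ) -> list[str]:
    """Assemble ``n`` valid SMILES from the fragment vocabulary.

    Fragments are joined sequentially by single bonds at hydrogen-bearing
    atoms; each candidate is sanitized before acceptance, and generation
    retries until a valid molecule is produced (raises RuntimeError only
    if the retry budget is exhausted, which does not occur with the
    built-in vocabulary).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    frags = [Chem.MolFromSmiles(s) for s, _ in vocabulary]
    if any(f is None for f in frags):
        raise ValueError("vocabulary contains an unparseable fragment")
    weights = np.array([w for _, w in vocabulary], dtype=np.float64)
    weights /= weights.sum()
    out: list[str] = []
    for _ in range(n):
        smi = None
        for _attempt in range(max_retries):
            k = int(rng.integers(min_fragments, max_fragments + 1))
            picks = rng.choice(len(frags), size=k, p=weights)
            mol = Chem.RWMol(frags[picks[0]])
            ok = True
            for fi in picks[1:]:
                sites = _attachable_atoms(mol)
                frag = frags[fi]
                frag_sites = _attachable_atoms(frag)
                if not sites or not frag_sites:
                    break  # molecule saturated; accept as-is
                a = int(rng.choice(sites))
                b = int(rng.choice(frag_sites))
                offset = mol.GetNumAtoms()
                combined = Chem.RWMol(Chem.CombineMols(mol, frag))
                combined.AddBond(a, b + offset, Chem.BondType.SINGLE)
                mol = combined
            try:
                m = mol.GetMol()
                Chem.SanitizeMol(m)
                smi = Chem.MolToSmiles(m)
            except Exception:
                ok = False
            if ok and smi is not None:
                break
        if smi is None:
            raise RuntimeError("molecule generation retry budget exhausted")
        out.append(smi)
    return out


def compile_motifs(motif_smarts) -> list[Chem.Mol]:
    queries = []
    for pattern in motif_smarts:
        q = Chem.MolFromSmarts(pattern)
        if q is None:
            raise MotifError(f"invalid substructure pattern: {pattern!r}")
        queries.append(q)
    return queries


def match_motifs(smiles: str, queries) -> np.ndarray:
    """Indicator vector: entry j is 1 iff the molecule contains motif j."""
    mol = parse_smiles(smiles)
    return np.array([int(mol.HasSubstructMatch(q)) for q in queries], dtype=np.int64)


def plant_labels(molecules: list[str], config: SyntheticConfig) -> SyntheticDataset:
    """Plant motif-rule labels, apply noise/masking, and split into pools.

    ``ground_truth`` holds the complete (post-noise) label matrix for every
    molecule, retained for recovery testing; it never flows through the
    masked pools.
    """
    queries = compile_motifs(config.motif_smarts)
    rng = np.random.default_rng(config.seed)
    n, t = len(molecules), config.n_targets
    truth = np.vstack([match_motifs(s, queries) for s in molecules])
    if config.label_noise > 0:
        flips = rng.random((n, t)) < config.label_noise
        truth = np.where(flips, 1 - truth, truth)
    is_unlabeled = rng.random(n) < config.unlabeled_fraction
    mask = rng.random((n, t)) < config.missing_rate
    fully, partial, unlabeled = [], [], []
    f_idx, p_idx, u_idx = [], [], []
    for i, smi in enumerate(molecules):
        if is_unlabeled[i]:
            unlabeled.append(smi)
            u_idx.append(i)
        elif mask[i].any():
            labels = truth[i].copy()
            labels[mask[i]] = MISSING
            partial.append((smi, labels))
            p_idx.append(i)
        else:
            fully.append((smi, truth[i].copy()))
            f_idx.append(i)
    return SyntheticDataset(
        smiles=list(molecules),
        ground_truth=truth,
        fully_labeled=fully,
        partially_labeled=partial,
        unlabeled=unlabeled,
        fully_idx=np.array(f_idx, dtype=np.int64),
        partial_idx=np.array(p_idx, dtype=np.int64),
        unlabeled_idx=np.array(u_idx, dtype=np.int64),
    )


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Convenience: generate molecules and plant labels in one call."""
    molecules = generate_molecules(config.n_molecules, config.seed)
    return plant_labels(molecules, config)


# ---------------------------------------------------------------------------
# CSV / SMILES-file round trip


def _pool_frame(pool, n_targets: int) -> pd.DataFrame:
    cols = [f"target_{j + 1}" for j in range(n_targets)]
    records = []
    for smi, labels in pool:
        row = {"smiles": smi}
        for j, c in enumerate(cols):
            row[c] = "" if labels[j] == MISSING else int(labels[j])
        records.append(row)
    return pd.DataFrame.from_records(records, columns=["smiles"] + cols)


def write_dataset(dataset: SyntheticDataset, out_dir, n_targets: int | None = None):
    """Write labeled.csv, partial.csv (empty cell = missing) and unlabeled.smi."""
    import os

    if n_targets is None:
        n_targets = dataset.ground_truth.shape[1]
    os.makedirs(out_dir, exist_ok=True)
    _pool_frame(dataset.fully_labeled, n_targets).to_csv(
        os.path.join(out_dir, "labeled.csv"), index=False)
    _pool_frame(dataset.partially_labeled, n_targets).to_csv(
        os.path.join(out_dir, "partial.csv"), index=False)
    with open(os.path.join(out_dir, "unlabeled.smi"), "w") as fh:
        fh.write("".join(s + "\n" for s in dataset.unlabeled))


def read_label_csv(path):
    """Read a label CSV; returns (smiles list, (n, t) int array, MISSING=-1)."""
    df = pd.read_csv(path, dtype={"smiles": str})
    cols = [c for c in df.columns if c != "smiles"]
    labels = df[cols].to_numpy(dtype=float)
    out = np.where(np.isnan(labels), MISSING, labels).astype(np.int64)
    return df["smiles"].tolist(), out
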