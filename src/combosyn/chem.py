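"""SMILES featurization: attributed molecular graphs and ECFP6 fingerprints.

A drug enters the model twice: as a heavy-atom molecular graph M = (V, E)
with a per-atom feature matrix, consumed by the graph encoders, and as a
2,048-bit extended-connectivity fingerprint (Morgan radius 3, i.e. ECFP6),
consumed by a linear embedding branch.

The atom-feature scheme is a fixed, documented 75-dimensional convolutional
featurization: one-hot element over a common-organic set plus "other",
one-hot degree 0-10, one-hot implicit valence 0-6, formal charge, number of
radical electrons, one-hot hybridization (sp, sp2, sp3, sp3d, sp3d2),
aromaticity flag, and one-hot total hydrogen count 0-4.  Hydrogens are
implicit; edge features are not computed.

SMILES are canonicalized before featurization so dialects of the same
molecule map to identical graphs and fingerprints.  Multi-fragment inputs
(salts, mixtures) are reduced to the largest fragment, with a log record.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = [
    "FeaturizationError",
    "MolecularGraph",
    "Fingerprint",
    "ATOM_FEATURE_DIM",
    "smiles_to_graph",
    "smiles_to_fingerprint",
    "canonical_smiles",
]


class FeaturizationError(ValueError):
    """Raised when a SMILES string cannot be turned into a model input."""


_ELEMENTS = [
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb",
]
_HYBRIDIZATIONS = [
    Chem.rdchem.HybridizationType.SP,
    Chem.rdchem.HybridizationType.SP2,
    Chem.rdchem.HybridizationType.SP3,
    Chem.rdchem.HybridizationType.SP3D,
    Chem.rdchem.HybridizationType.SP3D2,
]

#: width of the per-atom feature vector
ATOM_FEATURE_DIM = (len(_ELEMENTS) + 1) + 11 + 7 + 1 + 1 + len(_HYBRIDIZATIONS) + 1 + 5


def _one_hot(value, choices) -> list:
    vec = [0.0] * len(choices)
    if value in choices:
        vec[choices.index(value)] = 1.0
    return vec


def _one_hot_other(value, choices) -> list:
    """One-hot with a trailing 'other' bucket for out-of-set values."""
    vec = [0.0] * (len(choices) + 1)
    vec[choices.index(value) if value in choices else len(choices)] = 1.0
    return vec


def _atom_features(atom: Chem.Atom) -> np.ndarray:
    feats = (
        _one_hot_other(atom.GetSymbol(), _ELEMENTS)
        + _one_hot(atom.GetDegree(), list(range(11)))
        + _one_hot(atom.GetImplicitValence(), list(range(7)))
        + [float(atom.GetFormalCharge()), float(atom.GetNumRadicalElectrons())]
        + _one_hot(atom.GetHybridization(), _HYBRIDIZATIONS)
        + [1.0 if atom.GetIsAromatic() else 0.0]
        + _one_hot(atom.GetTotalNumHs(), list(range(5)))
    )
    return np.asarray(feats, dtype=np.float64)


@dataclass
class MolecularGraph:
    """Heavy-atom molecular graph with node features.

    ``edges`` stores each undirected bond as two symmetric directed pairs;
    ``adjacency`` is the |V|x|V| binary matrix (zero diagonal).
    """

    smiles: str
    drug_id: str
    node_features: np.ndarray          # |V| x ATOM_FEATURE_DIM
    edges: np.ndarray                  # 2E x 2 directed pairs
    adjacency: np.ndarray              # |V| x |V| binary, symmetric

    @property
    def num_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def num_undirected_edges(self) -> int:
        return self.edges.shape[0] // 2

    def to_json(self) -> str:
        return json.dumps(
            {
                "smiles": self.smiles,
                "drug_id": self.drug_id,
                "node_features": self.node_features.tolist(),
                "edges": self.edges.tolist(),
            }
        )

    def save_npz(self, path) -> None:
        np.savez(
            path,
            node_features=self.node_features,
            edges=self.edges,
            adjacency=self.adjacency,
        )


@dataclass
class Fingerprint:
    """Binary extended-connectivity fingerprint of one drug."""

    bits: np.ndarray
    d: int = 2048
    radius: int = 3
    drug_id: str = ""

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.float64)
        if self.bits.shape != (self.d,):
            raise ValueError(f"fingerprint has {self.bits.shape} bits, expected ({self.d},)")

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


def _parse(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles.strip():
        raise FeaturizationError(f"invalid SMILES: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparsable SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) > 1:
        # salts / mixtures: keep the largest fragment by heavy-atom count
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
        logger.info("multi-fragment SMILES %r reduced to largest fragment %s",
                    smiles, Chem.MolToSmiles(mol))
    if mol.GetNumHeavyAtoms() == 0:
        raise FeaturizationError(f"no heavy atoms in SMILES: {smiles!r}")
    return mol


def canonical_smiles(smiles: str) -> str:
    """Canonical SMILES of the largest fragment."""
    return Chem.MolToSmiles(_parse(smiles))


def smiles_to_graph(smiles: str, drug_id: str = "") -> MolecularGraph:
    """Convert a SMILES string into an attributed heavy-atom graph.

    Deterministic: the same molecule (any SMILES dialect) yields an
    identical graph because atoms follow the canonical SMILES order.
    """
    mol = Chem.MolFromSmiles(canonical_smiles(smiles))
    n = mol.GetNumHeavyAtoms()
    feats = np.vstack([_atom_features(a) for a in mol.GetAtoms()])
    adjacency = np.zeros((n, n), dtype=np.float64)
    directed = []
    for bond in mol.GetBonds():
        u, w = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adjacency[u, w] = adjacency[w, u] = 1.0
        directed.append((u, w))
        directed.append((w, u))
    edges = (
        np.asarray(sorted(directed), dtype=np.intp).reshape(-1, 2)
        if directed
        else np.zeros((0, 2), dtype=np.intp)
    )
    return MolecularGraph(
        smiles=smiles,
        drug_id=drug_id,
        node_features=feats,
        edges=edges,
        adjacency=adjacency,
    )


def smiles_to_fingerprint(
    smiles: str, d: int = 2048, radius: int = 3, drug_id: str = ""
) -> Fingerprint:
    """Hash a molecule to a `d`-bit Morgan fingerprint at the given radius.

    Defaults give ECFP6 (diameter 6 = radius 3) at 2,048 bits.
    """
    if d < 1:
        raise ValueError("fingerprint size d must be >= 1")
    mol = Chem.MolFromSmiles(canonical_smiles(smiles))
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=d)
    bv = gen.GetFingerprint(mol)
    bits = np.zeros(d, dtype=np.float64)
    bits[list(bv.GetOnBits())] = 1.0
    return Fingerprint(bits=bits, d=d, radius=radius, drug_id=drug_id)
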