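"""SMILES → molecular graph featurization for the directed message passing encoder.

Atoms are nodes and bonds are edges; each chemical bond yields two directed
edges. Edge features concatenate the source-atom feature vector with the bond
feature vector, which is what the D-MPNN edge-initialization consumes.
Hydrogens are implicit: the graph covers heavy atoms only, with attached-H
counts encoded as an atom feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from .data_io import DataError

# Element vocabulary: covers the atom types of the logP datasets used here
# (drug-like organics). Out-of-list elements map to a trailing "unknown" slot.
ELEMENTS = ("H", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I")
_ELEMENT_INDEX = {el: i for i, el in enumerate(ELEMENTS)}

DEGREES = (0, 1, 2, 3, 4, 5)
FORMAL_CHARGES = (-2, -1, 0, 1, 2)
NUM_HS = (0, 1, 2, 3, 4)
HYBRIDIZATIONS = (
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
)

ATOM_FDIM = (
    (len(ELEMENTS) + 1)
    + (len(DEGREES) + 1)
    + (len(FORMAL_CHARGES) + 1)
    + (len(NUM_HS) + 1)
    + (len(HYBRIDIZATIONS) + 1)
    + 1  # aromatic flag
    + 1  # atomic mass / 100
)
BOND_FDIM = 4 + 1 + 1  # bond-order one-hot + conjugation + ring
EDGE_FDIM = ATOM_FDIM + BOND_FDIM


def _onehot(value, choices) -> list[float]:
    """One-hot with a trailing slot for values outside `choices`."""
    vec = [0.0] * (len(choices) + 1)
    try:
        vec[list(choices).index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0
    return vec


def atom_features(atom: Chem.Atom) -> np.ndarray:
    """Feature vector for one atom (length ``ATOM_FDIM``)."""
    feats = (
        _onehot(atom.GetSymbol(), ELEMENTS)
        + _onehot(atom.GetTotalDegree(), DEGREES)
        + _onehot(atom.GetFormalCharge(), FORMAL_CHARGES)
        + _onehot(atom.GetTotalNumHs(), NUM_HS)
        + _onehot(atom.GetHybridization(), HYBRIDIZATIONS)
        + [1.0 if atom.GetIsAromatic() else 0.0]
        + [atom.GetMass() / 100.0]
    )
    return np.array(feats, dtype=np.float32)


def bond_features(bond: Chem.Bond) -> np.ndarray:
    """Feature vector for one bond (length ``BOND_FDIM``)."""
    bt = bond.GetBondType()
    feats = [
        1.0 if bt == Chem.BondType.SINGLE else 0.0,
        1.0 if bt == Chem.BondType.DOUBLE else 0.0,
        1.0 if bt == Chem.BondType.TRIPLE else 0.0,
        1.0 if bt == Chem.BondType.AROMATIC else 0.0,
        1.0 if bond.GetIsConjugated() else 0.0,
        1.0 if bond.IsInRing() else 0.0,
    ]
    return np.array(feats, dtype=np.float32)


@dataclass
class MolGraph:
    """Featurized molecular graph with directed-edge topology.

    ``edge_features[e]`` is ``concat(atom_features[src[e]], bond_features)``;
    ``rev[e]`` indexes the opposite-direction edge of the same chemical bond
    (an involution).
    """

    n_atoms: int
    n_bonds: int
    atom_feats: np.ndarray  # (n_atoms, ATOM_FDIM)
    edge_feats: np.ndarray  # (2*n_bonds, EDGE_FDIM)
    src: np.ndarray  # (2*n_bonds,) source atom of each directed edge
    tgt: np.ndarray  # (2*n_bonds,) target atom
    rev: np.ndarray  # (2*n_bonds,) index of the reverse edge

    @property
    def n_edges(self) -> int:
        return 2 * self.n_bonds


def _parse(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise DataError(f"unparseable SMILES: {smiles!r}")
    return mol


def featurize_molecule(smiles: str) -> MolGraph:
    """Build the directed molecular graph for one SMILES string."""
    mol = _parse(smiles)
    n_atoms = mol.GetNumAtoms()
    n_bonds = mol.GetNumBonds()
    afeat = np.zeros((n_atoms, ATOM_FDIM), dtype=np.float32)
    for atom in mol.GetAtoms():
        afeat[atom.GetIdx()] = atom_features(atom)
    n_edges = 2 * n_bonds
    efeat = np.zeros((n_edges, EDGE_FDIM), dtype=np.float32)
    src = np.zeros(n_edges, dtype=np.int64)
    tgt = np.zeros(n_edges, dtype=np.int64)
    rev = np.zeros(n_edges, dtype=np.int64)
    for bidx, bond in enumerate(mol.GetBonds()):
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bf = bond_features(bond)
        e1, e2 = 2 * bidx, 2 * bidx + 1
        src[e1], tgt[e1] = a, b
        src[e2], tgt[e2] = b, a
        efeat[e1] = np.concatenate([afeat[a], bf])
        efeat[e2] = np.concatenate([afeat[b], bf])
        rev[e1], rev[e2] = e2, e1
    return MolGraph(n_atoms, n_bonds, afeat, efeat, src, tgt, rev)


def molar_mass(smiles: str) -> float:
    """Molar mass in g/mol, implicit hydrogens included."""
    return float(Descriptors.MolWt(_parse(smiles)))
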