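"""Molecular graphs and the per-molecule tensors the network consumes.

A molecule enters as a SMILES string (hydrogens implicit; the graph is over
heavy atoms) and leaves as:

* an atom feature matrix (element one-hot, degree, formal charge, aromaticity,
  ring membership, total H count, hybridization one-hot),
* a directed-bond feature matrix (two rows per bond; bond-order one-hot,
  conjugation, ring membership, stereo one-hot),
* three symmetric inter-atomic matrices — binary adjacency A, topological
  distance D (bond hops), and the Coulomb matrix C with off-diagonal
  Z_i Z_j / ||R_i - R_j|| (distances in Bohr) and diagonal 0.5 * Z**2.4 —
  together with max-absolute-scaled variants used as structural bias terms.

Coordinates come from an SDF when available; otherwise a deterministic
distance-geometry (ETKDG) embedding seeded from the canonical SMILES is used.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.sparse.csgraph import shortest_path

ANGSTROM_TO_BOHR = 1.8897259886

ELEMENTS = [1, 6, 7, 8, 9, 15, 16, 17, 35, 53]  # H C N O F P S Cl Br I, + other
HYBRIDIZATIONS = [
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
]
BOND_ORDERS = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]
STEREO = [
    Chem.BondStereo.STEREONONE,
    Chem.BondStereo.STEREOANY,
    Chem.BondStereo.STEREOZ,
    Chem.BondStereo.STEREOE,
]

ATOM_FEATURE_DIM = (len(ELEMENTS) + 1) + 6 + 1 + 1 + 1 + 5 + (len(HYBRIDIZATIONS) + 1)
BOND_FEATURE_DIM = len(BOND_ORDERS) + 1 + 1 + len(STEREO)


class SmilesParseError(ValueError):
    pass


@dataclass
class Molecule:
    """Heavy-atom molecular graph with optional 3D geometry (Bohr)."""

    atoms: list[int]
    bonds: list[tuple[int, int, Chem.BondType]]
    smiles: str
    coords: np.ndarray | None = None
    rdmol: Chem.Mol = field(default=None, repr=False, compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)


@dataclass
class InterAtomicMatrices:
    """Adjacency, topological-distance and Coulomb matrices plus scaled forms."""

    A: np.ndarray
    Dtop: np.ndarray
    C: np.ndarray
    A_scaled: np.ndarray
    Dtop_scaled: np.ndarray
    C_scaled: np.ndarray

    def scaled(self, name: str) -> np.ndarray:
        try:
            return {"adjacency": self.A_scaled,
                    "distance": self.Dtop_scaled,
                    "coulomb": self.C_scaled}[name]
        except KeyError:
            raise KeyError(f"unknown inter-atomic matrix {name!r}") from None


def parse_molecule(smiles: str) -> Molecule:
    """Parse a SMILES string into a heavy-atom :class:`Molecule`.

    Raises :class:`SmilesParseError` naming the offending input when RDKit
    cannot parse it.
    """
    if not smiles or not isinstance(smiles, str):
        raise SmilesParseError(f"empty or non-string SMILES: {smiles!r}")
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    atoms = [a.GetAtomicNum() for a in rdmol.GetAtoms()]
    bonds = []
    for b in rdmol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        bonds.append((min(i, j), max(i, j), b.GetBondType()))
    return Molecule(atoms=atoms, bonds=bonds,
                    smiles=Chem.MolToSmiles(rdmol), rdmol=rdmol)


def _one_hot(value, choices) -> list[float]:
    vec = [0.0] * (len(choices) + 1)
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0
    return vec


def atom_featurize(mol: Molecule) -> np.ndarray:
    """Atom feature matrix, one row per heavy atom."""
    rows = []
    for atom in mol.rdmol.GetAtoms():
        row: list[float] = []
        row += _one_hot(atom.GetAtomicNum(), ELEMENTS)
        deg = [0.0] * 6
        deg[min(atom.GetDegree(), 5)] = 1.0
        row += deg
        row.append(float(atom.GetFormalCharge()))
        row.append(1.0 if atom.GetIsAromatic() else 0.0)
        row.append(1.0 if atom.IsInRing() else 0.0)
        hc = [0.0] * 5
        hc[min(atom.GetTotalNumHs(), 4)] = 1.0
        row += hc
        row += _one_hot(atom.GetHybridization(), HYBRIDIZATIONS)
        rows.append(row)
    out = np.array(rows, dtype=np.float64).reshape(mol.n_atoms, ATOM_FEATURE_DIM)
    return out


def directed_bonds(mol: Molecule) -> list[tuple[int, int]]:
    """Directed bond list; bond b yields rows 2b (i->j) and 2b+1 (j->i)."""
    out = []
    for i, j, _ in mol.bonds:
        out.append((i, j))
        out.append((j, i))
    return out


def bond_featurize(mol: Molecule) -> np.ndarray:
    """Directed-bond feature matrix: 2 rows per undirected bond.

    The reverse-direction row carries identical features; a bondless molecule
    yields an empty (0, BOND_FEATURE_DIM) matrix.
    """
    rows = []
    for i, j, _ in mol.bonds:
        bond = mol.rdmol.GetBondBetweenAtoms(i, j)
        row: list[float] = []
        order = [1.0 if bond.GetBondType() == t else 0.0 for t in BOND_ORDERS]
        row += order
        row.append(1.0 if bond.GetIsConjugated() else 0.0)
        row.append(1.0 if bond.IsInRing() else 0.0)
        row += [1.0 if bond.GetStereo() == s else 0.0 for s in STEREO]
        rows.append(row)
        rows.append(list(row))
    return np.array(rows, dtype=np.float64).reshape(2 * mol.n_bonds, BOND_FEATURE_DIM)


def adjacency_matrix(mol: Molecule) -> np.ndarray:
    n = mol.n_atoms
    A = np.zeros((n, n))
    for i, j, _ in mol.bonds:
        A[i, j] = A[j, i] = 1.0
    return A


def topological_distances(mol: Molecule) -> np.ndarray:
    """Minimum bond hops between every atom pair.

    Disconnected pairs carry the sentinel ``n_atoms`` (strictly larger than
    any real path), which the exponential decay gamma**d drives to near zero.
    """
    n = mol.n_atoms
    if n == 0:
        return np.zeros((0, 0))
    D = shortest_path(adjacency_matrix(mol), method="D", unweighted=True)
    D[np.isinf(D)] = float(n)
    return D


def coulomb_matrix(mol: Molecule) -> np.ndarray:
    """Standard Coulomb-matrix descriptor from nuclear charges and geometry."""
    if mol.coords is None:
        raise ValueError(
            "molecule has no 3D coordinates; supply an SDF or generate a "
            "geometry with synthetic_data.generate_coords / embed_coords"
        )
    Z = np.asarray(mol.atoms, dtype=np.float64)
    R = np.asarray(mol.coords, dtype=np.float64)
    if R.shape != (mol.n_atoms, 3):
        raise ValueError(f"coords shape {R.shape} != ({mol.n_atoms}, 3)")
    diff = R[:, None, :] - R[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    off = ~np.eye(mol.n_atoms, dtype=bool)
    if mol.n_atoms > 1 and np.any(dist[off] == 0.0):
        raise ValueError("coincident atoms: zero inter-atomic distance")
    C = np.zeros_like(dist)
    C[off] = Z[:, None].repeat(mol.n_atoms, 1)[off] * Z[None, :].repeat(mol.n_atoms, 0)[off] / dist[off]
    C[np.diag_indices_from(C)] = 0.5 * Z ** 2.4
    return C


def scale_matrix(M: np.ndarray, scheme: str = "maxabs") -> np.ndarray:
    """Per-molecule max-absolute scaling: output max |entry| <= 1."""
    M = np.asarray(M, dtype=np.float64)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {M.shape}")
    if scheme != "maxabs":
        raise ValueError(f"unknown scaling scheme {scheme!r}")
    m = np.abs(M).max() if M.size else 0.0
    return M / m if m > 0 else M.copy()


def embed_coords(mol: Molecule, seed: int | None = None) -> np.ndarray:
    """Deterministic ETKDG distance-geometry embedding, coordinates in Bohr.

    The random seed defaults to a hash of the canonical SMILES so the same
    molecule always receives the same geometry.
    """
    if seed is None:
        digest = hashlib.sha256(mol.smiles.encode()).digest()
        seed = int.from_bytes(digest[:4], "big") % (2 ** 31 - 1)
    # Embed the canonical-order form and map coordinates back onto this
    # molecule's atom numbering, so any SMILES rendering of the same molecule
    # receives the identical per-atom geometry.
    canon = Chem.MolFromSmiles(mol.smiles)
    match = mol.rdmol.GetSubstructMatch(canon)
    if len(match) != mol.n_atoms:
        canon, match = mol.rdmol, tuple(range(mol.n_atoms))
    m = Chem.AddHs(Chem.Mol(canon))
    params = AllChem.ETKDGv3()
    for attempt in range(3):
        params.randomSeed = int(seed) + attempt
        if AllChem.EmbedMolecule(m, params) == 0:
            break
    else:
        raise RuntimeError(f"distance-geometry embedding failed for {mol.smiles}")
    conf = m.GetConformer()
    pos = np.zeros((mol.n_atoms, 3))
    for canon_idx, own_idx in enumerate(match):
        p = conf.GetAtomPosition(canon_idx)
        pos[own_idx] = (p.x, p.y, p.z)
    return pos * ANGSTROM_TO_BOHR


def interatomic_matrices(mol: Molecule) -> InterAtomicMatrices:
    """All three inter-atomic matrices plus their scaled variants."""
    if mol.coords is None:
        mol.coords = embed_coords(mol)
    A = adjacency_matrix(mol)
    D = topological_distances(mol)
    C = coulomb_matrix(mol)
    return InterAtomicMatrices(
        A=A, Dtop=D, C=C,
        A_scaled=scale_matrix(A), Dtop_scaled=scale_matrix(D), C_scaled=scale_matrix(C),
    )


def read_sdf_coords(path: str) -> dict[str, np.ndarray]:
    """Map canonical SMILES -> coordinates (Bohr) from a V2000 SDF file."""
    out: dict[str, np.ndarray] = {}
    for m in Chem.SDMolSupplier(str(path), removeHs=True):
        if m is None or m.GetNumConformers() == 0:
            continue
        conf = m.GetConformer()
        pos = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
                         conf.GetAtomPosition(i).z] for i in range(m.GetNumAtoms())])
        out[Chem.MolToSmiles(m)] = pos * ANGSTROM_TO_BOHR
    return out


def save_feature_bundle(path: str, smiles_list: list[str]) -> None:
    """Serialize featurized molecules to an .npz container with shape metadata."""
    arrays: dict[str, np.ndarray] = {"smiles": np.array(smiles_list, dtype=object)}
    for k, smi in enumerate(smiles_list):
        mol = parse_molecule(smi)
        mats = interatomic_matrices(mol)
        arrays[f"atom_{k}"] = atom_featurize(mol)
        arrays[f"bond_{k}"] = bond_featurize(mol)
        arrays[f"A_{k}"] = mats.A
        arrays[f"Dtop_{k}"] = mats.Dtop
        arrays[f"C_{k}"] = mats.C
    arrays["smiles"] = np.array(smiles_list, dtype="U")  # fixed-width unicode, no pickling
    np.savez(path, **arrays)
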