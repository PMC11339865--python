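"""Synthetic drug-like molecules with known pKa ground truth.

The generator assembles small molecules from a fragment grammar — alkyl or
aryl cores decorated with halogen / methyl / methoxy substituents and exactly
one ionizable head group (carboxylic acid, phenol, sulfonamide, primary
amine, pyridine or amidine).  Each molecule's noise-free ("truth") pKa is a
documented additive, graph-local function of its composition:

    truth = base(group) + 0.04 * #sp3-C - 0.55 * #Cl - 0.45 * #F
            + 0.12 * #ether-O - 0.35 * (aromatic ring present)

with group base values spanning [0, 14] realistically (acids low, amines
high).  These constants are generator bookkeeping, not claimed chemistry;
they exist so that a graph network can in principle recover the labels.

Two label fidelities emulate the computed-versus-experimental pairing used
for multi-fidelity training: the high-fidelity label adds N(0, sigma_high)
noise to the truth, and the low-fidelity label adds a systematic bias b plus
extra N(0, sigma_low) noise on top of the high-fidelity value.  All labels
are clipped to [0, 14].  Everything is deterministic given (spec, seed).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem

from . import chem_graph
from .chem_graph import Molecule

# (class, base pKa, supports bare-alkyl core, aryl attachment fragment)
GROUPS: dict[str, dict] = {
    "carboxylic": {"cls": "acidic", "base": 4.0, "alkyl": "C(=O)O", "aryl": "C(=O)O",
                   "min_chain": 0},
    "phenol":     {"cls": "acidic", "base": 10.0, "alkyl": None, "aryl": "O",
                   "min_chain": 0},
    "sulfonamide": {"cls": "acidic", "base": 10.1, "alkyl": "S(N)(=O)=O",
                    "aryl": "S(N)(=O)=O", "min_chain": 1},
    "amine":      {"cls": "basic", "base": 10.5, "alkyl": "N", "aryl": "CN",
                   "min_chain": 1},
    "pyridine":   {"cls": "basic", "base": 5.2, "alkyl": None, "aryl": None,
                   "min_chain": 1},  # the ring itself is the group
    "amidine":    {"cls": "basic", "base": 11.5, "alkyl": "C(=N)N", "aryl": None,
                   "min_chain": 1},
}

# SMARTS used to re-identify the head group of a generated molecule
# (priority order resolves molecules matching several patterns).
GROUP_SMARTS = [
    ("carboxylic", "[CX3](=O)[OX2H1]"),
    ("sulfonamide", "[SX4](=[OX1])(=[OX1])[NX3;H1,H2]"),
    ("amidine", "[NX3;H2][CX3]=[NX2;H1]"),
    ("phenol", "[OX2H1][c]"),
    ("amine", "[NX3;H2;!$(N[CX3]=[OX1]);!$(N[SX4]);!$(N[CX3]=[NX2]);!$(Nc)]"),
    ("pyridine", "[nX2;H0;+0]"),
]
_GROUP_PATTERNS = [(name, Chem.MolFromSmarts(s)) for name, s in GROUP_SMARTS]

CHAIN_DECORATIONS = ["", "F", "Cl", "C", "OC"]  # on-chain substituents
ARYL_DECORATIONS = ["C", "CC", "Cl", "F", "OC"]

TRUTH_SHIFTS = {"sp3C": 0.04, "Cl": -0.55, "F": -0.45, "etherO": 0.12,
                "aromatic": -0.35}


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic benchmark."""

    n_low: int = 2000            # low-fidelity (computed-like) molecules
    n_high: int = 400            # high-fidelity (experimental-like) molecules
    acid_weight: float = 0.5
    base_weight: float = 0.5
    sigma_high: float = 0.3      # log-unit noise on experimental-like labels
    bias_low: float = 0.5        # systematic offset of computed-like labels
    sigma_low: float = 0.7       # extra noise on computed-like labels
    qm_sigma: float = 0.05       # noise scale of the synthetic QM scalars
    chain_max: int = 7
    max_decorations: int = 2

    def __post_init__(self) -> None:
        if min(self.sigma_high, self.sigma_low, self.qm_sigma) < 0:
            raise ValueError("noise scales must be non-negative")
        if self.acid_weight + self.base_weight <= 0:
            raise ValueError("group-class weights must have positive mass")


def _rng_for(seed: int, *tags) -> np.random.Generator:
    """Stable per-(seed, tags) generator, independent of Python hash salting."""
    key = ":".join([str(seed), *map(str, tags)]).encode()
    digest = hashlib.sha256(key).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "big"))


def _chain(rng: np.random.Generator, spec: SyntheticSpec, min_len: int) -> str:
    k = int(rng.integers(max(min_len, 1), spec.chain_max + 1))
    n_dec = int(rng.integers(0, spec.max_decorations + 1))
    decs = {int(i): CHAIN_DECORATIONS[int(rng.integers(1, len(CHAIN_DECORATIONS)))]
            for i in rng.choice(k, size=min(n_dec, k), replace=False)}
    return "".join(f"C({decs[i]})" if i in decs else "C" for i in range(k))


def _aryl(rng: np.random.Generator, spec: SyntheticSpec, group_frag: str) -> str:
    slots = ["", ""]
    for s in range(int(rng.integers(0, spec.max_decorations + 1))):
        slots[s] = ARYL_DECORATIONS[int(rng.integers(0, len(ARYL_DECORATIONS)))]
    a = f"c({slots[0]})" if slots[0] else "c"
    b = f"c({slots[1]})" if slots[1] else "c"
    # benzene ring with substituents at positions 3 and 5, group on position 6
    return "c1c" + a + "c" + b + "c1" + group_frag


def _assemble(rng: np.random.Generator, spec: SyntheticSpec, group: str) -> str:
    info = GROUPS[group]
    if group == "pyridine":
        return _chain(rng, spec, info["min_chain"]) + "c1ccncc1"
    use_aryl = info["alkyl"] is None or (info["aryl"] is not None and rng.random() < 0.4)
    if use_aryl:
        return _aryl(rng, spec, info["aryl"])
    return _chain(rng, spec, info["min_chain"]) + info["alkyl"]


def identify_group(mol: Molecule) -> str:
    """Head group of a generated molecule, by SMARTS priority match."""
    for name, patt in _GROUP_PATTERNS:
        if mol.rdmol.HasSubstructMatch(patt):
            return name
    raise ValueError(f"no ionizable head group found in {mol.smiles}")


def truth_pka(mol: Molecule) -> tuple[float, str]:
    """Noise-free generating pKa and its acid/base class."""
    group = identify_group(mol)
    rd = mol.rdmol
    n_sp3c = sum(1 for a in rd.GetAtoms()
                 if a.GetAtomicNum() == 6
                 and a.GetHybridization() == Chem.HybridizationType.SP3)
    n_cl = sum(1 for a in rd.GetAtoms() if a.GetAtomicNum() == 17)
    n_f = sum(1 for a in rd.GetAtoms() if a.GetAtomicNum() == 9)
    n_ether = len(rd.GetSubstructMatches(Chem.MolFromSmarts("[OX2;H0]")))
    aromatic = any(a.GetIsAromatic() for a in rd.GetAtoms())
    value = (GROUPS[group]["base"]
             + TRUTH_SHIFTS["sp3C"] * n_sp3c
             + TRUTH_SHIFTS["Cl"] * n_cl
             + TRUTH_SHIFTS["F"] * n_f
             + TRUTH_SHIFTS["etherO"] * n_ether
             + TRUTH_SHIFTS["aromatic"] * float(aromatic))
    return float(np.clip(value, 0.0, 14.0)), GROUPS[group]["cls"]


def generate_molecules(n: int, seed: int, spec: SyntheticSpec | None = None,
                       max_tries: int = 200000) -> list[str]:
    """``n`` unique, parseable SMILES from the fragment grammar."""
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or SyntheticSpec()
    rng = _rng_for(seed, "molecules")
    names = list(GROUPS)
    weights = np.array([spec.acid_weight if GROUPS[g]["cls"] == "acidic"
                        else spec.base_weight for g in names], dtype=float)
    weights /= weights.sum()
    out: list[str] = []
    seen: set[str] = set()
    for _ in range(max_tries):
        group = names[int(rng.choice(len(names), p=weights))]
        smi = _assemble(rng, spec, group)
        m = Chem.MolFromSmiles(smi)
        if m is None:
            continue
        canon = Chem.MolToSmiles(m)
        if canon in seen:
            continue
        seen.add(canon)
        out.append(canon)
        if len(out) == n:
            return out
    raise RuntimeError(f"grammar exhausted after {max_tries} tries "
                       f"({len(out)}/{n} unique molecules)")


def generate_coords(mol: Molecule, seed: int | None = None) -> np.ndarray:
    """Deterministic distance-geometry embedding (Bohr); see chem_graph."""
    return chem_graph.embed_coords(mol, seed)


def synth_qm_features(mol: Molecule, seed: int,
                      spec: SyntheticSpec | None = None) -> np.ndarray:
    """Five synthetic QM scalars: enthalpy, free energy, HOMO, LUMO, gap.

    All are deterministic functions of elemental composition plus seeded
    noise; the gap is LUMO - HOMO by construction and the enthalpy is
    strictly decreasing in heavy-atom count at zero noise.
    """
    spec = spec or SyntheticSpec()
    rng = _rng_for(seed, "qm", mol.smiles)
    z = np.array(mol.atoms)
    counts = {el: int((z == el).sum()) for el in (6, 7, 8, 16, 17, 9)}
    n_arom = sum(1 for a in mol.rdmol.GetAtoms() if a.GetIsAromatic())
    noise = rng.normal(0.0, spec.qm_sigma, size=4)
    enthalpy = -(0.6 * counts[6] + 0.8 * counts[7] + 1.0 * counts[8]
                 + 1.2 * counts[16] + 0.7 * counts[17] + 0.5 * counts[9]) + noise[0]
    free_energy = enthalpy - 0.03 * mol.n_atoms + noise[1]
    homo = -0.30 + 0.010 * n_arom - 0.020 * counts[8] - 0.015 * counts[7] + noise[2]
    gap = max(0.25 - 0.010 * n_arom + noise[3], 0.01)
    lumo = homo + gap
    return np.array([enthalpy, free_energy, homo, lumo, gap])


def synth_labels(mol: Molecule, fidelity: str, seed: int,
                 spec: SyntheticSpec | None = None) -> tuple[float, str]:
    """Noisy pKa label at the requested fidelity, plus the site class.

    The low-fidelity label is built on top of the same high-fidelity draw,
    so E[low - high] equals the configured bias.
    """
    spec = spec or SyntheticSpec()
    truth, site_class = truth_pka(mol)
    high = truth + _rng_for(seed, "label", mol.smiles).normal(0.0, spec.sigma_high)
    if fidelity == "experimental":
        value = high
    elif fidelity == "computed":
        value = (high + spec.bias_low
                 + _rng_for(seed, "low", mol.smiles).normal(0.0, spec.sigma_low))
    else:
        raise ValueError(f"unknown fidelity {fidelity!r}")
    return float(np.clip(value, 0.0, 14.0)), site_class


def _records(smiles: list[str], fidelity: str, seed: int,
             spec: SyntheticSpec, source: str) -> pd.DataFrame:
    rows = []
    for smi in smiles:
        mol = chem_graph.parse_molecule(smi)
        pka, site_class = synth_labels(mol, fidelity, seed, spec)
        qm = synth_qm_features(mol, seed, spec)
        rows.append({"smiles": mol.smiles, "pka": pka, "site_class": site_class,
                     "fidelity": fidelity, "source": source,
                     **{f"qm_{k+1}": qm[k] for k in range(5)}})
    return pd.DataFrame(rows)


def make_benchmark(spec: SyntheticSpec | None = None, seed: int = 0
                   ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Disjoint low-fidelity / high-fidelity datasets plus the truth table.

    Returns (pretrain records, finetune records, truth table); the truth
    table carries the noise-free generating pKa for recovery scoring.
    """
    spec = spec or SyntheticSpec()
    smiles = generate_molecules(spec.n_low + spec.n_high, seed, spec)
    rng = _rng_for(seed, "partition")
    order = rng.permutation(len(smiles))
    low = [smiles[i] for i in order[:spec.n_low]]
    high = [smiles[i] for i in order[spec.n_low:]]
    pretrain = _records(low, "computed", seed, spec, source="synthetic-low")
    finetune = _records(high, "experimental", seed, spec, source="synthetic-high")
    truth_rows = []
    for smi in smiles:
        mol = chem_graph.parse_molecule(smi)
        value, site_class = truth_pka(mol)
        truth_rows.append({"smiles": mol.smiles, "truth_pka": value,
                           "site_class": site_class,
                           "group": identify_group(mol)})
    return pretrain, finetune, pd.DataFrame(truth_rows)
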