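"""Dataset curation: ionizable-site detection, filtering, macro-pKa collapse,
acid/base partitioning, splits and diversity statistics.

Records travel as pandas DataFrames with columns
``smiles, pka, site_class, fidelity, source, qm_1..qm_5`` (the CSV schema).
The curation chain applied to raw records is:

    filter_pka_range  ->  omit molecules without detectable ionization sites
                      ->  collapse_macro (most-acidic / most-basic per molecule)
                      ->  partition_acid_base

Molecules outside pKa [0, 14] are excluded (bounds inclusive); a molecule
keeps only its minimum pKa among acidic records and its maximum among basic
records; molecules with sites of both classes belong to both partitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import MACCSkeys

from .chem_graph import Molecule, parse_molecule

log = logging.getLogger(__name__)

RECORD_COLUMNS = ["smiles", "pka", "site_class", "fidelity", "source"] + \
    [f"qm_{k}" for k in range(1, 6)]

PKA_MIN, PKA_MAX = 0.0, 14.0

# Curated default library of common ionizable groups.  Each SMARTS is written
# with the ionizable (titratable) atom first so site counting is unambiguous.
DEFAULT_SMARTS: list[tuple[str, str, str]] = [
    # --- acidic -----------------------------------------------------------
    ("[OX2H1][CX3]=[OX1]", "acidic", "carboxylic acid"),
    ("[OX2H1][c]", "acidic", "phenol"),
    ("[OX2H1][SX4](=[OX1])=[OX1]", "acidic", "sulfonic acid"),
    ("[OX2H1][PX4]=[OX1]", "acidic", "phosphonic/phosphoric acid"),
    ("[NX3;H1,H2][SX4](=[OX1])=[OX1]", "acidic", "sulfonamide N-H"),
    ("[NX3;H1]([CX3]=[OX1])[CX3]=[OX1]", "acidic", "imide"),
    ("[OX2H1][NX3][CX3]=[OX1]", "acidic", "hydroxamic acid"),
    ("[nX3;H1]1nnnc1", "acidic", "tetrazole"),
    ("[SX2H1]", "acidic", "thiol"),
    ("[OX2H1][NX2]=[CX3]", "acidic", "oxime"),
    # --- basic ------------------------------------------------------------
    ("[NX3;H2;+0;!$(N[CX3]=[OX1]);!$(N[SX4]);!$(N[CX3]=[NX2]);!$(Nc);!$(N[NX2]=O)]",
     "basic", "primary aliphatic amine"),
    ("[NX3;H1;+0;!$(N[CX3]=[OX1]);!$(N[SX4]);!$(N[CX3]=[NX2]);!$(Nc)]",
     "basic", "secondary aliphatic amine"),
    ("[NX3;H0;+0;!a;!$(N[CX3]=[OX1]);!$(N[SX4]);!$(N[CX3]=[NX2]);!$(Nc);!$(N=*);!$(N[OX1])]",
     "basic", "tertiary aliphatic amine"),
    ("[NX3;H2;+0][c]", "basic", "aromatic amine (aniline)"),
    ("[nX2;H0;+0;!$([n][#8])]", "basic", "pyridine-type aromatic N"),
    ("[NX2;+0]=[CX3][NX3]", "basic", "amidine"),
    ("[NX2;+0]=[CX3]([NX3])[NX3]", "basic", "guanidine"),
    ("[NX2;+0]=[CX3;$(C1NCCN1)]", "basic", "cyclic amidine (imidazoline)"),
    ("[NX3;H1;+0;$(N1CCCC1),$(N1CCCCC1)]", "basic", "cyclic secondary amine"),
    ("[NX2;H0;+0;!a;$(N=C)]", "basic", "imine N"),
]


@dataclass
class SmartsLibrary:
    """Compiled SMARTS patterns labeled acidic or basic."""

    entries: list[tuple[str, str, str]]  # (pattern, class, name)

    def __post_init__(self) -> None:
        self._compiled: list[tuple[Chem.Mol, str, str]] = []
        for pattern, cls, name in self.entries:
            if cls not in ("acidic", "basic"):
                raise ValueError(f"pattern {name!r}: unknown class {cls!r}")
            mol = Chem.MolFromSmarts(pattern)
            if mol is None:
                raise ValueError(f"invalid SMARTS for {name!r}: {pattern}")
            self._compiled.append((mol, cls, name))
        classes = {cls for _, cls, _ in self.entries}
        if not {"acidic", "basic"} <= classes:
            raise ValueError("library must contain both acidic and basic patterns")

    @classmethod
    def default(cls) -> "SmartsLibrary":
        return cls(list(DEFAULT_SMARTS))

    @classmethod
    def from_file(cls, path: str) -> "SmartsLibrary":
        """Two-column whitespace file: SMARTS pattern, class (name optional)."""
        entries = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 2)
                if len(parts) < 2:
                    raise ValueError(f"{path}:{ln}: need 'SMARTS class [name]'")
                pattern, cls_, *name = parts
                entries.append((pattern, cls_, name[0] if name else f"line{ln}"))
        return cls(entries)


def detect_ionization_sites(mol: Molecule | str,
                            lib: SmartsLibrary | None = None) -> dict[str, int]:
    """Count distinct ionizable atoms per class via SMARTS matching."""
    if isinstance(mol, str):
        mol = parse_molecule(mol)
    lib = lib or SmartsLibrary.default()
    sites: dict[str, set[int]] = {"acidic": set(), "basic": set()}
    for patt, cls, _ in lib._compiled:
        for match in mol.rdmol.GetSubstructMatches(patt):
            sites[cls].add(match[0])  # first SMARTS atom = titratable atom
    return {cls: len(atoms) for cls, atoms in sites.items()}


def _canonical(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["smiles"] = [parse_molecule(s).smiles for s in df["smiles"]]
    return df


def filter_pka_range(df: pd.DataFrame) -> pd.DataFrame:
    """Keep records with 0 <= pKa <= 14 (inclusive bounds)."""
    keep = (df["pka"] >= PKA_MIN) & (df["pka"] <= PKA_MAX) & np.isfinite(df["pka"])
    dropped = int((~keep).sum())
    if dropped:
        log.info("filter_pka_range: dropped %d of %d records", dropped, len(df))
    return df[keep].reset_index(drop=True)


def omit_siteless(df: pd.DataFrame,
                  lib: SmartsLibrary | None = None) -> pd.DataFrame:
    """Drop records whose molecule has no detectable ionization site."""
    lib = lib or SmartsLibrary.default()
    counts = {s: detect_ionization_sites(s, lib) for s in df["smiles"].unique()}
    keep = df["smiles"].map(lambda s: sum(counts[s].values()) > 0)
    dropped = int((~keep).sum())
    if dropped:
        log.info("omit_siteless: dropped %d records without ionizable sites", dropped)
    return df[keep].reset_index(drop=True)


def collapse_macro(df: pd.DataFrame) -> pd.DataFrame:
    """Keep each molecule's most acidic (min) acidic pKa and most basic (max)
    basic pKa, per fidelity tier: at most one record per (molecule, class,
    fidelity)."""
    df = _canonical(df)
    picks = []
    for (_, cls, _), grp in df.groupby(["smiles", "site_class", "fidelity"],
                                       sort=False):
        idx = grp["pka"].idxmin() if cls == "acidic" else grp["pka"].idxmax()
        picks.append(idx)
    out = df.loc[sorted(picks)].reset_index(drop=True)
    if len(out) < len(df):
        log.info("collapse_macro: %d -> %d records", len(df), len(out))
    return out


def partition_acid_base(df: pd.DataFrame, lib: SmartsLibrary | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into acidic and basic datasets by detected sites.

    A molecule with sites of both classes contributes its class-respective
    records to both outputs; molecules without sites go to neither.
    """
    lib = lib or SmartsLibrary.default()
    df = _canonical(df)
    counts = {s: detect_ionization_sites(s, lib) for s in df["smiles"].unique()}
    acid = df[[counts[s]["acidic"] > 0 and c == "acidic"
               for s, c in zip(df["smiles"], df["site_class"])]]
    base = df[[counts[s]["basic"] > 0 and c == "basic"
               for s, c in zip(df["smiles"], df["site_class"])]]
    return acid.reset_index(drop=True), base.reset_index(drop=True)


def curate(df: pd.DataFrame, lib: SmartsLibrary | None = None
           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full curation chain: range filter, omission, collapse, partition."""
    return partition_acid_base(collapse_macro(omit_siteless(
        filter_pka_range(df), lib)), lib)


def random_split(df: pd.DataFrame, ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
                 seed: int = 0) -> pd.Series:
    """Deterministic train/val/test labels; floor allocation, remainder to train."""
    if len(df) == 0:
        raise ValueError("cannot split an empty dataset")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    n = len(df)
    n_val, n_test = int(n * ratios[1]), int(n * ratios[2])
    n_train = n - n_val - n_test
    labels = np.array(["train"] * n_train + ["val"] * n_val + ["test"] * n_test)
    rng = np.random.default_rng(seed)
    return pd.Series(labels[rng.permutation(n)], index=df.index, name="split")


def maccs_fingerprints(smiles: list[str]):
    return [MACCSkeys.GenMACCSKeys(parse_molecule(s).rdmol) for s in smiles]


def maccs_tanimoto_diversity(smiles: list[str]) -> float:
    """Mean pairwise Tanimoto coefficient on 166-bit MACCS keys."""
    if len(smiles) < 2:
        raise ValueError("diversity needs at least 2 molecules")
    fps = maccs_fingerprints(smiles)
    sims, skipped = [], 0
    for i in range(len(fps)):
        for j in range(i + 1, len(fps)):
            if fps[i].GetNumOnBits() == 0 and fps[j].GetNumOnBits() == 0:
                skipped += 1
                continue
            sims.append(DataStructs.TanimotoSimilarity(fps[i], fps[j]))
    if skipped:
        log.warning("maccs_tanimoto_diversity: skipped %d all-zero pairs", skipped)
    if not sims:
        raise ValueError("no comparable fingerprint pairs")
    return float(np.mean(sims))


def load_records(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("smiles", "pka") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def save_records(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False)
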