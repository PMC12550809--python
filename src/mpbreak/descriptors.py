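"""Fingerprint featurization and fingerprint-collision analysis.

Four binary fingerprint families are supported:

- ``MACCS``: the 166 public MACCS structural keys;
- ``ECFP``: Morgan circular fingerprint, radius 2, hashed to 2048 bits;
- ``PATH_HASHED``: the RDKit path-enumeration fingerprint, 2048 bits;
- ``EPFP``: a rule-based fingerprint where bit *j* is set iff the SMARTS
  pattern of biotransformation rule *j* matches the molecule, i.e. an
  enzymatic transformation could plausibly attack that functional group.

The default rule set shipped with the package is a documented collection of
~60 functional-group transformation triggers (see ``data/biotransform_rules.tsv``);
any user rule file in the same tab-separated format can be substituted, so
an exported expert rule set reproduces its own bit space exactly.

Numeric descriptor backends (PaDEL/Mordred style) are not computed here;
:func:`load_descriptor_table` consumes a precomputed CSV instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .structures import ChemicalStructure

logger = logging.getLogger(__name__)


class FingerprintKind(str, Enum):
    MACCS = "MACCS"
    ECFP = "ECFP"
    PATH_HASHED = "PATH_HASHED"
    EPFP = "EPFP"


@dataclass(frozen=True)
class RuleSet:
    """Ordered biotransformation rules; order defines the EPFP bit order."""

    rules: tuple[tuple[str, str, str], ...]  # (rule_id, smarts, description)

    def __post_init__(self):
        ids = [r[0] for r in self.rules]
        if len(set(ids)) != len(ids):
            raise ValueError("rule ids must be unique")
        for rule_id, smarts, _ in self.rules:
            if Chem.MolFromSmarts(smarts) is None:
                raise ValueError(f"rule {rule_id}: SMARTS does not compile: {smarts}")

    def __len__(self) -> int:
        return len(self.rules)

    @property
    def patterns(self) -> list[Chem.Mol]:
        return [Chem.MolFromSmarts(smarts) for _, smarts, _ in self.rules]

    @classmethod
    def from_file(cls, path) -> "RuleSet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = {"rule_id", "smarts"} - set(df.columns)
        if missing:
            raise ValueError(f"rule file missing columns: {sorted(missing)}")
        if "description" not in df.columns:
            df["description"] = ""
        return cls(tuple(df[["rule_id", "smarts", "description"]].itertuples(index=False, name=None)))

    @classmethod
    def default(cls) -> "RuleSet":
        ref = resources.files("mpbreak").joinpath("data/biotransform_rules.tsv")
        with resources.as_file(ref) as path:
            return cls.from_file(path)


@dataclass
class FingerprintMatrix:
    kind: FingerprintKind
    substance_ids: list[str]
    bits: np.ndarray  # (n_substances, n_bits) uint8 in {0, 1}
    bit_names: list[str]
    invalid_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2 or self.bits.shape[0] != len(self.substance_ids):
            raise ValueError("bit matrix rows must align with substance_ids")
        if self.bits.shape[1] != len(self.bit_names):
            raise ValueError("bit matrix columns must align with bit_names")
        if self.bits.size and not np.isin(self.bits, (0, 1)).all():
            raise ValueError("fingerprint entries must be 0/1")

    @property
    def n_bits(self) -> int:
        return self.bits.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.bits, index=pd.Index(self.substance_ids, name="substance_id"),
                            columns=self.bit_names)

    def subset(self, substance_ids: list[str]) -> "FingerprintMatrix":
        index = {sid: i for i, sid in enumerate(self.substance_ids)}
        missing = [sid for sid in substance_ids if sid not in index]
        if missing:
            raise KeyError(f"substances absent from fingerprint matrix: {missing[:5]}")
        rows = [index[sid] for sid in substance_ids]
        return FingerprintMatrix(
            kind=self.kind,
            substance_ids=list(substance_ids),
            bits=self.bits[rows],
            bit_names=list(self.bit_names),
            invalid_ids=[sid for sid in self.invalid_ids if sid in set(substance_ids)],
        )


_ECFP_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
_PATH_GEN = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=2048)


def _mol_bits(mol: Chem.Mol, kind: FingerprintKind, patterns) -> np.ndarray:
    if kind is FingerprintKind.MACCS:
        # RDKit MACCS vectors have 167 positions with bit 0 unused
        fp = MACCSkeys.GenMACCSKeys(mol)
        arr = np.zeros(167, dtype=np.uint8)
        for b in fp.GetOnBits():
            arr[b] = 1
        return arr[1:]
    if kind is FingerprintKind.ECFP:
        return np.asarray(_ECFP_GEN.GetFingerprintAsNumPy(mol), dtype=np.uint8)
    if kind is FingerprintKind.PATH_HASHED:
        return np.asarray(_PATH_GEN.GetFingerprintAsNumPy(mol), dtype=np.uint8)
    if kind is FingerprintKind.EPFP:
        return np.array([1 if mol.HasSubstructMatch(p) else 0 for p in patterns],
                        dtype=np.uint8)
    raise ValueError(f"unknown fingerprint kind {kind!r}")


def compute_fingerprints(
    structures: list[ChemicalStructure],
    kind: FingerprintKind | str,
    ruleset: RuleSet | None = None,
) -> FingerprintMatrix:
    """Featurize standardized structures into one fingerprint family.

    Invalid structures get an all-zero row and are listed in
    ``invalid_ids`` — never silently dropped.
    """
    kind = FingerprintKind(kind)
    if kind is FingerprintKind.EPFP:
        if ruleset is None:
            raise ValueError("EPFP requires a RuleSet")
        patterns = ruleset.patterns
        bit_names = [r[0] for r in ruleset.rules]
    else:
        patterns = None
        n = {FingerprintKind.MACCS: 166, FingerprintKind.ECFP: 2048,
             FingerprintKind.PATH_HASHED: 2048}[kind]
        prefix = {FingerprintKind.MACCS: "maccs_", FingerprintKind.ECFP: "ecfp_",
                  FingerprintKind.PATH_HASHED: "path_"}[kind]
        bit_names = [f"{prefix}{i + 1}" for i in range(n)] if kind is FingerprintKind.MACCS \
            else [f"{prefix}{i}" for i in range(n)]

    rows, invalid = [], []
    for s in structures:
        if not s.valid:
            rows.append(np.zeros(len(bit_names), dtype=np.uint8))
            invalid.append(s.substance_id)
            logger.warning("zero fingerprint for invalid structure %r", s.substance_id)
            continue
        mol = Chem.MolFromSmiles(s.smiles_canonical)
        if mol is None:  # canonical SMILES should always reparse
            rows.append(np.zeros(len(bit_names), dtype=np.uint8))
            invalid.append(s.substance_id)
            continue
        rows.append(_mol_bits(mol, kind, patterns))

    bits = np.vstack(rows) if rows else np.zeros((0, len(bit_names)), dtype=np.uint8)
    return FingerprintMatrix(
        kind=kind,
        substance_ids=[s.substance_id for s in structures],
        bits=bits,
        bit_names=bit_names,
        invalid_ids=invalid,
    )


def count_unique_fingerprints(matrix: FingerprintMatrix) -> tuple[int, list[list[str]]]:
    """Number of distinct bit-rows and the groups of colliding substances.

    A collision group lists all substance ids sharing one identical row;
    singleton rows are not reported as groups.
    """
    if len(matrix.substance_ids) == 0:
        raise ValueError("empty fingerprint matrix")
    seen: dict[bytes, list[str]] = {}
    for sid, row in zip(matrix.substance_ids, matrix.bits):
        seen.setdefault(row.tobytes(), []).append(sid)
    groups = [ids for ids in seen.values() if len(ids) > 1]
    return len(seen), groups


def load_descriptor_table(path) -> pd.DataFrame:
    """Load a precomputed numeric descriptor CSV (plug-in interface).

    The file must have a ``substance_id`` column; all remaining columns are
    treated as numeric features.  Rows with any non-finite value are dropped
    with a warning.
    """
    df = pd.read_csv(path, dtype={"substance_id": str}).set_index("substance_id")
    df = df.apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(df.to_numpy(dtype=float)).all(axis=1)
    if bad.any():
        logger.warning("dropping %d descriptor rows with non-finite values", int(bad.sum()))
        df = df.loc[~bad]
    return df


#: Human-readable definitions for MACCS keys referenced in model reports.
#: Indices are the conventional 1-based MACCS key numbers.
MACCS_KEY_DESCRIPTIONS: dict[int, str] = {
    77: "N~*~N (two nitrogens separated by one atom, e.g. imidazole, guanidine)",
    101: "ring of size 8 or more (adjacent rings counted as one)",
    125: "more than one aromatic ring",
    131: "QH > 1 (multiple heteroatom-bound hydrogens, e.g. terminal N/O-H)",
    134: "halogen present (-F, -Cl, -Br, -I)",
    138: "Q~CH2~* (methylene bonded to a non-C, non-H atom)",
    139: "OH (hydroxyl group present)",
    157: "C-O single bond",
    161: "nitrogen present",
    162: "aromatic ring present",
    163: "6-membered ring present",
    165: "ring present (aromatic or aliphatic)",
}


def maccs_key_description(bit_name: str) -> str:
    """Best-effort description for a MACCS bit column name like ``maccs_134``."""
    try:
        key = int(bit_name.rsplit("_", 1)[1])
    except (IndexError, ValueError):
        return bit_name
    return MACCS_KEY_DESCRIPTIONS.get(key, f"MACCS key {key}")
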