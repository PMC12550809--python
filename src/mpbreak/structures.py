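"""Structure standardization and substance deduplication.

Every substance entering the pipeline is mapped to exactly one QSAR-ready
structure.  The standardization recipe is fixed:

1. parse the input SMILES;
2. drop carbon-free fragments (counterions, water, inorganics);
3. if more than one distinct organic fragment remains the entry is a true
   mixture and is marked invalid (breakthrough of a mixture is ill-defined
   per structure);
4. neutralize charges where a trivial proton transfer suffices;
5. emit the canonical SMILES (stereochemistry retained) and a
   connectivity-level structure key (InChIKey first block, stereo-insensitive)
   used for deduplication.

Unparseable input never raises: the structure is flagged ``valid=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

_UNCHARGER = rdMolStandardize.Uncharger()


@dataclass(frozen=True)
class ChemicalStructure:
    """One substance's standardized structure.

    ``structure_key`` is the first (connectivity) block of the InChIKey, so
    stereoisomers share a key and merge downstream; the fingerprints used for
    modeling are stereo-insensitive, so this loses no information the models
    can see.
    """

    substance_id: str
    smiles_input: str
    smiles_canonical: str = ""
    structure_key: str = ""
    valid: bool = False


def _organic_fragments(mol: Chem.Mol) -> list[Chem.Mol]:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    organic = []
    for frag in frags:
        if any(a.GetAtomicNum() == 6 for a in frag.GetAtoms()):
            organic.append(frag)
    return organic


def standardize_structure(smiles_input: str, substance_id: str = "") -> ChemicalStructure:
    """Standardize one SMILES string; never raises for bad structures.

    Returns a :class:`ChemicalStructure` with ``valid=False`` when the input
    does not parse, contains no organic fragment, or is a multi-component
    mixture after salt/solvent stripping.
    """
    if not isinstance(smiles_input, str) or not smiles_input.strip():
        raise ValueError("smiles_input must be a non-empty string")
    smiles_input = smiles_input.strip()

    invalid = ChemicalStructure(substance_id=substance_id, smiles_input=smiles_input)

    mol = Chem.MolFromSmiles(smiles_input)
    if mol is None:
        logger.warning("unparseable SMILES for %r: %s", substance_id, smiles_input)
        return invalid

    organic = _organic_fragments(mol)
    if not organic:
        logger.warning("no organic fragment for %r: %s", substance_id, smiles_input)
        return invalid

    # distinct organic fragments -> mixture -> invalid; identical fragments
    # (e.g. a doubled entry) collapse to one
    frag_smiles = {Chem.MolToSmiles(f) for f in organic}
    if len(frag_smiles) > 1:
        logger.warning("multi-component mixture for %r: %s", substance_id, smiles_input)
        return invalid

    frag = organic[0]
    try:
        Chem.SanitizeMol(frag)
        frag = _UNCHARGER.uncharge(frag)
        smiles_canonical = Chem.MolToSmiles(frag)
        inchikey = Chem.MolToInchiKey(frag)
    except Exception:  # pragma: no cover - rdkit internal failures
        logger.warning("standardization failed for %r: %s", substance_id, smiles_input)
        return invalid
    if not inchikey:
        return invalid

    return ChemicalStructure(
        substance_id=substance_id,
        smiles_input=smiles_input,
        smiles_canonical=smiles_canonical,
        structure_key=inchikey.split("-")[0],
        valid=True,
    )


def standardize_table(table: pd.DataFrame) -> list[ChemicalStructure]:
    """Standardize a table with columns ``substance_id`` and ``smiles``."""
    missing = {"substance_id", "smiles"} - set(table.columns)
    if missing:
        raise ValueError(f"structure table missing columns: {sorted(missing)}")
    return [
        standardize_structure(row.smiles, substance_id=str(row.substance_id))
        for row in table.itertuples()
    ]


def deduplicate_substances(
    structures: list[ChemicalStructure],
    records: pd.DataFrame,
) -> tuple[list[ChemicalStructure], pd.DataFrame, dict[str, str]]:
    """Merge substances sharing a structure key and re-key monitoring records.

    The first-seen substance id of each key becomes the canonical id.  The
    total number of monitoring records is preserved; only ``substance_id``
    values change.

    Returns ``(structures, records, id_map)`` where ``id_map`` maps every
    input id to its canonical id (identity for non-duplicates).

    Raises
    ------
    KeyError
        if ``records`` references a substance id absent from ``structures``.
    """
    known_ids = {s.substance_id for s in structures}
    dangling = set(records["substance_id"].astype(str)) - known_ids
    if dangling:
        raise KeyError(
            f"monitoring records reference unknown substance ids: {sorted(dangling)[:5]}"
        )

    id_map: dict[str, str] = {}
    canonical_for_key: dict[str, str] = {}
    kept: list[ChemicalStructure] = []
    n_merged = 0
    for s in structures:
        if not s.valid:
            id_map[s.substance_id] = s.substance_id
            kept.append(s)
            continue
        if s.structure_key in canonical_for_key:
            id_map[s.substance_id] = canonical_for_key[s.structure_key]
            n_merged += 1
        else:
            canonical_for_key[s.structure_key] = s.substance_id
            id_map[s.substance_id] = s.substance_id
            kept.append(s)

    if n_merged:
        logger.info("merged %d duplicate substances", n_merged)

    records = records.copy()
    records["substance_id"] = records["substance_id"].astype(str).map(id_map)
    return kept, records, id_map


def read_structures_csv(path: str) -> list[ChemicalStructure]:
    return standardize_table(pd.read_csv(path, dtype={"substance_id": str}))


def read_structures_sdf(path: str, id_property: str = "substance_id") -> list[ChemicalStructure]:
    """Read an SDF; the substance id is taken from ``id_property`` on each mol."""
    out = []
    for i, mol in enumerate(Chem.SDMolSupplier(path, sanitize=False)):
        if mol is None:
            out.append(ChemicalStructure(substance_id=f"sdf_{i}", smiles_input=""))
            continue
        sid = mol.GetProp(id_property) if mol.HasProp(id_property) else f"sdf_{i}"
        out.append(standardize_structure(Chem.MolToSmiles(mol), substance_id=sid))
    return out


def structures_to_frame(structures: list[ChemicalStructure]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "substance_id": [s.substance_id for s in structures],
            "smiles_input": [s.smiles_input for s in structures],
            "smiles_canonical": [s.smiles_canonical for s in structures],
            "structure_key": [s.structure_key for s in structures],
            "valid": [s.valid for s in structures],
        }
    )
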