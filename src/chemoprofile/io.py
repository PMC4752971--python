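"""Readers and writers for every external format the toolkit consumes.

Formats are deliberately plain: SMILES lists (one record per line, optional
whitespace-separated id/name), SDF V2000, tab-separated activity tables,
GMT-like annotation files (term_id, category, members...), and two-column
PPI edge lists. Invalid records are rejected and counted, never silently
dropped.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import pandas as pd
from rdkit import Chem

from .datatypes import (
    ActivityRecord,
    AnnotationCategory,
    AnnotationSet,
    Compound,
    DataType,
    PpiNetwork,
    RAW_CONCENTRATION_TYPES,
    Target,
)


class FormatError(ValueError):
    """Raised when a file does not match its declared format."""


class EmptyLibraryError(ValueError):
    """Raised when a structure file yields zero parsable molecules."""


#: multiplicative factors to nM for the supported concentration units
UNIT_TO_NM: Dict[str, float] = {
    "M": 1e9,
    "mM": 1e6,
    "uM": 1e3,
    "µM": 1e3,
    "nM": 1.0,
}

ACTIVITY_COLUMNS = ["compound_id", "target_id", "data_type", "value", "unit"]


# ---------------------------------------------------------------------------
# compound structures


def read_compounds(path, format: str = "smiles_list") -> Tuple[List[Compound], int]:
    """Read a compound library, returning ``(compounds, n_parse_failures)``.

    ``format`` is ``"smiles_list"`` (one ``SMILES [id [name]]`` per line) or
    ``"sdf"``. Records whose structure does not parse are counted as
    failures; duplicate compound_ids raise. A file with zero parsable
    molecules raises :class:`EmptyLibraryError`.
    """
    path = Path(path)
    if format == "smiles_list":
        compounds, failures = _read_smiles_list(path)
    elif format == "sdf":
        compounds, failures = _read_sdf(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if not compounds:
        raise EmptyLibraryError(f"{path}: no parsable molecules ({failures} failures)")
    seen = set()
    for c in compounds:
        if c.compound_id in seen:
            raise FormatError(f"{path}: duplicate compound_id {c.compound_id!r}")
        seen.add(c.compound_id)
    return compounds, failures


def _read_smiles_list(path: Path) -> Tuple[List[Compound], int]:
    compounds: List[Compound] = []
    failures = 0
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 2)
        smiles = parts[0]
        cid = parts[1] if len(parts) > 1 else f"CPD{i:06d}"
        name = parts[2] if len(parts) > 2 else None
        try:
            compounds.append(Compound(compound_id=cid, smiles=smiles, name=name))
        except ValueError:
            failures += 1
    return compounds, failures


def _read_sdf(path: Path) -> Tuple[List[Compound], int]:
    compounds: List[Compound] = []
    failures = 0
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier, start=1):
        if mol is None:
            failures += 1
            continue
        cid = mol.GetProp("_Name") if mol.GetProp("_Name") else f"CPD{i:06d}"
        compounds.append(Compound(compound_id=cid, smiles=Chem.MolToSmiles(mol)))
    return compounds, failures


def write_compounds(compounds: Sequence[Compound], path, format: str = "smiles_list") -> None:
    path = Path(path)
    if format == "smiles_list":
        lines = []
        for c in compounds:
            fieldsep = [c.smiles, c.compound_id]
            if c.name:
                fieldsep.append(c.name)
            lines.append(" ".join(fieldsep))
        path.write_text("\n".join(lines) + "\n")
    elif format == "sdf":
        with Chem.SDWriter(str(path)) as writer:
            for c in compounds:
                mol = Chem.MolFromSmiles(c.smiles)
                mol.SetProp("_Name", c.compound_id)
                writer.write(mol)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# activity tables


def normalize_unit(data_type: DataType, value: float, unit: str) -> float:
    """Convert a raw concentration to nM; p-types pass through unchanged.

    Idempotent: converting an already-nM value with unit ``nM`` is identity.
    """
    if data_type in RAW_CONCENTRATION_TYPES:
        unit = unit.strip()
        if unit not in UNIT_TO_NM:
            raise ValueError(f"unsupported concentration unit {unit!r}")
        return value * UNIT_TO_NM[unit]
    return value


def read_activity_table(path) -> Tuple[List[ActivityRecord], int]:
    """Read a tab-separated activity table -> ``(records, n_rejected)``.

    Required columns: compound_id, target_id, data_type, value, unit. Rows
    with an unknown data_type, unsupported unit, or invalid value are
    rejected and counted.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in ACTIVITY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    records: List[ActivityRecord] = []
    rejected = 0
    for row in df.itertuples(index=False):
        try:
            dt = DataType(row.data_type)
            value = normalize_unit(dt, float(row.value), row.unit)
            rec = ActivityRecord(
                compound_id=row.compound_id,
                target_id=row.target_id,
                data_type=dt,
                value=value,
                unit="nM" if dt in RAW_CONCENTRATION_TYPES else "",
            )
        except ValueError:
            rejected += 1
            continue
        if hasattr(row, "oriented_value") and row.oriented_value != "":
            rec.oriented_value = float(row.oriented_value)
        if hasattr(row, "z_score") and row.z_score != "":
            rec.z_score = float(row.z_score)
        records.append(rec)
    return records, rejected


def activity_frame(records: Sequence[ActivityRecord]) -> pd.DataFrame:
    """Records as a DataFrame, including derived columns when present."""
    return pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "target_id": [r.target_id for r in records],
            "data_type": [r.data_type.value for r in records],
            "value": [r.value for r in records],
            "unit": [r.unit for r in records],
            "oriented_value": [r.oriented_value for r in records],
            "z_score": [r.z_score for r in records],
        }
    )


def write_activity_table(records: Sequence[ActivityRecord], path) -> None:
    activity_frame(records).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# targets, annotations, networks


def read_targets(path) -> List[Target]:
    """Read a target table: target_id <TAB> family path joined by '/'."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("target_id", "family_path"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    targets = [
        Target(target_id=row.target_id, family_path=tuple(row.family_path.split("/")))
        for row in df.itertuples(index=False)
    ]
    seen = set()
    for t in targets:
        if t.target_id in seen:
            raise FormatError(f"{path}: duplicate target_id {t.target_id!r}")
        seen.add(t.target_id)
    return targets


def write_targets(targets: Sequence[Target], path) -> None:
    pd.DataFrame(
        {
            "target_id": [t.target_id for t in targets],
            "family_path": ["/".join(t.family_path) for t in targets],
        }
    ).to_csv(path, sep="\t", index=False)


def read_annotations(path) -> List[AnnotationSet]:
    """Read a GMT-like file: term_id <TAB> category <TAB> member1 <TAB> ..."""
    annotations = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}: annotation line needs term, category, >=1 member")
        annotations.append(
            AnnotationSet(
                term_id=parts[0],
                category=AnnotationCategory(parts[1]),
                members=frozenset(parts[2:]),
            )
        )
    return annotations


def write_annotations(annotations: Sequence[AnnotationSet], path) -> None:
    lines = [
        "\t".join([a.term_id, a.category.value, *sorted(a.members)]) for a in annotations
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_ppi(path) -> PpiNetwork:
    """Read a two-column tab-separated edge list."""
    pairs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}: edge line needs two columns")
        pairs.append((parts[0], parts[1]))
    return PpiNetwork.from_pairs(pairs)


def write_ppi(network: PpiNetwork, path) -> None:
    lines = ["\t".join(pair) for pair in network.to_pairs()]
    Path(path).write_text("\n".join(lines) + "\n")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
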