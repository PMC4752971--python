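"""Core domain types shared by every module.

All downstream code consumes these types only; file parsing lives in
:mod:`chemoprofile.io`. Compound identity is structure-based: SMILES are
canonicalized (RDKit) on construction via :func:`canonical_smiles`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import FrozenSet, List, Optional, Set, Tuple

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")


class DataType(str, enum.Enum):
    """The ten bioactivity data types handled by the standardization layer.

    Six raw concentration types (stored in nM) are log-transformed to the
    -log10 molar scale; three p-types are already on that scale; LogKi is a
    log10 molar value whose sign must be flipped. New types can be added by
    extending :data:`RAW_CONCENTRATION_TYPES` / :data:`P_TYPES` alongside the
    enum member.
    """

    IC50 = "IC50"
    EC50 = "EC50"
    POTENCY = "Potency"
    AC50 = "AC50"
    KD = "Kd"
    KI = "Ki"
    PIC50 = "pIC50"
    PKI = "pKi"
    PEC50 = "pEC50"
    LOGKI = "LogKi"


RAW_CONCENTRATION_TYPES: FrozenSet[DataType] = frozenset(
    {DataType.IC50, DataType.EC50, DataType.POTENCY, DataType.AC50, DataType.KD, DataType.KI}
)
P_TYPES: FrozenSet[DataType] = frozenset({DataType.PIC50, DataType.PKI, DataType.PEC50})


def canonical_smiles(smiles: str) -> str:
    """Return RDKit canonical SMILES, raising ``ValueError`` on parse failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class Compound:
    """A small molecule identified by id and canonical SMILES."""

    compound_id: str
    smiles: str
    name: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "smiles", canonical_smiles(self.smiles))

    @property
    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)


@dataclass(frozen=True)
class Target:
    """A protein target with its family classification path (root -> leaf)."""

    target_id: str
    family_path: Tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "family_path", tuple(self.family_path))
        if not self.family_path:
            raise ValueError(f"target {self.target_id}: family_path must be non-empty")


@dataclass
class ActivityRecord:
    """One compound-target bioactivity measurement.

    ``value`` is in nM for the six raw concentration types after unit
    normalization and dimensionless for p-types and LogKi. ``oriented_value``
    is the derived -log10 molar value (larger = stronger binding) and
    ``z_score`` the per-(target, data_type) standardized score, filled by
    :func:`chemoprofile.standardization.compute_zscores`.
    """

    compound_id: str
    target_id: str
    data_type: DataType
    value: float
    unit: str = ""
    oriented_value: Optional[float] = None
    z_score: Optional[float] = None

    def __post_init__(self) -> None:
        self.data_type = DataType(self.data_type)
        if self.data_type in RAW_CONCENTRATION_TYPES and not self.value > 0:
            raise ValueError(
                f"{self.data_type.value} requires a positive concentration, got {self.value}"
            )
        if not math.isfinite(self.value):
            raise ValueError(f"non-finite activity value {self.value}")


class AnnotationCategory(str, enum.Enum):
    DISEASE = "disease"
    PATHWAY = "pathway"
    GO_TERM = "go_term"


@dataclass(frozen=True)
class AnnotationSet:
    """A named term (disease / pathway / GO) with its protein members."""

    term_id: str
    category: AnnotationCategory
    members: FrozenSet[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "category", AnnotationCategory(self.category))
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValueError(f"annotation term {self.term_id} has no members")


@dataclass(frozen=True)
class PpiNetwork:
    """An undirected protein-protein interaction network as unique edges."""

    edges: FrozenSet[FrozenSet[str]]

    @classmethod
    def from_pairs(cls, pairs) -> "PpiNetwork":
        edges: Set[FrozenSet[str]] = set()
        for a, b in pairs:
            if a == b:
                raise ValueError(f"self-loop on {a!r} not allowed")
            edges.add(frozenset((a, b)))
        return cls(frozenset(edges))

    @property
    def nodes(self) -> Set[str]:
        out: Set[str] = set()
        for e in self.edges:
            out.update(e)
        return out

    def to_pairs(self) -> List[Tuple[str, str]]:
        """Edges as sorted tuples, deterministically ordered."""
        return sorted(tuple(sorted(e)) for e in self.edges)
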