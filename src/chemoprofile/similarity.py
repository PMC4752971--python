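"""Fingerprints and Tanimoto similarity search.

Five 1024-bit fingerprint variants spanning the two classic families:
``path1024`` (Daylight-style hashed linear paths, 1-7 bonds) and Morgan
circular fingerprints at radius 2 and 3, each in atom-type and
pharmacophore-feature flavors. Bit generation is delegated to RDKit; the
Tanimoto coefficient and the threshold search are implemented here on numpy
bit vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .datatypes import Compound

VARIANTS = ("path1024", "morgan_r2", "morgan_r3", "feat_morgan_r2", "feat_morgan_r3")

DEFAULT_NBITS = 1024


@dataclass(frozen=True)
class FingerprintVector:
    """Fixed-length binary substructure descriptor of one molecule."""

    compound_id: str
    variant: str
    bits: np.ndarray  # uint8 0/1 vector

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown fingerprint variant {self.variant!r}")
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=np.uint8))
        self.bits.setflags(write=False)

    @property
    def nbits(self) -> int:
        return int(self.bits.size)

    def popcount(self) -> int:
        return int(self.bits.sum())


_GENERATOR_CACHE: Dict[Tuple[str, int], object] = {}


def _generator(variant: str, nbits: int):
    key = (variant, nbits)
    if key not in _GENERATOR_CACHE:
        if variant == "path1024":
            gen = rdFingerprintGenerator.GetRDKitFPGenerator(maxPath=7, fpSize=nbits)
        elif variant in ("morgan_r2", "morgan_r3"):
            radius = 2 if variant.endswith("2") else 3
            gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
        elif variant in ("feat_morgan_r2", "feat_morgan_r3"):
            radius = 2 if variant.endswith("2") else 3
            gen = rdFingerprintGenerator.GetMorganGenerator(
                radius=radius,
                fpSize=nbits,
                atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen(),
            )
        else:
            raise ValueError(f"unknown fingerprint variant {variant!r}")
        _GENERATOR_CACHE[key] = gen
    return _GENERATOR_CACHE[key]


def fingerprint(
    compound: Compound, variant: str = "path1024", nbits: int = DEFAULT_NBITS
) -> FingerprintVector:
    """Compute one fingerprint; deterministic for a given canonical SMILES."""
    mol = Chem.MolFromSmiles(compound.smiles)
    fp = _generator(variant, nbits).GetFingerprint(mol)
    bits = np.zeros(nbits, dtype=np.uint8)
    bits[list(fp.GetOnBits())] = 1
    return FingerprintVector(compound_id=compound.compound_id, variant=variant, bits=bits)


def fingerprint_matrix(
    compounds: Sequence[Compound], variant: str = "path1024", nbits: int = DEFAULT_NBITS
) -> np.ndarray:
    """Stack fingerprints of a library into an (n, nbits) uint8 matrix."""
    return np.stack([fingerprint(c, variant, nbits).bits for c in compounds])


def tanimoto(a: FingerprintVector, b: FingerprintVector) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b|, with 0/0 defined as 0."""
    if a.variant != b.variant or a.nbits != b.nbits:
        raise ValueError(
            f"fingerprint mismatch: {a.variant}/{a.nbits} vs {b.variant}/{b.nbits}"
        )
    return _tanimoto_bits(a.bits, b.bits)


def _tanimoto_bits(a: np.ndarray, b: np.ndarray) -> float:
    union = int(np.bitwise_or(a, b).sum())
    if union == 0:
        return 0.0
    return int(np.bitwise_and(a, b).sum()) / union


def tanimoto_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """All-pairs Tanimoto between two fingerprint matrices (rows = molecules)."""
    A = A.astype(np.float64)
    B = B.astype(np.float64)
    inter = A @ B.T
    pa = A.sum(axis=1)[:, None]
    pb = B.sum(axis=1)[None, :]
    union = pa + pb - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    return sim


def similarity_search(
    query: Compound,
    library: Sequence[Compound],
    variant: str = "path1024",
    threshold: float = 0.85,
    strict: bool = True,
    nbits: int = DEFAULT_NBITS,
) -> List[Tuple[str, float]]:
    """Rank library members by Tanimoto to the query.

    Returns ``(compound_id, similarity)`` pairs with similarity strictly
    above ``threshold`` (``strict=False`` switches to >=), sorted descending
    with ties broken by compound_id. The query itself appears at 1.0 when
    present in the library.
    """
    if not library:
        raise ValueError("library must be non-empty")
    qfp = fingerprint(query, variant, nbits).bits
    mat = fingerprint_matrix(library, variant, nbits)
    sims = tanimoto_matrix(qfp[None, :], mat)[0]
    hits = []
    for compound, sim in zip(library, sims):
        keep = sim > threshold if strict else sim >= threshold
        if keep:
            hits.append((compound.compound_id, float(sim)))
    hits.sort(key=lambda h: (-h[1], h[0]))
    return hits
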