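"""Seeded synthetic-data generator for every input the toolkit consumes.

Compound libraries are enumerated from a small scaffold grammar (five ring
scaffolds, two decoration sites), so the scaffold-tree structure of a
generated library is known by construction. Bioactivity is planted through
pharmacophores: each synthetic target is assigned a substructure, and
compounds containing it draw potent oriented values (default mean 7.0, i.e.
~100 nM) while the rest draw weak values (default mean 3.5, sub-millimolar,
below every QSAR cutoff) — so activity is a learnable function of
structure, which is what makes classifier-recovery checks meaningful.
Oriented values are back-converted to a randomly chosen raw data type and
unit before being stored, exercising the normalization layer. The PPI
generator plants one dense module covered exactly by one annotation term.

All generation is a pure function of :class:`FixtureConfig`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
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
from .io import (
    normalize_unit,
    write_activity_table,
    write_annotations,
    write_compounds,
    write_ppi,
    write_targets,
)

#: scaffold grammar: (plain SMILES, template with one substitution site)
DEFAULT_SCAFFOLDS: Tuple[Tuple[str, str], ...] = (
    ("c1ccccc1", "c1ccc({})cc1"),          # benzene
    ("c1ccncc1", "c1ccc({})nc1"),          # pyridine
    ("C1CCCCC1", "C1CCC({})CC1"),          # cyclohexane
    ("c1ccsc1", "c1cc({})sc1"),            # thiophene
    # benzofuran: a two-ring scaffold whose tree root (furan, after the
    # carbocycle is removed first) is distinct from every other root
    ("c1ccc2c(c1)cco2", "c1ccc2c(c1)cc({})o2"),
)

#: decoration fragments, written so they attach as a SMILES prefix; neutral
#: fragments first, then three variants of each planted pharmacophore so each
#: pharmacophore class reaches a realistic focused-library hit rate (~10-15%)
DEFAULT_DECORATIONS: Tuple[str, ...] = (
    # neutral
    "",
    "C",
    "CC",
    "CCC",
    "C(C)C",
    "O",
    "N",
    "F",
    "Cl",
    "OC",
    # sulfonamide
    "CS(=O)(=O)N",
    "CCS(=O)(=O)N",
    "NS(=O)(=O)C",
    # nitrile
    "N#C",
    "N#CC",
    "N#CCC",
    # carboxyl / ester
    "OC(=O)",
    "OC(=O)C",
    "COC(=O)",
    # amide
    "NC(=O)",
    "CNC(=O)",
    "NC(=O)C",
    # bromo
    "Br",
    "BrC",
    "BrCC",
)

#: pharmacophore substructures assigned to targets cyclically
DEFAULT_PHARMACOPHORES: Tuple[str, ...] = (
    "S(=O)(=O)N",   # sulfonamide
    "C#N",          # nitrile
    "C(=O)O",       # carboxyl/ester
    "C(=O)N",       # amide
    "Br",           # bromo
)

FAMILY_PATHS: Tuple[Tuple[str, ...], ...] = (
    ("enzyme", "kinase"),
    ("enzyme", "protease"),
    ("gpcr", "family_a"),
    ("gpcr", "family_b"),
    ("ion_channel", "ligand_gated"),
)


@dataclass
class FixtureConfig:
    """Conditions for one synthetic study.

    ``noise_sd`` is the SD (log units) of oriented activity values around
    their planted means; ``active_mean``/``inactive_mean`` are the planted
    potencies of pharmacophore-matching and non-matching compounds.
    """

    n_compounds: int = 200
    n_targets: int = 20
    seed: int = 0
    noise_sd: float = 0.2
    active_mean: float = 7.0
    inactive_mean: float = 3.5
    missing_fraction: float = 0.0
    scaffolds: Tuple[Tuple[str, str], ...] = DEFAULT_SCAFFOLDS
    decorations: Tuple[str, ...] = DEFAULT_DECORATIONS
    pharmacophores: Tuple[str, ...] = DEFAULT_PHARMACOPHORES
    module_size: int = 8
    n_annotation_terms: int = 20

    def __post_init__(self) -> None:
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.scaffolds:
            raise ValueError("scaffold grammar must be non-empty")

    def target_ids(self) -> List[str]:
        return [f"T{i:05d}" for i in range(1, self.n_targets + 1)]

    def pharmacophore_of(self, target_id: str) -> str:
        idx = self.target_ids().index(target_id)
        return self.pharmacophores[idx % len(self.pharmacophores)]


def generate_library(config: FixtureConfig) -> List[Compound]:
    """Enumerate ``n_compounds`` decorated scaffolds, deterministically.

    Single-decorated molecules come first (every decoration on every
    scaffold), then doubly decorated combinations; duplicates by canonical
    SMILES are skipped. Exceeding the grammar's capacity is an error.
    """
    decos = config.decorations
    pairs = [(d, "") for d in decos] + [
        (d1, d2) for d1 in decos for d2 in decos if d2 != ""
    ]
    seen = set()
    compounds: List[Compound] = []
    for d1, d2 in pairs:
        for plain, template in config.scaffolds:
            smiles = d1 + (template.format(d2) if d2 else plain)
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:  # a grammar combination can be chemically invalid
                continue
            canonical = Chem.MolToSmiles(mol)
            if canonical in seen:
                continue
            seen.add(canonical)
            compounds.append(
                Compound(compound_id=f"CPD{len(compounds) + 1:05d}", smiles=canonical)
            )
            if len(compounds) == config.n_compounds:
                return compounds
    raise ValueError(
        f"grammar capacity {len(compounds)} < requested n_compounds {config.n_compounds}"
    )


def generate_targets(config: FixtureConfig) -> List[Target]:
    return [
        Target(target_id=tid, family_path=FAMILY_PATHS[i % len(FAMILY_PATHS)] + (tid,))
        for i, tid in enumerate(config.target_ids())
    ]


def pharmacophore_actives(
    library: Sequence[Compound], pharmacophore: str
) -> List[str]:
    """Compound ids containing the pharmacophore substructure."""
    patt = Chem.MolFromSmarts(pharmacophore)
    out = []
    for c in library:
        if Chem.MolFromSmiles(c.smiles).HasSubstructMatch(patt):
            out.append(c.compound_id)
    return out


_RAW_UNITS = ("nM", "uM")


def generate_activities(
    library: Sequence[Compound], config: FixtureConfig
) -> List[ActivityRecord]:
    """Draw one activity per (compound, target) pair minus the missing mask.

    Matching compounds draw N(active_mean, noise_sd) oriented values,
    others N(inactive_mean, noise_sd); each value is back-converted to a
    randomly chosen data type (and unit, for concentration types) and then
    normalized, so the round trip through the orientation transform
    recovers the drawn value.
    """
    rng = np.random.default_rng(config.seed)
    targets = config.target_ids()
    match_sets = {
        tid: set(pharmacophore_actives(library, config.pharmacophore_of(tid)))
        for tid in targets
    }
    data_types = list(DataType)
    records: List[ActivityRecord] = []
    for compound in library:
        for tid in targets:
            if rng.random() < config.missing_fraction:
                continue
            mean = config.active_mean if compound.compound_id in match_sets[tid] else config.inactive_mean
            oriented = float(rng.normal(mean, config.noise_sd))
            dt = data_types[int(rng.integers(len(data_types)))]
            if dt in RAW_CONCENTRATION_TYPES:
                value_nm = 10.0 ** (9.0 - oriented)
                unit = _RAW_UNITS[int(rng.integers(len(_RAW_UNITS)))]
                raw_value = value_nm / (1e3 if unit == "uM" else 1.0)
                value = normalize_unit(dt, raw_value, unit)
                records.append(
                    ActivityRecord(compound.compound_id, tid, dt, value, unit="nM")
                )
            elif dt is DataType.LOGKI:
                records.append(
                    ActivityRecord(compound.compound_id, tid, dt, -oriented, unit="")
                )
            else:  # p-types
                records.append(
                    ActivityRecord(compound.compound_id, tid, dt, oriented, unit="")
                )
    return records


def generate_network_and_annotations(
    config: FixtureConfig,
) -> Tuple[PpiNetwork, List[AnnotationSet]]:
    """Random PPI graph with one planted clique covered by one term.

    The first ``module_size`` targets form a clique; background edges are
    Erdos-Renyi with p = 0.1. The planted term (``TERM_MODULE``, category
    disease) covers exactly the clique; the remaining terms are random
    member sets with categories cycled through disease/pathway/go_term.
    """
    rng = np.random.default_rng(config.seed + 1)
    targets = config.target_ids()
    if config.module_size > len(targets):
        raise ValueError("module_size exceeds n_targets")
    module = targets[: config.module_size]
    pairs = set(itertools.combinations(module, 2))
    for i, a in enumerate(targets):
        for b in targets[i + 1 :]:
            if (a, b) not in pairs and rng.random() < 0.1:
                pairs.add((a, b))
    network = PpiNetwork.from_pairs(pairs)

    categories = list(AnnotationCategory)
    annotations = [
        AnnotationSet(
            term_id="TERM_MODULE",
            category=AnnotationCategory.DISEASE,
            members=frozenset(module),
        )
    ]
    for k in range(1, config.n_annotation_terms):
        size = int(rng.integers(4, 11))
        members = rng.choice(targets, size=min(size, len(targets)), replace=False)
        annotations.append(
            AnnotationSet(
                term_id=f"TERM{k:04d}",
                category=categories[k % len(categories)],
                members=frozenset(members.tolist()),
            )
        )
    return network, annotations


@dataclass
class FixtureBundle:
    """Everything one synthetic study produces, ready for any module."""

    config: FixtureConfig
    library: List[Compound]
    targets: List[Target]
    records: List[ActivityRecord]
    network: PpiNetwork
    annotations: List[AnnotationSet]

    @property
    def compounds_by_id(self) -> Dict[str, Compound]:
        return {c.compound_id: c for c in self.library}


def generate_all(config: FixtureConfig) -> FixtureBundle:
    library = generate_library(config)
    network, annotations = generate_network_and_annotations(config)
    return FixtureBundle(
        config=config,
        library=library,
        targets=generate_targets(config),
        records=generate_activities(library, config),
        network=network,
        annotations=annotations,
    )


PRESETS = {
    "small": dict(n_compounds=60, n_targets=8, module_size=5, n_annotation_terms=10),
    "medium": dict(n_compounds=200, n_targets=20),
}


def write_fixture_files(outdir, seed: int = 0, preset: str = "small") -> FixtureBundle:
    """Write the full synthetic study to standard-format files."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    config = FixtureConfig(seed=seed, **PRESETS[preset])
    bundle = generate_all(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_compounds(bundle.library, outdir / "compounds.smi", format="smiles_list")
    write_activity_table(bundle.records, outdir / "activities.tsv")
    write_targets(bundle.targets, outdir / "targets.tsv")
    write_ppi(bundle.network, outdir / "ppi.tsv")
    write_annotations(bundle.annotations, outdir / "annotations.gmt")
    return bundle
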