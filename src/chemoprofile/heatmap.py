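"""Pharmacological heatmap matrix assembly.

Rows are compounds in scaffold-forest depth-first order, columns are
targets in family-tree depth-first order, and each cell holds the
strongest standardized activity (max z across data types) for that pair.
The color convention is blue = low/weak to orange = high/strong, recorded
as legend metadata. Empty cells can be filled by the SEA or QSAR
predictors; predicted cells are origin-tagged and never overwrite measured
values. QSAR probabilities stay on their own [0, 1] origin-tagged scale
(there is no principled map from a class probability to a z-score);
SEA fills display the calibrated z with the raw score kept alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .datatypes import ActivityRecord, AnnotationSet, Compound, Target
from .scaffolds import ScaffoldForest
from . import qsar as qsar_mod
from . import sea as sea_mod

LEGEND = {"low_color": "blue", "high_color": "orange"}

ORIGINS = ("measured", "sea", "qsar")


@dataclass(frozen=True)
class Cell:
    value: float  # display value (z for measured/sea; probability for qsar)
    origin: str
    raw: Optional[float] = None  # predictor-native value for predicted cells

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown cell origin {self.origin!r}")


@dataclass
class HeatmapMatrix:
    row_order: List[str]
    col_order: List[str]
    cells: Dict[Tuple[str, str], Cell]
    scale: Tuple[float, float]

    def __post_init__(self) -> None:
        rows, cols = set(self.row_order), set(self.col_order)
        for cid, tid in self.cells:
            if cid not in rows or tid not in cols:
                raise ValueError(f"cell ({cid}, {tid}) outside row/col orders")

    def measured_cells(self) -> Dict[Tuple[str, str], Cell]:
        return {k: v for k, v in self.cells.items() if v.origin == "measured"}


def target_family_order(targets: Sequence[Target]) -> List[str]:
    """Depth-first linearization of the family tree.

    Equivalent to sorting by (family_path, target_id): a parent node's
    targets precede its children's, siblings are lexicographic.
    """
    return [t.target_id for t in sorted(targets, key=lambda t: (t.family_path, t.target_id))]


def build_matrix(
    records: Sequence[ActivityRecord],
    forest: ScaffoldForest,
    targets: Sequence[Target],
) -> HeatmapMatrix:
    """Assemble the measured-activity matrix.

    Cell value = max z across all records (data types and replicates) for
    the pair — the strongest evidence is shown. Records must have z_scores;
    compounds missing from the forest are an error listing the offenders.
    """
    forest_members: Set[str] = set()
    for node in forest.index.values():
        forest_members |= node.members
    offenders = sorted({r.compound_id for r in records} - forest_members)
    if offenders:
        raise ValueError(f"compounds in records but not in forest: {offenders}")
    known_targets = {t.target_id for t in targets}
    missing_t = sorted({r.target_id for r in records} - known_targets)
    if missing_t:
        raise ValueError(f"targets in records but not in target table: {missing_t}")

    cells: Dict[Tuple[str, str], Cell] = {}
    for rec in records:
        if rec.z_score is None:
            raise ValueError("records must carry z_score; run compute_zscores first")
        key = (rec.compound_id, rec.target_id)
        prev = cells.get(key)
        if prev is None or rec.z_score > prev.value:
            cells[key] = Cell(value=rec.z_score, origin="measured")
    values = [c.value for c in cells.values()]
    scale = (min(values), max(values)) if values else (0.0, 0.0)
    return HeatmapMatrix(
        row_order=forest.depth_first_compounds(),
        col_order=target_family_order(targets),
        cells=cells,
        scale=scale,
    )


def fill_gaps(
    matrix: HeatmapMatrix,
    mode: str,
    *,
    compounds_by_id: Dict[str, Compound],
    sea_model: Optional[sea_mod.SeaBackgroundModel] = None,
    target_ligand_sets: Optional[Dict[str, Sequence[Compound]]] = None,
    qsar_ensembles: Optional[Dict[str, qsar_mod.QsarEnsemble]] = None,
) -> Tuple[HeatmapMatrix, List[str]]:
    """Fill empty cells with predictions; measured cells are never touched.

    Returns a new matrix plus the list of columns that could not be
    predicted (no QSAR model / too few SEA ligands). ``mode`` is ``"sea"``
    (needs ``sea_model`` and ``target_ligand_sets``) or ``"qsar"`` (needs
    ``qsar_ensembles``).
    """
    if mode not in ("sea", "qsar"):
        raise ValueError(f"unknown fill mode {mode!r}")
    cells = dict(matrix.cells)
    unpredictable: List[str] = []
    for tid in matrix.col_order:
        empty_rows = [cid for cid in matrix.row_order if (cid, tid) not in cells]
        if not empty_rows:
            continue
        if mode == "qsar":
            ensemble = (qsar_ensembles or {}).get(tid)
            if ensemble is None or ensemble.total_weight <= 0:
                unpredictable.append(tid)
                continue
            for cid in empty_rows:
                p, _ = qsar_mod.predict(ensemble, compounds_by_id[cid])
                cells[(cid, tid)] = Cell(value=p, origin="qsar", raw=p)
        else:
            if sea_model is None or target_ligand_sets is None:
                raise ValueError("sea mode needs sea_model and target_ligand_sets")
            ligands = target_ligand_sets.get(tid, [])
            if len(ligands) <= sea_mod.MIN_LIGANDS:
                unpredictable.append(tid)
                continue
            preds, _ = sea_mod.sea_predict(
                [compounds_by_id[cid] for cid in empty_rows],
                {tid: ligands},
                sea_model,
            )
            # per-cell scores: score each empty compound individually
            for cid in empty_rows:
                single, _ = sea_mod.sea_predict(
                    [compounds_by_id[cid]], {tid: ligands}, sea_model
                )
                pred = single[0]
                cells[(cid, tid)] = Cell(
                    value=pred.z_score, origin="sea", raw=pred.raw_score
                )
    return (
        HeatmapMatrix(
            row_order=list(matrix.row_order),
            col_order=list(matrix.col_order),
            cells=cells,
            scale=matrix.scale,
        ),
        unpredictable,
    )


def collapse_columns(
    matrix: HeatmapMatrix, annotations: Sequence[AnnotationSet]
) -> HeatmapMatrix:
    """Annotation-mode matrix: one column per term, max-z over member targets."""
    cells: Dict[Tuple[str, str], Cell] = {}
    col_order = sorted(a.term_id for a in annotations)
    for ann in annotations:
        for (cid, tid), cell in matrix.cells.items():
            if tid not in ann.members:
                continue
            key = (cid, ann.term_id)
            prev = cells.get(key)
            if prev is None or cell.value > prev.value:
                cells[key] = Cell(value=cell.value, origin=cell.origin, raw=cell.raw)
    return HeatmapMatrix(
        row_order=list(matrix.row_order),
        col_order=col_order,
        cells=cells,
        scale=matrix.scale,
    )


# ---------------------------------------------------------------------------
# export / import


def export_tsv(matrix: HeatmapMatrix, path) -> None:
    """Dense value grid with a ``<path>.origin`` sidecar grid.

    Empty cells are blank. Values are written with ``str(float)`` so that
    export -> import -> export is byte-identical. Predicted raw values are
    carried by the JSON form only.
    """
    path = Path(path)

    def grid(getter) -> str:
        lines = ["\t".join(["compound_id", *matrix.col_order])]
        for cid in matrix.row_order:
            row = [cid]
            for tid in matrix.col_order:
                cell = matrix.cells.get((cid, tid))
                row.append("" if cell is None else getter(cell))
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"

    path.write_text(grid(lambda c: str(c.value)))
    path.with_suffix(path.suffix + ".origin").write_text(grid(lambda c: c.origin))


def import_tsv(path) -> HeatmapMatrix:
    path = Path(path)
    vlines = path.read_text().splitlines()
    olines = path.with_suffix(path.suffix + ".origin").read_text().splitlines()
    col_order = vlines[0].split("\t")[1:]
    row_order: List[str] = []
    cells: Dict[Tuple[str, str], Cell] = {}
    for vline, oline in zip(vlines[1:], olines[1:]):
        vparts = vline.split("\t")
        oparts = oline.split("\t")
        cid = vparts[0]
        row_order.append(cid)
        for tid, v, o in zip(col_order, vparts[1:], oparts[1:]):
            if v != "":
                cells[(cid, tid)] = Cell(value=float(v), origin=o)
    values = [c.value for c in cells.values() if c.origin == "measured"] or [0.0]
    return HeatmapMatrix(
        row_order=row_order, col_order=col_order, cells=cells, scale=(min(values), max(values))
    )


def export_json(matrix: HeatmapMatrix, path) -> None:
    obj = {
        "row_order": matrix.row_order,
        "col_order": matrix.col_order,
        "scale": {"low": matrix.scale[0], "high": matrix.scale[1], **LEGEND},
        "cells": [
            {
                "compound_id": cid,
                "target_id": tid,
                "value": cell.value,
                "origin": cell.origin,
                "raw": cell.raw,
            }
            for (cid, tid), cell in sorted(matrix.cells.items())
        ],
    }
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def import_json(path) -> HeatmapMatrix:
    obj = json.loads(Path(path).read_text())
    cells = {
        (c["compound_id"], c["target_id"]): Cell(
            value=c["value"], origin=c["origin"], raw=c.get("raw")
        )
        for c in obj["cells"]
    }
    return HeatmapMatrix(
        row_order=obj["row_order"],
        col_order=obj["col_order"],
        cells=cells,
        scale=(obj["scale"]["low"], obj["scale"]["high"]),
    )
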