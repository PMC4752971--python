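"""Per-target, per-data-type activity standardization (z-scores).

Heterogeneous bioactivity readouts (IC50, Ki, pIC50, ...) are first mapped
onto a common -log10 molar ("p") scale oriented so that larger always means
a stronger interaction, then z-standardized within each (target, data_type)
group against that group's own distribution. A z of +2 therefore reads "two
standard deviations more potent than the typical measurement of this type
on this target", regardless of the original readout.

Conventions, stated so the arithmetic is exactly testable:

* sample (n-1) standard deviation;
* degenerate groups (n = 1, or sd = 0) are kept and assigned z = 0, flagged
  in :class:`ZGroupStats`, so every stored interaction still renders;
* duplicate measurements are kept as separate records, never aggregated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .datatypes import (
    ActivityRecord,
    DataType,
    P_TYPES,
    RAW_CONCENTRATION_TYPES,
)

NM_TO_M = 1e-9


def orient_value(data_type: DataType, value: float) -> float:
    """Map one activity value onto the oriented -log10 molar scale.

    Raw concentration types (value in nM) become ``-log10(value * 1e-9)``;
    pIC50/pKi/pEC50 pass through; LogKi (log10 molar Ki) is negated. Larger
    output always means stronger binding.
    """
    data_type = DataType(data_type)
    if data_type in RAW_CONCENTRATION_TYPES:
        if not value > 0:
            raise ValueError(f"{data_type.value} must be positive, got {value}")
        return -math.log10(value * NM_TO_M)
    if data_type in P_TYPES:
        return float(value)
    if data_type is DataType.LOGKI:
        return -float(value)
    raise ValueError(f"no orientation rule for {data_type}")  # pragma: no cover


def orient_records(records: Sequence[ActivityRecord]) -> List[ActivityRecord]:
    """Fill ``oriented_value`` in place on every record; returns the list."""
    out = list(records)
    for rec in out:
        rec.oriented_value = orient_value(rec.data_type, rec.value)
    return out


@dataclass(frozen=True)
class ZGroupStats:
    """Summary of one (target, data_type) standardization group."""

    target_id: str
    data_type: DataType
    mean: float
    sd: float
    n: int

    @property
    def degenerate(self) -> bool:
        return self.n < 2 or self.sd == 0.0


def compute_zscores(
    records: Sequence[ActivityRecord],
) -> Tuple[List[ActivityRecord], List[ZGroupStats]]:
    """Standardize oriented values within each (target, data_type) group.

    Returns the records with ``z_score`` filled (0 for degenerate groups)
    and per-group statistics. Records must have ``oriented_value`` set;
    call :func:`orient_records` first if not.
    """
    records = list(records)
    groups: Dict[Tuple[str, DataType], List[ActivityRecord]] = {}
    for rec in records:
        if rec.oriented_value is None:
            raise ValueError(
                f"record ({rec.compound_id}, {rec.target_id}) lacks oriented_value"
            )
        groups.setdefault((rec.target_id, rec.data_type), []).append(rec)

    stats: List[ZGroupStats] = []
    for (target_id, data_type), members in sorted(groups.items(), key=lambda kv: (kv[0][0], kv[0][1].value)):
        values = np.array([m.oriented_value for m in members], dtype=float)
        mean = float(values.mean())
        sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
        stats.append(ZGroupStats(target_id, data_type, mean, sd, len(values)))
        if len(values) < 2 or sd == 0.0:
            for m in members:
                m.z_score = 0.0
        else:
            for m in members:
                m.z_score = (m.oriented_value - mean) / sd
    return records, stats


def group_stats_frame(stats: Sequence[ZGroupStats]):
    """Group statistics as a DataFrame for the tab-separated export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "target_id": [s.target_id for s in stats],
            "data_type": [s.data_type.value for s in stats],
            "mean": [s.mean for s in stats],
            "sd": [s.sd for s in stats],
            "n": [s.n for s in stats],
            "degenerate": [s.degenerate for s in stats],
        }
    )
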