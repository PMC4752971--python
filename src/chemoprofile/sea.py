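"""Similarity Ensemble Approach (SEA) target prediction.

A query compound set is scored against each target's ligand set by summing
all cross-pair Tanimoto similarities at or above an inclusion threshold
(the *raw score*). Because the raw score of two unrelated sets grows with
the product of the set sizes, it is calibrated against randomly drawn set
pairs from a background library: the mean and standard deviation of random
raw scores are fitted as linear functions of n1*n2, giving a z-score for
the observed pair. Chance high scores among many weakly related pairs
behave like an extreme-value (Gumbel) statistic, so the tail probability

    P(Z > z) = 1 - exp(-exp(-(z * pi/sqrt(6) + gamma)))

(the zero-mean, unit-variance Gumbel parameterization; gamma is the
Euler-Mascheroni constant) converts z to a p-value, and multiplying by the
number of targets scored gives the reported E-value.

Only targets with more than ``min_ligands`` (default 10) ligands are
scored; smaller sets are returned in a skipped list. The default pair
inclusion threshold is Tc >= 0.57, the established optimum for
Daylight-style path fingerprints; it is configurable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .datatypes import Compound
from .similarity import DEFAULT_NBITS, fingerprint_matrix, tanimoto_matrix

EULER_GAMMA = float(np.euler_gamma)
DEFAULT_TC_THRESHOLD = 0.57
MIN_LIGANDS = 10

#: floor for the fitted raw-score SD, to keep z finite on degenerate fits
_SD_FLOOR = 1e-12


def raw_score_from_matrices(A: np.ndarray, B: np.ndarray, tc_threshold: float) -> float:
    sims = tanimoto_matrix(A, B)
    return float(sims[sims >= tc_threshold].sum())


def raw_score(
    setA: Sequence[Compound],
    setB: Sequence[Compound],
    tc_threshold: float = DEFAULT_TC_THRESHOLD,
    variant: str = "path1024",
    nbits: int = DEFAULT_NBITS,
) -> float:
    """Sum of cross-pair Tanimoto values >= ``tc_threshold``."""
    if not setA or not setB:
        raise ValueError("both compound sets must be non-empty")
    return raw_score_from_matrices(
        fingerprint_matrix(setA, variant, nbits),
        fingerprint_matrix(setB, variant, nbits),
        tc_threshold,
    )


@dataclass
class SeaBackgroundModel:
    """Linear calibration of random-pair raw scores against n1*n2."""

    tc_threshold: float
    variant: str
    slope_mean: float
    intercept_mean: float
    slope_sd: float
    intercept_sd: float
    n_samples: int
    seed: int

    def expected_mean(self, size_product: float) -> float:
        return self.slope_mean * size_product + self.intercept_mean

    def expected_sd(self, size_product: float) -> float:
        return max(self.slope_sd * size_product + self.intercept_sd, _SD_FLOOR)

    def zscore(self, raw: float, n1: int, n2: int) -> float:
        prod = n1 * n2
        return (raw - self.expected_mean(prod)) / self.expected_sd(prod)

    def to_json(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "SeaBackgroundModel":
        from pathlib import Path

        return cls(**json.loads(Path(path).read_text()))


def fit_background(
    library: Sequence[Compound],
    set_sizes: Sequence[int] = (4, 8, 16, 32),
    n_samples: int = 100,
    tc_threshold: float = DEFAULT_TC_THRESHOLD,
    seed: int = 0,
    variant: str = "path1024",
    nbits: int = DEFAULT_NBITS,
) -> SeaBackgroundModel:
    """Fit the random-pair background model on a compound library.

    For every ordered size combination (s1 <= s2) it draws ``n_samples``
    disjoint random set pairs, computes their raw scores, and regresses the
    per-combination mean and SD on s1*s2. Deterministic given ``seed``.
    """
    max_size = max(set_sizes)
    if len(library) < 10 * max_size:
        raise ValueError(
            f"background library too small: {len(library)} < 10 x {max_size}"
        )
    rng = np.random.default_rng(seed)
    fps = fingerprint_matrix(library, variant, nbits)
    combos = [
        (s1, s2) for i, s1 in enumerate(sorted(set_sizes)) for s2 in sorted(set_sizes)[i:]
    ]
    prods: List[float] = []
    means: List[float] = []
    sds: List[float] = []
    total = 0
    for s1, s2 in combos:
        scores = np.empty(n_samples)
        for k in range(n_samples):
            idx = rng.choice(len(library), size=s1 + s2, replace=False)
            scores[k] = raw_score_from_matrices(fps[idx[:s1]], fps[idx[s1:]], tc_threshold)
        total += n_samples
        prods.append(s1 * s2)
        means.append(float(scores.mean()))
        sds.append(float(scores.std(ddof=1)) if n_samples > 1 else 0.0)
    if total < 100:
        raise ValueError(f"background fit needs >= 100 sampled pairs, got {total}")
    slope_mean, intercept_mean = np.polyfit(prods, means, 1)
    slope_sd, intercept_sd = np.polyfit(prods, sds, 1)
    return SeaBackgroundModel(
        tc_threshold=tc_threshold,
        variant=variant,
        slope_mean=float(slope_mean),
        intercept_mean=float(intercept_mean),
        slope_sd=float(slope_sd),
        intercept_sd=float(intercept_sd),
        n_samples=total,
        seed=seed,
    )


def gumbel_tail(z: float) -> float:
    """P(Z > z) for the zero-mean, unit-variance Gumbel distribution."""
    return float(-math.expm1(-math.exp(-(z * math.pi / math.sqrt(6.0) + EULER_GAMMA))))


@dataclass(frozen=True)
class SeaPrediction:
    target_id: str
    raw_score: float
    z_score: float
    e_value: float
    n_target_ligands: int


def sea_predict(
    query: Sequence[Compound],
    target_sets: Dict[str, Sequence[Compound]],
    model: SeaBackgroundModel,
    min_ligands: int = MIN_LIGANDS,
    nbits: int = DEFAULT_NBITS,
) -> Tuple[List[SeaPrediction], List[str]]:
    """Score a query set against every sufficiently populated target set.

    Returns predictions sorted by ascending E-value (ties by target_id) and
    the list of skipped targets (ligand count <= ``min_ligands``). The
    E-value multiplicity factor is the number of targets actually scored.
    """
    if not query:
        raise ValueError("query set must be non-empty")
    qfps = fingerprint_matrix(query, model.variant, nbits)
    eligible = {t: s for t, s in target_sets.items() if len(s) > min_ligands}
    skipped = sorted(t for t in target_sets if t not in eligible)
    n_tested = len(eligible)
    predictions: List[SeaPrediction] = []
    for target_id, ligands in eligible.items():
        lfps = fingerprint_matrix(ligands, model.variant, nbits)
        raw = raw_score_from_matrices(qfps, lfps, model.tc_threshold)
        z = model.zscore(raw, len(query), len(ligands))
        e_value = gumbel_tail(z) * n_tested
        predictions.append(
            SeaPrediction(
                target_id=target_id,
                raw_score=raw,
                z_score=z,
                e_value=e_value,
                n_target_ligands=len(ligands),
            )
        )
    predictions.sort(key=lambda p: (p.e_value, p.target_id))
    return predictions, skipped
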