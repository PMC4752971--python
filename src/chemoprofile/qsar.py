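"""Per-target QSAR ensembles: 15 Naive-Bayes models with CV weights.

For every protein with more than 20 measured compounds, one binary
classifier is trained per combination of 5 fingerprint variants and 3
activity cutoffs (oriented -log10 molar values 4, 5 and 6; a compound is
*active* on a target iff its strongest oriented measurement reaches the
cutoff). Each training set is balanced by topping up (or subsampling)
measured inactives with randomly drawn library compounds that have no
measurement on the target. A Bernoulli Naive-Bayes over fingerprint bits
(Laplace add-one smoothing) is assessed by stratified 5-fold
cross-validation; the ensemble weight of each model is its cross-validated
Matthews correlation coefficient clipped at zero (AUROC is stored for
reporting). Ensemble predictions are the weight-normalized convex
combination of the member active-class probabilities, always in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from sklearn.metrics import matthews_corrcoef, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import BernoulliNB

from .datatypes import ActivityRecord, Compound
from .similarity import DEFAULT_NBITS, VARIANTS, fingerprint_matrix

ACTIVITY_CUTOFFS = (4.0, 5.0, 6.0)
MIN_TRAINING_COMPOUNDS = 20  # strict: targets need > 20 measured compounds
N_FOLDS = 5


class InsufficientDataError(ValueError):
    """Raised when a target has too few measured compounds for QSAR."""


@dataclass(frozen=True)
class QsarModelSpec:
    fingerprint_variant: str
    cutoff: float


@dataclass
class CvPerformance:
    auroc: float
    mcc: float
    folds: int = N_FOLDS


@dataclass
class QsarModel:
    """One trained member: spec, NB state, CV performance and weight."""

    spec: QsarModelSpec
    classifier: Optional[BernoulliNB]
    performance: Optional[CvPerformance]
    weight: float
    n_positives: int
    n_negatives: int

    @property
    def degenerate(self) -> bool:
        return self.classifier is None


@dataclass
class QsarEnsemble:
    target_id: str
    models: List[QsarModel]
    n_training_molecules: int
    seed: int
    nbits: int = DEFAULT_NBITS

    @property
    def total_weight(self) -> float:
        return sum(m.weight for m in self.models if not m.degenerate)


def label_actives(
    records: Sequence[ActivityRecord], target_id: str, cutoff: float
) -> Dict[str, str]:
    """Label each measured compound on a target active/inactive at a cutoff.

    Active iff the compound's maximum oriented value on the target reaches
    the cutoff (inclusive boundary). Unmeasured targets give an empty map.
    """
    best: Dict[str, float] = {}
    for rec in records:
        if rec.target_id != target_id:
            continue
        if rec.oriented_value is None:
            raise ValueError("records must carry oriented_value; run orient_records")
        prev = best.get(rec.compound_id)
        if prev is None or rec.oriented_value > prev:
            best[rec.compound_id] = rec.oriented_value
    return {cid: ("active" if v >= cutoff else "inactive") for cid, v in best.items()}


def balance_negatives(
    positives: Set[str],
    measured_negatives: Set[str],
    pool: Sequence[Compound],
    seed: int,
) -> List[str]:
    """Return a negative id list of exactly ``len(positives)`` compounds.

    Measured inactives are used first; shortfalls are topped up with seeded
    uniform draws from ``pool`` (which must exclude the positives), and a
    surplus is subsampled. Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    positives = set(positives)
    if positives & measured_negatives:
        raise ValueError("positives and measured_negatives overlap")
    pool_ids = [c.compound_id for c in pool]
    if set(pool_ids) & positives:
        raise ValueError("pool must exclude positive compounds")
    n = len(positives)
    measured = sorted(measured_negatives)
    if len(measured) == n:
        return measured
    if len(measured) > n:
        idx = rng.choice(len(measured), size=n, replace=False)
        return [measured[i] for i in sorted(idx)]
    candidates = sorted(set(pool_ids) - measured_negatives)
    shortfall = n - len(measured)
    if len(candidates) < shortfall:
        raise ValueError(
            f"pool too small to balance: need {shortfall} more negatives, have {len(candidates)}"
        )
    idx = rng.choice(len(candidates), size=shortfall, replace=False)
    return measured + [candidates[i] for i in sorted(idx)]


def _cross_validate(
    X: np.ndarray, y: np.ndarray, seed: int
) -> Optional[CvPerformance]:
    """Stratified 5-fold CV AUROC/MCC; None when folds are infeasible."""
    n_min = min(np.bincount(y))
    if n_min < N_FOLDS:
        return None
    skf = StratifiedKFold(n_splits=N_FOLDS, shuffle=True, random_state=seed)
    y_prob = np.zeros(len(y))
    y_pred = np.zeros(len(y), dtype=int)
    for train_idx, test_idx in skf.split(X, y):
        clf = BernoulliNB(alpha=1.0)
        clf.fit(X[train_idx], y[train_idx])
        y_prob[test_idx] = clf.predict_proba(X[test_idx])[:, 1]
        y_pred[test_idx] = clf.predict(X[test_idx])
    return CvPerformance(
        auroc=float(roc_auc_score(y, y_prob)),
        mcc=float(matthews_corrcoef(y, y_pred)),
    )


def train_ensemble(
    records: Sequence[ActivityRecord],
    target_id: str,
    pool: Sequence[Compound],
    seed: int,
    compounds_by_id: Optional[Dict[str, Compound]] = None,
    nbits: int = DEFAULT_NBITS,
) -> QsarEnsemble:
    """Train the 15-model ensemble for one target.

    ``pool`` supplies structures for every measured compound plus the
    random-negative candidates; compounds measured on the target are never
    drawn as random negatives. Targets with <= 20 measured compounds raise
    :class:`InsufficientDataError`. A cutoff with no positives (or no
    negatives after labeling) yields degenerate members with weight 0,
    which are recorded but never vote.
    """
    if compounds_by_id is None:
        compounds_by_id = {c.compound_id: c for c in pool}
    measured = sorted({r.compound_id for r in records if r.target_id == target_id})
    if len(measured) <= MIN_TRAINING_COMPOUNDS:
        raise InsufficientDataError(
            f"target {target_id}: {len(measured)} measured compounds, need > {MIN_TRAINING_COMPOUNDS}"
        )
    missing = [cid for cid in measured if cid not in compounds_by_id]
    if missing:
        raise ValueError(f"no structure for measured compounds: {missing[:5]}")
    random_pool = [c for c in pool if c.compound_id not in set(measured)]

    fp_cache: Dict[str, np.ndarray] = {}

    def fps(ids: List[str], variant: str) -> np.ndarray:
        key_missing = [cid for cid in ids if f"{variant}:{cid}" not in fp_cache]
        if key_missing:
            mat = fingerprint_matrix(
                [compounds_by_id[cid] for cid in key_missing], variant, nbits
            )
            for cid, row in zip(key_missing, mat):
                fp_cache[f"{variant}:{cid}"] = row
        return np.stack([fp_cache[f"{variant}:{cid}"] for cid in ids])

    models: List[QsarModel] = []
    seed_stream = np.random.SeedSequence(seed).generate_state(len(VARIANTS) * len(ACTIVITY_CUTOFFS))
    i = 0
    for cutoff in ACTIVITY_CUTOFFS:
        labels = label_actives(records, target_id, cutoff)
        positives = {cid for cid, lab in labels.items() if lab == "active"}
        negatives = {cid for cid, lab in labels.items() if lab == "inactive"}
        for variant in VARIANTS:
            spec = QsarModelSpec(fingerprint_variant=variant, cutoff=cutoff)
            member_seed = int(seed_stream[i] % (2**31 - 1))
            i += 1
            if not positives or (not negatives and not random_pool):
                models.append(QsarModel(spec, None, None, 0.0, len(positives), 0))
                continue
            neg_ids = balance_negatives(positives, negatives, random_pool, member_seed)
            pos_ids = sorted(positives)
            ids = pos_ids + neg_ids
            X = fps(ids, variant)
            y = np.array([1] * len(pos_ids) + [0] * len(neg_ids))
            perf = _cross_validate(X, y, member_seed)
            if perf is None:
                models.append(QsarModel(spec, None, None, 0.0, len(pos_ids), len(neg_ids)))
                continue
            clf = BernoulliNB(alpha=1.0)
            clf.fit(X, y)
            weight = max(perf.mcc, 0.0)
            models.append(QsarModel(spec, clf, perf, weight, len(pos_ids), len(neg_ids)))
    return QsarEnsemble(
        target_id=target_id,
        models=models,
        n_training_molecules=len(measured),
        seed=seed,
        nbits=nbits,
    )


def predict(ensemble: QsarEnsemble, compound: Compound) -> Tuple[float, int]:
    """Weighted ensemble probability of activity, with training-set size.

    Returns ``(prediction in [0,1], n_training_molecules)``; raises when no
    member carries positive weight ("no reliable model").
    """
    total = ensemble.total_weight
    if total <= 0:
        raise ValueError(
            f"target {ensemble.target_id}: no reliable model (all CV weights zero)"
        )
    num = 0.0
    for model in ensemble.models:
        if model.degenerate or model.weight <= 0:
            continue
        X = fingerprint_matrix([compound], model.spec.fingerprint_variant, ensemble.nbits)
        p = float(model.classifier.predict_proba(X)[0, 1])
        num += model.weight * p
    return num / total, ensemble.n_training_molecules


# ---------------------------------------------------------------------------
# transparent JSON persistence (no opaque binary blobs)


def _model_to_obj(model: QsarModel) -> dict:
    obj = {
        "fingerprint_variant": model.spec.fingerprint_variant,
        "cutoff": model.spec.cutoff,
        "weight": model.weight,
        "n_positives": model.n_positives,
        "n_negatives": model.n_negatives,
        "performance": None,
        "nb": None,
    }
    if model.performance is not None:
        obj["performance"] = {
            "auroc": model.performance.auroc,
            "mcc": model.performance.mcc,
            "folds": model.performance.folds,
        }
    if model.classifier is not None:
        clf = model.classifier
        obj["nb"] = {
            "class_log_prior": clf.class_log_prior_.tolist(),
            "feature_log_prob": clf.feature_log_prob_.tolist(),
            "classes": clf.classes_.tolist(),
            "n_features": int(clf.n_features_in_),
        }
    return obj


def _model_from_obj(obj: dict) -> QsarModel:
    clf = None
    if obj["nb"] is not None:
        clf = BernoulliNB(alpha=1.0)
        clf.classes_ = np.array(obj["nb"]["classes"])
        clf.class_log_prior_ = np.array(obj["nb"]["class_log_prior"])
        clf.feature_log_prob_ = np.array(obj["nb"]["feature_log_prob"])
        clf.n_features_in_ = obj["nb"]["n_features"]
        clf.class_count_ = np.exp(clf.class_log_prior_)  # placeholder, unused
        clf.feature_count_ = np.zeros_like(clf.feature_log_prob_)
    perf = None
    if obj["performance"] is not None:
        perf = CvPerformance(**obj["performance"])
    return QsarModel(
        spec=QsarModelSpec(obj["fingerprint_variant"], obj["cutoff"]),
        classifier=clf,
        performance=perf,
        weight=obj["weight"],
        n_positives=obj["n_positives"],
        n_negatives=obj["n_negatives"],
    )


def save_ensemble(ensemble: QsarEnsemble, path) -> None:
    obj = {
        "target_id": ensemble.target_id,
        "n_training_molecules": ensemble.n_training_molecules,
        "seed": ensemble.seed,
        "nbits": ensemble.nbits,
        "models": [_model_to_obj(m) for m in ensemble.models],
    }
    Path(path).write_text(json.dumps(obj) + "\n")


def load_ensemble(path) -> QsarEnsemble:
    obj = json.loads(Path(path).read_text())
    return QsarEnsemble(
        target_id=obj["target_id"],
        models=[_model_from_obj(m) for m in obj["models"]],
        n_training_molecules=obj["n_training_molecules"],
        seed=obj["seed"],
        nbits=obj["nbits"],
    )
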