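import numpy as np
import pytest

from chemoprofile.datatypes import ActivityRecord, Compound, DataType
from chemoprofile.fixtures import pharmacophore_actives
from chemoprofile.qsar import (
    CvPerformance,
    InsufficientDataError,
    QsarEnsemble,
    QsarModel,
    QsarModelSpec,
    balance_negatives,
    label_actives,
    load_ensemble,
    predict,
    save_ensemble,
    train_ensemble,
)
from chemoprofile.standardization import orient_records


class TestLabelActives:
    def _rec(self, cid, value_nm, dt=DataType.IC50):
        return orient_records([ActivityRecord(cid, "t1", dt, value_nm)])[0]

    def test_boundary_is_inclusive(self):
        labels = label_actives([self._rec("c1", 1000.0)], "t1", cutoff=6.0)
        assert labels == {"c1": "active"}  # oriented exactly 6.0

    def test_orientation_decides_the_class(self):
        records = [self._rec("c1", 1000.0), self._rec("c2", 100_000.0, DataType.KI)]
        labels = label_actives(records, "t1", cutoff=5.0)
        assert labels == {"c1": "active", "c2": "inactive"}  # oriented 6.0 vs 4.0

    def test_max_over_replicates_wins(self):
        records = [self._rec("c1", 1000.0), self._rec("c1", 1_000_000.0)]
        assert label_actives(records, "t1", cutoff=6.0) == {"c1": "active"}

    def test_absent_target_gives_empty_mapping(self):
        assert label_actives([self._rec("c1", 10.0)], "other", 5.0) == {}

    def test_planted_potency_counts_match_construction(self, standardized_bundle):
        bundle, records, _ = standardized_bundle
        planted = set(
            pharmacophore_actives(bundle.library, bundle.config.pharmacophore_of("T00001"))
        )
        labels = label_actives(records, "T00001", cutoff=5.0)
        actives = {cid for cid, lab in labels.items() if lab == "active"}
        # cutoff 5 sits >7 sd from both planted means: classes = pharmacophore split
        assert actives == planted


class TestBalanceNegatives:
    POOL = [Compound(f"p{i}", "CC") for i in range(30)]

    def test_already_balanced_unchanged(self):
        negs = balance_negatives({"a", "b"}, {"x", "y"}, self.POOL, seed=0)
        assert sorted(negs) == ["x", "y"]

    def test_top_up_from_pool_is_deterministic(self):
        negs1 = balance_negatives(set("abcdefghij"), {"x", "y", "z", "w"}, self.POOL, seed=7)
        negs2 = balance_negatives(set("abcdefghij"), {"x", "y", "z", "w"}, self.POOL, seed=7)
        assert negs1 == negs2
        assert len(negs1) == 10
        assert set("xyzw") <= set(negs1)

    def test_surplus_is_subsampled_to_class_balance(self):
        measured = {f"n{i}" for i in range(25)}
        negs = balance_negatives(set("abcdefghij"), measured, self.POOL, seed=3)
        assert len(negs) == 10
        assert set(negs) <= measured

    def test_pool_too_small_names_the_shortfall(self):
        with pytest.raises(ValueError, match="pool too small"):
            balance_negatives(set("abcdefghij"), set(), self.POOL[:4], seed=0)

    def test_pool_containing_positives_rejected(self):
        with pytest.raises(ValueError):
            balance_negatives({"p1"}, set(), self.POOL, seed=0)


class TestTrainEnsemble:
    def test_twenty_compound_target_is_refused(self):
        records = orient_records(
            [ActivityRecord(f"c{i}", "t1", DataType.PKI, 7.0) for i in range(20)]
        )
        pool = [Compound(f"c{i}", "CC") for i in range(20)]
        with pytest.raises(InsufficientDataError):
            train_ensemble(records, "t1", pool, seed=0)

    def test_ensemble_on_separable_fixture(self, standardized_bundle):
        bundle, records, _ = standardized_bundle
        ensemble = train_ensemble(records, "T00001", bundle.library, seed=1)
        assert len(ensemble.models) == 15
        assert ensemble.n_training_molecules == len(bundle.library)
        trained = [m for m in ensemble.models if not m.degenerate]
        assert trained, "separable fixture must yield usable models"
        for model in trained:
            assert model.n_positives == model.n_negatives  # exact class balance
            assert model.weight >= 0
        planted = set(
            pharmacophore_actives(bundle.library, bundle.config.pharmacophore_of("T00001"))
        )
        preds = {c.compound_id: predict(ensemble, c)[0] for c in bundle.library[:60]}
        assert all(0 <= p <= 1 for p in preds.values())
        pos = [p for cid, p in preds.items() if cid in planted]
        neg = [p for cid, p in preds.items() if cid not in planted]
        assert np.mean(pos) > np.mean(neg)

    def test_same_seed_gives_identical_weights(self, standardized_bundle):
        bundle, records, _ = standardized_bundle
        e1 = train_ensemble(records, "T00002", bundle.library, seed=9)
        e2 = train_ensemble(records, "T00002", bundle.library, seed=9)
        assert [m.weight for m in e1.models] == [m.weight for m in e2.models]

    def test_save_load_round_trip_preserves_predictions(self, tmp_path, standardized_bundle):
        bundle, records, _ = standardized_bundle
        ensemble = train_ensemble(records, "T00001", bundle.library, seed=1)
        save_ensemble(ensemble, tmp_path / "t1.json")
        reloaded = load_ensemble(tmp_path / "t1.json")
        for compound in bundle.library[:10]:
            assert predict(reloaded, compound)[0] == pytest.approx(
                predict(ensemble, compound)[0], abs=1e-9
            )


class TestPredictAggregation:
    class _FixedProb:
        def __init__(self, p):
            self.p = p

        def predict_proba(self, X):
            return np.array([[1 - self.p, self.p]] * len(X))

    def _ensemble(self, weighted_probs):
        models = [
            QsarModel(
                spec=QsarModelSpec("path1024", 5.0),
                classifier=self._FixedProb(p),
                performance=CvPerformance(auroc=1.0, mcc=w),
                weight=w,
                n_positives=5,
                n_negatives=5,
            )
            for w, p in weighted_probs
        ]
        return QsarEnsemble(target_id="t", models=models, n_training_molecules=30, seed=0)

    def test_weighted_mean_matches_hand_computation(self):
        ensemble = self._ensemble([(0.2, 0.5), (0.6, 1.0)])
        p, n_train = predict(ensemble, Compound("q", "CC"))
        assert p == pytest.approx(0.875)  # (0.2*0.5 + 0.6*1.0) / 0.8
        assert n_train == 30

    @pytest.mark.parametrize("p_all,expected", [(1.0, 1.0), (0.0, 0.0)])
    def test_convexity_endpoints(self, p_all, expected):
        ensemble = self._ensemble([(0.3, p_all), (0.5, p_all)])
        assert predict(ensemble, Compound("q", "CC"))[0] == pytest.approx(expected)

    def test_all_zero_weights_is_no_reliable_model_error(self):
        ensemble = self._ensemble([(0.0, 1.0), (0.0, 0.3)])
        with pytest.raises(ValueError, match="no reliable model"):
            predict(ensemble, Compound("q", "CC"))
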