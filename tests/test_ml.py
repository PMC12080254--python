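"""Classifier training, applicability domain, prediction gating, explanations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold

from pmtscreen import ml
from pmtscreen import simulate as sim
from pmtscreen.rules import CANDIDATE, NOT_PMT_VPVM, UNRESOLVED


@pytest.fixture(scope="module")
def toy_features():
    rng = np.random.default_rng(11)
    X = pd.DataFrame(
        rng.normal(size=(120, 5)),
        columns=[f"d{i}" for i in range(5)],
        index=[f"C{i:03d}" for i in range(120)],
    )
    y = (X["d0"] + 0.5 * X["d1"] < 0).astype(int)
    return X, y


class TestTrain:
    def test_single_class_labels_error(self, toy_features):
        X, _ = toy_features
        with pytest.raises(ValueError, match="single class"):
            ml.train(X, np.ones(len(X)), seed=0)

    def test_length_mismatch_error(self, toy_features):
        X, y = toy_features
        with pytest.raises(ValueError, match="mismatch"):
            ml.train(X, y[:-5], seed=0)

    def test_deterministic_given_seed(self, toy_features):
        X, y = toy_features
        b1 = ml.train(X, y, seed=7)
        b2 = ml.train(X, y, seed=7)
        Xs = b1.transform(X)
        np.testing.assert_array_equal(
            b1.model.predict_proba(Xs), b2.model.predict_proba(Xs)
        )
        assert b1.ad_threshold == b2.ad_threshold

    def test_nan_features_imputed_with_training_medians(self, toy_features):
        X, y = toy_features
        Xn = X.copy()
        Xn.iloc[0, 0] = np.nan
        bundle = ml.train(Xn, y, seed=0)
        assert np.isfinite(bundle.transform(Xn)).all()

    def test_serialization_roundtrip_identical_predictions(self, tmp_path, toy_features):
        X, y = toy_features
        bundle = ml.train(X, y, seed=3)
        ml.save_bundle(bundle, tmp_path / "bundle")
        again = ml.load_bundle(tmp_path / "bundle")
        Xs = bundle.transform(X)
        np.testing.assert_array_equal(
            bundle.model.predict_proba(Xs), again.model.predict_proba(Xs)
        )
        assert again.ad_threshold == bundle.ad_threshold
        assert again.feature_names == bundle.feature_names


class TestApplicabilityDomain:
    def test_training_compound_distance_zero(self, toy_features):
        X, y = toy_features
        bundle = ml.train(X, y, seed=0)
        stats = ml.applicability_domain(bundle, X.iloc[[0]])
        assert stats[0].distance == pytest.approx(0.0, abs=1e-9)
        assert stats[0].in_domain

    def test_euclidean_identity_3_4_5(self):
        # two scaled features, nearest neighbor offset by (3, 4)
        X = pd.DataFrame({"a": [0.0, 3.0], "b": [0.0, 4.0]}, index=["t0", "t1"])
        y = [0, 1]
        bundle = ml.train(X, y, seed=0)
        # overwrite scaling to the identity so distances are raw Euclidean
        bundle.scale_center = np.zeros(2)
        bundle.scale_spread = np.ones(2)
        bundle.training_scaled = X.to_numpy(float)
        bundle.nn_index = None
        q = pd.DataFrame({"a": [0.0], "b": [0.0]}, index=["q"])
        stats = ml.applicability_domain(bundle, q)
        assert stats[0].distance == pytest.approx(0.0)
        q2 = pd.DataFrame({"a": [6.0], "b": [8.0]}, index=["q2"])
        stats2 = ml.applicability_domain(bundle, q2)
        assert stats2[0].distance == pytest.approx(5.0)

    def test_in_domain_monotone_in_threshold(self, toy_features):
        X, y = toy_features
        bundle = ml.train(X, y, seed=0)
        rng = np.random.default_rng(1)
        Q = X + rng.normal(scale=0.5, size=X.shape)
        stats = ml.applicability_domain(bundle, Q)
        frac = lambda thr: np.mean([s.distance <= thr for s in stats])
        thresholds = np.linspace(0, 10, 20)
        fracs = [frac(t) for t in thresholds]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_column_mismatch_error(self, toy_features):
        X, y = toy_features
        bundle = ml.train(X, y, seed=0)
        with pytest.raises(ValueError, match="columns"):
            ml.applicability_domain(bundle, X.rename(columns={"d0": "zzz"}))


class TestPredict:
    def test_out_of_domain_is_unresolved_regardless_of_score(self, toy_features):
        X, y = toy_features
        bundle = ml.train(X, y, seed=0)
        far = X.iloc[[0]] + 1e3  # certainly outside the domain
        far.index = ["far"]
        out = ml.predict(bundle, far)
        assert out[0].hazard_class == UNRESOLVED
        assert "outside AD" in out[0].detail

    def test_in_domain_positive_is_candidate_only(self, toy_features):
        X, y = toy_features
        bundle = ml.train(X, y, seed=0)
        out = ml.predict(bundle, X)
        classes = {a.hazard_class for a in out}
        assert classes <= {CANDIDATE, NOT_PMT_VPVM, UNRESOLVED}
        assert all(a.decided_by == "ml_model" for a in out
                   if a.hazard_class != UNRESOLVED)


class TestPlantedRuleRecovery:
    def test_cross_validated_balanced_accuracy(self, training_data):
        """Five-fold CV on the default planted-rule training set."""
        feats, labels, _ = training_data
        scores = []
        for tr, te in StratifiedKFold(5, shuffle=True, random_state=42).split(
            feats, labels
        ):
            b = ml.train(feats.iloc[tr], labels.iloc[tr], seed=42)
            pred = b.model.predict(b.transform(feats.iloc[te]))
            scores.append(balanced_accuracy_score(labels.iloc[te], pred))
        assert np.mean(scores) >= 0.9

    def test_global_importance_ranks_logp_first_with_negative_sign(
        self, bundle, training_data
    ):
        feats, _, _ = training_data
        records, importance = ml.explain(bundle, feats)
        assert importance.index[0] == "logP_estimate"
        assert ml.dependence_sign(records, feats, "logP_estimate") < 0

    def test_shap_additivity_on_every_explained_compound(self, bundle, training_data):
        feats, _, _ = training_data
        sample = feats.iloc[:100]
        records, _ = ml.explain(bundle, sample)
        out = bundle.model.predict_proba(bundle.transform(sample))[:, 1]
        for rec, o in zip(records, out):
            total = rec.base_value + rec.shap_values.sum()
            assert total == pytest.approx(o, rel=1e-6, abs=1e-9)

    def test_planted_features_recovered_across_seeds(self):
        """Top-5 global importance contains the planted features, 5 repeats."""
        for seed in range(5):
            spec = sim.GeneratorSpec(seed=seed, n_train=200)
            feats, labels, _ = sim.generate_training_set(spec)
            b = ml.train(feats, labels, seed=seed)
            _, importance = ml.explain(b, feats.iloc[:120])
            top5 = set(importance.index[:5])
            assert "logP_estimate" in top5


class TestExplainProperties:
    def test_constant_feature_zero_attribution(self, toy_features):
        X, y = toy_features
        Xc = X.copy()
        Xc["const"] = 1.0
        bundle = ml.train(Xc, y, seed=0)
        records, _ = ml.explain(bundle, Xc.iloc[:20])
        assert all(abs(r.shap_values["const"]) < 1e-12 for r in records)

    def test_interaction_matrix_contract(self, toy_features):
        X, y = toy_features
        bundle = ml.train(X, y, seed=0)
        records, _ = ml.explain(bundle, X.iloc[:5], with_interactions=True,
                                background_size=6)
        for r in records:
            m = r.interaction_matrix.to_numpy()
            np.testing.assert_allclose(m, m.T, atol=1e-12)
            np.testing.assert_allclose(
                m.sum(axis=1), r.shap_values.to_numpy(), atol=1e-10
            )


class TestOriginContrast:
    def _records(self, phi_by_compound):
        return [
            ml.ExplanationRecord(compound_id=cid, shap_values=pd.Series(vals),
                                 base_value=0.0)
            for cid, vals in phi_by_compound.items()
        ]

    def test_identical_strata_identical_lists(self):
        vals = {"A": {"f1": 1.0, "f2": 0.5}, "B": {"f1": 1.0, "f2": 0.5}}
        records = self._records(vals)
        origins = pd.Series({"A": "synthetic", "B": "natural"})
        out = ml.contrast_importance_by_origin(records, origins, k=2)
        assert out["unique_to_synthetic"] == []
        assert out["unique_to_natural_or_other"] == []
        assert list(out["rankings"]["synthetic"].index) == list(
            out["rankings"]["natural_or_other"].index
        )

    def test_stratum_specific_feature_surfaces_only_there(self):
        records = self._records({
            "A": {"f1": 1.0, "f2": 0.0, "f3": 0.9},
            "B": {"f1": 1.0, "f2": 0.0, "f3": 0.8},
            "C": {"f1": 1.0, "f2": 0.9, "f3": 0.0},
            "D": {"f1": 1.0, "f2": 0.8, "f3": 0.0},
        })
        origins = pd.Series({"A": "synthetic", "B": "synthetic",
                             "C": "natural", "D": "undefined"})
        out = ml.contrast_importance_by_origin(records, origins, k=2)
        assert out["unique_to_synthetic"] == ["f3"]
        assert out["unique_to_natural_or_other"] == ["f2"]
        assert out["shared"] == ["f1"]

    def test_empty_stratum_errors(self):
        records = self._records({"A": {"f1": 1.0}})
        origins = pd.Series({"A": "synthetic"})
        with pytest.raises(ValueError, match="empty origin stratum"):
            ml.contrast_importance_by_origin(records, origins)

    def test_k_beyond_feature_count_returns_full_ranking(self):
        records = self._records({"A": {"f1": 1.0, "f2": 0.5},
                                 "B": {"f1": 0.2, "f2": 0.1}})
        origins = pd.Series({"A": "synthetic", "B": "natural"})
        out = ml.contrast_importance_by_origin(records, origins, k=10)
        assert len(out["rankings"]["synthetic"]) == 2
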