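"""Activity labelling, fingerprinting, metrics and cross-validation."""

import numpy as np
import pytest

from molgen import (
    ActivityRecord, DiscriminatorError, MLPConfig, assemble_training_set,
    classification_metrics, cross_validate, label_by_ki, maccs_matrix,
    predict_likelihood, separable_fingerprint_dataset, train_discriminator,
)
from molgen.fixtures import FixtureError, class_templates


class TestLabelByKi:
    def test_strict_cutoff_semantics(self):
        records = [ActivityRecord("C", 50.0), ActivityRecord("CC", 100.0),
                   ActivityRecord("CCC", 150.0)]
        actives, inactives, rejected = label_by_ki(records)
        assert [r.ki_nm for r in actives] == [50.0]
        assert [r.ki_nm for r in inactives] == [100.0, 150.0]  # boundary inactive
        assert rejected == []

    def test_bad_rows_rejected_with_reason(self):
        records = [ActivityRecord("C", -5.0), ActivityRecord("CC", float("nan")),
                   ActivityRecord("CCC", 10.0)]
        actives, _, rejected = label_by_ki(records)
        assert len(actives) == 1
        assert {reason for _, reason in rejected} == {"non-positive Ki -5.0", "missing Ki"}


class TestFingerprints:
    def test_maccs_width_is_166(self):
        mat, kept, rejected = maccs_matrix(["CCO", "c1ccccc1"])
        assert mat.shape == (2, 166)
        assert rejected == []
        assert set(np.unique(mat)) <= {0, 1}

    def test_unparseable_rows_reported(self):
        mat, kept, rejected = maccs_matrix(["CCO", "C(", "CN"])
        assert kept == [0, 2]
        assert rejected[0][0] == 1

    def test_assemble_counts_and_provenance(self):
        ds = assemble_training_set(["CCO"], ["CCN"], ["c1ccccc1", "CCCC"])
        assert len(ds) == 4
        assert ds.labels.tolist() == [1, 0, 0, 0]
        assert ds.provenance == ["active", "inactive", "decoy", "decoy"]

    def test_zero_decoys_allowed_zero_actives_not(self):
        assert len(assemble_training_set(["CCO"], ["CCN"], [])) == 2
        with pytest.raises(DiscriminatorError):
            assemble_training_set([], ["CCN"], ["CC"])


class TestClassificationMetrics:
    def test_closed_form_example(self):
        m = classification_metrics(tp=40, fp=10, tn=45, fn=5)
        assert m["precision"] == pytest.approx(0.800, abs=1e-3)
        assert m["recall"] == pytest.approx(0.8889, abs=1e-3)
        assert m["f1"] == pytest.approx(0.8421, abs=1e-3)
        assert m["accuracy"] == pytest.approx(0.850, abs=1e-3)
        assert m["mcc"] == pytest.approx(0.7035, abs=1e-3)

    def test_perfect_classifier(self):
        m = classification_metrics(tp=30, fp=0, tn=70, fn=0)
        for key in ("precision", "recall", "f1", "accuracy", "kappa", "mcc"):
            assert m[key] == 1.0

    def test_majority_class_prediction_has_zero_kappa(self):
        m = classification_metrics(tp=0, fp=0, tn=80, fn=20)
        assert m["kappa"] == 0.0
        assert m["degenerate"]  # precision undefined -> flagged 0

    def test_agrees_with_sklearn_on_random_tables(self):
        """Every metric matches scikit-learn's reference implementation,
        reconstructing label vectors from the confusion counts."""
        from sklearn.metrics import (
            accuracy_score, cohen_kappa_score, f1_score, matthews_corrcoef,
            precision_score, recall_score,
        )

        rng = np.random.default_rng(12)
        for _ in range(100):
            tp, fp, tn, fn = (int(x) for x in rng.integers(0, 30, size=4))
            if tp + fp + tn + fn == 0:
                continue
            y_true = [1] * tp + [0] * fp + [0] * tn + [1] * fn
            y_pred = [1] * tp + [1] * fp + [0] * tn + [0] * fn
            m = classification_metrics(tp, fp, tn, fn)
            assert m["accuracy"] == pytest.approx(accuracy_score(y_true, y_pred), abs=1e-9)
            assert m["precision"] == pytest.approx(
                precision_score(y_true, y_pred, zero_division=0), abs=1e-9)
            assert m["recall"] == pytest.approx(
                recall_score(y_true, y_pred, zero_division=0), abs=1e-9)
            assert m["f1"] == pytest.approx(
                f1_score(y_true, y_pred, zero_division=0), abs=1e-9)
            if len(set(y_true)) > 1 or len(set(y_pred)) > 1:
                assert m["kappa"] == pytest.approx(
                    cohen_kappa_score(y_true, y_pred), abs=1e-9)
            assert m["mcc"] == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-9)

    def test_empty_table_rejected(self):
        with pytest.raises(DiscriminatorError):
            classification_metrics(0, 0, 0, 0)


class TestSyntheticFingerprintSet:
    def test_flip_noise_matches_binomial_mean(self):
        ds = separable_fingerprint_dataset(300, 300, flip_rate=0.05, seed=3)
        tpl_a, tpl_b = class_templates()
        dist_a = (ds.fingerprints[:300] ^ tpl_a[None, :]).sum(axis=1).mean()
        dist_b = (ds.fingerprints[300:] ^ tpl_b[None, :]).sum(axis=1).mean()
        assert dist_a == pytest.approx(166 * 0.05, abs=1.5)
        assert dist_b == pytest.approx(166 * 0.05, abs=1.5)

    def test_zero_noise_rows_equal_templates(self):
        ds = separable_fingerprint_dataset(5, 5, flip_rate=0.0, seed=1)
        tpl_a, tpl_b = class_templates()
        assert np.array_equal(ds.fingerprints[:5], np.tile(tpl_a, (5, 1)))
        assert np.array_equal(ds.fingerprints[5:], np.tile(tpl_b, (5, 1)))

    def test_seed_reproducibility_and_flip_rate_bound(self):
        a = separable_fingerprint_dataset(20, 20, 0.1, seed=9)
        b = separable_fingerprint_dataset(20, 20, 0.1, seed=9)
        assert np.array_equal(a.fingerprints, b.fingerprints)
        with pytest.raises(FixtureError):
            separable_fingerprint_dataset(5, 5, 0.5)


class TestCrossValidation:
    def test_noisy_separable_set_classified_accurately(self):
        """Six-fold CV on the flip-rate-0.05 synthetic set: templates differ
        in dozens of bits while noise flips ~8, so accuracy must be high."""
        ds = separable_fingerprint_dataset(300, 300, flip_rate=0.05, seed=3)
        report = cross_validate(ds, MLPConfig(seed=1), k=6, seed=3)
        assert len(report.fold_metrics) == 6
        assert report.mean_metrics["accuracy"] >= 0.95

    def test_permuted_labels_give_chance_auc(self):
        ds = separable_fingerprint_dataset(300, 300, flip_rate=0.05, seed=3)
        rng = np.random.default_rng(17)
        ds.labels = rng.permutation(ds.labels)
        ds.provenance = ["active" if l == 1 else "inactive" for l in ds.labels]
        report = cross_validate(ds, MLPConfig(seed=1, max_iter=60), k=6, seed=3)
        assert report.mean_auc == pytest.approx(0.5, abs=0.07)

    def test_fold_assignment_is_a_partition(self):
        from sklearn.model_selection import StratifiedKFold

        ds = separable_fingerprint_dataset(30, 30, 0.1, seed=2)
        seen = []
        for _, test_idx in StratifiedKFold(6, shuffle=True, random_state=5).split(
                ds.fingerprints, ds.labels):
            seen.extend(test_idx.tolist())
        assert sorted(seen) == list(range(60))

    def test_class_smaller_than_fold_count_rejected(self):
        ds = separable_fingerprint_dataset(4, 30, 0.1, seed=2)
        with pytest.raises(DiscriminatorError):
            cross_validate(ds, MLPConfig(seed=1), k=6, seed=0)


@pytest.fixture(scope="module")
def fitted():
    ds = separable_fingerprint_dataset(150, 150, flip_rate=0.05, seed=5)
    return train_discriminator(ds, MLPConfig(seed=2, max_iter=200))


class TestPredictLikelihood:

    def test_scores_bounded_with_full_histogram(self, fitted, toy_corpus):
        scores, rejected, hist = predict_likelihood(fitted, toy_corpus[:20])
        assert rejected == []
        assert np.all((scores >= 0) & (scores <= 1))
        assert hist.sum() == 20

    def test_identical_molecules_identical_scores(self, fitted):
        scores, _, _ = predict_likelihood(fitted, ["CCO", "CCO"])
        assert scores[0] == scores[1]

    def test_row_order_invariance(self, fitted, toy_corpus):
        mols = toy_corpus[:15]
        a, _, _ = predict_likelihood(fitted, mols)
        b, _, _ = predict_likelihood(fitted, mols[::-1])
        assert np.allclose(a, b[::-1])

    def test_unparseable_molecule_flagged(self, fitted):
        scores, rejected, _ = predict_likelihood(fitted, ["CCO", "C("])
        assert len(scores) == 1
        assert rejected[0][0] == 1

    def test_trained_actives_separate_from_nonactives(self):
        ds = separable_fingerprint_dataset(150, 150, flip_rate=0.05, seed=5)
        clf = train_discriminator(ds, MLPConfig(seed=2, max_iter=200))
        scores = clf.predict_proba(ds.fingerprints.astype(float))[:, 1]
        assert scores[:150].mean() > scores[150:].mean()
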