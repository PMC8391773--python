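"""Classification, metrics and the backward-evaluation protocol."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afpredict import (
    ConfusionMatrix,
    EvalRecord,
    FeatureVector,
    MetricsReport,
    SynthConfig,
    backward_evaluate,
    cross_validate,
    generate_nsr_rr,
    metrics,
    predict,
    train,
)
from afpredict.classify import CLASSIFIER_KINDS


def blob_vectors(n_per_class=10, sep=6.0, seed=0, n_features=3):
    """Two well-separated Gaussian blobs -> trivially separable table."""
    rng = np.random.default_rng(seed)
    vecs = []
    for label, center in (("control", 0.0), ("pre-AF", sep)):
        for i in range(n_per_class):
            x = rng.normal(center, 1.0, n_features)
            vecs.append(
                FeatureVector(
                    segment_id=f"{label}{i}",
                    values={f"f{j}": float(v) for j, v in enumerate(x)},
                    label=label,
                )
            )
    return vecs


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics(ConfusionMatrix(tp=10, fn=0, fp=0, tn=10))
        assert (m.sen, m.spe, m.acc, m.ppv, m.npv) == (100, 100, 100, 100, 100)

    def test_svm_test_matrix(self):
        m = metrics(ConfusionMatrix(tp=20, fn=5, fp=0, tn=25))
        assert (m.sen, m.spe, m.acc, m.ppv, m.npv) == (80, 100, 90, 100, 83.33)

    def test_rf_test_matrix(self):
        m = metrics(ConfusionMatrix(tp=20, fn=5, fp=1, tn=24))
        assert (m.sen, m.spe, m.acc, m.ppv, m.npv) == (80, 96, 88, 95.24, 82.76)

    def test_undefined_sentinels(self):
        m = metrics(ConfusionMatrix(tp=0, fn=0, fp=0, tn=8))
        assert np.isnan(m.sen) and np.isnan(m.ppv)
        assert m.spe == 100 and m.acc == 100

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionMatrix())

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.tuples(*[st.integers(0, 50)] * 4))
    def test_matches_per_sample_recomputation(self, counts):
        """metrics() equals brute-force recomputation from label pairs."""
        tp, fn, fp, tn = counts
        if tp + fn + fp + tn == 0:
            return
        y_true = ["pre-AF"] * (tp + fn) + ["control"] * (fp + tn)
        y_pred = (
            ["pre-AF"] * tp + ["control"] * fn + ["pre-AF"] * fp + ["control"] * tn
        )
        cm = ConfusionMatrix.from_labels(y_true, y_pred)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (tp, fn, fp, tn)
        m = metrics(cm)
        pos = [i for i, t in enumerate(y_true) if t == "pre-AF"]
        if pos:
            sen = 100 * sum(y_pred[i] == "pre-AF" for i in pos) / len(pos)
            assert m.sen == pytest.approx(sen, abs=0.005)
        acc = 100 * sum(t == p for t, p in zip(y_true, y_pred)) / len(y_true)
        assert m.acc == pytest.approx(acc, abs=0.005)


class TestTrainPredict:
    @pytest.mark.parametrize("kind", ["svm_rbf", "rf"])
    def test_separable_training_is_perfect(self, kind):
        vecs = blob_vectors()
        model = train(vecs, kind=kind, seed=0)
        preds = predict(model, vecs)
        assert preds == [v.label for v in vecs]

    def test_determinism_same_seed(self):
        vecs = blob_vectors(sep=2.0, seed=1)
        held = blob_vectors(sep=2.0, seed=2)
        p1 = predict(train(vecs, kind="rf", seed=5), held)
        p2 = predict(train(vecs, kind="rf", seed=5), held)
        assert p1 == p2

    def test_rf_default_tree_count(self):
        model = train(blob_vectors(), kind="rf", seed=0)
        assert model.estimator.n_estimators == 50

    def test_single_class_rejected(self):
        vecs = [v for v in blob_vectors() if v.label == "control"]
        with pytest.raises(ValueError):
            train(vecs, kind="rf")

    def test_empty_predict(self):
        model = train(blob_vectors(), kind="rf", seed=0)
        assert predict(model, []) == []

    def test_nan_feature_rejected(self):
        model = train(blob_vectors(), kind="rf", seed=0)
        bad = FeatureVector("x", {"f0": np.nan, "f1": 0.0, "f2": 0.0})
        with pytest.raises(ValueError, match="non-finite"):
            predict(model, [bad])

    def test_schema_mismatch_rejected(self):
        model = train(blob_vectors(), kind="rf", seed=0)
        bad = FeatureVector("x", {"other": 1.0})
        with pytest.raises(ValueError, match="schema"):
            predict(model, [bad])

    @pytest.mark.parametrize(
        "kind", [k for k in CLASSIFIER_KINDS if k not in ("svm_rbf", "rf")]
    )
    def test_classifier_menu_fits_separable_data(self, kind):
        vecs = blob_vectors()
        model = train(vecs, kind=kind, seed=0)
        assert predict(model, vecs) == [v.label for v in vecs]


class TestCrossValidate:
    def test_separable_synthetic_cohort_accuracy(self):
        vecs = blob_vectors(n_per_class=25, sep=6.0)
        report, cm = cross_validate(vecs, kind="rf", k=5, seed=3)
        assert report.acc >= 90
        assert cm.total == 50  # every sample predicted exactly once

    def test_label_shuffle_null(self):
        vecs = blob_vectors(n_per_class=25, sep=6.0, seed=4)
        labels = [v.label for v in vecs]
        rng = np.random.default_rng(0)
        shuffled = list(labels)
        rng.shuffle(shuffled)
        null_vecs = [
            FeatureVector(v.segment_id, v.values, lab)
            for v, lab in zip(vecs, shuffled)
        ]
        report, _ = cross_validate(null_vecs, kind="rf", k=5, seed=3)
        assert 35 <= report.acc <= 65

    def test_k_exceeding_class_size_rejected(self):
        with pytest.raises(ValueError):
            cross_validate(blob_vectors(n_per_class=3), kind="rf", k=5)

    def test_loo_equals_manual_folding(self):
        """Leave-one-out on a 6-sample separable table == exhaustive folds."""
        vecs = blob_vectors(n_per_class=3, sep=8.0, seed=6)
        report, cm = cross_validate(vecs, kind="da_linear", k=3, seed=0)
        # manual: for each fold of the same splitter, train/test by hand
        from sklearn.model_selection import StratifiedKFold

        y = np.array([v.label for v in vecs])
        X = np.arange(len(vecs))
        manual = ConfusionMatrix()
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=0)
        for tr, te in skf.split(X[:, None], y):
            m = train([vecs[i] for i in tr], kind="da_linear", seed=0)
            preds = predict(m, [vecs[i] for i in te])
            part = ConfusionMatrix.from_labels(y[te], preds)
            manual.tp += part.tp
            manual.fn += part.fn
            manual.fp += part.fp
            manual.tn += part.tn
        assert vars(cm) == vars(manual)


@pytest.fixture(scope="module")
def trained():
    recs = [
        generate_nsr_rr(SynthConfig(seed=40 + i, pac_rate_per_min=rate))
        for rate, base in ((0.5, 0), (10.0, 8))
        for i in range(base, base + 8)
    ]
    labels = ["control"] * 8 + ["pre-AF"] * 8
    from afpredict import assemble_features

    vecs = [
        assemble_features(r.rr, "selected14", f"t{i}", lab)
        for i, (r, lab) in enumerate(zip(recs, labels))
    ]
    return train(vecs, kind="rf", seed=1)


class TestBackwardEvaluate:
    def test_offsets_and_degradation(self, trained):
        records = []
        for i in range(6):
            ctl = generate_nsr_rr(SynthConfig(
                duration_s=1220, pac_rate_per_min=0.5, seed=900 + i))
            records.append(EvalRecord(ctl.rr, 1210.0, "control", f"c{i}"))
            pre = generate_nsr_rr(SynthConfig(
                duration_s=1220, pac_rate_per_min=6.0, pac_ramp=8.0,
                seed=950 + i))
            records.append(EvalRecord(pre.rr, 1210.0, "pre-AF", f"p{i}"))
        results = backward_evaluate(records, trained)
        assert [r.offset_s for r in results] == [0.0, 150.0, 300.0, 450.0, 600.0]
        for r in results:
            assert r.cm.total == 12
            assert isinstance(r.report, MetricsReport)

    def test_short_records_excluded_with_count(self, trained):
        short = generate_nsr_rr(SynthConfig(duration_s=400, seed=1))
        long_c = generate_nsr_rr(SynthConfig(
            duration_s=1000, pac_rate_per_min=0.5, seed=2))
        long_p = generate_nsr_rr(SynthConfig(
            duration_s=1000, pac_rate_per_min=10.0, seed=3))
        records = [
            EvalRecord(short.rr, 390.0, "pre-AF", "short"),
            EvalRecord(long_c.rr, 990.0, "control", "c"),
            EvalRecord(long_p.rr, 990.0, "pre-AF", "p"),
        ]
        results = backward_evaluate(records, trained, offsets_s=(0.0, 600.0))
        assert results[0].n_excluded == 0
        assert results[1].n_excluded == 1
        assert results[1].excluded_ids == ["short"]
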