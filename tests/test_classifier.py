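"""Tests for the class-weighted linear SVM, CV, screening, tuning, scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orfsvm.classifier import (
    accuracy_from_sn_sp,
    confusion_from_scores,
    cross_validate,
    decision_scores,
    evaluate,
    grid_search,
    load_model,
    make_folds,
    predict_orfs,
    save_model,
    screen_combinations,
    threshold_sweep,
    train,
    train_on_sequences,
)
from orfsvm.features import ScalingModel, encode_matrix
from orfsvm.synthetic import gc_contrast_benchmark


def _strong_xy(strong_small, selection=(1, 2, 3, 5)):
    seqs = [s.sequence for s in strong_small.sequences]
    y = np.array([s.label for s in strong_small.sequences])
    ids = [s.seq_id for s in strong_small.sequences]
    return encode_matrix(seqs, selection), y, ids


class TestEvaluate:
    def test_degenerate_tables(self):
        perfect = evaluate(1, 0, 1, 0)
        assert (perfect.sn, perfect.sp, perfect.accuracy) == (100.0, 100.0, 100.0)
        skewed = evaluate(0, 1, 1, 0)
        assert (skewed.sn, skewed.sp, skewed.accuracy) == (0.0, 100.0, 50.0)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate(0, 0, 5, 5)
        with pytest.raises(ValueError):
            evaluate(5, 5, 0, 0)
        with pytest.raises(ValueError):
            evaluate(-1, 2, 3, 4)

    @settings(max_examples=100, deadline=None)
    @given(
        tp=st.integers(0, 10_000),
        fn=st.integers(0, 10_000),
        tn=st.integers(0, 10_000),
        fp=st.integers(0, 10_000),
    )
    def test_identities_hold_for_fuzzed_tables(self, tp, fn, tn, fp):
        if tp + fn == 0 or tn + fp == 0:
            return
        rep = evaluate(tp, fn, tn, fp)
        assert rep.sn == pytest.approx(100.0 * tp / (tp + fn))
        assert rep.sp == pytest.approx(100.0 * tn / (tn + fp))
        assert rep.accuracy == (rep.sn + rep.sp) / 2  # exact
        assert rep.accuracy == accuracy_from_sn_sp(rep.sn, rep.sp)


class TestTrain:
    def test_separable_1d(self):
        X = np.array([[0.0], [1.0]])
        y = [-1, 1]
        model = train(X, y, C=10.0, w_ratio=1.0)
        scores = decision_scores(model, X)
        assert scores[0] < 0 < scores[1]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            train(np.zeros((3, 2)), [1, 1, 1])

    def test_duplicated_dataset_same_boundary(self):
        rng = np.random.default_rng(0)
        X = rng.random((40, 3))
        y = np.where(X[:, 0] + 0.2 * rng.random(40) > 0.5, 1, -1)
        if len(set(y)) < 2:
            pytest.skip("degenerate draw")
        m1 = train(X, y, C=1.0)
        m2 = train(np.vstack([X, X]), np.concatenate([y, y]), C=0.5)
        # duplicating every sample while halving C keeps the objective, hence
        # the boundary, unchanged up to solver tolerance
        np.testing.assert_allclose(m1.weights, m2.weights, atol=5e-3)
        assert m1.bias == pytest.approx(m2.bias, abs=5e-3)

    def test_w_ratio_reduces_false_positives(self):
        rng = np.random.default_rng(1)
        n = 300
        X = np.vstack(
            [rng.normal(0.8, 1.0, (n, 2)), rng.normal(-0.2, 1.0, (n, 2))]
        )
        y = np.array([1] * n + [-1] * n)
        fp_equal = confusion_from_scores(decision_scores(train(X, y, w_ratio=1.0), X), y)[3]
        fp_heavy = confusion_from_scores(decision_scores(train(X, y, w_ratio=8.0), X), y)[3]
        assert fp_heavy <= fp_equal

    def test_agrees_with_independent_libsvm_oracle(self, strong_small):
        """Cross-check against libsvm's linear C-SVC as an external referee."""
        from sklearn.svm import SVC

        X, y, _ = _strong_xy(strong_small, selection=(1, 3))
        scaler = ScalingModel.fit(X)
        Xs = scaler.transform(X)
        model = train(Xs, y, C=2.0**-3.5, w_ratio=2.0**0.6)
        ours = decision_scores(model, Xs) > 0
        ref = SVC(kernel="linear", C=2.0**-3.5, class_weight={1: 1.0, -1: 2.0**0.6})
        ref.fit(Xs, y)
        agreement = np.mean(ours == (ref.decision_function(Xs) > 0))
        assert agreement >= 0.99


class TestDecisionScores:
    def test_zero_vector_scores_bias(self):
        X = np.array([[0.0, 1.0], [1.0, 0.0]])
        model = train(X, [-1, 1])
        assert decision_scores(model, np.zeros((1, 2)))[0] == pytest.approx(model.bias)

    def test_width_mismatch(self):
        model = train(np.array([[0.0], [1.0]]), [-1, 1])
        with pytest.raises(ValueError, match="width mismatch"):
            decision_scores(model, np.zeros((1, 3)))

    def test_bias_offset_shifts_scores_uniformly(self):
        X = np.random.default_rng(2).random((10, 2))
        model = train(np.array([[0.0, 0.0], [1.0, 1.0]]), [-1, 1])
        base = decision_scores(model, X)
        model.bias += 0.7
        np.testing.assert_allclose(decision_scores(model, X), base + 0.7)


class TestCrossValidation:
    def test_separated_classes_are_perfect(self, strong_small):
        X, y, ids = _strong_xy(strong_small)
        rep = cross_validate(X, y, k=5, seed=0, ids=ids)
        assert rep.sn == 100.0 and rep.sp == 100.0
        assert rep.sn_std == 0.0 and rep.sp_std == 0.0
        assert rep.misclassified_positives == ()

    def test_fixed_seed_is_bit_reproducible(self, strong_small):
        X, y, _ = _strong_xy(strong_small, selection=(1,))
        r1 = cross_validate(X, y, k=5, seed=42)
        r2 = cross_validate(X, y, k=5, seed=42)
        assert (r1.tp, r1.fn, r1.tn, r1.fp) == (r2.tp, r2.fn, r2.tn, r2.fp)
        assert r1.sn_folds == r2.sn_folds and r1.sp_folds == r2.sp_folds

    def test_leave_one_out_boundary(self):
        X = np.array([[0.0], [0.1], [0.9], [1.0]])
        y = [-1, -1, 1, 1]
        rep = cross_validate(X, y, k=4, C=10.0, w_ratio=1.0, seed=0)
        assert rep.tp + rep.fn == 2 and rep.tn + rep.fp == 2
        assert rep.accuracy == 100.0

    def test_misclassified_positive_ids_reported(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0.3, 1, (50, 1)), rng.normal(-0.3, 1, (50, 1))])
        y = np.array([1] * 50 + [-1] * 50)
        ids = [f"s{i}" for i in range(100)]
        rep = cross_validate(X, y, k=5, seed=0, ids=ids)
        assert len(rep.misclassified_positives) == rep.fn
        assert all(i.startswith("s") and int(i[1:]) < 50 for i in rep.misclassified_positives)

    def test_needs_both_classes(self):
        with pytest.raises(ValueError):
            make_folds(np.ones(10, dtype=int), 2, 0)


class TestScreen:
    def test_63_rows_ordered_by_subset_size(self, strong_small):
        X, y, _ = _strong_xy(strong_small, selection=(1, 2, 3, 4, 5, 6))
        rows = screen_combinations(X, y, k=3, seed=0)
        combos = [c for c, _ in rows]
        assert len(combos) == 63
        assert combos[:6] == [(1,), (2,), (3,), (4,), (5,), (6,)]
        assert combos[-1] == (1, 2, 3, 4, 5, 6)
        sizes = [len(c) for c in combos]
        assert sizes == sorted(sizes)
        assert len(set(combos)) == 63

    def test_rejects_partial_matrix(self):
        with pytest.raises(ValueError, match="full six-block"):
            screen_combinations(np.zeros((4, 64)), [1, 1, -1, -1], k=2)


class TestGridSearch:
    def test_single_cell_is_best(self, strong_small):
        X, y, _ = _strong_xy(strong_small, selection=(1,))
        res = grid_search(X, y, log2C_grid=[-3.5], log2w_grid=[0.6], k=3, seed=0)
        assert res.best_log2C == -3.5 and res.best_log2w == 0.6
        assert res.best_C == pytest.approx(2.0**-3.5)

    def test_duplicated_column_identical_accuracies(self, strong_small):
        X, y, _ = _strong_xy(strong_small, selection=(1,))
        res = grid_search(X, y, log2C_grid=[0.0, 0.0], log2w_grid=[0.0], k=3, seed=1)
        assert res.accuracy[0, 0] == res.accuracy[1, 0]

    def test_tie_breaks_prefer_small_C_then_small_weight(self, strong_small):
        # perfectly separable data ties every cell at 100%
        X, y, _ = _strong_xy(strong_small)
        res = grid_search(X, y, log2C_grid=[2.0, -1.0], log2w_grid=[1.0, 0.0], k=3, seed=0)
        assert np.all(res.accuracy == 100.0)
        assert res.best_log2C == -1.0 and res.best_log2w == 0.0

    def test_empty_grid_rejected(self, strong_small):
        X, y, _ = _strong_xy(strong_small, selection=(1,))
        with pytest.raises(ValueError, match="non-empty"):
            grid_search(X, y, log2C_grid=[], k=3)


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(4)
    X = np.vstack([rng.normal(0.5, 1, (200, 2)), rng.normal(-0.5, 1, (200, 2))])
    y = np.array([1] * 200 + [-1] * 200)
    scaler = ScalingModel.fit(X)
    Xs = scaler.transform(X)
    return train(Xs, y), Xs, y


class TestThresholdSweep:
    def test_zero_offset_reproduces_model_confusion(self, fitted):
        model, X, y = fitted
        _, sn, sp = threshold_sweep(model, X, y, [0.0])[0]
        tp, fn, tn, fp = confusion_from_scores(decision_scores(model, X), y)
        assert sn == pytest.approx(100.0 * tp / (tp + fn))
        assert sp == pytest.approx(100.0 * tn / (tn + fp))

    def test_large_negative_offset_gives_full_sensitivity(self, fitted):
        model, X, y = fitted
        _, sn, sp = threshold_sweep(model, X, y, [-1e6])[0]
        assert sn == 100.0 and sp == 0.0

    def test_monotone_over_41_point_sweep(self, fitted):
        model, X, y = fitted
        sweep = threshold_sweep(model, X, y, np.linspace(-2, 2, 41))
        sns = [sn for _, sn, _ in sweep]
        sps = [sp for _, _, sp in sweep]
        assert all(a >= b for a, b in zip(sns, sns[1:]))  # Sn non-increasing
        assert all(a <= b for a, b in zip(sps, sps[1:]))  # Sp non-decreasing

    def test_nonfinite_offset_rejected(self, fitted):
        model, X, y = fitted
        with pytest.raises(ValueError, match="finite"):
            threshold_sweep(model, X, y, [float("inf")])


@pytest.fixture(scope="module")
def model(strong_small):
    seqs = [s.sequence for s in strong_small.sequences]
    y = [s.label for s in strong_small.sequences]
    return train_on_sequences(seqs, y, selection=(1, 2, 3, 5))


class TestPredictOrfs:
    def test_resubstitution_recovers_positives(self, strong_small, model):
        preds = predict_orfs(
            model, [(s.seq_id, s.sequence) for s in strong_small.positives]
        )
        coding = sum(p.label == "coding" for p in preds)
        assert coding / len(preds) >= 0.99

    def test_empty_input(self, model):
        assert predict_orfs(model, []) == []

    def test_deterministic(self, strong_small, model):
        pairs = [(s.seq_id, s.sequence) for s in strong_small.sequences[:10]]
        assert predict_orfs(model, pairs) == predict_orfs(model, pairs)

    def test_short_sequence_flagged_unscorable(self, model):
        preds = predict_orfs(model, [("tiny", "AT"), ("ok", "ATGGCTTAA")])
        assert preds[0].label == "unscorable" and preds[0].score is None
        assert preds[1].label in ("coding", "noncoding")


class TestPersistence:
    def test_round_trip_reproduces_scores(self, tmp_path, strong_small):
        seqs = [s.sequence for s in strong_small.sequences]
        y = [s.label for s in strong_small.sequences]
        model = train_on_sequences(seqs, y, selection=(1, 3))
        path = tmp_path / "model.json"
        save_model(model, path)
        reloaded = load_model(path)
        X = encode_matrix(seqs[:20], (1, 3))
        s1 = decision_scores(model, model.scaler.transform(X))
        s2 = decision_scores(reloaded, reloaded.scaler.transform(X))
        np.testing.assert_allclose(s1, s2, atol=1e-10)
        assert reloaded.selection == (1, 3)

    def test_feature_version_guard(self, tmp_path):
        import json

        path = tmp_path / "model.json"
        path.write_text(json.dumps({"format": "orfsvm-model-1", "feature_order": "other"}))
        with pytest.raises(ValueError, match="feature ordering"):
            load_model(path)


def test_parameter_recovery_near_bayes_floor():
    """CV accuracy tracks the analytic Bayes accuracy of a GC-contrast task.

    Two i.i.d. base models differing only in GC content admit an exact
    likelihood-ratio classifier; with the default GC gap and lengths its
    accuracy is ~97%.  The SVM on positional base frequencies must come
    within 3 percentage points across seeds.
    """
    from orfsvm.synthetic import NoncodingModel

    code = {b: i for i, b in enumerate("ACGT")}
    for seed in (1, 2, 3):
        bm = gc_contrast_benchmark(700, 700, seed=seed)
        lp = np.log(NoncodingModel(gc=bm.params["gc_pos"]).base_probs)
        lq = np.log(NoncodingModel(gc=bm.params["gc_neg"]).base_probs)
        correct = 0
        for s in bm.sequences:
            idx = np.array([code[b] for b in s.sequence])
            correct += (1 if (lp[idx] - lq[idx]).sum() > 0 else -1) == s.label
        bayes = 100.0 * correct / len(bm.sequences)
        X = encode_matrix([s.sequence for s in bm.sequences], (1,))
        rep = cross_validate(X, [s.label for s in bm.sequences], k=10, seed=seed)
        assert abs(rep.accuracy - bayes) <= 3.0
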