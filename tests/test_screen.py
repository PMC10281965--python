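import numpy as np
import pandas as pd
import pytest

from pentrace.screen import (ModelSpec, assemble_matrix, auc, best_threshold,
                             enumerate_models, loocv_scores, roc_curve,
                             tune_hyperparameters, _fold_standardize)


def _blobs(n_per=10, sep=5.0, dims=2, seed=0):
    rng = np.random.default_rng(seed)
    neg = rng.standard_normal((n_per, dims))
    pos = rng.standard_normal((n_per, dims)) + sep
    x = np.vstack([neg, pos])
    y = np.array([0] * n_per + [1] * n_per)
    return x, y


def _features_frame(participants):
    rows = []
    for pid, group, shapes in participants:
        for shape in shapes:
            rows.append({"participant_id": pid, "group": group,
                         "shape": shape, "DT": 5.0 + len(pid), "AP": 1.5,
                         "SP": -50.0 - len(shape)})
    return pd.DataFrame(rows)


class TestEnumerate:
    def test_three_shapes_make_seven_models(self):
        models = enumerate_models({"spiral", "square", "triangular"})
        assert len(models) == 7
        names = [m.name for m in models]
        assert names == ["spiral", "square", "triangular",
                         "spiral+square", "spiral+triangular",
                         "square+triangular", "spiral+square+triangular"]

    def test_single_shape(self):
        assert [m.name for m in enumerate_models({"triangular"})] == \
            ["triangular"]

    def test_two_shapes_make_three_models(self):
        assert len(enumerate_models({"square", "spiral"})) == 3

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            enumerate_models(set())


class TestAssemble:
    def test_full_cohort_matrix_shapes(self, default_features):
        x, y, ids = assemble_matrix(default_features,
                                    ModelSpec(("triangular",)))
        assert x.shape == (104, 3)
        assert y.sum() == 38
        x9, _, _ = assemble_matrix(
            default_features, ModelSpec(("spiral", "square", "triangular")))
        assert x9.shape == (104, 9)

    def test_incomplete_participant_dropped(self):
        frame = _features_frame([
            ("A", "nonCM", ["spiral", "square"]),
            ("B", "CM", ["square"]),
            ("C", "nonCM", ["spiral", "square"]),
            ("D", "CM", ["spiral", "square"]),
        ])
        x, y, ids = assemble_matrix(frame, ModelSpec(("spiral",)))
        assert set(ids) == {"A", "C", "D"}
        assert x.shape == (3, 3)

    def test_column_order_is_shape_major(self, default_features):
        model = ModelSpec(("square", "triangular"))
        x, _, ids = assemble_matrix(default_features, model)
        row = default_features.query(
            "participant_id == @ids[0] and shape == 'square'").iloc[0]
        np.testing.assert_allclose(x[0, :3],
                                   [row["DT"], row["AP"], row["SP"]])


class TestLoocv:
    def test_separable_blobs_all_sign_correct(self):
        x, y = _blobs(n_per=10, sep=5.0)
        scores = loocv_scores(x, y, {"kernel": "rbf", "C": 10.0})
        assert ((scores > 0) == (y == 1)).all()

    def test_label_permutation_gives_chance_auc(self):
        x, y = _blobs(n_per=10, sep=5.0)
        rng = np.random.default_rng(7)
        yp = rng.permutation(y)
        while (yp == y).all():
            yp = rng.permutation(y)
        scores = loocv_scores(x, yp, {"kernel": "rbf", "C": 10.0})
        fpr, tpr, _ = roc_curve(scores, yp)
        assert 0.2 <= auc(fpr, tpr) <= 0.8

    def test_duplicated_columns_leave_linear_roc_unchanged(self):
        x, y = _blobs(n_per=10, sep=3.0, seed=3)
        s1 = loocv_scores(x, y, {"kernel": "linear", "C": 10.0})
        s2 = loocv_scores(np.hstack([x, x]), y,
                          {"kernel": "linear", "C": 10.0})
        f1, t1, _ = roc_curve(s1, y)
        f2, t2, _ = roc_curve(s2, y)
        np.testing.assert_allclose(f1, f2)
        np.testing.assert_allclose(t1, t2)

    def test_outlier_does_not_shift_its_own_fold_scaling(self):
        """Leakage guard: the scaler for fold i must come from the other
        rows only, so an extreme held-out row stays extreme."""
        x = np.vstack([np.zeros((5, 2)), np.ones((5, 2)),
                       [[1000.0, 1000.0]]])
        train, test = _fold_standardize(x[:-1], x[[-1]])
        # scaling from the 10 inlier rows: mean 0.5, sd 0.5
        np.testing.assert_allclose(test, [[1999.0, 1999.0]])

    def test_single_class_fold_rejected(self):
        x = np.arange(6, dtype=float).reshape(3, 2)
        y = np.array([1, 0, 0])
        with pytest.raises(ValueError):
            loocv_scores(x, y)  # removing the lone positive leaves 1 class


class TestRoc:
    def test_perfect_separation_hits_corner(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [0, 0, 1, 1]
        fpr, tpr, _ = roc_curve(scores, labels)
        assert any((f == 0 and t == 1) for f, t in zip(fpr, tpr))
        assert auc(fpr, tpr) == pytest.approx(1.0)

    def test_all_tied_scores_are_diagonal(self):
        fpr, tpr, _ = roc_curve([0.5] * 6, [0, 1, 0, 1, 0, 1])
        np.testing.assert_allclose(fpr, [0, 1])
        np.testing.assert_allclose(tpr, [0, 1])
        assert auc(fpr, tpr) == pytest.approx(0.5)

    def test_four_score_example_matches_exhaustive_enumeration(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 0, 1, 1])
        fpr, tpr, thr = roc_curve(scores, labels)
        # brute force: sweep every threshold between consecutive scores
        expected = {(0.0, 0.0)}
        for cut in [0.9, 0.6, 0.375, 0.225, 0.0]:
            pred = scores >= cut
            tp = (pred & (labels == 1)).sum() / 2
            fp = (pred & (labels == 0)).sum() / 2
            expected.add((fp, tp))
        assert set(zip(fpr, tpr)) == expected
        assert auc(fpr, tpr) == pytest.approx(0.75)

    def test_auc_monotone_boundaries(self, default_features):
        from pentrace.screen import assemble_matrix
        x, y, _ = assemble_matrix(default_features, ModelSpec(("spiral",)))
        scores = loocv_scores(x, y, {"kernel": "rbf", "C": 1.0})
        fpr, tpr, _ = roc_curve(scores, y)
        assert fpr[0] == 0 and tpr[0] == 0
        assert fpr[-1] == 1 and tpr[-1] == 1
        assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()

    def test_auc_equals_rank_statistic(self, rng):
        """Dual route: trapezoidal ROC area equals the tie-corrected
        Mann-Whitney statistic scaled by n1*n2."""
        scores = np.round(rng.standard_normal(60), 1)  # induce ties
        labels = (rng.uniform(size=60) < 0.4).astype(int)
        fpr, tpr, _ = roc_curve(scores, labels)
        from scipy.stats import rankdata
        r = rankdata(scores)
        n1, n0 = labels.sum(), (1 - labels).sum()
        u_pos = r[labels == 1].sum() - n1 * (n1 + 1) / 2
        assert auc(fpr, tpr) == pytest.approx(u_pos / (n1 * n0),
                                              abs=1e-12)


class TestThreshold:
    def test_perfect_vertex_selected(self):
        fpr = np.array([0.0, 0.0, 1.0])
        tpr = np.array([0.0, 1.0, 1.0])
        thr = np.array([np.inf, 0.5, 0.1])
        t, sens, spec = best_threshold(fpr, tpr, thr)
        assert (t, sens, spec) == (0.5, 1.0, 1.0)

    def test_toy_roc_upper_left_vertex(self):
        fpr = np.array([0.0, 0.2, 0.24, 0.6, 1.0])
        tpr = np.array([0.0, 0.6, 0.76, 0.9, 1.0])
        thr = np.array([np.inf, 4.0, 3.0, 2.0, 1.0])
        t, sens, spec = best_threshold(fpr, tpr, thr)
        assert t == 3.0
        assert sens == pytest.approx(0.76)
        assert spec == pytest.approx(0.76)
        # exhaustive check of the distance rule
        d = np.hypot(fpr, 1 - tpr)
        assert d[2] == d.min()

    def test_diagonal_tie_resolves_to_higher_sensitivity(self):
        fpr = np.array([0.0, 1.0])
        tpr = np.array([0.0, 1.0])
        thr = np.array([np.inf, 0.0])
        t, sens, spec = best_threshold(fpr, tpr, thr)
        assert sens == 1.0 and spec == 0.0


class TestTuning:
    def test_single_grid_point_returned_unchanged(self):
        x, y = _blobs(n_per=8, sep=4.0)
        res = tune_hyperparameters(x, y, c_grid=[3.0])
        assert res.hyperparams["C"] == 3.0

    def test_separable_data_reaches_perfect_operating_point(self):
        x, y = _blobs(n_per=10, sep=5.0)
        res = tune_hyperparameters(x, y, mode="paper_faithful")
        assert res.sensitivity == 1.0
        assert res.specificity == 1.0

    def test_paper_faithful_objective_at_least_nested(self):
        x, y = _blobs(n_per=12, sep=1.0, seed=5)
        faithful = tune_hyperparameters(x, y, mode="paper_faithful")
        nested = tune_hyperparameters(x, y, mode="nested")
        assert (faithful.sensitivity + faithful.specificity
                >= nested.sensitivity + nested.specificity - 1e-12)
        assert faithful.mode == "paper_faithful"
        assert nested.mode == "nested"
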