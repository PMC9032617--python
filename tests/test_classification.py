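import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import betainc

from oilnmr.classification import (
    ConfusionCounts,
    PrincipalComponents,
    SimcaClassifier,
    UnitVarianceScaler,
    auc_from_scores,
    classification_metrics,
    confusion_from_labels,
    detect_outliers,
    fit_pca,
    fit_simca_class,
    fit_uv_scaler,
    overall_accuracy,
    q2_cross_validation,
    roc_auc,
    simca_classify,
)
from oilnmr.relaxometry import FEATURE_COLUMNS, features_table
from oilnmr.synthetic_oils import default_oil_library, simulate_cpmg


class TestUnitVarianceScaler:
    def test_training_columns_centred_and_scaled(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5, 3, size=(40, 6))
        Xs = fit_uv_scaler(X).transform(X)
        np.testing.assert_allclose(Xs.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(Xs.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_inverse_round_trip(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 4))
        scaler = fit_uv_scaler(X)
        np.testing.assert_allclose(scaler.inverse_transform(scaler.transform(X)), X, atol=1e-10)

    def test_two_point_column_scales_to_plus_minus_inv_sqrt2(self):
        # sd with the n-1 denominator: {0, 2} -> mean 1, sd sqrt(2)
        X = np.array([[0.0], [2.0]])
        Xs = fit_uv_scaler(X).transform(X)
        np.testing.assert_allclose(Xs.ravel(), [-1 / np.sqrt(2), 1 / np.sqrt(2)], atol=1e-12)

    def test_constant_column_rejected_by_name(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [7.0, 7.0, 7.0]})
        with pytest.raises(ValueError, match="flat"):
            fit_uv_scaler(df)


class TestPca:
    def test_rank_one_data_fully_explained_by_one_component(self):
        rng = np.random.default_rng(2)
        X = np.outer(rng.normal(size=30), rng.normal(size=5))
        model = fit_pca(X, 1)
        assert model.r2x_ == pytest.approx(1.0, abs=1e-10)

    def test_isotropic_noise_has_roughly_equal_shares(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(4000, 4))
        X -= X.mean(axis=0)
        model = fit_pca(X, 4)
        assert np.all(np.abs(model.explained_variance_ratio_ - 0.25) < 0.03)

    def test_eigenvalues_match_characteristic_polynomial_roots(self):
        # 5x3 hand table; oracle: roots of the cubic characteristic polynomial
        # of the 3x3 covariance matrix of the scaled data
        X = np.array([[1.0, 2.0, 0.5],
                      [2.0, 1.5, 1.0],
                      [3.0, 4.0, 1.5],
                      [4.0, 3.5, 2.5],
                      [5.0, 5.5, 2.0]])
        Xs = fit_uv_scaler(X).transform(X)
        C = Xs.T @ Xs / (X.shape[0] - 1)
        c2 = -np.trace(C)
        minors = (C[0, 0] * C[1, 1] - C[0, 1] ** 2
                  + C[0, 0] * C[2, 2] - C[0, 2] ** 2
                  + C[1, 1] * C[2, 2] - C[1, 2] ** 2)
        c0 = -np.linalg.det(C)
        roots = np.sort(np.roots([1.0, c2, minors, c0]).real)[::-1]
        model = fit_pca(Xs, 3)
        eig = (model.scores_**2).sum(axis=0) / (X.shape[0] - 1)
        np.testing.assert_allclose(np.sort(eig)[::-1], roots, atol=1e-10)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 6))
        model = fit_pca(X, 4)
        np.testing.assert_allclose(model.loadings_.T @ model.loadings_, np.eye(4), atol=1e-8)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(np.random.default_rng(0).normal(size=(5, 3)), 5)


class TestQ2:
    def test_rank_one_noiseless_is_predictable(self):
        rng = np.random.default_rng(0)
        X = np.outer(rng.normal(size=20), rng.normal(size=5))
        assert q2_cross_validation(X, 1) > 0.99

    def test_pure_noise_is_not_predictable(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 6))
        assert q2_cross_validation(X, 1) <= 0.0

    def test_matches_literal_deletion_loop(self):
        # independent bookkeeping oracle: same deletion scheme written as an
        # explicit cell-by-cell loop
        from oilnmr.classification import _nipals_loadings_missing

        rng = np.random.default_rng(11)
        X = rng.normal(size=(20, 5)) + np.outer(rng.normal(size=20), rng.normal(size=5))
        folds, A = 7, 2
        press, ss = 0.0, 0.0
        for i in range(20):
            for j in range(5):
                ss += X[i, j] ** 2
        for f in range(folds):
            mask = np.zeros_like(X, dtype=bool)
            for i in range(20):
                for j in range(5):
                    if (i + j) % folds == f:
                        mask[i, j] = True
            P = _nipals_loadings_missing(X, mask, A)
            for i in range(20):
                obs = ~mask[i]
                t_i, *_ = np.linalg.lstsq(P[obs], X[i, obs], rcond=0.15)
                for j in range(5):
                    if mask[i, j]:
                        press += (X[i, j] - P[j] @ t_i) ** 2
        expected = 1.0 - press / ss
        assert q2_cross_validation(X, A, folds=folds) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_folds_rejected(self):
        with pytest.raises(ValueError):
            q2_cross_validation(np.eye(4), 1, folds=1)


def _f_quantile_by_bisection(p, d1, d2):
    """0.95-quantile of F(d1, d2) via bisection on the regularized
    incomplete beta representation of the F CDF."""
    def cdf(x):
        return betainc(d1 / 2, d2 / 2, d1 * x / (d1 * x + d2))

    lo, hi = 0.0, 1e6
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if cdf(mid) < p:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@pytest.fixture(scope="module")
def class_table():
    rng = np.random.default_rng(21)
    latent = rng.normal(size=(40, 3)) @ rng.normal(size=(3, 8))
    return latent + 0.05 * rng.normal(size=(40, 8))


class TestSimcaClassModel:

    def test_mean_squared_training_dmodx_is_one(self, class_table):
        model = fit_simca_class(class_table, n_components=3, label="c")
        assert np.mean(model.training_dmodx**2) == pytest.approx(1.0, rel=0.10)

    def test_far_point_has_large_dmodx(self, class_table):
        model = fit_simca_class(class_table, n_components=3, label="c")
        far = class_table[:1] + 50.0
        assert model.dmodx(far)[0] > 10 * model.dcrit

    def test_dcrit_matches_bisection_quantile_oracle(self):
        rng = np.random.default_rng(5)
        # construct a class with K-A = 10 and denominator df = 100:
        # K = 17, A = 7 -> need (N-8) * 10 = 100 -> N = 18
        X = rng.normal(size=(18, 17)) + rng.normal(size=(1, 17))
        model = fit_simca_class(X, n_components=7, label="c")
        expected = np.sqrt(_f_quantile_by_bisection(0.95, 10, 100))
        assert model.dcrit == pytest.approx(expected, abs=1e-6)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_simca_class(np.random.default_rng(0).normal(size=(4, 6)),
                            n_components=3, label="tiny")

    def test_outlier_detection(self, class_table):
        model = fit_simca_class(class_table, n_components=3, label="c")
        # training set of a well-specified class: few flags at alpha = 0.05
        assert detect_outliers(model).mean() <= 0.10
        # empty table -> empty flags
        assert detect_outliers(model, class_table[:0]).size == 0
        # gross contaminant -> flagged
        contaminated = class_table[:1] + 10 * class_table.std()
        assert detect_outliers(model, contaminated)[0]

    def test_row_permutation_does_not_change_model(self, class_table):
        rng = np.random.default_rng(9)
        perm = rng.permutation(len(class_table))
        m1 = fit_simca_class(class_table, n_components=3, label="c")
        m2 = fit_simca_class(class_table[perm], n_components=3, label="c")
        assert m1.s0 == pytest.approx(m2.s0, abs=1e-10)
        probe = class_table[:5] + 0.3
        np.testing.assert_allclose(m1.dmodx(probe), m2.dmodx(probe), atol=1e-10)


class TestSimcaClassification:
    def test_sample_at_centroid_is_accepted_by_its_class(self):
        rng = np.random.default_rng(31)
        X = rng.normal(size=(30, 6)) * [1, 1, 1, 2, 2, 2]
        model = fit_simca_class(X, n_components=2, label="c")
        detail = simca_classify([model], X.mean(axis=0, keepdims=True))
        assert detail["accepted_by"].iloc[0] == ["c"]

    def test_forced_assignment_flagged_when_all_reject(self):
        rng = np.random.default_rng(32)
        models = []
        for label, shift in (("a", 0.0), ("b", 30.0)):
            X = rng.normal(size=(25, 5)) + shift
            models.append(fit_simca_class(X, n_components=2, label=label))
        probe = np.full((1, 5), 15.0)  # between the classes, far from both
        detail = simca_classify(models, probe)
        assert detail["forced"].iloc[0]
        assert detail["assigned"].iloc[0] in {"a", "b"}

    def test_well_separated_pure_oils_classified_correctly(self, oil_library):
        """Four clearly distinct pure-oil classes: single-label accuracy on
        held-out replicates must exceed 95 %."""
        train_rows, train_labels, test_rows, test_labels = [], [], [], []
        oils = ["AO-1", "SO", "CO", "RO"]
        for name in oils:
            decays = [simulate_cpmg(oil_library[name], snr=2000, seed=1000 + 97 * i + hash(name) % 50)
                      for i in range(20)]
            feats = features_table(decays)[FEATURE_COLUMNS]
            train_rows.append(feats.iloc[:10])
            test_rows.append(feats.iloc[10:])
            train_labels += [name] * 10
            test_labels += [name] * 10
        clf = SimcaClassifier(n_components=3)
        clf.fit(pd.concat(train_rows), train_labels)
        acc = overall_accuracy(test_labels, clf.predict(pd.concat(test_rows)))
        assert acc >= 0.95

    def test_priority_class_wins_when_accepted(self):
        rng = np.random.default_rng(33)
        a = rng.normal(size=(25, 5))
        b = rng.normal(size=(25, 5)) * 3.0  # broader class enclosing a
        ma = fit_simca_class(a, n_components=2, label="a")
        mb = fit_simca_class(b, n_components=2, label="b")
        probe = a[:5]
        with_priority = simca_classify([ma, mb], probe, priority="a")
        assert (with_priority["assigned"] == "a").all()
        with pytest.raises(ValueError):
            simca_classify([ma, mb], probe, priority="missing")


class TestMetrics:
    def test_tpr_of_14_in_15(self):
        m = classification_metrics(ConfusionCounts(tp=14, fp=0, tn=0, fn=1))
        assert round(m.tpr, 2) == 0.93

    def test_overall_accuracy_of_study_counts(self):
        # per-class correct counts (14, 41, 42, 41) of (15, 42, 42, 42)
        y_true, y_pred = [], []
        for cls, n, correct in (("AO", 15, 14), ("SO", 42, 41), ("CO", 42, 42), ("RO", 42, 41)):
            y_true += [cls] * n
            y_pred += [cls] * correct + ["other"] * (n - correct)
        assert round(100 * overall_accuracy(y_true, y_pred), 2) == 97.87

    def test_no_false_positives_gives_ppv_one_fdr_zero(self):
        m = classification_metrics(ConfusionCounts(tp=9, fp=0, tn=20, fn=1))
        assert m.ppv == 1.0 and m.fdr == 0.0

    def test_undefined_metrics_are_none_not_zero(self):
        m = classification_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert m.tpr is None and m.ppv is None

    @given(tp=st.integers(0, 50), fp=st.integers(0, 50),
           tn=st.integers(0, 50), fn=st.integers(0, 50))
    @settings(max_examples=100, deadline=None)
    def test_complementarity_whenever_defined(self, tp, fp, tn, fn):
        m = classification_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        if m.tpr is not None:
            assert m.tpr + m.fnr == pytest.approx(1.0)
        if m.ppv is not None:
            assert m.ppv + m.fdr == pytest.approx(1.0)

    def test_confusion_from_labels_tallies(self):
        y_true = ["a", "a", "b", "b", "b"]
        y_pred = ["a", "b", "b", "b", "a"]
        counts = confusion_from_labels(y_true, y_pred)
        assert counts["a"] == ConfusionCounts(tp=1, fp=1, tn=2, fn=1)
        assert counts["b"] == ConfusionCounts(tp=2, fp=1, tn=1, fn=1)


class TestRocAuc:
    def test_perfect_separation(self):
        assert auc_from_scores(np.array([1.0, 2.0]), np.array([5.0, 6.0])) == 1.0

    def test_identical_distributions_give_half(self):
        s = np.array([1.0, 2.0, 3.0])
        assert auc_from_scores(s, s) == pytest.approx(0.5)

    def test_matches_exhaustive_pair_enumeration(self):
        rng = np.random.default_rng(13)
        d_in = rng.normal(0, 1, size=10)
        d_out = rng.normal(1, 1, size=10)
        concordant = sum((a < b) + 0.5 * (a == b) for a in d_in for b in d_out)
        assert auc_from_scores(d_in, d_out) == pytest.approx(concordant / 100.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(14)
        X_in = rng.normal(size=(30, 5))
        X_out = rng.normal(size=(15, 5)) + 2.0
        model = fit_simca_class(X_in, n_components=2, label="c")
        base = roc_auc(model, X_in, X_out)
        d_in, d_out = model.dmodx(X_in), model.dmodx(X_out)
        transformed = auc_from_scores(np.exp(3 * d_in) + 1, np.exp(3 * d_out) + 1)
        assert transformed == pytest.approx(base, abs=1e-12)
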