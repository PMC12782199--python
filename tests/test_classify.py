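import numpy as np
import pandas as pd
import pytest

from ssvepipe.classify import (
    ClassifierConfig,
    feature_subset,
    fit_elastic_net_cv,
    make_folds,
    performance,
    predictor_columns,
    roc_auc,
)
from ssvepipe.features import feature_columns


def _table_from_X(X, y, subjects=None):
    df = pd.DataFrame(X, columns=[f"f{i}_rc1_h1_rho" for i in range(X.shape[1])])
    df.insert(0, "subject_id", subjects if subjects is not None else [f"S{i}" for i in range(len(y))])
    df.insert(1, "eye", "OD")
    df.insert(2, "label", y)
    return df


def _paired_table(n_subjects, n_features, rng, effect=0.0):
    rows = []
    for i in range(n_subjects):
        label = i % 2
        base = rng.normal(size=n_features)
        for eye in ("OD", "OS"):
            rows.append({"subject_id": f"S{i}", "eye": eye, "label": label,
                         **{f"f{j}_rc1_h1_rho": base[j] + effect * label + 0.3 * rng.normal()
                            for j in range(n_features)}})
    return pd.DataFrame(rows)


class TestFolds:
    def test_grouped_keeps_eyes_together(self):
        rng = np.random.default_rng(0)
        table = _paired_table(20, 2, rng)
        scheme = make_folds(table, k=10, grouped=True, seed=1)
        assert scheme.assignment.shape == (40,)
        for sid, grp in table.groupby("subject_id"):
            assert len(set(scheme.assignment[grp.index])) == 1

    def test_ungrouped_splits_some_subject(self):
        rng = np.random.default_rng(1)
        table = _paired_table(20, 2, rng)
        split = False
        for seed in range(10):
            scheme = make_folds(table, k=10, grouped=False, seed=seed)
            for sid, grp in table.groupby("subject_id"):
                if len(set(scheme.assignment[grp.index])) > 1:
                    split = True
        assert split

    def test_deterministic(self):
        table = _paired_table(12, 2, np.random.default_rng(2))
        a = make_folds(table, k=5, grouped=True, seed=9).assignment
        b = make_folds(table, k=5, grouped=True, seed=9).assignment
        np.testing.assert_array_equal(a, b)

    def test_more_folds_than_groups_rejected(self):
        table = _paired_table(5, 2, np.random.default_rng(3))
        with pytest.raises(ValueError):
            make_folds(table, k=6, grouped=True, seed=0)


@pytest.fixture(scope="module")
def table():
    cols = feature_columns()
    rng = np.random.default_rng(4)
    df = pd.DataFrame(rng.normal(size=(12, len(cols))), columns=cols)
    df.insert(0, "subject_id", [f"S{i // 2}" for i in range(12)])
    df.insert(1, "eye", ["OD", "OS"] * 6)
    df.insert(2, "label", [0, 0, 1, 1] * 3)
    df["age"] = 60.0
    df["sex_M"] = 0
    df["sex_unknown"] = 0
    return df


class TestFeatureSubset:
    def test_full_set_has_144(self, table):
        sub = feature_subset(table, "both", "both", include_demographics=False)
        assert len(predictor_columns(sub)) == 144

    def test_on_amplitude_24(self, table):
        sub = feature_subset(table, "ON", "amplitude", include_demographics=False)
        cols = predictor_columns(sub)
        assert len(cols) == 24  # 6 RCs × 4 harmonics
        assert all(c.startswith("ON_") and c.endswith("_rho") for c in cols)

    def test_off_phase_48(self, table):
        sub = feature_subset(table, "OFF", "phase", include_demographics=False)
        cols = predictor_columns(sub)
        assert len(cols) == 48
        assert all(c.endswith(("_cos", "_sin")) for c in cols)

    def test_demographics_appended(self, table):
        sub = feature_subset(table, "ON", "amplitude", include_demographics=True)
        assert {"age", "sex_M", "sex_unknown"} <= set(sub.columns)

    def test_bad_names_rejected(self, table):
        with pytest.raises(ValueError):
            feature_subset(table, "nasal", "both")


class TestROCAUC:
    def test_reversed_perfect_ranking(self):
        assert roc_auc([3, 2, 1, 0], [0, 0, 1, 1]) == 0.0

    def test_all_ties(self):
        assert roc_auc([1, 1, 1, 1], [0, 1, 0, 1]) == 0.5

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = 50
            scores = rng.choice(np.linspace(0, 1, 17), size=n)  # ties likely
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            pos, neg = scores[labels == 1], scores[labels == 0]
            brute = np.mean(
                (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
            )
            assert abs(roc_auc(scores, labels) - brute) < 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestPerformance:
    def test_perfect(self):
        m = performance([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert (m.accuracy, m.sensitivity, m.specificity, m.auc) == (1, 1, 1, 1)

    def test_worked_auc_example(self):
        m = performance([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert abs(m.auc - 0.75) < 1e-12

    def test_tie_rule_at_threshold(self):
        """Scores exactly at threshold count as predicted-patient."""
        m = performance([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0])
        assert m.sensitivity == 1.0 and m.specificity == 0.0


class TestElasticNet:
    def test_separable_toy_perfect_auc(self):
        rng = np.random.default_rng(6)
        n = 40
        y = np.array([0, 1] * (n // 2))
        X = np.stack([y * 4.0 - 2.0 + 0.05 * rng.normal(size=n), rng.normal(size=n)], axis=1)
        table = _table_from_X(X, y)
        scheme = make_folds(table, k=5, grouped=False, seed=0)
        res = fit_elastic_net_cv(table, scheme, ClassifierConfig(alpha_grid=(0.5,), n_lambda=8, inner_folds=3))
        assert roc_auc(res.oof_scores, res.labels) == 1.0

    def test_null_features_near_chance(self):
        """Label-independent features under grouped CV: AUC stays near 0.5."""
        rng = np.random.default_rng(7)
        aucs = []
        for seed in range(5):
            table = _paired_table(50, 10, rng)
            scheme = make_folds(table, k=10, grouped=True, seed=seed)
            cfg = ClassifierConfig(alpha_grid=(0.5,), n_lambda=6, inner_folds=3, tol=1e-3, max_iter=300)
            res = fit_elastic_net_cv(table, scheme, cfg)
            aucs.append(roc_auc(res.oof_scores, res.labels))
        assert 0.35 < np.mean(aucs) < 0.65

    def test_sparse_recovery(self):
        """One informative feature among 99 noise features: elastic net keeps
        the informative one and zeroes most of the noise."""
        rng = np.random.default_rng(8)
        n = 120
        y = rng.integers(0, 2, size=n)
        X = rng.normal(size=(n, 100))
        X[:, 0] += 3.0 * y
        table = _table_from_X(X, y)
        scheme = make_folds(table, k=5, grouped=False, seed=1)
        cfg = ClassifierConfig(alpha_grid=(1.0,), n_lambda=10, inner_folds=3)
        res = fit_elastic_net_cv(table, scheme, cfg)
        assert res.retained.iloc[0]
        assert res.retained.iloc[1:].sum() < 30
        assert res.coefficients.abs().idxmax() == res.coefficients.index[0]

    def test_every_row_scored_once(self):
        rng = np.random.default_rng(9)
        table = _paired_table(15, 3, rng)
        scheme = make_folds(table, k=5, grouped=True, seed=2)
        res = fit_elastic_net_cv(table, scheme, ClassifierConfig(alpha_grid=(0.5,), n_lambda=5, inner_folds=2))
        assert np.isfinite(res.oof_scores).all()
        assert len(res.per_fold_params) == 5

    def test_no_test_fold_leakage_into_training(self):
        """Modifying one held-out row must not change the scores of other rows
        in the same fold (their model saw neither row)."""
        rng = np.random.default_rng(10)
        table = _paired_table(16, 4, rng)
        scheme = make_folds(table, k=4, grouped=True, seed=3)
        cfg = ClassifierConfig(alpha_grid=(0.5,), n_lambda=5, inner_folds=2, seed=0)
        res1 = fit_elastic_net_cv(table, scheme, cfg)
        fold0_rows = np.flatnonzero(scheme.assignment == 0)
        corrupted = table.copy()
        feat_cols = predictor_columns(table)
        corrupted.loc[fold0_rows[0], feat_cols] = 1e4
        res2 = fit_elastic_net_cv(corrupted, scheme, cfg)
        np.testing.assert_allclose(
            res1.oof_scores[fold0_rows[1:]], res2.oof_scores[fold0_rows[1:]], atol=1e-10
        )

    def test_zero_variance_predictor_dropped(self):
        rng = np.random.default_rng(11)
        table = _paired_table(15, 3, rng)
        table["const_rc1_h1_rho"] = 1.0
        scheme = make_folds(table, k=5, grouped=True, seed=4)
        res = fit_elastic_net_cv(table, scheme, ClassifierConfig(alpha_grid=(0.5,), n_lambda=4, inner_folds=2))
        assert "const_rc1_h1_rho" not in res.coefficients.index
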