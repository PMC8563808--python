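"""Elastic-net fitting and nested leave-one-subject-out cross-validation."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as scipy_stats
from scipy.optimize import minimize

from lfpstate.classify import (
    DEFAULT_LAMBDA_GRID,
    compare_subject_aucs,
    enet_path,
    fit_enet_logistic,
    nested_cv,
    subject_level_cv,
    CvResult,
)

SMALL_GRID = np.logspace(-3, 1, 10)


def toy_data(n=60, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 4))
    X = (X - X.mean(0)) / X.std(0)
    w = np.array([1.5, -1.0, 0.5, 0.0])
    y = (X @ w + 0.5 * rng.normal(size=n) > 0).astype(int)
    return X, y


class TestEnetFit:
    def test_full_shrinkage_limit(self):
        """Huge lambda: all coefficients zero, intercept = class log-odds."""
        X, y = toy_data()
        m = fit_enet_logistic(X, y, 1e6)
        assert np.all(m.coefficients == 0.0)
        assert m.intercept == pytest.approx(np.log(y.mean() / (1 - y.mean())), abs=1e-6)

    def test_separable_1d_sign(self):
        m = fit_enet_logistic(np.array([[-1.0], [1.0]]), np.array([0, 1]), 0.0)
        assert m.coefficients[0] > 0

    def test_unregularized_matches_direct_optimizer(self):
        """lambda = 0 agrees with an independent BFGS maximum-likelihood fit."""
        X, y = toy_data()
        m = fit_enet_logistic(X, y, 0.0)

        def nll(params):
            w, b = params[:-1], params[-1]
            z = X @ w + b
            return np.logaddexp(0, -z)[y == 1].sum() + np.logaddexp(0, z)[y == 0].sum()

        res = minimize(nll, np.zeros(X.shape[1] + 1), method="BFGS", options={"gtol": 1e-10})
        np.testing.assert_allclose(
            np.r_[m.coefficients, m.intercept], res.x, atol=1e-4
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            fit_enet_logistic(np.zeros((5, 2)), np.ones(5), 0.1)

    def test_non_finite_rejected(self):
        X, y = toy_data(20)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_enet_logistic(X, y, 0.1)

    def test_path_sparsity_monotone_in_lambda(self):
        """Number of surviving coefficients is non-increasing along the
        default grid for l1-dominant mixing."""
        X, y = toy_data(100, seed=3)
        for mixing in (0.5, 0.9):
            path = enet_path(X, y, DEFAULT_LAMBDA_GRID, mixing=mixing)
            nnz = [(np.abs(m.coefficients) > 1e-8).sum() for m in path]
            assert all(a >= b for a, b in zip(nnz, nnz[1:]))


def synthetic_features(n_subjects=4, n_seg=15, effect=3.0, seed=0, epochs=("PRE", "POST")):
    """Feature frame where beta_L separates the epochs; others are noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for epoch in epochs:
            shift = effect if epoch in ("POST", "MID") and effect else 0.0
            for k in range(n_seg):
                rows.append(
                    {
                        "subject_id": f"s{s}",
                        "epoch": epoch,
                        "segment_index": k,
                        "theta_L": rng.lognormal(0, 0.3),
                        "alpha_L": rng.lognormal(0, 0.3),
                        "beta_L": rng.lognormal(0, 0.3) + shift,
                        "theta_R": rng.lognormal(0, 0.3),
                        "alpha_R": rng.lognormal(0, 0.3),
                        "beta_R": rng.lognormal(0, 0.3),
                    }
                )
    return pd.DataFrame(rows)


class TestNestedCv:
    def test_shapes_and_determinism(self):
        feats = synthetic_features()
        cv1 = nested_cv(feats, ("PRE", "POST"), lambda_grid=SMALL_GRID, seed=4)
        cv2 = nested_cv(feats, ("PRE", "POST"), lambda_grid=SMALL_GRID, seed=4)
        assert len(cv1.outer) == 4
        assert all(len(f.inner_models) == 3 for f in cv1.outer)
        assert cv1.auc_mean == pytest.approx(np.mean(cv1.outer_aucs))
        assert cv1.to_dict() == cv2.to_dict()
        assert cv1.auc_mean > 0.9  # strong injected effect

    def test_round_trip_serialization(self, tmp_path):
        cv = nested_cv(synthetic_features(), lambda_grid=SMALL_GRID, seed=0)
        cv.save(tmp_path / "cv.json")
        back = CvResult.load(tmp_path / "cv.json")
        assert back.to_dict() == cv.to_dict()

    def test_incomplete_subjects_excluded_with_warning(self):
        feats = synthetic_features(n_subjects=5)
        feats = feats[~((feats.subject_id == "s4") & (feats.epoch == "POST"))]
        feats.loc[feats.subject_id == "s3", "beta_R"] = np.nan
        with pytest.warns(UserWarning, match="excluded"):
            cv = nested_cv(feats, ("PRE", "POST"), lambda_grid=SMALL_GRID)
        assert {f.held_out for f in cv.outer} == {"s0", "s1", "s2"}

    def test_too_few_subjects_rejected(self):
        feats = synthetic_features(n_subjects=2)
        with pytest.raises(ValueError, match=">= 3"):
            nested_cv(feats, ("PRE", "POST"), lambda_grid=SMALL_GRID)

    def test_no_leakage_from_held_out_labels(self):
        """Permuting the held-out subject's labels must leave every fitted
        model untouched (only that fold's AUC may move)."""
        feats = synthetic_features(seed=6)
        cv_a = nested_cv(feats, ("PRE", "POST"), lambda_grid=SMALL_GRID, seed=0)
        shuffled = feats.copy()
        mask = shuffled.subject_id == "s0"
        rng = np.random.default_rng(0)
        shuffled.loc[mask, "epoch"] = rng.permutation(shuffled.loc[mask, "epoch"].to_numpy())
        # keep key uniqueness after label shuffle
        shuffled.loc[mask, "segment_index"] = (
            shuffled.loc[mask].groupby("epoch").cumcount().to_numpy()
        )
        cv_b = nested_cv(shuffled, ("PRE", "POST"), lambda_grid=SMALL_GRID, seed=0)
        fold_a = next(f for f in cv_a.outer if f.held_out == "s0")
        fold_b = next(f for f in cv_b.outer if f.held_out == "s0")
        np.testing.assert_array_equal(fold_a.model.coefficients, fold_b.model.coefficients)
        assert fold_a.chosen_lambda == fold_b.chosen_lambda


class TestSubjectLevel:
    def test_one_row_per_eligible_subject(self):
        feats = synthetic_features(n_subjects=3, n_seg=20, epochs=("PRE", "MID", "POST"))
        table = subject_level_cv(feats, lambda_grid=SMALL_GRID, seed=1)
        assert list(table.columns) == ["subject_id", "auc_pre_mid", "auc_pre_post"]
        assert len(table) == 3
        assert table[["auc_pre_mid", "auc_pre_post"]].le(1.0).all().all()

    def test_too_few_segments_skipped(self):
        feats = synthetic_features(n_subjects=3, n_seg=5, epochs=("PRE", "MID", "POST"))
        with pytest.warns(UserWarning, match="too few segments"):
            table = subject_level_cv(feats, lambda_grid=SMALL_GRID)
        assert len(table) == 0


class TestAucComparison:
    def test_identical_columns_give_zero_f(self):
        table = pd.DataFrame(
            {"subject_id": list("abcd"), "auc_pre_mid": [0.5, 0.6, 0.7, 0.8],
             "auc_pre_post": [0.5, 0.6, 0.7, 0.8]}
        )
        res = compare_subject_aucs(table)
        assert res.F == 0.0

    def test_f_equals_squared_paired_t(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(0.4, 0.7, size=8)
        b = a + rng.normal(0.1, 0.05, size=8)
        table = pd.DataFrame({"subject_id": range(8), "auc_pre_mid": a, "auc_pre_post": b})
        res = compare_subject_aucs(table)
        t = scipy_stats.ttest_rel(a, b)
        assert res.F == pytest.approx(t.statistic**2, rel=1e-9)
        assert res.p == pytest.approx(t.pvalue, rel=1e-9)
        assert res.df == (1, 7)
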