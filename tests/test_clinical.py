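"""Clinical-outcome statistics: summaries, correlation, permutation correction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as scipy_stats

from lfpstate.clinical import (
    beta_outcome_correlation,
    load_reference_cohort,
    pearson_slope_test,
    percent_change,
    permutation_fdr,
    pre_post_rmanova,
    summarize_hdrs,
)
from lfpstate.sigio import ClinicalTable, ValidationError
from lfpstate.simulate import generate_cohort, reference_cohort_spec
from conftest import cohort_to_features


def table(baseline, post, **extra):
    return ClinicalTable(
        pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(len(baseline))],
                "hdrs_baseline": baseline,
                "hdrs_post": post,
                **extra,
            }
        )
    )


class TestHdrsSummary:
    def test_reference_cohort_summary_cells(self):
        """The eight-subject reference table reproduces the published-style
        summary cells exactly at reporting precision."""
        summary = summarize_hdrs(load_reference_cohort()).rounded()
        assert summary["mean_baseline"] == 22.75
        assert summary["sd_baseline"] == 1.50
        assert summary["mean_post"] == 12.38
        assert summary["sd_post"] == 3.66
        assert summary["percent_decline"] == 45.6
        assert summary["n_responders"] == 3
        assert summary["mean_age"] == 50.0
        assert summary["n"] == 8

    def test_no_change_means_no_decline(self):
        s = summarize_hdrs(table([20.0, 24.0], [20.0, 24.0]))
        assert s.percent_decline == 0.0
        assert s.n_responders == 0

    def test_single_subject_responder_boundary(self):
        s = summarize_hdrs(table([20.0], [9.0]))
        assert s.percent_decline == pytest.approx(55.0)
        assert s.n_responders == 1
        # exactly 50% decline is NOT a responder (strict rule)
        assert summarize_hdrs(table([20.0], [10.0])).n_responders == 0


class TestPrePostRmanova:
    def test_identical_columns_zero_f(self):
        res = pre_post_rmanova(table([20.0, 22.0, 24.0], [20.0, 22.0, 24.0]))
        assert res.F == 0.0

    def test_f_equals_squared_paired_t(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(18, 26, size=8)
        post = base - rng.uniform(2, 14, size=8)
        res = pre_post_rmanova(table(base, post))
        t = scipy_stats.ttest_rel(base, post)
        assert res.F == pytest.approx(t.statistic**2, rel=1e-9)
        assert res.df == (1, 7)


class TestPercentChange:
    @pytest.mark.parametrize(
        "pre,post,expected",
        [(22.75, 12.375, -45.6), (10.0, 10.0, 0.0), (10.0, 15.0, 50.0)],
    )
    def test_closed_forms(self, pre, post, expected):
        assert percent_change(pre, post) == pytest.approx(expected, abs=0.05)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ZeroDivisionError):
            percent_change(0.0, 5.0)


class TestPearsonSlopeTest:
    def test_longhand_covariance_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        res = pearson_slope_test(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        r_longhand = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert res.r == pytest.approx(r_longhand, rel=1e-12)
        t = r_longhand * np.sqrt(3 / (1 - r_longhand**2))
        assert res.p_uncorrected == pytest.approx(2 * scipy_stats.t.sf(abs(t), 3), rel=1e-9)

    def test_perfect_linear_relations(self):
        x = np.arange(5.0)
        assert pearson_slope_test(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson_slope_test(x, -x).r == pytest.approx(-1.0)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=8), rng.normal(size=8)
        assert pearson_slope_test(x, y).r == pytest.approx(pearson_slope_test(y, x).r)
        assert pearson_slope_test(3 * x + 2, y).r == pytest.approx(
            pearson_slope_test(x, y).r, rel=1e-12
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_slope_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match=">= 3"):
            pearson_slope_test([1.0, 2.0], [1.0, 2.0])


class TestPermutationFdr:
    def test_single_test_matches_direct_permutation_p(self):
        """Family of one: corrected p converges to the plain permutation p
        (fraction of permuted |r| at or above the observed |r|)."""
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=8), rng.normal(size=8)
        res = permutation_fdr([(x, y)], n_perm=5000, seed=3)[0]
        rng2 = np.random.default_rng(99)
        abs_r = np.array(
            [abs(np.corrcoef(x, rng2.permutation(y))[0, 1]) for _ in range(5000)]
        )
        direct = (abs_r >= abs(res.r)).mean()
        assert res.p_corrected == pytest.approx(direct, abs=0.03)
        assert res.p_corrected == res.p_permutation

    def test_corrected_never_below_marginal(self):
        rng = np.random.default_rng(11)
        for rep in range(5):
            tests = [(rng.normal(size=8), rng.normal(size=8)) for _ in range(3)]
            for res in permutation_fdr(tests, n_perm=500, seed=rep):
                assert res.p_corrected >= res.p_permutation

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            permutation_fdr([(np.arange(5.0), np.ones(5))], n_perm=200)

    def test_small_n_perm_warns(self):
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_fdr([(rng.normal(size=6), rng.normal(size=6))], n_perm=50)


class TestBetaOutcomeCorrelation:
    def test_per_feature_n_convention(self, preset_seed1):
        """One bad right lead: left-hemisphere features keep n = 8, right
        features drop to n = 7."""
        res = beta_outcome_correlation(
            preset_seed1["features"], preset_seed1["clinical"], n_perm=500, seed=0
        )
        by_name = {r.name: r for r in res}
        assert by_name["beta_L"].n == 8
        assert by_name["alpha_R"].n == 7

    def test_strong_coupling_recovered(self):
        """Slope 1 with small outcome noise: significant positive left-beta
        correlation after family correction."""
        spec = reference_cohort_spec(
            epoch_seconds=20.0, coupling_slope=1.0, outcome_noise_sd=0.3
        )
        recordings, clinical, _ = generate_cohort(spec, seed=5)
        features = cohort_to_features(recordings)
        res = beta_outcome_correlation(features, clinical, n_perm=2000, seed=5)
        beta = next(r for r in res if r.name == "beta_L")
        assert beta.r > 0.7
        assert beta.p_corrected < 0.05

    def test_validation_error_on_bad_scores(self):
        with pytest.raises(ValidationError):
            table([20.0, -1.0], [10.0, 5.0])
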