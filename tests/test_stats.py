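"""Rest-task statistics: percent change, rank tests, MAD filter, Holm, Clogg."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intflex import stats


class TestPercentChange:
    @pytest.mark.parametrize(
        "rest,task,expected", [(2.0, 3.0, 50.0), (3.0, 3.0, 0.0), (4.0, 3.0, -25.0)]
    )
    def test_printed_formula(self, rest, task, expected):
        assert stats.percent_change(rest, task) == pytest.approx(expected)

    def test_nonpositive_rest_rejected(self):
        with pytest.raises(ValueError):
            stats.percent_change(0.0, 1.0)

    @given(
        rest=st.floats(0.01, 1e3),
        task=st.floats(-1e3, 1e3),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_algebraic_identity(self, rest, task):
        pc = stats.percent_change(rest, task)
        assert pc + 100.0 == pytest.approx(100.0 * task / rest, rel=1e-9, abs=1e-6)


class TestVariabilityChangeCorrelation:
    def _summary(self, var, change):
        import pandas as pd

        return pd.DataFrame({"rest_sd": var, "pct_change": change})

    def test_monotone_identity_gives_rho_one(self):
        v = np.arange(10.0)
        rho, p, df = stats.variability_change_correlation(self._summary(v, v))
        assert rho == pytest.approx(1.0)
        assert df == 8

    def test_antitone_identity_gives_rho_minus_one(self):
        v = np.arange(10.0)
        rho, _, _ = stats.variability_change_correlation(self._summary(v, -v))
        assert rho == pytest.approx(-1.0)

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError):
            stats.variability_change_correlation(
                self._summary(np.ones(5), np.arange(5.0))
            )


class TestCompareGroups:
    def test_identical_paired_groups_give_null_result(self):
        a = np.arange(20.0)
        res = stats.compare_groups(a, a.copy(), paired=True)
        assert res.z == 0.0 and res.p == 1.0 and res.effect_r == 0.0

    def test_complete_separation_gives_rank_biserial_one(self):
        a = np.arange(10.0) + 100.0
        b = np.arange(10.0)
        res = stats.compare_groups(a, b)
        assert res.effect_r == pytest.approx(1.0)

    def test_shifted_distributions_detected(self, rng):
        a = rng.normal(1.0, 1.0, size=200)
        b = rng.normal(0.0, 1.0, size=200)
        res = stats.compare_groups(a, b)
        assert res.p < 1e-3 and res.effect_r > 0.5

    @pytest.mark.parametrize("paired", [False, True])
    def test_antisymmetric_in_arguments(self, rng, paired):
        a = rng.normal(0.5, 1.0, size=30)
        b = rng.normal(0.0, 1.0, size=30)
        r1 = stats.compare_groups(a, b, paired=paired)
        r2 = stats.compare_groups(b, a, paired=paired)
        assert r1.z == pytest.approx(-r2.z)
        assert r1.effect_r == pytest.approx(-r2.effect_r)
        assert r1.p == pytest.approx(r2.p)

    def test_exact_path_below_ten_observations(self, rng):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = a + 0.5
        res = stats.compare_groups(a, b, paired=True)
        assert 0.0 <= res.p <= 1.0 and res.z < 0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            stats.compare_groups(np.array([]), np.array([1.0]))

    def test_z_sqrt_n_variant(self, rng):
        a = rng.normal(1.0, 1.0, size=50)
        b = rng.normal(0.0, 1.0, size=80)
        res = stats.compare_groups(a, b, effect="z_sqrt_n")
        assert res.effect_r == pytest.approx(res.z / np.sqrt(50))


class TestMADOutliers:
    def test_gross_outlier_removed(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        kept, mask = stats.remove_outliers_mad(x)
        assert list(kept) == [1.0, 2.0, 3.0, 4.0]
        assert not mask[-1]

    def test_clean_data_fully_kept(self, rng):
        x = rng.normal(size=100)
        _, mask = stats.remove_outliers_mad(x)
        assert mask.mean() > 0.95

    def test_constant_vector_degenerate_branch(self):
        with pytest.warns(UserWarning, match="zero MAD"):
            kept, mask = stats.remove_outliers_mad(np.array([5.0, 5.0, 5.0, 6.0]))
        assert np.all(kept == 5.0)


class TestHolm:
    def test_single_p_unchanged(self):
        assert stats.holm_correct([0.03])[0] == pytest.approx(0.03)

    def test_two_p_step_down(self):
        adj = stats.holm_correct([0.01, 0.04])
        assert adj == pytest.approx([0.02, 0.04])

    def test_all_ones_stay_one(self):
        assert np.all(stats.holm_correct([1.0, 1.0, 1.0]) == 1.0)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_adjusted_never_below_raw(self, pvals):
        adj = stats.holm_correct(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)


class TestClogg:
    def test_equal_coefficients_give_zero_z(self):
        res = stats.clogg_compare(1.2, 0.1, 1.2, 0.15)
        assert res.z == 0.0 and res.p == 1.0

    def test_unit_z_quantile(self):
        # coefficient gap equal to the SE of the difference -> z = 1
        res = stats.clogg_compare(1.0, 0.3, 0.6, 0.5)
        assert res.z == pytest.approx((1.0 - 0.6) / np.sqrt(0.5**2 - 0.3**2))
        res = stats.clogg_compare(1.0, 0.0, 1.0 - 0.4, 0.4)
        assert res.z == pytest.approx(1.0)
        assert res.p == pytest.approx(0.3173, abs=1e-3)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            stats.clogg_compare(1.0, 0.5, 0.9, 0.3)

    def test_independent_covariate_rarely_significant(self):
        # null simulation: an unrelated covariate should not move the
        # predictor's coefficient between nested logistic fits
        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 10
        for _ in range(n_rep):
            x = rng.normal(size=5000)
            cov = rng.normal(size=5000)
            p_true = 1.0 / (1.0 + np.exp(-(0.5 * x)))
            y = rng.random(5000) < p_true
            res = stats.clogg_logistic(y, x, cov)
            hits += res.p > 0.05
        assert hits >= int(0.9 * n_rep)


class TestRestTaskSummary:
    def test_pipeline_reports_positive_change_for_longer_task_tau(self):
        # end-to-end: channels with tau_task > tau_rest should almost all
        # show positive percent change and a significant group difference
        from intflex import synthetic
        from intflex.timescales import windowed_int

        rng = np.random.default_rng(0)
        n_ch = 40
        tau_rest = 0.3 * np.exp(rng.normal(0, 0.2, n_ch))
        rec = synthetic.gen_state_recording(
            [("sustained_rest", 300.0), ("locomotion", 300.0)],
            {"sustained_rest": tau_rest, "locomotion": 2.0 * tau_rest},
            n_channels=n_ch, fs=20.0, seed=3,
        )
        tbl = windowed_int(rec)
        summary = stats.rest_task_summary(tbl, "sustained_rest", "locomotion")
        assert (summary["pct_change"] > 0).mean() > 0.95
        conv = tbl[tbl.converged]
        res = stats.compare_groups(
            conv.loc[conv.state == "locomotion", "tau_s"].to_numpy(),
            conv.loc[conv.state == "sustained_rest", "tau_s"].to_numpy(),
        )
        assert res.p < 1e-6 and res.effect_r > 0
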