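"""Two-sample summary MR: harmonization, pruning, estimators, heterogeneity."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from poismr import (
    cochran_q,
    harmonize,
    heterogeneity_report,
    ivw_closed_form,
    ivw_exact,
    ld_prune,
    leave_one_out,
    mr_egger,
    mvmr_ivw_twosample,
    penalized_weighted_median,
    rucker_q,
    wald_ratios,
    weighted_mode,
)
from poismr.twosample import (
    EggerEstimator,
    IVWEstimator,
    MultivariableIVWEstimator,
    WeightedMedianEstimator,
    WeightedModeEstimator,
    _weighted_median,
)


def _stats_table(vid, ea, oa, beta, se, eaf):
    return pd.DataFrame(
        {
            "variant_id": vid,
            "effect_allele": ea,
            "other_allele": oa,
            "beta": beta,
            "se": se,
            "pval": [0.001] * len(vid),
            "eaf": eaf,
        }
    )


class TestHarmonize:
    def test_identical_coding_passes_through(self):
        e = _stats_table(["rs1"], ["A"], ["G"], [0.1], [0.01], [0.3])
        o = _stats_table(["rs1"], ["A"], ["G"], [0.05], [0.02], [0.3])
        h, audit = harmonize(e, o)
        assert h.iloc[0]["beta_outcome"] == 0.05
        assert len(audit) == 0

    def test_swapped_alleles_flip_outcome_beta(self):
        e = _stats_table(["rs1"], ["A"], ["G"], [0.1], [0.01], [0.3])
        o = _stats_table(["rs1"], ["G"], ["A"], [0.05], [0.02], [0.7])
        h, audit = harmonize(e, o)
        assert h.iloc[0]["beta_outcome"] == -0.05
        assert audit.iloc[0]["action"] == "flipped"

    def test_palindromic_at_half_frequency_dropped(self):
        e = _stats_table(["rs1"], ["A"], ["T"], [0.1], [0.01], [0.50])
        o = _stats_table(["rs1"], ["A"], ["T"], [0.05], [0.02], [0.50])
        h, audit = harmonize(e, o)
        assert len(h) == 0
        assert audit.iloc[0]["reason"] == "palindromic"

    def test_palindromic_outside_window_aligned_by_frequency(self):
        e = _stats_table(["rs1"], ["A"], ["T"], [0.1], [0.01], [0.10])
        o = _stats_table(["rs1"], ["A"], ["T"], [0.05], [0.02], [0.88])
        h, _ = harmonize(e, o)  # frequencies disagree -> coding flipped
        assert h.iloc[0]["beta_outcome"] == -0.05

    def test_strand_flip_resolved(self):
        e = _stats_table(["rs1"], ["A"], ["G"], [0.1], [0.01], [0.3])
        o = _stats_table(["rs1"], ["T"], ["C"], [0.05], [0.02], [0.3])
        h, audit = harmonize(e, o)
        assert h.iloc[0]["beta_outcome"] == 0.05
        assert audit.iloc[0]["action"] == "strand_flipped"

    def test_incompatible_alleles_dropped_with_reason(self):
        e = _stats_table(["rs1"], ["A"], ["G"], [0.1], [0.01], [0.3])
        o = _stats_table(["rs1"], ["A"], ["C"], [0.05], [0.02], [0.3])
        h, audit = harmonize(e, o)
        assert len(h) == 0
        assert "incompatible" in audit.iloc[0]["reason"]


class TestLDPrune:
    def test_uncorrelated_all_retained(self):
        snps = pd.DataFrame({"variant_id": list("abc"), "pval_exposure": [0.1, 0.2, 0.3]})
        kept = ld_prune(snps, np.zeros((3, 3)), 0.001)
        assert set(kept) == {"a", "b", "c"}

    def test_duplicate_keeps_smaller_p(self):
        snps = pd.DataFrame({"variant_id": ["a", "b"], "pval_exposure": [0.5, 0.001]})
        r2 = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert ld_prune(snps, r2, 0.001) == ["b"]

    def test_no_retained_pair_violates_threshold(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            j = rng.integers(3, 12)
            m = rng.random((j, j)) * 0.01
            m = (m + m.T) / 2
            np.fill_diagonal(m, 1.0)
            snps = pd.DataFrame(
                {"variant_id": [f"v{i}" for i in range(j)], "pval_exposure": rng.random(j)}
            )
            kept = ld_prune(snps, m, 0.005)
            dfm = pd.DataFrame(m, index=snps.variant_id, columns=snps.variant_id)
            for i, a in enumerate(kept):
                for b in kept[i + 1 :]:
                    assert dfm.loc[a, b] < 0.005

    def test_missing_entry_is_error(self):
        snps = pd.DataFrame({"variant_id": ["a", "b"], "pval_exposure": [0.1, 0.2]})
        r2 = pd.DataFrame({"a": [1.0]}, index=["a"])
        with pytest.raises(ValueError, match="missing"):
            ld_prune(snps, r2, 0.001)


def _frame(bx, by, sy, sx=None, vid=None):
    j = len(bx)
    return pd.DataFrame(
        {
            "variant_id": vid or [f"v{i}" for i in range(j)],
            "beta_exposure": bx,
            "se_exposure": np.zeros(j) if sx is None else sx,
            "beta_outcome": by,
            "se_outcome": sy,
        }
    )


class TestWaldRatios:
    def test_ratio_and_se_arithmetic(self):
        wr = wald_ratios(_frame([0.1], [0.02], [0.01]))
        assert wr.iloc[0]["ratio"] == pytest.approx(0.2)
        assert wr.iloc[0]["ratio_se"] == pytest.approx(0.1)

    def test_zero_outcome_beta_gives_zero_ratio(self):
        wr = wald_ratios(_frame([0.1], [0.0], [0.01]))
        assert wr.iloc[0]["ratio"] == 0.0

    def test_joint_negation_invariance(self):
        a = wald_ratios(_frame([0.1], [0.02], [0.01]))
        b = wald_ratios(_frame([-0.1], [-0.02], [0.01]))
        assert a.iloc[0]["ratio"] == b.iloc[0]["ratio"]

    def test_zero_exposure_beta_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero exposure beta"):
            wr = wald_ratios(_frame([0.0, 0.1], [0.01, 0.02], [0.01, 0.01]))
        assert len(wr) == 1

    def test_second_order_se_adds_term(self):
        f = _frame([0.1], [0.02], [0.01], sx=[0.02])
        first = wald_ratios(f).iloc[0]["ratio_se"]
        second = wald_ratios(f, second_order=True).iloc[0]["ratio_se"]
        expect = math.sqrt(0.01**2 / 0.1**2 + 0.02**2 * 0.02**2 / 0.1**4)
        assert second == pytest.approx(expect, rel=1e-12) and second > first


class TestIVW:
    def test_equal_weight_mean_of_two_ratios(self):
        res = ivw_exact(_frame([1.0, 1.0], [0.1, 0.3], [1.0, 1.0]))
        assert res.slope == pytest.approx(0.2, abs=1e-12)

    def test_matches_wls_through_origin_oracle(self, summary_factory):
        rng = np.random.default_rng(1)
        for _ in range(50):
            s = summary_factory(rng, j=int(rng.integers(3, 40)), sx=0.0)
            # independent oracle: explicit weighted least squares through origin
            w = 1.0 / s["se_outcome"] ** 2
            oracle = np.sum(w * s.beta_exposure * s.beta_outcome) / np.sum(
                w * s.beta_exposure**2
            )
            assert abs(ivw_closed_form(s) - oracle) < 1e-10
            assert abs(ivw_exact(s).slope - oracle) < 1e-10

    def test_exact_weights_continuous_at_tiny_sigma_x(self, summary_factory):
        rng = np.random.default_rng(2)
        s = summary_factory(rng, j=25, sx=0.0)
        base = ivw_exact(s).slope
        s2 = s.assign(se_exposure=np.full(len(s), 1e-8))
        assert ivw_exact(s2).slope == pytest.approx(base, abs=1e-6)

    def test_random_effects_se_never_below_fixed(self, summary_factory):
        rng = np.random.default_rng(3)
        s = summary_factory(rng, j=20)
        assert ivw_exact(s, "random").se >= ivw_exact(s, "fixed").se

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValueError):
            ivw_exact(_frame([0.1], [0.01], [0.01]))


class TestEgger:
    def test_exact_fit_recovers_intercept_and_slope(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        by = 0.05 + 0.2 * bx
        res = mr_egger(_frame(bx, by, np.full(4, 0.01)))
        assert res.intercept == pytest.approx(0.05, abs=1e-10)
        assert res.slope == pytest.approx(0.2, abs=1e-10)
        assert res.q_statistic == pytest.approx(0.0, abs=1e-12)

    def test_orientation_invariance(self):
        bx = np.array([0.05, -0.1, 0.15, 0.2])
        by = 0.02 + 0.3 * bx
        by[1] = 0.02 - 0.3 * 0.1  # direct effect on the oriented scale
        a = mr_egger(_frame(bx, by, np.full(4, 0.01)))
        flip = _frame(-bx, -by, np.full(4, 0.01))
        b = mr_egger(flip)
        assert a.slope == pytest.approx(b.slope, rel=1e-10)
        assert a.intercept == pytest.approx(b.intercept, rel=1e-10)

    def test_constant_exposure_betas_rejected(self):
        with pytest.raises(ValueError, match="not separable"):
            mr_egger(_frame([0.1, 0.1, 0.1], [0.01, 0.02, 0.03], [0.01] * 3))


class TestMedian:
    def test_all_ratios_equal_returns_that_ratio(self):
        bx = np.array([0.05, 0.1, 0.2])
        res = penalized_weighted_median(_frame(bx, 0.3 * bx, [0.01, 0.02, 0.005]), n_boot=100)
        assert res.slope == pytest.approx(0.3, abs=1e-10)

    def test_equal_weights_odd_j_is_simple_median(self):
        ratios = np.array([0.1, 0.5, 0.2, 0.4, 0.3])
        assert _weighted_median(ratios, np.ones(5)) == pytest.approx(0.3)

    def test_interpolation_even_weights(self):
        assert _weighted_median(np.array([0.0, 1.0]), np.ones(2)) == pytest.approx(0.5)

    def test_robust_to_minority_outliers_where_ivw_is_not(self):
        rng = np.random.default_rng(4)
        j = 30
        bx = rng.uniform(0.05, 0.15, j)
        by = 0.1 * bx + rng.normal(0, 0.002, j)
        by[:9] += 0.05  # 30% invalid, common directional offset
        f = _frame(bx, by, np.full(j, 0.002))
        med = penalized_weighted_median(f, n_boot=100, seed=0)
        ivw = ivw_exact(f)
        assert abs(med.slope - 0.1) < 0.03
        assert ivw.slope > 0.15  # pulled in the injected direction

    def test_bootstrap_se_deterministic_under_seed(self, summary_factory):
        rng = np.random.default_rng(5)
        s = summary_factory(rng, j=15)
        a = penalized_weighted_median(s, n_boot=100, seed=3)
        b = penalized_weighted_median(s, n_boot=100, seed=3)
        assert a.se == b.se


class TestMode:
    def test_all_ratios_equal_returns_that_ratio(self):
        bx = np.array([0.05, 0.1, 0.2])
        res = weighted_mode(_frame(bx, 0.25 * bx, [0.01, 0.02, 0.005]), n_boot=100)
        assert res.slope == pytest.approx(0.25, abs=1e-9)

    def test_majority_cluster_located(self):
        rng = np.random.default_rng(6)
        j = 20
        bx = rng.uniform(0.08, 0.15, j)
        ratios = np.concatenate([np.full(12, 0.2) + rng.normal(0, 0.005, 12),
                                 rng.uniform(0.5, 1.5, 8)])
        by = ratios * bx
        f = _frame(bx, by, np.full(j, 0.003))
        res = weighted_mode(f, n_boot=100, seed=0)
        assert abs(res.slope - 0.2) < 0.05

    def test_invariant_to_snp_order(self, summary_factory):
        rng = np.random.default_rng(7)
        s = summary_factory(rng, j=18)
        perm = s.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = weighted_mode(s, n_boot=50, seed=2)
        b = weighted_mode(perm, n_boot=50, seed=2)
        assert a.slope == pytest.approx(b.slope, abs=1e-8)


class TestHeterogeneity:
    def test_identical_ratios_give_zero_q(self):
        bx = np.array([0.1, 0.2, 0.4])
        q, contrib = cochran_q(_frame(bx, 0.3 * bx, [0.01] * 3), 0.3)
        assert q == pytest.approx(0.0, abs=1e-20)

    def test_hand_worked_two_snp_example(self):
        # unit outcome weights, ratios 0 and 1, reference at the midpoint
        f = _frame([1.0, 1.0], [0.0, 1.0], [1.0, 1.0])
        q, contrib = cochran_q(f, 0.5)
        assert q == pytest.approx(0.5)
        assert np.allclose(contrib, [0.25, 0.25])

    def test_rucker_zero_for_exact_egger_fit(self):
        bx = np.array([0.05, 0.1, 0.15, 0.25])
        by = 0.03 + 0.4 * bx
        f = _frame(bx, by, np.full(4, 0.01))
        qr, _ = rucker_q(f, mr_egger(f))
        assert qr == pytest.approx(0.0, abs=1e-12)

    def test_rucker_nested_below_cochran(self, summary_factory):
        rng = np.random.default_rng(8)
        for _ in range(200):
            s = summary_factory(rng, j=int(rng.integers(3, 25)))
            rep = heterogeneity_report(s)
            assert rep.q_rucker <= rep.q_cochran + 1e-9

    def test_contributions_sum_to_q(self, summary_factory):
        rng = np.random.default_rng(9)
        s = summary_factory(rng, j=17)
        rep = heterogeneity_report(s)
        assert rep.contributions["q_contribution"].sum() == pytest.approx(rep.q_cochran)


class TestLeaveOneOut:
    def test_homogeneous_data_unflagged(self):
        bx = np.linspace(0.05, 0.2, 10)
        f = _frame(bx, 0.2 * bx, np.full(10, 0.01))
        loo = leave_one_out(f)
        assert not loo["flagged"].any()
        assert np.allclose(loo["delta_estimate"], 0.0, atol=1e-10)

    def test_constructed_outlier_has_max_contribution(self, summary_factory):
        rng = np.random.default_rng(10)
        s = summary_factory(rng, j=15, sy_range=(0.01, 0.01))
        s.loc[4, "beta_outcome"] += 10 * 0.01  # 10-sigma outlier
        loo = leave_one_out(s)
        assert loo.iloc[0]["variant_id"] == s.loc[4, "variant_id"]
        assert loo.iloc[0]["flagged"]
        # removing the outlier reduces Q the most
        assert loo.iloc[0]["delta_q_cochran"] == loo["delta_q_cochran"].min()

    def test_top_k_override(self, summary_factory):
        rng = np.random.default_rng(11)
        s = summary_factory(rng, j=12)
        loo = leave_one_out(s, top_k=3)
        assert loo["flagged"].sum() == 3


class TestMultivariableIVW:
    def test_single_exposure_reduces_to_closed_form(self, summary_factory):
        rng = np.random.default_rng(12)
        s = summary_factory(rng, j=20, sx=0.0)
        res = mvmr_ivw_twosample(s, ["beta_exposure"])["beta_exposure"]
        assert res.slope == pytest.approx(ivw_closed_form(s), abs=1e-12)

    def test_exact_linear_construction(self):
        rng = np.random.default_rng(13)
        j = 15
        b1, b2 = rng.uniform(0.05, 0.2, j), rng.uniform(-0.1, 0.1, j)
        f = pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(j)],
                "bx1": b1,
                "bx2": b2,
                "beta_outcome": 0.1 * b1 + 0.3 * b2,
                "se_outcome": np.full(j, 0.01),
            }
        )
        res = mvmr_ivw_twosample(f, ["bx1", "bx2"])
        assert res["bx1"].slope == pytest.approx(0.1, abs=1e-10)
        assert res["bx2"].slope == pytest.approx(0.3, abs=1e-10)
        assert res["bx1"].q_statistic == pytest.approx(0.0, abs=1e-12)

    def test_null_exposure_identified_against_causal_one(self):
        # mirrors the multivariable design: only exposure 2 causal
        rng = np.random.default_rng(14)
        hits_null, hits_causal = 0, 0
        for rep in range(40):
            j = 40
            b1, b2 = rng.uniform(0.05, 0.2, j), rng.uniform(0.05, 0.2, j)
            sy = np.full(j, 0.003)
            f = pd.DataFrame(
                {
                    "variant_id": [f"v{i}" for i in range(j)],
                    "bx1": rng.normal(b1, 0.002),
                    "bx2": rng.normal(b2, 0.002),
                    "beta_outcome": rng.normal(0.3 * b2, sy),
                    "se_outcome": sy,
                }
            )
            res = mvmr_ivw_twosample(f, ["bx1", "bx2"])
            hits_null += res["bx1"].ci_low <= 0.0 <= res["bx1"].ci_high
            hits_causal += not (res["bx2"].ci_low <= 0.0 <= res["bx2"].ci_high)
        assert hits_null >= 36  # >= 90%
        assert hits_causal >= 36

    def test_collinear_exposures_rejected(self):
        j = 10
        b1 = np.linspace(0.05, 0.2, j)
        f = pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(j)],
                "bx1": b1,
                "bx2": 2 * b1,
                "beta_outcome": 0.1 * b1,
                "se_outcome": np.full(j, 0.01),
            }
        )
        with pytest.raises(ValueError, match="collinear"):
            mvmr_ivw_twosample(f, ["bx1", "bx2"])


class TestEstimatorClasses:
    def test_sklearn_style_fit_on_arrays(self, summary_factory):
        rng = np.random.default_rng(15)
        s = summary_factory(rng, j=25)
        for cls, ref in (
            (IVWEstimator(), ivw_exact(s)),
            (EggerEstimator(), mr_egger(s)),
        ):
            m = cls.fit(
                s["beta_exposure"], s["beta_outcome"], s["se_outcome"], s["se_exposure"]
            )
            assert m.slope_ == pytest.approx(ref.slope, rel=1e-6)
        med = WeightedMedianEstimator(n_boot=50, seed=1).fit(
            s["beta_exposure"], s["beta_outcome"], s["se_outcome"], s["se_exposure"]
        )
        mode = WeightedModeEstimator(n_boot=50, seed=1).fit(
            s["beta_exposure"], s["beta_outcome"], s["se_outcome"], s["se_exposure"]
        )
        assert np.isfinite(med.slope_) and np.isfinite(mode.slope_)

    def test_predict_returns_fitted_outcome_betas(self, summary_factory):
        rng = np.random.default_rng(16)
        s = summary_factory(rng, j=12)
        m = IVWEstimator().fit(s["beta_exposure"], s["beta_outcome"], s["se_outcome"])
        pred = m.predict(s["beta_exposure"])
        assert np.allclose(pred, m.slope_ * s["beta_exposure"])

    def test_rate_view_is_exact_exponentiation(self, summary_factory):
        rng = np.random.default_rng(17)
        res = ivw_exact(summary_factory(rng, j=10))
        for scale in (1.0, 4.74, 0.1):
            view = res.rate_view(scale)
            assert view["rate_ratio"] == math.exp(res.slope * scale)

    def test_multivariable_estimator_class(self):
        rng = np.random.default_rng(18)
        j = 12
        X = pd.DataFrame({"a": rng.uniform(0.05, 0.2, j), "b": rng.uniform(0.05, 0.2, j)})
        y = 0.2 * X["a"] - 0.1 * X["b"]
        m = MultivariableIVWEstimator().fit(X, y, np.full(j, 0.01))
        assert m.slopes_ == pytest.approx([0.2, -0.1], abs=1e-9)


def test_diagnostic_plots_written(tmp_path, summary_factory):
    from poismr.twosample import plot_leave_one_out, plot_scatter

    rng = np.random.default_rng(20)
    s = summary_factory(rng, j=12)
    plot_scatter(s, tmp_path / "scatter.png", [ivw_exact(s), mr_egger(s)])
    plot_leave_one_out(leave_one_out(s), tmp_path / "loo.png")
    assert (tmp_path / "scatter.png").stat().st_size > 0
    assert (tmp_path / "loo.png").stat().st_size > 0
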