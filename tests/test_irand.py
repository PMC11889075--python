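import numpy as np
import pytest
from scipy import stats

from irand import (
    DGPConfig,
    PositivityError,
    draw_subsamples,
    gen_panel,
    irand_estimate,
    permutation_pvalue,
    subsample_ate,
    summarize_pvalues,
)
from irand.matching import _ate_core

from oracles import brute_matched_ate, exact_permutation_pvalue


class TestDrawSubsamples:
    def test_single_individual_single_subsample(self):
        a = draw_subsamples(1, 1, seed=0)
        assert a.shape == (1, 1) and a[0, 0] in (0, 1)

    def test_iid_uniform_over_all_patterns(self):
        # n=3: the 8 visit patterns must be equally likely
        a = draw_subsamples(3, 10_000, scheme="iid", seed=42)
        codes = a @ np.array([4, 2, 1])
        counts = np.bincount(codes, minlength=8)
        assert stats.chisquare(counts).pvalue > 0.01

    def test_balanced_exact_counts(self):
        a = draw_subsamples(10, 100, scheme="balanced", seed=1)
        np.testing.assert_array_equal((a == 0).sum(axis=0), np.full(10, 50))

    def test_balanced_odd_m_rounds(self):
        a = draw_subsamples(5, 7, scheme="balanced", seed=2)
        np.testing.assert_array_equal((a == 0).sum(axis=0), np.full(5, 3))

    def test_seed_determinism(self):
        np.testing.assert_array_equal(draw_subsamples(20, 50, seed=9),
                                      draw_subsamples(20, 50, seed=9))

    def test_bad_args(self):
        with pytest.raises(ValueError):
            draw_subsamples(5, 0)
        with pytest.raises(ValueError):
            draw_subsamples(5, 3, scheme="sobol")


class TestSubsampleATE:
    def test_lcd_treatment_equals_visit_indicator(self, lcd_panel):
        a = draw_subsamples(lcd_panel.n, 1, seed=3)[0]
        from irand.irand import _PanelArrays
        arrays = _PanelArrays(lcd_panel, "treatment", "outcome", ["age", "group"])
        _, T, _ = arrays.cross_section(a)
        np.testing.assert_array_equal(T, a)

    def test_noise_free_effect_recovered_for_every_assignment(self):
        cfg = DGPConfig(n=30, sigma=0.0, beta=(0.0, 0.0), alpha=0.0, delta=2.0,
                        treatment_design="lcd_like", seed=5)
        panel = gen_panel(cfg)
        for seed in range(5):
            a = draw_subsamples(panel.n, 1, seed=seed)[0]
            if 0 < a.sum() < panel.n:
                assert subsample_ate(panel, a) == pytest.approx(2.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_small_panel_matches_enumeration_oracle(self, seed):
        cfg = DGPConfig(n=6, sigma=1.0, treatment_design="lcd_like", seed=seed)
        panel = gen_panel(cfg)
        a = draw_subsamples(6, 1, seed=seed)[0]
        if a.sum() in (0, 6):
            return
        from irand.irand import _PanelArrays
        arrays = _PanelArrays(panel, "treatment", "outcome", ["age", "group"])
        X, T, Y = arrays.cross_section(a)
        from irand.matching import _propensity_scores
        scores = _propensity_scores(X, T)
        expected = brute_matched_ate(scores, T, Y, X=X)
        assert subsample_ate(panel, a) == pytest.approx(expected, abs=1e-9)

    def test_one_class_subsample_redraw_then_error(self):
        # all-zero assignment on an LCD panel is all-control; the redraw is
        # seeded, so a panel of n=2 can still land one-class and must raise
        cfg = DGPConfig(n=12, sigma=1.0, treatment_design="lcd_like", seed=0)
        panel = gen_panel(cfg)
        a = np.zeros(12, dtype=int)
        # redraw rescues this with overwhelming probability
        val = subsample_ate(panel, a, seed=1)
        assert np.isfinite(val)


class TestPermutationPvalue:
    def test_constant_outcome_p_is_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 1))
        T = np.r_[np.ones(6), np.zeros(6)]
        Y = np.full(12, 3.3)
        assert permutation_pvalue(X, T, Y, 0.0, S=40, seed=1) == 1.0

    def test_matches_exhaustive_enumeration_small_sample(self):
        rng = np.random.default_rng(4)
        n = 6
        X = rng.normal(size=(n, 1))
        T = np.r_[np.ones(3), np.zeros(3)]
        Y = rng.normal(size=n) + 1.5 * T
        obs = _ate_core(X, T, Y)
        mc = permutation_pvalue(X, T, Y, obs, S=4000, seed=7)
        exact = exact_permutation_pvalue(lambda Tp: _ate_core(X, Tp, Y), T, obs)
        assert abs(mc - exact) < 0.02

    def test_strong_effect_detected(self):
        cfg = DGPConfig(n=100, sigma=0.1, delta=5.0,
                        treatment_design="bmi_like", seed=3)
        panel = gen_panel(cfg)
        from irand.irand import _PanelArrays
        arrays = _PanelArrays(panel, "treatment", "outcome", ["age", "group"])
        a = draw_subsamples(100, 1, seed=0)[0]
        X, T, Y = arrays.cross_section(a)
        obs = _ate_core(X, T, Y)
        assert permutation_pvalue(X, T, Y, obs, S=200, seed=5) <= 0.01


class TestIRandEstimate:
    def test_eq1_identity_estimate_is_mean_of_subsample_ates(self, bmi_panel):
        res = irand_estimate(bmi_panel, M=20, S=0, seed=1)
        assert res.estimate == pytest.approx(res.ates.mean(), abs=1e-12)

    def test_pvalues_in_unit_interval(self, bmi_panel):
        res = irand_estimate(bmi_panel, M=6, S=30, seed=2)
        assert np.all(res.pvalues > 0) and np.all(res.pvalues <= 1)

    def test_noise_free_pure_effect(self):
        # Y = 3*T exactly: every subsample ATE is 3 and no permutation can
        # reproduce the observed magnitude, so every p-value is the floor
        cfg = DGPConfig(n=30, sigma=0.0, beta=(0.0, 0.0), alpha=0.0, delta=3.0,
                        treatment_design="lcd_like", seed=6)
        panel = gen_panel(cfg)
        res = irand_estimate(panel, M=10, S=50, seed=7)
        assert res.estimate == pytest.approx(3.0, abs=1e-9)
        np.testing.assert_allclose(res.pvalues, 1 / 51)

    def test_determinism_given_seed(self, bmi_panel):
        r1 = irand_estimate(bmi_panel, M=8, S=20, seed=11)
        r2 = irand_estimate(bmi_panel, M=8, S=20, seed=11)
        np.testing.assert_array_equal(r1.ates, r2.ates)
        np.testing.assert_array_equal(r1.pvalues, r2.pvalues)
        np.testing.assert_array_equal(r1.assignments, r2.assignments)

    def test_null_pvalues_approximately_uniform(self):
        # delta=0: pooled subsample p-values across replicates near U(0,1)
        pooled = []
        for r in range(8):
            cfg = DGPConfig(n=120, sigma=1.0, delta=0.0,
                            treatment_design="lcd_like", seed=500 + r)
            res = irand_estimate(gen_panel(cfg), M=8, S=99, seed=r)
            pooled.append(res.pvalues)
        ks = stats.kstest(np.concatenate(pooled), "uniform").statistic
        assert ks < 0.1

    def test_unbiased_over_replicates(self):
        # mean of the estimator over replicates within 3 MC SE of delta
        est = []
        for r in range(60):
            cfg = DGPConfig(n=150, sigma=1.0, delta=1.0,
                            treatment_design="lcd_like", seed=900 + r)
            est.append(irand_estimate(gen_panel(cfg), M=40, S=0, seed=r).estimate)
        est = np.array(est)
        mc_se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - 1.0) < 3 * mc_se

    def test_positivity_abort_names_subsample(self):
        cfg = DGPConfig(n=8, sigma=0.5, treatment_design="lcd_like", seed=1)
        panel = gen_panel(cfg)
        # force every assignment (and its redraw) towards one class by using
        # a contrast that matches no units at all
        with pytest.raises(PositivityError, match="subsample"):
            irand_estimate(panel, M=2, S=0, seed=0, contrast=(7, 8))


class TestSummarizePvalues:
    def test_all_ones_no_rejection(self):
        from irand.irand import IRandResult
        r = IRandResult(ates=np.zeros(4), estimate=0.0, pvalues=np.ones(4),
                        perm_ates=np.empty((4, 0)), assignments=np.zeros((4, 2)),
                        M=4, S=10, seed=0, scheme="iid")
        s = summarize_pvalues(r, alpha=0.05)
        assert s["frac_below_alpha"] == 0.0 and not s["reject"]

    def test_uniform_pvalues_fraction_below_alpha(self):
        rng = np.random.default_rng(0)
        from irand.irand import IRandResult
        p = rng.random(500)
        r = IRandResult(ates=np.zeros(500), estimate=0.0, pvalues=p,
                        perm_ates=np.empty((500, 0)), assignments=np.zeros((500, 2)),
                        M=500, S=10, seed=0, scheme="iid")
        s = summarize_pvalues(r, alpha=0.05)
        se = np.sqrt(0.05 * 0.95 / 500)
        assert abs(s["frac_below_alpha"] - 0.05) < 4 * se

    def test_empty_pvalues_rejected(self, bmi_panel):
        res = irand_estimate(bmi_panel, M=3, S=0, seed=0)
        with pytest.raises(ValueError):
            summarize_pvalues(res)
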