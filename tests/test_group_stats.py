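import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from readscan.group_stats import (SampleStats, build_design, hedges_g,
                                  hedges_g_from_values, independent_t,
                                  jzs_bf, lrt, one_sample_t_vs_chance,
                                  percentage_bend_correlation,
                                  proportion_consistent)

from conftest import seeds_for

CONTROL_CODING = SampleStats(12.84, 2.53, 32)
DYSLEXIA_CODING = SampleStats(9.40, 2.27, 35)


class TestHedgesG:
    def test_worked_example_matches_published_values(self):
        res = hedges_g(CONTROL_CODING, DYSLEXIA_CODING)
        assert res.g == pytest.approx(1.422, abs=0.01)
        assert res.ci95[0] == pytest.approx(0.895, abs=0.02)
        assert res.ci95[1] == pytest.approx(1.973, abs=0.02)
        assert res.ci95[0] <= res.g <= res.ci95[1]

    def test_identical_samples_zero_effect_symmetric_ci(self):
        s = SampleStats(10.0, 2.0, 20)
        res = hedges_g(s, s)
        assert res.g == 0.0
        assert res.ci95[0] == pytest.approx(-res.ci95[1])

    def test_swapping_groups_negates_g_and_mirrors_ci(self):
        a = hedges_g(CONTROL_CODING, DYSLEXIA_CODING)
        b = hedges_g(DYSLEXIA_CODING, CONTROL_CODING)
        assert b.g == pytest.approx(-a.g)
        assert b.ci95[0] == pytest.approx(-a.ci95[1], abs=1e-6)
        assert b.ci95[1] == pytest.approx(-a.ci95[0], abs=1e-6)

    def test_exact_ci_approaches_normal_approximation_at_large_n(self):
        s1, s2 = SampleStats(0.5, 1.0, 500), SampleStats(0.0, 1.0, 500)
        res = hedges_g(s1, s2)
        se = math.sqrt(1 / 500 + 1 / 500 + 0.5 ** 2 / (2 * 998))
        lo, hi = 0.5 - 1.96 * se, 0.5 + 1.96 * se
        assert res.ci95[0] == pytest.approx(lo, rel=0.01)
        assert res.ci95[1] == pytest.approx(hi, rel=0.01)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            hedges_g(SampleStats(1.0, 0.0, 10), SampleStats(2.0, 0.0, 10))


class TestIndependentT:
    def test_worked_example(self):
        t, df, p = independent_t(CONTROL_CODING, DYSLEXIA_CODING)
        assert t == pytest.approx(5.88, abs=0.05)
        assert df == 65
        assert p < 1e-6

    def test_identical_samples(self):
        s = SampleStats(3.0, 1.0, 12)
        t, df, p = independent_t(s, s)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_p_matches_survival_function(self):
        t, df, p = independent_t(SampleStats(1.0, 2.0, 18),
                                 SampleStats(0.2, 2.2, 21))
        assert p == pytest.approx(2 * sps.t.sf(abs(t), df), rel=1e-12)


class TestOneSampleT:
    def test_scores_at_chance_give_t_zero_p_one(self):
        t, p, padj = one_sample_t_vs_chance([0.5] * 10 + [0.4, 0.6])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(0.52, 0.05, 40)
        _, p, padj = one_sample_t_vs_chance(scores, n_tests_bonferroni=3)
        assert padj == pytest.approx(min(1.0, 3 * p))
        assert padj >= p

    def test_zero_variance_away_from_chance(self):
        t, p, padj = one_sample_t_vs_chance([0.8] * 5)
        assert math.isinf(t) and p == 0.0


class TestJzsBf:
    def test_t_zero_supports_null(self):
        for n in (5, 30, 100):
            assert jzs_bf(0.0, n).bf10 < 1.0

    def test_monotone_in_t_at_fixed_n(self):
        bfs = [jzs_bf(t, 25, 25).bf10 for t in (0.0, 1.0, 2.0, 3.0, 4.0)]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))

    def test_quadrature_matches_riemann_sum(self):
        t, n1, n2, r = 2.3, 20, 24, 0.7
        df, neff = n1 + n2 - 2, n1 * n2 / (n1 + n2)
        grid = np.linspace(-30, 30, 400_001)
        f = sps.nct.pdf(t, df, grid * math.sqrt(neff)) \
            * sps.cauchy.pdf(grid, 0, r)
        brute = np.trapezoid(f, grid) / sps.t.pdf(t, df)
        assert jzs_bf(t, n1, n2, r).bf10 == pytest.approx(brute, rel=1e-6)

    def test_reciprocal_identity(self):
        bf10 = jzs_bf(1.7, 30, 28).bf10
        assert bf10 * (1.0 / bf10) == pytest.approx(1.0)

    def test_cross_check_against_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        for t, n in ((1.5, 30), (2.8, 45)):
            ours = jzs_bf(t, n, n, cauchy_width=0.707).bf10
            theirs = float(pingouin.bayesfactor_ttest(t, n, n, r=0.707))
            assert ours == pytest.approx(theirs, rel=1e-3)


class TestPercentageBend:
    def test_exact_linear_relation_gives_r_one(self):
        x = np.arange(20.0)
        r, p = percentage_bend_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_more_robust_to_outlier_than_pearson(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 60)
        y = x + rng.normal(0, 0.3, 60)
        r0, _ = percentage_bend_correlation(x, y)
        pearson0 = np.corrcoef(x, y)[0, 1]
        x_out, y_out = x.copy(), y.copy()
        x_out[0], y_out[0] = 10.0, -10.0
        r1, _ = percentage_bend_correlation(x_out, y_out)
        pearson1 = np.corrcoef(x_out, y_out)[0, 1]
        assert abs(r1 - r0) < abs(pearson1 - pearson0)

    def test_cross_check_against_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        for _ in range(10):
            x = rng.normal(0, 1, 35)
            y = 0.4 * x + rng.normal(0, 1, 35)
            r, p = percentage_bend_correlation(x, y)
            out = pingouin.corr(x, y, method="percbend")
            assert r == pytest.approx(float(out["r"].iloc[0]), abs=1e-6)
            assert p == pytest.approx(float(out["p_val"].iloc[0]), abs=1e-6)

    def test_degenerate_scale_rejected(self):
        x = np.array([1.0] * 30 + [2.0, 3.0])
        with pytest.raises(ValueError):
            percentage_bend_correlation(x, np.arange(32.0))


class TestProportionConsistent:
    def test_all_above_direction_greater_is_one(self):
        assert proportion_consistent([2.0, 3.0, 4.0], 1.0, "greater") == 1.0

    def test_all_below_direction_greater_is_zero(self):
        assert proportion_consistent([0.1, 0.2], 1.0, "greater") == 0.0

    def test_symmetric_null_near_half(self):
        rng = np.random.default_rng(4)
        props = [proportion_consistent(rng.normal(0, 1, 35), 0.0, "greater")
                 for _ in range(300)]
        assert np.mean(props) == pytest.approx(0.5, abs=0.02)


class TestDesignAndLrt:
    def _trials(self, n_per_cell=25, seed=0, imbalance=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g in ("control", "dyslexia"):
            for f in ("TNR", "OpenDyslexic"):
                n = n_per_cell + (imbalance if g == "control" else 0)
                for i in range(n):
                    rows.append({"participant": f"{g[0]}{i}",
                                 "text": f"T{i % 5}", "group": g, "font": f,
                                 "reading_duration": rng.gamma(9.0, 5.0)})
        return pd.DataFrame(rows)

    def test_balanced_codes_sum_to_zero(self):
        spec, coded = build_design(self._trials())
        for col in spec.fixed_effects:
            assert coded[col].sum() == pytest.approx(0.0, abs=1e-9)

    def test_imbalanced_codes_still_centred(self):
        _, coded = build_design(self._trials(imbalance=9))
        for col in ("group_c", "font_c", "group_x_font"):
            assert coded[col].sum() == pytest.approx(0.0, abs=1e-9)

    def test_single_level_predictor_rejected(self):
        t = self._trials()
        t["font"] = "TNR"
        with pytest.raises(ValueError, match="levels"):
            build_design(t)

    def test_duplicated_predictor_flags_collinearity(self):
        t = self._trials()
        t["font"] = np.where(t["group"] == "control", "TNR", "OpenDyslexic")
        with pytest.raises(ValueError, match="collinear"):
            build_design(t)

    def test_lrt_values(self):
        res = lrt(100.0, 103.84, 1)
        assert res.chisq == pytest.approx(3.84)
        assert res.p == pytest.approx(0.050, abs=5e-4)
        assert lrt(50.0, 50.0, 2).p == 1.0

    def test_lrt_matches_chi2_sf_on_grid(self):
        for x2 in (0.5, 2.0, 7.7, 15.0):
            for df in (1, 2, 3):
                assert lrt(0.0, x2, df).p == pytest.approx(
                    sps.chi2.sf(x2, df), rel=1e-12)

    def test_negative_chisq_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            res = lrt(10.0, 9.0, 1)
        assert res.chisq == 0.0 and res.p == 1.0
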