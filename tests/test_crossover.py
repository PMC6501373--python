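import numpy as np
import pandas as pd
import pytest

from oxialarm import (
    PairedCrossover,
    compare_paired,
    hl_median_difference_ci,
    paired_t,
    percent_reduction,
    power_paired_t_analytic,
    power_simulation,
    wilcoxon_signed_rank,
)
from oxialarm.crossover import choose_test, signed_rank_cdf, walsh_averages

from _oracles import hl_interval_enum, signed_rank_cdf_enum, wilcoxon_exact_enum


class TestWilcoxon:
    def test_five_positive_differences_exact_p(self):
        _, p = wilcoxon_signed_rank([1, 2, 3, 4, 5])
        assert p == pytest.approx(0.0625)  # 2/2^5, all sign mass in one tail

    def test_all_zero_differences_degenerate(self):
        with pytest.warns(UserWarning):
            stat, p = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert p == 1.0

    def test_antisymmetric_input_same_p(self, rng):
        d = rng.normal(0.4, 1.0, size=9)
        assert wilcoxon_signed_rank(d)[1] == pytest.approx(wilcoxon_signed_rank(-d)[1])

    def test_zero_differences_dropped_by_default(self):
        _, p_with_zeros = wilcoxon_signed_rank([0, 0, 1, 2, 3, 4, 5])
        _, p_without = wilcoxon_signed_rank([1, 2, 3, 4, 5])
        assert p_with_zeros == pytest.approx(p_without)

    @pytest.mark.parametrize("n", [4, 6, 8, 10, 12])
    def test_exact_p_matches_sign_enumeration(self, n, rng):
        for _ in range(6):
            d = rng.normal(0.5, 1.0, size=n)
            d = np.round(d, 6)
            d[d == 0] = 0.1
            while len(np.unique(np.abs(d))) < n:  # force tie-free input
                d = rng.normal(0.5, 1.0, size=n)
            _, p = wilcoxon_signed_rank(d)
            _, p_enum = wilcoxon_exact_enum(d)
            assert p == pytest.approx(p_enum, abs=1e-12)


class TestHodgesLehmann:
    def test_constant_differences_zero_width_interval(self):
        est, lo, hi = hl_median_difference_ci([2.5] * 8)
        assert est == lo == hi == 2.5

    def test_symmetric_differences_centre_on_zero(self):
        est, lo, hi = hl_median_difference_ci([-1.0, 0.0, 1.0])
        assert est == 0.0
        assert lo <= 0.0 <= hi

    def test_walsh_average_count(self):
        assert len(walsh_averages([1, 2, 3, 4])) == 4 * 5 // 2

    def test_signed_rank_cdf_matches_enumeration(self):
        for n in (3, 5, 8, 10):
            np.testing.assert_allclose(signed_rank_cdf(n), signed_rank_cdf_enum(n))

    def test_interval_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            d = rng.normal(1.0, 2.0, size=10)
            got = hl_median_difference_ci(d, level=0.95)
            want = hl_interval_enum(d, level=0.95)
            assert got == pytest.approx(want)

    def test_interval_ordering_invariant(self, rng):
        for n in (5, 12, 40):  # 40 exercises the normal-approximation branch
            d = rng.normal(0.0, 1.0, size=n)
            est, lo, hi = hl_median_difference_ci(d)
            assert lo <= est <= hi


class TestPower:
    def test_null_effect_rejection_rate_near_alpha(self):
        res = power_simulation(0.0, 75.0, 20, alpha=0.05, reps=10_000, seed=7)
        assert abs(res.power - 0.05) <= 3.0 * np.sqrt(0.05 * 0.95 / res.reps)

    def test_design_power_exceeds_threshold_and_matches_closed_form(self):
        res = power_simulation(50.0, 75.0, 20, alpha=0.05, reps=10_000, seed=3)
        analytic = power_paired_t_analytic(50.0, 75.0, 20, alpha=0.05)
        assert res.power > 0.80
        assert analytic > 0.80
        assert abs(res.power - analytic) <= 3.0 * res.se

    def test_power_monotone_in_n_effect_and_sd(self):
        by_n = [power_paired_t_analytic(50, 75, n) for n in (10, 20, 40)]
        assert by_n == sorted(by_n)
        by_eff = [power_paired_t_analytic(e, 75, 20) for e in (25, 50, 75)]
        assert by_eff == sorted(by_eff)
        by_sd = [power_paired_t_analytic(50, sd, 20) for sd in (50, 75, 100)]
        assert by_sd == sorted(by_sd, reverse=True)
        # and the simulation agrees on direction at matched seeds
        sims = [power_simulation(50, 75, n, reps=2000, seed=5).power for n in (10, 20, 40)]
        assert sims == sorted(sims)

    def test_wilcoxon_power_option_runs(self):
        res = power_simulation(50.0, 75.0, 12, reps=200, seed=1, test="wilcoxon")
        assert 0.0 <= res.power <= 1.0


class TestModel:
    def test_percent_reduction(self):
        assert percent_reduction(4.0, 1.0) == pytest.approx(75.0)

    def test_comparison_contains_estimate_within_ci(self, rng):
        tight = rng.normal(5.0, 1.0, size=12)
        loose = tight - rng.normal(2.0, 0.5, size=12)
        c = compare_paired(tight, loose, metric="alarm_rate")
        assert c.ci_low <= c.hl_estimate <= c.ci_high
        assert c.hl_estimate > 0
        assert 0 < c.p_value < 0.05

    def test_test_selection_by_normality(self, rng):
        gaussian = rng.normal(1.0, 1.0, size=30)
        assert choose_test(gaussian) == "t"
        skewed = rng.lognormal(0.0, 1.5, size=30)
        assert choose_test(skewed) == "wilcoxon"
        assert choose_test([1.0, 1.0]) == "wilcoxon"  # degenerate fallback

    def test_from_dataframe_drops_unpaired_subjects(self, rng):
        rows = []
        for i in range(6):
            for strat in ("tight", "loose"):
                rows.append(
                    {"subject_id": f"S{i}", "strategy": strat, "m": float(i + (strat == "tight"))}
                )
        rows.append({"subject_id": "S9", "strategy": "tight", "m": 99.0})  # one arm only
        model = PairedCrossover.from_dataframe(pd.DataFrame(rows), metrics=["m"])
        a, b = model.data["m"]
        assert len(a) == len(b) == 6  # S9 excluded
        res = model.fit()
        c = res["m"]
        assert c.n == 6 and c.hl_estimate == pytest.approx(1.0)
        assert "m" in res.summary()

    def test_paired_t_matches_difference_t(self, rng):
        d = rng.normal(0.5, 1.0, size=15)
        t1, p1 = paired_t(d)
        assert p1 < 1.0 and np.isfinite(t1)
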