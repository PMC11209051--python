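"""Period staging, rank statistics, slope/plateau fits, maturity panel."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from testecho import staging
from testecho.staging import (
    assign_periods,
    detect_plateau,
    first_fertile_week,
    fit_gi_slope,
    kruskal_wallis,
    lagged_correlation,
    left_right_compare,
    maturity_panel,
    spearman,
)


def spearman_bruteforce(x, y):
    """1 - 6 sum(d^2) / (n(n^2-1)) on tie-free data."""
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    n = len(x)
    return 1 - 6 * ((rx - ry) ** 2).sum() / (n * (n ** 2 - 1))


class TestAssignPeriods:
    @pytest.mark.parametrize("week,period", [
        (4, "pre-pubertal"), (28, "pre-pubertal"),
        (30, "pubertal"), (34, "pubertal"),
        (36, "post-pubertal"), (40, "post-pubertal"),
    ])
    def test_cohort_default_boundaries(self, week, period):
        df = pd.DataFrame({"dog_id": ["d1"], "week": [week]})
        assert assign_periods(df)["period"].iloc[0] == period

    def test_periods_partition_the_grid(self, cohort):
        staged = assign_periods(cohort)
        assert staged["period"].notna().all()
        assert set(staged["period"]) == set(staging.PERIODS)

    def test_per_dog_mode_requires_milestones(self, cohort):
        with pytest.raises(KeyError):
            assign_periods(cohort, per_dog={"dog01": (28, 30, 36)})
        ms = {d: (26, 28, 34) for d in cohort.dog_id.unique()}
        staged = assign_periods(cohort, per_dog=ms)
        assert (staged.loc[staged.week == 34, "period"]
                == "post-pubertal").all()


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40])[0] == pytest.approx(1)
        assert spearman([1, 2, 3, 4], [9, 7, 5, 3])[0] == pytest.approx(-1)

    def test_matches_rank_formula_oracle(self):
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
        rho, p = spearman(x, y)
        assert rho == pytest.approx(spearman_bruteforce(x, y))
        assert rho == pytest.approx(0.8)
        assert 0 <= p <= 1

    def test_constant_vector_flagged(self):
        with pytest.warns(RuntimeWarning):
            rho, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(rho)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])


class TestKruskalWallis:
    def test_identical_groups_degenerate(self):
        assert kruskal_wallis([5, 5, 5], [5, 5], [5]) == (0.0, 1.0)

    def test_three_separated_groups_oracle(self):
        # direct rank computation: H = 12/(N(N+1)) * sum(R^2/n) - 3(N+1) = 7.2
        h, p = kruskal_wallis([1, 2, 3], [4, 5, 6], [7, 8, 9])
        assert h == pytest.approx(7.2)
        assert p < 0.05

    @given(st.sampled_from([np.exp, np.cbrt,
                            lambda v: 3 * np.asarray(v) + 1]))
    def test_invariant_under_increasing_transforms(self, f):
        a, b, c = [1, 3, 2, 5], [4, 6, 8], [2, 9, 7]
        h0, _ = kruskal_wallis(a, b, c)
        h1, _ = kruskal_wallis(f(a), f(b), f(c))
        assert h1 == pytest.approx(h0)
        x, y = [3, 1, 4, 1, 5, 9, 2, 6], [2, 7, 1, 8, 2, 8, 1, 8]
        assert spearman(f(x), f(y))[0] == pytest.approx(spearman(x, y)[0])

    def test_bad_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2, 3])
        with pytest.raises(ValueError):
            kruskal_wallis([1], [])


class TestLeftRight:
    def test_identical_sides_give_p_one(self):
        df = pd.DataFrame({
            "dog_id": ["d1"] * 4, "week": [4, 4, 6, 6],
            "testis_side": ["left", "right"] * 2,
            "testis_l": [1.0, 1.0, 1.2, 1.2],
        })
        assert left_right_compare(df, ["testis_l"]).iloc[0] == 1.0

    def test_shifted_side_detected(self, measured):
        df = measured.copy()
        df.loc[df.testis_side == "left", "gi_region"] += 50
        assert left_right_compare(df, ["gi_region"]).iloc[0] < 0.01

    def test_default_cohort_sides_exchangeable(self, measured):
        # no parameter differs between sides after Bonferroni adjustment,
        # and nominal rejections stay at the chance level
        ps = left_right_compare(measured)
        assert (ps * len(ps)).min() > 0.05
        assert (ps > 0.05).mean() >= 0.85


class TestLaggedCorrelation:
    def test_no_future_exam_raises(self, measured):
        last = measured.week.max()
        with pytest.raises(ValueError, match="lag"):
            lagged_correlation(measured, lags=(int(last),))

    def test_noiseless_coupled_toy_cohort(self):
        weeks = [28, 30, 32, 34, 36]
        df = pd.DataFrame({
            "dog_id": ["d1"] * 5, "testis_side": ["left"] * 5,
            "week": weeks,
            "gi_region": [100 + w for w in weeks],
            "total_sperm": [1e6 * w ** 2 for w in weeks],
        })
        out = lagged_correlation(df, lags=(0, 2))
        assert out[0][0] == pytest.approx(1.0)
        assert out[2][0] == pytest.approx(1.0)

    def test_same_day_correlation_strongest(self, measured):
        out = lagged_correlation(measured)
        assert out[0][0] >= out[4][0]


class TestSlopeAndPlateau:
    def test_noiseless_line_recovered_exactly(self):
        weeks = list(range(6, 31, 2))
        df = pd.DataFrame({"week": weeks,
                           "gi_region": [55 + 2.525 * (w - 6) for w in weeks]})
        slope, se = fit_gi_slope(df, "parenchyma")
        assert slope == pytest.approx(2.525)
        assert se == pytest.approx(0, abs=1e-9)

    def test_constant_series_slope_zero(self):
        df = pd.DataFrame({"week": [6, 8, 10, 12], "gi_region": [80.0] * 4})
        assert fit_gi_slope(df, "parenchyma")[0] == pytest.approx(0)

    def test_too_few_weeks_rejected(self):
        df = pd.DataFrame({"week": [6, 8], "gi_region": [1.0, 2.0]})
        with pytest.raises(ValueError):
            fit_gi_slope(df, "parenchyma")

    def test_mediastinum_slope_recovery(self, measured):
        slope, se = fit_gi_slope(measured, "mediastinum")
        assert slope == pytest.approx(4.251, abs=max(3 * se, 0.05))

    def test_plateau_detection_cases(self):
        rising = {w: 10 * w for w in range(4, 20, 2)}
        assert detect_plateau(rising) is None
        const = {w: 42 for w in range(4, 20, 2)}
        assert detect_plateau(const) == 4
        mixed = {4: 10, 6: 30, 8: 50, 10: 51, 12: 50.5, 14: 51.2}
        assert detect_plateau(mixed) == 8
        with pytest.raises(ValueError):
            detect_plateau({4: 1, 6: 2, 8: 3})

    def test_parenchyma_plateau_at_week_30(self, measured):
        med = measured.groupby("week").gi_region.median()
        assert detect_plateau(med.to_dict()) == 30


class TestMaturityPanel:
    def test_week36_all_indicators_true(self, measured):
        panel = maturity_panel(measured, 36,
                               doppler_col="doppler_score_measured")
        assert all(panel.indicators())
        assert panel.verdict == "mature"

    def test_week12_all_indicators_false(self, measured):
        panel = maturity_panel(measured, 12,
                               doppler_col="doppler_score_measured")
        assert not any(panel.indicators())
        assert panel.verdict == "immature"

    def test_empty_slice_rejected(self, measured):
        with pytest.raises(ValueError):
            maturity_panel(measured, 5)


class TestCohortBattery:
    def test_correlation_sign_structure(self, measured):
        rho, _ = staging.correlation_matrix(measured)
        growth = ["weight", "height", "total_sperm", "us_volume",
                  "gi_region", "het_region", "gi_mt", "gi_capsule"]
        for a in growth:
            for b in growth:
                if a != b:
                    assert rho.loc[a, b] > 0, (a, b)
            assert rho.loc["ratio_cap", a] < 0, a
        assert np.allclose(rho.values, rho.values.T, equal_nan=True)
        assert np.allclose(np.diag(rho.values), 1.0)

    def test_periodwise_kruskal_wallis_separates_structures(self, measured):
        report = staging.analyze_cohort(measured)
        assert report.kw_structures[1] < 0.01
        for structure, (h, p) in report.kw_periods.items():
            assert p < 0.01, structure

    def test_first_fertile_week(self, measured):
        assert first_fertile_week(measured) == 36
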