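"""Unit, oracle and property tests for the psychometric statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from copsway.errors import InvalidArgumentError, UndefinedStatisticError
from copsway.psychometrics import (
    MDC95_DEFAULT_Z,
    anova_vision_support,
    coefficient_of_variation,
    correlate,
    effect_size,
    icc_3_1,
    mdc95,
    munro_class,
    pct_mdc,
    reliability_bundle,
    sem,
)


def icc31_bruteforce(m):
    """Independent ANOVA-decomposition oracle: explicit residual sums."""
    m = np.asarray(m, float)
    n, k = m.shape
    grand = m.mean()
    row = m.mean(axis=1)
    col = m.mean(axis=0)
    ss_rows = k * sum((r - grand) ** 2 for r in row)
    ss_err = sum(
        (m[i, j] - row[i] - col[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    bms = ss_rows / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    return (bms - ems) / (bms + (k - 1) * ems)


class TestCoefficientOfVariation:
    def test_no_dispersion(self):
        assert coefficient_of_variation([7, 7, 7]) == 0.0

    def test_hand_computed(self):
        # SD(10,10,13) = sqrt(3), mean 11
        assert coefficient_of_variation([10, 10, 13]) == pytest.approx(
            100 * np.sqrt(3) / 11
        )

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        factor=st.floats(0.01, 1000),
        values=st.lists(st.floats(1.0, 100.0), min_size=2, max_size=8),
    )
    def test_scale_invariance(self, factor, values):
        v = np.asarray(values)
        if v.std(ddof=1) == 0:
            return
        assert coefficient_of_variation(factor * v) == pytest.approx(
            coefficient_of_variation(v), rel=1e-9
        )

    def test_mean_zero_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            coefficient_of_variation([-1.0, 1.0])

    def test_needs_two_values(self):
        with pytest.raises(InvalidArgumentError):
            coefficient_of_variation([5.0])


class TestICC:
    def test_constant_occasion_offset_gives_one(self):
        icc, (lo, hi) = icc_3_1([[1, 2], [3, 4], [5, 6]])
        assert icc == 1.0

    def test_worked_example(self):
        # BMS = 8, EMS = 2/3 -> (8 - 2/3)/(8 + 2/3)
        icc, _ = icc_3_1([[1, 2], [4, 3], [5, 6]])
        assert icc == pytest.approx((8 - 2 / 3) / (8 + 2 / 3), rel=1e-12)
        assert icc == pytest.approx(0.8462, abs=5e-5)

    def test_column_offset_invariance(self, rng):
        m = rng.normal(size=(10, 3))
        shifted = m + np.array([0.0, 5.0, -2.0])
        assert icc_3_1(shifted)[0] == pytest.approx(icc_3_1(m)[0], rel=1e-9)

    def test_matches_bruteforce_on_random_matrices(self, rng):
        for n in (3, 4, 5, 6):
            for k in (2, 3, 4):
                for _ in range(5):
                    m = rng.integers(0, 20, size=(n, k)).astype(float)
                    if np.ptp(m) == 0:
                        continue
                    assert icc_3_1(m)[0] == pytest.approx(
                        icc31_bruteforce(m), rel=1e-9, abs=1e-12
                    )

    def test_matches_pingouin(self, rng):
        """Cross-check point estimate and CI against an independent
        implementation of the consistency-form single-measure ICC."""
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        m = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1))
        df = pd.DataFrame(m).stack().reset_index()
        df.columns = ["subject", "occasion", "value"]
        ref = pg.intraclass_corr(df, "subject", "occasion", "value")
        ref = ref[ref["Type"] == "ICC(C,1)"].iloc[0]
        icc, (lo, hi) = icc_3_1(m)
        assert icc == pytest.approx(float(ref["ICC"]), abs=1e-9)
        assert (lo, hi) == pytest.approx(tuple(ref["CI95"]), abs=5e-3)

    def test_rejects_incomplete_cases(self):
        with pytest.raises(InvalidArgumentError):
            icc_3_1([[1.0, np.nan], [2.0, 3.0]])


class TestSemMdc:
    def test_simple_values(self):
        assert sem(2.0, 0.75) == pytest.approx(1.0)
        assert sem(3.0, 1.0) == 0.0

    def test_negative_icc_clamped(self, caplog):
        assert sem(2.0, -0.5) == pytest.approx(2.0)

    def test_icc_above_one_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sem(2.0, 1.5)

    def test_mdc_sem_ratio_is_constant(self):
        for s in (0.0, 0.5, 2.07, 100.0):
            assert mdc95(s) == pytest.approx(MDC95_DEFAULT_Z * np.sqrt(2) * s)
        assert mdc95(1.0) == pytest.approx(2.771808, abs=1e-6)

    def test_pct_mdc(self):
        assert pct_mdc(5.0, 50.0) == pytest.approx(10.0)
        with pytest.raises(UndefinedStatisticError):
            pct_mdc(5.0, 0.0)

    def test_sem_recovers_within_subject_sd(self, rng):
        # 200 subjects, 2 occasions, between SD 2, within SD 1
        subj = rng.normal(0, 2, size=(200, 1))
        m = subj + rng.normal(0, 1, size=(200, 2))
        res = reliability_bundle(m)
        assert res.sem == pytest.approx(1.0, rel=0.10)


class TestEffectSize:
    def test_no_change(self):
        assert effect_size([3.0, 4.0, 5.0], [3.0, 4.0, 5.0]) == 0.0

    def test_forced_arithmetic(self):
        assert effect_size([10, 20, 30], [12, 22, 32]) == pytest.approx(0.2)

    def test_absolute_value(self):
        assert effect_size([12, 22, 32], [10, 20, 30]) == pytest.approx(0.2)

    def test_zero_baseline_sd_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            effect_size([5.0, 5.0], [6.0, 7.0])

    def test_monte_carlo_recovery(self, rng):
        d = 0.7
        first = rng.normal(50, 4, 500)
        second = first + d * 4 + rng.normal(0, 1, 500)
        assert effect_size(first, second) == pytest.approx(d, abs=0.1)


class TestCorrelation:
    def test_perfect_monotone(self, rng):
        x = rng.normal(size=20)
        res = correlate(x, np.exp(x), "spearman")
        assert res.coefficient == pytest.approx(1.0)
        assert res.munro_class == "very_high"

    def test_antimonotone(self, rng):
        x = rng.normal(size=20)
        assert correlate(x, -x, "spearman").coefficient == pytest.approx(-1.0)

    def test_symmetry(self, rng):
        x, y = rng.normal(size=(2, 30))
        assert correlate(x, y).coefficient == pytest.approx(
            correlate(y, x).coefficient
        )

    @pytest.mark.parametrize(
        "r,label",
        [
            (0.10, "little"),
            (0.25, "little"),
            (0.26, "low"),
            (-0.48, "low"),
            (0.50, "moderate"),
            (0.69, "moderate"),
            (0.70, "high"),
            (-0.89, "high"),
            (0.90, "very_high"),
            (1.00, "very_high"),
            (0.2549, "little"),  # rounds to 0.25
            (0.695, "high"),  # rounds to 0.70
        ],
    )
    def test_munro_bands(self, r, label):
        assert munro_class(r) == label

    @pytest.mark.parametrize(
        "transform", [np.exp, lambda v: 2 * v + 1, lambda v: v**3]
    )
    def test_spearman_monotone_invariance(self, rng, transform):
        x, y = rng.normal(size=(2, 40))
        base = correlate(x, y, "spearman").coefficient
        assert correlate(transform(x), y, "spearman").coefficient == pytest.approx(
            base
        )

    def test_constant_input_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestAnova:
    def test_balanced_design_type2_equals_type1(self, rng):
        import pandas as pd
        import statsmodels.api as sm_api
        from statsmodels.formula.api import ols

        vision = ["OE", "CE"] * 20
        support = ["OF"] * 20 + ["CF"] * 20
        values = rng.normal(size=40) + (np.array(vision) == "CE") * 2.0
        res = anova_vision_support(values, vision, support)
        df = pd.DataFrame({"value": values, "vision": vision, "support": support})
        t1 = sm_api.stats.anova_lm(
            ols("value ~ C(vision) * C(support)", df).fit(), typ=1
        )
        assert res.f_vision == pytest.approx(float(t1.loc["C(vision)", "F"]))
        assert res.f_support == pytest.approx(float(t1.loc["C(support)", "F"]))

    def test_null_calibration(self, rng):
        """Under independence the vision p-value is uniform: the rejection
        rate at alpha = 0.05 stays within 0.05 +/- 0.02 over 1000 draws."""
        hits = 0
        reps = 1000
        vision = np.array(["OE", "CE"] * 10)
        support = np.array(["OF", "OF", "CF", "CF"] * 5)
        for _ in range(reps):
            res = anova_vision_support(rng.normal(size=20), vision, support)
            hits += res.p_vision < 0.05
        assert abs(hits / reps - 0.05) <= 0.02

    def test_strong_vision_effect_detected(self, rng):
        vision = np.array(["OE", "CE"] * 30)
        support = np.array(["OF"] * 30 + ["CF"] * 30)
        values = rng.normal(size=60) + (vision == "CE") * 3.0
        res = anova_vision_support(values, vision, support)
        assert res.p_vision < 0.001
        assert res.p_support > 0.05

    def test_empty_cell_rejected(self):
        with pytest.raises(InvalidArgumentError):
            anova_vision_support(
                [1.0, 2.0, 3.0], ["OE", "OE", "CE"], ["OF", "OF", "OF"]
            )
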