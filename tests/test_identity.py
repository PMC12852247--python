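import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vocalid.identity import (
    bonferroni_threshold,
    calc_pic,
    corrected_cv,
    kmo_overall,
    ols_trend,
    pic_by_age_class,
)


def cv_oracle(values):
    """Independent hand formula: (SD/|mean|) * (1 + 1/(4n))."""
    v = np.asarray(values, float)
    n = len(v)
    sd = math.sqrt(sum((x - v.mean()) ** 2 for x in v) / (n - 1))
    return sd / abs(v.mean()) * (1 + 1 / (4 * n))


class TestCorrectedCV:
    def test_zero_variance(self):
        assert corrected_cv([5, 5, 5]) == 0.0

    def test_hand_example(self):
        # SD = sqrt(2), mean = 3, correction 1 + 1/8 = 1.125
        assert corrected_cv([2, 4]) == pytest.approx(math.sqrt(2) / 3 * 1.125, abs=1e-12)
        assert corrected_cv([2, 4]) == pytest.approx(0.5303, abs=5e-5)

    def test_zero_mean_raises(self):
        with pytest.raises(ValueError, match="zero mean"):
            corrected_cv([0, 0])
        with pytest.raises(ValueError, match="zero mean"):
            corrected_cv([-1, 1])

    def test_n_below_two_raises(self):
        with pytest.raises(ValueError):
            corrected_cv([1.0])

    def test_negative_mean_uses_absolute(self):
        assert corrected_cv([-2, -4]) == corrected_cv([2, 4])

    @settings(max_examples=50)
    @given(st.lists(st.floats(1, 100), min_size=2, max_size=20))
    def test_matches_oracle(self, values):
        assert corrected_cv(values) == pytest.approx(cv_oracle(values), rel=1e-10)


class TestCalcPIC:
    def test_hand_example(self):
        # pooled CV = 0.41707..., mean within CV = 0.11932...
        pic = calc_pic([9, 11, 19, 21], ["A", "A", "B", "B"])
        expected = cv_oracle([9, 11, 19, 21]) / np.mean(
            [cv_oracle([9, 11]), cv_oracle([19, 21])]
        )
        assert pic == pytest.approx(expected, rel=1e-12)
        assert pic == pytest.approx(3.495, abs=1e-3)

    def test_degenerate_zero_within_variance(self, caplog):
        with caplog.at_level("WARNING"):
            pic = calc_pic([1, 1, 2, 2], ["A", "A", "B", "B"])
        assert math.isinf(pic)
        assert "infinite" in caplog.text

    def test_single_individual_raises(self):
        with pytest.raises(ValueError, match="2 individuals"):
            calc_pic([1, 2, 3], ["A", "A", "A"])

    def test_individual_with_one_call_raises(self):
        with pytest.raises(ValueError, match="fewer than 2 calls"):
            calc_pic([1, 2, 3], ["A", "A", "B"])

    def test_null_distribution_pic_near_one(self):
        rng = np.random.default_rng(11)
        values = rng.normal(50, 5, size=250)
        groups = np.repeat([f"i{k}" for k in range(5)], 50)
        assert calc_pic(values, groups) == pytest.approx(1.0, abs=0.1)

    @settings(max_examples=30)
    @given(k=st.floats(0.01, 100))
    def test_scale_invariance(self, k):
        v = np.array([9.0, 11.0, 19.0, 21.0, 14.0, 16.0])
        g = ["A", "A", "B", "B", "C", "C"]
        assert calc_pic(v * k, g) == pytest.approx(calc_pic(v, g), rel=1e-9)

    def test_monotone_in_separation(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, 40)
        g = np.repeat(["A", "B", "C", "D"], 10)
        offsets = {"A": 0.0, "B": 1.0, "C": 2.0, "D": 3.0}
        prev = None
        for sep in (0.0, 0.5, 1.0, 2.0, 4.0):
            v = 100 + base + sep * np.vectorize(offsets.get)(g)
            pic = calc_pic(v, g)
            if prev is not None:
                assert pic >= prev - 1e-9
            prev = pic


class TestOLSTrend:
    def test_hand_slope(self):
        fit = ols_trend([1, 2, 2, 3], [1, 2, 3, 4])
        assert fit.slope == pytest.approx(0.6, abs=1e-12)

    def test_matches_closed_form(self):
        x = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
        y = np.array([2.0, 2.5, 4.5, 6.0, 10.5])
        fit = ols_trend(y, x)
        # closed-form slope/p via normal equations and the t distribution
        from scipy import stats as ss

        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * x.mean()
        resid = y - intercept - slope * x
        se = math.sqrt(np.sum(resid**2) / (len(x) - 2) / sxx)
        p = 2 * ss.t.sf(abs(slope / se), df=len(x) - 2)
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.p == pytest.approx(p, rel=1e-10)
        assert fit.stderr == pytest.approx(se, rel=1e-10)

    def test_exact_fit_flagged(self):
        fit = ols_trend([3, 5, 7, 9, 11], [1, 2, 3, 4, 5])
        assert fit.slope == pytest.approx(2.0)
        assert fit.exact_fit
        assert 0 < fit.p < 1e-300

    def test_constant_x_raises(self):
        with pytest.raises(ValueError, match="constant"):
            ols_trend([1, 2, 3], [5, 5, 5])

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError, match="3 points"):
            ols_trend([1, 2], [1, 2])


def partial_correlation_oracle(X, i, j):
    """Brute-force partial correlation of columns i, j controlling for the
    rest, via OLS residuals."""
    others = [k for k in range(X.shape[1]) if k not in (i, j)]
    Z = np.column_stack([np.ones(len(X))] + [X[:, k] for k in others])
    ri = X[:, i] - Z @ np.linalg.lstsq(Z, X[:, i], rcond=None)[0]
    rj = X[:, j] - Z @ np.linalg.lstsq(Z, X[:, j], rcond=None)[0]
    return np.corrcoef(ri, rj)[0, 1]


class TestKMO:
    def test_two_variables_always_half(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.normal(size=100)
            y = 0.5 * x + rng.normal(size=100)
            assert kmo_overall(np.column_stack([x, y])) == pytest.approx(0.5, abs=1e-12)

    def test_three_variable_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 3))
        X[:, 1] += 0.6 * X[:, 0]
        X[:, 2] += 0.3 * X[:, 0] - 0.4 * X[:, 1]
        R = np.corrcoef(X, rowvar=False)
        r2 = q2 = 0.0
        for i in range(3):
            for j in range(3):
                if i != j:
                    r2 += R[i, j] ** 2
                    q2 += partial_correlation_oracle(X, i, j) ** 2
        assert kmo_overall(X) == pytest.approx(r2 / (r2 + q2), abs=1e-10)

    def test_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            X = rng.normal(size=(50, 4))
            assert 0 <= kmo_overall(X) <= 1

    def test_zero_variance_column_raises(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            kmo_overall(X)

    def test_too_few_rows_raises(self):
        with pytest.raises(ValueError):
            kmo_overall(np.ones((2, 3)))


class TestBonferroni:
    @pytest.mark.parametrize("m,rounded", [(8, 0.006), (7, 0.007), (1, 0.05)])
    def test_reported_thresholds(self, m, rounded):
        thr = bonferroni_threshold(0.05, m)
        assert thr.rounded == rounded
        assert thr.raw == pytest.approx(0.05 / m, rel=1e-15)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 4)


class TestPICByAgeClass:
    @pytest.fixture()
    def calls(self):
        from conftest import make_separated_config
        from vocalid.dissimilarity import assign_age_class
        from vocalid.synthetic import generate_dataset

        cfg = make_separated_config(31, calls_per_day=4)
        cfg.age_range_days = (11, 45)
        df = generate_dataset(cfg)
        df["age_class"] = df["age_days"].map(assign_age_class)
        return df

    def test_pooled_shape(self, calls):
        table = pic_by_age_class(calls, contexts=[])
        pooled = table[table.context == "pooled"]
        assert len(pooled) == 5 * 8
        assert pooled["pic"].notna().all()

    def test_trend_columns_present(self, calls):
        table = pic_by_age_class(calls, contexts=["beg"])
        assert {"trend_slope", "trend_p"} <= set(table.columns)
        pooled = table[(table.context == "pooled") & (table.parameter == "duration")]
        assert pooled["trend_p"].nunique() == 1

    def test_targeted_offset_dominates(self):
        # individual offsets only in duration -> duration PIC far above others
        from conftest import make_null_config
        from vocalid.dissimilarity import assign_age_class
        from vocalid.synthetic import generate_dataset

        cfg = make_null_config(32, calls_per_day=6)
        cfg.age_range_days = (11, 45)
        offset = np.zeros(8)
        offset[0] = 0.4
        cfg.offset_sd = offset
        df = generate_dataset(cfg)
        df["age_class"] = df["age_days"].map(assign_age_class)
        table = pic_by_age_class(df, contexts=[])
        pooled = table[table.context == "pooled"].set_index("parameter")
        dur = pooled.loc["duration", "pic"].mean()
        rest = pooled.drop("duration")["pic"].mean()
        assert dur > 2 * rest

    def test_single_individual_stratum_missing(self, caplog):
        df = pd.DataFrame(
            {
                "individual": ["A"] * 4,
                "context": ["beg"] * 4,
                "age_class": ["11–17"] * 4,
                **{c: np.random.default_rng(0).normal(10, 1, 4) for c in ["duration"]},
            }
        )
        with caplog.at_level("INFO"):
            table = pic_by_age_class(df, parameters=["duration"], contexts=[])
        assert table["pic"].isna().all()
        assert "fewer than 2 individuals" in caplog.text

    def test_missing_age_class_column_raises(self):
        with pytest.raises(ValueError, match="age_class"):
            pic_by_age_class(pd.DataFrame({"individual": [], "context": []}))
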