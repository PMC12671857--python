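"""Statistical battery vs brute-force enumeration oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ighvstrat.association import (
    ComparisonVariable,
    bonferroni,
    fisher_exact,
    format_percent,
    group_comparison_table,
    mann_whitney,
    percent,
    scaled_regression,
    spearman,
)
from ighvstrat.errors import MissingDataError, UndefinedStatisticError


def mw_permutation_oracle(a, b):
    """Exact two-sided p by enumerating all group assignments."""
    pooled = np.concatenate([a, b])
    na = len(a)
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    obs = ranks[:na].sum()
    mean = na * (len(pooled) + 1) / 2
    stats = [
        abs(sum(ranks[list(idx)]) - mean)
        for idx in itertools.combinations(range(len(pooled)), na)
    ]
    return np.mean([s >= abs(obs - mean) - 1e-9 for s in stats])


def fisher_enumeration_oracle(table):
    """Sum hypergeometric probabilities <= that of the observed table."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestSpearman:
    def test_monotone_invariance(self):
        x = np.array([1.0, 2.0, 5.0, 7.0, 11.0])
        rho, _ = spearman(x, x**3)
        assert rho == pytest.approx(1.0)

    def test_reverse(self):
        x = np.arange(6.0)
        rho, _ = spearman(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        rho, p = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)  # 1 - 6*4 / (4*15)
        # exact permutation p: 10 of 24 permutations have |rho| >= 0.6
        assert p == pytest.approx(10 / 24)

    def test_pairwise_complete_deletion(self):
        x = [1, 2, 3, 4, np.nan]
        y = [2, 1, 4, 3, 9]
        assert spearman(x, y)[0] == pytest.approx(0.6)

    def test_constant_vector_is_error(self):
        with pytest.raises(UndefinedStatisticError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 5_000))
    def test_strictly_increasing_transform_gives_one(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.choice(100, size=8, replace=False).astype(float)
        rho, _ = spearman(x, np.arctan(x) + 3)
        assert rho == pytest.approx(1.0)


class TestMannWhitney:
    def test_separated_toy_exact(self):
        U, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert U == 0.0
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_samples_null_centre(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.9

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 5_000))
    def test_matches_permutation_oracle_small_n(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(2, 5), rng.integers(2, 6)
        pool = rng.choice(1000, size=na + nb, replace=False) / 10.0
        a, b = pool[:na], pool[na:]
        _, p = mann_whitney(a, b)
        assert p == pytest.approx(mw_permutation_oracle(a, b), abs=1e-9)


class TestFisherExact:
    def test_worked_example(self):
        assert fisher_exact([[3, 1], [1, 3]]) == pytest.approx(0.4857, abs=5e-5)

    def test_zero_margin_gives_one(self):
        assert fisher_exact([[0, 0], [3, 5]]) == pytest.approx(1.0)

    def test_extreme_table_matches_enumeration(self):
        t = [[10, 0], [0, 10]]
        assert fisher_exact(t) == pytest.approx(fisher_enumeration_oracle(t), rel=1e-9)

    def test_negative_count_is_error(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [2, 3]])

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 5_000))
    def test_matches_enumeration_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 8, size=(2, 2))
        if t.sum() == 0:
            t[0, 0] = 1
        assert fisher_exact(t.tolist()) == pytest.approx(
            fisher_enumeration_oracle(t.tolist()), rel=1e-7
        )


class TestBonferroni:
    def test_elementwise_and_cap(self):
        assert bonferroni([0.01], 5)[0] == pytest.approx(0.05)
        assert bonferroni([0.5], 3)[0] == 1.0
        assert np.allclose(bonferroni([0.001, 0.02, 0.04], 3), [0.003, 0.06, 0.12])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2], 2)

    def test_family_smaller_than_vector_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2, 0.3], 2)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8), st.integers(8, 40))
    def test_adjusted_never_below_raw_and_monotone_in_m(self, ps, m):
        adj = bonferroni(ps, m)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(bonferroni(ps, m + 5) >= adj - 1e-15)


class TestScaledRegression:
    def test_noise_free_recovery(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(
            rng.normal(size=(50, 5)), columns=["NAIVE", "USM", "SM", "DN", "PB"]
        )
        y = 0.5 * X["USM"] - 0.2 * X["NAIVE"]
        out = scaled_regression(y.rename("lab"), X)
        est = out.set_index("predictor").estimate
        # standardized truth: beta_j * sd_xj / sd_y
        sd_y = y.std(ddof=1)
        assert est["USM"] == pytest.approx(0.5 * X["USM"].std(ddof=1) / sd_y, abs=1e-10)
        assert est["NAIVE"] == pytest.approx(-0.2 * X["NAIVE"].std(ddof=1) / sd_y, abs=1e-10)
        assert est[["SM", "DN", "PB"]].abs().max() < 1e-10
        assert np.all(out.ci_low <= out.estimate) and np.all(out.estimate <= out.ci_high)

    def test_permuted_outcome_ci_covers_zero(self):
        """Null calibration: CIs cover 0 close to nominally 95% of the time."""
        rng = np.random.default_rng(42)
        cover = 0
        reps = 500
        for _ in range(reps):
            X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["USM", "NAIVE"])
            y = pd.Series(rng.normal(size=30), name="lab")
            row = scaled_regression(y, X).iloc[0]
            cover += row.ci_low <= 0 <= row.ci_high
        assert cover / reps == pytest.approx(0.95, abs=0.03)

    def test_too_few_cases(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(8, 2)), columns=list("ab"))
        with pytest.raises(MissingDataError):
            scaled_regression(pd.Series(np.arange(8.0)), X)

    def test_collinear_design_names_columns(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"USM": rng.normal(size=20)})
        X["COPY"] = X["USM"] * 2.0
        with pytest.raises(ValueError, match="USM~COPY"):
            scaled_regression(pd.Series(rng.normal(size=20), name="y"), X)


class TestGroupComparisonTable:
    def _data(self):
        rng = np.random.default_rng(5)
        n = 40
        df = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "esr": rng.normal(20, 8, n),
                "item_arthritis": rng.random(n) < 0.3,
            }
        )
        df.loc[3, "esr"] = np.nan
        groups = {f"P{i}": ("HIGH" if i < 22 else "LOW") for i in range(n)}
        return df, groups

    def test_rows_typed_and_adjusted(self):
        df, groups = self._data()
        out = group_comparison_table(
            df,
            groups,
            [
                ComparisonVariable("ESR", "continuous", "esr"),
                ComparisonVariable("arthritis", "categorical", "item_arthritis"),
            ],
        )
        assert list(out.test) == ["mann_whitney", "fisher"]
        assert np.all(out.p_adj >= out.p_raw - 1e-15)
        assert np.allclose(out.p_adj, np.minimum(1, 2 * out.p_raw))

    def test_denominators_exclude_missing(self):
        df, groups = self._data()
        df["item_arthritis"] = df["item_arthritis"].astype(object)
        df.loc[0, "item_arthritis"] = np.nan  # patient 0 is HIGH
        out = group_comparison_table(
            df, groups, [ComparisonVariable("arthritis", "categorical", "item_arthritis")]
        )
        n_high = int(out.summary_high.iloc[0].split("(")[0])
        k = df.loc[1:21, "item_arthritis"].sum()
        assert n_high == int(k)
        # percentage uses the 21 non-missing HIGH patients
        assert format_percent(int(k), 21) in out.summary_high.iloc[0]

    def test_absent_variable_skipped_with_warning(self):
        df, groups = self._data()
        with pytest.warns(UserWarning, match="nope"):
            out = group_comparison_table(
                df, groups, [ComparisonVariable("nope", "categorical")]
            )
        assert out.empty


class TestPercentFormatting:
    @pytest.mark.parametrize(
        "k, n, expected",
        [
            (49, 80, "61.3"),
            (28, 80, "35.0"),
            (34, 49, "69.4"),
            (4, 49, "8.16"),
            (2, 49, "4.08"),
            (1, 49, "2.04"),
            (17, 80, "21.3"),
            (23, 80, "28.8"),
            (12, 80, "15.0"),
            (39, 80, "48.8"),
            (23, 76, "30.3"),
            (80, 80, "100"),
            (0, 49, "0.00"),
            (6, 80, "7.50"),
            (5, 80, "6.25"),
            (1, 80, "1.25"),
        ],
    )
    def test_report_precision(self, k, n, expected):
        assert format_percent(k, n) == expected

    def test_percent_is_numeric_half_up(self):
        assert percent(49, 80) == 61.3  # 61.25 rounds up
        assert percent(17, 80) == 21.3  # 21.25 rounds up
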