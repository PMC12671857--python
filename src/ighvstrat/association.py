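"""Statistical battery linking usage to clinical variables.

Continuous variables are compared with the Mann-Whitney test, categorical
variables with Fisher's exact test, correlations use Spearman's rank
correlation, multiplicity is handled by Bonferroni correction, and the
joint relation of a clinical outcome to the five subset usages is
estimated by multiple linear regression on z-scaled data.

scipy.stats provides the underlying test machinery; the wrappers here pin
down method selection (exact vs asymptotic) and the missing-data policy,
and every wrapper is checked against brute-force enumeration oracles in
the test suite.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import MissingDataError, UndefinedStatisticError

__all__ = [
    "spearman",
    "mann_whitney",
    "fisher_exact",
    "bonferroni",
    "scaled_regression",
    "RegressionEstimate",
    "ComparisonVariable",
    "ComparisonRow",
    "group_comparison_table",
    "format_percent",
    "percent",
]

_EXACT_MW_MAX_N = 10  # pooled size up to which the exact MW null is used
_EXACT_SPEARMAN_MAX_N = 9  # full n! permutation enumeration up to here


def _clean_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties.

    Missing values are removed pairwise. For n <= 9 the p-value is exact,
    from full enumeration of all n! rank permutations; for larger n the
    t-approximation is used.
    """
    x, y = _clean_pairs(x, y)
    n = len(x)
    if n < 3:
        raise MissingDataError(f"need >=3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("Spearman rho undefined for a constant vector")
    rho, p_t = stats.spearmanr(x, y)
    rho = float(rho)
    if n <= _EXACT_SPEARMAN_MAX_N:
        rx = stats.rankdata(x) - (n + 1) / 2
        ry = stats.rankdata(y) - (n + 1) / 2
        perms = np.array(list(itertools.permutations(range(n))))
        rho_perm = (ry[perms] @ rx) / (np.linalg.norm(rx) * np.linalg.norm(ry))
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
    else:
        p = float(p_t)
    return rho, p


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when the pooled sample size is <= 10 and there
    are no ties; otherwise the normal approximation with tie correction.
    Returns (U of the first sample, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise UndefinedStatisticError("Mann-Whitney needs two non-empty samples")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= _EXACT_MW_MAX_N and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Two-sided by summing hypergeometric probabilities <= that of the
    observed table.
    """
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {table.shape}")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if not np.issubdtype(table.dtype, np.integer):
        as_int = table.astype(int)
        if not np.array_equal(as_int, table):
            raise ValueError("counts must be integers")
        table = as_int
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m * p).

    ``m`` defaults to the length of the vector and must be at least that
    length (a family can be wider than the tests reported, never narrower).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"family size m={m} smaller than number of p-values {p.size}")
    return np.minimum(1.0, m * p)


@dataclass(frozen=True)
class RegressionEstimate:
    """One standardized coefficient from the joint usage regression."""

    outcome: str
    predictor: str
    estimate: float
    ci_low: float
    ci_high: float
    p: float


def _zscale(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def scaled_regression(outcome: pd.Series, predictors: pd.DataFrame) -> pd.DataFrame:
    """OLS of a z-scaled outcome on jointly z-scaled predictors.

    Complete-case deletion; at least 10 complete cases are required.
    Returns one row per predictor with the standardized coefficient, its
    95% CI from the t distribution, and the p-value. A rank-deficient
    design raises an error naming the collinear columns.
    """
    df = pd.concat([outcome.rename("__y__"), predictors], axis=1).dropna()
    if len(df) < 10:
        raise MissingDataError(
            f"scaled regression needs >=10 complete cases, got {len(df)}"
        )
    y = df["__y__"].to_numpy(dtype=float)
    X = df[predictors.columns].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise UndefinedStatisticError("outcome is constant")
    constant = [c for c, col in zip(predictors.columns, X.T) if np.ptp(col) == 0]
    if constant:
        raise ValueError(f"collinear (constant) predictor columns: {', '.join(constant)}")
    Xs = np.column_stack([_zscale(col) for col in X.T])
    if np.linalg.matrix_rank(Xs) < Xs.shape[1]:
        corr = np.corrcoef(Xs, rowvar=False)
        pairs = [
            f"{a}~{b}"
            for (i, a), (j, b) in itertools.combinations(enumerate(predictors.columns), 2)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {', '.join(pairs)}")
    fit = sm.OLS(_zscale(y), sm.add_constant(Xs)).fit()
    ci = fit.conf_int(alpha=0.05)
    name = outcome.name if outcome.name is not None else "outcome"
    rows = [
        RegressionEstimate(
            outcome=str(name),
            predictor=str(col),
            estimate=float(fit.params[i + 1]),
            ci_low=float(ci[i + 1, 0]),
            ci_high=float(ci[i + 1, 1]),
            p=float(fit.pvalues[i + 1]),
        )
        for i, col in enumerate(predictors.columns)
    ]
    return pd.DataFrame([r.__dict__ for r in rows])


# --------------------------------------------------------------------------
# Group comparison report (Table-1/Table-2 style)
# --------------------------------------------------------------------------


def percent(k: int, n: int) -> float:
    """Within-group percentage at report precision.

    One decimal place at >= 10%, two decimal places (three significant
    figures) below 10%, with half-up rounding — the convention used in
    clinical cohort tables.
    """
    if n <= 0:
        raise ValueError("denominator must be positive")
    p = Decimal(100 * k) / Decimal(n)
    q = Decimal("0.1") if p >= 10 else Decimal("0.01")
    return float(p.quantize(q, rounding=ROUND_HALF_UP))


def format_percent(k: int, n: int) -> str:
    p = percent(k, n)
    if p >= 99.95:
        return "100"
    return f"{p:.1f}" if p >= 10 else f"{p:.2f}"


def _fmt_num(v: float) -> str:
    return f"{v:.3g}"


@dataclass(frozen=True)
class ComparisonVariable:
    """Declares how one clinical variable is summarized and tested."""

    name: str
    kind: str  # "continuous" -> Mann-Whitney; "categorical" -> Fisher exact
    column: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown variable kind: {self.kind!r}")


@dataclass(frozen=True)
class ComparisonRow:
    variable: str
    summary_high: str
    summary_low: str
    test: str
    p_raw: float
    p_adj: float


def group_comparison_table(
    clinical: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    variables: Sequence[ComparisonVariable],
    m: int | None = None,
) -> pd.DataFrame:
    """High- vs low-group comparison battery.

    Continuous rows report median (IQR) per group with a Mann-Whitney p;
    categorical rows report n (%) with group-specific non-missing
    denominators and a Fisher exact p. The Bonferroni family size defaults
    to the number of rows actually tested and is echoed via the p_adj
    column. Variables absent from the clinical table are skipped with a
    warning.
    """
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    df = clinical.copy()
    if "patient_id" in df.columns:
        df = df.set_index("patient_id")
    df = df.loc[df.index.intersection(groups.index)]
    grp = groups.reindex(df.index)

    rows: list[ComparisonRow] = []
    for var in variables:
        col = var.column or var.name
        if col not in df.columns:
            warnings.warn(f"variable {var.name!r} absent from clinical table; skipped",
                          stacklevel=2)
            continue
        hi = df.loc[grp == "HIGH", col]
        lo = df.loc[grp == "LOW", col]
        if var.kind == "continuous":
            hi_v, lo_v = hi.dropna(), lo.dropna()
            _, p = mann_whitney(hi_v, lo_v)
            summaries = [
                f"{_fmt_num(v.median())} ({_fmt_num(v.quantile(0.25))}, "
                f"{_fmt_num(v.quantile(0.75))})"
                for v in (hi_v, lo_v)
            ]
            test = "mann_whitney"
        else:
            hi_v, lo_v = hi.dropna().astype(bool), lo.dropna().astype(bool)
            k_h, n_h = int(hi_v.sum()), len(hi_v)
            k_l, n_l = int(lo_v.sum()), len(lo_v)
            p = fisher_exact([[k_h, n_h - k_h], [k_l, n_l - k_l]])
            summaries = [
                f"{k_h} ({format_percent(k_h, n_h)})",
                f"{k_l} ({format_percent(k_l, n_l)})",
            ]
            test = "fisher"
        rows.append(ComparisonRow(var.name, summaries[0], summaries[1], test, p, np.nan))

    family = m if m is not None else len(rows)
    p_adj = bonferroni([r.p_raw for r in rows], family)
    out = pd.DataFrame([r.__dict__ for r in rows])
    if len(out):
        out["p_adj"] = p_adj
    return out
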