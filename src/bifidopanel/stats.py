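"""Univariate statistics of the cohort analysis.

Group comparisons use the bilateral Wilcoxon rank-sum (Mann-Whitney)
test without any correction for multiplicity, sex-by-group independence
a Pearson chi-square test, and association structure Spearman's rho.
Zero abundances are treated as true zeros (tied ranks), not as missing
values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison", "CorrelationMatrix", "DemographicSummary",
    "rank_sum_test", "pairwise_group_tests", "chi_square_independence",
    "spearman", "correlation_matrix", "autoscale", "demographic_summary",
    "lv_association",
]

#: switch to the exact null distribution at or below this combined n
EXACT_MAX_N = 12


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    significant: bool


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    The exact permutation null is used when the combined sample size is
    at most 12 and there are no ties; otherwise the normal approximation
    with tie and continuity corrections. Returns ``(U, p)`` with U the
    Mann-Whitney statistic of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank-sum test requires two non-empty samples")
    combined = np.concatenate([x, y])
    if np.unique(combined).size == 1:
        # every observation tied: no evidence of a shift in either direction
        return float(x.size * y.size / 2.0), 1.0
    tie_free = np.unique(combined).size == combined.size
    method = "exact" if tie_free and combined.size <= EXACT_MAX_N else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def pairwise_group_tests(
    table: pd.DataFrame,
    variables: list[str],
    groups: list[str] | None = None,
    *,
    group_col: str = "group",
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Rank-sum tests for every variable over every unordered group pair.

    No multiplicity correction is applied by default, matching the study
    analysis; ``fdr=True`` adds a Benjamini-Hochberg adjusted column
    ``p_adjusted`` without changing the ``significant`` flag, which is
    always the raw p against ``alpha``.
    """
    present = list(dict.fromkeys(table[group_col]))
    if groups is None:
        groups = present
    unknown = sorted(set(groups) - set(present))
    if unknown:
        raise ValueError(f"group label(s) {unknown} not present in column {group_col!r}")
    if len(groups) < 2:
        raise ValueError("at least two groups are required")

    rows = []
    for var in variables:
        for a, b in itertools.combinations(groups, 2):
            xa = table.loc[table[group_col] == a, var].dropna().to_numpy()
            xb = table.loc[table[group_col] == b, var].dropna().to_numpy()
            stat, p = rank_sum_test(xa, xb)
            rows.append(GroupComparison(var, a, b, stat, p, len(xa), len(xb), p < alpha))
    out = pd.DataFrame([r.__dict__ for r in rows])
    if fdr:
        out["p_adjusted"] = sps.false_discovery_control(out["p_value"], method="bh")
    return out


def chi_square_independence(contingency) -> tuple[float, float]:
    """Pearson chi-square test of independence on a counts table.

    No continuity correction, so degenerate-free tables give the
    textbook statistic with (rows-1)(cols-1) degrees of freedom.
    """
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or (table < 0).any():
        raise ValueError("contingency table must be a 2-D array of non-negative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has an empty row or column margin")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    Rho is the Pearson correlation of mid-ranks; constant input makes
    rho undefined and is rejected rather than silently returned as 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("Spearman correlation requires at least 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("Spearman correlation is undefined for constant input")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class CorrelationMatrix:
    """Spearman correlation structure over a variable set.

    ``rho`` and ``p`` are square DataFrames indexed by ``variables``;
    cells with fewer than 3 pairwise-complete observations (or a
    constant variable) are NaN in both.
    """

    variables: tuple[str, ...]
    rho: pd.DataFrame
    p: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        rows = []
        for a in self.variables:
            for b in self.variables:
                rows.append((a, b, self.rho.loc[a, b], self.p.loc[a, b]))
        return pd.DataFrame(rows, columns=["variable_a", "variable_b", "rho", "p_value"])


def correlation_matrix(table: pd.DataFrame, variables: list[str]) -> CorrelationMatrix:
    """Pairwise Spearman matrix over ``variables`` of ``table``.

    Missing values are handled pairwise-complete; zeros are ordinary
    tied values. The diagonal is exactly 1 with p 0.
    """
    k = len(variables)
    rho = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        rho[i, i], p[i, i] = 1.0, 0.0
        for j in range(i + 1, k):
            pair = table[[variables[i], variables[j]]].dropna()
            if len(pair) < 3:
                continue
            xi = pair.iloc[:, 0].to_numpy()
            xj = pair.iloc[:, 1].to_numpy()
            if np.unique(xi).size == 1 or np.unique(xj).size == 1:
                continue
            rho[i, j], p[i, j] = spearman(xi, xj)
            rho[j, i], p[j, i] = rho[i, j], p[i, j]
    idx = list(variables)
    return CorrelationMatrix(
        variables=tuple(variables),
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
    )


def autoscale(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Scale every column to zero mean and unit variance (n-1 denominator).

    Returns the scaled table plus the means and scales needed to apply
    the same transform to new data. Zero-variance columns are rejected
    by name.
    """
    means = table.mean()
    scales = table.std(ddof=1)
    dead = scales.index[(scales == 0) | scales.isna()].tolist()
    if dead:
        raise ValueError(f"zero-variance column(s) cannot be autoscaled: {dead}")
    return (table - means) / scales, means, scales


@dataclass(frozen=True)
class DemographicSummary:
    """Per-group counts and mean +/- SD demographics."""

    table: pd.DataFrame

    def __str__(self) -> str:
        return self.table.to_string(index=False)


def demographic_summary(participants: pd.DataFrame) -> DemographicSummary:
    """Per-group male/female counts, male %, and mean +/- SD of age, BMI
    and (where assayed) HbA1c; percentages rounded to one decimal."""
    if participants.empty:
        raise ValueError("participants table is empty")
    rows = []
    for group, sub in participants.groupby("group", sort=False):
        if sub.empty:
            raise ValueError(f"group {group!r} is empty")
        m = int((sub["sex"] == "M").sum())
        f = int((sub["sex"] == "F").sum())
        row = {
            "group": group,
            "male": m,
            "female": f,
            "male_pct": round(100.0 * m / (m + f), 1),
            "age_mean": float(sub["age"].mean()),
            "age_sd": float(sub["age"].std(ddof=1)) if len(sub) > 1 else 0.0,
            "bmi_mean": float(sub["bmi"].mean()),
            "bmi_sd": float(sub["bmi"].std(ddof=1)) if len(sub) > 1 else 0.0,
        }
        hba1c = sub["hba1c"].dropna() if "hba1c" in sub else pd.Series(dtype=float)
        row["hba1c_mean"] = float(hba1c.mean()) if len(hba1c) else np.nan
        row["hba1c_sd"] = float(hba1c.std(ddof=1)) if len(hba1c) > 1 else np.nan
        rows.append(row)
    return DemographicSummary(pd.DataFrame(rows))


def lv_association(model, covariate) -> tuple[float, float]:
    """Spearman association between LV1 scores and a per-sample covariate
    (e.g. BMI), the validation check for a fitted PLS-DA model."""
    scores = np.asarray(model.x_scores)[:, 0]
    covariate = np.asarray(covariate, dtype=float)
    if covariate.size != scores.size:
        raise ValueError(
            f"covariate length {covariate.size} != number of samples {scores.size}"
        )
    return spearman(scores, covariate)
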