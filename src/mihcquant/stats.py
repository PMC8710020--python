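"""Non-survival statistics: Spearman correlations, Welch t, simple OLS.

Densities enter the tests untransformed by default (a log1p option is
exposed for the right-skew of density variables). No multiplicity
adjustment is applied anywhere; significance is flagged at unadjusted
p < 0.05.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps


class UndefinedCorrelationError(ValueError):
    """Constant (zero rank-variance) input: correlation undefined."""


class UntestableError(ValueError):
    """Group sizes or variances do not admit the test."""


class SingularFitError(ValueError):
    """Constant regressor: least squares is singular."""


@dataclass
class CorrelationResult:
    variable_pair: Tuple[str, str]
    rho: float
    p_value: float
    n: int


@dataclass
class GroupComparison:
    variable: str
    groups: Tuple[str, str]
    means: Tuple[float, float]
    t_statistic: float
    degrees_of_freedom: float
    p_value: float


def _pairwise_complete(x, y) -> Tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def spearman(x, y, names: Tuple[str, str] = ("x", "y"),
             method: str = "t") -> CorrelationResult:
    """Spearman rank correlation with mid-rank (average) tie handling.

    p-value from the t-approximation with n-2 df (method="t"), or from
    exact enumeration of all rank permutations for n <= 10
    (method="exact"); missing values are dropped pairwise.
    """
    x, y = _pairwise_complete(x, y)
    n = x.size
    if n < 4:
        raise ValueError(f"need >= 4 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant vector: rank correlation undefined")
    rho, p = sps.spearmanr(x, y)
    if not np.isfinite(rho):
        raise UndefinedCorrelationError("rank correlation undefined for these data")
    if method == "exact":
        if n > 10:
            raise ValueError("exact permutation p only supported for n <= 10")
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        rx_c = rx - rx.mean()
        denom = np.sqrt((rx_c ** 2).sum())
        ry_c = ry - ry.mean()
        ry_norm = ry_c / np.sqrt((ry_c ** 2).sum())
        for perm in itertools.permutations(range(n)):
            r = abs(np.dot(rx_c[list(perm)], ry_norm) / denom)
            count += r >= obs - 1e-12
            total += 1
        p = count / total
    elif method != "t":
        raise ValueError(f"unknown p-value method {method!r}")
    p = float(min(max(p, np.finfo(float).tiny), 1.0))
    return CorrelationResult(variable_pair=names, rho=float(rho), p_value=p, n=n)


def correlation_matrix(table: pd.DataFrame, variables: Sequence[str],
                       alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs Spearman correlations as a long-format table.

    Columns: var1, var2, rho, p, n, significant (p < alpha, unadjusted).
    Pairs with undefined correlation are reported with missing rho/p.
    """
    if len(variables) < 2:
        raise ValueError("need at least two variables")
    rows = []
    for v1, v2 in itertools.combinations(variables, 2):
        row = {"var1": v1, "var2": v2, "rho": np.nan, "p": np.nan,
               "n": 0, "significant": False}
        try:
            res = spearman(table[v1], table[v2], names=(v1, v2))
            row.update(rho=res.rho, p=res.p_value, n=res.n,
                       significant=bool(res.p_value < alpha))
        except (UndefinedCorrelationError, ValueError):
            pass
        rows.append(row)
    return pd.DataFrame(rows, columns=["var1", "var2", "rho", "p", "n", "significant"])


def correlation_matrix_wide(table: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    """Symmetric rho matrix with unit diagonal (NaN where undefined)."""
    long = correlation_matrix(table, variables)
    mat = pd.DataFrame(np.eye(len(variables)), index=variables, columns=variables)
    for _, r in long.iterrows():
        mat.loc[r["var1"], r["var2"]] = r["rho"]
        mat.loc[r["var2"], r["var1"]] = r["rho"]
    return mat


def welch_t(values, group_labels, variable: str = "value") -> GroupComparison:
    """Welch unequal-variance two-sample t-test (two-sided).

    Requires two groups with n >= 2 each and non-zero pooled variance.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    keep = np.isfinite(values)
    values, group_labels = values[keep], group_labels[keep]
    labels = np.unique(group_labels)
    if labels.size != 2:
        raise UntestableError(f"need exactly two groups, got {labels.size}")
    a = values[group_labels == labels[0]]
    b = values[group_labels == labels[1]]
    if a.size < 2 or b.size < 2:
        raise UntestableError("each group needs n >= 2")
    if np.ptp(values) == 0:
        raise UntestableError("zero total variance: t-test undefined")
    res = sps.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        variable=variable, groups=(str(labels[0]), str(labels[1])),
        means=(float(a.mean()), float(b.mean())),
        t_statistic=float(res.statistic), degrees_of_freedom=float(res.df),
        p_value=float(min(max(res.pvalue, np.finfo(float).tiny), 1.0)),
    )


def ols_fit(x, y) -> Dict[str, float]:
    """Simple least-squares line y = slope * x + intercept.

    Returns slope, intercept, r_squared and the two-sided p-value of the
    slope (t with n-2 df).
    """
    x, y = _pairwise_complete(x, y)
    if x.size < 3:
        raise ValueError(f"need >= 3 complete pairs, got {x.size}")
    if np.ptp(x) == 0:
        raise SingularFitError("constant x: least-squares fit is singular")
    res = sps.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue ** 2),
        "p_value": float(min(max(res.pvalue, np.finfo(float).tiny), 1.0)),
    }


def group_comparisons(table: pd.DataFrame, variables: Sequence[str],
                      stratum: str, transform: Optional[str] = None) -> pd.DataFrame:
    """Welch t-tests of each variable across a two-level stratum column.

    Columns: variable, stratum, group1, group2, mean1, mean2, t, df, p.
    ``transform="log1p"`` applies log(1 + x) before testing.
    """
    rows = []
    labels = table[stratum]
    for var in variables:
        vals = table[var].to_numpy(float)
        if transform == "log1p":
            vals = np.log1p(vals)
        row = {"variable": var, "stratum": stratum, "group1": "", "group2": "",
               "mean1": np.nan, "mean2": np.nan, "t": np.nan, "df": np.nan,
               "p": np.nan}
        try:
            cmp = welch_t(vals, labels, variable=var)
            row.update(group1=cmp.groups[0], group2=cmp.groups[1],
                       mean1=cmp.means[0], mean2=cmp.means[1],
                       t=cmp.t_statistic, df=cmp.degrees_of_freedom, p=cmp.p_value)
        except UntestableError:
            pass
        rows.append(row)
    return pd.DataFrame(rows, columns=["variable", "stratum", "group1", "group2",
                                       "mean1", "mean2", "t", "df", "p"])
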