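"""Inferential layer: normality, one-way ANOVA + Tukey, Pearson correlation.

Group comparisons across control / susceptible / resilient phenotypes use
one-way ANOVA followed by the Tukey(-Kramer) post hoc procedure (pooled
within-group variance, studentized-range distribution); normality is
assessed with the D'Agostino-Pearson omnibus test. Linear association is
summarized by Pearson's r with a two-sided t-based p, both pairwise and
as a star-annotated lower-triangle matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05


class StatsError(ValueError):
    """Invalid input to a statistical routine."""


@dataclass(frozen=True)
class TukeyComparison:
    pair: tuple[str, str]
    mean_difference: float
    q: float
    p_adjusted: float


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    group_ns: tuple[int, ...]
    analyte: str = ""
    area: str = ""
    tukey: tuple[TukeyComparison, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class CorrelationResult:
    x_name: str
    y_name: str
    r: float
    p: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def dagostino_pearson(values) -> tuple[float, float]:
    """D'Agostino-Pearson omnibus K^2 normality test.

    K^2 combines the z-transforms of sample skewness and kurtosis and is
    referred to a chi-square distribution with 2 df. Undefined for n < 8.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 8:
        raise StatsError(
            f"D'Agostino-Pearson test requires n >= 8, got n={values.size}"
        )
    k2, p = stats.normaltest(values)
    return float(k2), float(p)


def _check_groups(groups: Sequence) -> list[np.ndarray]:
    if len(groups) < 2:
        raise StatsError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise StatsError(f"group {i} has size {g.size}, need >= 2")
    return arrays


def one_way_anova(groups: Sequence, analyte: str = "", area: str = ""
                  ) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    Degenerate within-group variance is handled explicitly: identical
    group means give F = 0, p = 1; distinct means with zero within-group
    variance give F = inf, p = 0.
    """
    arrays = _check_groups(groups)
    ns = tuple(int(g.size) for g in arrays)
    grand = np.concatenate(arrays)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    ssb = sum(g.size * (g.mean() - grand.mean()) ** 2 for g in arrays)
    if ssw == 0.0:
        if np.isclose(ssb, 0.0):
            return AnovaResult(0.0, 1.0, ns, analyte, area)
        return AnovaResult(float("inf"), 0.0, ns, analyte, area)
    f, p = stats.f_oneway(*arrays)
    return AnovaResult(float(f), float(p), ns, analyte, area)


def tukey_hsd(groups: Sequence, names: Sequence[str] | None = None
              ) -> tuple[TukeyComparison, ...]:
    """Tukey's HSD with the Tukey-Kramer allowance for unbalanced groups.

    q = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j)), with the
    adjusted p from the studentized-range distribution with parameters
    (k, N - k).
    """
    arrays = _check_groups(groups)
    k = len(arrays)
    names = list(names) if names is not None else [f"group{i}" for i in range(k)]
    if len(names) != k:
        raise StatsError("names length must match number of groups")
    n_total = sum(g.size for g in arrays)
    df_within = n_total - k
    msw = sum(((g - g.mean()) ** 2).sum() for g in arrays) / df_within
    if msw == 0.0:
        raise StatsError("zero pooled within-group variance")
    out = []
    for i, j in combinations(range(k), 2):
        diff = arrays[i].mean() - arrays[j].mean()
        se = np.sqrt(msw / 2.0 * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
        q = abs(diff) / se
        p = float(stats.studentized_range.sf(q, k, df_within))
        out.append(TukeyComparison((names[i], names[j]), float(diff),
                                   float(q), min(max(p, 0.0), 1.0)))
    return tuple(out)


def pearson(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Pearson's r with the two-sided t-based p (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise StatsError("x and y must have equal length")
    if x.size < 3:
        raise StatsError(f"need n >= 3 for a correlation, got n={x.size}")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise StatsError("zero variance input to pearson()")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(x_name, y_name, float(r), float(p), int(x.size))


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p for a given Pearson r at sample size n (t on n-2 df)."""
    if n < 3:
        raise StatsError("need n >= 3")
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(t, n - 2))


@dataclass
class CorrelationMatrix:
    """Lower-triangle Pearson matrix with significance stars.

    ``r``, ``p`` and ``n`` are variable-by-variable DataFrames (upper
    triangle mirrored); ``formatted`` renders each lower-triangle cell as
    ``"r<stars>"`` and marks pairs without enough complete observations
    as ``"NC"`` (not computable).
    """

    variables: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    formatted: pd.DataFrame


def correlation_matrix(data: pd.DataFrame,
                       variables: Sequence[str] | None = None,
                       min_n: int = 3) -> CorrelationMatrix:
    """All-pairs Pearson correlation over the columns of ``data``.

    Pairs are evaluated on their complete rows; a pair with fewer than
    ``min_n`` complete rows (including a variable absent from ``data``)
    is marked not computable.
    """
    variables = tuple(variables if variables is not None else data.columns)
    k = len(variables)
    r = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    p = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables)
    n = pd.DataFrame(np.zeros((k, k), dtype=int), index=variables,
                     columns=variables)
    formatted = pd.DataFrame("", index=variables, columns=variables)
    for i, j in combinations(range(k), 2):
        a, b = variables[i], variables[j]
        computable = a in data.columns and b in data.columns
        if computable:
            sub = data[[a, b]].dropna()
            computable = (len(sub) >= min_n
                          and sub[a].std(ddof=1) > 0
                          and sub[b].std(ddof=1) > 0)
        if not computable:
            r.loc[a, b] = r.loc[b, a] = np.nan
            p.loc[a, b] = p.loc[b, a] = np.nan
            formatted.loc[b, a] = "NC"
            continue
        res = pearson(sub[a], sub[b], a, b)
        r.loc[a, b] = r.loc[b, a] = res.r
        p.loc[a, b] = p.loc[b, a] = res.p
        n.loc[a, b] = n.loc[b, a] = res.n
        formatted.loc[b, a] = f"{res.r:.2f}{significance_stars(res.p)}"
    return CorrelationMatrix(variables, r, p, n, formatted)
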