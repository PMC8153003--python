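"""Combinatorial ("synergic") linear-model search over miRNA predictors.

For each target mRNA (FKBP5, BDNF) in each brain area, every subset of
2, 3, and 4 miRNAs drawn from the admissible pool is fitted by ordinary
least squares on relative quantities, and the subset with the highest
multiple correlation R is reported per subset size, alongside the full
enumeration ledger. The admissible pool keeps, by default, only miRNAs
whose sample correlation with the target is negative (the repression-
consistent direction); a permissive mode keeps all candidates.

The same OLS machinery fits the behavioral-score models: for each of the
four composite scores and each area, three models — miRNAs + mRNAs (6
predictors), miRNAs only (4), mRNAs only (2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .group_stats import pearson
from .synthetic_cohort import AREAS, MIRNAS, MRNAS

logger = logging.getLogger(__name__)


class RegressionError(ValueError):
    """Invalid regression input."""


@dataclass(frozen=True)
class RegressionModelResult:
    target: str
    area: str
    predictors: tuple[str, ...]
    R: float
    R2: float
    p: float
    n: int


@dataclass
class ModelSearchReport:
    target: str
    area: str
    pool: tuple[str, ...]
    #: best model per subset size (only sizes that could be fitted)
    best: dict[int, RegressionModelResult] = field(default_factory=dict)
    #: every fitted subset, in enumeration order
    ledger: list[RegressionModelResult] = field(default_factory=list)


def ols_fit(y, X, predictor_names: Sequence[str],
            target: str = "", area: str = "") -> RegressionModelResult:
    """Ordinary least squares with intercept; reports R, R^2 and the
    overall F-test p of the fitted model."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if len(predictor_names) != k:
        raise RegressionError("predictor_names length must match X columns")
    if n <= k + 1:
        raise RegressionError(
            f"n={n} too small for {k} predictors (need n > k + 1)"
        )
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < k + 1:
        raise RegressionError(
            f"rank-deficient design; collinear predictors among "
            f"{tuple(predictor_names)}"
        )
    res = sm.OLS(y, design).fit()
    r2 = float(res.rsquared)
    p = float(res.f_pvalue)
    if np.isnan(p):  # exact fit: ssr == 0
        p = 0.0 if r2 > 0 else 1.0
    r2 = min(max(r2, 0.0), 1.0)
    return RegressionModelResult(target, area, tuple(predictor_names),
                                 float(np.sqrt(r2)), r2, p, n)


def admissible_predictors(target: str, candidates: Sequence[str],
                          data: pd.DataFrame,
                          mode: str = "strict") -> tuple[str, ...]:
    """Candidate predictors allowed into the subset search.

    ``strict`` keeps candidates with a negative sample Pearson r against
    the target (computed on complete rows); ``permissive`` keeps all.
    """
    if mode not in ("strict", "permissive"):
        raise RegressionError(f"unknown admissibility mode {mode!r}")
    candidates = tuple(candidates)
    if mode == "permissive":
        return candidates
    kept = []
    for cand in candidates:
        sub = data[[target, cand]].dropna()
        r = pearson(sub[target], sub[cand], target, cand).r
        if r < 0:
            kept.append(cand)
    return tuple(kept)


def best_subset_search(target: str, data: pd.DataFrame,
                       pool: Sequence[str],
                       sizes: Sequence[int] = (4, 3, 2),
                       area: str = "") -> ModelSearchReport:
    """Exhaustive best-subset enumeration.

    Fits every subset of each requested size drawn from ``pool`` and
    reports, per size, the subset with maximal R; ties go to the
    lexicographically smallest predictor-name tuple (subsets are
    enumerated from name-sorted pools, so the first maximum wins).
    """
    pool = tuple(sorted(pool))
    report = ModelSearchReport(target, area, pool)
    if not pool:
        raise RegressionError(f"empty predictor pool for {target} in {area}")
    complete = data[[target, *pool]].dropna()
    y = complete[target].to_numpy()
    for size in sizes:
        if size > len(pool):
            logger.info("subset size %d exceeds pool of %d for %s/%s; skipped",
                        size, len(pool), target, area)
            continue
        if len(complete) <= size + 1:
            logger.info("n=%d too small for %d predictors for %s/%s; skipped",
                        len(complete), size, target, area)
            continue
        best = None
        for subset in combinations(pool, size):
            fit = ols_fit(y, complete[list(subset)].to_numpy(), subset,
                          target=target, area=area)
            report.ledger.append(fit)
            if best is None or fit.R > best.R:
                best = fit
        report.best[size] = best
    return report


def search_all_targets(rq_wide_by_area: Mapping[str, pd.DataFrame],
                       targets: Sequence[str] = MRNAS,
                       candidates: Sequence[str] = MIRNAS,
                       mode: str = "strict",
                       sizes: Sequence[int] = (4, 3, 2),
                       ) -> list[ModelSearchReport]:
    """Run the admissibility filter + subset search per (target, area).

    Targets whose admissible pool is empty (no negatively correlated
    miRNA) are skipped, mirroring their absence from the reported model
    tables.
    """
    reports = []
    for area, data in rq_wide_by_area.items():
        for target in targets:
            pool = admissible_predictors(target, candidates, data, mode)
            if not pool:
                logger.info("no admissible predictors for %s in %s; skipped",
                            target, area)
                continue
            reports.append(best_subset_search(target, data, pool,
                                              sizes=sizes, area=area))
    return reports


SCORE_PREDICTOR_SETS: dict[str, tuple[str, ...]] = {
    "miRNAs+mRNAs": MIRNAS + MRNAS,
    "miRNAs": MIRNAS,
    "mRNAs": MRNAS,
}


def score_regressions(scores: pd.DataFrame,
                      rq_wide_by_area: Mapping[str, pd.DataFrame],
                      score_columns: Sequence[str] = (
                          "arousal_score", "avoidance_score",
                          "social_memory_score", "ptsd_like_score"),
                      population: str = "stressed",
                      ) -> list[RegressionModelResult]:
    """Behavioral-score models per (score, area, predictor set).

    ``population`` restricts the fit to stressed (susceptible + resilient)
    mice (default) or uses all mice with data in the area. Models whose
    sample size cannot support the predictor count are skipped with a log
    notice.
    """
    scores = scores.set_index("mouse_id") if "mouse_id" in scores.columns else scores
    if population == "stressed":
        scores = scores[scores["phenotype"].isin(("susceptible", "resilient"))]
    results = []
    for area, rq in rq_wide_by_area.items():
        merged = scores.join(rq, how="inner")
        for score in score_columns:
            for set_name, predictors in SCORE_PREDICTOR_SETS.items():
                cols = [p for p in predictors if p in merged.columns]
                complete = merged[[score, *cols]].dropna()
                if len(cols) < len(predictors) or len(complete) <= len(cols) + 1:
                    logger.info("model %s on %s in %s skipped (n=%d, k=%d)",
                                set_name, score, area, len(complete), len(cols))
                    continue
                fit = ols_fit(complete[score].to_numpy(),
                              complete[cols].to_numpy(), cols,
                              target=f"{score}|{set_name}", area=area)
                results.append(fit)
    return results


def report_frame(reports: Sequence[ModelSearchReport]) -> pd.DataFrame:
    """Best-model table (one row per target/area/subset size)."""
    rows = []
    for rep in reports:
        for size in sorted(rep.best, reverse=True):
            fit = rep.best[size]
            rows.append((rep.area, rep.target, ", ".join(fit.predictors),
                         fit.R, fit.R2, fit.p, fit.n))
    return pd.DataFrame(rows, columns=["area", "target", "predictors",
                                       "R", "R2", "p", "n"])


def ledger_frame(reports: Sequence[ModelSearchReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        for fit in rep.ledger:
            rows.append((rep.area, rep.target, ", ".join(fit.predictors),
                         len(fit.predictors), fit.R, fit.R2, fit.p, fit.n))
    return pd.DataFrame(rows, columns=["area", "target", "predictors", "size",
                                       "R", "R2", "p", "n"])
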