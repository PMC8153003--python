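from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import stressmirseg as s
from stressmirseg.synergy_regression import RegressionError


def brute_force_best(y, data, pool, size):
    """Independent enumeration oracle using raw least squares."""
    y = np.asarray(y, float)
    sst = ((y - y.mean()) ** 2).sum()
    best_r2, best_subset = -1.0, None
    for subset in combinations(sorted(pool), size):
        X = np.column_stack([np.ones(len(y)), data[list(subset)].to_numpy()])
        ssr = ((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2).sum()
        r2 = 1.0 - ssr / sst
        if r2 > best_r2 + 1e-12:
            best_r2, best_subset = r2, subset
    return best_subset, np.sqrt(max(best_r2, 0.0))


class TestOlsFit:
    def test_perfect_linear_fit(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 2))
        y = 2.0 * X[:, 0] - 1.0 * X[:, 1] + 3.0
        fit = s.ols_fit(y, X, ["a", "b"])
        assert fit.R2 == pytest.approx(1.0, abs=1e-12)
        assert fit.p == pytest.approx(0.0, abs=1e-50)

    def test_single_predictor_equals_pearson(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        fit = s.ols_fit(y, x, ["x"])
        corr = s.pearson(x, y)
        assert fit.R == pytest.approx(abs(corr.r), abs=1e-9)
        assert fit.p == pytest.approx(corr.p, abs=1e-9)

    def test_null_model_p_uniform(self):
        rng = np.random.default_rng(2)
        ps = []
        for _ in range(300):
            X = rng.normal(size=(50, 3))
            y = rng.normal(size=50)
            ps.append(s.ols_fit(y, X, list("abc")).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_collinear_predictors_rejected(self):
        x = np.arange(10.0)
        X = np.column_stack([x, 2.0 * x])
        with pytest.raises(RegressionError, match="collinear"):
            s.ols_fit(x, X, ["a", "b"])

    def test_too_few_observations_rejected(self):
        with pytest.raises(RegressionError, match="too small"):
            s.ols_fit([1.0, 2.0, 3.0], np.eye(3)[:, :2], ["a", "b"])


class TestAdmissiblePredictors:
    def _data(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 30
        base = rng.normal(size=n)
        return pd.DataFrame({
            "t": base + 0.1 * rng.normal(size=n),
            "neg1": -base + 0.5 * rng.normal(size=n),
            "neg2": -0.7 * base + rng.normal(size=n),
            "pos1": base + 0.5 * rng.normal(size=n),
            "pos2": 0.5 * base + rng.normal(size=n),
        })

    def test_strict_keeps_only_negative_correlations(self):
        data = self._data()
        pool = s.admissible_predictors("t", ["neg1", "neg2", "pos1", "pos2"],
                                       data, "strict")
        expected = tuple(c for c in ("neg1", "neg2", "pos1", "pos2")
                         if s.pearson(data["t"], data[c]).r < 0)
        assert pool == expected == ("neg1", "neg2")

    def test_permissive_keeps_all(self):
        pool = s.admissible_predictors("t", ["neg1", "pos1"], self._data(),
                                       "permissive")
        assert pool == ("neg1", "pos1")

    def test_all_positive_gives_empty_pool_and_search_skip(self):
        data = self._data()
        pool = s.admissible_predictors("t", ["pos1", "pos2"], data, "strict")
        assert pool == ()
        reports = s.search_all_targets({"HIP": data.rename(columns={
            "t": "BDNF"})}, targets=("BDNF",), candidates=("pos1", "pos2"))
        assert reports == []


class TestBestSubsetSearch:
    def test_pool_of_two_forced_winner(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.normal(size=(20, 3)), columns=["y", "a", "b"])
        report = s.best_subset_search("y", data, ["a", "b"], sizes=(2,))
        assert report.best[2].predictors == ("a", "b")
        assert len(report.ledger) == 1

    def test_suppressor_pair_beats_marginally_stronger_single(self):
        """Predictors a and c jointly determine y (c is a classical
        suppressor carrying no marginal signal), while b is only a noisy
        proxy; exhaustive search must return {a, c}."""
        rng = np.random.default_rng(4)
        n = 40
        signal = rng.normal(size=n)
        noise = rng.normal(size=n)
        data = pd.DataFrame({
            "a": signal + noise,
            "c": noise,
            "b": signal + 0.8 * rng.normal(size=n),
            "y": signal,
        })
        report = s.best_subset_search("y", data, ["a", "b", "c"], sizes=(2,))
        oracle_subset, oracle_r = brute_force_best(data["y"], data,
                                                   ["a", "b", "c"], 2)
        assert report.best[2].predictors == oracle_subset == ("a", "c")
        assert report.best[2].R == pytest.approx(oracle_r, abs=1e-9)

    def test_matches_brute_force_on_random_problems(self):
        rng = np.random.default_rng(5)
        pool = list("abcdef")
        for _ in range(20):
            X = rng.normal(size=(25, 6))
            y = X @ rng.normal(size=6) + rng.normal(size=25) * 2.0
            data = pd.DataFrame(X, columns=pool)
            data["y"] = y
            report = s.best_subset_search("y", data, pool, sizes=(4, 3, 2))
            for size in (4, 3, 2):
                oracle_subset, oracle_r = brute_force_best(y, data, pool, size)
                assert report.best[size].predictors == oracle_subset
                assert report.best[size].R == pytest.approx(oracle_r, abs=1e-9)

    def test_ledger_covers_every_subset_once(self):
        rng = np.random.default_rng(6)
        data = pd.DataFrame(rng.normal(size=(20, 5)),
                            columns=["y", "a", "b", "c", "d"])
        report = s.best_subset_search("y", data, list("abcd"), sizes=(4, 3, 2))
        seen = [fit.predictors for fit in report.ledger]
        assert len(seen) == len(set(seen)) == 1 + 4 + 6
        for size in (4, 3, 2):
            fits_of_size = [f for f in report.ledger
                            if len(f.predictors) == size]
            assert report.best[size].R == max(f.R for f in fits_of_size)

    def test_oversized_subset_skipped(self):
        rng = np.random.default_rng(7)
        data = pd.DataFrame(rng.normal(size=(20, 3)), columns=["y", "a", "b"])
        report = s.best_subset_search("y", data, ["a", "b"], sizes=(4, 3, 2))
        assert set(report.best) == {2}

    def test_nesting_monotonicity(self):
        rng = np.random.default_rng(8)
        data = pd.DataFrame(rng.normal(size=(30, 5)),
                            columns=["y", "a", "b", "c", "d"])
        report = s.best_subset_search("y", data, list("abcd"), sizes=(4, 3, 2))
        assert (report.best[4].R2 >= report.best[3].R2 - 1e-12
                >= report.best[2].R2 - 2e-12)

    def test_orthonormal_predictors_r2_adds(self):
        """With orthonormal centred predictors, model R^2 equals the sum of
        squared simple correlations."""
        n = 16
        q, _ = np.linalg.qr(np.random.default_rng(9).normal(size=(n, 3)))
        q = q - q.mean(axis=0)
        q, _ = np.linalg.qr(q)  # re-orthonormalize after centring
        y = 1.0 * q[:, 0] + 2.0 * q[:, 1] + 0.5 * q[:, 2]
        data = pd.DataFrame(q, columns=["a", "b", "c"])
        data["y"] = y
        fit = s.ols_fit(y, q, ["a", "b", "c"])
        total = sum(s.pearson(q[:, i], y).r ** 2 for i in range(3))
        assert fit.R2 == pytest.approx(total, abs=1e-9)


class TestScoreRegressions:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 16
        mice = [f"m{i}" for i in range(n)]
        rq = pd.DataFrame(rng.lognormal(0, 0.4, size=(n, 6)),
                          columns=list(s.MIRNAS + s.MRNAS), index=mice)
        scores = pd.DataFrame({
            "mouse_id": mice,
            "arousal_score": rq[list(s.MIRNAS)].to_numpy()
            @ np.array([1.0, -0.5, 0.25, 2.0]),
            "avoidance_score": rng.normal(size=n),
            "social_memory_score": rng.normal(size=n),
            "ptsd_like_score": rng.normal(size=n),
            "phenotype": ["susceptible"] * 8 + ["resilient"] * 8,
        })
        return scores, {"HIP": rq}

    def test_planted_linear_combination_gives_unit_r2(self):
        scores, by_area = self._setup()
        fits = s.score_regressions(scores, by_area)
        mirna_fit = [f for f in fits
                     if f.target == "arousal_score|miRNAs"][0]
        assert mirna_fit.R2 == pytest.approx(1.0, abs=1e-10)

    def test_nested_model_dominance(self):
        scores, by_area = self._setup(seed=1)
        fits = {f.target: f for f in s.score_regressions(scores, by_area)}
        for score in ("arousal_score", "avoidance_score",
                      "social_memory_score", "ptsd_like_score"):
            both = fits[f"{score}|miRNAs+mRNAs"].R2
            assert both >= fits[f"{score}|miRNAs"].R2 - 1e-10
            assert both >= fits[f"{score}|mRNAs"].R2 - 1e-10

    def test_full_grid_on_default_cohort(self, default_scores, default_rq):
        by_area = {a: s.rq_wide(default_rq, a) for a in s.AREAS}
        fits = s.score_regressions(default_scores, by_area)
        # 4 scores x 3 predictor sets x 3 areas
        assert len(fits) == 36
        labels = {(f.area, f.target) for f in fits}
        assert len(labels) == 36

    def test_undersized_models_skipped(self):
        scores, by_area = self._setup()
        scores = scores.iloc[:6]  # n=6 cannot support 6 predictors
        fits = s.score_regressions(scores, by_area)
        assert all(f.target.split("|")[1] != "miRNAs+mRNAs" for f in fits)
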