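"""Correlation screen, LASSO ranking, guided model and baseline selector."""

import numpy as np
import pandas as pd
import pytest

from radguide.guided_selection import (
    baseline_radiomics_model,
    correlation_screen,
    fit_guided_model,
    lasso_rank,
    odds_ratio,
    pearson,
    predict,
    wald_ci,
)
from radguide.io_core import FeatureTable


def table(arr, prefix, seed_ids=None):
    n = arr.shape[0]
    ids = seed_ids or [f"s{i:03d}" for i in range(n)]
    cols = [f"{prefix}{j}" for j in range(arr.shape[1])]
    return FeatureTable(pd.DataFrame(arr, index=ids, columns=cols))


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)
        r, _ = pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 6])
        r, p = pearson(x, y)
        # direct covariance formula evaluated independently
        r_ref = (((x - x.mean()) * (y - y.mean())).sum()
                 / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        assert r == pytest.approx(r_ref, abs=1e-14)
        from scipy import stats
        assert (r, p) == pytest.approx(stats.pearsonr(x, y), abs=1e-12)

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson([1, 2], [3, 4])
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])


class TestCorrelationScreen:
    def test_duplicated_column_retained(self):
        rng = np.random.default_rng(0)
        rad = rng.standard_normal((30, 5))
        lat = np.column_stack([rad[:, 2], rng.standard_normal(30)])
        res = correlation_screen(table(lat, "L"), table(rad, "R"))
        assert "L0" in res.retained
        i = res.latent_names.index("L0")
        assert res.p_corr[i].min() == pytest.approx(0.0, abs=1e-12)

    def test_null_noise_rarely_retains(self):
        """50 x 50 independent Gaussian pairs at n=120: the Bonferroni screen
        should retain nothing in at least 19 of 20 seeded replicates."""
        zero_count = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            lat = table(rng.standard_normal((120, 50)), "L")
            rad = table(rng.standard_normal((120, 50)), "R")
            res = correlation_screen(lat, rad)
            if len(res.retained) == 0:
                zero_count += 1
        assert zero_count >= 19

    def test_retention_rule_matches_brute_force(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(40)
        lat_arr = np.column_stack([base + rng.standard_normal(40) * s
                                   for s in (0.1, 1.0, 5.0, 10.0)])
        rad_arr = np.column_stack([base, rng.standard_normal(40)])
        lat, rad = table(lat_arr, "L"), table(rad_arr, "R")
        res = correlation_screen(lat, rad)
        m = 4 * 2
        for i, lname in enumerate(res.latent_names):
            hits = []
            for j in range(rad_arr.shape[1]):
                r, p = pearson(lat_arr[:, i], rad_arr[:, j])
                hits.append(abs(r) > 0.4 and min(p * m, 1.0) < 0.05)
            assert (lname in res.retained) == any(hits)

    def test_constant_feature_excluded_and_m_reduced(self):
        rng = np.random.default_rng(4)
        lat_arr = rng.standard_normal((20, 3))
        lat_arr[:, 1] = 7.0
        rad = table(rng.standard_normal((20, 4)), "R")
        res = correlation_screen(table(lat_arr, "L"), rad)
        assert res.constant_latent == ["L1"]
        assert res.m == 2 * 4

    def test_subject_mismatch_rejected(self):
        rng = np.random.default_rng(5)
        lat = table(rng.standard_normal((10, 2)), "L")
        rad = table(rng.standard_normal((10, 2)), "R",
                    seed_ids=[f"x{i}" for i in range(10)])
        with pytest.raises(ValueError, match="subjects"):
            correlation_screen(lat, rad)


class TestLassoRank:
    def test_planted_feature_ranked_first(self):
        """One feature with a 2-sigma class-mean separation among 20 noise
        features is ranked first in >= 18/20 seeded replicates."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 200
            y = np.array(["A", "B"] * (n // 2))
            x = rng.standard_normal((n, 21))
            x[:, 0] += np.where(y == "A", 1.0, -1.0)  # delta = 2 sigma
            x = (x - x.mean(0)) / x.std(0)
            rank = lasso_rank(table(x, "F"), list(y), seed=seed)
            if rank["feature"].iloc[0] == "F0":
                wins += 1
        assert wins >= 18

    def test_duplicated_informative_pair_top2(self):
        rng = np.random.default_rng(7)
        n = 200
        y = np.array(["A", "B"] * (n // 2))
        informative = np.where(y == "A", 1.0, -1.0) + rng.standard_normal(n)
        x = np.column_stack([informative, informative.copy(),
                             rng.standard_normal((n, 10)).T.flatten()[:n]])
        x = np.column_stack([x, rng.standard_normal((n, 9))])
        x = (x - x.mean(0)) / x.std(0)
        rank = lasso_rank(table(x, "F"), list(y), seed=0)
        top2 = set(rank["feature"].iloc[:2])
        assert top2 & {"F0", "F1"}

    def test_all_zero_coefficients_fall_back_to_tie_break(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((40, 5))
        x = (x - x.mean(0)) / x.std(0)
        y = list(rng.choice(["A", "B"], 40))
        tie = pd.Series([0.1, 0.9, 0.5, 0.3, 0.7],
                        index=[f"F{j}" for j in range(5)])
        rank = lasso_rank(table(x, "F"), y, seed=0,
                          c_grid=np.array([1e-6]), tie_break=tie)
        assert (rank["score"] == 0).all()
        # caller-side fallback: sort by tie-break when all scores are zero
        order = rank.sort_values(["tie_break", "feature"],
                                 ascending=[False, True])["feature"]
        assert list(order)[:2] == ["F1", "F4"]


class TestOddsRatioIdentities:
    @pytest.mark.parametrize("beta,expected,decimals", [
        (2.748, 15.6, 1), (1.498, 4.47, 2), (-1.885, 0.15, 2), (1.108, 3.03, 2)])
    def test_printed_or_values(self, beta, expected, decimals):
        assert round(odds_ratio(beta), decimals) == expected

    def test_beta_zero_or_one_ci_contains_one(self):
        assert odds_ratio(0.0) == 1.0
        lo, hi = wald_ci(0.0, 0.5)
        assert lo < 1.0 < hi

    def test_ci_brackets_or(self):
        lo, hi = wald_ci(1.2, 0.3)
        assert lo < odds_ratio(1.2) < hi
        assert lo == pytest.approx(np.exp(1.2 - 1.96 * 0.3), rel=1e-4)


class TestGuidedModelFit:
    def _fixture(self, seed=0, n=120):
        rng = np.random.default_rng(seed)
        y = np.array(["IPD", "MSA", "PSP"] * (n // 3))
        signal1 = np.where(y == "MSA", 1.2, -0.6) + rng.standard_normal(n)
        signal2 = np.where(y == "PSP", 1.2, -0.6) + rng.standard_normal(n)
        lat = np.column_stack([signal1, signal2,
                               rng.standard_normal((n, 4))])
        lat = (lat - lat.mean(0)) / lat.std(0)
        rad = np.column_stack([signal1 + 0.3 * rng.standard_normal(n),
                               signal2 + 0.3 * rng.standard_normal(n)])
        rad = (rad - rad.mean(0)) / rad.std(0)
        lt = table(lat, "DenseNet_Latent_")
        rt = FeatureTable(pd.DataFrame(
            rad, index=lt.subjects,
            columns=["putamen__glcm__Contrast", "caudate__glcm__Contrast"]))
        screen = correlation_screen(lt, rt)
        return lt, list(y), screen

    def test_or_equals_exp_beta(self):
        lt, y, screen = self._fixture()
        model = fit_guided_model(lt, y, screen, k=2)
        for cls in model.classes:
            cc = model.per_class[cls]
            np.testing.assert_allclose(cc.odds_ratio.to_numpy(),
                                       np.exp(cc.beta.to_numpy()), rtol=1e-12)
            assert ((cc.ci_low <= cc.odds_ratio)
                    & (cc.odds_ratio <= cc.ci_high)).all()

    def test_too_few_retained_advises_lower_k(self):
        lt, y, screen = self._fixture()
        with pytest.raises(ValueError, match="lower k"):
            fit_guided_model(lt, y, screen, k=len(screen.retained) + 1)

    def test_predict_probabilities_sum_to_one(self):
        lt, y, screen = self._fixture()
        model = fit_guided_model(lt, y, screen, k=2)
        labels, probs = predict(model, lt)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert set(labels) <= {"IPD", "MSA", "PSP"}
        labels2, _ = predict(model, lt)
        assert labels == labels2

    def test_symmetric_two_class_problem(self):
        rng = np.random.default_rng(11)
        n = 200
        y = ["A"] * (n // 2) + ["B"] * (n // 2)
        x = rng.standard_normal(n)
        x[:n // 2] += 1.0
        x[n // 2:] -= 1.0
        lat = np.column_stack([x, rng.standard_normal(n)])
        lat = (lat - lat.mean(0)) / lat.std(0)
        lt = table(lat, "L")
        rt = FeatureTable(pd.DataFrame(
            {"r__glcm__A": lat[:, 0] + 0.2 * rng.standard_normal(n)},
            index=lt.subjects))
        screen = correlation_screen(lt, rt)
        model = fit_guided_model(lt, list(y), screen, k=1)
        labels, _ = predict(model, lt)
        frac_a = np.mean([l == "A" for l in labels])
        assert 0.4 < frac_a < 0.6


class TestBaselineSelector:
    def _data(self, seed=0, n=120, p=60, informative=6):
        rng = np.random.default_rng(seed)
        y = np.array(["IPD", "MSA", "PSP"] * (n // 3))
        x = rng.standard_normal((n, p))
        for j in range(informative):
            cls = ["IPD", "MSA", "PSP"][j % 3]
            x[:, j] += np.where(y == cls, 1.5, -0.75)
        x = (x - x.mean(0)) / x.std(0)
        return table(x, "F"), list(y)

    def test_returns_exactly_n_select(self):
        t, y = self._data()
        model = baseline_radiomics_model(t, y, n_select=10, n_iter=25, seed=0)
        assert len(model.selected) == 10
        assert ((model.frequencies >= 0) & (model.frequencies <= 1)).all()

    def test_seed_deterministic(self):
        t, y = self._data()
        m1 = baseline_radiomics_model(t, y, n_select=8, n_iter=15, seed=3)
        m2 = baseline_radiomics_model(t, y, n_select=8, n_iter=15, seed=3)
        assert m1.selected == m2.selected
        pd.testing.assert_series_equal(m1.frequencies, m2.frequencies)

    def test_informative_features_dominate_selection(self):
        t, y = self._data()
        model = baseline_radiomics_model(t, y, n_select=10, n_iter=25, seed=1)
        top6 = set(model.frequencies.sort_values(ascending=False).index[:6])
        assert len(top6 & {f"F{j}" for j in range(6)}) >= 5

    def test_n_select_exceeding_ever_selected_rejected(self):
        t, y = self._data()
        with pytest.raises(ValueError, match="exceeds"):
            baseline_radiomics_model(t, y, n_select=61, n_iter=5, seed=0)
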