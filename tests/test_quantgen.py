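"""Balanced ANOVA, variance components, heritability, rG, LSD, EI."""

import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import fluorosel as fs
from fluorosel.quantgen import _components_raw
from conftest import make_balanced_table


class TestAnova:
    def test_study_layout_degrees_of_freedom(self, paper_trial):
        aov = fs.anova(paper_trial.agro, "gy_t_ha")
        assert list(aov["df"]) == [15, 2, 9, 9, 30, 126]
        assert aov["df"].sum() == 191

    def test_constant_response_zero_ss(self, balanced_table_factory):
        table = balanced_table_factory(seed=1)
        table["y"] = 4.2
        aov = fs.anova(table, "y")
        assert np.allclose(aov["ss"], 0.0)

    def test_matches_cell_mean_bruteforce(self, balanced_table_factory):
        table = balanced_table_factory(n_genotypes=4, n_years=2, n_reps=2,
                                       seed=3, blocks=False)
        y = (table.sort_values(["genotype", "year", "rep"])["y"]
             .to_numpy().reshape(4, 2, 2))
        grand = y.mean()
        ss_g = 4 * ((y.mean(axis=(1, 2)) - grand) ** 2).sum()
        ss_y = 8 * ((y.mean(axis=(0, 2)) - grand) ** 2).sum()
        ss_ry = 4 * ((y.mean(axis=0) - y.mean(axis=(0, 2))[:, None]) ** 2).sum()
        ss_gy = 2 * ((y.mean(axis=2) - y.mean(axis=(1, 2))[:, None]
                      - y.mean(axis=(0, 2))[None, :] + grand) ** 2).sum()
        aov = fs.anova(table, "y").set_index("source")
        assert aov.loc["Genotype", "ss"] == pytest.approx(ss_g)
        assert aov.loc["Year", "ss"] == pytest.approx(ss_y)
        assert aov.loc["Replication", "ss"] == pytest.approx(ss_ry)
        assert aov.loc["Genotype:Year", "ss"] == pytest.approx(ss_gy)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), g=st.integers(3, 8),
           e=st.integers(2, 4), r=st.integers(2, 4))
    def test_ss_partition_sums_to_total(self, seed, g, e, r):
        table = make_balanced_table(g, e, r, seed=seed)
        aov = fs.anova(table, "y")
        total = ((table["y"] - table["y"].mean()) ** 2).sum()
        assert aov["ss"].sum() == pytest.approx(total, rel=1e-8)
        assert aov["df"].sum() == len(table) - 1

    def test_unbalanced_table_rejected(self, balanced_table_factory):
        table = balanced_table_factory(seed=2).iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            fs.anova(table, "y")


class TestVarianceComponents:
    def test_hand_applied_ems_formulas(self, balanced_table_factory):
        table = balanced_table_factory(n_genotypes=4, n_years=2, n_reps=2,
                                       seed=7, sigma_g=2.0)
        aov = fs.anova(table, "y").set_index("source")
        ms = aov["ms"]
        vc = fs.estimate_variance_components(table, "y", jackknife=False)
        assert vc.sigma2_e == pytest.approx(ms["Error"])
        assert vc.sigma2_gxe == pytest.approx(
            max(0.0, (ms["Genotype:Year"] - ms["Error"]) / 2))
        assert vc.sigma2_g == pytest.approx(
            max(0.0, (ms["Genotype"] - ms["Genotype:Year"]) / 4))
        assert vc.sigma2_env == pytest.approx(
            max(0.0, (ms["Year"] - ms["Replication"]) / 8))

    def test_constant_response_all_zero(self, balanced_table_factory):
        table = balanced_table_factory(seed=4)
        table["y"] = 1.0
        vc = fs.estimate_variance_components(table, "y", jackknife=False)
        assert (vc.sigma2_g, vc.sigma2_gxe, vc.sigma2_e) == (0, 0, 0)

    def test_matches_reml_oracle_without_truncation(self, tmp_path):
        """EMS solutions agree with an lme4 REML fit (year and rep-in-year
        fixed, genotype and genotype:year random) on balanced data."""
        table = make_balanced_table(n_genotypes=12, n_years=3, n_reps=4,
                                    seed=7, sigma_g=1.2, sigma_gxe=0.9,
                                    sigma_e=0.8, blocks=False)
        vc = fs.estimate_variance_components(table, "y", jackknife=False)
        assert min(vc.sigma2_g, vc.sigma2_gxe, vc.sigma2_e) > 0  # interior
        csv = tmp_path / "tab.csv"
        table.to_csv(csv, index=False)
        rcode = (
            'suppressMessages(library(lme4));'
            f'd <- read.csv("{csv}");'
            'fit <- lmer(y ~ factor(year) + factor(year):factor(rep)'
            ' + (1|genotype) + (1|genotype:year), data=d);'
            'v <- as.data.frame(VarCorr(fit));'
            'cat(sprintf("%.12g,%.12g,%.12g",'
            ' v$vcov[v$grp=="genotype"], v$vcov[v$grp=="genotype:year"],'
            ' v$vcov[v$grp=="Residual"]))')
        res = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                             text=True, check=True)
        s2g, s2gxe, s2e = map(float, res.stdout.strip().split(","))
        assert s2g == pytest.approx(vc.sigma2_g, rel=1e-4)
        assert s2gxe == pytest.approx(vc.sigma2_gxe, rel=1e-4)
        assert s2e == pytest.approx(vc.sigma2_e, rel=1e-4)

    def test_jackknife_se_shrinks_with_genotype_count(self):
        ses = []
        for g in (8, 32):
            table = make_balanced_table(n_genotypes=g, n_years=3, n_reps=4,
                                        seed=9, sigma_g=1.0)
            vc = fs.estimate_variance_components(table, "y")
            assert vc.se_h2 >= 0
            ses.append(vc.se_h2)
        assert ses[1] < ses[0]


class TestHeritability:
    @pytest.mark.parametrize("sg, sgxe, se, expected", [
        (1.296, 2.209, 0.795, 0.62),     # grain moisture components
        (0.120, 0.003, 0.272, 0.84),     # performance index components
    ])
    def test_two_decimal_worked_examples(self, sg, sgxe, se, expected):
        vc = fs.VarianceComponents(sigma2_g=sg, sigma2_env=0.0,
                                   sigma2_gxe=sgxe, sigma2_e=se,
                                   n_env=3, n_rep=4)
        assert round(fs.heritability(vc), 2) == expected

    def test_noise_free_limit_is_one(self):
        vc = fs.VarianceComponents(1.0, 0.0, 0.0, 0.0, 3, 4)
        assert fs.heritability(vc) == 1.0

    def test_all_zero_components_flagged(self):
        vc = fs.VarianceComponents(0.0, 0.0, 0.0, 0.0, 3, 4)
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(fs.heritability(vc))


class TestGeneticCorrelation:
    def test_self_correlation_is_one(self, balanced_table_factory):
        table = balanced_table_factory(seed=11)
        table["y2"] = table["y"]
        gc = fs.genetic_covariance(table, "y", "y2", jackknife=False)
        assert gc.r_g == pytest.approx(1.0)
        table["neg"] = -table["y"]
        gc = fs.genetic_covariance(table, "y", "neg", jackknife=False)
        assert gc.r_g == pytest.approx(-1.0)

    def test_cell_centered_noise_keeps_genetic_covariance(self):
        """Y = X + within-cell noise (cell means untouched): CovG(X, Y)
        equals the EMS genetic variance of X exactly."""
        rng = np.random.default_rng(13)
        table = make_balanced_table(n_genotypes=6, n_years=3, n_reps=4,
                                    seed=13)
        noise = rng.standard_normal(len(table))
        table["noise"] = noise
        table["noise"] -= table.groupby(["genotype", "year"])["noise"] \
            .transform("mean")
        table["y2"] = table["y"] + table["noise"]
        gc = fs.genetic_covariance(table, "y", "y2", jackknife=False)
        assert gc.cov_g == pytest.approx(_components_raw(table, "y")[0])

    def test_zero_genetic_variance_flagged_not_clipped(self,
                                                       balanced_table_factory):
        table = balanced_table_factory(seed=14, sigma_g=0.0, sigma_gxe=0.0,
                                       sigma_e=0.01)
        table["flat"] = np.tile([0.0, 1.0], len(table) // 2)
        with pytest.warns(UserWarning, match="undefined"):
            gc = fs.genetic_covariance(table, "y", "flat", jackknife=False)
        assert np.isnan(gc.r_g)

    def test_jackknife_se_nonnegative(self, balanced_table_factory):
        table = balanced_table_factory(n_genotypes=8, seed=15)
        table["y2"] = table["y"] + np.random.default_rng(5).normal(
            size=len(table))
        gc = fs.genetic_covariance(table, "y", "y2")
        assert gc.se_r_g >= 0


class TestPearson:
    def test_trivial_cases(self, balanced_table_factory):
        table = balanced_table_factory(seed=21)
        table["same"] = table["y"]
        r, p, stars = fs.pearson(table, "y", "same")
        assert r == pytest.approx(1.0) and stars == "***"

    def test_five_point_hand_example(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        table = pd.DataFrame({"x": x, "y": y})
        r, _, _ = fs.pearson(table, "x", "y")
        expected = (((x - 3) * (y - 3)).sum()
                    / np.sqrt(((x - 3) ** 2).sum() * ((y - 3) ** 2).sum()))
        assert r == pytest.approx(expected)

    def test_zero_variance_flagged(self):
        table = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero variance"):
            r, p, stars = fs.pearson(table, "x", "y")
        assert np.isnan(r)


class TestSelectionEfficiency:
    def test_identity_and_null(self):
        assert fs.indirect_selection_efficiency(1.0, 0.6, 0.6).ei_percent \
            == pytest.approx(100.0)
        assert fs.indirect_selection_efficiency(0.0, 0.6, 0.6).ei_percent == 0.0

    def test_hand_computed_value(self):
        ei = fs.indirect_selection_efficiency(0.97, 0.50, 0.64)
        assert ei.ei_percent == pytest.approx(100 * 0.97 * np.sqrt(0.50 / 0.64))
        assert round(ei.ei_percent, 1) == 85.7

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            fs.indirect_selection_efficiency(0.5, -0.1, 0.6)
        with pytest.raises(ValueError, match="> 0"):
            fs.indirect_selection_efficiency(0.5, 0.5, 0.0)
        with pytest.raises(ValueError, match="finite"):
            fs.indirect_selection_efficiency(np.nan, 0.5, 0.5)


class TestFisherLSD:
    def _anova_stub(self, ms_error=1.0, df_error=12):
        return pd.DataFrame({"source": ["Error"], "df": [df_error],
                             "ss": [ms_error * df_error], "ms": [ms_error]})

    def test_hand_computed_lsd(self):
        from scipy import stats
        means = pd.Series({"A": 0.0, "B": 0.4, "C": 3.0})
        out = fs.fisher_lsd(self._anova_stub(), means, n_per_mean=4)
        expected = stats.t.ppf(0.975, 12) * np.sqrt(0.5)
        assert out["lsd"].iloc[0] == pytest.approx(expected)

    def test_equal_means_share_letter(self):
        means = pd.Series({"A": 1.0, "B": 1.0})
        out = fs.fisher_lsd(self._anova_stub(), means, n_per_mean=4)
        assert out.loc["A", "group"] == out.loc["B", "group"]

    def test_distant_means_get_distinct_letters(self):
        means = pd.Series({"A": 0.0, "B": 10.0})
        out = fs.fisher_lsd(self._anova_stub(), means, n_per_mean=4)
        assert out.loc["A", "group"] != out.loc["B", "group"]

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fs.fisher_lsd(self._anova_stub(), pd.Series({"A": 1.0}), 0)


class TestStandardError:
    def test_examples(self):
        assert fs.standard_error([1, 1, 1, 1]) == 0.0
        assert fs.standard_error([0, 2]) == pytest.approx(1.0)
        v = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        assert fs.standard_error(v + 100.0) == pytest.approx(
            fs.standard_error(v))

    def test_too_few_values(self):
        with pytest.raises(ValueError, match="two values"):
            fs.standard_error([1.0])


class TestYieldStandardization:
    def test_formula_hand_check(self):
        # 9.8 kg plot at 22.4% moisture on 7 m^2:
        # (9.8 * 77.6 / 86 * 10000/7) / 1000 t/ha
        expected = 9.8 * (100 - 22.4) / 86.0 * (10000.0 / 7.0) / 1000.0
        assert fs.standardize_gy(9.8, 22.4, 7.0) == pytest.approx(expected)
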