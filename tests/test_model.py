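import numpy as np
import pandas as pd
import pytest

from methexpr import (OmicsMatrix, PhenotypeTable, SyntheticConfig,
                      ValidationError, fit_all_pairs, fit_pair,
                      generate_dataset, shapiro_filter)
from methexpr.model import pair_fits_frame

from conftest import build_design, ols_oracle


def make_pheno(er, subtype):
    return PhenotypeTable(pd.DataFrame(
        {"er_status": er, "subtype": subtype},
        index=pd.Index([f"S{i}" for i in range(len(er))], name="sample_id")))


def series(vals):
    return pd.Series(vals, index=[f"S{i}" for i in range(len(vals))], dtype=float)


class TestFitPair:
    def test_hand_built_design_matches_normal_equations_oracle(self):
        # n=8 small integers, both covariates varying
        y = series([3, 5, 4, 7, 6, 9, 8, 11])
        x = series([0, 1, 1, 2, 2, 3, 3, 4])
        er = ["ERneg", "ERpos"] * 4
        sub = ["Luminal", "Luminal", "BasalA", "BasalA",
               "BasalB", "BasalB", "Luminal", "BasalA"]
        pheno = make_pheno(er, sub)
        fit = fit_pair(y, x, pheno)
        X, names = build_design(x.to_numpy(), pheno.data)
        beta, se, p, df = ols_oracle(y.to_numpy(), X)
        i = names.index("meth")
        assert fit.status == "ok"
        assert fit.beta1 == pytest.approx(beta[i], rel=1e-10)
        assert fit.beta0 == pytest.approx(beta[names.index("intercept")], rel=1e-10)
        assert fit.beta1_se == pytest.approx(se[i], rel=1e-10)
        assert fit.beta1_p == pytest.approx(p[i], rel=1e-10)
        assert fit.residual_df == df

    def test_perfect_linear_relation_is_degenerate_with_coefficient(self):
        x = series([0, 1, 2, 3, 4, 5, 6, 7])
        y = 2.0 + 1.5 * x
        pheno = make_pheno(["ERpos"] * 8, ["Luminal"] * 8)  # levels drop out
        fit = fit_pair(y, x, pheno)
        assert fit.status == "degenerate"
        assert fit.beta1 == pytest.approx(1.5)
        assert np.isnan(fit.beta1_p)

    def test_constant_methylation_is_degenerate(self):
        y = series([1, 2, 3, 4, 5, 6, 7, 8])
        x = series([2.0] * 8)
        fit = fit_pair(y, x, make_pheno(["ERneg", "ERpos"] * 4,
                                        ["Luminal", "BasalA"] * 4))
        assert fit.status == "degenerate"

    def test_pairwise_deletion_and_insufficient_samples(self):
        y = series([1, np.nan, 3, 4, np.nan, 6, 7, 8])
        x = series([1, 2, np.nan, 4, 5, 6, 7, 8])
        pheno = make_pheno(["ERneg", "ERpos"] * 4, ["Luminal", "BasalA"] * 4)
        fit = fit_pair(y, x, pheno)
        assert fit.n_used == 5  # 3 samples lost to pairwise deletion
        tiny = fit_pair(y.iloc[:4], x.iloc[:4], pheno)
        assert tiny.status == "degenerate"

    def test_mismatched_sample_ids_raise(self):
        y = series([1, 2, 3])
        x = pd.Series([1.0, 2.0, 3.0], index=["A", "B", "C"])
        with pytest.raises(ValidationError):
            fit_pair(y, x, make_pheno(["ERneg"] * 3, ["Luminal"] * 3))

    def test_sequential_anova_matches_statsmodels_type1(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(8)
        n = 24
        er = rng.choice(["ERneg", "ERpos"], n)
        sub = rng.choice(["Luminal", "BasalA", "BasalB"], n)
        x = series(rng.normal(size=n))
        y = series(1 + 0.8 * x.to_numpy()
                   + (er == "ERpos") * 0.5 + rng.normal(size=n))
        pheno = make_pheno(er, sub)
        fit = fit_pair(y, x, pheno, anova="sequential")
        # numeric dummies keep the term order (meth, ER, subtype): patsy
        # would otherwise move categorical terms ahead of the numeric one
        df = pd.DataFrame({"y": y.to_numpy(), "x": x.to_numpy(),
                           "er_pos": (er == "ERpos").astype(float),
                           "sub_a": (sub == "BasalA").astype(float),
                           "sub_b": (sub == "BasalB").astype(float)})
        table = sm.stats.anova_lm(
            ols("y ~ x + er_pos + sub_a + sub_b", data=df).fit(), typ=1)
        assert fit.beta1_p == pytest.approx(table.loc["x", "PR(>F)"], rel=1e-8)


class TestShapiroFilter:
    def test_normal_probesets_mostly_retained(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(rng.standard_normal((300, 40)),
                            index=[f"ps{i}" for i in range(300)],
                            columns=[f"S{i}" for i in range(40)])
        reports = shapiro_filter(OmicsMatrix(data))
        retained = sum(not r.excluded for r in reports)
        assert retained >= 0.90 * 300

    def test_two_point_distribution_excluded(self):
        rng = np.random.default_rng(1)
        vals = rng.choice([0.0, 10.0], size=40)
        data = pd.DataFrame([vals], index=["ps1"],
                            columns=[f"S{i}" for i in range(40)])
        reports = shapiro_filter(OmicsMatrix(data))
        assert reports[0].excluded and reports[0].shapiro_p < 1e-4

    def test_alpha_zero_excludes_nothing_testable(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(rng.choice([0.0, 10.0], size=(5, 40)),
                            index=[f"ps{i}" for i in range(5)],
                            columns=[f"S{i}" for i in range(40)])
        reports = shapiro_filter(OmicsMatrix(data), alpha_norm=0.0)
        assert not any(r.excluded for r in reports)

    def test_under_three_values_excluded_with_nan_p(self):
        data = pd.DataFrame([[1.0, np.nan, np.nan, np.nan]], index=["ps1"],
                            columns=[f"S{i}" for i in range(4)])
        reports = shapiro_filter(OmicsMatrix(data))
        assert reports[0].excluded and np.isnan(reports[0].shapiro_p)

    def test_bh_adjustment_is_less_strict(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.standard_normal((200, 40)),
                            index=[f"ps{i}" for i in range(200)],
                            columns=[f"S{i}" for i in range(40)])
        m = OmicsMatrix(data)
        raw = sum(r.excluded for r in shapiro_filter(m, adjust="raw"))
        bh = sum(r.excluded for r in shapiro_filter(m, adjust="bh"))
        assert bh <= raw


class TestFitAllPairs:
    def test_pair_counts_are_m_times_n(self, small_dataset):
        ds = small_dataset
        fits = fit_all_pairs(ds.expression, ds.methylation, ds.phenotypes,
                             ds.annotations)
        frame = pair_fits_frame(fits)
        counts = frame.groupby("gene").size()
        for ann in ds.annotations:
            assert counts[ann.gene] == ann.m * ann.n

    def test_normality_exclusion_removes_probeset_rows(self, small_dataset):
        ds = small_dataset
        multi = next(a for a in ds.annotations if a.m >= 2)
        from methexpr.model import NormalityReport
        reports = [NormalityReport(multi.probesets[0], 0.001, True)]
        fits = fit_all_pairs(ds.expression, ds.methylation, ds.phenotypes,
                             [multi], reports)
        assert len(fits) == (multi.m - 1) * multi.n
        assert all(f.probeset_id != multi.probesets[0] for f in fits)

    def test_every_pair_matches_independent_ols_refit(self):
        ds = generate_dataset(SyntheticConfig(
            n_genes=2, m_range=(2, 2), n_range=(3, 3), seed=21))
        fits = fit_all_pairs(ds.expression, ds.methylation, ds.phenotypes,
                             ds.annotations)
        assert len(fits) == 12
        for f in fits:
            y = ds.expression.feature(f.probeset_id).to_numpy()
            x = ds.methylation.feature(f.probe_id).to_numpy()
            X, names = build_design(x, ds.phenotypes.data)
            beta, se, p, _ = ols_oracle(y, X)
            i = names.index("meth")
            assert f.beta1 == pytest.approx(beta[i], rel=1e-8)
            assert f.beta1_p == pytest.approx(p[i], rel=1e-8)

    def test_deterministic_lexicographic_order(self, small_dataset):
        ds = small_dataset
        fits = fit_all_pairs(ds.expression, ds.methylation, ds.phenotypes,
                             ds.annotations)
        keys = [(f.gene, f.probeset_id, f.probe_id) for f in fits]
        assert keys == sorted(keys)


class TestInference:
    def test_power_monotone_in_effect_size(self):
        rates = []
        for beta1 in (0.0, 0.5, 1.0):
            ds = generate_dataset(SyntheticConfig(
                n_genes=150, frac_positive=0.0 if beta1 == 0 else 1.0,
                frac_negative=0.0,
                beta1_magnitude=beta1, seed=31))  # paired seeds across levels
            fits = fit_all_pairs(ds.expression, ds.methylation, ds.phenotypes,
                                 ds.annotations)
            p = np.array([f.beta1_p for f in fits])
            rates.append(np.mean(p < 0.05))
        assert rates[0] < 0.10
        assert rates[0] <= rates[1] + 0.02 <= rates[2] + 0.04
        assert rates[2] > 0.9
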