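import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from braya import inference as inf
from braya import synthdata as sd
from braya import thermal as th


@pytest.fixture(scope="module")
def timm_clean(timm_sim):
    df, truth = timm_sim
    clean, _ = th.apply_exclusions(df)
    clean = clean.rename(columns={})
    clean["weight"] = 9.015362 * clean["body_length_mm"] ** 2.86448
    return clean, truth


@pytest.fixture(scope="module")
def binom_data():
    """Binary reached-P_crit records with run and clone random intercepts."""
    rng = np.random.default_rng(42)
    rows = []
    for c in range(16):
        sub = "modern" if c % 2 else "historical"
        ce = rng.normal(0, 0.7)
        for rep in range(6):
            run = f"r{rep % 4}"
            re_run = {"r0": 0.3, "r1": -0.2, "r2": 0.1, "r3": -0.2}[run]
            eta = -0.4 + (1.0 if sub == "modern" else 0.0) + ce + re_run
            rows.append(
                {"reached": int(rng.random() < 1 / (1 + np.exp(-eta))),
                 "subpopulation": sub, "clone": f"c{c}", "run": run}
            )
    return pd.DataFrame(rows)


class TestFitMixed:
    def test_aic_and_bic_identities(self, timm_clean):
        clean, _ = timm_clean
        res = inf.fit_mixed(inf.timm_model_sets()["set2"][1], clean)
        assert res.aic == pytest.approx(-2 * res.llf + 2 * res.npar)
        assert res.bic == pytest.approx(-2 * res.llf + res.npar * np.log(res.n_obs))
        assert res.deviance == pytest.approx(-2 * res.llf)

    def test_npar_counts_fixed_vc_and_residual(self, timm_clean):
        clean, _ = timm_clean
        res = inf.fit_mixed(inf.timm_model_sets()["set2"][1], clean)
        # intercept + subpopulation + 2 variance components + residual
        assert res.npar == 5

    def test_missing_term_is_an_error(self, timm_clean):
        clean, _ = timm_clean
        spec = inf.ModelSpec("t_imm", ("nonexistent",), ("run",))
        with pytest.raises(ValueError, match="nonexistent"):
            inf.fit_mixed(spec, clean)

    def test_fixed_effect_estimate_near_truth(self, timm_clean):
        clean, truth = timm_clean
        res = inf.fit_mixed(inf.timm_model_sets()["set2"][1], clean)
        name = [n for n in res.params.index if "modern" in n][0]
        assert abs(res.params[name] - truth["subpop_effect"]) < 4 * res.bse[name]

    def test_reml_refit_increases_or_changes_objective_only(self, timm_clean):
        clean, _ = timm_clean
        spec = inf.timm_model_sets()["set2"][1]
        ml = inf.fit_mixed(spec, clean)
        reml = inf.refit_reml(spec, clean)
        assert reml.spec.estimation == "REML"
        assert all(v >= 0 for v in reml.vc.values())
        # coefficients agree closely between ML and REML at this size
        name = [n for n in ml.params.index if "modern" in n][0]
        assert ml.params[name] == pytest.approx(reml.params[name], rel=0.05)

    def test_no_random_terms_ml_equals_reml_estimates(self, timm_clean):
        clean, _ = timm_clean
        spec = inf.ModelSpec("t_imm", ("subpopulation",), ())
        ml = inf.fit_mixed(spec, clean)
        reml = inf.refit_reml(spec, clean)
        pd.testing.assert_series_equal(ml.params, reml.params)

    def test_gaussian_fit_matches_lme4_lmer(self, timm_clean, tmp_path):
        """Dual-route check: the profiled-likelihood LMM against lme4 (ML and REML)."""
        clean, _ = timm_clean
        spec = inf.timm_model_sets()["set2"][1]
        ml = inf.fit_mixed(spec, clean)
        reml = inf.refit_reml(spec, clean)
        csv = tmp_path / "timm.csv"
        clean.to_csv(csv, index=False)
        script = tmp_path / "lmm.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(lme4))
                d <- read.csv("{csv}")
                d$cl <- interaction(d$subpopulation, d$clone)
                m <- lmer(t_imm ~ subpopulation + (1|run) + (1|cl), data=d, REML=FALSE)
                mr <- lmer(t_imm ~ subpopulation + (1|run) + (1|cl), data=d, REML=TRUE)
                cat(sprintf("%.6f %.6f %.6f", logLik(m), logLik(mr),
                            fixef(m)[["subpopulationmodern"]]))
                """
            )
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        ll_ml, ll_reml, beta = map(float, out.stdout.split())
        assert ml.llf == pytest.approx(ll_ml, abs=1e-4)
        assert reml.llf == pytest.approx(ll_reml, abs=1e-4)
        name = [n for n in ml.params.index if "modern" in n][0]
        assert ml.params[name] == pytest.approx(beta, abs=1e-4)

    def test_summary_is_informative(self, timm_clean):
        clean, _ = timm_clean
        text = inf.fit_mixed(inf.timm_model_sets()["set2"][1], clean).summary()
        assert "logLik" in text and "subpopulation" in text


class TestLrt:
    def test_identical_fits_give_zero_chisq_p_one(self):
        res = inf.lrt_from_stats(100.0, 4, 100.0, 5)
        assert res.chisq == 0.0
        assert res.p_value == pytest.approx(1.0)
        assert res.winner == "null"

    def test_non_nested_is_an_error(self):
        with pytest.raises(ValueError):
            inf.lrt_from_stats(100.0, 5, 90.0, 5)

    def test_chisq_additivity_across_nested_chain(self, timm_clean):
        clean, _ = timm_clean
        specs = inf.timm_model_sets()["set2"]
        fits = [inf.fit_mixed(s, clean, auto_simplify=False) for s in specs]
        c01 = inf.lrt(fits[0], fits[1]).chisq
        c12 = inf.lrt(fits[1], fits[2]).chisq
        c02 = inf.lrt(fits[0], fits[2]).chisq
        assert c02 == pytest.approx(c01 + c12, abs=1e-6)

    def test_structural_nesting_enforced_on_fits(self, timm_clean):
        clean, _ = timm_clean
        sets = inf.timm_model_sets()
        gen1 = inf.fit_mixed(sets["set1"][1], clean, auto_simplify=False)
        sub1 = inf.fit_mixed(sets["set2"][1], clean, auto_simplify=False)
        with pytest.raises(ValueError, match="nested"):
            inf.lrt(gen1, sub1)

    def test_compare_models_emits_table_one_columns(self, timm_clean):
        clean, _ = timm_clean
        tab = inf.compare_models(inf.timm_model_sets()["set2"], clean)
        assert list(tab.columns) == ["npar", "AIC", "BIC", "logLik", "deviance", "Chisq", "df", "p_value"]
        assert np.isnan(tab["Chisq"].iloc[0])
        assert tab["deviance"].iloc[1] == pytest.approx(-2 * tab["logLik"].iloc[1])


class TestBinomialGlmm:
    def test_laplace_fit_matches_lme4_glmer(self, binom_data, tmp_path):
        """Dual-route check: the Laplace ML fitter against lme4's Laplace glmer."""
        spec0 = inf.ModelSpec("reached", (), ("run", "subpopulation:clone"), family="binomial")
        spec1 = inf.ModelSpec("reached", ("subpopulation",), ("run", "subpopulation:clone"), family="binomial")
        r0 = inf.fit_mixed(spec0, binom_data)
        r1 = inf.fit_mixed(spec1, binom_data)
        csv = tmp_path / "fixture.csv"
        binom_data.to_csv(csv, index=False)
        script = tmp_path / "cmp.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(lme4))
                d <- read.csv("{csv}")
                d$cl <- interaction(d$subpopulation, d$clone)
                m0 <- glmer(reached ~ 1 + (1|run) + (1|cl), data=d, family=binomial)
                m1 <- glmer(reached ~ subpopulation + (1|run) + (1|cl), data=d, family=binomial)
                cat(sprintf("%.6f %.6f %.6f", logLik(m0), logLik(m1),
                            fixef(m1)[["subpopulationmodern"]]))
                """
            )
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        ll0, ll1, beta = map(float, out.stdout.split())
        assert r0.llf == pytest.approx(ll0, abs=5e-3)
        assert r1.llf == pytest.approx(ll1, abs=5e-3)
        name = [n for n in r1.params.index if "modern" in n][0]
        assert r1.params[name] == pytest.approx(beta, abs=5e-3)

    def test_npar_counts_no_residual_variance(self, binom_data):
        spec = inf.ModelSpec("reached", (), ("run", "subpopulation:clone"), family="binomial")
        res = inf.fit_mixed(spec, binom_data)
        assert res.npar == 3  # intercept + two variance components
        assert res.scale is None

    def test_reml_undefined_for_binomial(self, binom_data):
        spec = inf.ModelSpec(
            "reached", (), ("run",), family="binomial", estimation="REML"
        )
        with pytest.raises(ValueError, match="REML"):
            inf.fit_mixed(spec, binom_data)

    def test_non_binary_response_rejected(self, binom_data):
        data = binom_data.assign(reached=binom_data["reached"] + 0.5)
        spec = inf.ModelSpec("reached", (), ("run",), family="binomial")
        with pytest.raises(ValueError, match="0/1"):
            inf.fit_mixed(spec, data)


class TestHolm:
    def test_hand_worked_example(self):
        assert inf.holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_single_p_unchanged_and_dominance(self):
        assert inf.holm_adjust([0.3]) == [0.3]
        raw = [0.001, 0.02, 0.04, 0.3]
        adj = inf.holm_adjust(raw)
        assert all(a >= r for a, r in zip(adj, raw))
        assert all(a <= 1 for a in adj)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            inf.holm_adjust([0.5, 1.2])


class TestWelchAndAnova:
    def test_identical_groups_give_t_zero(self):
        t, df, p = inf.welch_t([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_equal_variance_case_matches_pooled_t(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 30)
        t_welch, _, _ = inf.welch_t(a, b)
        from scipy import stats

        t_pooled = stats.ttest_ind(a, b, equal_var=True).statistic
        assert t_welch == pytest.approx(t_pooled, rel=1e-6)  # equal n, equal var

    def test_sign_flips_with_group_order(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 7.0]
        assert inf.welch_t(a, b)[0] == pytest.approx(-inf.welch_t(b, a)[0])

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            inf.welch_t([1, 1], [2, 2])

    def test_two_group_anova_f_equals_t_squared(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 20)
        b = rng.normal(1, 1, 25)
        from scipy import stats

        t_pooled = stats.ttest_ind(a, b, equal_var=True).statistic
        f, df1, df2, _ = inf.oneway_anova([a, b])
        assert f == pytest.approx(t_pooled**2, rel=1e-9)
        assert (df1, df2) == (1, 43)

    def test_three_group_df_bookkeeping(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(m, 1, 15) for m in (0, 0.5, 1.0)]
        _, df1, df2, _ = inf.oneway_anova(groups)
        assert (df1, df2) == (2, 42)

    def test_constant_data_is_an_error(self):
        with pytest.raises(ValueError, match="identical"):
            inf.oneway_anova([[1.0, 1.0], [1.0, 1.0]])


class TestLogLogRegression:
    def test_exact_power_law(self):
        x = np.linspace(0.5, 5, 20)
        y = 2.0 * x**1.7
        res = inf.loglog_regression(x, y)
        assert res.slope == pytest.approx(1.7)
        assert res.intercept == pytest.approx(np.log(2.0))
        assert res.adj_r2 == pytest.approx(1.0)

    def test_permuted_response_has_no_signal(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0.5, 3, 40)
        y = 1.5 * x**0.8 * np.exp(rng.normal(0, 0.1, 40))
        r2s = []
        for s in range(20):
            perm = np.random.default_rng(s).permutation(40)
            r2s.append(inf.loglog_regression(x, y[perm]).adj_r2)
        assert abs(float(np.mean(r2s))) < 0.05

    def test_minimal_fit_degrees_of_freedom(self):
        res = inf.loglog_regression([1.0, 2.0, 3.0], [1.0, 2.1, 2.9])
        assert res.df == (1, 1)

    def test_non_positive_values_named(self):
        with pytest.raises(ValueError, match="record 1"):
            inf.loglog_regression([1.0, -2.0], [1.0, 1.0])
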