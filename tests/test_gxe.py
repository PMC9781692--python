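import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from famgxe import (
    FamGxeError,
    exposure_codes,
    fit_gxe_lmm,
    parametric_bootstrap_ci,
    reml_criterion,
    simulate_from_fit,
    summarize_fit,
)
from famgxe.gxe import GxeLmmFit
from famgxe.simulate import BehaviorSimParams, simulate_phenotypes


def make_fit(s2g, s2gxe, s2e, mu=0.0, alpha=0.0, coding="ordinal",
             design=None):
    return GxeLmmFit(mu_hat=mu, alpha_hat=alpha, se_mu=0.0, se_alpha=0.0,
                     sigma2_G=s2g, sigma2_GxE=s2gxe, sigma2_E=s2e,
                     reml_loglik=0.0, converged=True, coding=coding,
                     n_obs=0, n_families=0, design=design)


class TestFit:
    def test_recovers_generating_variances_at_scale(self):
        # large design: estimates should approach the generating values
        p = BehaviorSimParams(mu=50.0, alpha=3.0, sigma2_G=2.0,
                              sigma2_GxE=5.0, sigma2_E=10.0,
                              families_per_exposure=60, n_per_family=30,
                              seed=21)
        fit = fit_gxe_lmm(simulate_phenotypes(p).table, coding="ordinal")
        assert fit.sigma2_G == pytest.approx(2.0, rel=0.5)
        assert fit.sigma2_GxE == pytest.approx(5.0, rel=0.5)
        assert fit.sigma2_E == pytest.approx(10.0, rel=0.05)
        assert fit.mu_hat == pytest.approx(50.0, abs=1.0)
        assert fit.alpha_hat == pytest.approx(3.0, abs=2.0)

    def test_null_interaction_estimates_near_zero(self):
        # no interaction generated: the mean estimate across replicates
        # stays a small fraction of the residual variance
        est = []
        for rep in range(200):
            p = BehaviorSimParams(mu=10.0, alpha=1.0, sigma2_G=0.3,
                                  sigma2_GxE=0.0, sigma2_E=1.0,
                                  families_per_exposure=20, n_per_family=40,
                                  seed=3000 + rep)
            est.append(fit_gxe_lmm(simulate_phenotypes(p).table,
                                   coding="ordinal").sigma2_GxE)
        assert np.mean(est) <= 0.1
        assert np.median(est) == 0.0  # boundary solutions are exact zeros

    @pytest.mark.parametrize("seed", range(3))
    def test_reml_optimum_beats_theta_grid(self, seed):
        p = BehaviorSimParams(mu=5.0, alpha=0.5, sigma2_G=1.0,
                              sigma2_GxE=2.0, sigma2_E=4.0, n_per_family=10,
                              seed=40 + seed)
        table = simulate_phenotypes(p).table
        fit = fit_gxe_lmm(table, coding="ordinal")
        grid = np.linspace(0, 5, 20)
        grid_min = min(reml_criterion(table, tg, ts, coding="ordinal")
                       for tg in grid for ts in grid)
        assert fit.criterion <= grid_min + 1e-6

    def test_reduced_model_matches_random_intercept_oracle(self, gxe_sim):
        # theta_GxE pinned at 0: the model is the random-intercept LMM,
        # which statsmodels fits independently
        import statsmodels.api as sm

        table = gxe_sim.table.copy()
        res = minimize_scalar(
            lambda tg: reml_criterion(table, abs(tg), 0.0, coding="ordinal"),
            bounds=(0.0, 100.0), method="bounded",
            options={"xatol": 1e-10})
        table["x"] = exposure_codes(table["exposure"], "ordinal")
        md = sm.MixedLM.from_formula("value ~ x", groups="family_id",
                                     data=table)
        ml = md.fit(reml=True)
        # convert: criterion minimizer is theta_G; recompute sigma2s
        from famgxe._reml import build_family_stats, profiled_criterion

        stats = build_family_stats(table["value"].to_numpy(),
                                   table["family_id"].to_numpy(),
                                   covariates=table["x"].to_numpy()[:, None])
        tg = abs(float(res.x))
        _, beta, s2e, _ = profiled_criterion(
            np.full(len(stats.families), tg**2), stats)
        assert tg**2 * s2e == pytest.approx(float(ml.cov_re.iloc[0, 0]),
                                            rel=1e-3, abs=1e-6)
        assert s2e == pytest.approx(float(ml.scale), rel=1e-3)

    def test_full_model_criterion_never_worse_than_reduced(self, gxe_sim):
        fit = fit_gxe_lmm(gxe_sim.table, coding="ordinal")
        res = minimize_scalar(
            lambda tg: reml_criterion(gxe_sim.table, abs(tg), 0.0,
                                      coding="ordinal"),
            bounds=(0.0, 100.0), method="bounded", options={"xatol": 1e-8})
        assert fit.criterion <= res.fun + 1e-8

    def test_matches_lme4_reml(self, gxe_sim, tmp_path):
        # independent oracle: lme4's REML fit of the same random-slope model
        table = gxe_sim.table.copy()
        table["x"] = exposure_codes(table["exposure"], "ordinal")
        csv = tmp_path / "pheno.csv"
        table.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- lmer(value ~ x + (1 | family_id) + (0 + x | family_id),
                      data = d, REML = TRUE)
            vc <- as.data.frame(VarCorr(m))
            cat(vc$vcov, sep = "\\n")
        """))
        out = subprocess.run(["Rscript", "--vanilla", str(script)],
                             capture_output=True, text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        s2g_r, s2gxe_r, s2e_r = [float(v) for v in out.stdout.split()]
        fit = fit_gxe_lmm(gxe_sim.table, coding="ordinal")
        assert fit.sigma2_G == pytest.approx(s2g_r, rel=1e-3, abs=1e-6)
        assert fit.sigma2_GxE == pytest.approx(s2gxe_r, rel=1e-3, abs=1e-6)
        assert fit.sigma2_E == pytest.approx(s2e_r, rel=1e-3)

    def test_cell_coding_fits(self, gxe_sim):
        fit = fit_gxe_lmm(gxe_sim.table, coding="cell")
        assert fit.converged
        assert fit.sigma2_E > 0

    def test_input_validation(self):
        one_env = pd.DataFrame({
            "individual_id": ["a", "b", "c", "d"],
            "family_id": ["F1", "F1", "F2", "F2"],
            "exposure": ["control"] * 4,
            "value": [1.0, 2.0, 3.0, 4.0],
        })
        with pytest.raises(FamGxeError, match="2 exposure"):
            fit_gxe_lmm(one_env)


class TestSummarize:
    def test_sd_and_relative_sd_identities(self):
        fit = make_fit(9.0, 16.0, 4.0)
        tables = summarize_fit(fit)
        var = tables["variances"]
        np.testing.assert_allclose(var["sd"] ** 2, var["variance"])
        rel = tables["relative"].set_index("group")["estimate"]
        assert rel["family"] == pytest.approx(3.0 / 2.0)
        assert rel["family_x_exposure"] == pytest.approx(4.0 / 2.0)
        assert rel["residual"] == pytest.approx(2.0)

    def test_zero_random_variances(self):
        tables = summarize_fit(make_fit(0.0, 0.0, 4.0))
        assert tables["variances"]["sd"].tolist()[:2] == [0.0, 0.0]
        assert tables["relative"]["estimate"].tolist()[:2] == [0.0, 0.0]


class TestSimulateFromFit:
    @staticmethod
    def design():
        return pd.DataFrame({"family_id": [f"F{k}" for k in range(6)],
                             "n": [8] * 6,
                             "x": [0.0, 0.0, 1.0, 1.0, 2.0, 2.0]})

    def test_zero_variances_reproduce_fixed_effects(self):
        fit = make_fit(0.0, 0.0, 0.0, mu=2.0, alpha=3.0, design=self.design())
        sim = simulate_from_fit(fit, seed=0)
        np.testing.assert_allclose(sim["value"],
                                   2.0 + 3.0 * sim["exposure_code"])

    def test_seed_determinism(self):
        fit = make_fit(1.0, 2.0, 3.0, design=self.design())
        a = simulate_from_fit(fit, seed=11)
        b = simulate_from_fit(fit, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_marginal_variance_moment_check(self):
        s2g, s2gxe, s2e = 1.5, 2.0, 3.0
        fit = make_fit(s2g, s2gxe, s2e, mu=1.0, alpha=0.5,
                       design=self.design())
        rng = np.random.default_rng(0)
        resids = []
        for _ in range(500):
            sim = simulate_from_fit(fit, rng=rng)
            resids.append(sim["value"] - 1.0 - 0.5 * sim["exposure_code"])
        resids = np.concatenate(resids)
        x = np.tile(np.repeat(self.design()["x"].to_numpy(), 8), 500)
        expected = s2g + np.mean(x**2) * s2gxe + s2e
        assert np.var(resids) == pytest.approx(expected, rel=0.10)


class TestBootstrap:
    def test_single_replicate_degenerate_percentiles(self, gxe_sim):
        res = parametric_bootstrap_ci(gxe_sim.table, coding="ordinal",
                                      n_boot=1, seed=0,
                                      keep_replicates=True)
        assert res.ci_low == res.ci_high == res.replicates[0]

    def test_null_data_ci_touches_zero(self):
        p = BehaviorSimParams(mu=10.0, alpha=1.0, sigma2_G=0.3,
                              sigma2_GxE=0.0, sigma2_E=1.0,
                              n_per_family=40, seed=77)
        table = simulate_phenotypes(p).table
        res = parametric_bootstrap_ci(table, coding="ordinal", n_boot=100,
                                      seed=1, keep_replicates=True)
        assert res.ci_low == 0.0
        assert not res.significant
        assert (res.replicates == 0.0).mean() > 0.3  # boundary mass

    def test_strong_interaction_detected(self):
        p = BehaviorSimParams(mu=10.0, alpha=1.0, sigma2_G=0.3,
                              sigma2_GxE=4.0, sigma2_E=1.0,
                              n_per_family=40, seed=501)
        table = simulate_phenotypes(p).table
        res = parametric_bootstrap_ci(table, coding="ordinal", n_boot=200,
                                      seed=2)
        assert res.significant
        assert res.ci_low > 0.0
        assert res.ci_low <= res.sigma2_gxe_hat <= res.ci_high
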