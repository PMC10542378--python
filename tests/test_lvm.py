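"""Latent-variable model: algebra oracles, estimation, search, LRT."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import multivariate_normal

from conftest import scaled_config
from httgen.lvm import (
    LatentVariableSEM,
    LvmSpec,
    _loglik,
    _ParamLayout,
    fit_lvm,
    implied_moments,
    lrt_genotypes,
    reduced_spec,
)
from httgen.simulate import COVARIATES, REGIONS, GeneratorConfig, generate_cohort

SPEC3 = LvmSpec(
    regions=("caudate", "putamen", "midbrain"),
    covariates=("rs1137070", "age_c"),
    direct_paths=(),
    residual_cov_pairs=(("caudate", "putamen"),),
)
# theta layout: nu(3), lambda(2), gamma(2), tau2, psi(3), psi_pair
THETA3 = np.array([0.6, 0.7, 0.8, 0.9, 0.7, 0.05, -0.01, 0.02, 0.05, 0.06, 0.04, 0.01])


def _ols_spec():
    return LvmSpec(
        regions=("caudate",), covariates=COVARIATES, direct_paths=(), residual_cov_pairs=()
    )


class TestImpliedMoments:
    def test_no_shared_factor_gives_diagonal_covariance(self):
        theta = THETA3.copy()
        theta[7] = 0.0  # tau2
        theta[11] = 0.0  # pair covariance
        _, cov = implied_moments(SPEC3, theta, np.zeros(2))
        assert cov == pytest.approx(np.diag([0.05, 0.06, 0.04]))

    def test_unit_loadings_zero_noise_gives_all_ones(self):
        spec = LvmSpec(
            regions=("caudate", "putamen", "midbrain"),
            covariates=(),
            direct_paths=(),
            residual_cov_pairs=(),
        )
        theta = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        _, cov = implied_moments(spec, theta, np.zeros((1, 0)))
        assert cov == pytest.approx(np.ones((3, 3)))

    def test_matches_hand_computed_matrix_algebra(self):
        lam = np.array([1.0, 0.9, 0.7])
        tau2, psi, pair = 0.02, np.array([0.05, 0.06, 0.04]), 0.01
        oracle = tau2 * np.outer(lam, lam) + np.diag(psi)
        oracle[0, 1] = oracle[1, 0] = oracle[0, 1] + pair
        x = np.array([1.0, 3.0])
        mean, cov = implied_moments(SPEC3, THETA3, x)
        assert cov == pytest.approx(oracle)
        eta = 0.05 * 1.0 + (-0.01) * 3.0
        assert mean == pytest.approx(np.array([0.6, 0.7, 0.8]) + lam * eta)


class TestLoglik:
    def _instance(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([rng.integers(0, 2, 5), rng.normal(0, 5, 5)]).astype(float)
        Y = rng.normal(0.7, 0.3, (5, 3))
        return X, Y

    def test_matches_multivariate_normal_oracle(self):
        X, Y = self._instance()
        layout = _ParamLayout(SPEC3)
        ll = _loglik(layout, THETA3, X, Y)
        p = layout.unpack(THETA3)
        S = layout.sigma(p["lam"], p["tau2"], p["psi"], p["pairs"])
        oracle = sum(
            multivariate_normal.logpdf(
                Y[i], mean=implied_moments(SPEC3, THETA3, X[i])[0], cov=S
            )
            for i in range(5)
        )
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_invariant_under_row_permutation(self):
        X, Y = self._instance()
        layout = _ParamLayout(SPEC3)
        perm = np.array([4, 2, 0, 1, 3])
        assert _loglik(layout, THETA3, X, Y) == pytest.approx(
            _loglik(layout, THETA3, X[perm], Y[perm]), abs=1e-10
        )

    def test_single_region_equals_univariate_normal_loglik(self):
        rng = np.random.default_rng(5)
        spec = LvmSpec(
            regions=("caudate",), covariates=("age_c",), direct_paths=(), residual_cov_pairs=()
        )
        layout = _ParamLayout(spec)
        x = rng.normal(0, 2, 8)
        y = 0.5 - 0.1 * x + rng.normal(0, 0.3, 8)
        theta = np.array([0.5, -0.1, 0.09])  # nu, gamma, psi
        resid = y - (0.5 - 0.1 * x)
        oracle = -0.5 * np.sum(np.log(2 * np.pi * 0.09) + resid**2 / 0.09)
        assert _loglik(layout, theta, x[:, None], y[:, None]) == pytest.approx(oracle)

    def test_non_positive_definite_covariance_is_signalled(self):
        spec = LvmSpec(
            regions=("caudate", "putamen", "midbrain"),
            covariates=(),
            direct_paths=(),
            residual_cov_pairs=(),
        )
        theta = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        assert _loglik(_ParamLayout(spec), theta, np.zeros((2, 0)), np.zeros((2, 3))) == -np.inf


class TestSpecValidation:
    def test_two_region_latent_spec_rejected(self):
        with pytest.raises(ValueError, match="not identified"):
            LvmSpec(regions=("caudate", "putamen"), direct_paths=(), residual_cov_pairs=())

    def test_direct_paths_to_every_region_rejected(self):
        paths = tuple(("sex", r) for r in REGIONS)
        with pytest.raises(ValueError, match="unidentified"):
            LvmSpec(direct_paths=paths)

    def test_unknown_reference_region_rejected(self):
        with pytest.raises(ValueError, match="reference region"):
            LvmSpec(reference_region="cerebellum")

    def test_more_parameters_than_observations_rejected(self, default_cohort):
        with pytest.raises(ValueError, match="observations"):
            fit_lvm(default_cohort.head(30))


class TestFit:
    def test_single_region_fit_reproduces_ols(self, default_cohort):
        fit = fit_lvm(default_cohort, _ols_spec())
        df = default_cohort.assign(
            age_c=default_cohort["age"] - default_cohort["age"].mean()
        )
        X = sm.add_constant(df[list(COVARIATES)].astype(float))
        ols = sm.OLS(df["caudate"], X).fit()
        est = np.array(
            [fit.params_["nu[caudate]"]]
            + [fit.params_[f"gamma[{c}]"] for c in COVARIATES]
        )
        assert np.abs(est - ols.params.to_numpy()).max() < 1e-6
        assert fit.params_["psi[caudate]"] == pytest.approx(
            float((ols.resid**2).mean()), abs=1e-6
        )

    def test_recovery_of_planted_effects_at_large_n(self, big_fit):
        assert big_fit.converged_
        assert big_fit.params_["gamma[rs1137070]"] == pytest.approx(0.07, abs=0.01)
        assert big_fit.params_["gamma[age_c]"] == pytest.approx(-0.009, abs=0.002)
        assert big_fit.params_["delta[sex->caudate]"] == pytest.approx(0.14, abs=0.015)

    def test_estimation_error_shrinks_with_n(self, big_fit):
        small = fit_lvm(generate_cohort(GeneratorConfig(), seed=11), compute_se=False)
        err_small = abs(small.params_["gamma[rs1137070]"] - 0.07)
        err_big = abs(big_fit.params_["gamma[rs1137070]"] - 0.07)
        assert err_big < err_small

    def test_wald_machinery_consistency(self, default_cohort):
        fit = fit_lvm(default_cohort)
        se = fit.se_["gamma[rs1137070]"]
        est = fit.params_["gamma[rs1137070]"]
        lo, hi = fit.conf_int_.loc["gamma[rs1137070]"]
        assert lo == pytest.approx(est - 1.959964 * se, abs=1e-9)
        assert hi == pytest.approx(est + 1.959964 * se, abs=1e-9)
        from scipy.stats import norm

        assert fit.pvalues_["gamma[rs1137070]"] == pytest.approx(
            2 * norm.sf(abs(est) / se), abs=1e-12
        )

    def test_coverage_of_nominal_wald_intervals(self):
        cfg = scaled_config(1000)
        cover = 0
        n_rep = 25
        for s in range(n_rep):
            c = generate_cohort(cfg, seed=900 + s)
            f = fit_lvm(c)
            lo, hi = f.conf_int_.loc["gamma[rs1137070]"]
            cover += lo <= 0.07 <= hi
        assert cover >= 21  # ~95% nominal; binomial floor at 25 replicates

    def test_genotype_wald_p_roughly_uniform_under_null(self):
        ps = []
        for s in range(30):
            c = generate_cohort(GeneratorConfig.null(), seed=600 + s)
            f = fit_lvm(c)
            ps += [
                f.pvalues_[f"gamma[{v}]"]
                for v in ("httlpr", "rs6295", "rs7333412", "rs1137070", "rs6265")
            ]
        ps = np.asarray(ps)
        assert 0.35 < ps.mean() < 0.65
        assert (ps < 0.05).mean() < 0.12  # 150 draws, nominal 0.05


class TestPathSearch:
    def test_no_candidates_when_spec_is_saturated(self, default_cohort):
        spec = LvmSpec(
            regions=("caudate",), covariates=(), direct_paths=(), residual_cov_pairs=()
        )
        fit = fit_lvm(default_cohort, spec)
        res = fit.path_search()
        assert res.candidates.empty and res.added == []

    def test_null_model_adds_nothing(self, default_cohort):
        fit = fit_lvm(default_cohort)
        res = fit.path_search()
        assert len(res.candidates) == 9 * 7 - 2 + (21 - 3)
        assert (res.candidates["p_fdr"] >= res.candidates["p"] - 1e-12).all()
        assert res.added == []

    def test_planted_direct_path_is_detected(self):
        cfg = scaled_config(2000)
        coh = generate_cohort(cfg, seed=5)
        coh["amygdala"] = coh["amygdala"] + 0.02 * (coh["age"] - coh["age"].mean())
        fit = fit_lvm(coh, compute_se=False)
        res = fit.path_search()
        assert "age_c->amygdala" in res.added

    def test_false_discovery_rate_bounded_on_null_replicates(self):
        # the default generator's true model IS the fitted spec, so every
        # candidate edge is null; with BH at 0.05 the share of replicates with
        # any addition stays small. The chi-square reference is asymptotic —
        # its far tail is optimistic at n = 140 across 79 candidates — so the
        # calibration is checked at n = 500.
        cfg = scaled_config(500)
        n_rep, any_added = 12, 0
        for s in range(n_rep):
            fit = fit_lvm(generate_cohort(cfg, seed=400 + s), compute_se=False)
            any_added += bool(fit.path_search().added)
        assert any_added <= 3

    def test_wald_confirmation_mode_detects_a_planted_path(self, default_cohort):
        spec = LvmSpec(
            regions=("caudate", "putamen", "thalamus", "midbrain"),
            covariates=("rs1137070", "age_c"),
            direct_paths=(),
            residual_cov_pairs=(("thalamus", "midbrain"),),
        )
        coh = default_cohort.copy()
        coh["midbrain"] = coh["midbrain"] + 0.05 * (coh["age"] - coh["age"].mean())
        fit = fit_lvm(coh, spec)
        res = fit.path_search(method="wald")
        assert res.method == "wald"
        assert "age_c->midbrain" in res.added
        assert res.candidates["p"].between(0, 1).all()


class TestLrt:
    def test_identical_specs_give_zero_statistic(self, default_cohort):
        spec = reduced_spec(LvmSpec())  # no genotype terms at all
        stat, df, p = lrt_genotypes(default_cohort, spec)
        assert df == 0
        assert stat == pytest.approx(0.0, abs=1e-4)
        assert p == 1.0

    def test_single_region_matches_closed_form_gaussian_lrt(self, default_cohort):
        spec = _ols_spec()
        stat, df, p = lrt_genotypes(default_cohort, spec)
        assert df == 5
        df_cohort = default_cohort.assign(
            age_c=default_cohort["age"] - default_cohort["age"].mean()
        )
        X_full = sm.add_constant(df_cohort[list(COVARIATES)].astype(float))
        X_red = sm.add_constant(
            df_cohort[[c for c in COVARIATES if c not in
                       ("httlpr", "rs6295", "rs7333412", "rs1137070", "rs6265")]].astype(float)
        )
        y = df_cohort["caudate"]
        rss_full = float((sm.OLS(y, X_full).fit().resid ** 2).sum())
        rss_red = float((sm.OLS(y, X_red).fit().resid ** 2).sum())
        oracle = len(y) * np.log(rss_red / rss_full)
        assert stat == pytest.approx(oracle, abs=1e-4)

    def test_p_roughly_uniform_under_genotype_null(self):
        ps = [
            lrt_genotypes(generate_cohort(GeneratorConfig.null(), seed=100 + s))[2]
            for s in range(20)
        ]
        ps = np.asarray(ps)
        assert 0.25 < ps.mean() < 0.75
        assert (ps < 0.05).mean() <= 0.25

    def test_detects_planted_genotype_effects(self, default_cohort):
        stat, df, p = lrt_genotypes(default_cohort)
        assert df == 6
        assert stat >= 0.0
        assert 0.0 <= p <= 1.0
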