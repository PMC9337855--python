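"""Hierarchical growth-model fitting: information criteria, recovery,
coefficient arithmetic."""

import numpy as np
import pandas as pd
import pytest

from thermogrowth.config import SimConfig
from thermogrowth.curves import powerlaw_size
from thermogrowth.io import phenotypes_to_series
from thermogrowth.nlmm import (
    ModelFit,
    accession_estimates,
    compare_models,
    comparison_table,
    fit_stage1,
    fit_stage2,
    plant_estimates,
    temperature_response,
)
from thermogrowth.series import PlantSeries
from thermogrowth.simulate import simulate_dataset


def mkfit(model_kind, loglik, k, n_obs=291407, q=2, **kw):
    names = ["logM0", "r"] + (["beta"] if model_kind == "powerlaw" else [])
    return ModelFit(
        model_kind=model_kind,
        fixed_effects=pd.Series(np.zeros(len(names)), index=names),
        re_cov=np.eye(q) * 0.1,
        phi=None,
        sigma2=1.0,
        loglik=loglik,
        k=k,
        n_obs=n_obs,
        **kw,
    )


class TestInformationCriteria:
    def test_aic_bic_identities(self):
        fit = mkfit("exponential", loglik=-1234.5, k=6, n_obs=500)
        assert fit.aic == pytest.approx(2 * 6 - 2 * (-1234.5))
        assert fit.bic == pytest.approx(6 * np.log(500) - 2 * (-1234.5))

    def test_published_scale_arithmetic(self):
        """AIC identity at the published stage-1 log-likelihoods: the
        parameter counts 6 (exponential) and 10 (power-law) reproduce the
        reported AIC values to printed precision."""
        exp = mkfit("exponential", loglik=334281.8, k=6)
        pl = mkfit("powerlaw", loglik=435312.5, k=10, q=3)
        assert exp.aic == pytest.approx(-668551.6, abs=0.05)
        assert pl.aic == pytest.approx(-870605.0, abs=0.05)
        assert exp.bic == pytest.approx(-668488.1, abs=0.5)
        assert pl.bic == pytest.approx(-870499.1, abs=0.5)

    def test_asymmetric_re_cov_rejected(self):
        C = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            ModelFit(
                model_kind="exponential",
                fixed_effects=pd.Series([0.0, 0.0], index=["logM0", "r"]),
                re_cov=C, phi=None, sigma2=1.0, loglik=0.0, k=6, n_obs=10,
            )


class TestCompareModels:
    def test_likelihood_ratio_and_pvalue(self):
        exp = mkfit("exponential", loglik=334281.8, k=6)
        pl = mkfit("powerlaw", loglik=435312.5, k=10, q=3)
        cmp = compare_models(exp, pl)
        assert cmp["l_ratio"] == pytest.approx(2 * (435312.5 - 334281.8))
        assert cmp["df_diff"] == 4
        assert cmp["p_value"] < 0.001
        assert cmp["preferred"] == "powerlaw"

    def test_identical_logliks_give_null_result(self):
        exp = mkfit("exponential", loglik=-100.0, k=6)
        pl = mkfit("powerlaw", loglik=-100.0, k=10, q=3)
        cmp = compare_models(exp, pl)
        assert cmp["l_ratio"] == 0.0 and cmp["p_value"] == 1.0

    def test_non_nested_counts_rejected(self):
        exp = mkfit("exponential", loglik=-100.0, k=10)
        pl = mkfit("powerlaw", loglik=-90.0, k=10, q=3)
        with pytest.raises(ValueError, match="nest"):
            compare_models(exp, pl)

    def test_comparison_table_layout(self):
        exp = mkfit("exponential", loglik=-100.0, k=6, n_obs=50)
        pl = mkfit("powerlaw", loglik=-90.0, k=10, n_obs=50, q=3)
        tab = comparison_table(exp, pl)
        assert list(tab.columns) == ["model", "df", "AIC", "BIC", "logLik", "L.ratio", "p"]
        assert tab["df"].tolist() == [6, 10]


class TestStage1:
    def test_parameter_counts_and_nesting(self, small_series):
        fit_exp = fit_stage1(small_series, "exponential")
        fit_pl = fit_stage1(small_series, "powerlaw")
        assert fit_exp.k == 6  # 2 fixed + 3 RE-cov + 1 residual
        assert fit_pl.k == 10  # 3 fixed + 6 RE-cov + 1 residual
        assert fit_pl.loglik >= fit_exp.loglik - 3.0  # nesting, optimizer slack
        assert abs(fit_pl.fixed_effects["beta"] - 0.9) < 0.05

    def test_unknown_model_kind_rejected(self, small_series):
        with pytest.raises(ValueError, match="model_kind"):
            fit_stage1(small_series, "gompertz")


class TestStage2:
    def test_beta_and_phi_recovery(self, stage2_fit, small_dataset):
        cfg, truth, _, _ = small_dataset
        assert abs(stage2_fit.fixed_effects["beta"] - cfg.beta_true) < 0.05
        assert abs(stage2_fit.phi - cfg.phi_true) < 0.3
        est = accession_estimates(stage2_fit)
        m = est.merge(truth.accession_params, on="accession", suffixes=("_hat", "_true"))
        pooled = np.corrcoef(
            np.r_[m.r16_hat, m.r6_hat], np.r_[m.r16_true, m.r6_true]
        )[0, 1]
        assert pooled > 0.9

    def test_k_counts_fixed_effects_and_variances(self, stage2_fit):
        A = len(stage2_fit.accessions)
        assert stage2_fit.k == (3 * A + 1) + 6 + 1 + 1  # fixed + RE cov + sigma2 + phi

    def test_phi_near_zero_when_noise_white(self):
        # the Laplace linearization leaves a small positive bias in phi at
        # truth 0 (smooth residuals of shrunken modes), hence the 0.15 bound
        cfg = SimConfig.desk_scale(seed=6, n_accessions=12, n_experiments=3,
                                   phi_true=0.0, artifact_rate=0.0)
        _, pheno, _ = simulate_dataset(cfg)
        fit = fit_stage2(phenotypes_to_series(pheno), car1=True)
        assert fit.phi < 0.15

    def test_noiseless_fixed_effects_recovered(self):
        """Without noise or random effects the stage-2 fixed effects
        reproduce the generating parameters almost exactly."""
        t = np.linspace(0, 21, 12)
        beta = 0.9
        params = {("a1", "16C"): (30.0, 0.25), ("a1", "6C"): (30.0, 0.10),
                  ("a2", "16C"): (40.0, 0.28), ("a2", "6C"): (40.0, 0.12),
                  ("a3", "16C"): (25.0, 0.22), ("a3", "6C"): (25.0, 0.09)}
        series = []
        for i, ((acc, temp), (m0, r)) in enumerate(params.items()):
            for rep in range(2):
                series.append(PlantSeries(
                    plant_id=f"p{i}_{rep}", accession=acc, experiment="e1",
                    temperature=temp, times=t,
                    areas=powerlaw_size(t, m0, r, beta)))
        fit = fit_stage2(series, car1=False)
        est = accession_estimates(fit).set_index("accession")
        assert fit.fixed_effects["beta"] == pytest.approx(beta, abs=1e-3)
        for acc in ("a1", "a2", "a3"):
            assert est.at[acc, "M0"] == pytest.approx(params[(acc, "16C")][0], rel=1e-4)
            assert est.at[acc, "r16"] == pytest.approx(params[(acc, "16C")][1], rel=1e-4)
            assert est.at[acc, "r6"] == pytest.approx(params[(acc, "6C")][1], rel=1e-4)

    def test_single_temperature_warns(self, small_series):
        warm = [s for s in small_series if s.temperature == "16C"]
        with pytest.warns(UserWarning, match="single temperature"):
            fit = fit_stage2(warm, car1=False, max_outer=30)
        assert np.isnan(accession_estimates(fit)["r6"]).all()


class TestExtraction:
    def _handmade_fit(self):
        names = ["logM0:(Intercept)", "logM0:a2", "r:(Intercept)", "r:a2",
                 "r:temp6C", "r:a2:temp6C", "beta"]
        vals = [np.log(30.0), 0.2, 0.25, 0.03, -0.15, -0.01, 0.9]
        plants = pd.DataFrame({
            "plant_id": ["p1", "p2"], "accession": ["a1", "a2"],
            "experiment": ["e1", "e1"], "temperature": ["16C", "6C"],
            "b_logM0": [0.0, 0.1], "b_r": [0.0, -0.02], "b_beta": [0.0, 0.0],
        })
        return ModelFit(
            model_kind="powerlaw", fixed_effects=pd.Series(vals, index=names),
            re_cov=np.eye(3) * 1e-4, phi=0.5, sigma2=1.0, loglik=-10.0, k=14,
            n_obs=100, plants=plants, accessions=["a1", "a2"],
            temperatures=["16C", "6C"],
        )

    def test_accession_estimates_reference_coding(self):
        est = accession_estimates(self._handmade_fit()).set_index("accession")
        assert est.at["a1", "M0"] == pytest.approx(30.0)
        assert est.at["a1", "r16"] == pytest.approx(0.25)
        assert est.at["a1", "r6"] == pytest.approx(0.25 - 0.15)
        assert est.at["a2", "M0"] == pytest.approx(30.0 * np.exp(0.2))
        assert est.at["a2", "r16"] == pytest.approx(0.28)
        assert est.at["a2", "r6"] == pytest.approx(0.25 + 0.03 - 0.15 - 0.01)
        assert est.at["a2", "response"] == pytest.approx(est.at["a2", "r16"] - est.at["a2", "r6"])

    def test_plant_estimates_add_modes(self):
        fit = self._handmade_fit()
        pe = plant_estimates(fit).set_index("plant_id")
        assert pe.at["p1", "M0"] == pytest.approx(30.0)  # zero RE -> accession value
        assert pe.at["p1", "r"] == pytest.approx(0.25)
        assert pe.at["p2", "M0"] == pytest.approx(30.0 * np.exp(0.2 + 0.1))
        assert pe.at["p2", "r"] == pytest.approx(0.25 + 0.03 - 0.15 - 0.01 - 0.02)

    def test_plant_estimates_beat_accession_means(self, stage2_fit, small_dataset):
        """Conditional modes track plant-level truth better than the
        accession fixed effects alone."""
        _, _, _, plant_truth = small_dataset
        pe = plant_estimates(stage2_fit).merge(
            plant_truth[["plant_id", "M0", "r"]], on="plant_id",
            suffixes=("_hat", "_true"))
        acc = accession_estimates(stage2_fit).set_index("accession")
        acc_r = np.where(pe["temperature"] == "16C",
                         acc.loc[pe["accession"], "r16"],
                         acc.loc[pe["accession"], "r6"])
        r_plant = np.corrcoef(pe["r_hat"], pe["r_true"])[0, 1]
        r_acc = np.corrcoef(acc_r, pe["r_true"])[0, 1]
        assert r_plant > r_acc

    def test_shrinkage_centers_on_accession_estimates(self, stage2_fit):
        pe = plant_estimates(stage2_fit)
        acc = accession_estimates(stage2_fit).set_index("accession")
        merged = pe.groupby(["accession", "temperature"])["r"].mean().reset_index()
        for _, row in merged.iterrows():
            ref = acc.at[row.accession, "r16" if row.temperature == "16C" else "r6"]
            assert abs(row.r - ref) < 0.05


class TestTemperatureResponse:
    @pytest.mark.parametrize("r6, r16, expected", [(0.1, 0.4, 0.3), (0.2, 0.2, 0.0)])
    def test_difference(self, r6, r16, expected):
        assert temperature_response(r6, r16) == pytest.approx(expected)

    def test_matches_ordered_contrast_up_to_scale(self):
        """An ordered two-level polynomial contrast slope equals the plain
        difference divided by sqrt(2): same sign, fixed rescaling."""
        rng = np.random.default_rng(0)
        r6 = rng.uniform(0.05, 0.15, 20)
        r16 = rng.uniform(0.2, 0.3, 20)
        contrast = np.array([-1 / np.sqrt(2), 1 / np.sqrt(2)])
        for a, b in zip(r6, r16):
            X = np.stack([np.ones(2), contrast], 1)
            slope = np.linalg.lstsq(X, np.array([a, b]), rcond=None)[0][1]
            resp = temperature_response(a, b)
            assert slope == pytest.approx(resp / np.sqrt(2))
            assert np.sign(slope) == np.sign(resp)
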