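"""Kinship, heritability, and structure-corrected correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thermogrowth.config import SimConfig
from thermogrowth.quantgen import (
    CorrResult,
    H2Result,
    KinshipMatrix,
    heritability,
    kinship_centered,
    kinship_corrected_correlation,
    pearson_correlations,
    standardize,
    variance_partition,
)
from thermogrowth.simulate import simulate_genotypes, simulate_neutral_phenotype


class TestKinship:
    def test_hand_computed_three_accession_example(self):
        G = np.array([[0, 1], [1, 0], [1, 1]], dtype=float)
        kin = kinship_centered(G, ids=["a", "b", "c"])
        Gc = G - G.mean(axis=0)
        expected = Gc @ Gc.T / 2.0
        np.testing.assert_allclose(kin.K, expected, atol=1e-12)

    def test_rows_sum_to_zero(self, panel_kinship):
        assert np.abs(panel_kinship.K.sum(axis=1)).max() < 1e-8

    def test_identical_accessions_have_equal_rows(self):
        rng = np.random.default_rng(0)
        G = (rng.random((6, 80)) < 0.4).astype(float)
        G[3] = G[0]
        kin = kinship_centered(G)
        np.testing.assert_allclose(kin.K[0], kin.K[3], atol=1e-12)

    def test_psd_and_sorted_eigensystem(self, panel_kinship):
        assert panel_kinship.eigvals.min() > -1e-8 * panel_kinship.eigvals.max()
        assert np.all(np.diff(panel_kinship.eigvals) <= 1e-12)

    def test_monomorphic_only_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            kinship_centered(np.ones((4, 3)))

    def test_missing_calls_mean_imputed(self):
        rng = np.random.default_rng(1)
        G = (rng.random((10, 50)) < 0.5).astype(float)
        G2 = G.copy()
        G2[0, 0] = np.nan
        kin = kinship_centered(G2)
        assert np.isfinite(kin.K).all()

    def test_trace_stable_under_snp_bootstrap(self, panel_truth):
        _, truth = panel_truth
        G = truth.genotypes.to_numpy(float)
        rng = np.random.default_rng(3)
        traces = []
        for _ in range(12):
            cols = rng.choice(G.shape[1], size=G.shape[1], replace=True)
            traces.append(np.trace(kinship_centered(G[:, cols]).K) / G.shape[0])
        traces = np.array(traces)
        assert traces.std() / traces.mean() < 0.10


class TestPearsonCorrelations:
    def test_perfect_and_null_pairs(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10_000)
        idx = [f"a{i}" for i in range(x.size)]
        traits = pd.DataFrame({"t": x}, index=idx)
        climate = pd.DataFrame({"same": x, "indep": rng.normal(size=x.size)}, index=idx)
        res = {r.variable: r for r in pearson_correlations(traits, climate)}
        assert res["same"].pearson_r == pytest.approx(1.0)
        assert abs(res["indep"].pearson_r) < 0.05
        assert 0 < res["indep"].p_pearson <= 1

    def test_zero_variance_reported_missing(self):
        idx = list("abcd")
        traits = pd.DataFrame({"t": [1.0, 2.0, 3.0, 4.0]}, index=idx)
        climate = pd.DataFrame({"const": [5.0] * 4}, index=idx)
        (res,) = pearson_correlations(traits, climate)
        assert np.isnan(res.pearson_r)


class TestKinshipCorrectedCorrelation:
    def test_identity_kinship_reduces_to_pearson(self):
        rng = np.random.default_rng(2)
        n = 80
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        kin = KinshipMatrix(K=np.eye(n), ids=[str(i) for i in range(n)])
        res = kinship_corrected_correlation(y, x, kin)
        assert res.corrected_beta == pytest.approx(res.pearson_r, abs=1e-6)

    def test_structure_confounding_attenuated(self, panel_kinship):
        """When x and y are only linked through the leading axis of
        structure, the corrected coefficient shrinks toward zero."""
        rng = np.random.default_rng(3)
        pc1 = panel_kinship.eigvecs[:, 0]
        y = pc1 + 0.05 * rng.normal(size=pc1.size)
        x = pc1 + 0.5 * rng.normal(size=pc1.size)
        res = kinship_corrected_correlation(y, x, panel_kinship)
        assert abs(res.corrected_beta) < abs(res.pearson_r)

    def test_type_one_error_calibrated(self, panel_kinship):
        """Monte-Carlo size of the corrected Wald test under independent
        structured traits."""
        rng = np.random.default_rng(4)
        n_sims = 400
        Y = simulate_neutral_phenotype(panel_kinship.K, 1.0, rng, size=n_sims)
        X = simulate_neutral_phenotype(panel_kinship.K, 1.0, rng, size=n_sims)
        rej = 0
        for y, x in zip(Y, X):
            res = kinship_corrected_correlation(y, x, panel_kinship)
            rej += res.p_corrected < 0.05
        assert abs(rej / n_sims - 0.05) < 0.03


class TestHeritability:
    @staticmethod
    def _table(rng, n_acc=40, n_rep=6, vg=1.0, ve=1.0, exp_effect=0.0):
        acc_vals = rng.normal(0, np.sqrt(vg), n_acc)
        rows = []
        for i in range(n_acc):
            for j in range(n_rep):
                exp = f"e{j % 2}"
                rows.append({
                    "accession": f"a{i}", "experiment": exp, "temperature": "16C",
                    "r": acc_vals[i] + rng.normal(0, np.sqrt(ve))
                    + (exp_effect if exp == "e1" else 0.0),
                })
        return pd.DataFrame(rows)

    def test_identical_replicates_give_h2_one(self):
        rng = np.random.default_rng(0)
        df = self._table(rng, ve=1e-12)
        res = heritability(df, "r")
        assert res.H2 > 0.99

    def test_shuffled_labels_give_h2_near_zero(self):
        rng = np.random.default_rng(1)
        df = self._table(rng, vg=1.0, ve=1.0)
        df["accession"] = rng.permutation(df["accession"].to_numpy())
        res = heritability(df, "r")
        assert res.H2 < 0.05

    def test_boundary_estimate_warns_and_clamps(self):
        # accession means identical, all variance within: Vg sits at the boundary
        df = pd.DataFrame({
            "accession": np.repeat([f"a{i}" for i in range(10)], 4),
            "experiment": ["e0"] * 40,
            "temperature": ["16C"] * 40,
            "r": np.tile([-1.0, 1.0, -2.0, 2.0], 10),
        })
        with pytest.warns(UserWarning, match="boundary"):
            res = heritability(df, "r")
        assert res.H2 == 0.0 and res.Vg == 0.0

    def test_recovery_and_experiment_adjustment(self):
        rng = np.random.default_rng(2)
        df = self._table(rng, n_acc=120, n_rep=10, vg=1.0, ve=1.0, exp_effect=3.0)
        res = heritability(df, "r")
        assert abs(res.H2 - 0.5) < 0.1  # experiment shift absorbed by fixed effect

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        df = self._table(rng)
        res1 = heritability(df, "r")
        df2 = df.assign(r=5.0 * df["r"] - 7.0)
        res2 = heritability(df2, "r")
        assert res2.H2 == pytest.approx(res1.H2, abs=1e-6)

    def test_matches_statsmodels_reml(self):
        """Independent oracle: statsmodels MixedLM (REML) on the same layout."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(4)
        df = self._table(rng, n_acc=30, n_rep=5, vg=0.8, ve=1.2, exp_effect=0.5)
        res = heritability(df, "r")
        sm_fit = smf.mixedlm("r ~ experiment", df, groups=df["accession"]).fit(reml=True)
        vg_sm = float(sm_fit.cov_re.iloc[0, 0])
        ve_sm = float(sm_fit.scale)
        assert res.Vg == pytest.approx(vg_sm, rel=1e-3)
        assert res.Ve == pytest.approx(ve_sm, rel=1e-3)

    def test_temperature_subsetting(self):
        rng = np.random.default_rng(5)
        df = self._table(rng)
        df2 = df.copy()
        df2["temperature"] = "6C"
        df2["r"] = rng.normal(size=len(df2))  # no accession signal at 6C
        both = pd.concat([df, df2], ignore_index=True)
        h_warm = heritability(both, "r", temperature="16C")
        assert h_warm.H2 > 0.2


class TestVariancePartition:
    def test_orthogonal_fractions_sum_to_r2(self):
        rng = np.random.default_rng(0)
        n = 400
        x1 = rng.normal(size=n)
        x1 -= x1.mean()
        x2 = rng.normal(size=n)
        x2 -= x2.mean()
        x2 = x2 - x1 * (x1 @ x2) / (x1 @ x1)  # exactly sample-orthogonal
        y = 0.6 * x1 + 0.3 * x2 + rng.normal(0, 0.5, n)
        out = variance_partition(y, x1, x2)
        assert out["frac_winter_temp"] + out["frac_seed_size"] == pytest.approx(
            out["r2_joint"], abs=1e-6)

    def test_irrelevant_seed_size_gets_zero_fraction(self):
        rng = np.random.default_rng(1)
        n = 500
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = 0.7 * x1 + rng.normal(0, 0.5, n)
        out = variance_partition(y, x1, x2)
        assert out["frac_seed_size"] < 0.02
        assert out["p_winter_temp_corrected"] < 1e-6

    def test_collinear_predictors_rejected(self):
        x = np.random.default_rng(2).normal(size=50)
        with pytest.raises(ValueError, match="collinear"):
            variance_partition(x + 1.0, x, x * 1.0000001)


class TestStandardize:
    def test_idempotent(self):
        x = np.random.default_rng(0).normal(3.0, 2.0, 100)
        z = standardize(x)
        np.testing.assert_allclose(standardize(z), z, atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            standardize(np.ones(5))
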