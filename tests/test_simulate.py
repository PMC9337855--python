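"""Generator contracts: structure, calibration targets, determinism."""

import numpy as np
import pandas as pd
import pytest

from thermogrowth.config import SimConfig
from thermogrowth.curves import powerlaw_size
from thermogrowth.quantgen import kinship_centered
from thermogrowth.simulate import (
    car1_noise,
    simulate_climate_and_traits,
    simulate_dataset,
    simulate_genotypes,
    simulate_neutral_phenotype,
    simulate_plant_series,
)


def hudson_fst(G: np.ndarray, pops: np.ndarray) -> float:
    """Independent two-population Hudson-style Fst estimator (mean of ratios
    of averages over SNPs), used as an oracle for the Balding-Nichols draw."""
    labels = np.unique(pops)
    num, den = 0.0, 0.0
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            g1, g2 = G[pops == labels[i]], G[pops == labels[j]]
            p1, p2 = g1.mean(0), g2.mean(0)
            n1, n2 = g1.shape[0], g2.shape[0]
            within = p1 * (1 - p1) * n1 / (n1 - 1) + p2 * (1 - p2) * n2 / (n2 - 1)
            between = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
            num += np.sum(between)
            den += np.sum(between + within)
    return num / den


class TestGenotypes:
    def test_balding_nichols_fst_matches_target(self):
        cfg = SimConfig(n_accessions=150, n_pops=3, fst=0.3, n_snps=1000, seed=3)
        G, pops = simulate_genotypes(cfg)
        est = hudson_fst(G.to_numpy(float), pops.to_numpy())
        assert abs(est - 0.3) < 0.05

    def test_no_divergence_limit(self):
        cfg = SimConfig(n_accessions=200, n_pops=2, fst=1e-6, n_snps=400, seed=4)
        G, pops = simulate_genotypes(cfg)
        X, lab = G.to_numpy(float), pops.to_numpy()
        diff = X[lab == "pop0"].mean(0) - X[lab == "pop1"].mean(0)
        assert np.var(diff) < 0.01

    def test_fst_zero_multiple_pops_warns(self):
        cfg = SimConfig(n_accessions=20, n_pops=2, fst=0.0, n_snps=50, seed=1)
        with pytest.warns(UserWarning, match="panmixia"):
            simulate_genotypes(cfg)

    def test_all_snps_segregate(self):
        cfg = SimConfig(n_accessions=30, n_pops=2, n_snps=300, seed=5)
        G, _ = simulate_genotypes(cfg)
        counts = G.sum(axis=0)
        assert ((counts > 0) & (counts < 30)).all()

    def test_deterministic_under_seed(self):
        cfg = SimConfig(n_accessions=25, n_snps=100, seed=11)
        G1, p1 = simulate_genotypes(cfg)
        G2, p2 = simulate_genotypes(cfg)
        pd.testing.assert_frame_equal(G1, G2)
        pd.testing.assert_series_equal(p1, p2)


class TestClimateAndTraits:
    def test_default_calibration_targets(self, panel_truth):
        """Realized trait-climate and seed-size correlations track the
        generator targets at panel size (+-0.1)."""
        cfg, truth = panel_truth
        clim = truth.climate["bio11_winter_temp_C"].to_numpy()
        ap = truth.accession_params
        for trait, target in cfg.target_climate_r.items():
            r = np.corrcoef(ap[trait], clim)[0, 1]
            assert abs(r - target) < 0.1, f"{trait}: r={r:.3f} target={target}"
        seed = truth.seed_size["seed_size_mm2"].to_numpy()
        assert abs(np.corrcoef(seed, clim)[0, 1] - cfg.seed_climate_r) < 0.1
        assert abs(np.corrcoef(ap["M0"], seed)[0, 1] - cfg.seed_m0_r) < 0.12

    def test_null_climate_target(self):
        cfg = SimConfig(seed=9, target_climate_r={"M0": 0.0, "r16": 0.0, "r6": 0.0})
        G, pops = simulate_genotypes(cfg)
        truth = simulate_climate_and_traits(cfg, G, pops)
        clim = truth.climate["bio11_winter_temp_C"].to_numpy()
        for trait in ("M0", "r16", "r6"):
            assert abs(np.corrcoef(truth.accession_params[trait], clim)[0, 1]) < 0.15

    def test_infeasible_targets_rejected(self):
        cfg = SimConfig(seed=1, n_accessions=50, n_snps=100,
                        target_climate_r={"M0": -0.39, "r16": 0.995, "r6": 0.28})
        G, pops = simulate_genotypes(cfg)
        with pytest.raises(ValueError, match="variance"):
            simulate_climate_and_traits(cfg, G, pops)

    def test_h2_targets_on_replicate_draws(self):
        """One-way variance components on the plant-level draws recover the
        broad-sense targets."""
        cfg = SimConfig(seed=13, n_accessions=150, n_snps=200, n_pops=3,
                        target_h2={"M0": 0.5, "r16": 0.5, "r6": 0.5},
                        timepoints=(0.0, 1.0, 2.0, 3.0), n_reps=5, n_experiments=3)
        truth, _, plant_truth = simulate_dataset(cfg)
        sub = plant_truth[plant_truth.temperature_C == "16C"].copy()
        # remove experiment means, then one-way ANOVA over accessions
        sub["r_adj"] = sub["r"] - sub.groupby("experiment")["r"].transform("mean")
        within = sub.groupby("accession")["r_adj"].var(ddof=1).mean()
        between = sub.groupby("accession")["r_adj"].mean().var(ddof=1) - within / 15
        h2 = between / (between + within)
        assert abs(h2 - 0.5) < 0.1


class TestPlantSeries:
    def test_noiseless_series_equals_forward_model(self):
        cfg = SimConfig.desk_scale(seed=21, n_accessions=5, sigma_meas=0.0,
                                   artifact_rate=0.0)
        truth, pheno, plant_truth = simulate_dataset(cfg)
        pt = plant_truth.set_index("plant_id")
        t = np.asarray(cfg.timepoints)
        for pid, g in pheno.groupby("plant_id"):
            expected = powerlaw_size(t, pt.at[pid, "M0"], pt.at[pid, "r"], cfg.beta_true)
            np.testing.assert_allclose(g["area"].to_numpy(), expected, rtol=1e-12)
            np.testing.assert_allclose(g["time_dap"].to_numpy(), t + 14.0)

    def test_car1_noise_correlation(self):
        rng = np.random.default_rng(2)
        t = np.arange(0, 40, 0.5)
        draws = np.array([car1_noise(t, 1.0, 0.6, rng) for _ in range(800)])
        lag1 = np.corrcoef(draws[:, :-1].ravel(), draws[:, 1:].ravel())[0, 1]
        assert abs(lag1 - 0.6**0.5) < 0.03  # phi**dt at dt = 0.5
        white = np.array([car1_noise(t, 1.0, 0.0, rng) for _ in range(400)])
        lag1w = np.corrcoef(white[:, :-1].ravel(), white[:, 1:].ravel())[0, 1]
        assert abs(lag1w) < 0.03

    def test_artifact_rate_matches_filter_removals(self):
        from thermogrowth.io import phenotypes_to_series

        cfg = SimConfig.desk_scale(seed=22, n_accessions=20, artifact_rate=0.05,
                                   sigma_meas=0.5)
        truth, pheno, _ = simulate_dataset(cfg)
        series = phenotypes_to_series(pheno)
        kept = sum(len(s) for s in series)
        total = len(pheno)
        removed = 1 - kept / total
        assert 0.02 < removed < 0.10  # ~ artifact_rate, some noise dips too

    def test_full_dataset_deterministic(self):
        cfg = SimConfig.desk_scale(seed=33, n_accessions=6)
        _, p1, t1 = simulate_dataset(cfg)
        _, p2, t2 = simulate_dataset(cfg)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(t1, t2)


class TestNeutralPhenotype:
    def test_zero_variance_gives_constant(self, panel_kinship):
        rng = np.random.default_rng(0)
        z = simulate_neutral_phenotype(panel_kinship.K, 0.0, rng, mu=3.0)
        np.testing.assert_allclose(z, 3.0, atol=1e-12)

    def test_identity_kinship_iid(self):
        rng = np.random.default_rng(1)
        Z = simulate_neutral_phenotype(np.eye(40), 2.5, rng, size=4000)
        assert abs(Z.var() - 2.5) < 0.1
        offdiag = np.corrcoef(Z[:, 0], Z[:, 1])[0, 1]
        assert abs(offdiag) < 0.05

    def test_covariance_proportional_to_kinship(self):
        cfg = SimConfig(n_accessions=40, n_snps=500, seed=8)
        G, _ = simulate_genotypes(cfg)
        K = kinship_centered(G).K
        rng = np.random.default_rng(2)
        Z = simulate_neutral_phenotype(K, 1.0, rng, size=6000)
        emp = np.cov(Z, rowvar=False)
        iu = np.triu_indices(40)
        r = np.corrcoef(emp[iu], K[iu])[0, 1]
        assert r > 0.95

    def test_non_psd_rejected(self):
        K = np.eye(5)
        K[0, 0] = -1.0
        with pytest.raises(ValueError, match="PSD"):
            simulate_neutral_phenotype(K, 1.0, np.random.default_rng(0))
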