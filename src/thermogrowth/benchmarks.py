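"""Desk-scale benchmark routines validating the pipeline end to end.

Each function runs a self-contained study: simulate data with known truth,
run the estimation machinery, and measure recovery or calibration.  They are
used both by the test suite and by the repository's acceptance script; sizes
are chosen to finish on a single CPU in minutes (documented in
docs/methods.md).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import solve_ivp

from .config import SimConfig
from .curves import exponential_size, powerlaw_size
from .gwas import lmm_scan, maf_filter
from .io import phenotypes_to_series
from .nlmm import ModelFit, accession_estimates, fit_stage1, fit_stage2, select_growth_model
from .qpc import conditional_eigen, qpc_test
from .quantgen import KinshipMatrix, heritability, kinship_centered
from .series import PlantSeries, clean_series
from .simulate import simulate_dataset, simulate_genotypes, simulate_neutral_phenotype

# published stage-1 log-likelihoods used as inputs to the information-
# criterion identities (the data behind them are not desk-reproducible)
REFERENCE_LOGLIK = {"exponential": 334281.8, "powerlaw": 435312.5}


def _sub_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence(seed).generate_state(index + 1)[index] % (2**31))


def table1_arithmetic(seed: int = 0) -> dict:
    """Stage-1 parameter counts and the AIC identity at the published
    log-likelihoods.

    The parameter counts come from actually fitting both stage-1 families on
    a small simulated dataset (they are structural: fixed effects + unique
    RE-covariance entries + residual variance); the AICs apply the 2k - 2logL
    identity at the published likelihood values.
    """
    cfg = SimConfig.desk_scale(seed=_sub_seed(seed, 0), n_accessions=6,
                               n_experiments=2, timepoints=tuple(np.linspace(0, 21, 8)))
    _, pheno, _ = simulate_dataset(cfg)
    series = phenotypes_to_series(pheno)
    fit_exp = fit_stage1(series, "exponential", max_outer=20)
    fit_pl = fit_stage1(series, "powerlaw", max_outer=20)
    out = {"stage1_df_exponential": fit_exp.k, "stage1_df_powerlaw": fit_pl.k}
    for kind, fit in (("exponential", fit_exp), ("powerlaw", fit_pl)):
        ref = ModelFit(
            model_kind=kind, fixed_effects=fit.fixed_effects, re_cov=fit.re_cov,
            phi=None, sigma2=fit.sigma2, loglik=REFERENCE_LOGLIK[kind], k=fit.k,
            n_obs=fit.n_obs,
        )
        out[f"stage1_aic_{kind}"] = ref.aic
    out["n"] = len(series)
    return out


def powerlaw_limit_error(n_grid: int = 64) -> dict:
    """Max relative deviation of the power law at beta = 1 - 1e-7 from the
    exponential, over t in [0, 21]."""
    t = np.linspace(0.0, 21.0, n_grid)
    pl = powerlaw_size(t, 20.0, 0.2, 1.0 - 1e-7)
    ex = exponential_size(t, 20.0, 0.2)
    return {"value": float(np.max(np.abs(pl - ex) / ex)), "n": n_grid}


def ode_equivalence_error(seed: int = 0, n_grid: int = 10) -> dict:
    """Closed-form power-law curve vs RK45 integration of dM/dt = r*M**beta
    over a parameter grid; returns the max relative error."""
    rng = np.random.default_rng(_sub_seed(seed, 1))
    worst = 0.0
    for _ in range(n_grid):
        M0 = rng.uniform(5.0, 60.0)
        r = rng.uniform(0.05, 0.5)
        beta = rng.uniform(0.5, 0.98)
        t = np.linspace(0, 21, 12)
        sol = solve_ivp(lambda s, m: r * m**beta, (0.0, 21.0), [M0],
                        method="RK45", rtol=1e-10, atol=1e-12, dense_output=True)
        closed = powerlaw_size(t, M0, r, beta)
        worst = max(worst, float(np.max(np.abs(closed - sol.sol(t)[0]) / closed)))
    return {"value": worst, "n": n_grid}


def recovery_benchmark(seed: int = 0, n_reps: int = 20) -> dict:
    """Stage-2 parameter recovery over replicate simulated studies.

    Conditions: 50 accessions x 3 experiments x 1 plant x 2 treatments,
    20 timepoints over 21 days, beta = 0.9, phi = 0.6.  Reports the median
    absolute beta error, the median phi estimate, and the median Spearman
    rank correlation between estimated and true accession growth rates
    (both temperatures pooled).
    """
    beta_errs, phis, rhos = [], [], []
    for rep in range(n_reps):
        cfg = SimConfig.desk_scale(seed=_sub_seed(seed, 2) + rep)
        truth, pheno, _ = simulate_dataset(cfg)
        series = phenotypes_to_series(pheno)
        fit = fit_stage2(series, car1=True, seed=rep)
        est = accession_estimates(fit)
        m = est.merge(truth.accession_params, on="accession", suffixes=("_hat", "_true"))
        rho = stats.spearmanr(
            np.r_[m.r16_hat, m.r6_hat], np.r_[m.r16_true, m.r6_true]
        ).statistic
        beta_errs.append(abs(fit.fixed_effects["beta"] - cfg.beta_true))
        phis.append(fit.phi)
        rhos.append(rho)
    return {
        "beta_median_abs_error": float(np.median(beta_errs)),
        "phi_median": float(np.median(phis)),
        "rank_correlation_median": float(np.median(rhos)),
        "n": n_reps,
    }


def model_selection_benchmark(seed: int = 0, n_reps: int = 20) -> dict:
    """Size and power of the stage-1 likelihood-ratio test.

    Data are simulated under each curve family with i.i.d. Gaussian noise
    (the test's own residual assumption): power-law truth at beta = 0.8
    should be detected at p < 0.001; exponential truth should not prefer the
    power law at that level.
    """
    detected = 0
    for rep in range(n_reps):
        cfg = SimConfig.desk_scale(
            seed=_sub_seed(seed, 3) + rep, n_accessions=20, n_experiments=2,
            beta_true=0.8, phi_true=0.0, artifact_rate=0.0)
        _, pheno, _ = simulate_dataset(cfg)
        _, _, cmp = select_growth_model(phenotypes_to_series(pheno), seed=rep)
        detected += cmp["p_value"] < 0.001
    not_preferred = 0
    for rep in range(n_reps):
        cfg = SimConfig.desk_scale(
            seed=_sub_seed(seed, 4) + rep, n_accessions=20, n_experiments=2,
            beta_true=1.0, phi_true=0.0, artifact_rate=0.0)
        _, pheno, _ = simulate_dataset(cfg)
        _, _, cmp = select_growth_model(phenotypes_to_series(pheno), seed=rep)
        not_preferred += cmp["p_value"] >= 0.001
    return {
        "powerlaw_truth_detection_rate": detected / n_reps,
        "exponential_truth_nonpreference_rate": not_preferred / n_reps,
        "n": n_reps,
    }


def h2_benchmark(seed: int = 0) -> dict:
    """Heritability recovery: 200 accessions x 15 plants per temperature at
    a generating broad-sense H2 of 0.5 (growth rate at 16C)."""
    cfg = SimConfig(
        seed=_sub_seed(seed, 5), n_accessions=200, n_snps=300, n_pops=4,
        target_h2={"M0": 0.5, "r16": 0.5, "r6": 0.5},
        timepoints=(0.0, 1.0, 2.0, 3.0),  # plant draws are what matters here
    )
    _, _, plant_truth = simulate_dataset(cfg)
    plant_truth = plant_truth.rename(columns={"temperature_C": "temperature"})
    res = heritability(plant_truth, "r", temperature="16C")
    return {"value": res.H2, "n": 200 * 15}


def qpc_calibration(seed: int = 0, n_draws: int = 1000) -> dict:
    """Type-I error of the differentiation test on a 249-accession panel.

    Draws neutral MVN(0, Va*K) phenotypes and reports the PC1 rejection rate
    at alpha = 0.05 plus a KS test of the F statistics against F(1, n_tail).
    """
    cfg = SimConfig(seed=_sub_seed(seed, 6))
    G, _ = simulate_genotypes(cfg)
    kin = kinship_centered(G)
    ce = conditional_eigen(kin)
    rng = np.random.default_rng(_sub_seed(seed, 7))
    Z = simulate_neutral_phenotype(kin.K, 1.0, rng, size=n_draws)
    rej = 0
    F1 = np.empty(n_draws)
    n_tail = 0
    for i, z in enumerate(Z):
        q = qpc_test(z, ce)
        rej += q.p[0] < 0.05
        F1[i] = q.F[0]
        n_tail = len(q.tail)
    ks = stats.kstest(F1, lambda x: stats.f.cdf(x, 1, n_tail))
    return {
        "pc1_rejection_rate": rej / n_draws,
        "f_ks_pvalue": float(ks.pvalue),
        "n": n_draws,
    }


def lmm_ols_identity(seed: int = 0, n: int = 80, m: int = 300) -> dict:
    """With K = I the mixed-model scan must reproduce per-SNP OLS; returns
    the maximum relative p-value difference."""
    rng = np.random.default_rng(_sub_seed(seed, 8))
    G = pd.DataFrame(
        (rng.random((n, m)) < rng.uniform(0.15, 0.5, m)).astype(float),
        index=[f"a{i}" for i in range(n)],
        columns=[f"s{j}" for j in range(m)],
    )
    G, _ = maf_filter(G)
    y = rng.normal(size=n)
    kin = KinshipMatrix(K=np.eye(n), ids=list(G.index))
    scan = lmm_scan(y, G, kin)
    ols = np.array([stats.linregress(G.iloc[:, j], y).pvalue for j in range(G.shape[1])])
    rel = np.abs(scan.table.p.to_numpy() - ols) / ols
    return {"value": float(rel.max()), "n": int(G.shape[1])}


def filter_semantics() -> dict:
    """Worked examples of the negative-growth filter and the MAF filter."""
    s = PlantSeries(plant_id="p", accession="a", experiment="e", temperature="16C",
                    times=np.array([0.0, 1.0, 2.0, 3.0]),
                    areas=np.array([5.0, 6.0, 4.0, 7.0]))
    cleaned = clean_series(s)
    boundary = pd.DataFrame(
        np.concatenate([np.ones((2, 1)), np.zeros((18, 1))]),  # f = 0.10 exactly
        index=[f"a{i}" for i in range(20)], columns=["snp"],
    )
    try:
        maf_filter(boundary, threshold=0.10)
        kept = 1
    except ValueError:
        kept = 0
    return {
        "clean_kept_areas": cleaned.areas.tolist(),
        "clean_n_kept": len(cleaned),
        "maf_boundary_kept": kept,
    }
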