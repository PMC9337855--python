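"""Synthetic data with the statistical structure the analyses assume.

The generator produces, in order: structured genotypes for a panel of
naturally inbred accessions (Balding-Nichols populations, haploid {0,1}
coding), a winter-temperature gradient across those populations, heritable
accession-level growth parameters correlated with that gradient, seed sizes,
and plant-level rosette-area time series following power-law growth with
CAR1-correlated measurement noise and occasional downward imaging artifacts.

Every quantity the downstream analyses try to estimate is returned as ground
truth in :class:`SyntheticTruth`, so recovery can be tested end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimConfig
from .curves import powerlaw_size

# natural trait scales: accession-level mean and SD of initial rosette area
# (mm^2) and of the power-law growth rates at the two treatment temperatures
TRAIT_SCALES = {
    "M0": (35.0, 6.0),
    "r16": (0.25, 0.025),
    "r6": (0.10, 0.012),
}

# SD of additive experiment shifts, as a fraction of the trait SD
_EXPERIMENT_SHIFT_FRAC = 0.3


@dataclass
class SyntheticTruth:
    """Ground truth behind one synthetic dataset."""

    accession_params: pd.DataFrame  # accession, M0, r16, r6 (true values)
    genetic_values: pd.DataFrame  # standardized polygenic scores per trait
    climate: pd.DataFrame  # accession, bio11_winter_temp_C
    seed_size: pd.DataFrame  # accession, seed_size_mm2
    genotypes: pd.DataFrame  # accessions x SNPs, {0,1}
    pop_labels: pd.Series  # accession -> population
    config: SimConfig


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg_seed).spawn(stream + 1)[stream])


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Balding-Nichols structured genotypes for inbred accessions.

    Ancestral allele frequencies are Uniform(0.1, 0.9); population
    frequencies are Beta(p(1-fst)/fst, (1-p)(1-fst)/fst); each accession
    carries a single allele (0/1) drawn from its population frequency.
    Monomorphic SNPs are re-drawn so every column segregates.

    Returns ``(genotypes, pop_labels)``: an accessions x SNPs DataFrame of
    {0,1} and a Series mapping accession id to population label.
    """
    if rng is None:
        rng = _rng(cfg.seed, 0)
    if cfg.fst == 0.0 and cfg.n_pops > 1:
        warnings.warn("fst=0 with multiple populations collapses to panmixia", stacklevel=2)

    n, p = cfg.n_accessions, cfg.n_snps
    accessions = [f"acc{i:04d}" for i in range(n)]
    pops = np.arange(n) % cfg.n_pops  # balanced assignment
    pops.sort()

    G = np.empty((n, p), dtype=np.int8)
    todo = np.arange(p)
    for _ in range(200):  # re-draw monomorphic columns
        m = todo.size
        if m == 0:
            break
        anc = rng.uniform(0.1, 0.9, size=m)
        if cfg.fst > 0:
            a = anc * (1 - cfg.fst) / cfg.fst
            b = (1 - anc) * (1 - cfg.fst) / cfg.fst
            popfreq = rng.beta(a, b, size=(cfg.n_pops, m))
        else:
            popfreq = np.tile(anc, (cfg.n_pops, 1))
        draws = (rng.random((n, m)) < popfreq[pops]).astype(np.int8)
        G[:, todo] = draws
        counts = G[:, todo].sum(axis=0)
        todo = todo[(counts == 0) | (counts == n)]
    else:
        raise RuntimeError("could not produce polymorphic SNPs; fst/n too extreme?")

    genotypes = pd.DataFrame(G, index=accessions, columns=[f"snp{j:05d}" for j in range(p)])
    genotypes.index.name = "accession"
    pop_labels = pd.Series([f"pop{k}" for k in pops], index=accessions, name="population")
    return genotypes, pop_labels


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _polygenic_score(G: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    w = rng.normal(size=G.shape[1])
    Gc = G - G.mean(axis=0)
    s = Gc @ w
    return _standardize(s)


def simulate_climate_and_traits(
    cfg: SimConfig,
    genotypes: pd.DataFrame,
    pop_labels: pd.Series,
    rng: np.random.Generator | None = None,
) -> SyntheticTruth:
    """Winter temperatures, accession growth parameters, and seed sizes.

    Winter temperature (mean temperature of the coldest quarter, deg C) is a
    population mean on an even gradient plus accession jitter.  Each trait's
    accession value is built on a standardized latent scale as

        A = rho * climate_z + g * polygenic_z + e * noise_z

    with the polygenic score residualized on climate so that the realized
    trait-climate correlation equals the target ``rho``; the genetic and
    noise weights split the remaining variance equally.  Initial size gets an
    extra seed-size path calibrated to the target M0-seed and seed-climate
    correlations.  Latent values are mapped affinely to natural units.
    """
    if rng is None:
        rng = _rng(cfg.seed, 1)
    n = cfg.n_accessions
    accessions = list(genotypes.index)
    G = genotypes.to_numpy(dtype=float)

    lo, hi = cfg.winter_temp_range
    pop_means = dict(
        zip(sorted(pop_labels.unique()), np.linspace(lo, hi, pop_labels.nunique()))
    )
    climate = pop_labels.map(pop_means).to_numpy() + rng.normal(0.0, 1.5, size=n)
    clim_z = _standardize(climate)

    # seed size: correlated with winter temperature
    r_sc = cfg.seed_climate_r
    seed_z = r_sc * clim_z + np.sqrt(1 - r_sc**2) * _standardize(rng.normal(size=n))
    seed_z = _standardize(seed_z)

    # path coefficients for M0 on (climate, seed) from the two correlation
    # targets: r_M0c = b_c + b_s*r_sc ; r_M0s = b_c*r_sc + b_s
    r_m0c = cfg.target_climate_r.get("M0", 0.0)
    r_m0s = cfg.seed_m0_r
    det = 1 - r_sc**2
    b_c = (r_m0c - r_m0s * r_sc) / det
    b_s = (r_m0s - r_m0c * r_sc) / det

    latents: dict[str, np.ndarray] = {}
    gvalues: dict[str, np.ndarray] = {}
    for trait in ("M0", "r16", "r6"):
        poly = _polygenic_score(G, rng)
        # residualize on the systematic covariates so correlations are exact
        # in expectation
        covs = np.stack([clim_z, seed_z], axis=1) if trait == "M0" else clim_z[:, None]
        coef, *_ = np.linalg.lstsq(covs, poly, rcond=None)
        poly_res = _standardize(poly - covs @ coef)
        gvalues[trait] = poly_res
        if trait == "M0":
            sys_part = b_c * clim_z + b_s * seed_z
            v_sys = b_c**2 + b_s**2 + 2 * b_c * b_s * r_sc
        else:
            rho = cfg.target_climate_r.get(trait, 0.0)
            sys_part = rho * clim_z
            v_sys = rho**2
        if v_sys >= 0.98:
            raise ValueError(
                f"trait {trait}: climate/seed correlation targets leave no "
                f"variance for genetic and residual components (systematic "
                f"fraction {v_sys:.3f})"
            )
        rem = 1.0 - v_sys
        latents[trait] = (
            sys_part
            + np.sqrt(rem / 2) * poly_res
            + np.sqrt(rem / 2) * _standardize(rng.normal(size=n))
        )

    params = pd.DataFrame({"accession": accessions})
    for trait, (mean, sd) in TRAIT_SCALES.items():
        params[trait] = mean + sd * latents[trait]
    if (params["M0"] <= 0).any():
        params["M0"] = params["M0"].clip(lower=1.0)

    seed_mm2 = 0.12 + 0.015 * seed_z
    return SyntheticTruth(
        accession_params=params,
        genetic_values=pd.DataFrame(gvalues, index=accessions),
        climate=pd.DataFrame(
            {"accession": accessions, "bio11_winter_temp_C": climate}
        ),
        seed_size=pd.DataFrame({"accession": accessions, "seed_size_mm2": seed_mm2}),
        genotypes=genotypes,
        pop_labels=pop_labels,
        config=cfg,
    )


def car1_noise(
    times: np.ndarray, sigma: float, phi: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with corr(e_i, e_j) = phi**|t_i - t_j| and SD sigma."""
    n = times.size
    z = rng.normal(size=n)
    e = np.empty(n)
    e[0] = z[0]
    if phi > 0:
        rho = phi ** np.diff(times)
        for k in range(1, n):
            e[k] = rho[k - 1] * e[k - 1] + np.sqrt(1 - rho[k - 1] ** 2) * z[k]
    else:
        e[1:] = z[1:]
    return sigma * e


def simulate_plant_series(
    truth: SyntheticTruth, cfg: SimConfig | None = None, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant-level power-law time series in long format.

    Every plant draws its own (log M0, r) around the accession value (the
    broad-sense heritability targets set the plant-level SDs), experiments
    add small additive shifts, and observations get CAR1-correlated Gaussian
    noise.  A random ``artifact_rate`` fraction of observations is shrunk by
    Uniform(0.5, 0.95) to mimic segmentation dropouts (negative growth).

    Returns ``(phenotypes, plant_truth)``: the long-format table (plant_id,
    accession, experiment, temperature_C, time_dap, area — times as days
    after stratification, treatment starting at day 14) and the per-plant
    true parameter draws used by heritability-recovery tests.
    """
    cfg = cfg or truth.config
    if rng is None:
        rng = _rng(cfg.seed, 2)
    t = np.asarray(cfg.timepoints, dtype=float)
    temps = ["16C", "6C"][: cfg.n_temps]

    # plant-level SDs on the natural trait scale from the H2 targets
    plant_sd = {
        tr: TRAIT_SCALES[tr][1] * np.sqrt((1 - h2) / h2)
        for tr, h2 in cfg.target_h2.items()
    }
    # additive experiment shifts, centered so the accession values stay the
    # panel means (a single experiment gets no shift)
    exp_shift = {}
    for tr in TRAIT_SCALES:
        s = rng.normal(0.0, _EXPERIMENT_SHIFT_FRAC * TRAIT_SCALES[tr][1], cfg.n_experiments)
        exp_shift[tr] = s - s.mean()

    pheno_rows: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    params = truth.accession_params.set_index("accession")
    counter = 0
    for acc in params.index:
        acc_m0 = params.at[acc, "M0"]
        acc_r = {"16C": params.at[acc, "r16"], "6C": params.at[acc, "r6"]}
        for e in range(cfg.n_experiments):
            for temp in temps:
                rkey = "r16" if temp == "16C" else "r6"
                for rep in range(cfg.n_reps):
                    m0 = acc_m0 + exp_shift["M0"][e] + rng.normal(0.0, plant_sd["M0"])
                    m0 = max(m0, 1.0)
                    r = (
                        acc_r[temp]
                        + exp_shift[rkey][e]
                        + rng.normal(0.0, plant_sd[rkey])
                    )
                    curve = powerlaw_size(t, m0, r, cfg.beta_true)
                    area = curve + car1_noise(t, cfg.sigma_meas, cfg.phi_true, rng)
                    if cfg.artifact_rate > 0:
                        hit = rng.random(t.size) < cfg.artifact_rate
                        area[hit] *= rng.uniform(0.5, 0.95, size=int(hit.sum()))
                    area = np.maximum(area, 0.1)
                    pid = f"plant{counter:06d}"
                    counter += 1
                    pheno_rows.append(
                        pd.DataFrame(
                            {
                                "plant_id": pid,
                                "accession": acc,
                                "experiment": f"exp{e + 1}",
                                "temperature_C": temp,
                                "time_dap": t + 14.0,
                                "area": area,
                            }
                        )
                    )
                    truth_rows.append(
                        {
                            "plant_id": pid,
                            "accession": acc,
                            "experiment": f"exp{e + 1}",
                            "temperature_C": temp,
                            "M0": m0,
                            "r": r,
                            "beta": cfg.beta_true,
                        }
                    )
    phenotypes = pd.concat(pheno_rows, ignore_index=True)
    plant_truth = pd.DataFrame(truth_rows)
    return phenotypes, plant_truth


def simulate_dataset(cfg: SimConfig):
    """Run the full generator: genotypes -> climate/traits -> plant series.

    Returns ``(truth, phenotypes, plant_truth)``; fixing ``cfg.seed`` fixes
    all three outputs exactly.
    """
    g, pops = simulate_genotypes(cfg)
    truth = simulate_climate_and_traits(cfg, g, pops)
    phenotypes, plant_truth = simulate_plant_series(truth, cfg)
    return truth, phenotypes, plant_truth


def simulate_neutral_phenotype(
    K: np.ndarray,
    Va: float,
    rng: np.random.Generator,
    mu: float = 0.0,
    size: int | None = None,
) -> np.ndarray:
    """Draw phenotypes from the neutral model z ~ MVN(mu*1, Va*K).

    Used to calibrate the adaptive-differentiation test's null.  ``K`` must
    be symmetric positive semi-definite (tolerance -1e-8 * trace); tiny
    negative eigenvalues from finite-precision kinship estimates are clipped
    to zero.  With ``size`` given, returns a (size, n) matrix of draws.
    """
    K = np.asarray(K, dtype=float)
    w, U = np.linalg.eigh(K)
    if w.min() < -1e-8 * max(np.trace(K), 1.0):
        raise ValueError(f"kinship not PSD: min eigenvalue {w.min():g}")
    scale = np.sqrt(Va * np.clip(w, 0.0, None))
    shape = (K.shape[0],) if size is None else (size, K.shape[0])
    z = rng.normal(size=shape)
    return mu + z @ (U * scale).T
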