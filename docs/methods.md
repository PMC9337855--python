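# Methods

## Growth model

Rosette area is modelled by dM/dt = r·Mᵝ with β ∈ (0, 1]. For β < 1 this
integrates to M(t) = (M0^(1−β) + r·t·(1−β))^(1/(1−β)); β = 1 is exponential
growth. The model clock starts at the beginning of the temperature
treatment, 14 days after stratification, so input times given as
days-after-stratification are shifted by −14 and M0 is the size at treatment
start (unaffected by treatment). Units: M0 in area units (mm²-scale), r in
area^(1−β)/day (1/day when β = 1), β unitless.

Records showing a smaller area than any earlier record of the same plant are
imaging artifacts (segmentation dropout) and are removed by a
running-maximum filter before fitting: a record is kept iff its area is ≥
the maximum of all previously kept areas (ties kept). The filter is
idempotent; plants left with fewer than 4 records are flagged unusable.
Because the filter also removes genuine noise dips that happen to undershoot
the running maximum, it slightly censors the noise distribution — see
*Limitations*.

### Two fitting stages

**Stage 1 (family choice).** For each curve family, a nonlinear mixed model
with only global fixed effects (log M0, r, and β for the power law) and
per-plant random effects on every parameter with unstructured covariance;
i.i.d. Gaussian residuals. Parameter counts: exponential 2 + 3 + 1 = 6,
power law 3 + 6 + 1 = 10 (fixed effects + unique random-effect covariance
entries + residual variance). Families are compared by AIC, BIC, and the
likelihood-ratio test (χ² on 4 df); maximum likelihood (not REML) is used so
the LRT across these nested families is valid. Since the exponential is the
power law at β = 1, a power-law fit whose likelihood lands below the
exponential's has failed to converge; `select_growth_model` refits it
warm-started from the exponential solution (and symmetrically refits the
exponential from a power-law fit that sits at β ≈ 1), which makes the
comparison robust to the occasional stalled fit.

**Stage 2 (accession structure).** The power-law model with fixed effects:
accession on log M0; accession, temperature, and their interaction on r
(reference coding — first accession and the warmer treatment as baseline —
with absolute values reconstructed by `accession_estimates`); a single
shared β. Per-plant random effects on (log M0, r, β) with unstructured 3×3
covariance. Within-plant residuals follow a continuous-AR1 process,
corr(eᵢ, eⱼ) = φ^|tᵢ−tⱼ| (φ per day), handled by exact bidiagonal whitening
per plant. Plants are uniquely labelled within experiments, so "individuals
nested in experiment" reduces to per-plant effects; no separate
experiment-level random intercept is fitted (experiment shifts in the data
are absorbed by the plant effects for curve fitting and by an explicit
experiment fixed effect in the heritability model).

M0 enters the optimizer on the log scale — both its fixed and random effects
— which keeps M0 positive without constraints. β is clipped to [0.02, 1.0];
the curve and its gradient switch to a first-order expansion around the
exponential limit for |1−β| < 1e−4, so β = 1 is an interior-quality point,
not a singular boundary.

### Estimation algorithm

An alternating scheme in the penalized nonlinear least squares tradition:

1. **PNLS step.** Given variance parameters (Ψ, σ², φ): Gauss–Newton updates
   of each plant's random-effect mode (batched 3×3 systems with per-plant
   step halving), a gauge-fixing step moving the mean of the modes into the
   global intercepts (removes the flat ridge between intercepts and
   random-effect means), and a Gauss–Newton update of all fixed effects via
   sparse normal equations.
2. **Variance step.** Laplace/EM updates of Ψ (conditional mean of bbᵀ plus
   conditional covariance) and σ²; φ by bounded 1-D maximization of the
   linearized marginal likelihood, held fixed for the first 5 outer
   iterations so the curve settles before residual correlation is estimated.

Iterated to a relative log-likelihood tolerance of 1e−6 (max 200 outer
iterations), with up to 3 jittered restarts on failure. The scheme is not
monotone in the linearized marginal likelihood, so the best iterate seen is
returned. All per-plant work is vectorized over one stacked observation
array: CAR1 whitening is a bidiagonal transform that never crosses plant
boundaries (boundary lags treated as infinite), and per-plant reductions use
segmented sums. Self-start values: per-plant profile of β over a grid with a
linearized inner fit; plant-level (log M0, r) starts are then re-estimated
at the shared median β — mixing linearized estimates made at different β
values produces useless starts because r's scale depends on β.

Reported log-likelihoods are the linearized (Laplace) marginal likelihood at
the converged modes. k-counting for AIC/BIC: fixed effects + unique
random-effect covariance entries + residual variance, +1 for φ when CAR1 is
active (stage 1 has no φ).

### Temperature response

Defined as the plain difference r16 − r6. A two-level ordered polynomial
contrast gives this difference divided by √2 — a fixed positive rescaling
that cannot change any correlation or test downstream, so the unscaled
difference is stored.

## Quantitative genetics

**Kinship.** K = (1/p) Σₛ (gₛ − ḡₛ)(gₛ − ḡₛ)ᵀ over p SNPs ({0,1} inbred
coding, per-SNP mean imputation of missing calls). Centered by construction
(rows sum to 0, PSD); the eigendecomposition is cached on the object.

**Heritability.** H² = V_g/(V_g+V_e) from the REML fit of
trait ~ experiment (fixed) + accession (random) on per-plant parameter
estimates. The accession blocks make H = I + δZZᵀ block diagonal, so the
REML profile over δ uses exact Sherman–Morrison block algebra (no generic
dense solver); δ is optimized on a log grid plus Brent polish, with boundary
estimates clamped to V_g = 0 (warned). Growth-rate H² is computed within one
temperature; initial-size H² over all plants. Verified in tests against
statsmodels MixedLM on the same layout.

**Climate correlations.** Pearson correlations (pairwise complete) plus a
structure-corrected version: both variables standardized, then
y = βx + g + e with g ~ N(0, σ_g²K) fitted by ML on the kinship eigensystem
(1-D profile over the variance ratio), so β̂ is on the correlation scale;
Wald t test for β. With K = I this reduces exactly to the Pearson
correlation.

**Seed-size variance partition.** Joint linear model of M0 on standardized
winter temperature and seed size; the fraction attributed to predictor j is
var(β̂ⱼxⱼ)/var(M0) — an order-independent definition that sums to R² for
orthogonal predictors. The seed-size-corrected winter-temperature p-value
comes from a mixed model with seed size as a one-column random effect
(K = ssᵀ), matching the random-effect formulation of the correction.

## Association scan

Null model y = μ + g + e fitted once by REML on the kinship eigensystem;
each SNP tested by GLS in the rotated coordinates with the variance ratio
fixed (EMMAX approximation; per-SNP re-optimization behind `exact=True`).
Wald t tests with n−2 df, so the K = I limit reproduces per-SNP OLS exactly.
MAF filter is strict (`maf > threshold`, so exactly 10% is removed at the
default threshold); SNPs with > 20% missing calls are dropped, remaining
missing calls mean-imputed. Bonferroni threshold −log10(α/m). QQ data carry
a pointwise null band from Beta(i, n−i+1) order statistics. Under strong
stratification the fixed-ratio approximation differs from the exact per-SNP
fit by up to ~0.1 in −log10 p at the 99th percentile (measured at F_st 0.15,
6 populations); use `exact` where that matters.

## Adaptive differentiation (Q_pc)

The trait is conditioned on its mean by projecting onto an orthonormal
(Helmert) basis of the complement of the 1-vector; the conditional kinship
K_c = TKTᵀ is eigendecomposed into n−1 axes. Standardized projections
c_m = u_mᵀTz/√λ_m are i.i.d. N(0, V_a) under neutrality; the neutral
variance is estimated as the mean of c² over the tail PCs (default: PCs
n_tested+1 … n−1, with near-null eigenvalues dropped), and
F_m = c_m²/V̂_a is referred to F(1, |tail|). The orthonormal-basis
conditioning is mathematically the same conditional-MVN construction as a
drop-one-accession transform but is exactly invariant to accession ordering,
which the drop-one variant is not; a simple-centering variant is available
(`centering="simple"`). No multiple-testing correction is applied across the
tested PCs (per-PC p-values are reported, flagged at 0.05). The neutral
envelope for trait-vs-PC plots has half-width z_{(1+c)/2}·√(V̂_a·λ_m)·|s|/‖s‖
at PC score s. Analytic power: a mean shift of k standard deviations along a
tested PC gives a noncentral F(1, |tail|; ncp = k²) — about 0.52 at k = 2
and 0.85 at k = 3 for a 249-accession panel — which the power tests verify
by simulation.

## Synthetic data generator

The generator mirrors the emulated study design; its defaults are the study
conditions, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| n_accessions | 249 | panel size |
| n_pops / fst | 6 / 0.15 | Balding–Nichols admixture groups, divergence |
| n_snps | 2000 | biallelic SNPs, {0,1} inbred coding |
| winter_temp_range | −11…5 °C | population means on an even gradient, ±1.5 °C accession jitter |
| target_h2 | 0.41 / 0.57 / 0.32 | broad-sense H² of M0, r16, r6 |
| target_climate_r | −0.39 / 0.33 / 0.28 | trait–winter-temperature correlations |
| seed_climate_r / seed_m0_r | −0.75 / 0.28 | seed-size correlations |
| beta_true / phi_true | 0.9 / 0.6 | curve exponent, CAR1 correlation per day |
| sigma_meas | 4.0 area units | measurement noise SD |
| reps × experiments × temps | 5 × 3 × 2 | replicate plants per accession |
| timepoints | 2/day × 21 d | 1 h after/before a 9 h photoperiod (0.42 d gap) |
| artifact_rate | 0.02 | fraction of records shrunk by U(0.5, 0.95) |

Trait construction: winter temperature is assigned by population; each
trait's accession value is ρ·climate_z + g·polygenic_z + e·noise_z on a
standardized latent scale, with the polygenic score (random SNP weights)
residualized on climate so the realized correlation is ρ in expectation, and
the remaining variance split equally between the polygenic and noise parts.
Initial size gets an extra seed-size path with coefficients solved from the
two correlation targets. Latents map affinely to natural scales (M0
35 ± 6 mm², r16 0.25 ± 0.025, r6 0.10 ± 0.012). Plant-level SDs follow from
the H² targets; experiments add small centered additive shifts (SD = 30% of
the trait SD). Series are exact power-law curves plus CAR1 noise generated
by its AR recursion; artifacts are multiplicative shrinkage, mimicking
segmentation dropouts. Measurement-noise magnitude and plant-level SDs are
not published quantities; the defaults above are realistic choices exposed
in `SimConfig`.

What the generator does **not** emulate: linkage disequilibrium beyond
population structure, spatial or temporal chamber effects, diurnal area
fluctuations, heteroscedastic imaging noise, genotype-specific β. Passing
recovery tests therefore show the estimators work when their model is close
to true with realistic noise — not that the model is right for any
particular real dataset.

## Benchmark study sizes

The acceptance benchmarks use these desk-scale designs (chosen so the whole
suite runs in minutes on one CPU): parameter recovery — 20 replicates of 50
accessions × 3 experiments × 1 plant × 2 treatments, 20 timepoints;
model selection — 20 replicates per family of 20 accessions × 2 experiments
with i.i.d. noise and no artifacts (the LRT's own null; with CAR1 noise or
artifact censoring the stage-1 comparison is no longer a size test, because
the power law's extra random-effect direction legitimately absorbs residual
correlation); heritability — 200 accessions × 15 plants per temperature;
Q_pc calibration — 1000 neutral draws on a 249-accession kinship; LMM/OLS
identity — 80 samples × 300 SNPs.

## Numerical choices and known limitations

- Tolerances: outer loop 1e−6 relative log-likelihood; φ optimized on
  [0, 0.98] with xatol 1e−3; variance-ratio profiles on 25-point log grids
  with Brent polish; kinship PSD tolerance −1e−8·λ_max; residual variance
  floored at 1e−12 so noiseless inputs stay finite.
- φ̂ carries a small positive bias (~0.1) at φ = 0 in small designs: the
  Laplace linearization at shrunken modes leaves smooth within-plant
  residual structure that CAR1 absorbs. Conversely, the running-maximum
  filter's censoring of noise dips biases φ̂ slightly downward when
  artifacts are enabled (median φ̂ ≈ 0.5 at truth 0.6 under the default
  artifact rate). Both effects are well inside the ±0.15 recovery band.
- Stage-1 β̂ is mildly biased upward when the two temperature treatments are
  pooled (the plant random effects must absorb a bimodal growth-rate
  distribution); stage 2, which models temperature explicitly, shows no such
  bias (median |β̂ − β| < 0.01).
- The accession-level growth-rate rank correlation is reported with both
  temperatures pooled; per-temperature correlations are bounded by the
  replicate count (3 plants per cell give an attainable ceiling near 0.9
  even with perfect curve fits at the default H² targets).
- The variance partition reports var(β̂ⱼxⱼ)/var(y); with the generator's
  correlation targets (r(M0, winter temp) = −0.39) the winter-temperature
  fraction is necessarily near r² ≈ 0.15. Larger published fractions for a
  subsetted panel imply stronger marginal correlations in that subset and
  are not reproducible from these targets; the tests assert the
  decomposition identities, not a specific fraction.
- One centered kinship matrix is used everywhere (correlation correction,
  GWAS, Q_pc).
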