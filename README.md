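# thermogrowth

Analysis toolkit for temperature-dependent vegetative growth in panels of
naturally inbred plant accessions (the *Arabidopsis thaliana* setting:
hundreds of genotyped accessions grown as replicate plants under two
temperature treatments, with rosette area imaged twice a day).

It answers four linked questions about such an experiment:

1. **How do rosettes grow?** Size trajectories are fitted with the power-law
   growth model dM/dt = r·Mᵝ, whose solution is
   M(t) = (M0^(1−β) + r·t·(1−β))^(1/(1−β)); β = 1 recovers exponential
   growth M(t) = M0·eʳᵗ. A hierarchical (nonlinear mixed) model estimates a
   global β, per-accession initial sizes M0 and growth rates r per
   temperature, per-plant random effects, and continuous-AR1 residual
   correlation corr(eᵢ, eⱼ) = φ^|tᵢ−tⱼ| within plants. Exponential and
   power-law fits are compared by AIC/BIC and likelihood-ratio test.
2. **Is growth variation heritable and climate-linked?** Broad-sense
   heritability H² = V_g/(V_g + V_e) from accession random effects on
   plant-level estimates; Pearson and kinship-corrected correlations between
   growth parameters and climate of origin (winter temperature); a variance
   partition of initial size into winter-temperature and seed-size
   contributions.
3. **Which loci associate with growth?** An EMMAX-style linear-mixed-model
   GWAS with the centered genomic relatedness matrix, MAF > 10% filter,
   Bonferroni threshold, and QQ diagnostics.
4. **Is the trait adaptively differentiated?** A conditional-PC test (Q_pc):
   trait projections on the top kinship PCs are compared with the neutral
   variance estimated from the tail PCs via F statistics, with 90% neutral
   envelopes for trait-vs-PC plots.

Because the original phenotyping data are a large external deposit, the
package ships a **synthetic-data generator** that reproduces the study's
statistical structure end to end — Balding–Nichols population structure with
inbred {0,1} genotypes, a winter-temperature gradient, heritable growth
parameters with calibrated climate correlations, power-law trajectories with
CAR1 noise, and downward imaging artifacts — so every stage is testable with
known ground truth.

## Worked example

```python
import numpy as np
from thermogrowth import (SimConfig, simulate_dataset, select_growth_model,
                          fit_stage2, accession_estimates, kinship_centered, qpc_test)
from thermogrowth.io import phenotypes_to_series
from thermogrowth.nlmm import comparison_table

cfg = SimConfig.desk_scale(seed=1, n_accessions=30)   # 30 accessions, 3 experiments
truth, pheno, plant_truth = simulate_dataset(cfg)
series = phenotypes_to_series(pheno)                  # cleans negative-growth records

fit_exp, fit_pl, cmp = select_growth_model(series)    # stage 1: which curve family?
print(comparison_table(fit_exp, fit_pl).round(1).to_string(index=False))
```

```
      model  df     AIC     BIC   logLik  L.ratio   p
exponential   6 24225.5 24262.1 -12106.8      NaN NaN
   powerlaw  10 20713.2 20774.2 -10346.6   3520.3 0.0
```

The power law wins decisively (ΔAIC ≈ −3512, likelihood-ratio 3520 on 4
degrees of freedom): growth slows as rosettes get bigger. Stage 2 then fits
the accession-structured model with CAR1 residuals:

```python
fit = fit_stage2(series)
print(fit.fixed_effects["beta"], fit.phi)      # 0.902, 0.539  (truth: 0.9, 0.6)
est = accession_estimates(fit)
print(est.head(3).round(3).to_string(index=False))
```

```
accession     M0   r16    r6  response
  acc0000 37.651 0.205 0.076     0.129
  acc0001 29.792 0.240 0.126     0.114
  acc0002 37.837 0.232 0.090     0.142
```

`M0` is the rosette area (mm²-scale units) at the start of the temperature
treatment, `r16`/`r6` the growth rates in the warm and cold treatment, and
`response` = r16 − r6 the temperature response. Against the generator's
truth, the estimated warm growth rates correlate at r = 0.92. Finally, a
differentiation test of the warm growth rate along the top 5 kinship PCs:

```python
kin = kinship_centered(truth.genotypes)
q = qpc_test(est.set_index("accession").loc[kin.ids, "r16"].to_numpy(), kin, n_tested=5)
print(np.round(q.p, 3))        # [0.488 0.42 0.256 0.724 0.26]
```

No PC is significant — correct here, since this generator run ties traits to
climate only through their polygenic and climate paths, without extra
selection along a specific axis.

The same pipeline runs from the shell:

```bash
thermogrowth pipeline --outdir out/ --desk-scale --seed 1
thermogrowth gwas --phenotypes out/accession_phenotypes.tsv \
    --genotypes out/genotypes.tsv --kinship out/kinship.tsv --out out/gwas.tsv
```

Stages are cached by content hash; deleting an intermediate re-runs only the
stages downstream of it.

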