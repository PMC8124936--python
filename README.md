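# greenrisk

Bayesian spatial disease mapping of areal mental-health counts against
satellite-derived vegetation measures.

## The problem

Ecological studies of urban greenness and mental health face two coupled
methodological hazards: the choice of vegetation measure (band-ratio
indices such as NDVI/EVI/SAVI versus area-based percent-cover measures can
flip the significance of an association) and spatial structure (areal
disease counts are autocorrelated and driven by latent spatial covariates,
which non-spatial regressions cannot absorb).  `greenrisk` implements the
full analysis pipeline for studying this at the neighbourhood level:

1. **Raster chain** — top-of-atmosphere reflectance rescaling, dark-object
   atmospheric correction, NDVI/EVI/SAVI construction, NDVI-based masking
   of non-vegetation, zonal means and percent cover per areal unit.
2. **Standardization** — indirect (internal) standardization of expected
   counts from sex-specific rates, so that Σ E = Σ O by construction, and
   assembly of the covariate table (vegetation measure X1 plus four
   area-marginalization scores X2–X5 and a substance-use rate X6) with a
   Pearson/VIF collinearity screen.
3. **Spatial screen** — queen/rook contiguity from polygons and the global
   Moran's I permutation test on the standardized morbidity ratio.
4. **Model** — the BYM Poisson-lognormal model, one fit per vegetation
   measure × disorder (the 10-model grid):

       O_i ~ Poisson(λ_i),
       log λ_i = log E_i + β0 + Σ_j β_j X_ji + u_i + s_i,

   with iid heterogeneity u, an intrinsic CAR (ICAR) spatial effect s under
   a sum-to-zero constraint, a flat prior on β0, Normal(0, precision 1e-5)
   priors on β1..β6 and Γ(0.001, 0.001) priors on both precisions — fit by
   a Metropolis-within-Gibbs sampler with Gibbs precision updates.  Outputs
   are posterior means and 95% credible intervals per coefficient, the
   spatial fraction ψ = SD(s)/(SD(s)+SD(u)), DIC and pD, Gelman-Rubin and
   Monte-Carlo-error diagnostics, and per-unit relative-risk surfaces
   r_i = exp(β0 + Σ β_j X_ji + u_i + s_i) with quantile bins for mapping.
5. **Synthetic data** — a first-class generator reproducing the study's
   structure (140-unit lattice, published covariate moments and count
   scales, ICAR + iid latent fields with controllable spatial fraction,
   multiband scenes with ground truth), since the original health extracts
   are restricted.

## Worked example

```sh
python analysis/01_simulate_inputs.py  --seed 1 --out results/run
python analysis/02_vegetation_indices.py --seed 1 --out results/run
python analysis/03_collinearity_screen.py --out results/run
python analysis/04_moran_gate.py       --seed 1 --out results/run
python analysis/05_fit_models.py       --seed 1 --out results/run
python analysis/06_report.py           --out results/run
```

`01` prints the conservation check of the standardization (seed 1):

```
non_psychotic: n=140 units, mean O=2358.7, sum O=330221, sum E=330221.000 (conserved)
psychotic: n=140 units, mean O=294.3, sum O=41203, sum E=41203.000 (conserved)
```

`03` prints the Pearson matrix and VIFs (all ≈ 1, `screen passed`), and
`04` prints the Moran gate on the observed/expected ratio:

```
psychotic: I=0.076, p=0.0410 (significant spatial autocorrelation)
non_psychotic: I=-0.012, p=0.5080 (not significant spatial autocorrelation)
```

The SMR's spatial signal is the latent ICAR field diluted by the iid
confounder effects, so the gate can be weak for some seeds — it reports
rather than blocks.  `05` fits the ten models (≈2 minutes) and prints one
line per fit:

```
EVI      psychotic      psi=0.768 pD=103.2 DIC=1277.1 max R-hat=1.006
```

Read: about three quarters of the latent (unmeasured-covariate) variation
in relative risk is spatially structured (ψ, generated at 0.75), roughly
103 effective parameters, and chains that agree (R-hat near 1).  `06`
prints the cross-measure comparison tables, one column per vegetation
measure, rows β0..β6, ψ, pD, DIC, with `*` marking coefficients whose 95%
CrI excludes zero; the psychotic table's vegetation row reads

```
beta1  -3.510 (-7.030, -0.035)*   -0.577 (-1.146, 0.034)   -3.467 (-6.866, -0.121)*  ...
```

(EVI, NDVI, SAVI columns): the EVI and SAVI credible intervals cover the
generative value of −4.0 on the index scale and exclude zero.

The same stages are available as a CLI (`greenrisk simulate|indices|
standardize|moran|fit|report|run-all`), and `greenrisk run-all` executes
the whole pipeline into one run directory.

## Layout

- `src/greenrisk/` — the library (raster, standardize, spatial, bym,
  simulate, io, pipeline, cli)
- `analysis/` — numbered drivers for the narrative analysis
- `tests/` — unit, property and acceptance suites
- `docs/methods.md` — model, sampler, generator and design notes
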