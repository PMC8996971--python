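# fovpower

Mixed-model design and power analysis for field-of-view (FoV)
immunostaining cell counts.

Quantitative immunohistochemistry scores such as Ki67 positivity in
patient-derived tumour explants are obtained by counting positive and
total cells over several microscope fields of view per tissue sample,
with paired control/treated samples per patient. The counts are
clustered (FoVs within samples within patients) and overdispersed, so
both the choice of error distribution and the allocation of counting
effort (how many FoVs vs how many cells per FoV) matter for detecting a
treatment effect. `fovpower` is for biostatisticians and pathology
groups designing or analysing such studies.

## What it does

- **Six candidate count families** — binomial, beta-binomial (logit
  link), Poisson, generalized Poisson, NB1, NB2 (log link with
  `log(total)` offset) — with stable log-masses, analytic
  linear-predictor derivatives, and samplers.
- **Nested-random-intercept mixed models**: fixed effects for treatment
  and assessment batch, random intercepts for each sample nested within
  each individual. The marginal likelihood uses a Laplace approximation
  (cross-checked against Gauss–Hermite quadrature and glmmTMB);
  standard errors come from the finite-difference observed information.
- **AIC model comparison** across families, reporting ΔAIC and the mean
  percent positivity per arm for the average subject.
- **Simulation-based power study**: simulate–fit–test loops over a
  FoV-per-sample × cells-per-FoV grid with a two-sided Wald test on the
  treatment coefficient (α = 0.05), Wilson confidence intervals on every
  power estimate, and order-independent per-replicate seeding.
- **Synthetic-data generator** for the full hierarchy, used by the power
  engine and the test suite.

The central model is beta-binomial: counts `k_r | p ~ Bin(m_r, p)` with
`p ~ Beta(mu*phi, (1-mu)*phi)`, `logit(mu) = beta0 + beta_trt*treat +
batch + u_i + v_ij`, `u_i ~ N(0, sd_ind²)`, `v_ij ~ N(0, sd_samp²)`,
and intra-FoV correlation `rho = 1/(phi+1)`.

## Worked example

```python
import fovpower as fp

# 10 patients, paired control/treated samples, 8 FoVs of 50 cells
design = fp.StudyDesign(n_individuals=10, n_fov=8, cells_per_fov=50)
data = fp.simulate_dataset(design, fp.SimulationParams(), seed=13)

rows = fp.compare_models(data, spec=fp.GlmmSpec(include_batch=False))
for r in rows[:3]:
    print(f"{r.family_id:>13}  AIC={r.aic:9.2f}  dAIC={r.delta_aic:8.2f}  "
          f"ctrl%={r.mean_pct_control:5.2f}  trt%={r.mean_pct_treated:5.2f}")
```

prints

```
 betabinomial  AIC=  1195.57  dAIC=    0.00  ctrl%=36.67  trt%=30.46
          nb1  AIC=  1228.88  dAIC=   33.31  ctrl%=34.92  trt%=29.06
          nb2  AIC=  1248.58  dAIC=   53.01  ctrl%=37.00  trt%=30.09
```

The beta-binomial fit wins by ΔAIC. Its average-subject positivity
(36.7% control vs 30.5% treated — this small 10-patient draw landed
above the 30% generative baseline) shows the simulated treatment
reduction of −0.2 on the logit scale, which from a 30% baseline is
about a 4-point drop (`fp.effect_translation(30, -0.2)` → `-4.03`).

The same machinery is available from the shell:

```sh
fovpower simulate --seed 7 -o out/
fovpower compare --input out/counts.tsv --no-batch -o out/
fovpower power --fov 10,25 --cells 25,100 --reps 300 --seed 1 -o out/
```

Every command writes a JSON config echo beside its outputs, so any
result is reproducible from the echo plus the seed.

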