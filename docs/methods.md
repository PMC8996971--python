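# Methods

## The problem

Immunostaining readouts such as Ki67 positivity in cultured tumour
explants are scored by counting positive and total cells over several
microscope fields of view (FoV) per tissue sample, with paired
control/treated samples per patient. Counts from FoVs of the same
sample are correlated, samples from the same patient are correlated,
and FoV-level counts are typically overdispersed relative to a
binomial. `fovpower` provides (i) maximum-likelihood fitting of
mixed-effects count models that respect this three-level hierarchy,
(ii) AIC comparison across six candidate error distributions, and
(iii) a simulation-based power study over the FoV-per-sample ×
cells-per-FoV design grid.

## Model

For FoV *r* in sample *j* of individual *i*, the positive count
*k<sub>r</sub>* out of *m<sub>r</sub>* cells follows one of six families
with linear predictor

    eta_r = beta0 + beta_trt * treat_ij + batch effects + u_i + v_ij,
    u_i ~ N(0, sd_individual^2),   v_ij ~ N(0, sd_sample^2).

Binomial and beta-binomial use a logit link on the positive fraction;
Poisson, generalized Poisson, NB1 and NB2 use a log link on the
positive count with `log(total)` as offset, so `exp(eta)` is again a
positivity rate. Fixed effects are treatment and (when the data have
more than one level) reference-coded batch.

Family parameterizations (chosen so that every family has at most one
dispersion parameter on a common mean scale, making AICs comparable):

- beta-binomial: precision `phi`, Beta shapes `mu*phi`, `(1-mu)*phi`;
  intra-FoV correlation `rho = 1/(phi+1)`; variance
  `m*mu*(1-mu)*(1+(m-1)*rho)`.
- generalized Poisson: variance `mu*phi` via `theta = mu/sqrt(phi)`,
  `lam = 1-1/sqrt(phi)`; underdispersion (`phi < 1`) is rejected
  because it truncates the support and is never needed for this data
  regime.
- NB1: variance `mu*(1+alpha)` (size `mu/alpha`); NB2: variance
  `mu + mu^2/theta` (size `theta`). Both are reparameterizations of
  the standard negative binomial.

These conventions follow the common mixed-model software practice
(e.g. glmmTMB's `betabinomial`, `genpois`, `nbinom1`, `nbinom2`); the
fitted values here have been cross-checked against glmmTMB on simulated
data (log-likelihood agrees to ~1e-4, coefficients to ~1e-4).

## Marginal likelihood and fitting

The random effects are integrated out per individual with a Laplace
approximation: the joint mode of each individual's `1 + S_i` effects is
found by damped Newton iterations (analytic first/second derivatives of
every family's log-mass with respect to `eta`), then the log-determinant
correction is added. Individuals are independent, so blocks are
processed in one batched, vectorized pass; the per-block Newton steps
are 3×3 solves for the paired two-sample design. Adaptive quadrature is
not used in the fitter — it is retained only as a test oracle (dense
Gauss–Hermite over the reduced per-sample representation
`a_j = u_i + v_ij`, covariance `sd_ind^2 J + sd_samp^2 I`), which agrees
with the Laplace value to well under 0.05 log-units on small instances.

The outer optimization is L-BFGS-B on the packed vector
(fixed effects, log-SDs, log dispersion; `log(phi-1)` for the
generalized Poisson so that `phi >= 1`). Log-SDs are floored at
`log(1e-8)`; a fit at the floor is reported as a zero variance
component. Starting values are deterministic: intercept from the pooled
positivity, a short fixed-effects Newton polish, SDs at 0.3, dispersion
from a method-of-moments guess. Standard errors come from the inverse
of a central-finite-difference observed-information matrix
(step `1e-5 * (1+|theta|)`); a singular information matrix yields
absent SEs and a flagged fit rather than an exception, and
non-convergence is likewise reported via `converged=False`.

Model comparison fits every requested family to the same data and ranks
by `AIC = -2 loglik + 2 n_params`, where `n_params` counts fixed
effects + variance components + dispersion (beta-binomial with four
batches: 1+1+3+2+1 = 8). Non-converged families stay in the table but
are excluded from the delta-AIC reference. Mean percent positivity per
arm is reported for the average subject (random effects at zero), both
at the reference batch and averaged over batch levels.

## Detection rule and power

The treatment effect is declared detected by a two-sided Wald z-test on
the treatment coefficient at alpha = 0.05 — the default reported test in
the mixed-model software convention this package mirrors (a
likelihood-ratio rule would be a reasonable alternative; Wald was
chosen as the declared default). A replicate whose fit does not
converge, or whose treatment SE is unavailable, contributes no
rejection; power is `rejections / converged` with a Wilson 95% CI
(well-behaved near 0 and 1), and the convergence counts are reported so
the pessimistic convention (failures as non-rejections) can be
recomputed. A cell with more than 20% fit failures is flagged
unreliable.

Replicate seeds derive from `(master_seed, n_fov, cells_per_fov,
replicate)` through `numpy.random.SeedSequence`, so grid results are
identical regardless of execution order.

## Synthetic data: what it emulates and what it does not

The generator mirrors the explant study structure: 25 individuals, each
with a paired control and treated sample, a logit-scale treatment shift
of −0.2 (≈ −4 percentage points from a 30% baseline), optional
assessment batches, and a configurable FoV/cells grid. Default variance
components — sd_individual 0.5, sd_sample 0.1, beta-binomial phi 3
(rho 0.25), no batch effects — are declared stand-ins chosen to give a
realistic control-arm positivity range (25–32% for the average subject)
and heterogeneity typical of explant Ki67 scoring; no particular
cohort's fitted values are built in, and all of them are overridable
through `SimulationParams`. For log-link families, counts are drawn with
mean `total*exp(eta)` and redrawn if they exceed the total (a counter
records residual censoring); the logit-link families never need this.

The generator does not emulate: spatial FoV layout, varying totals per
FoV, missing or necrotic samples, batch-by-treatment confounding, or
scorer effects. A passing power study therefore says the *method*
behaves correctly under the declared hierarchy; transferring the exact
power numbers to a real cohort requires plugging in that cohort's
fitted variance components.

## Problem sizes and numerical choices

Simulation-backed checks run at desk scale with Monte-Carlo error
quantified by Wilson intervals: 300 replicates per power grid cell
(the full 2000-replicate grid is available through configuration),
500 null replicates for type-I calibration (10 FoV × 25 cells),
50 datasets (8 FoV × 30 cells) for model-of-best-fit recovery, and 20
fits for parameter recovery. Inner Newton tolerance is 1e-10 on the
scaled gradient with step-halving and a ridge fallback for non-PD
blocks; tie-breaks in AIC ranking favour converged fits.

At the default truth the simulated power at 25 FoV × 25 cells sits near
the 80% design threshold and 10 FoV × 100 cells near the 50% mark;
both estimates carry a Wilson CI of roughly ±4.5 points at 300
replicates, so individual runs can land on either side of those round
numbers. The ordering power(25×25) > power(10×100) — more FoVs beat
more cells per FoV despite 625 vs 1000 total cells — is the robust
finding, stable across perturbations of sd_sample and phi.

## Known limitations

- Laplace (not adaptive quadrature) marginal likelihood: adequate here
  (checked against Gauss–Hermite), but accuracy degrades for very small
  cluster sizes with strong overdispersion.
- No REML, random slopes, crossed random effects, zero-inflation, or
  likelihood-ratio/bootstrap tests.
- The generalized Poisson is restricted to overdispersion.
- Wald SEs rely on a finite-difference observed information; on flat
  likelihood surfaces (tiny datasets) they can be unavailable, which is
  surfaced rather than patched.
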