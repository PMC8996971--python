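"""Mixed-model fitting: design building, Laplace accuracy, ML recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import fovpower as fp
from fovpower.glmm import (GlmmSpec, build_design, fit_glmm, marginal_loglik,
                           compare_models, wald_test, n_parameters)
from fovpower.families import get_family

import oracles


# ---------------------------------------------------------------------------
# design building
# ---------------------------------------------------------------------------

def _make_dataset(n_ind=2, n_samp=2, n_fov=3, cells=10, n_batches=1,
                  seed=0):
    design = fp.StudyDesign(n_individuals=n_ind,
                            samples_per_individual=n_samp,
                            n_batches=n_batches, n_fov=n_fov,
                            cells_per_fov=cells)
    params = fp.SimulationParams(
        beta_batch=tuple(0.0 for _ in range(n_batches - 1))
        if n_batches > 1 else ())
    return fp.simulate_dataset(design, params, seed)


def test_design_dimensions_single_batch():
    data = _make_dataset(n_ind=2, n_samp=2, n_fov=3)
    des = build_design(data, GlmmSpec())
    assert des.X.shape == (12, 2)  # intercept + treatment
    assert des.term_names == ["intercept", "treatment"]
    assert des.n_random_dim == 2 + 4  # 2 individuals + 4 samples


def test_design_dimensions_four_batches():
    data = _make_dataset(n_ind=8, n_batches=4)
    des = build_design(data, GlmmSpec())
    assert des.X.shape[1] == 2 + 3  # reference coding drops one batch


def test_offset_rule_per_family():
    data = _make_dataset()
    des_logit = build_design(data, GlmmSpec(family="betabinomial"))
    assert np.all(des_logit.offset == 0)
    des_log = build_design(data, GlmmSpec(family="nb2"))
    assert np.allclose(des_log.offset, np.log(data.df["total"]))


def test_n_params_arithmetic_betabinomial_four_batches():
    data = _make_dataset(n_ind=8, n_batches=4)
    des = build_design(data, GlmmSpec(family="betabinomial"))
    assert n_parameters(des) == 1 + 1 + 3 + 2 + 1


# ---------------------------------------------------------------------------
# marginal likelihood
# ---------------------------------------------------------------------------

def test_degenerate_random_effects_reduce_to_fixed_loglik(tiny_dataset):
    """SDs at the floor: Laplace equals the plain fixed-effects loglik."""
    fam = get_family("binomial")
    beta = np.array([logit(0.3), -0.2])
    theta = np.concatenate([beta, [np.log(1e-8), np.log(1e-8)]])
    spec = GlmmSpec(family="binomial")
    ll = marginal_loglik(theta, tiny_dataset, spec)
    df = tiny_dataset.df
    eta = beta[0] + beta[1] * df["treatment"].to_numpy()
    direct = float(np.sum(fam.logpmf_eta(df["positive"].to_numpy(),
                                         df["total"].to_numpy(), eta)))
    assert ll == pytest.approx(direct, abs=1e-6)


@pytest.mark.parametrize("family,disp", [("binomial", None),
                                         ("betabinomial", 3.0)])
@pytest.mark.parametrize("sds", [(0.5, 0.1), (0.3, 0.3), (0.8, 0.05)])
def test_laplace_matches_gauss_hermite(tiny_dataset, family, disp, sds):
    """Laplace within 0.05 of dense GH quadrature on tiny instances."""
    sd_u, sd_v = sds
    beta = np.array([logit(0.3), -0.2])
    theta = [beta[0], beta[1], np.log(sd_u), np.log(sd_v)]
    if disp is not None:
        theta.append(np.log(disp))
    spec = GlmmSpec(family=family)
    ll = marginal_loglik(np.asarray(theta), tiny_dataset, spec)
    des = build_design(tiny_dataset, spec)
    oracle = oracles.gh_marginal_loglik(
        tiny_dataset, get_family(family), beta, sd_u, sd_v, disp,
        des.X, des.offset, n_nodes=31)
    assert ll == pytest.approx(oracle, abs=0.05)


def test_loglik_invariant_under_intercept_shift(tiny_dataset):
    """Adding c to beta0 while modes absorb -c leaves the inner objective
    maximum unchanged; the Laplace value moves only through the prior,
    so at a large sd the value is insensitive to small shifts."""
    spec = GlmmSpec(family="binomial")
    base = np.array([logit(0.3), -0.2, np.log(10.0), np.log(1e-8)])
    shift = base.copy()
    shift[0] += 0.05
    # with a nearly flat individual prior the likelihood profile in beta0
    # is nearly flat too: the modes re-center
    assert marginal_loglik(shift, tiny_dataset, spec) == pytest.approx(
        marginal_loglik(base, tiny_dataset, spec), abs=1e-3)


def test_row_permutation_and_relabeling_invariance(small_dataset):
    spec = GlmmSpec(include_batch=False)
    fit_a = fit_glmm(small_dataset, spec)
    df = small_dataset.df.sample(frac=1.0, random_state=3).reset_index(
        drop=True)
    df["individual_id"] = df["individual_id"].map(
        lambda s: "X" + s[::-1])
    df["sample_id"] = df["sample_id"].map(lambda s: "X" + s[::-1])
    shuffled = fp.CountDataset(df=df)
    fit_b = fit_glmm(shuffled, spec)
    assert fit_b.loglik == pytest.approx(fit_a.loglik, abs=1e-6)
    assert np.allclose(fit_b.fixed_estimates, fit_a.fixed_estimates,
                       atol=1e-6)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_intercept_only_binomial_matches_pooled_proportion():
    """One sample, no random effects: MLE is the pooled proportion."""
    df = pd.DataFrame(dict(
        individual_id=["a"] * 4, sample_id=["s"] * 4, batch=["B1"] * 4,
        treatment=[0] * 4, fov_index=range(4),
        positive=[3, 5, 2, 6], total=[10, 10, 10, 10]))
    data = fp.CountDataset(df=df)
    spec = GlmmSpec(family="binomial", include_treatment=False,
                    include_batch=False, include_individual_re=False,
                    include_sample_re=False)
    fit = fit_glmm(data, spec)
    assert expit(fit.fixed_estimates[0]) == pytest.approx(16 / 40, abs=1e-6)
    assert fit.converged


def test_aic_identity_and_param_count(small_dataset):
    fit = fit_glmm(small_dataset, GlmmSpec(include_batch=False))
    assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)
    assert fit.n_params == 2 + 2 + 1


def test_treatment_term_never_decreases_loglik(small_dataset):
    with_t = fit_glmm(small_dataset, GlmmSpec(include_batch=False))
    without = fit_glmm(small_dataset, GlmmSpec(include_batch=False,
                                               include_treatment=False))
    assert with_t.loglik >= without.loglik - 1e-6


def test_matches_glmmtmb_reference(tmp_path):
    """Cross-check loglik, coefficients and SEs against glmmTMB (the
    standard Laplace GLMM implementation) on one simulated dataset."""
    import shutil
    import subprocess
    rscript = shutil.which("Rscript")
    if rscript is None:
        pytest.skip("Rscript not on PATH")
    design = fp.StudyDesign(n_individuals=8, n_fov=6, cells_per_fov=30)
    data = fp.simulate_dataset(design, fp.SimulationParams(), seed=5)
    csv = tmp_path / "counts.csv"
    fp.write_count_table(data, csv)
    script = tmp_path / "fit.R"
    script.write_text(f"""
suppressMessages(library(glmmTMB))
d <- read.csv("{csv}")
m <- glmmTMB(cbind(positive, total-positive) ~ treatment +
             (1|individual_id/sample_id),
             family=betabinomial(link="logit"), data=d)
s <- summary(m)
cat(as.numeric(logLik(m)), fixef(m)$cond, s$coefficients$cond[,2],
    sigma(m), "\\n")
""")
    out = subprocess.run([rscript, str(script)], capture_output=True,
                         text=True, check=True, timeout=300)
    ll_r, b0_r, b1_r, se0_r, se1_r, phi_r = map(
        float, out.stdout.split()[-6:])
    fit = fit_glmm(data, GlmmSpec(include_batch=False))
    assert fit.loglik == pytest.approx(ll_r, abs=0.01)
    assert fit.fixed_estimates[0] == pytest.approx(b0_r, abs=0.005)
    assert fit.fixed_estimates[1] == pytest.approx(b1_r, abs=0.005)
    assert fit.std_error("treatment") == pytest.approx(se1_r, rel=0.05)
    assert fit.dispersion_hat == pytest.approx(phi_r, rel=0.02)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def test_single_family_delta_aic_zero(small_dataset):
    rows = compare_models(small_dataset, ["betabinomial"],
                          spec=GlmmSpec(include_batch=False))
    assert len(rows) == 1 and rows[0].delta_aic == 0.0


def test_compare_all_families_on_overdispersed_data():
    design = fp.StudyDesign(n_individuals=10, n_fov=8, cells_per_fov=50)
    data = fp.simulate_dataset(design, fp.SimulationParams(), seed=13)
    rows = compare_models(data, spec=GlmmSpec(include_batch=False))
    assert len(rows) == 6
    assert sum(r.delta_aic == 0.0 for r in rows if r.converged) == 1
    best = rows[0]
    assert best.family_id == "betabinomial"
    # mean positivity for the average subject should be near 30%/26%
    assert 15 < best.mean_pct_control < 45
    assert best.mean_pct_treated < best.mean_pct_control


def test_binomial_parsimony_on_pure_binomial_data():
    """Without overdispersion the extra beta-binomial parameter should
    cost about 2 AIC points (chi2 parsimony), tested over replicates."""
    wins = 0
    n = 6
    for s in range(n):
        design = fp.StudyDesign(n_individuals=8, n_fov=6, cells_per_fov=30)
        params = fp.SimulationParams(family="binomial", dispersion=None)
        data = fp.simulate_dataset(design, params, seed=100 + s)
        rows = {r.family_id: r for r in compare_models(
            data, ["binomial", "betabinomial"],
            spec=GlmmSpec(include_batch=False))}
        if rows["binomial"].aic <= rows["betabinomial"].aic + 2.0:
            wins += 1
    assert wins >= n - 1


# ---------------------------------------------------------------------------
# Wald test
# ---------------------------------------------------------------------------

def test_wald_zero_estimate_gives_p_one(small_dataset):
    fit = fit_glmm(small_dataset, GlmmSpec(include_batch=False))
    fit.fixed_estimates[fit.term_names.index("treatment")] = 0.0
    res = wald_test(fit, "treatment", alpha=0.05)
    assert res.p_value == pytest.approx(1.0)
    assert not res.reject


def test_wald_rejection_boundary(small_dataset):
    fit = fit_glmm(small_dataset, GlmmSpec(include_batch=False))
    i = fit.term_names.index("treatment")
    fit.fixed_estimates[i] = 1.959964 * fit.std_errors[i]
    res = wald_test(fit, "treatment", alpha=0.05)
    assert res.p_value == pytest.approx(0.05, abs=1e-4)


def test_wald_unavailable_se_is_non_rejection(small_dataset):
    fit = fit_glmm(small_dataset, GlmmSpec(include_batch=False))
    fit.std_errors = None
    res = wald_test(fit, "treatment", alpha=0.05)
    assert not res.reject and not res.available
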