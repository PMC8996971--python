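"""Mixed-effects models for clustered FoV counts, fitted by Laplace ML.

Model
-----
For FoV ``r`` in sample ``j`` of individual ``i`` the positive count
``k_r`` (out of ``m_r`` cells) follows one of the six count families with
linear predictor

    eta_r = x_r' beta + offset_r + u_i + v_ij,
    u_i  ~ N(0, sd_individual^2),   v_ij ~ N(0, sd_sample^2),

where ``x_r`` holds the intercept, a treatment indicator and
reference-coded batch indicators, and ``offset_r = log m_r`` for the
log-link families (zero otherwise).  The marginal likelihood integrates
the nested random intercepts out per individual with a Laplace
approximation around the joint mode of that individual's ``1 + S_i``
effects, found by damped Newton iterations; individuals are independent,
so blocks are processed in a batched, vectorized pass.

Variance components are optimized on the log-SD scale (floored at
log 1e-8; fits at the floor report an SD of zero), dispersion on the log
scale, the whole packed vector by L-BFGS-B.  Standard errors come from
the inverse of a central-finite-difference observed-information matrix.
Model comparison is by AIC = -2 loglik + 2 (n fixed effects + n variance
components + n dispersion parameters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .families import CountFamily, get_family
from .synth import CountDataset

__all__ = [
    "GlmmSpec",
    "GlmmFit",
    "ModelComparisonRow",
    "build_design",
    "marginal_loglik",
    "fit_glmm",
    "compare_models",
    "wald_test",
]

_LOG_SD_FLOOR = np.log(1e-8)
_LOG_SD_CEIL = np.log(50.0)


@dataclass(frozen=True)
class GlmmSpec:
    """Which family and which terms enter the mixed model."""

    family: str = "betabinomial"
    include_treatment: bool = True
    include_batch: bool = True
    include_individual_re: bool = True
    include_sample_re: bool = True

    def resolved_family(self) -> CountFamily:
        return get_family(self.family)


@dataclass
class Design:
    """Packed design: fixed-effects matrix plus random-effect block maps."""

    X: np.ndarray                # (n, p) fixed-effects matrix
    term_names: list             # length p
    k: np.ndarray                # (n,) positive counts
    m: np.ndarray                # (n,) totals
    offset: np.ndarray           # (n,) log totals for log link, else 0
    n_blocks: int                # number of individuals
    d: int                       # random-effect slots per block (padded)
    row_block: np.ndarray        # (n,) block index of each row
    row_slots: list              # list of (n,) slot-index arrays (<= 2)
    active: np.ndarray           # (n_blocks, d) bool: slot is a real effect
    n_sample_slots: np.ndarray   # (n_blocks,) count of sample-level slots
    has_ind_slot: bool
    spec: GlmmSpec = None

    @property
    def n_random_dim(self) -> int:
        return int(self.active.sum())


def build_design(dataset: CountDataset, spec: GlmmSpec) -> Design:
    """Build fixed/random design structures from a validated count table."""
    df = dataset.df
    if len(df) == 0:
        raise ValueError("dataset is empty")
    family = spec.resolved_family()

    cols = [np.ones(len(df))]
    names = ["intercept"]
    if spec.include_treatment:
        cols.append(df["treatment"].to_numpy(dtype=float))
        names.append("treatment")
    batches = sorted(df["batch"].unique())
    if spec.include_batch and len(batches) > 1:
        for b in batches[1:]:
            cols.append((df["batch"] == b).to_numpy(dtype=float))
            names.append(f"batch[{b}]")
    X = np.column_stack(cols)

    k = df["positive"].to_numpy(dtype=float)
    m = df["total"].to_numpy(dtype=float)
    offset = np.log(m) if family.spec.uses_offset else np.zeros(len(df))

    ind_codes, ind_idx = np.unique(df["individual_id"], return_inverse=True)
    n_blocks = len(ind_codes)
    # sample slot within block: 1..S_i when the individual slot is present
    pair_codes, pair_idx = np.unique(
        df["individual_id"].astype(str) + "\x00" + df["sample_id"].astype(str),
        return_inverse=True)
    samp_within = np.zeros(len(df), dtype=np.int64)
    n_samples_per = np.zeros(n_blocks, dtype=np.int64)
    seen: dict = {}
    for r in range(len(df)):
        key = pair_idx[r]
        if key not in seen:
            seen[key] = n_samples_per[ind_idx[r]]
            n_samples_per[ind_idx[r]] += 1
        samp_within[r] = seen[key]

    has_ind = spec.include_individual_re
    has_samp = spec.include_sample_re
    if not has_ind and not has_samp:
        d = 1  # one pinned dummy slot keeps array shapes uniform
        row_slots = []
        active = np.zeros((n_blocks, 1), dtype=bool)
        n_sample_slots = np.zeros(n_blocks, dtype=np.int64)
    elif has_ind and has_samp:
        d = 1 + int(n_samples_per.max())
        row_slots = [np.zeros(len(df), dtype=np.int64), samp_within + 1]
        active = np.zeros((n_blocks, d), dtype=bool)
        active[:, 0] = True
        for b in range(n_blocks):
            active[b, 1:1 + n_samples_per[b]] = True
        n_sample_slots = n_samples_per
    elif has_ind:
        d = 1
        row_slots = [np.zeros(len(df), dtype=np.int64)]
        active = np.ones((n_blocks, 1), dtype=bool)
        n_sample_slots = np.zeros(n_blocks, dtype=np.int64)
    else:
        d = int(n_samples_per.max())
        row_slots = [samp_within]
        active = np.zeros((n_blocks, d), dtype=bool)
        for b in range(n_blocks):
            active[b, :n_samples_per[b]] = True
        n_sample_slots = n_samples_per

    return Design(X=X, term_names=names, k=k, m=m, offset=offset,
                  n_blocks=n_blocks, d=d, row_block=ind_idx,
                  row_slots=row_slots, active=active,
                  n_sample_slots=n_sample_slots, has_ind_slot=has_ind,
                  spec=spec)


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------

def _unpack(theta, design: Design):
    p = design.X.shape[1]
    beta = np.asarray(theta[:p], dtype=float)
    i = p
    spec = design.spec
    log_sd_u = theta[i] if spec.include_individual_re else _LOG_SD_FLOOR
    i += spec.include_individual_re
    log_sd_v = theta[i] if spec.include_sample_re else _LOG_SD_FLOOR
    i += spec.include_sample_re
    family = spec.resolved_family()
    disp = None
    if family.spec.has_dispersion:
        disp = np.exp(theta[i])
        if family.family_id == "genpois":
            disp = 1.0 + np.exp(theta[i])  # genpois needs phi >= 1
        i += 1
    return beta, float(np.exp(log_sd_u)), float(np.exp(log_sd_v)), disp


def n_parameters(design: Design) -> int:
    spec = design.spec
    return (design.X.shape[1]
            + int(spec.include_individual_re) + int(spec.include_sample_re)
            + int(spec.resolved_family().spec.has_dispersion))


# ---------------------------------------------------------------------------
# Laplace marginal log-likelihood
# ---------------------------------------------------------------------------

class _LaplaceState:
    """Warm-started random-effect modes reused across outer iterations."""

    def __init__(self):
        self.b = None
        self.n_failures = 0


def _laplace(theta, design: Design, state: _LaplaceState | None = None,
             inner_tol=1e-10, max_inner=100):
    """Laplace-approximated marginal loglik; -inf if any block fails."""
    family = design.spec.resolved_family()
    beta, sd_u, sd_v, disp = _unpack(theta, design)
    B, d = design.n_blocks, design.d
    blk, slots = design.row_block, design.row_slots
    k, m = design.k, design.m
    eta_fixed = design.X @ beta + design.offset

    prec = np.ones((B, d))  # pinned/padding slots keep unit precision
    if design.has_ind_slot:
        prec[:, 0] = np.where(design.active[:, 0], 1.0 / sd_u ** 2, 1.0)
        if d > 1:
            prec[:, 1:] = np.where(design.active[:, 1:], 1.0 / sd_v ** 2, 1.0)
    elif slots:  # sample-only random effect
        prec[:, :] = np.where(design.active, 1.0 / sd_v ** 2, 1.0)

    b = np.zeros((B, d))
    if state is not None and state.b is not None and state.b.shape == b.shape:
        b = state.b.copy()

    def eta_of(bb):
        eta = eta_fixed.copy()
        for s in slots:
            eta = eta + bb[blk, s]
        return eta

    def f_blocks(bb):
        ll = family.logpmf_eta(k, m, eta_of(bb), disp)
        fb = np.bincount(blk, weights=ll, minlength=B)
        return fb - 0.5 * np.sum(prec * bb * bb * design.active, axis=1)

    if not slots:  # no random effects at all: plain fixed-effects loglik
        ll = float(np.sum(family.logpmf_eta(k, m, eta_fixed, disp)))
        if state is not None:
            state.n_failures = 0
        return ll

    eye = np.eye(d)
    f_old = f_blocks(b)
    converged = np.zeros(B, dtype=bool)
    for _ in range(max_inner):
        ll, d1, d2 = family.dlogpmf_eta(k, m, eta_of(b), disp)
        grad = -prec * b * design.active
        M = np.zeros((B, d, d))
        for s in slots:
            np.add.at(grad, (blk, s), d1)
        for s1 in slots:
            for s2 in slots:
                flat = np.bincount(blk * d * d + s1 * d + s2,
                                   weights=d2, minlength=B * d * d)
                M -= flat.reshape(B, d, d)
        M[:, np.arange(d), np.arange(d)] += prec
        grad *= design.active

        gmax = np.max(np.abs(grad), axis=1)
        converged = gmax < inner_tol * (1.0 + np.abs(f_old))
        if converged.all():
            break

        ridge = 0.0
        for _try in range(6):
            try:
                Mr = M if ridge == 0.0 else M + ridge * eye[None]
                delta = np.linalg.solve(Mr, grad[:, :, None])[:, :, 0]
                break
            except np.linalg.LinAlgError:
                ridge = 1e-6 if ridge == 0.0 else ridge * 100.0
        else:  # pragma: no cover
            delta = grad

        step = np.ones(B)
        for _half in range(30):
            b_new = b + step[:, None] * delta
            f_new = f_blocks(b_new)
            worse = f_new < f_old - 1e-13 * (1.0 + np.abs(f_old))
            if not worse.any():
                break
            step[worse] *= 0.5
        b = b_new
        f_old = f_new
    n_fail = int(B - converged.sum())
    if state is not None:
        state.b = b
        state.n_failures = n_fail
    if n_fail:
        return -np.inf

    sign, logdet = np.linalg.slogdet(M)
    if np.any(sign <= 0):
        return -np.inf
    prior_const = np.zeros(B)
    if design.has_ind_slot:
        prior_const -= 0.5 * np.log(sd_u ** 2) * design.active[:, 0]
        prior_const -= 0.5 * design.n_sample_slots * np.log(sd_v ** 2)
    else:
        prior_const -= 0.5 * design.n_sample_slots * np.log(sd_v ** 2)
    return float(np.sum(f_old + prior_const - 0.5 * logdet))


def marginal_loglik(theta, dataset: CountDataset, spec: GlmmSpec) -> float:
    """Laplace marginal log-likelihood at a packed parameter vector.

    ``theta`` packs fixed effects, then log-SDs of the included random
    intercepts, then log dispersion (log(phi-1) for the generalized
    Poisson) when the family has one.
    """
    design = build_design(dataset, spec)
    return _laplace(np.asarray(theta, dtype=float), design)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class GlmmFit:
    """Result of a maximum-likelihood mixed-model fit."""

    family_id: str
    term_names: list
    fixed_estimates: np.ndarray
    sd_individual_hat: float
    sd_sample_hat: float
    dispersion_hat: float | None
    std_errors: np.ndarray | None   # fixed-effect SEs, None if singular info
    loglik: float
    n_params: int
    aic: float
    converged: bool
    n_laplace_failures: int
    n_obs: int
    theta: np.ndarray = field(repr=False, default=None)
    spec: GlmmSpec = field(repr=False, default=None)

    def estimate(self, term: str) -> float:
        return float(self.fixed_estimates[self.term_names.index(term)])

    def std_error(self, term: str) -> float | None:
        if self.std_errors is None:
            return None
        se = self.std_errors[self.term_names.index(term)]
        return float(se) if np.isfinite(se) else None

    def to_dict(self) -> dict:
        return {
            "family": self.family_id,
            "fixed_effects": {t: float(e) for t, e in
                              zip(self.term_names, self.fixed_estimates)},
            "std_errors": None if self.std_errors is None else
                          {t: float(s) for t, s in
                           zip(self.term_names, self.std_errors)},
            "sd_individual": self.sd_individual_hat,
            "sd_sample": self.sd_sample_hat,
            "dispersion": self.dispersion_hat,
            "loglik": self.loglik,
            "n_params": self.n_params,
            "aic": self.aic,
            "converged": self.converged,
            "n_laplace_failures": self.n_laplace_failures,
            "n_obs": self.n_obs,
        }


def _start_values(design: Design) -> np.ndarray:
    """Deterministic starting point: moment-based, then a short Newton
    polish of the fixed effects with random effects off."""
    family = design.spec.resolved_family()
    k, m = design.k, design.m
    pooled = np.clip(k.sum() / m.sum(), 1e-4, 1 - 1e-4)
    p = design.X.shape[1]
    beta = np.zeros(p)
    beta[0] = special.logit(pooled) if family.spec.link == "logit" \
        else np.log(pooled)

    disp0 = None
    if family.spec.has_dispersion:
        prop = k / m
        mean_p = max(float(prop.mean()), 1e-4)
        var_p = float(prop.var())
        mbar = float(m.mean())
        if family.family_id == "betabinomial":
            denom = mean_p * (1 - mean_p)
            rho = (mbar * var_p / max(denom, 1e-8) - 1.0) / max(mbar - 1.0, 1.0)
            rho = float(np.clip(rho, 1e-3, 0.9))
            disp0 = np.log(1.0 / rho - 1.0)
        else:
            mean_k = max(float(k.mean()), 1e-4)
            var_k = float(k.var())
            ratio = max(var_k / mean_k, 1.0 + 1e-3)
            if family.family_id == "genpois":
                disp0 = np.log(max(ratio - 1.0, 1e-3))  # phi = 1 + exp(.)
            elif family.family_id == "nb1":
                disp0 = np.log(max(ratio - 1.0, 1e-3))
            else:  # nb2: var = mu + mu^2/theta
                theta0 = mean_k ** 2 / max(var_k - mean_k, mean_k * 1e-2)
                disp0 = np.log(max(theta0, 1e-3))

    # short fixed-effects Newton (random effects at zero)
    disp_val = None if disp0 is None else (
        1.0 + np.exp(disp0) if family.family_id == "genpois" else np.exp(disp0))
    eta0 = design.offset
    for _ in range(25):
        eta = design.X @ beta + eta0
        ll, d1, d2 = family.dlogpmf_eta(k, m, eta, disp_val)
        g = design.X.T @ d1
        H = design.X.T @ (np.minimum(d2, -1e-10)[:, None] * design.X)
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        step = np.clip(step, -2.0, 2.0)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break

    parts = [beta]
    if design.spec.include_individual_re:
        parts.append([np.log(0.3)])
    if design.spec.include_sample_re:
        parts.append([np.log(0.3)])
    if disp0 is not None:
        parts.append([disp0])
    return np.concatenate([np.atleast_1d(np.asarray(x, float)) for x in parts])


def _fd_hessian(fun, x, rel_step=1e-5):
    """Central-difference Hessian with step 1e-5*(1+|theta_i|)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            if i == j:
                fpp = fun(x + 2 * h[i] * _e(n, i))
                fp = fun(x + h[i] * _e(n, i))
                fm = fun(x - h[i] * _e(n, i))
                fmm = fun(x - 2 * h[i] * _e(n, i))
                H[i, i] = (-fpp + 16 * fp - 30 * fun(x) + 16 * fm - fmm) \
                    / (12 * h[i] ** 2)
            else:
                fpp = fun(x + h[i] * _e(n, i) + h[j] * _e(n, j))
                fpm = fun(x + h[i] * _e(n, i) - h[j] * _e(n, j))
                fmp = fun(x - h[i] * _e(n, i) + h[j] * _e(n, j))
                fmm = fun(x - h[i] * _e(n, i) - h[j] * _e(n, j))
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def _e(n, i):
    v = np.zeros(n)
    v[i] = 1.0
    return v


def fit_glmm(dataset: CountDataset, spec: GlmmSpec | None = None, *,
             start=None, max_iter: int = 300, tol: float = 1e-9,
             compute_se: bool = True) -> GlmmFit:
    """Fit the nested-random-intercept mixed model by Laplace ML.

    Non-convergence never raises; the returned fit carries
    ``converged=False``.  Standard errors are ``None`` when the observed
    information is singular.
    """
    if spec is None:
        spec = GlmmSpec()
    design = build_design(dataset, spec)
    family = spec.resolved_family()
    state = _LaplaceState()

    def nll(theta):
        val = _laplace(theta, design, state)
        return -val if np.isfinite(val) else 1e12

    x0 = np.asarray(start, float) if start is not None \
        else _start_values(design)
    p = design.X.shape[1]
    bounds = [(None, None)] * p
    if spec.include_individual_re:
        bounds.append((_LOG_SD_FLOOR, _LOG_SD_CEIL))
    if spec.include_sample_re:
        bounds.append((_LOG_SD_FLOOR, _LOG_SD_CEIL))
    if family.spec.has_dispersion:
        bounds.append((np.log(1e-8), np.log(1e8)))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-6,
                     "maxcor": 25})
    theta = res.x
    loglik = _laplace(theta, design, state)
    n_fail = state.n_failures
    converged = bool(res.success) and np.isfinite(loglik) and n_fail == 0

    beta, sd_u, sd_v, disp = _unpack(theta, design)
    sd_u = 0.0 if np.log(max(sd_u, 1e-300)) <= _LOG_SD_FLOOR + 1e-6 else sd_u
    sd_v = 0.0 if np.log(max(sd_v, 1e-300)) <= _LOG_SD_FLOOR + 1e-6 else sd_v

    std_errors = None
    if compute_se and np.isfinite(loglik):
        se_state = _LaplaceState()
        se_state.b = None if state.b is None else state.b.copy()

        def ll_fun(th):
            v = _laplace(th, design, se_state)
            return v if np.isfinite(v) else -1e12

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            H = _fd_hessian(ll_fun, theta)
            info = -H
            try:
                cov = np.linalg.inv(info)
                diag = np.diag(cov)[:p]
                if np.all(diag > 0):
                    std_errors = np.sqrt(diag)
            except np.linalg.LinAlgError:
                std_errors = None

    n_par = n_parameters(design)
    return GlmmFit(
        family_id=family.family_id, term_names=list(design.term_names),
        fixed_estimates=beta,
        sd_individual_hat=float(sd_u) if spec.include_individual_re else 0.0,
        sd_sample_hat=float(sd_v) if spec.include_sample_re else 0.0,
        dispersion_hat=None if disp is None else float(disp),
        std_errors=std_errors, loglik=float(loglik), n_params=n_par,
        aic=float(-2.0 * loglik + 2.0 * n_par), converged=converged,
        n_laplace_failures=n_fail, n_obs=len(dataset.df),
        theta=theta, spec=spec)


# ---------------------------------------------------------------------------
# model comparison and Wald test
# ---------------------------------------------------------------------------

@dataclass
class ModelComparisonRow:
    family_id: str
    loglik: float
    n_params: int
    aic: float
    delta_aic: float
    mean_pct_control: float
    mean_pct_treated: float
    mean_pct_control_batch_avg: float
    mean_pct_treated_batch_avg: float
    converged: bool


def _mean_pct(fit: GlmmFit, treated: int) -> tuple[float, float]:
    """Percent positivity for the average subject (random effects zero),
    at the reference batch and averaged over batch levels."""
    family = get_family(fit.family_id)
    inv = special.expit if family.spec.link == "logit" else np.exp
    eta = fit.fixed_estimates[0]
    if treated and "treatment" in fit.term_names:
        eta = eta + fit.estimate("treatment")
    batch_terms = [t for t in fit.term_names if t.startswith("batch[")]
    ref = float(inv(eta)) * 100.0
    etas = [eta] + [eta + fit.estimate(t) for t in batch_terms]
    avg = float(np.mean([inv(e) for e in etas])) * 100.0
    return ref, avg


def compare_models(dataset: CountDataset, families=None,
                   spec: GlmmSpec | None = None,
                   **fit_kw) -> list[ModelComparisonRow]:
    """Fit each candidate family and rank by AIC (smallest first).

    Families that fail to converge are kept in the table but excluded
    from the delta-AIC reference.
    """
    from .families import FAMILY_IDS
    if families is None:
        families = list(FAMILY_IDS)
    if not families:
        raise ValueError("families: need at least one family")
    base = spec if spec is not None else GlmmSpec()
    fits = []
    for fam in families:
        fam_id = fam if isinstance(fam, str) else fam.family_id
        fspec = GlmmSpec(family=fam_id,
                         include_treatment=base.include_treatment,
                         include_batch=base.include_batch,
                         include_individual_re=base.include_individual_re,
                         include_sample_re=base.include_sample_re)
        fits.append(fit_glmm(dataset, fspec, **fit_kw))
    ref_aics = [f.aic for f in fits if f.converged and np.isfinite(f.aic)]
    best = min(ref_aics) if ref_aics else min(f.aic for f in fits)
    rows = []
    for f in fits:
        pc_ref, pc_avg = _mean_pct(f, treated=0)
        pt_ref, pt_avg = _mean_pct(f, treated=1)
        rows.append(ModelComparisonRow(
            family_id=f.family_id, loglik=f.loglik, n_params=f.n_params,
            aic=f.aic, delta_aic=float(f.aic - best),
            mean_pct_control=pc_ref, mean_pct_treated=pt_ref,
            mean_pct_control_batch_avg=pc_avg,
            mean_pct_treated_batch_avg=pt_avg,
            converged=f.converged))
    rows.sort(key=lambda r: (not r.converged, r.aic))
    return rows


@dataclass
class WaldResult:
    term: str
    estimate: float
    std_error: float | None
    z: float
    p_value: float
    reject: bool
    available: bool = True


def wald_test(fit: GlmmFit, term: str = "treatment",
              alpha: float = 0.05) -> WaldResult:
    """Two-sided Wald z-test on one fixed-effect term.

    A missing or non-finite standard error yields an unavailable result
    that downstream power tallies treat as a non-rejection.
    """
    est = fit.estimate(term)
    se = fit.std_error(term)
    if se is None or se <= 0:
        return WaldResult(term, est, None, np.nan, np.nan,
                          reject=False, available=False)
    z = est / se
    p = 2.0 * stats.norm.sf(abs(z))
    return WaldResult(term, est, se, float(z), float(p),
                      reject=bool(p < alpha))
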