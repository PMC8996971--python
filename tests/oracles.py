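"""Independent oracles used only by the test suite.

These deliberately avoid the code paths they check: exact rational /
high-precision arithmetic (mpmath), brute-force moment sums, numerical
quadrature of the beta-binomial mixture, and dense Gauss-Hermite
quadrature of the random-effects integral.
"""

from __future__ import annotations

import itertools

import mpmath as mp
import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy import integrate, special, stats


def binom_logpmf_exact(k: int, m: int, p) -> float:
    """Exact product-form binomial mass at 50-digit precision."""
    with mp.workdps(50):
        p = mp.mpf(p)
        val = mp.binomial(m, k) * p ** k * (1 - p) ** (m - k)
        return float(mp.log(val))


def pois_logpmf_exact(k: int, mu) -> float:
    with mp.workdps(50):
        mu = mp.mpf(mu)
        return float(k * mp.log(mu) - mu - mp.log(mp.factorial(k)))


def betabinom_logpmf_quadrature(k: int, m: int, mu: float,
                                phi: float) -> float:
    """Beta-binomial mass by integrating binomial(k; m, p) against the
    Beta(mu*phi, (1-mu)*phi) density over p."""
    a, b = mu * phi, (1.0 - mu) * phi

    def integrand(p):
        return stats.binom.pmf(k, m, p) * stats.beta.pdf(p, a, b)

    val, _ = integrate.quad(integrand, 0.0, 1.0, limit=200)
    return float(np.log(val))


def brute_moments(logpmf, kmax: int):
    """(mean, variance) by direct summation of k * pmf over 0..kmax."""
    ks = np.arange(kmax + 1)
    pmf = np.exp(logpmf(ks))
    mean = float(np.sum(ks * pmf))
    var = float(np.sum(ks ** 2 * pmf) - mean ** 2)
    return mean, var, float(pmf.sum())


def gh_marginal_loglik(dataset, family, beta, sd_ind, sd_samp, disp,
                       X, offset, n_nodes=31):
    """Dense Gauss-Hermite marginal log-likelihood, one individual block
    at a time.

    Integrates over the per-sample linear-predictor offsets
    a_j = u_i + v_ij, which are jointly normal with covariance
    sd_ind^2 * J + sd_samp^2 * I -- the same marginal integral the
    Laplace approximation targets, in its minimal dimension.
    """
    df = dataset.df
    eta_fixed = X @ np.asarray(beta, float) + offset
    nodes, weights = hermegauss(n_nodes)  # weight exp(-x^2/2)
    logw = np.log(weights) - 0.5 * np.log(2 * np.pi)

    total_ll = 0.0
    for ind, idx in df.groupby("individual_id", sort=False).indices.items():
        samples = df.iloc[idx].groupby("sample_id", sort=False).indices
        sample_rows = [np.asarray(idx)[v] for v in samples.values()]
        S = len(sample_rows)
        cov = sd_ind ** 2 * np.ones((S, S)) + sd_samp ** 2 * np.eye(S)
        # regularize the degenerate (sd -> 0) direction for the Cholesky
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(S))
        block_logs = []
        for combo in itertools.product(range(len(nodes)), repeat=S):
            z = nodes[np.array(combo)]
            a = L @ z
            lw = logw[np.array(combo)].sum()
            ll = 0.0
            for j, rows in enumerate(sample_rows):
                eta = eta_fixed[rows] + a[j]
                ll += float(np.sum(family.logpmf_eta(
                    df["positive"].to_numpy()[rows],
                    df["total"].to_numpy()[rows], eta, disp)))
            # the Hermite_e weight e^{-z^2/2} supplies the standard-normal
            # density up to the 1/sqrt(2*pi) folded into logw
            block_logs.append(lw + ll)
        total_ll += special.logsumexp(np.array(block_logs))
    return total_ll
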