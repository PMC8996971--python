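"""Candidate error distributions for field-of-view (FoV) cell counts.

Six families are supported for modelling the number of marker-positive
cells among the cells counted in one microscope field of view:

================  =====  ==========  ====================================
family_id         link   offset      variance (count scale)
================  =====  ==========  ====================================
binomial          logit  no          m*mu*(1-mu)
betabinomial      logit  no          m*mu*(1-mu)*(1 + (m-1)*rho)
poisson           log    log(total)  mu
genpois           log    log(total)  mu*phi          (phi >= 1)
nb1               log    log(total)  mu*(1 + disp)
nb2               log    log(total)  mu + mu^2/disp
================  =====  ==========  ====================================

The logit-link families model the positive count out of the total count
directly; the log-link families model the positive count with the log of
the total count as an offset, so the linear predictor is on the scale of
log positivity in both conventions.

Parameterizations
-----------------
* beta-binomial: precision ``phi`` with Beta shapes ``a = mu*phi``,
  ``b = (1-mu)*phi``; the intra-FoV correlation is ``rho = 1/(phi+1)``.
* generalized Poisson: mean ``mu`` and variance ``mu*phi`` via the
  internal form ``theta = mu/sqrt(phi)``, ``lam = 1 - 1/sqrt(phi)``,
  ``P(k) = theta*(theta+lam*k)^(k-1) * exp(-theta-lam*k)/k!``.
  Underdispersion (``phi < 1``) is not supported.
* nb1 / nb2: reparameterizations of the standard size/probability
  negative binomial with ``size = mu/disp`` and ``size = disp``.

Each family exposes the log-pmf, the first and second derivatives of the
per-observation log-likelihood with respect to the linear predictor
``eta`` (needed by the Laplace inner Newton iterations), and a sampler.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "FamilySpec",
    "CountFamily",
    "FAMILIES",
    "FAMILY_IDS",
    "get_family",
    "binom_logpmf",
    "betabinom_logpmf",
    "pois_logpmf",
    "genpois_logpmf",
    "nb_logpmf",
]


@dataclass(frozen=True)
class FamilySpec:
    """Static description of one candidate error distribution."""

    family_id: str
    link: str  # "logit" or "log"
    uses_offset: bool
    dispersion_name: str | None  # None for binomial / poisson

    @property
    def has_dispersion(self) -> bool:
        return self.dispersion_name is not None


def _check(cond: np.ndarray | bool, field: str, msg: str) -> None:
    if not np.all(cond):
        raise ValueError(f"{field}: {msg}")


def _as_counts(k, field: str) -> np.ndarray:
    k = np.asarray(k)
    _check(np.all(k == np.floor(k)) and np.all(k >= 0), field,
           "must be a non-negative integer")
    return k.astype(np.int64)


# ---------------------------------------------------------------------------
# log-pmfs (public, validated)
# ---------------------------------------------------------------------------

def binom_logpmf(k, m, p):
    """Binomial log mass log C(m,k) + k log p + (m-k) log(1-p)."""
    k = _as_counts(k, "k")
    m = _as_counts(m, "m")
    p = np.asarray(p, dtype=float)
    _check(m >= 1, "m", "must be a positive integer")
    _check(k <= m, "k", "must not exceed m")
    _check((p > 0) & (p < 1), "p", "must lie strictly in (0, 1)")
    return stats.binom.logpmf(k, m, p)


def betabinom_logpmf(k, m, mu, phi):
    """Beta-binomial log mass with mean ``m*mu`` and precision ``phi``.

    Beta shapes are ``a = mu*phi`` and ``b = (1-mu)*phi``; the variance is
    ``m*mu*(1-mu)*(1 + (m-1)*rho)`` with ``rho = 1/(phi+1)``.
    """
    k = _as_counts(k, "k")
    m = _as_counts(m, "m")
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    _check(m >= 1, "m", "must be a positive integer")
    _check(k <= m, "k", "must not exceed m")
    _check((mu > 0) & (mu < 1), "mu", "must lie strictly in (0, 1)")
    _check(phi > 0, "phi", "must be positive")
    return stats.betabinom.logpmf(k, m, mu * phi, (1.0 - mu) * phi)


def pois_logpmf(k, mu):
    """Poisson log mass k log mu - mu - log k!."""
    k = _as_counts(k, "k")
    mu = np.asarray(mu, dtype=float)
    _check(mu > 0, "mu", "must be positive")
    return stats.poisson.logpmf(k, mu)


def genpois_logpmf(k, mu, phi):
    """Generalized-Poisson log mass, mean ``mu`` and variance ``mu*phi``.

    Only equi- or overdispersion (``phi >= 1``) is supported; the
    underdispersed branch truncates the support and is rejected.
    """
    k = _as_counts(k, "k")
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    _check(mu > 0, "mu", "must be positive")
    if not np.all(phi >= 1.0):
        raise ValueError("phi: underdispersion (phi < 1) is not supported")
    theta = mu / np.sqrt(phi)
    lam = 1.0 - 1.0 / np.sqrt(phi)
    kk = k.astype(float)
    return (np.log(theta) + (kk - 1.0) * np.log(theta + lam * kk)
            - theta - lam * kk - special.gammaln(kk + 1.0))


def nb_logpmf(k, mu, disp, variant):
    """Negative-binomial log mass, linear (nb1) or quadratic (nb2) variance.

    nb1: variance ``mu*(1+disp)`` via size ``mu/disp``, prob ``1/(1+disp)``.
    nb2: variance ``mu + mu^2/disp`` via size ``disp``, prob ``disp/(disp+mu)``.
    """
    k = _as_counts(k, "k")
    mu = np.asarray(mu, dtype=float)
    disp = np.asarray(disp, dtype=float)
    _check(mu > 0, "mu", "must be positive")
    _check(disp > 0, "disp", "must be positive")
    if variant == "nb1":
        size = mu / disp
        prob = 1.0 / (1.0 + disp)
    elif variant == "nb2":
        size = disp
        prob = disp / (disp + mu)
    else:
        raise ValueError(f"variant: unknown negative-binomial variant {variant!r}")
    return stats.nbinom.logpmf(k, size, prob)


# ---------------------------------------------------------------------------
# family objects: eta-scale derivatives and samplers
# ---------------------------------------------------------------------------

class CountFamily:
    """One error distribution, seen through its linear predictor.

    ``eta`` is the linear predictor including any offset.  For logit-link
    families the per-FoV mean fraction is ``expit(eta)``; for log-link
    families the mean count is ``exp(eta + log(total))`` and the offset is
    folded into ``eta`` by the caller.
    """

    def __init__(self, spec: FamilySpec):
        self.spec = spec

    @property
    def family_id(self) -> str:
        return self.spec.family_id

    def __repr__(self) -> str:  # pragma: no cover
        return f"CountFamily({self.spec.family_id!r})"

    # --- interface -------------------------------------------------------
    def logpmf_eta(self, k, total, eta, disp=None):
        """Per-observation log-likelihood at linear predictor ``eta``."""
        raise NotImplementedError

    def dlogpmf_eta(self, k, total, eta, disp=None):
        """(l, dl/deta, d2l/deta2), all vectorized over observations."""
        raise NotImplementedError

    def sample(self, rng, total, eta, disp=None):
        """Draw positive counts; always satisfies 0 <= draw <= total."""
        raise NotImplementedError


class _Binomial(CountFamily):
    def logpmf_eta(self, k, total, eta, disp=None):
        mu = special.expit(eta)
        return stats.binom.logpmf(k, total, mu)

    def dlogpmf_eta(self, k, total, eta, disp=None):
        mu = special.expit(eta)
        ll = stats.binom.logpmf(k, total, mu)
        d1 = k - total * mu
        d2 = -total * mu * (1.0 - mu)
        return ll, d1, d2

    def sample(self, rng, total, eta, disp=None):
        return rng.binomial(total, special.expit(eta))


def _betabinom_ll(k, m, a, b):
    # direct log-beta form; identical to scipy.stats.betabinom.logpmf but
    # without per-call distribution overhead (hot path of the inner Newton)
    k = np.asarray(k, dtype=float)
    m = np.asarray(m, dtype=float)
    return (special.gammaln(m + 1.0) - special.gammaln(k + 1.0)
            - special.gammaln(m - k + 1.0)
            + special.betaln(k + a, m - k + b) - special.betaln(a, b))


class _BetaBinomial(CountFamily):
    def logpmf_eta(self, k, total, eta, disp=None):
        mu = special.expit(eta)
        return _betabinom_ll(k, total, mu * disp, (1.0 - mu) * disp)

    def dlogpmf_eta(self, k, total, eta, disp=None):
        phi = disp
        mu = special.expit(eta)
        a = mu * phi
        b = (1.0 - mu) * phi
        ll = _betabinom_ll(k, total, a, b)
        w = phi * mu * (1.0 - mu)  # da/deta = w, db/deta = -w
        dga, tga = _gamma_diffs(a, np.asarray(k))
        dgb, tgb = _gamma_diffs(b, np.asarray(total) - np.asarray(k))
        g = dga - dgb
        gp = tga + tgb
        d1 = w * g
        d2 = w * (1.0 - 2.0 * mu) * g + w * w * gp
        return ll, d1, d2

    def sample(self, rng, total, eta, disp=None):
        mu = special.expit(np.asarray(eta, dtype=float))
        p = rng.beta(mu * disp, (1.0 - mu) * disp)
        return rng.binomial(total, p)


class _Poisson(CountFamily):
    def logpmf_eta(self, k, total, eta, disp=None):
        return stats.poisson.logpmf(k, np.exp(eta))

    def dlogpmf_eta(self, k, total, eta, disp=None):
        mu = np.exp(eta)
        ll = stats.poisson.logpmf(k, mu)
        return ll, k - mu, -mu

    def sample(self, rng, total, eta, disp=None):
        return _draw_capped(rng, lambda r, n: r.poisson(np.exp(eta), size=n),
                            total)


class _GenPoisson(CountFamily):
    def logpmf_eta(self, k, total, eta, disp=None):
        return genpois_logpmf(k, np.exp(eta), disp)

    def dlogpmf_eta(self, k, total, eta, disp=None):
        phi = disp
        mu = np.exp(eta)
        sq = np.sqrt(phi)
        theta = mu / sq
        lam = 1.0 - 1.0 / sq
        kk = np.asarray(k, dtype=float)
        denom = theta + lam * kk
        ll = (np.log(theta) + (kk - 1.0) * np.log(denom)
              - theta - lam * kk - special.gammaln(kk + 1.0))
        # only theta depends on eta, with dtheta/deta = theta
        d1 = 1.0 + (kk - 1.0) * theta / denom - theta
        d2 = (kk - 1.0) * theta * lam * kk / denom ** 2 - theta
        return ll, d1, d2

    def sample(self, rng, total, eta, disp=None):
        mu = np.exp(np.asarray(eta, dtype=float))
        return _draw_capped(
            rng, lambda r, n: _genpois_rvs(r, mu, disp, n), total)


class _NegBinomial(CountFamily):
    def __init__(self, spec: FamilySpec, variant: str):
        super().__init__(spec)
        self.variant = variant

    def _size_prob(self, mu, disp):
        if self.variant == "nb1":
            return mu / disp, np.broadcast_to(1.0 / (1.0 + disp), np.shape(mu))
        return np.broadcast_to(disp, np.shape(mu)), disp / (disp + mu)

    def logpmf_eta(self, k, total, eta, disp=None):
        size, prob = self._size_prob(np.exp(eta), disp)
        return stats.nbinom.logpmf(k, size, prob)

    def dlogpmf_eta(self, k, total, eta, disp=None):
        mu = np.exp(eta)
        kk = np.asarray(k, dtype=float)
        size, prob = self._size_prob(mu, disp)
        ll = stats.nbinom.logpmf(kk, size, prob)
        if self.variant == "nb2":
            r = size
            d1 = kk - mu * (kk + r) / (r + mu)
            d2 = -mu * r * (kk + r) / (r + mu) ** 2
        else:  # nb1: size r = mu/disp grows with mu, prob fixed
            r = size
            base = special.digamma(kk + r) - special.digamma(r) + np.log(prob)
            d1 = r * base
            d2 = r * base + r * r * (special.polygamma(1, kk + r)
                                     - special.polygamma(1, r))
        return ll, d1, d2

    def sample(self, rng, total, eta, disp=None):
        mu = np.exp(np.asarray(eta, dtype=float))
        size, prob = self._size_prob(mu, disp)

        def draw(r, n):
            return r.negative_binomial(np.broadcast_to(size, (n,)),
                                       np.broadcast_to(prob, (n,)))

        return _draw_capped(rng, draw, total)


def _gamma_diffs(a, k):
    """(psi(a+k)-psi(a), psi1(a+k)-psi1(a)) for integer k >= 0.

    Uses the recurrence psi(a+k)-psi(a) = sum_{t<k} 1/(a+t) (and its
    derivative), which for the cell counts seen here (k <= a few hundred)
    is much cheaper than polygamma's Hurwitz-zeta path.
    """
    a = np.broadcast_to(np.asarray(a, dtype=float), np.shape(k)).ravel()
    k = np.asarray(k, dtype=np.int64).ravel()
    kmax = int(k.max()) if k.size else 0
    if kmax > 2048:  # fall back for unusually large counts
        dg = special.digamma(a + k) - special.digamma(a)
        tg = special.polygamma(1, a + k) - special.polygamma(1, a)
        return dg, tg
    t = np.arange(kmax, dtype=float)
    inv = np.where(t[None, :] < k[:, None], 1.0 / (a[:, None] + t[None, :]),
                   0.0)
    return inv.sum(axis=1), -(inv * inv).sum(axis=1)


def _genpois_rvs(rng, mu, phi, n):
    """Inversion sampler for the generalized Poisson (vectorized over rows)."""
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (n,))
    out = np.empty(n, dtype=np.int64)
    u = rng.random(n)
    # group identical means so the cdf table is built once per group
    uniq, inv = np.unique(mu, return_inverse=True)
    for g, m in enumerate(uniq):
        kmax = int(np.ceil(m + 12.0 * np.sqrt(m * phi) + 20))
        ks = np.arange(kmax + 1)
        cdf = np.cumsum(np.exp(genpois_logpmf(ks, m, phi)))
        sel = inv == g
        out[sel] = np.searchsorted(cdf, u[sel])
    return out


def _draw_capped(rng, draw, total, max_rounds=100):
    """Redraw log-link count draws that exceed the per-FoV total.

    Keeps the ``positive <= total`` invariant for families whose support
    is unbounded; draws still exceeding the cap after ``max_rounds`` are
    censored at the total.  Returns an int array shaped like ``total``.
    """
    total = np.asarray(total)
    n = total.size
    out = np.asarray(draw(rng, n)).astype(np.int64).reshape(total.shape)
    over = out > total
    rounds = 0
    while over.any() and rounds < max_rounds:
        redraw = np.asarray(draw(rng, n)).astype(np.int64).reshape(total.shape)
        out = np.where(over, redraw, out)
        over = out > total
        rounds += 1
    if over.any():
        out = np.minimum(out, total)
    return out


_SPECS = {
    "binomial": FamilySpec("binomial", "logit", False, None),
    "betabinomial": FamilySpec("betabinomial", "logit", False, "phi"),
    "poisson": FamilySpec("poisson", "log", True, None),
    "genpois": FamilySpec("genpois", "log", True, "phi"),
    "nb1": FamilySpec("nb1", "log", True, "alpha"),
    "nb2": FamilySpec("nb2", "log", True, "theta"),
}

FAMILIES: dict[str, CountFamily] = {
    "binomial": _Binomial(_SPECS["binomial"]),
    "betabinomial": _BetaBinomial(_SPECS["betabinomial"]),
    "poisson": _Poisson(_SPECS["poisson"]),
    "genpois": _GenPoisson(_SPECS["genpois"]),
    "nb1": _NegBinomial(_SPECS["nb1"], "nb1"),
    "nb2": _NegBinomial(_SPECS["nb2"], "nb2"),
}

FAMILY_IDS = tuple(FAMILIES)


def get_family(family_id) -> CountFamily:
    """Look up a family by id string (or pass a CountFamily through)."""
    if isinstance(family_id, CountFamily):
        return family_id
    try:
        return FAMILIES[family_id]
    except KeyError:
        raise ValueError(
            f"family_id: unknown family {family_id!r}; "
            f"expected one of {', '.join(FAMILY_IDS)}") from None
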