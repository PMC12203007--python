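"""Distribution of the number of pairwise sequence differences.

Under the infinite-sites assumption a locus of ``n`` sites with pairwise
coalescence time ``t`` carries ``x ~ Poisson(2nt)`` differences.  Averaging
over the coalescence-time density gives the marginal pmf

    ``f(x) = integral f(x | t) f(t) dt``,

which is available in closed form whenever ``f(t)`` is a piecewise sum of
shifted exponentials: each term reduces to a regularized incomplete-gamma
difference.  Everything is evaluated in log space; a numeric-quadrature
fallback (:func:`diff_count_pmf_quad`) is kept as a cross-check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad
from scipy.special import gammainc, gammaincc, gammaln

from .densities import CoalDensity, coal_density_two_species
from .models import ModelError, TwoSpeciesModelSpec

__all__ = ["diff_count_logpmf", "diff_count_pmf", "diff_count_pmf_quad",
           "logpmf_from_density"]


def _log_gammainc_diff(k: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """log of P(k, hi) - P(k, lo) (regularized lower incomplete gamma),
    switching to the upper-tail difference when both sides are near 1."""
    if math.isinf(hi):
        d = gammaincc(k, lo)
    else:
        p_lo = gammainc(k, lo)
        d = np.where(p_lo < 0.5,
                     gammainc(k, hi) - p_lo,
                     gammaincc(k, lo) - gammaincc(k, hi))
    with np.errstate(divide="ignore"):
        return np.log(np.maximum(d, 0.0))


def logpmf_from_density(x, n: int, density: CoalDensity) -> np.ndarray:
    """log f(x) for difference counts x (array-like) out of n sites."""
    x = np.atleast_1d(np.asarray(x))
    if np.any(x < 0) or np.any(x > n) or n < 1:
        raise ModelError("need 0 <= x <= n and n >= 1")
    xf = x.astype(float)
    two_n = 2.0 * float(n)

    logs = []   # each: array of log-magnitudes over x
    signs = []
    for ep in density.epochs:
        s, E = ep.start, ep.end
        for c, r, p in zip(ep.coef, ep.rate, ep.power):
            if c == 0.0:
                continue
            a = two_n + r
            if a <= 0:
                raise ModelError("epoch rate too negative for the pmf integral")
            for j in range(p + 1):
                # (t-s)^p expanded in powers of t
                if s == 0.0 and j < p:
                    continue
                binom = math.comb(p, j)
                const = (math.log(abs(c)) + r * s + math.log(binom)
                         + (p - j) * (math.log(s) if p > j else 0.0))
                k = xf + j + 1.0
                term = (const + xf * math.log(two_n)
                        - gammaln(xf + 1.0) + gammaln(k)
                        - k * math.log(a)
                        + _log_gammainc_diff(k, a * s, a * E))
                logs.append(term)
                signs.append(math.copysign(1.0, c) * (-1.0) ** (p - j))

    if not logs:
        return np.full(x.shape, -np.inf)
    # signed log-sum-exp over the analytic terms (kept manual: this sits in
    # the MCMC inner loop and the scipy wrapper is comparatively expensive)
    stack = np.stack(logs)
    sgn = np.asarray(signs)[:, None]
    m = stack.max(axis=0)
    m = np.where(np.isfinite(m), m, 0.0)
    tot = (sgn * np.exp(stack - m)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(tot > 0.0, m + np.log(np.maximum(tot, 1e-300)), -np.inf)
    return out


def diff_count_logpmf(x, n: int, spec: TwoSpeciesModelSpec) -> np.ndarray:
    return logpmf_from_density(x, n, coal_density_two_species(spec))


def diff_count_pmf(x, n: int, spec: TwoSpeciesModelSpec):
    """f(x; theta): probability of x differences out of n sites under the
    two-species family `spec` (closed form)."""
    res = np.exp(diff_count_logpmf(x, n, spec))
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(res[0])
    return res


def diff_count_pmf_quad(x: int, n: int, spec: TwoSpeciesModelSpec,
                        qtail: float = 1e-10) -> float:
    """Adaptive-quadrature evaluation of f(x), truncated at the 1-qtail
    quantile of the coalescence time.  Cross-check for the closed form."""
    if x < 0 or x > n:
        raise ModelError("need 0 <= x <= n")
    dens = coal_density_two_species(spec)
    # truncate where both the time density and the Poisson kernel are spent
    hi = max(dens.quantile(1.0 - qtail),
             (x + 12.0 * math.sqrt(x + 1.0) + 30.0) / (2.0 * n))
    two_n = 2.0 * n
    lfac = gammaln(x + 1.0)

    def integrand(t: float) -> float:
        if t <= 0.0:
            return 0.0
        lp = x * math.log(two_n * t) - two_n * t - lfac
        return math.exp(lp) * float(dens.pdf(t)[0])

    total = 0.0
    cuts = [e.start for e in dens.epochs if e.start < hi] + [hi]
    for lo_c, hi_c in zip(cuts[:-1], cuts[1:]):
        val, _ = quad(integrand, lo_c, hi_c, limit=200, epsabs=0.0,
                      epsrel=1e-13)
        total += val
    return total
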