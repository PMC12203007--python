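"""Pairwise coalescence-time densities under gene-flow models.

Two routes to the same object:

* :func:`coal_density_two_species` — hand-derived closed forms for the
  two-species families (MSCI, IM, IIM, SC, isolation), expressed epoch by
  epoch as weighted sums of shifted exponentials.
* :func:`pairwise_coal_density_ctmc` — an exact Markov-chain construction on
  arbitrary species trees with migration bands and introgression pulses,
  solved per epoch by eigendecomposition of the transient generator.

Both produce a :class:`CoalDensity`; the test suite holds them against each
other and against the event-driven simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.special import gammainc, gammaln

from .models import GeneFlowModel, ModelError, TwoSpeciesModelSpec

__all__ = ["CoalDensity", "Epoch", "coal_density_two_species",
           "pairwise_coal_density_ctmc"]


@dataclass(frozen=True)
class Epoch:
    """One piece of a piecewise density.

    The segment density for ``t`` in ``[start, end)`` is

        ``f(t) = sum_k coef_k * (t - start)**power_k * exp(-rate_k*(t-start))``

    Coefficients may be negative (the pieces come from differences of
    exponentials); the summed density is nonnegative.  Powers above zero
    arise only in the degenerate equal-rate convolution.
    """

    start: float
    end: float  # math.inf on the last epoch
    coef: tuple[float, ...]
    rate: tuple[float, ...]
    power: tuple[int, ...]

    def pdf(self, t: np.ndarray) -> np.ndarray:
        u = np.asarray(t, dtype=float) - self.start
        out = np.zeros_like(u)
        for c, r, p in zip(self.coef, self.rate, self.power):
            out += c * u**p * np.exp(-r * u)
        return out

    def _term_mass(self, c: float, r: float, p: int, upto: float) -> float:
        """integral of c * u^p e^{-ru} du over [0, upto]."""
        if upto <= 0:
            return 0.0
        if r * max(upto, 0.0) < 1e-12:  # effectively no decay
            if math.isinf(upto):
                return math.inf if c != 0 else 0.0
            return c * upto**(p + 1) / (p + 1)
        if math.isinf(upto):
            frac = 1.0
        else:
            frac = gammainc(p + 1, r * upto)
        return c * math.exp(gammaln(p + 1) - (p + 1) * math.log(r)) * frac

    def mass(self, upto: float | None = None) -> float:
        """Probability mass of the epoch (optionally only up to `upto`)."""
        hi = self.end if upto is None else min(upto, self.end)
        return sum(self._term_mass(c, r, p, hi - self.start)
                   for c, r, p in zip(self.coef, self.rate, self.power))


class CoalDensity:
    """Piecewise sum-of-shifted-exponentials density of a pairwise
    coalescence time, tiling [0, inf)."""

    def __init__(self, epochs: list[Epoch]):
        if not epochs:
            raise ModelError("density needs at least one epoch")
        if epochs[0].start != 0.0 or not math.isinf(epochs[-1].end):
            raise ModelError("epochs must tile [0, inf)")
        for a, b in zip(epochs, epochs[1:]):
            if not math.isclose(a.end, b.start, rel_tol=0, abs_tol=1e-15):
                raise ModelError("epochs must be contiguous")
        self.epochs = list(epochs)
        self._cum_cache: np.ndarray | None = None

    @property
    def _cum(self) -> np.ndarray:
        # epoch masses are only needed for cdf/quantile work; computing them
        # lazily keeps density construction cheap inside MCMC loops
        if self._cum_cache is None:
            self._cum_cache = np.concatenate(
                [[0.0], np.cumsum([e.mass() for e in self.epochs])])
        return self._cum_cache

    # -- evaluation ---------------------------------------------------------

    def pdf(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros_like(t)
        for e in self.epochs:
            sel = (t >= e.start) & (t < e.end)
            if sel.any():
                out[sel] = e.pdf(t[sel])
        return out

    def cdf(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros_like(t)
        for i, e in enumerate(self.epochs):
            sel = (t >= e.start) & (t < e.end)
            if sel.any():
                out[sel] = self._cum[i] + np.array(
                    [e.mass(upto=x) for x in t[sel]])
        out[t >= self.epochs[-1].end] = 1.0
        return np.clip(out, 0.0, 1.0)

    def total_mass(self) -> float:
        return float(self._cum[-1])

    def mean(self) -> float:
        """E[t], from the closed-form epoch integrals."""
        total = 0.0
        for e in self.epochs:
            for c, r, p in zip(e.coef, e.rate, e.power):
                # integral of (u + start) * c u^p e^{-ru} over the epoch
                hi = e.end - e.start
                total += e._term_mass(c, r, p + 1, hi)
                total += e.start * e._term_mass(c, r, p, hi)
        return total

    def quantile(self, q: float, tol: float = 1e-12) -> float:
        """Inverse CDF by bisection (used to truncate quadrature)."""
        lo, hi = 0.0, self.epochs[-1].start + 1.0
        while float(self.cdf(hi)[0]) < q:
            hi = 2.0 * hi + 1.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if float(self.cdf(mid)[0]) < q:
                lo = mid
            else:
                hi = mid
            if hi - lo < tol * max(1.0, hi):
                break
        return 0.5 * (lo + hi)

    def sample(self, rng: np.random.Generator, size: int,
               grid_points: int = 4096) -> np.ndarray:
        """Draw coalescence times by numeric inverse-CDF on a dense grid."""
        hi = self.quantile(1.0 - 1e-10)
        grid = np.linspace(0.0, hi, grid_points)
        cdf = self.cdf(grid)
        cdf, idx = np.unique(cdf, return_index=True)
        return np.interp(rng.uniform(0.0, cdf[-1], size=size), cdf, grid[idx])

    def to_tsv(self, grid) -> str:
        """Two-column TSV (t, f(t)) on the user-supplied grid."""
        vals = self.pdf(np.asarray(grid, dtype=float))
        lines = ["t\tdensity"]
        lines += [f"{t:.10g}\t{f:.10g}" for t, f in zip(np.asarray(grid), vals)]
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Closed-form two-species densities
# ---------------------------------------------------------------------------

def _im_segment(w: float, lam: float) -> tuple[tuple, tuple, tuple]:
    """Density terms for 'b jumps at rate w, then the pair coalesces at rate
    lam', measured from the segment start (both events within the segment)."""
    if w == 0.0:
        return (), (), ()
    if abs(lam - w) <= 1e-9 * lam:
        # equal-rate convolution: lam*w * u * exp(-lam u)
        return (lam * w,), (lam,), (1,)
    a = lam * w / (lam - w)
    return (a, -a), (w, lam), (0, 0)


def _im_survival(w: float, lam: float, dt: float) -> tuple[float, float]:
    """(P[no jump], P[jumped, not yet coalesced]) after time dt."""
    if w == 0.0:
        return 1.0, 0.0
    p_sep = math.exp(-w * dt)
    if abs(lam - w) <= 1e-9 * lam:
        p_tog = w * dt * math.exp(-lam * dt)
    else:
        p_tog = w / (lam - w) * (math.exp(-w * dt) - math.exp(-lam * dt))
    return p_sep, p_tog


def coal_density_two_species(spec: TwoSpeciesModelSpec) -> CoalDensity:
    """Density of the between-species coalescence time ``t_ab`` for one
    sequence sampled from each of A and B.

    Backward in time, the sampled pair starts separated.  Under MSCI the B
    lineage switches to A with probability ``phi`` at ``tauX``; under the
    MSC-M families it jumps at Poisson rate ``w = 4M/theta_dest`` while the
    band is active.  Once co-located in A the pair coalesces at rate
    ``2/thetaA``; surviving lineages meet in the ancestor R and coalesce at
    rate ``2/thetaR``.
    """
    lamA = 2.0 / spec.thetaA
    lamR = 2.0 / spec.thetaR
    tauR = spec.tauR
    epochs: list[Epoch] = []

    if spec.family == "MSCI":
        phi, tauX = spec.phi, spec.tauX
        epochs.append(Epoch(0.0, tauX, (), (), ()))
        epochs.append(Epoch(tauX, tauR, (phi * lamA,), (lamA,), (0,)))
        surv = (1.0 - phi) + phi * math.exp(-lamA * (tauR - tauX))
    elif spec.family == "IM" or spec.family == "none" or \
            (spec.family in ("IIM", "SC") and spec.w == 0.0):
        w = spec.w if spec.family == "IM" else 0.0
        c, r, p = _im_segment(w, lamA)
        epochs.append(Epoch(0.0, tauR, c, r, p))
        p_sep, p_tog = _im_survival(w, lamA, tauR)
        surv = p_sep + p_tog
    elif spec.family == "IIM":
        tauT = spec.tauT
        epochs.append(Epoch(0.0, tauT, (), (), ()))
        c, r, p = _im_segment(spec.w, lamA)
        epochs.append(Epoch(tauT, tauR, c, r, p))
        p_sep, p_tog = _im_survival(spec.w, lamA, tauR - tauT)
        surv = p_sep + p_tog
    elif spec.family == "SC":
        tauT = spec.tauT
        c, r, p = _im_segment(spec.w, lamA)
        epochs.append(Epoch(0.0, tauT, c, r, p))
        p_sep, p_tog = _im_survival(spec.w, lamA, tauT)
        # after contact ends only the co-located pair keeps coalescing in A
        epochs.append(Epoch(tauT, tauR, (p_tog * lamA,), (lamA,), (0,)))
        surv = p_sep + p_tog * math.exp(-lamA * (tauR - tauT))
    else:  # pragma: no cover
        raise ModelError(f"no closed form for family {spec.family!r}")

    epochs.append(Epoch(tauR, math.inf, (surv * lamR,), (lamR,), (0,)))
    return CoalDensity(epochs)


# ---------------------------------------------------------------------------
# Generic CTMC construction
# ---------------------------------------------------------------------------

def _breakpoints(model: GeneFlowModel) -> list[float]:
    tree = model.tree
    pts = {0.0}
    pts.update(tree.tau[v] for v in tree.parent)
    for b in model.bands:
        pts.update((b.t_start, b.t_end))
    for e in model.events:
        pts.add(e.tau)
    return sorted(pts)


def pairwise_coal_density_ctmc(model: GeneFlowModel, origin_a: str,
                               origin_b: str) -> CoalDensity:
    """Exact density of the coalescence time of one lineage sampled from each
    of two populations, on an arbitrary gene-flow model.

    The pair's joint location is a continuous-time Markov chain: within an
    epoch (delimited by node ages, band endpoints and pulse times) rates are
    constant — per-lineage backward jumps at ``4M/theta_dest`` inside active
    bands, pair coalescence at ``2/theta`` when co-located — and the epoch is
    solved by eigendecomposition.  At epoch boundaries lineages are remapped
    deterministically (speciation) or redistributed with probability ``phi``
    (introgression pulses).
    """
    tree = model.tree
    for lbl in (origin_a, origin_b):
        if lbl not in tree.parent or tree.tau[lbl] != 0.0:
            raise ModelError(f"origin {lbl!r} must be a population at time 0")

    pts = _breakpoints(model)
    pops = sorted(tree.parent)
    pop_ix = {p: i for i, p in enumerate(pops)}
    n = len(pops)
    nstates = n * n  # ordered pair (loc_a, loc_b)

    def six(pa: str, pb: str) -> int:
        return pop_ix[pa] * n + pop_ix[pb]

    # state distribution over ordered pairs (transient only)
    p = np.zeros(nstates)
    p[six(origin_a, origin_b)] = 1.0

    epochs: list[Epoch] = []
    events_at = {e.tau: e for e in model.events}

    boundaries = pts + [math.inf]
    for start, end in zip(boundaries[:-1], boundaries[1:]):
        # --- instantaneous boundary maps at `start` -----------------------
        if start in events_at:
            ev = events_at[start]
            d, s = pop_ix[ev.dest], pop_ix[ev.source]
            A = np.eye(n)
            A[d, d] = 1.0 - ev.phi
            A[d, s] = ev.phi
            # per-lineage independent move: p'_{(i,j)} = sum A[a,i] A[b,j] ...
            P2 = np.kron(A, A)  # row = old state, col = new state
            p = p @ P2
        # speciation: remap lineages in populations that just ended
        for v in pops:
            s0, e0 = tree.span(v)
            if e0 == start:
                parent = tree.parent[v]
                assert parent is not None
                A = np.eye(n)
                A[pop_ix[v], pop_ix[v]] = 0.0
                A[pop_ix[v], pop_ix[parent]] = 1.0
                p = p @ np.kron(A, A)

        if start == end:  # pragma: no cover
            continue

        # --- build the epoch generator ------------------------------------
        alive = [v for v in pops if tree.span(v)[0] <= start
                 and tree.span(v)[1] >= end]
        jump = np.zeros((n, n))  # per-lineage backward jump rates
        for b in model.bands:
            # epochs are delimited by band endpoints, so a band is either
            # active throughout the epoch or not at all
            if b.t_start <= start and b.t_end >= end:
                jump[pop_ix[b.dest], pop_ix[b.source]] += b.backward_rate(tree)
        kill = np.zeros(nstates)
        Q = np.zeros((nstates, nstates))
        for pa in alive:
            for pb in alive:
                i = six(pa, pb)
                tot = 0.0
                for dest_pop in alive:  # lineage a jumps
                    r = jump[pop_ix[pa], pop_ix[dest_pop]]
                    if r > 0:
                        Q[i, six(dest_pop, pb)] += r
                        tot += r
                for dest_pop in alive:  # lineage b jumps
                    r = jump[pop_ix[pb], pop_ix[dest_pop]]
                    if r > 0:
                        Q[i, six(pa, dest_pop)] += r
                        tot += r
                if pa == pb:
                    k = 2.0 / tree.theta[pa]
                    kill[i] = k
                    tot += k
                Q[i, i] = -tot

        # --- restrict to states reachable with nonzero mass ---------------
        active = p > 1e-300
        while True:
            reachable = active | (Q[active] != 0).any(axis=0)
            if (reachable == active).all():
                break
            active = reachable
        idx = np.flatnonzero(active)
        if math.isinf(end) and kill[idx].sum() == 0:
            raise ModelError("chain cannot be absorbed; model malformed")
        Qr = Q[np.ix_(idx, idx)]
        kr = kill[idx]
        pr = p[idx]

        coefs, rates, powers = _expsum_epoch(pr, Qr, kr)
        epochs.append(Epoch(start, end, coefs, rates, powers))

        if not math.isinf(end):
            # advance the state distribution to the epoch end
            pr_end = pr @ expm(Qr * (end - start))
            p = np.zeros(nstates)
            p[idx] = pr_end

    return CoalDensity(epochs)


def _expsum_epoch(p0: np.ndarray, Q: np.ndarray, kill: np.ndarray,
                  tol: float = 1e-9):
    """Decompose f(t) = p0 expm(Q t) kill into sum_k c_k e^{lambda_k t}.

    The generators arising here are symmetrizable (migration is a reversible
    single-lineage chain and coalescence only adds a diagonal killing term),
    so eigenvalues are real.  Near-defective generators (e.g. a jump rate
    numerically equal to a coalescence rate) are handled by an infinitesimal
    deterministic perturbation of the diagonal.
    """
    m = Q.shape[0]
    if m == 0:
        return (), (), ()
    lam, V = np.linalg.eig(Q)
    if np.abs(lam.imag).max(initial=0.0) > 1e-8 * max(1.0, np.abs(lam.real).max()):
        raise ModelError("complex epoch spectrum; model outside supported class")
    lam = lam.real
    V = V.real
    # guard against a defective eigenbasis
    order = np.argsort(lam)
    gaps = np.diff(lam[order])
    scale = max(1.0, np.abs(lam).max())
    if m > 1 and (np.abs(gaps) < 1e-10 * scale).any():
        jitter = 1e-8 * scale * (np.arange(m) - (m - 1) / 2.0) / max(m - 1, 1)
        Qj = Q + np.diag(jitter)
        lam, V = np.linalg.eig(Qj)
        lam, V = lam.real, V.real
    c = (p0 @ V) * np.linalg.solve(V, kill)
    keep = np.abs(c) > 1e-300
    return (tuple(float(x) for x in c[keep]),
            tuple(float(-l) for l in lam[keep]),
            tuple(0 for _ in range(int(keep.sum()))))
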