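"""Likelihood and Bayesian inference for the two-species families.

The data are per-locus pairwise difference counts (one sequence per species),
for which the likelihood is available in closed form.  Estimation offers
maximum likelihood (multi-restart quasi-Newton, sharing the pseudo-true
machinery) and Metropolis-Hastings MCMC with gamma priors, posterior means
and highest-posterior-density intervals.

Parameters are sampled on unconstrained scales (log for positive parameters,
logit for the introgression probability).  The migration prior is a config
switch: a gamma prior on M migrants/generation (converted to the
identifiable intensity w = 4M/thetaB through a supplied thetaB), or a gamma
prior on w itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .asymptotics import _assemble, _free_names, _initial_guesses, _log_bounds
from .data import DiffCountDataset
from .models import ModelError, TwoSpeciesModelSpec
from .pmf import diff_count_logpmf

__all__ = ["PriorSpec", "McmcTrace", "PosteriorSummary", "loglik", "fit_mle",
           "run_mcmc", "summarize"]


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Independent gamma priors (shape, rate) per free parameter.

    `migration_on` selects whether the gamma prior for gene flow is placed
    on M (migrants/generation; needs `thetaB` to map to the identifiable
    w = 4M/thetaB) or on w directly.  phi (MSCI) is uniform(0,1).
    """

    gammas: dict[str, tuple[float, float]]
    migration_on: str = "M"        # "M" | "w"
    thetaB: float = 0.01           # used to convert M <-> w
    phi_uniform: bool = True

    def __post_init__(self) -> None:
        for k, (a, b) in self.gammas.items():
            if a <= 0 or b <= 0:
                raise ModelError(f"gamma prior for {k!r} needs shape,rate > 0")
        if self.migration_on not in ("M", "w"):
            raise ModelError("migration_on must be 'M' or 'w'")

    @classmethod
    def default(cls, family: str, migration_on: str = "M",
                thetaB: float = 0.01) -> "PriorSpec":
        """Study defaults: theta ~ G(2,200) (mean 0.01), tau ~ G(4,200)
        (mean 0.02), M ~ G(2,10) (mean 0.2) or w ~ G(2,1) (mean 2)."""
        g: dict[str, tuple[float, float]] = {"thetaA": (2, 200),
                                             "thetaR": (2, 200),
                                             "tauR": (4, 200)}
        if family in ("IIM", "SC"):
            g["tauT"] = (4, 200)
        if family == "MSCI":
            g["tauX"] = (4, 200)
        if family in ("IM", "IIM", "SC"):
            g["mig"] = (2, 10) if migration_on == "M" else (2, 1)
        return cls(gammas=g, migration_on=migration_on, thetaB=thetaB)

    def mig_to_w(self, value: float) -> float:
        return 4.0 * value / self.thetaB if self.migration_on == "M" else value

    def w_to_mig(self, w: float):
        return w * self.thetaB / 4.0 if self.migration_on == "M" else w

    def logpdf(self, name: str, value: float) -> float:
        if name == "phi":
            return 0.0 if 0.0 < value < 1.0 else -math.inf
        if value <= 0.0:
            return -math.inf
        a, b = self.gammas[name]
        # gamma log-density, written out to keep the MCMC inner loop cheap
        return (a * math.log(b) - math.lgamma(a)
                + (a - 1.0) * math.log(value) - b * value)

    def sample_one(self, name: str, rng: np.random.Generator) -> float:
        if name == "phi":
            return float(rng.uniform())
        a, b = self.gammas[name]
        return float(rng.gamma(a, 1.0 / b))


def _param_names(family: str) -> list[str]:
    """Sampled parameters, with gene flow under the generic name 'mig'."""
    if family == "MSCI":
        return ["phi", "tauX", "tauR", "thetaA", "thetaR"]
    if family == "IM":
        return ["mig", "tauR", "thetaA", "thetaR"]
    if family in ("IIM", "SC"):
        return ["mig", "tauT", "tauR", "thetaA", "thetaR"]
    if family == "none":
        return ["tauR", "thetaA", "thetaR"]
    raise ModelError(f"unknown family {family!r}")


def _spec_of(family: str, values: dict[str, float],
             priors: PriorSpec) -> TwoSpeciesModelSpec:
    kw = dict(values)
    if "mig" in kw:
        kw["w"] = priors.mig_to_w(kw.pop("mig"))
    return TwoSpeciesModelSpec(family=family, **kw)


def _valid(family: str, values: dict[str, float]) -> bool:
    if values.get("tauR", 1.0) <= 0:
        return False
    if family == "MSCI" and not values["tauX"] < values["tauR"]:
        return False
    if family in ("IIM", "SC") and not values["tauT"] < values["tauR"]:
        return False
    return True


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _group(data: DiffCountDataset):
    """Unique (n, x) cells with multiplicities — the loci are i.i.d. so the
    log-likelihood is a weighted sum over cells."""
    key = data.n.astype(np.int64) * (data.x.max() + 1) + data.x
    uniq, counts = np.unique(key, return_counts=True)
    n_u = uniq // (data.x.max() + 1)
    x_u = uniq % (data.x.max() + 1)
    return n_u, x_u, counts


def loglik(data: DiffCountDataset, spec: TwoSpeciesModelSpec) -> float:
    """Sum over loci of log f(x_i; spec) (loci independent)."""
    n_u, x_u, counts = _group(data)
    total = 0.0
    for n in np.unique(n_u):
        sel = n_u == n
        lp = diff_count_logpmf(x_u[sel], int(n), spec)
        total += float(np.dot(counts[sel], lp))
    return total


class _CachedLoglik:
    def __init__(self, data: DiffCountDataset):
        self.n_u, self.x_u, self.counts = _group(data)
        self.ns = np.unique(self.n_u)

    def __call__(self, spec: TwoSpeciesModelSpec) -> float:
        total = 0.0
        for n in self.ns:
            sel = self.n_u == n
            lp = diff_count_logpmf(self.x_u[sel], int(n), spec)
            total += float(np.dot(self.counts[sel], lp))
        return total


# ---------------------------------------------------------------------------
# maximum likelihood
# ---------------------------------------------------------------------------

def fit_mle(data: DiffCountDataset, family: str, restarts: int = 10,
            seed: int = 0, equal_theta: bool = False):
    """Multi-restart L-BFGS-B maximization of the closed-form likelihood on
    log parameters (logit for phi), with the same restart/boundary
    bookkeeping as the pseudo-true fits.

    Returns (params dict, max log-likelihood, diagnostics DataFrame).
    """
    if family == "MSCI":
        return _fit_mle_msci(data, restarts, seed, equal_theta)
    rng = np.random.default_rng(seed)
    names = _free_names(family, equal_theta)
    ll = _CachedLoglik(data)
    # crude scale hints from the data for start points
    n_bar = float(np.mean(data.n))
    t_bar = max(float(np.mean(data.x)) / (2.0 * n_bar), 1e-6)
    hint = TwoSpeciesModelSpec(family="MSCI", phi=0.2, tauX=0.5 * t_bar,
                               tauR=t_bar, thetaA=t_bar, thetaR=t_bar)

    def objective(logp: np.ndarray) -> float:
        spec = _assemble(family, names, np.exp(logp), equal_theta)
        v = ll(spec)
        return -v if math.isfinite(v) else 1e12

    lo, hi = _log_bounds(names)
    rows = []
    for i, g in enumerate(_initial_guesses(hint, family, names, restarts, rng)):
        res = minimize(objective, g, method="L-BFGS-B",
                       bounds=list(zip(lo, hi)),
                       options=dict(maxiter=500, ftol=1e-12))
        rows.append(dict(restart=i, nll=float(res.fun),
                         converged=bool(res.success),
                         boundary=bool(np.any(res.x - lo < 1e-3) or
                                       np.any(hi - res.x < 1e-3)),
                         **{k: float(v) for k, v in zip(names, np.exp(res.x))}))
    table = pd.DataFrame(rows)
    ok = table[table.converged]
    pool = ok if not ok.empty else table
    best = pool.sort_values("nll").iloc[0]
    params = {k: float(best[k]) for k in names}
    if "dtau" in params:
        params["tauR"] = params["tauT"] + params.pop("dtau")
    return params, -float(best.nll), table


def _fit_mle_msci(data, restarts, seed, equal_theta):
    rng = np.random.default_rng(seed)
    ll = _CachedLoglik(data)
    names = ["phi", "tauX", "dtau", "thetaA"] + ([] if equal_theta else ["thetaR"])

    def to_spec(vec):
        phi = 1.0 / (1.0 + math.exp(-vec[0]))
        tauX, dtau, thetaA = np.exp(vec[1:4])
        thetaR = thetaA if equal_theta else float(np.exp(vec[4]))
        return TwoSpeciesModelSpec(family="MSCI", phi=phi, tauX=tauX,
                                   tauR=tauX + dtau, thetaA=thetaA,
                                   thetaR=thetaR, equal_theta=equal_theta)

    n_bar = float(np.mean(data.n))
    t_bar = max(float(np.mean(data.x)) / (2.0 * n_bar), 1e-6)
    base = np.array([0.0] + list(np.log([0.5 * t_bar, 0.5 * t_bar, t_bar]))
                    + ([] if equal_theta else [math.log(t_bar)]))
    rows = []
    for i in range(restarts):
        g = base + (rng.normal(0, 0.5, size=base.size) if i else 0.0)
        res = minimize(lambda v: -ll(to_spec(v)), g, method="L-BFGS-B",
                       options=dict(maxiter=500, ftol=1e-12))
        s = to_spec(res.x)
        rows.append(dict(restart=i, nll=float(res.fun),
                         converged=bool(res.success), boundary=False,
                         phi=s.phi, tauX=s.tauX, tauR=s.tauR,
                         thetaA=s.thetaA, thetaR=s.thetaR))
    table = pd.DataFrame(rows)
    ok = table[table.converged]
    pool = ok if not ok.empty else table
    best = pool.sort_values("nll").iloc[0]
    params = {k: float(best[k]) for k in
              ["phi", "tauX", "tauR", "thetaA", "thetaR"]}
    return params, -float(best.nll), table


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

def mle_init(data: DiffCountDataset, family: str, priors: PriorSpec,
             seed: int = 0, restarts: int = 4) -> dict[str, float]:
    """Starting state for `run_mcmc` at the maximum-likelihood estimate.

    The IIM/SC posteriors can be bimodal (a no-flow 'recent divergence' mode
    competes with the gene-flow mode); a random-walk chain started from a
    prior draw may never cross between them, so chains are best launched
    from the MLE.
    """
    params, _, _ = fit_mle(data, family, restarts=restarts, seed=seed)
    out: dict[str, float] = {}
    for k, v in params.items():
        if k == "w":
            out["mig"] = priors.w_to_mig(max(v, 1e-6))
        else:
            out[k] = v
    # keep strictly inside the support
    if "tauT" in out and out["tauT"] >= out["tauR"]:
        out["tauT"] = 0.5 * out["tauR"]
    if "tauX" in out and out["tauX"] >= out["tauR"]:
        out["tauX"] = 0.5 * out["tauR"]
    return out


@dataclass
class McmcTrace:
    """Post-burn-in samples (natural scale) with their provenance."""

    samples: pd.DataFrame          # columns: params + loglik
    family: str
    priors: PriorSpec
    seed: int
    acceptance: dict[str, float]
    step_sizes: dict[str, float]
    thin: int

    def param_names(self) -> list[str]:
        return [c for c in self.samples.columns if c != "loglik"]

    def M_samples(self) -> np.ndarray:
        """Migration-rate samples in migrants/generation."""
        if "mig" not in self.samples.columns:
            raise ModelError("trace has no migration parameter")
        vals = self.samples["mig"].to_numpy()
        if self.priors.migration_on == "w":
            return vals * self.priors.thetaB / 4.0
        return vals

    def to_tsv(self, path) -> None:
        """Write the kept samples as TSV (iteration, parameters, loglik)."""
        out = self.samples.copy()
        out.insert(0, "iteration", np.arange(len(out)) * self.thin)
        out.to_csv(path, sep="\t", index=False)


def run_mcmc(data: DiffCountDataset | None, family: str, priors: PriorSpec,
             iterations: int = 50_000, burnin: int = 2_000, thin: int = 10,
             seed: int = 0, beta: float = 1.0, init: dict | None = None,
             adapt_interval: int = 100) -> McmcTrace:
    """Random-walk Metropolis on transformed parameters.

    One parameter is updated per proposal, cycling through the blocks; step
    sizes adapt toward ~30% acceptance during burn-in only (frozen
    afterwards, preserving detailed balance).  ``data=None`` (or an empty
    beta) targets the prior.  `beta` tempers the likelihood (power
    posterior), used by the marginal-likelihood quadrature.
    """
    if iterations <= burnin:
        raise ModelError("iterations must exceed burnin")
    if thin < 1:
        raise ModelError("thin must be >= 1")
    rng = np.random.default_rng(seed)
    names = _param_names(family)
    ll = _CachedLoglik(data) if data is not None else None

    def loglik_at(values: dict[str, float]) -> float:
        if ll is None or beta == 0.0:
            return 0.0
        return ll(_spec_of(family, values, priors))

    def logprior(values: dict[str, float]) -> float:
        if not _valid(family, values):
            return -math.inf
        return sum(priors.logpdf(k, v) for k, v in values.items())

    # initial state: prior draws until valid (or caller-supplied)
    if init is not None:
        state = dict(init)
    else:
        for _ in range(1000):
            state = {k: priors.sample_one(k, rng) for k in names}
            if _valid(family, state):
                break
        else:  # pragma: no cover
            raise ModelError("could not find a valid initial state")
    cur_lp = logprior(state)
    cur_ll = loglik_at(state)

    step = {k: 0.5 for k in names}
    acc = {k: 0 for k in names}
    tries = {k: 0 for k in names}
    acc_win = {k: [0, 0] for k in names}

    kept_rows = []
    for it in range(iterations):
        for k in names:
            x = state[k]
            if k == "phi":
                z = math.log(x / (1.0 - x)) + step[k] * rng.normal()
                xp = 1.0 / (1.0 + math.exp(-z))
                # Jacobian of the logit transform
                log_jac = (math.log(xp * (1.0 - xp)) -
                           math.log(x * (1.0 - x)))
            else:
                xp = x * math.exp(step[k] * rng.normal())
                log_jac = math.log(xp) - math.log(x)
            prop = dict(state)
            prop[k] = xp
            tries[k] += 1
            acc_win[k][1] += 1
            if _valid(family, prop):
                # only the updated block's prior term changes
                lp = cur_lp - priors.logpdf(k, x) + priors.logpdf(k, xp)
                llp = loglik_at(prop)
                ratio = (lp + beta * llp) - (cur_lp + beta * cur_ll) + log_jac
                if math.log(rng.random() + 1e-300) < ratio:
                    state, cur_lp, cur_ll = prop, lp, llp
                    acc[k] += 1
                    acc_win[k][0] += 1
        if it < burnin and (it + 1) % adapt_interval == 0:
            for k in names:
                a, t = acc_win[k]
                if t:
                    rate = a / t
                    step[k] *= math.exp(0.6 * (rate - 0.30))
                    step[k] = min(max(step[k], 1e-3), 20.0)
                acc_win[k] = [0, 0]
        if it >= burnin and (it - burnin) % thin == 0:
            kept_rows.append({**state, "loglik": cur_ll})

    samples = pd.DataFrame(kept_rows)
    rates = {k: acc[k] / max(tries[k], 1) for k in names}
    if any(v == 0.0 for v in rates.values()):
        import warnings
        warnings.warn("zero-acceptance parameter block after adaptation",
                      RuntimeWarning, stacklevel=2)
    return McmcTrace(samples=samples, family=family, priors=priors,
                     seed=seed, acceptance=rates, step_sizes=dict(step),
                     thin=thin)


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSummary:
    table: pd.DataFrame  # index: param; columns: mean, hpd_lo, hpd_hi, ess

    def to_json(self, path=None) -> str:
        import json
        doc = {k: {c: float(v) for c, v in row.items()}
               for k, row in self.table.iterrows()}
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def covers(self, truth: dict[str, float]) -> dict[str, bool]:
        out = {}
        for k, v in truth.items():
            if k in self.table.index:
                row = self.table.loc[k]
                out[k] = bool(row.hpd_lo <= v <= row.hpd_hi)
        return out


def hpd_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing `level` of the draws."""
    x = np.sort(np.asarray(draws, dtype=float))
    m = x.size
    k = max(int(math.ceil(level * m)), 2)
    if k >= m:
        return float(x[0]), float(x[-1])
    widths = x[k - 1:] - x[:m - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def summarize(trace: McmcTrace, level: float = 0.95) -> PosteriorSummary:
    """Posterior means, 95% HPD intervals and effective sample sizes."""
    if trace.samples.empty:
        raise ModelError("empty trace")
    m = len(trace.samples)
    if m < 1.0 / (1.0 - level):
        raise ModelError(f"too few samples ({m}) for level {level}")
    import arviz as az
    rows = {}
    for k in trace.param_names():
        draws = trace.samples[k].to_numpy()
        lo, hi = hpd_interval(draws, level)
        ess = float(az.ess(np.asarray(draws)[None, :]))
        rows[k] = dict(mean=float(draws.mean()), hpd_lo=lo, hpd_hi=hi, ess=ess)
    return PosteriorSummary(pd.DataFrame(rows).T)
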