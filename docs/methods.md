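# Methods

`mscflow` studies what happens when gene flow between species is inferred
under the *wrong* model of gene flow. Two idealizations are in play:

* **Pulse introgression (MSC-I)** — at a single time `tauX`, a fraction
  `phi` of the recipient population is replaced by migrants.
* **Continuous migration (MSC-M)** — migrants arrive at a constant rate of
  `M` individuals per generation over a time window. Three variants differ
  only in the window: **IM** (the whole post-divergence interval), **IIM**
  (only early, stopping at `tauT`) and **SC** (only recently, starting at
  `tauT`).

All quantities are mutation-scaled: population sizes `theta = 4*N*mu`,
times `tau = T*mu` in expected substitutions per site. On this scale a
co-located pair of lineages coalesces at rate `2/theta`, and a lineage in a
migration band's destination jumps (backward in time) to the source at rate
`w = 4*M/theta_dest`. Gene-flow parameters are defined forward in time; the
simulator and all densities run backward, so an `A -> B` band moves sampled
lineages `B -> A`.

## Coalescence densities and the pairwise likelihood

For two species with one sequence sampled from each, the density of the
between-species coalescence time `t_ab` is piecewise analytic: on every
epoch it is a weighted sum of shifted exponentials (`CoalDensity`). The
closed forms for MSCI/IM/IIM/SC are derived from the three-state chain
{separated, co-located, coalesced} and validated against two independent
routes:

1. a generic continuous-time Markov chain on the joint lineage locations
   (`pairwise_coal_density_ctmc`), solved per epoch by eigendecomposition —
   agreement to sup-norm < 1e-6 (in practice ~1e-13);
2. the event-driven structured-coalescent simulator — Kolmogorov–Smirnov
   distance < 0.01 at 1e5 genealogies.

Under infinite sites, a locus of `n` sites with coalescence time `t`
carries `x ~ Poisson(2nt)` differences. Because the time density is a sum
of shifted exponentials, the marginal pmf `f(x)` is a closed form in
regularized incomplete-gamma differences, evaluated in log space (signed
log-sum-exp over analytic terms). An adaptive-quadrature evaluation is kept
as a cross-check and agrees to ~1e-13 relative error. Equal-rate
degeneracies (jump rate == coalescence rate) are handled exactly via a
`t * exp(-rt)` term rather than by perturbation.

## Pseudo-true parameters

With loci i.i.d. and their number growing without bound, the ML (and
Bayesian) estimate under a misspecified family converges to the
*pseudo-true* parameter vector minimizing the KL divergence
`D = sum_x f_true(x) log(f_true(x)/f_fit(x))`. The minimization runs on
log parameters with L-BFGS-B under box bounds, multi-restart (the default
10 start points mix a gene-flow-conversion heuristic with jittered and
wider draws), followed by a Nelder–Mead polish of the three best basins:
the objective carries ~1e-11 quadrature noise, which defeats
finite-difference gradients near the optimum. Restarts that end on a box
boundary (within 1e-3 on the log scale) are excluded; ties (within 1e-12
in KL) break to the smallest log-parameter norm. Bounds are [1e-8, 10] for
`tau` and `theta`; the migration intensity `w = 4M/theta_dest` lives on a
much larger scale (w ~ 130 at M ~ 0.33, thetaB = 0.01), so its upper bound
is 1e6. The two-epoch families are optimized in `(tauT, dtau)` coordinates
so `tauT < tauR` holds by construction.

`n = inf` selects the infinite-sequence limit, where the divergence is
computed between the coalescence-time densities themselves (piecewise
adaptive quadrature with a closed-form exponential tail). By data
processing the finite-`n` divergence increases monotonically to this
limit. The package reads the study's headline limiting migration rate as
this `n -> inf` value — the finite-`n` KL optimum keeps drifting (M* =
0.42 at n = 1000 down to 0.36 at n = 64,000, toward 0.317 in the limit) —
while the bound on the fitted migration-end time `tauT*` is evaluated on
the finite grid n in {250, ..., 64000}, where it stays in 0.00146–0.00154,
below the true pulse time 0.002. In the infeasible region of the limit
objective (fitting support starting after the truth's, where D = +inf) a
graded penalty restores a descent direction.

## Simulation

`sample_gene_tree` is an exact event-driven (Gillespie) structured
coalescent on arbitrary species trees: within an epoch all rates are
constant; pulses apply an independent Bernoulli(`phi`) relocation to each
lineage in the destination; populations merge at speciation nodes.
Bidirectional bands are two independent bands. Sequences evolve under
JC69 from a uniform root sequence; infinite-sites data instead draw
`x ~ Poisson(2nt)` capped at `n` (the cap is immaterial at the study's
parameter scales). Loci use counter-derived RNG substreams of one master
seed, so enlarging `L` never perturbs earlier loci. Two-species difference
counts also have a vectorized exact sampler used where throughput matters.

What the generator emulates: the study's two-species base design
(theta0 = 0.002 thin branches, thetaB = 5*theta0, tauX = theta0,
tauR = 2*theta0, phi = 0.2) and the four-species models A–D with their
directional variants (all branches theta0; M = 0.2). What it does not:
recombination within loci, mutation-model misspecification beyond applying
the infinite-sites likelihood to JC69 data (no multiple-hit correction —
a documented, deliberate mismatch), rate variation across loci, and
ascertainment. Passing tests therefore speak to model-misspecification
behavior under the stated coalescent assumptions, not to artifacts of real
alignments.

## Bayesian inference

The closed-form likelihood restricts inference to two species with one
sequence per species per locus; richer layouts (S > 1, four species) are
simulated but analyzed only through their analytic densities. Under that
restriction `thetaB` (and `thetaT`) never enter the likelihood: migration
is sampled as the identifiable compound, and `M` is reported through a
user-supplied true `thetaB` (default 0.01).

MCMC is random-walk Metropolis on log parameters (logit for `phi`), one
parameter per proposal in a fixed cycle, step sizes adapted toward ~30%
acceptance during burn-in only. Default priors follow the study:
`theta ~ G(2, 200)`, `tau ~ G(4, 200)`, and for migration either
`M ~ G(2, 10)` (the simulation prior) or `w ~ G(2, 1)` (the empirical-data
prior) — a config switch. Defaults here are scaled down from the original
million-iteration chains (typically 6,000–26,000 iterations, burn-in
1,000–2,000, thinning 2–5); all lengths are configurable. Summaries are
posterior means and shortest (HPD) intervals, with effective sample sizes
from `arviz`.

Two numerical caveats discovered and handled here:

* The IIM/SC posteriors on pulse-generated data are **bimodal**: a no-flow
  "recent divergence" mode competes with the gene-flow mode, and a
  random-walk chain started from the prior may never cross. Chains for
  those families start at the MLE (`mle_init`).
* The `w ~ G(2, 1)` prior is appropriate when `w` is genuinely of order
  one; at the simulation truths (w = 80–130) its log-penalty (~ -100)
  overwhelms desk-scale likelihoods and flips the IIM fit into the no-flow
  mode. Estimation on simulated data therefore uses the `M ~ G(2, 10)`
  prior.

## The test of gene flow

The Savage–Dickey ratio `B10 = P(M < eps) / P(M < eps | X)` uses the exact
gamma-CDF prior mass and the posterior fraction of samples in the null
interval; an empty interval is replaced by the pseudo-count
`0.5/(sample size)` and flagged. `eps` is defined on the `M` scale
(default 0.001, with 0.01 available) and mapped through `thetaB` when the
prior sits on `w`.

The pseudo-count makes the attainable Bayes factor finite:
`B10 <= P(null) * 2 * N` for `N` posterior draws. Consequently the
decisiveness threshold `B10 > 100` is only *expressible* when
`N > 50 / P(null)`. With `M ~ G(2, 10)` and `eps = 0.001`,
`P(null) ~ 5e-5` — the threshold would need millions of draws, so
strong-flow demonstrations under that prior use `eps = 0.01`
(`P(null) ~ 4.7e-3`, N >= 12,000), while power studies use the
`w ~ G(2, 1)` prior with `eps = 0.001` (`P(null) ~ 0.06`), where a few
thousand draws suffice. Power is the fraction of replicates with
`B10 > 100`; replicate seeds derive from the master seed so single
replicates re-run in isolation.

Non-nested comparisons (pulse vs continuous) use thermodynamic
integration: power-posterior chains at Gauss–Legendre `beta` points on
(0, 1) (default K = 32; tests use K = 8–16), `log Z` by quadrature of the
expected log-likelihood. The generic core is validated against a conjugate
Poisson–gamma toy evidence to < 0.05 nats.

## Experiment drivers and sizes

The `analysis/` scripts and the `experiments` module run the study designs
at desk scale: pseudo-true grids over a handful of `(n, phi)` points; one
two-species dataset of L = 2,000 loci fitted by all three migration
families; exact four-species density tables (no MCMC — inference there
belongs to gene-tree-integrating samplers, out of scope); and replicate
power tables at L = 1,000, R = 10–20. The mis-assignment demonstration
fits model D to model C's pairwise densities by minimizing summed squared
Hellinger distance (KL is infinite there because the fitted support starts
after zero while the truth's does not) — it reproduces the qualitative
pattern that the sister-lineage fit forces `t_ab` and `t_ac` to coincide
while the truth separates them (L1 distance 0.79 vs 0).

## Known limitations

* No gene-tree-integrating MCMC: multi-sequence and multi-species
  *inference* is out of scope by design; the four-species work is
  analytic + simulated only.
* The CTMC density construction assumes the per-epoch generator is
  diagonalizable with a real spectrum (true for migration + coalescence,
  which is symmetrizable); a deterministic diagonal jitter guards
  near-defective cases.
* Finite-`n` pseudo-true fits at `n` well beyond 64,000 can lose the
  incomplete-gamma difference to underflow; the infinite-`n` route covers
  that regime analytically.
* The equal-rate IM convolution is exact, but rates within 1e-9 relative
  of each other are folded into the degenerate branch.
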