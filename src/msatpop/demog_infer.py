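"""Bayesian inference of effective-population-size change from
microsatellite data.

Two model parameterizations are supported, mirroring the two classic
formulations of coalescent-based bottleneck inference:

* the bounded log-scale model over ``(theta, r, tf)`` with
  ``theta = 2 * N_crnt * mu``, ``r = N_crnt / N_stbl`` and ``tf`` the time
  of change in generations scaled by ``N_crnt``, with uniform priors on
  log10 inside fixed bounds; and
* the full-scale model over ``(N_crnt, N_stbl, Tfa)`` with normal priors
  on the log10 scale.

The reference sampler is a Metropolis-Hastings chain over the demographic
parameters and per-locus genealogies: node-time perturbations and
time-respecting topology exchanges are interleaved with log-scale
random-walk parameter updates.  The data term is the stepwise-mutation
likelihood of the observed repeat counts on each genealogy (Felsenstein
pruning with a reflected single-step random walk on the bounded allele
lattice), and the genealogy prior is the time-inhomogeneous coalescent
density under the exponential size-change trajectory.

Because full-length chains are expensive, an ABC backend (rejection
sampling against simulated summary statistics, sharing the simulator with
the scenario-choice module) is provided behind the same
:func:`estimate_sizes` interface and is the default at desk scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core_io import GenotypeMatrix, LocusSpec
from . import coalsim
from .sumstats import summaries_from_tips, summary_vector

__all__ = [
    "ThetaModelPriors",
    "FullModelPriors",
    "McmcSettings",
    "PosteriorSample",
    "IntervalSummary",
    "ConvergenceReport",
    "run_mcmc",
    "gelman_rubin",
    "posterior_mode",
    "hdi",
    "detect_decline",
    "estimate_sizes",
]


# ---------------------------------------------------------------------------
# priors and containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThetaModelPriors:
    """Uniform log10 priors of the bounded (theta, r, tf) model."""

    log10_theta: tuple[float, float] = (-5.0, 2.0)
    log10_r: tuple[float, float] = (-5.5, 1.5)
    log10_tf: tuple[float, float] = (-1.0, 1.0)
    mu_ref: float = 3.5e-4
    generation_time: float = 1.0


@dataclass(frozen=True)
class FullModelPriors:
    """Normal (mean, variance) log10 priors of the full-scale model."""

    log10_n_crnt: tuple[float, float] = (4.0, 2.25)
    log10_n_stbl: tuple[float, float] = (4.0, 2.25)
    log10_tfa: tuple[float, float] = (5.0, 2.5)
    log10_mu: tuple[float, float] = (math.log10(3.5e-4), 0.09)
    mu_ref: float = 3.5e-4
    generation_time: float = 1.0  # Tfa interpreted in generations by default


@dataclass(frozen=True)
class McmcSettings:
    n_steps: int = 20_000
    n_record: int = 500
    n_chains: int = 3
    seed: int = 0
    likelihood: bool = True
    update_mu: bool = True
    step_param: float = 0.25       # log10 random-walk sd
    step_mu: float = 0.15
    backend: str = "mcmc"          # estimate_sizes: "abc" | "mcmc"
    n_sims_abc: int = 20_000
    tol_abc: float = 0.01
    regression_adjust: bool = True  # Beaumont local-linear ABC adjustment


@dataclass
class PosteriorSample:
    """Posterior draws per chain per parameter."""

    draws: dict[str, np.ndarray]   # param -> (n_chains, n_draws)
    seed: int
    thin: int = 1

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    def pooled(self, param: str, last_half: bool = False) -> np.ndarray:
        x = self.draws[param]
        if last_half:
            x = x[:, x.shape[1] // 2:]
        return x.ravel()


@dataclass
class IntervalSummary:
    mode: float
    q1: float
    q3: float
    hdi_low: float
    hdi_high: float
    hdi_mass: float = 0.95
    n_draws: int = 0


@dataclass
class ConvergenceReport:
    psrf: dict[str, tuple[float, float]]   # param -> (point, 97.5% quantile)
    converged: bool
    threshold: float = 1.02


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------


def posterior_mode(samples: np.ndarray, mass: float = 0.95) -> IntervalSummary:
    """Mode (Gaussian-KDE argmax on a 512-point grid, Silverman bandwidth,
    lowest-index tie-break), empirical quartiles, and HDI bounds."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 1:
        raise ValueError("empty sample")
    if np.ptp(x) == 0.0:
        c = float(x[0])
        return IntervalSummary(c, c, c, c, c, mass, x.size)
    kde = sps.gaussian_kde(x, bw_method="silverman")
    h = float(kde.factor * x.std(ddof=1))
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, 512)
    dens = kde(grid)
    mode = float(grid[int(np.argmax(dens))])
    q1, q3 = np.percentile(x, [25, 75])
    lo, hi = hdi(x, mass)
    return IntervalSummary(mode, float(q1), float(q3), lo, hi, mass, x.size)


def hdi(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the draws
    (leftmost among ties)."""
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 2:
        return float(x[0]), float(x[0])
    k = max(int(math.ceil(mass * n)), 2)
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def detect_decline(r_samples: np.ndarray, mass: float = 0.95):
    """Decline flag: true iff the upper bound of the HDI of log10 r is
    below zero (the interval "does not reach zero")."""
    summ = posterior_mode(np.asarray(r_samples), mass)
    return bool(summ.hdi_high < 0.0), summ


def gelman_rubin(chains, params: list[str] | None = None,
                 threshold: float = 1.02) -> ConvergenceReport:
    """Gelman-Rubin potential scale reduction factor with its 97.5%
    quantile, per parameter (the corrected estimator used by coda's
    ``gelman.diag``).  Input: :class:`PosteriorSample` or a dict
    ``param -> (n_chains, n_draws)``; the caller is responsible for
    discarding burn-in (the convention here is to pass last halves).
    """
    draws = chains.draws if isinstance(chains, PosteriorSample) else chains
    params = list(draws) if params is None else params
    out = {}
    ok = True
    for p in params:
        x = np.asarray(draws[p], dtype=float)
        m, n = x.shape
        if m < 2:
            raise ValueError("need >= 2 chains")
        xbar = x.mean(axis=1)
        s2 = x.var(axis=1, ddof=1)
        W = float(s2.mean())
        B = float(n * xbar.var(ddof=1))
        if W <= 0.0:
            point = upper = 1.0 if B <= 0.0 else math.inf
            out[p] = (point, upper)
            ok = ok and upper <= threshold
            continue
        V = (n - 1) / n * W + (1.0 + 1.0 / m) * B / n
        var_w = float(s2.var(ddof=1)) / m
        var_b = 2.0 * B**2 / (m - 1)
        cov_wb = (n / m) * (
            float(np.cov(s2, xbar**2, ddof=1)[0, 1])
            - 2.0 * float(xbar.mean()) * float(np.cov(s2, xbar, ddof=1)[0, 1])
        )
        var_v = ((n - 1) ** 2 * var_w + (1 + 1 / m) ** 2 * var_b
                 + 2 * (n - 1) * (1 + 1 / m) * cov_wb) / n**2
        d = 2 * V**2 / var_v if var_v > 0 else math.inf
        df_adj = (d + 3) / (d + 1) if math.isfinite(d) else 1.0
        r2_fixed = (n - 1) / n
        r2_random = (1 + 1 / m) * B / (n * W)
        point = math.sqrt(df_adj * (r2_fixed + r2_random))
        w_df = 2 * W**2 / (var_w * m) if var_w > 0 else math.inf
        q = sps.f.ppf(0.975, m - 1, w_df) if math.isfinite(w_df) else 1.0
        upper = math.sqrt(df_adj * (r2_fixed + q * r2_random))
        out[p] = (float(point), float(upper))
        ok = ok and upper <= threshold
    return ConvergenceReport(out, bool(ok), threshold)


# ---------------------------------------------------------------------------
# coalescent prior and mutation likelihood
# ---------------------------------------------------------------------------


def _decline_epochs(n_crnt: float, n_stbl: float, t_gen: float):
    b = math.log(n_stbl / n_crnt) / t_gen
    return (np.array([0.0, t_gen]), np.array([n_crnt, n_stbl]),
            np.array([b, 0.0]))


def _size_at(starts, sizes, rates, t):
    j = int(np.searchsorted(starts, t, side="right")) - 1
    return sizes[j] * math.exp(rates[j] * (t - starts[j]))


def _invN_integral(starts, sizes, rates, t1, t2):
    """integral of 1/N(u) du over [t1, t2] across epochs."""
    total = 0.0
    m = len(starts)
    j = int(np.searchsorted(starts, t1, side="right")) - 1
    u1 = t1
    while u1 < t2 - 1e-15:
        t0, n0, b = starts[j], sizes[j], rates[j]
        u2 = min(t2, starts[j + 1]) if j + 1 < m else t2
        if b == 0.0:
            total += (u2 - u1) / n0
        else:
            total += (math.exp(-b * (u1 - t0)) - math.exp(-b * (u2 - t0))) \
                / (n0 * b)
        u1 = u2
        j += 1
    return total


def _genealogy_logprior(times, n_tips, epochs):
    """Log density of a labelled coalescent history with the given internal
    node times under the size trajectory ``epochs``."""
    starts, sizes, rates = epochs
    ev = np.sort(times[n_tips:])
    k = n_tips
    t_prev = 0.0
    lp = 0.0
    for te in ev:
        pairs = k * (k - 1) / 2.0
        lp -= pairs * 0.5 * _invN_integral(starts, sizes, rates, t_prev, te)
        lp -= math.log(2.0 * _size_at(starts, sizes, rates, te))
        t_prev = te
        k -= 1
    return lp


class _SmmLikelihood:
    """Felsenstein pruning for a reflected single-step mutation walk on the
    bounded repeat lattice.  The rate matrix is symmetric (outward steps at
    the boundary are suppressed), so its stationary distribution is uniform
    and one eigendecomposition serves every branch length."""

    def __init__(self, n_states: int):
        S = n_states
        q = np.zeros((S, S))
        for i in range(S):
            if i > 0:
                q[i, i - 1] = 0.5
            if i < S - 1:
                q[i, i + 1] = 0.5
            q[i, i] = -q[i].sum()
        self.n_states = S
        self.evals, self.evecs = np.linalg.eigh(q)

    def transition(self, mu_t: float) -> np.ndarray:
        p = (self.evecs * np.exp(self.evals * mu_t)) @ self.evecs.T
        np.clip(p, 0.0, None, out=p)
        return p

    def loglik(self, parent: np.ndarray, times: np.ndarray, tip_states:
               np.ndarray, mu: float) -> float:
        n_tips = tip_states.shape[0]
        n_nodes = 2 * n_tips - 1
        S = self.n_states
        partial = np.zeros((n_nodes, S))
        partial[np.arange(n_tips), tip_states] = 1.0
        partial[n_tips:] = 1.0
        logscale = 0.0
        # propagate child messages into parents; children always have a
        # lower index than their parent, so one ascending pass suffices
        for v in range(n_nodes - 1):
            p = parent[v]
            bl = times[p] - times[v]
            msg = self.transition(mu * bl) @ partial[v]
            partial[p] *= msg
            s = partial[p].max()
            if s > 0 and (s < 1e-150 or s > 1e150):
                partial[p] /= s
                logscale += math.log(s)
        root = n_nodes - 1
        tot = float(partial[root].sum()) / S
        if tot <= 0.0:
            return -math.inf
        return math.log(tot) + logscale


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------


def _tip_states(gm: GenotypeMatrix):
    """Per-locus arrays of repeat-count states for non-missing gene copies."""
    out = []
    for j, locus in enumerate(gm.loci):
        obs = gm.locus_calls(j)
        out.append(np.asarray(locus.size_to_repeat(obs), dtype=np.int64))
    return out


def _params_to_demography(x, priors):
    """Map a parameter vector to (N_crnt, N_stbl, T_gen)."""
    if isinstance(priors, ThetaModelPriors):
        n_crnt = 10.0 ** x[0] / (2.0 * priors.mu_ref)
        n_stbl = n_crnt / 10.0 ** x[1]
        t_gen = 10.0 ** x[2] * n_crnt
    else:
        n_crnt = 10.0 ** x[0]
        n_stbl = 10.0 ** x[1]
        t_gen = 10.0 ** x[2] / priors.generation_time
    return n_crnt, n_stbl, t_gen


def _log_prior(x, priors):
    if isinstance(priors, ThetaModelPriors):
        bounds = (priors.log10_theta, priors.log10_r, priors.log10_tf)
        for xi, (lo, hi) in zip(x, bounds):
            if not lo <= xi <= hi:
                return -math.inf
        return 0.0
    lp = 0.0
    for xi, (mean, var) in zip(
            x, (priors.log10_n_crnt, priors.log10_n_stbl, priors.log10_tfa)):
        lp += -0.5 * (xi - mean) ** 2 / var - 0.5 * math.log(
            2 * math.pi * var)
    return lp


_PARAM_NAMES = {
    ThetaModelPriors: ("log10_theta", "log10_r", "log10_tf"),
    FullModelPriors: ("log10_N_crnt", "log10_N_stbl", "log10_Tfa"),
}


def _init_params(priors, rng):
    if isinstance(priors, ThetaModelPriors):
        return np.array([
            rng.uniform(*priors.log10_theta),
            rng.uniform(*priors.log10_r),
            rng.uniform(*priors.log10_tf),
        ])
    return np.array([
        rng.normal(m, math.sqrt(v))
        for m, v in (priors.log10_n_crnt, priors.log10_n_stbl,
                     priors.log10_tfa)
    ])


def _simulate_start_tree(epochs, n_tips, rng):
    starts, sizes, rates = epochs
    n_nodes = 2 * n_tips - 1
    parent = np.empty(n_nodes, dtype=np.int64)
    times = np.empty(n_nodes, dtype=np.float64)
    coalsim._build_tree_seeded(starts, sizes, rates, n_tips, parent, times,
                               int(rng.integers(1, 2**31 - 1)))
    return parent, times


def _children_of(parent, n_nodes):
    ch = [[] for _ in range(n_nodes)]
    for v in range(n_nodes - 1):
        ch[parent[v]].append(v)
    return ch


def _run_single_chain(tip_states, loci, priors, settings, seed):
    rng = np.random.default_rng(seed)
    names = _PARAM_NAMES[type(priors)]
    x = _init_params(priors, rng)
    lp_x = _log_prior(x, priors)
    n_loci = len(tip_states)
    use_lik = settings.likelihood

    mus = np.full(n_loci, getattr(priors, "mu_ref", 3.5e-4))
    if use_lik:
        n_crnt, n_stbl, t_gen = _params_to_demography(x, priors)
        epochs = _decline_epochs(n_crnt, n_stbl, t_gen)
        liks = [_SmmLikelihood(l.n_states) for l in loci]
        trees = []
        for j in range(n_loci):
            n_tips = tip_states[j].shape[0]
            parent, times = _simulate_start_tree(epochs, n_tips, rng)
            trees.append([parent, times])
        log_mut = np.array([
            liks[j].loglik(trees[j][0], trees[j][1], tip_states[j], mus[j])
            for j in range(n_loci)
        ])
        log_gen = np.array([
            _genealogy_logprior(trees[j][1], tip_states[j].shape[0], epochs)
            for j in range(n_loci)
        ])

    record_every = max(settings.n_steps // settings.n_record, 1)
    rec = {nm: [] for nm in names}
    mu_mean, mu_var = getattr(priors, "log10_mu", (math.log10(3.5e-4), 0.09))
    n_events = np.array([t.shape[0] - 1 for t in tip_states])

    def _mu_logprior(mu_arr):
        lm = np.log10(mu_arr)
        return float(np.sum(-0.5 * (lm - mu_mean) ** 2 / mu_var))

    for step in range(settings.n_steps):
        u = rng.random() if use_lik else 0.0
        if u < 0.25:
            # demographic parameter random walk
            i = rng.integers(3)
            xp = x.copy()
            xp[i] += rng.normal(0.0, settings.step_param)
            lp_p = _log_prior(xp, priors)
            if lp_p == -math.inf:
                pass
            elif not use_lik:
                if math.log(rng.random() + 1e-300) < lp_p - lp_x:
                    x, lp_x = xp, lp_p
            else:
                n_crnt, n_stbl, t_gen = _params_to_demography(xp, priors)
                ep_p = _decline_epochs(n_crnt, n_stbl, t_gen)
                log_gen_p = np.array([
                    _genealogy_logprior(trees[j][1], tip_states[j].shape[0],
                                        ep_p)
                    for j in range(n_loci)
                ])
                delta = (lp_p - lp_x) + (log_gen_p.sum() - log_gen.sum())
                if math.log(rng.random() + 1e-300) < delta:
                    x, lp_x, epochs, log_gen = xp, lp_p, ep_p, log_gen_p
        elif u < 0.35 and settings.update_mu:
            j = int(rng.integers(n_loci))
            lmu = math.log10(mus[j])
            lmu_p = lmu + rng.normal(0.0, settings.step_mu)
            new_mu = 10.0 ** lmu_p
            ll_p = liks[j].loglik(trees[j][0], trees[j][1], tip_states[j],
                                  new_mu)
            delta = (ll_p - log_mut[j]
                     - 0.5 * ((lmu_p - mu_mean) ** 2
                              - (lmu - mu_mean) ** 2) / mu_var)
            if math.log(rng.random() + 1e-300) < delta:
                mus[j] = new_mu
                log_mut[j] = ll_p
        elif u < 0.45 and isinstance(priors, FullModelPriors):
            # global scaling along the mu*N ridge: node times, sizes and the
            # change time scale by c, mutation rates by 1/c; the mutation
            # likelihood and the coalescent rate integrals are invariant and
            # the event-density terms cancel against the time Jacobian, so
            # the move is judged on the priors alone
            c = math.exp(rng.uniform(-0.7, 0.7))
            xp = x + math.log10(c)
            lp_p = _log_prior(xp, priors)
            mus_p = mus / c
            delta = (lp_p - lp_x) + (_mu_logprior(mus_p) - _mu_logprior(mus))
            if lp_p > -math.inf and math.log(rng.random() + 1e-300) < delta:
                x, lp_x, mus = xp, lp_p, mus_p
                n_crnt, n_stbl, t_gen = _params_to_demography(x, priors)
                epochs = _decline_epochs(n_crnt, n_stbl, t_gen)
                for j in range(n_loci):
                    trees[j][1] *= c
                log_gen = log_gen - n_events * math.log(c)
        elif u < 0.55:
            # per-locus tree-depth rescale
            j = int(rng.integers(n_loci))
            c = math.exp(rng.uniform(-0.5, 0.5))
            parent, times = trees[j]
            times_p = times * c
            ll_p = liks[j].loglik(parent, times_p, tip_states[j], mus[j])
            n_tips = tip_states[j].shape[0]
            lg_p = _genealogy_logprior(times_p, n_tips, epochs)
            delta = (ll_p - log_mut[j]) + (lg_p - log_gen[j]) \
                + (n_tips - 1) * math.log(c)
            if math.log(rng.random() + 1e-300) < delta:
                trees[j][1] = times_p
                log_mut[j] = ll_p
                log_gen[j] = lg_p
        elif u < 0.65:
            # genealogy regeneration: propose a fresh tree from the
            # coalescent prior at the current demography; the prior terms
            # cancel against the proposal, leaving the mutation-likelihood
            # ratio.  Jumps between tree-space basins that local moves
            # cannot cross.
            j = int(rng.integers(n_loci))
            n_tips = tip_states[j].shape[0]
            parent_p, times_p = _simulate_start_tree(epochs, n_tips, rng)
            ll_p = liks[j].loglik(parent_p, times_p, tip_states[j], mus[j])
            if math.log(rng.random() + 1e-300) < ll_p - log_mut[j]:
                trees[j][0] = parent_p
                trees[j][1] = times_p
                log_mut[j] = ll_p
                log_gen[j] = _genealogy_logprior(times_p, n_tips, epochs)
        elif u < 0.85:
            # node-time perturbation
            j = int(rng.integers(n_loci))
            parent, times = trees[j]
            n_tips = tip_states[j].shape[0]
            n_nodes = 2 * n_tips - 1
            v = int(rng.integers(n_tips, n_nodes))
            ch = [c for c in range(n_nodes - 1) if parent[c] == v]
            lo = max(times[c] for c in ch)
            hastings = 0.0
            if v == n_nodes - 1:  # root: multiplicative gap scaling
                gap = times[v] - lo
                factor = math.exp(rng.uniform(-1.0, 1.0))
                t_new = lo + gap * factor
                hastings = math.log(factor)
            else:
                hi = times[parent[v]]
                t_new = rng.uniform(lo, hi)
            t_old = times[v]
            times[v] = t_new
            ll_p = liks[j].loglik(parent, times, tip_states[j], mus[j])
            lg_p = _genealogy_logprior(times, n_tips, epochs)
            delta = (ll_p - log_mut[j]) + (lg_p - log_gen[j]) + hastings
            if math.log(rng.random() + 1e-300) < delta:
                log_mut[j] = ll_p
                log_gen[j] = lg_p
            else:
                times[v] = t_old
        else:
            # topology exchange: swap a node's child with its sibling when
            # node times allow (symmetric proposal)
            j = int(rng.integers(n_loci))
            parent, times = trees[j]
            n_tips = tip_states[j].shape[0]
            n_nodes = 2 * n_tips - 1
            if n_nodes - 1 > n_tips:
                p = int(rng.integers(n_tips, n_nodes - 1))
                g = parent[p]
                sibs = [c for c in range(n_nodes - 1)
                        if parent[c] == g and c != p]
                kids = [c for c in range(n_nodes - 1) if parent[c] == p]
                u_node = sibs[0]
                v_node = kids[int(rng.integers(len(kids)))]
                if times[u_node] < times[p]:
                    parent[u_node], parent[v_node] = p, g
                    ll_p = liks[j].loglik(parent, times, tip_states[j],
                                          mus[j])
                    if math.log(rng.random() + 1e-300) < ll_p - log_mut[j]:
                        log_mut[j] = ll_p
                    else:
                        parent[u_node], parent[v_node] = g, p

        if step % record_every == 0 and len(rec[names[0]]) < settings.n_record:
            for i, nm in enumerate(names):
                rec[nm].append(x[i])

    return {nm: np.array(v) for nm, v in rec.items()}


def run_mcmc(gm: GenotypeMatrix, priors, settings: McmcSettings
             ) -> PosteriorSample:
    """Sample the posterior of the size-change model by MCMC.

    Refuses data with no polymorphic locus (no signal).  With
    ``settings.likelihood = False`` the data term is dropped entirely and
    the chain samples the parameter prior (a sampler-validity control).
    Deterministic given ``settings.seed``.
    """
    tips = _tip_states(gm)
    if settings.likelihood and not any(len(np.unique(t)) > 1 for t in tips):
        raise ValueError("all loci monomorphic: no signal for inference")
    ss = np.random.SeedSequence(settings.seed)
    chain_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) or 1
                   for s in ss.spawn(settings.n_chains)]
    names = _PARAM_NAMES[type(priors)]
    per_chain = [
        _run_single_chain(tips, gm.loci, priors, settings, s)
        for s in chain_seeds
    ]
    draws = {
        nm: np.stack([c[nm] for c in per_chain]) for nm in names
    }
    return PosteriorSample(draws, settings.seed)


# ---------------------------------------------------------------------------
# ABC backend and the combined interface
# ---------------------------------------------------------------------------


def _abc_posterior(gm: GenotypeMatrix, priors: FullModelPriors,
                   settings: McmcSettings) -> PosteriorSample:
    """Rejection-ABC posterior of the full-scale model: particles drawn
    from the priors, datasets simulated at the observed sample size and
    locus panel, closest fraction retained under standardized Euclidean
    distance on the summary vector."""
    rng = np.random.default_rng(settings.seed)
    obs = summary_vector(gm)
    n = settings.n_sims_abc
    x = np.column_stack([
        rng.normal(m, math.sqrt(v), size=n)
        for m, v in (priors.log10_n_crnt, priors.log10_n_stbl,
                     priors.log10_tfa)
    ])
    loci = [LocusSpec(l.name, motif_bp=l.motif_bp, min_len=l.min_len,
                      max_len=l.max_len, mu=priors.mu_ref, p_gsm=l.p_gsm)
            for l in gm.loci]
    table = np.empty((n, obs.shape[0]))
    seeds = rng.integers(1, 2**31 - 1, size=n)
    for i in range(n):
        n_crnt = max(10.0 ** x[i, 0], 2.0)
        n_stbl = max(10.0 ** x[i, 1], 2.0)
        t_years = max(10.0 ** x[i, 2], 2.0 * priors.generation_time)
        model = coalsim.DemographicModel(
            n_crnt, n_stbl, t_years, priors.generation_time)
        tips_sizes = coalsim.simulate_tip_sizes(
            model, loci, gm.n_individuals, int(seeds[i]), "source")
        table[i] = summaries_from_tips(tips_sizes, loci[0].motif_bp)
    sd = table.std(axis=0, ddof=1)
    keep_cols = sd > 0
    z = (table[:, keep_cols] - obs[keep_cols]) / sd[keep_cols]
    dist = np.sqrt(np.sum(z**2, axis=1))
    n_keep = max(int(round(settings.tol_abc * n)), 50)
    idx = np.argsort(dist, kind="stable")[:n_keep]
    theta = x[idx]
    if settings.regression_adjust:
        # local-linear regression adjustment: project retained particles to
        # the observed summaries, Epanechnikov-weighted on distance
        d = dist[idx]
        dmax = d.max() * (1.0 + 1e-12) or 1.0
        w = 1.0 - (d / dmax) ** 2
        design = np.column_stack([np.ones(n_keep), z[idx]])
        sw = np.sqrt(np.maximum(w, 1e-12))
        beta, *_ = np.linalg.lstsq(design * sw[:, None],
                                   theta * sw[:, None], rcond=None)
        theta = theta - z[idx] @ beta[1:]
    draws = {
        "log10_N_crnt": theta[:, 0][None, :],
        "log10_N_stbl": theta[:, 1][None, :],
        "log10_Tfa": theta[:, 2][None, :],
    }
    return PosteriorSample(draws, settings.seed)


def estimate_sizes(gm: GenotypeMatrix, priors: FullModelPriors | None = None,
                   settings: McmcSettings | None = None):
    """Estimate (N_crnt, N_stbl, Tfa) on the natural scale.

    Runs the configured backend; the MCMC backend runs >= 2 chains, checks
    convergence on the last halves (97.5% PSRF quantile <= 1.02) and pools
    them; non-convergence is reported via the flag, not by discarding.
    Returns ``(summaries, report, sample)`` where ``summaries`` maps
    ``N_crnt | N_stbl | Tfa`` to an :class:`IntervalSummary` whose mode is
    computed by KDE on the log10 scale and transformed back.
    """
    priors = priors or FullModelPriors()
    settings = settings or McmcSettings()
    if settings.backend == "abc":
        sample = _abc_posterior(gm, priors, settings)
        report = ConvergenceReport({}, True)
        pooled = {nm: sample.pooled(nm) for nm in sample.draws}
    else:
        if settings.n_chains < 2:
            raise ValueError("need >= 2 chains for convergence assessment")
        sample = run_mcmc(gm, priors, settings)
        halves = {nm: v[:, v.shape[1] // 2:] for nm, v in sample.draws.items()}
        report = gelman_rubin(halves)
        pooled = {nm: x.ravel() for nm, x in halves.items()}

    natural = {"log10_N_crnt": "N_crnt", "log10_N_stbl": "N_stbl",
               "log10_Tfa": "Tfa"}
    summaries = {}
    for key, name in natural.items():
        logx = pooled[key]
        s_log = posterior_mode(logx)
        xs = 10.0 ** logx
        q1, q3 = np.percentile(xs, [25, 75])
        lo, hi = hdi(xs, 0.95)
        summaries[name] = IntervalSummary(
            10.0 ** s_log.mode, float(q1), float(q3), lo, hi, 0.95,
            logx.size)
    return summaries, report, sample
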