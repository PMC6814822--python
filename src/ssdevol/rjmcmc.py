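"""Reversible-jump MCMC detection of SDI optimum shifts (multi-peak OU).

Rather than pre-assigning selective regimes, the sampler explores
configurations of optimum shifts placed on branches: the number of shifts K
carries a Poisson(15) prior truncated at the branch count, each configuration
places at most one shift per branch (branch subsets uniform), the shift
position within a branch is uniform, and each new optimum (and the
background/root optimum) carries a normal prior.  alpha and sigma^2 are
shared across the tree and carry log-normal priors.  Birth and death moves
propose new optima directly from their prior, which collapses the
reversible-jump acceptance ratio to ``(L'/L) * lambda/(K+1)`` (birth) and
``(L'/L) * K/lambda`` (death).

Convergence is assessed with the Gelman-Rubin potential scale reduction
factor across chains and autocorrelation-based effective sample sizes
(Geyer's initial positive sequence).  Shift support is reported as the
per-branch posterior probability (pp) of carrying a shift.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .tree import PhyloTree
from .ou import ou_vcv

__all__ = [
    "Shift",
    "ShiftConfig",
    "ShiftPriors",
    "ShiftModel",
    "RJMCMCRun",
    "ShiftPosterior",
    "prior_logdensity",
    "run_rjmcmc",
    "summarize_posterior",
    "gelman_rubin",
    "effective_sample_size",
]


@dataclass(frozen=True)
class Shift:
    branch: int  # node id at the tipward end of the branch carrying the shift
    pos: float  # relative position in [0, 1) from the rootward end
    theta: float  # new optimum, percent


@dataclass
class ShiftConfig:
    shifts: tuple
    theta0: float
    alpha: float
    sigma2: float

    @property
    def K(self) -> int:
        return len(self.shifts)


@dataclass
class ShiftPriors:
    """Hyperpriors of the shift model (weakly informative, scale-aware)."""

    k_lambda: float = 15.0
    theta_mean: float = 0.0
    theta_sd: float = 1.0
    log_alpha_mu: float = 0.0
    log_alpha_sd: float = 1.5
    log_sigma2_mu: float = 0.0
    log_sigma2_sd: float = 1.5

    @classmethod
    def from_data(cls, tree: PhyloTree, y, k_lambda: float = 15.0):
        """Centre the hyperpriors on the data scale.

        theta ~ N(data mean, 2 x data SD); alpha log-normal centred on a
        half-life of depth/3; sigma^2 log-normal centred on the ML Brownian
        rate.
        """
        y = np.asarray(y, dtype=float)
        C = tree.vcv()
        cho = linalg.cho_factor(C, lower=True)
        one = np.ones(len(y))
        Ci1 = linalg.cho_solve(cho, one)
        mu = float(y @ Ci1 / (one @ Ci1))
        r = y - mu
        s2_bm = float(r @ linalg.cho_solve(cho, r)) / len(y)
        return cls(
            k_lambda=k_lambda,
            theta_mean=float(np.mean(y)),
            theta_sd=2.0 * float(np.std(y)),
            log_alpha_mu=math.log(math.log(2.0) / (tree.depth / 3.0)),
            log_alpha_sd=1.5,
            log_sigma2_mu=math.log(max(s2_bm, 1e-12)),
            log_sigma2_sd=1.5,
        )


def _trunc_poisson_logpmf(k: int, lam: float, kmax: int) -> float:
    if k < 0 or k > kmax:
        return -math.inf
    ks = np.arange(kmax + 1)
    logZ = float(np.log(np.sum(stats.poisson.pmf(ks, lam))))
    return float(stats.poisson.logpmf(k, lam)) - logZ


def prior_logdensity(config: ShiftConfig, tree: PhyloTree, priors: ShiftPriors) -> float:
    """Log prior density of a shift configuration.

    The density is with respect to counting measure on (K, branch subset),
    Lebesgue on positions and optima, and Lebesgue on (ln alpha, ln sigma^2).
    Two shifts on a branch have prior density zero (-inf).
    """
    B = len(tree.branch_ids())
    K = config.K
    branches = [s.branch for s in config.shifts]
    if len(set(branches)) != K:
        return -math.inf
    if any(not (0.0 <= s.pos < 1.0) for s in config.shifts):
        return -math.inf
    lp = _trunc_poisson_logpmf(K, priors.k_lambda, B)
    lp -= math.lgamma(B + 1) - math.lgamma(K + 1) - math.lgamma(B - K + 1)  # ln C(B,K)
    for s in config.shifts:
        lp += stats.norm.logpdf(s.theta, priors.theta_mean, priors.theta_sd)
    lp += stats.norm.logpdf(config.theta0, priors.theta_mean, priors.theta_sd)
    lp += stats.norm.logpdf(math.log(config.alpha), priors.log_alpha_mu, priors.log_alpha_sd)
    lp += stats.norm.logpdf(math.log(config.sigma2), priors.log_sigma2_mu, priors.log_sigma2_sd)
    return float(lp)


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------


class _ShiftLikelihood:
    """Multi-peak OU likelihood for shift configurations on a fixed tree."""

    def __init__(self, tree: PhyloTree, y):
        self.tree = tree
        self.y = np.asarray(y, dtype=float)
        self.n = tree.n_tips
        # per-branch: start time and descendant tips; per-tip: path branch set
        self.t_start = tree.depths - tree.lengths
        self.desc_tips = [None] * tree.n_nodes
        for v in tree.postorder:
            if v < tree.n_tips:
                self.desc_tips[v] = [v]
            else:
                acc = []
                for c in tree.children[v]:
                    acc.extend(self.desc_tips[c])
                self.desc_tips[v] = acc
        self.T = tree.depths[: tree.n_tips]
        self._alpha_cache = (None, None, None)  # alpha -> (cho, logdet)

    def _chol(self, alpha: float):
        ca, cho, logdet = self._alpha_cache
        if ca == alpha:
            return cho, logdet
        V0 = ou_vcv(self.tree, alpha, 1.0)
        cho = linalg.cho_factor(V0, lower=True)
        logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        self._alpha_cache = (alpha, cho, logdet)
        return cho, logdet

    def mean(self, config: ShiftConfig) -> np.ndarray:
        """Expected tip values: exponentially discounted optimum history."""
        alpha = config.alpha
        # change points per tip: (time, theta) of shifts on the tip's path
        events = [[] for _ in range(self.n)]
        for s in config.shifts:
            t_abs = self.t_start[s.branch] + s.pos * self.tree.lengths[s.branch]
            for tip in self.desc_tips[s.branch]:
                events[tip].append((t_abs, s.theta))
        mu = np.zeros(self.n)
        for i in range(self.n):
            T = self.T[i]
            pieces = [(0.0, config.theta0)] + sorted(events[i])
            m = math.exp(-alpha * T) * config.theta0  # root term, merged into background
            for j, (t1, th) in enumerate(pieces):
                t2 = pieces[j + 1][0] if j + 1 < len(pieces) else T
                m += th * (math.exp(-alpha * (T - t2)) - math.exp(-alpha * (T - t1)))
            mu[i] = m
        return mu

    def loglik(self, config: ShiftConfig, mu: np.ndarray = None):
        if mu is None:
            mu = self.mean(config)
        cho, logdet = self._chol(config.alpha)
        r = self.y - mu
        q = float(r @ linalg.cho_solve(cho, r))
        lnL = -0.5 * (
            self.n * math.log(2 * math.pi)
            + self.n * math.log(config.sigma2)
            + logdet
            + q / config.sigma2
        )
        return lnL, q, logdet


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

_MOVES = ("birth", "death", "relocate", "theta", "alpha", "sigma2")
_DEFAULT_WEIGHTS = {
    "birth": 0.15, "death": 0.15, "relocate": 0.10,
    "theta": 0.30, "alpha": 0.15, "sigma2": 0.15,
}


@dataclass
class RJMCMCRun:
    """Sampled chains with traces, acceptance rates, and run settings."""

    samples: list  # per chain: list of ShiftConfig snapshots
    traces: list  # per chain: dict scalar name -> np.ndarray
    acceptance: list  # per chain: dict move -> (accepted, proposed)
    n_gens: int
    thin: int
    seed: object
    tree: PhyloTree = field(repr=False, default=None)
    prior_only: bool = False


class ShiftModel:
    """Bayesian multi-peak OU shift model of a continuous trait on a tree.

    ``run()`` draws RJ-MCMC samples over shift configurations; pass
    ``prior_only=True`` to hold the likelihood constant (sampler validation
    mode: the K posterior must then reproduce its truncated Poisson prior).
    """

    def __init__(self, tree: PhyloTree, sdi, priors: ShiftPriors = None,
                 prior_only: bool = False):
        self.tree = tree
        self.y = np.asarray(sdi, dtype=float)
        if len(self.y) != tree.n_tips:
            raise ValueError("trait length does not match tip count")
        self.priors = priors if priors is not None else ShiftPriors.from_data(tree, self.y)
        self.prior_only = prior_only
        self.lik = _ShiftLikelihood(tree, self.y)
        self.branches = np.array(tree.branch_ids())

    # -- one chain -----------------------------------------------------------

    def _run_chain(self, n_gens, thin, rng, move_weights, scales, init=None):
        pri = self.priors
        B = len(self.branches)
        mv_names = list(_MOVES)
        mv_p = np.array([move_weights[m] for m in mv_names], dtype=float)
        mv_p /= mv_p.sum()
        mv_cum = np.cumsum(mv_p)

        config = init if init is not None else ShiftConfig(
            shifts=(),
            theta0=pri.theta_mean,
            alpha=math.exp(pri.log_alpha_mu),
            sigma2=math.exp(pri.log_sigma2_mu),
        )
        occupied = {s.branch for s in config.shifts}
        lnL = 0.0 if self.prior_only else self.lik.loglik(config)[0]
        n_fail = 0
        samples, traces = [], {k: [] for k in ("K", "lnL", "alpha", "sigma2", "theta0")}
        acc = {m: [0, 0] for m in mv_names}

        def loglik_of(cfg):
            if self.prior_only:
                return 0.0
            return self.lik.loglik(cfg)[0]

        for g in range(n_gens):
            mi = int(np.searchsorted(mv_cum, rng.uniform()))
            move = mv_names[mi]
            acc[move][1] += 1
            new = None
            log_a = -math.inf
            try:
                if move == "birth":
                    if config.K < B:
                        free = [b for b in self.branches if b not in occupied]
                        b = free[rng.integers(len(free))]
                        s = Shift(int(b), float(rng.uniform()),
                                  float(rng.normal(pri.theta_mean, pri.theta_sd)))
                        new = replace(config, shifts=config.shifts + (s,))
                        lnL_new = loglik_of(new)
                        log_a = (lnL_new - lnL) + math.log(pri.k_lambda / (config.K + 1))
                elif move == "death":
                    if config.K > 0:
                        j = int(rng.integers(config.K))
                        new = replace(
                            config,
                            shifts=config.shifts[:j] + config.shifts[j + 1:],
                        )
                        lnL_new = loglik_of(new)
                        log_a = (lnL_new - lnL) + math.log(config.K / pri.k_lambda)
                elif move == "relocate":
                    if config.K > 0:
                        j = int(rng.integers(config.K))
                        others = occupied - {config.shifts[j].branch}
                        free = [b for b in self.branches if b not in others]
                        b = free[rng.integers(len(free))]
                        s = replace(config.shifts[j], branch=int(b),
                                    pos=float(rng.uniform()))
                        new = replace(
                            config,
                            shifts=config.shifts[:j] + (s,) + config.shifts[j + 1:],
                        )
                        lnL_new = loglik_of(new)
                        log_a = lnL_new - lnL
                elif move == "theta":
                    j = int(rng.integers(config.K + 1))
                    step = rng.normal(0.0, scales["theta"])
                    if j == 0:
                        old_th, new_th = config.theta0, config.theta0 + step
                        new = replace(config, theta0=new_th)
                    else:
                        s = config.shifts[j - 1]
                        old_th, new_th = s.theta, s.theta + step
                        new = replace(
                            config,
                            shifts=config.shifts[: j - 1]
                            + (replace(s, theta=new_th),)
                            + config.shifts[j:],
                        )
                    lnL_new = loglik_of(new)
                    dprior = stats.norm.logpdf(new_th, pri.theta_mean, pri.theta_sd) - \
                        stats.norm.logpdf(old_th, pri.theta_mean, pri.theta_sd)
                    log_a = (lnL_new - lnL) + dprior
                elif move == "alpha":
                    la = math.log(config.alpha) + rng.normal(0.0, scales["alpha"])
                    new = replace(config, alpha=math.exp(la))
                    lnL_new = loglik_of(new)
                    dprior = stats.norm.logpdf(la, pri.log_alpha_mu, pri.log_alpha_sd) - \
                        stats.norm.logpdf(math.log(config.alpha), pri.log_alpha_mu,
                                          pri.log_alpha_sd)
                    log_a = (lnL_new - lnL) + dprior
                else:  # sigma2
                    ls = math.log(config.sigma2) + rng.normal(0.0, scales["sigma2"])
                    new = replace(config, sigma2=math.exp(ls))
                    lnL_new = loglik_of(new)
                    dprior = stats.norm.logpdf(ls, pri.log_sigma2_mu, pri.log_sigma2_sd) - \
                        stats.norm.logpdf(math.log(config.sigma2), pri.log_sigma2_mu,
                                          pri.log_sigma2_sd)
                    log_a = (lnL_new - lnL) + dprior
            except (linalg.LinAlgError, np.linalg.LinAlgError, FloatingPointError):
                n_fail += 1
                if n_fail > max(10, 0.01 * n_gens):
                    raise RuntimeError("too many likelihood failures; aborting chain")
                new = None
            if new is not None and math.log(rng.uniform() + 1e-300) < log_a:
                config, lnL = new, lnL_new
                occupied = {s.branch for s in config.shifts}
                acc[move][0] += 1
            if (g + 1) % thin == 0:
                samples.append(config)
                traces["K"].append(config.K)
                traces["lnL"].append(lnL)
                traces["alpha"].append(config.alpha)
                traces["sigma2"].append(config.sigma2)
                traces["theta0"].append(config.theta0)
        traces = {k: np.asarray(v) for k, v in traces.items()}
        return samples, traces, {m: tuple(v) for m, v in acc.items()}

    def run(self, n_gens: int = 200_000, thin: int = 100, n_chains: int = 2,
            seed=None, move_weights: dict = None, scales: dict = None,
            init: ShiftConfig = None) -> RJMCMCRun:
        """Run independent chains; reproducible given ``seed``.

        Defaults are desk-scale (200k generations, thin 100, 2 chains); for a
        production analysis raise ``n_gens``/``thin`` via configuration.
        ``init`` sets the starting configuration of every chain (used with
        zeroed birth/death move weights for fixed-dimension validation runs).
        """
        mw = dict(_DEFAULT_WEIGHTS)
        if move_weights:
            mw.update(move_weights)
        sc = {"theta": max(self.priors.theta_sd / 4.0, 1e-6),
              "alpha": 0.4, "sigma2": 0.4}
        if scales:
            sc.update(scales)
        ss = np.random.SeedSequence(seed)
        children = ss.spawn(n_chains)
        samples, traces, acc = [], [], []
        for c in range(n_chains):
            rng = np.random.default_rng(children[c])
            s, t, a = self._run_chain(n_gens, thin, rng, mw, sc, init=init)
            samples.append(s)
            traces.append(t)
            acc.append(a)
        return RJMCMCRun(samples=samples, traces=traces, acceptance=acc,
                         n_gens=n_gens, thin=thin, seed=seed, tree=self.tree,
                         prior_only=self.prior_only)


def run_rjmcmc(tree: PhyloTree, sdi, n_gens: int = 200_000, thin: int = 100,
               n_chains: int = 2, seed=None, priors: ShiftPriors = None,
               prior_only: bool = False, **kw) -> RJMCMCRun:
    """Functional front-end to :class:`ShiftModel.run`."""
    return ShiftModel(tree, sdi, priors=priors, prior_only=prior_only).run(
        n_gens=n_gens, thin=thin, n_chains=n_chains, seed=seed, **kw
    )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def gelman_rubin(traces) -> float:
    """Potential scale reduction factor across >= 2 equal-length chains.

    Zero-variance traces return exactly 1.0 (degenerate but converged by
    construction; a warning flags the degeneracy).
    """
    X = np.asarray(traces, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = X.shape
    if n < 2:
        raise ValueError("chains too short")
    means = X.mean(axis=1)
    W = float(np.mean(X.var(axis=1, ddof=1)))
    if W == 0.0:
        warnings.warn("zero within-chain variance; R-hat degenerate, reported as 1")
        return 1.0
    B_over_n = float(np.var(means, ddof=1))
    var_plus = (n - 1) / n * W + B_over_n
    # truncated below at 1: values below 1 arise only from sampling noise
    return float(max(math.sqrt(var_plus / W), 1.0))


def effective_sample_size(trace) -> float:
    """Autocorrelation-based ESS (Geyer initial positive sequence).

    Capped at the trace length; a constant trace reports its length with a
    degeneracy warning.
    """
    x = np.asarray(trace, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("trace too short for an ESS estimate")
    v = x.var()
    if v == 0:
        warnings.warn("constant trace; ESS degenerate, reported as trace length")
        return float(n)
    xc = x - x.mean()
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # Geyer: sum pair sums Gamma_k = rho_{2k} + rho_{2k+1} while positive
    tau = -1.0
    k = 0
    while 2 * k + 1 < n:
        gamma = rho[2 * k] + rho[2 * k + 1]
        if gamma <= 0:
            break
        tau += 2.0 * gamma
        k += 1
    tau = max(tau, 1.0 / n)
    return float(min(n / tau, n))


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------


@dataclass
class ShiftPosterior:
    """Per-branch shift support and posterior parameter summaries."""

    branch_pp: pd.Series  # index: branch id, value: posterior shift probability
    shifts: pd.DataFrame  # branches above the pp threshold, with theta summaries
    pp_threshold: float
    burn_in: float
    rhat: dict
    ess: dict
    k_posterior: pd.Series  # P(K = k)
    mean_k: float
    n_samples: int

    def summary(self) -> str:
        lines = [
            f"Shift posterior from {self.n_samples} retained samples "
            f"(burn-in {self.burn_in:.0%})",
            f"E[K] = {self.mean_k:.2f}; "
            f"{len(self.shifts)} branches with pp > {self.pp_threshold}",
        ]
        if len(self.shifts):
            lines.append(self.shifts.round(4).to_string(index=False))
        lines.append("R-hat: " + ", ".join(f"{k}={v:.3f}" for k, v in self.rhat.items()))
        lines.append("ESS:   " + ", ".join(f"{k}={v:.0f}" for k, v in self.ess.items()))
        return "\n".join(lines)

    def to_tsv(self, path):
        out = pd.DataFrame({
            "branch_id": self.branch_pp.index,
            "pp": self.branch_pp.values,
        })
        merged = out.merge(self.shifts, on="branch_id", how="left") if len(self.shifts) \
            else out.assign(theta_mean=np.nan, theta_ci_low=np.nan, theta_ci_high=np.nan)
        if "pp_y" in merged.columns:
            merged = merged.drop(columns=["pp_y"]).rename(columns={"pp_x": "pp"})
        merged.to_csv(path, sep="\t", index=False)


def summarize_posterior(run: RJMCMCRun, burn_in: float = 0.30,
                        pp_threshold: float = 0.5) -> ShiftPosterior:
    """Pool post-burn-in samples across chains into shift support summaries."""
    if not 0.0 <= burn_in < 1.0:
        raise ValueError("burn_in must be in [0, 1)")
    kept = []
    kept_traces = {k: [] for k in ("K", "lnL", "alpha", "sigma2", "theta0")}
    for samples, traces in zip(run.samples, run.traces):
        cut = int(len(samples) * burn_in)
        if cut >= len(samples):
            raise ValueError("burn-in removes every sample")
        kept.append(samples[cut:])
        for k in kept_traces:
            kept_traces[k].append(traces[k][cut:])
    pooled = [s for chain in kept for s in chain]
    if not pooled:
        raise ValueError("no post-burn-in samples")
    branch_ids = run.tree.branch_ids() if run.tree is not None else sorted(
        {s.branch for cfg in pooled for s in cfg.shifts}
    )
    counts = {b: 0 for b in branch_ids}
    theta_draws: dict = {b: [] for b in branch_ids}
    k_vals = []
    for cfg in pooled:
        k_vals.append(cfg.K)
        for s in cfg.shifts:
            counts[s.branch] += 1
            theta_draws[s.branch].append(s.theta)
    n_s = len(pooled)
    pp = pd.Series({b: counts[b] / n_s for b in branch_ids}).sort_index()
    rows = []
    for b in branch_ids:
        if pp[b] > pp_threshold:
            th = np.asarray(theta_draws[b])
            rows.append({
                "branch_id": b,
                "pp": pp[b],
                "theta_mean": float(th.mean()),
                "theta_ci_low": float(np.quantile(th, 0.025)),
                "theta_ci_high": float(np.quantile(th, 0.975)),
            })
    shifts = pd.DataFrame(rows, columns=["branch_id", "pp", "theta_mean",
                                         "theta_ci_low", "theta_ci_high"])
    rhat, ess = {}, {}
    for name, chains in kept_traces.items():
        lens = {len(c) for c in chains}
        arr = np.asarray([c[: min(lens)] for c in chains], dtype=float)
        if arr.shape[0] >= 2:
            rhat[name] = gelman_rubin(arr)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess[name] = float(sum(effective_sample_size(c) for c in chains))
    k_arr = np.asarray(k_vals)
    k_post = pd.Series(k_arr).value_counts(normalize=True).sort_index()
    return ShiftPosterior(
        branch_pp=pp,
        shifts=shifts,
        pp_threshold=pp_threshold,
        burn_in=burn_in,
        rhat=rhat,
        ess=ess,
        k_posterior=k_post,
        mean_k=float(k_arr.mean()),
        n_samples=n_s,
    )
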