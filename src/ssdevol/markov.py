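"""Continuous-time Markov (Mk) models of discrete regimes and stochastic
character mapping.

A discrete character (social system, diet, or the combined six-regime
coding) evolves along the tree under a rate matrix Q (transitions/Myr).
Three standard structures are supported: ER (one rate), SYM (symmetric
pairwise rates) and ARD (all rates different).  Rates are estimated by
maximum likelihood via Felsenstein pruning, and full character histories
("stochastic maps") are drawn conditionally on the tip states: node states
are sampled from their joint conditional distribution, then each branch
history is sampled by uniformization, which bounds the work per branch and
keeps runtime deterministic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .tree import PhyloTree, SimmapTree

__all__ = [
    "MkModel",
    "MkFit",
    "TransitionSummary",
    "build_q",
    "mk_loglik",
    "fit_mk",
    "sample_simmaps",
    "summarize_maps",
]

_RATE_LO, _RATE_HI = 1e-9, 1e4


@dataclass
class MkModel:
    """Mk rate model: alphabet, generator Q, root prior, structure."""

    alphabet: tuple
    Q: np.ndarray
    root_prior: np.ndarray = None
    structure: str = "ER"

    def __post_init__(self):
        k = len(self.alphabet)
        self.Q = np.asarray(self.Q, dtype=float)
        if self.Q.shape != (k, k):
            raise ValueError("Q shape does not match alphabet size")
        off = self.Q.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if np.max(np.abs(self.Q.sum(axis=1))) > 1e-10 * max(np.max(np.abs(self.Q)), 1.0):
            raise ValueError("Q rows must sum to 0")
        if self.root_prior is None:
            self.root_prior = np.full(k, 1.0 / k)
        self.root_prior = np.asarray(self.root_prior, dtype=float)
        if abs(self.root_prior.sum() - 1.0) > 1e-9:
            raise ValueError("root prior must sum to 1")

    @property
    def k(self) -> int:
        return len(self.alphabet)

    def state_index(self, s) -> int:
        return self.alphabet.index(s)


def build_q(structure: str, rates, k: int) -> np.ndarray:
    """Assemble a generator matrix from free rates.

    ER: 1 rate; SYM: k(k-1)/2 rates filling the upper triangle row-wise;
    ARD: k(k-1) rates filling off-diagonals row-wise.
    """
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    Q = np.zeros((k, k))
    if structure == "ER":
        if rates.size != 1:
            raise ValueError("ER takes exactly 1 rate")
        Q[:] = rates[0]
    elif structure == "SYM":
        if rates.size != k * (k - 1) // 2:
            raise ValueError(f"SYM takes {k*(k-1)//2} rates")
        iu = np.triu_indices(k, 1)
        Q[iu] = rates
        Q.T[iu] = rates
    elif structure == "ARD":
        if rates.size != k * (k - 1):
            raise ValueError(f"ARD takes {k*(k-1)} rates")
        idx = 0
        for i in range(k):
            for j in range(k):
                if i != j:
                    Q[i, j] = rates[idx]
                    idx += 1
    else:
        raise ValueError(f"unknown structure {structure!r}")
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def n_free_rates(structure: str, k: int) -> int:
    return {"ER": 1, "SYM": k * (k - 1) // 2, "ARD": k * (k - 1)}[structure]


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def _transition_matrices(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """P(t) = expm(Q t) for a batch of branch lengths (m, k, k).

    Symmetric generators (ER/SYM) are diagonalized once; general Q falls
    back to expm per unique length.
    """
    lengths = np.asarray(lengths, dtype=float)
    k = Q.shape[0]
    if np.allclose(Q, Q.T, atol=1e-12):
        w, U = np.linalg.eigh(Q)
        E = np.exp(np.outer(lengths, w))  # (m, k)
        P = np.einsum("ik,mk,jk->mij", U, E, U)
    else:
        uniq, inv = np.unique(lengths, return_inverse=True)
        Ps = np.stack([linalg.expm(Q * t) for t in uniq])
        P = Ps[inv]
    np.clip(P, 0.0, None, out=P)
    return P


def _tip_partial(model: MkModel, state) -> np.ndarray:
    """Indicator partial for an observed state or a set of candidate states."""
    v = np.zeros(model.k)
    states = state if isinstance(state, (set, frozenset, list, tuple)) else [state]
    for s in states:
        if s not in model.alphabet:
            raise ValueError(f"state {s!r} not in alphabet {list(model.alphabet)}")
        v[model.state_index(s)] = 1.0
    return v


def _pruning(tree: PhyloTree, tip_states: dict, model: MkModel):
    """Felsenstein pruning; returns (partials, log scale, P matrices).

    ``partials[v]`` is the conditional likelihood of the data below node v
    given each state at v (scaled); ``P[v]`` is the transition matrix on the
    branch above v.
    """
    P = _transition_matrices(model.Q, tree.lengths)
    L = np.zeros((tree.n_nodes, model.k))
    log_scale = 0.0
    for lab in tree.tip_labels:
        if lab not in tip_states:
            raise ValueError(f"tip {lab!r} has no assigned state")
    for v in tree.postorder:
        if v < tree.n_tips:
            L[v] = _tip_partial(model, tip_states[tree.tip_labels[v]])
        else:
            prod = np.ones(model.k)
            for c in tree.children[v]:
                prod *= P[c] @ L[c]
            s = prod.max()
            if s <= 0:
                return None  # impossible data under this Q
            log_scale += math.log(s)
            L[v] = prod / s
    return L, log_scale, P


def mk_loglik(tree: PhyloTree, tip_states: dict, model: MkModel) -> float:
    """Log-likelihood of tip states under the Mk model (pruning algorithm).

    ``tip_states`` maps tip label -> state (or a set of states for
    ambiguous tips).
    """
    out = _pruning(tree, tip_states, model)
    if out is None:
        return -math.inf
    L, log_scale, _ = out
    lik = float(model.root_prior @ L[tree.root])
    if lik <= 0:
        return -math.inf
    return math.log(lik) + log_scale


@dataclass
class MkFit:
    """ML-fitted Mk model with optimization diagnostics."""

    model: MkModel
    loglik: float
    rates: np.ndarray
    converged: bool
    n_iter: int = 0
    at_bound: bool = False

    def summary(self) -> str:
        k = self.model.k
        lines = [
            f"Mk model ({self.model.structure}, {k} states), lnL = {self.loglik:.4f}",
            f"  rates: {np.array2string(self.rates, precision=5)}"
            + ("  [at optimization bound]" if self.at_bound else ""),
        ]
        return "\n".join(lines)


def fit_mk(tree: PhyloTree, tip_states: dict, structure: str = "ER",
           alphabet=None, root_prior=None) -> MkFit:
    """Maximum-likelihood Mk rates for the observed tip states.

    Rates are optimized on the log scale (bounded L-BFGS-B, multi-start).
    A character with no observed variation drives the rate to the lower
    optimization bound, which is reported via ``at_bound``.
    """
    if alphabet is None:
        observed = set()
        for s in tip_states.values():
            observed.update(s if isinstance(s, (set, frozenset, list, tuple)) else [s])
        alphabet = tuple(sorted(observed))
    k = len(alphabet)
    if k < 1:
        raise ValueError("no observed states")
    nr = n_free_rates(structure, k)

    def negll(logr):
        Q = build_q(structure, np.exp(logr), k)
        m = MkModel(alphabet, Q, root_prior=root_prior, structure=structure)
        return -mk_loglik(tree, tip_states, m)

    total_len = float(tree.lengths.sum())
    q0 = max(k / max(total_len, 1e-12), _RATE_LO * 10)
    best = None
    bounds = [(math.log(_RATE_LO), math.log(_RATE_HI))] * nr
    for mult in (0.1, 1.0, 10.0):
        x0 = np.full(nr, math.log(min(max(q0 * mult, _RATE_LO), _RATE_HI)))
        res = optimize.minimize(negll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun):
        raise RuntimeError(
            f"Mk optimization failed to find a finite likelihood "
            f"(best point {np.exp(best.x)}, gradient norm "
            f"{np.linalg.norm(getattr(best, 'jac', np.nan)):.3g})"
        )
    rates = np.exp(best.x)
    # a rate this small implies << 1 expected event on the whole tree:
    # effectively the lower boundary (flat likelihood region)
    at_bound = bool(np.any(rates <= max(10 * _RATE_LO, 1e-3 / max(total_len, 1.0))))
    Q = build_q(structure, rates, k)
    model = MkModel(alphabet, Q, root_prior=root_prior, structure=structure)
    return MkFit(model=model, loglik=-best.fun, rates=rates,
                 converged=bool(best.success or at_bound),
                 n_iter=int(best.nit), at_bound=at_bound)


# ---------------------------------------------------------------------------
# Stochastic mapping
# ---------------------------------------------------------------------------


class _Uniformizer:
    """Cached uniformization machinery for one generator Q."""

    def __init__(self, Q: np.ndarray):
        self.Q = Q
        self.mu = float(max(np.max(-np.diag(Q)), 0.0)) * 1.05
        k = Q.shape[0]
        if self.mu > 0:
            self.R = np.eye(k) + Q / self.mu
        else:
            self.R = np.eye(k)
        self._pows = [np.eye(k), self.R.copy()]

    def rpow(self, n: int) -> np.ndarray:
        while len(self._pows) <= n:
            self._pows.append(self._pows[-1] @ self.R)
        return self._pows[n]

    def sample_n_jumps(self, a: int, b: int, t: float, p_ab: float, rng,
                       max_n: int = 10000) -> int:
        """Number of uniformized jumps given endpoints, by inverse CDF."""
        mt = self.mu * t
        if mt == 0.0:
            if a != b:
                raise RuntimeError("impossible endpoints on a zero-rate branch")
            return 0
        u = rng.uniform() * p_ab
        log_pois = -mt
        acc = 0.0
        n = 0
        while n <= max_n:
            w = math.exp(log_pois) * self.rpow(n)[a, b]
            acc += w
            if acc >= u:
                return n
            n += 1
            log_pois += math.log(mt) - math.log(n)
        # numerical slack: p_ab can exceed the partial sum by a hair
        return n - 1

    def sample_path(self, a: int, b: int, t: float, p_ab: float, rng):
        """Jump chain and times of a CTMC bridge from a to b over [0, t]."""
        if t == 0.0:
            return [a], []
        n = self.sample_n_jumps(a, b, t, p_ab, rng)
        states = [a]
        s = a
        for kk in range(1, n + 1):
            w = self.R[s] * self.rpow(n - kk)[:, b]
            tot = w.sum()
            if tot <= 0:
                raise RuntimeError("zero-probability jump-chain step")
            s = int(rng.choice(len(w), p=w / tot))
            states.append(s)
        times = np.sort(rng.uniform(0.0, t, size=n))
        return states, list(times)


def _sample_node_states(tree, L, P, model, rng, n_draws):
    """Joint draws of all node states given tips (root-to-tip sampling)."""
    k = model.k
    out = np.zeros((n_draws, tree.n_nodes), dtype=int)
    pr_root = model.root_prior * L[tree.root]
    pr_root = pr_root / pr_root.sum()
    out[:, tree.root] = rng.choice(k, size=n_draws, p=pr_root)
    for v in tree.preorder[1:]:
        pa = out[:, tree.parent[v]]
        w = P[v][pa, :] * L[v][None, :]  # (n_draws, k)
        tot = w.sum(axis=1, keepdims=True)
        if np.any(tot <= 0):
            raise RuntimeError("zero-probability node state")
        cum = np.cumsum(w / tot, axis=1)
        u = rng.uniform(size=(n_draws, 1))
        out[:, v] = (u > cum).sum(axis=1)
    return out


def sample_simmaps(tree: PhyloTree, model: MkModel, tip_states: dict,
                   n_maps: int, seed=None, rng=None) -> list[SimmapTree]:
    """Draw stochastic character maps conditionally on the tip states.

    Node states are sampled from their joint conditional distribution given
    the tips and Q; each branch history is then sampled by uniformization
    conditioned on its endpoint states.  Reproducible given ``seed`` (or an
    explicit numpy Generator).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    out = _pruning(tree, tip_states, model)
    if out is None:
        raise ValueError("tip states have zero likelihood under this model")
    L, _, P = out
    uni = _Uniformizer(model.Q)
    node_states = _sample_node_states(tree, L, P, model, rng, n_maps)
    maps = []
    alpha = model.alphabet
    for m in range(n_maps):
        ns = node_states[m]
        segments: list = [None] * tree.n_nodes
        segments[tree.root] = [(alpha[ns[tree.root]], 0.0)]
        for v in tree.preorder[1:]:
            a, b = int(ns[tree.parent[v]]), int(ns[v])
            t = float(tree.lengths[v])
            if t == 0.0:
                segments[v] = [(alpha[b], 0.0)]
                continue
            p_ab = float(P[v][a, b])
            states, times = uni.sample_path(a, b, t, p_ab, rng)
            # merge virtual (self) jumps into piecewise-constant segments
            segs = []
            cur, t0 = states[0], 0.0
            for s, tt in zip(states[1:], times):
                if s != cur:
                    segs.append((alpha[cur], tt - t0))
                    cur, t0 = s, tt
            segs.append((alpha[cur], t - t0))
            if cur != b:  # uniformization guarantees this; guard anyway
                raise RuntimeError("branch endpoint mismatch in sampled path")
            segments[v] = segs
        maps.append(SimmapTree(tree, segments, alphabet=alpha))
    return maps


# ---------------------------------------------------------------------------
# Map summaries
# ---------------------------------------------------------------------------


@dataclass
class TransitionSummary:
    """Ancestral-state frequencies and mean transition counts across maps."""

    node_frequencies: pd.DataFrame  # index: node id, columns: states
    mean_counts: pd.DataFrame  # index: from state, columns: to state
    n_maps: int

    def summary(self) -> str:
        lines = [f"Summary of {self.n_maps} stochastic maps"]
        lines.append("mean transition counts (from -> to):")
        lines.append(self.mean_counts.round(3).to_string())
        return "\n".join(lines)

    def node_frequencies_tsv(self, path):
        long = (
            self.node_frequencies.rename_axis("node_id")
            .reset_index()
            .melt(id_vars="node_id", var_name="state", value_name="frequency")
            .sort_values(["node_id", "state"], kind="stable")
        )
        long.to_csv(path, sep="\t", index=False)

    def counts_tsv(self, path):
        long = (
            self.mean_counts.rename_axis("from_state")
            .reset_index()
            .melt(id_vars="from_state", var_name="to_state", value_name="mean_count")
            .sort_values(["from_state", "to_state"], kind="stable")
        )
        long = long[long["from_state"] != long["to_state"]]
        long.to_csv(path, sep="\t", index=False)


def summarize_maps(maps: list[SimmapTree]) -> TransitionSummary:
    """Per-node state frequencies and mean per-pair transition counts.

    All maps must share the same tree and regime alphabet.
    """
    if not maps:
        raise ValueError("need at least one map")
    t0 = maps[0].tree
    alpha = maps[0].alphabet
    for m in maps[1:]:
        if (
            m.tree.n_nodes != t0.n_nodes
            or m.tree.tip_labels != t0.tip_labels
            or not np.array_equal(m.tree.parent, t0.parent)
        ):
            raise ValueError("maps are over different trees")
        if m.alphabet != alpha:
            raise ValueError("maps use different regime alphabets")
    k = len(alpha)
    sidx = {s: i for i, s in enumerate(alpha)}
    freq = np.zeros((t0.n_nodes, k))
    counts = np.zeros((k, k))
    for m in maps:
        for v, s in enumerate(m.node_states()):
            freq[v, sidx[s]] += 1
        for (a, b), c in m.transition_counts().items():
            counts[sidx[a], sidx[b]] += c
    freq /= len(maps)
    counts /= len(maps)
    return TransitionSummary(
        node_frequencies=pd.DataFrame(freq, columns=list(alpha)),
        mean_counts=pd.DataFrame(counts, index=list(alpha), columns=list(alpha)),
        n_maps=len(maps),
    )
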