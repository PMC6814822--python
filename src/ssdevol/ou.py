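"""Brownian and Ornstein-Uhlenbeck models of SDI evolution on mapped trees.

Three model classes are fitted to the size dimorphism index (in percent):

``BM1``
    single-rate Brownian motion (free parameters: root mean, sigma^2);

``OU1``
    single-optimum Ornstein-Uhlenbeck (alpha, sigma^2, theta);

``OUM``
    multi-optima OU with one optimum per mapped regime and a single shared
    alpha and sigma^2 (parameters: alpha, sigma^2, Theta_1..Theta_k).

The OU covariance uses the non-stationary-root form
``V[i,j] = sigma^2/(2 alpha) * exp(-alpha d_ij) * (1 - exp(-2 alpha t_ij))``
(``d_ij`` patristic distance, ``t_ij`` shared time), and the expectation at a
tip is a weighted mix of regime optima with weights given by exponentially
discounted occupancy of each regime along the root-to-tip history (Hansen's
model).  The root term ``exp(-alpha T)`` is merged into the ancestral-most
(root) regime's optimum; a stationary-root variant is not provided.

Given alpha, both Theta (by GLS) and sigma^2 (by its ML closed form) profile
out analytically, so fitting reduces to a one-dimensional search over
log(alpha) on a deterministic grid followed by bounded refinement.

Model comparison across stochastic-map replicates uses small-sample AICc;
per-map Akaike weights are averaged across maps (not recomputed from mean
AICc values).
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
    "OUModel",
    "OUFitResult",
    "ModelComparison",
    "BootstrapCI",
    "ou_weight_matrix",
    "ou_vcv",
    "aicc",
    "aicc_weights",
    "half_life",
    "compare_models",
    "parametric_bootstrap",
    "bm_ancestral_states",
]

_ALPHA_LO = 1e-10  # 1/Myr; keeps the OU covariance well-conditioned
_LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# Expectation and covariance machinery
# ---------------------------------------------------------------------------


def _tip_path_segments(smap: SimmapTree):
    """Flattened root-to-tip regime segments of every tip.

    Returns ``(tip_idx, reg_idx, t1, t2, regimes)`` where segment ``s`` of
    tip ``tip_idx[s]`` occupies regime ``regimes[reg_idx[s]]`` over absolute
    times ``[t1[s], t2[s]]`` measured from the root.  Cached on the map.
    """
    cached = getattr(smap, "_tip_path_cache", None)
    if cached is not None:
        return cached
    t = smap.tree
    regimes = tuple(smap.alphabet)
    ridx = {r: i for i, r in enumerate(regimes)}
    tip_idx, reg_idx, t1s, t2s = [], [], [], []
    for tip in range(t.n_tips):
        chain = []
        v = tip
        while v != t.root:
            chain.append(v)
            v = t.parent[v]
        chain.reverse()
        t0 = 0.0
        for v in chain:
            for s, d in smap.segments[v]:
                tip_idx.append(tip)
                reg_idx.append(ridx[s])
                t1s.append(t0)
                t2s.append(t0 + d)
                t0 += d
    cached = (
        np.array(tip_idx, dtype=int),
        np.array(reg_idx, dtype=int),
        np.array(t1s),
        np.array(t2s),
        regimes,
    )
    smap._tip_path_cache = cached
    return cached


def ou_weight_matrix(smap: SimmapTree, alpha: float, check_ultrametric: bool = True):
    """Regime weight matrix of tip expectations under a multi-optima OU model.

    Row i gives the weights with which each regime's optimum enters tip i's
    expected value: ``sum over segments [t1, t2] in regime r of
    exp(-alpha (T - t2)) - exp(-alpha (T - t1))``, with the root weight
    ``exp(-alpha T)`` allocated to the root regime.  Rows sum to 1 exactly
    (the sum telescopes).

    Returns ``(W, regimes)`` with ``W`` of shape (n_tips, n_regimes).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    t = smap.tree
    if check_ultrametric and not t.is_ultrametric(1e-6):
        raise ValueError("OU regime weights require an ultrametric tree")
    tip_idx, reg_idx, t1, t2, regimes = _tip_path_segments(smap)
    n, k = t.n_tips, len(regimes)
    T = t.depths[:n]
    W = np.zeros((n, k))
    if alpha < 1e-14:
        contrib = np.zeros(len(tip_idx))
    else:
        Ti = T[tip_idx]
        contrib = np.exp(-alpha * (Ti - t2)) - np.exp(-alpha * (Ti - t1))
    np.add.at(W, (tip_idx, reg_idx), contrib)
    root_reg = regimes.index(smap.root_state)
    W[:, root_reg] += np.exp(-alpha * T)
    return W, regimes


def _vcv_parts(tree: PhyloTree):
    cached = getattr(tree, "_vcv_parts_cache", None)
    if cached is None:
        C = tree.vcv()
        d = np.diag(C)
        D = d[:, None] + d[None, :] - 2.0 * C
        cached = (C, D)
        tree._vcv_parts_cache = cached
    return cached


def ou_vcv(tree: PhyloTree, alpha: float, sigma2: float) -> np.ndarray:
    """OU trait covariance among tips (non-stationary root).

    ``V[i,j] = sigma^2/(2 alpha) exp(-alpha d_ij)(1 - exp(-2 alpha t_ij))``;
    the ``alpha -> 0`` limit is handled analytically as ``sigma^2 * C``.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    C, D = _vcv_parts(tree)
    if alpha < 1e-12:
        return sigma2 * C
    return (sigma2 / (2.0 * alpha)) * np.exp(-alpha * D) * (-np.expm1(-2.0 * alpha * C))


# ---------------------------------------------------------------------------
# Information criteria
# ---------------------------------------------------------------------------


def aicc(lnL: float, p: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n <= p + 1:
        raise ValueError(f"AICc undefined for n={n} <= p+1={p + 1}")
    return -2.0 * lnL + 2.0 * p + 2.0 * p * (p + 1) / (n - p - 1)


def aicc_weights(values) -> np.ndarray:
    """Akaike weights from a vector of AICc values."""
    v = np.asarray(values, dtype=float)
    delta = v - v.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


def half_life(alpha: float) -> float:
    """Phylogenetic half-life ln(2)/alpha in Myr (+inf for alpha = 0, BM-like)."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if alpha == 0:
        return math.inf
    return _LN2 / alpha


# ---------------------------------------------------------------------------
# Model / results objects
# ---------------------------------------------------------------------------


@dataclass
class OUFitResult:
    """ML fit of one evolutionary model on one (mapped) tree."""

    model_id: str
    alpha: float
    sigma2: float
    theta: np.ndarray  # regime optima (OUM), single optimum (OU1), root mean (BM1)
    regimes: tuple
    loglik: float
    p: int
    n: int
    aicc: float
    converged: bool = True
    _model: "OUModel" = field(default=None, repr=False)

    @property
    def half_life(self) -> float:
        if self.model_id == "BM1":
            return math.inf
        return half_life(self.alpha)

    def theta_dict(self) -> dict:
        return {r: float(th) for r, th in zip(self.regimes, self.theta)}

    def expected_means(self) -> np.ndarray:
        W, _ = self._model._design(self.alpha)
        return W @ self.theta

    def covariance(self) -> np.ndarray:
        return self._model._cov(self.alpha, self.sigma2)

    def simulate(self, rng) -> np.ndarray:
        """One draw of tip values from the fitted Gaussian (W theta, V)."""
        V = self.covariance()
        Lc = np.linalg.cholesky(V + 1e-12 * np.mean(np.diag(V)) * np.eye(len(V)))
        return self.expected_means() + Lc @ rng.standard_normal(self.n)

    def summary(self) -> str:
        hl = self.half_life
        hl_s = "inf (BM-like)" if math.isinf(hl) else f"{hl:.3f} Myr"
        lines = [
            f"{self.model_id} fit: lnL = {self.loglik:.4f}, AICc = {self.aicc:.4f} "
            f"(p = {self.p}, n = {self.n})",
            f"  alpha   = {self.alpha:.6g} /Myr   (half-life {hl_s})",
            f"  sigma^2 = {self.sigma2:.6g} %^2/Myr",
        ]
        label = "root mean" if self.model_id == "BM1" else "theta"
        for r, th in zip(self.regimes, self.theta):
            lines.append(f"  {label}[{r}] = {th:.4f} %")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model": self.model_id,
            "alpha_per_myr": self.alpha,
            "sigma2": self.sigma2,
            "theta_percent": self.theta_dict(),
            "loglik": self.loglik,
            "p": self.p,
            "n": self.n,
            "aicc": self.aicc,
            "half_life_myr": self.half_life,
        }


class OUModel:
    """Evolutionary model of a continuous trait on a (mapped) tree.

    Parameters
    ----------
    sdi : array
        Trait values (SDI in percent) aligned with ``tree.tip_labels``.
    model : {"BM1", "OU1", "OUM"}
    smap : SimmapTree, required for OUM
    tree : PhyloTree, required for BM1/OU1 when no map is given
    """

    def __init__(self, sdi, model: str = "OUM", smap: SimmapTree = None,
                 tree: PhyloTree = None):
        if model not in ("BM1", "OU1", "OUM"):
            raise ValueError(f"unknown model {model!r}")
        if model == "OUM":
            if smap is None:
                raise ValueError("OUM requires a stochastic map")
            tree = smap.tree
        if tree is None:
            if smap is None:
                raise ValueError("need a tree or a mapped tree")
            tree = smap.tree
        self.model_id = model
        self.smap = smap
        self.tree = tree
        self.y = np.asarray(sdi, dtype=float)
        if len(self.y) != tree.n_tips:
            raise ValueError(
                f"{len(self.y)} trait values for {tree.n_tips} tips"
            )
        self.n = tree.n_tips
        if model == "OUM":
            self.k = len(smap.alphabet)
            self.regimes = tuple(smap.alphabet)
            self.p = 2 + self.k
        elif model == "OU1":
            self.k = 1
            self.regimes = ("theta",)
            self.p = 3
        else:
            self.k = 1
            self.regimes = ("root",)
            self.p = 2

    # -- building blocks -----------------------------------------------------

    def _design(self, alpha: float):
        if self.model_id == "OUM":
            return ou_weight_matrix(self.smap, alpha)
        return np.ones((self.n, 1)), self.regimes

    def _cov(self, alpha: float, sigma2: float) -> np.ndarray:
        if self.model_id == "BM1":
            C, _ = _vcv_parts(self.tree)
            return sigma2 * C
        return ou_vcv(self.tree, alpha, sigma2)

    def profile_loglik(self, alpha: float):
        """(lnL, theta_hat, sigma2_hat) with theta and sigma^2 profiled out."""
        V0 = self._cov(alpha, 1.0)
        W, _ = self._design(alpha)
        try:
            cho = linalg.cho_factor(V0, lower=True)
        except linalg.LinAlgError:
            jitter = 1e-10 * float(np.mean(np.diag(V0)))
            warnings.warn(f"ill-conditioned covariance at alpha={alpha:g}; "
                          f"adding diagonal jitter {jitter:g}")
            cho = linalg.cho_factor(V0 + jitter * np.eye(self.n), lower=True)
        ViW = linalg.cho_solve(cho, W)
        Viy = linalg.cho_solve(cho, self.y)
        G = W.T @ ViW
        try:
            theta = np.linalg.solve(G, W.T @ Viy)
        except np.linalg.LinAlgError:
            theta = np.linalg.lstsq(G, W.T @ Viy, rcond=None)[0]
        r = self.y - W @ theta
        q = float(r @ linalg.cho_solve(cho, r))
        if q <= 0:
            return -math.inf, theta, 0.0
        sigma2 = q / self.n
        logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
        lnL = -0.5 * (
            self.n * (math.log(2 * math.pi) + 1)
            + self.n * math.log(sigma2)
            + logdet
        )
        return lnL, theta, sigma2

    def loglik(self, alpha: float, sigma2: float, theta) -> float:
        """Exact multivariate-normal log-likelihood at given parameters."""
        V = self._cov(alpha, sigma2)
        W, _ = self._design(alpha)
        r = self.y - W @ np.atleast_1d(theta)
        cho = linalg.cho_factor(V, lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
        q = float(r @ linalg.cho_solve(cho, r))
        return -0.5 * (self.n * math.log(2 * math.pi) + logdet + q)

    # -- fitting ---------------------------------------------------------------

    def _alpha_bounds(self):
        depth = self.tree.depth
        return _LN2 / (20.0 * depth), _LN2 / (depth / 500.0)

    def fit(self, alpha_init: float = None, n_grid: int = 24) -> OUFitResult:
        """Maximum-likelihood fit.

        For OU models, alpha is profiled on a log-spaced grid spanning
        half-lives from 20x tree depth down to depth/500, then refined by
        bounded scalar search between the best grid point's neighbours.
        ``alpha_init`` narrows the search to a bracket around a known
        starting point (used by bootstrap refits).
        """
        if self.n <= self.p + 1:
            raise ValueError(
                f"n = {self.n} tips too few for {self.model_id} "
                f"(AICc needs n > {self.p + 1})"
            )
        if self.model_id == "BM1":
            lnL, theta, sigma2 = self.profile_loglik(0.0)
            return self._result(0.0, sigma2, theta, lnL)

        lo, hi = self._alpha_bounds()
        if alpha_init is not None:
            lo = max(lo, alpha_init / 16.0)
            hi = min(hi, alpha_init * 16.0)
            if lo >= hi:
                lo, hi = self._alpha_bounds()
            n_grid = max(7, n_grid // 3)
        grid = np.geomspace(lo, hi, n_grid)
        vals = [self.profile_loglik(a)[0] for a in grid]
        i = int(np.argmax(vals))
        blo = grid[max(i - 1, 0)]
        bhi = grid[min(i + 1, n_grid - 1)]
        if blo == bhi:
            best_alpha = grid[i]
        else:
            res = optimize.minimize_scalar(
                lambda la: -self.profile_loglik(math.exp(la))[0],
                bounds=(math.log(blo), math.log(bhi)),
                method="bounded",
                options={"xatol": 1e-4},
            )
            best_alpha = math.exp(res.x)
            if -res.fun < vals[i]:
                best_alpha = grid[i]
        lnL, theta, sigma2 = self.profile_loglik(best_alpha)
        if not np.isfinite(lnL):
            raise RuntimeError(
                f"{self.model_id} optimization failed: non-finite likelihood "
                f"at alpha={best_alpha:g}"
            )
        return self._result(max(best_alpha, _ALPHA_LO), sigma2, theta, lnL)

    def _result(self, alpha, sigma2, theta, lnL) -> OUFitResult:
        return OUFitResult(
            model_id=self.model_id,
            alpha=float(alpha),
            sigma2=float(sigma2),
            theta=np.atleast_1d(theta).astype(float),
            regimes=self.regimes,
            loglik=float(lnL),
            p=self.p,
            n=self.n,
            aicc=aicc(lnL, self.p, self.n),
            _model=self,
        )


# ---------------------------------------------------------------------------
# Model comparison across stochastic maps
# ---------------------------------------------------------------------------


@dataclass
class ModelComparison:
    """AICc comparison of candidate models averaged over stochastic maps."""

    models: list
    per_map_aicc: pd.DataFrame  # rows: maps, cols: models
    per_map_weights: pd.DataFrame
    mean_aicc: pd.Series
    delta_aicc: pd.Series
    mean_weights: pd.Series
    best_model: str
    n_maps: int
    n_dropped: int = 0
    fits: dict = field(default_factory=dict, repr=False)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.models,
                "mean_AICc": [self.mean_aicc[m] for m in self.models],
                "dAICc": [self.delta_aicc[m] for m in self.models],
                "mean_AICcW": [self.mean_weights[m] for m in self.models],
            }
        )

    def summary(self) -> str:
        lines = [f"Model comparison over {self.n_maps} stochastic maps"
                 + (f" ({self.n_dropped} dropped)" if self.n_dropped else "")]
        lines.append(self.table().round(4).to_string(index=False))
        lines.append(f"best model: {self.best_model} "
                     f"(mean AICcW = {self.mean_weights[self.best_model]:.3f})")
        return "\n".join(lines)

    def to_tsv(self, path):
        self.table().to_csv(path, sep="\t", index=False)


def compare_models(maps_by_model: dict, sdi, tree: PhyloTree = None) -> ModelComparison:
    """Fit {BM1, OU1} plus one OUM per regime mapping and compare by AICc.

    ``maps_by_model`` maps an OUM model label (e.g. ``"OUM_social"``) to a
    list of :class:`SimmapTree` replicates; all lists must have equal length
    and share one tree.  BM1 and OU1 are map-independent and fitted once.
    Per-map AICc weights are computed across the five models and then
    averaged over maps; a map is dropped (with a warning) if any of its fits
    fails, and more than 10% dropped maps is an error.
    """
    if not maps_by_model:
        raise ValueError("need at least one OUM regime mapping")
    oum_ids = list(maps_by_model.keys())
    lengths = {len(v) for v in maps_by_model.values()}
    if len(lengths) != 1:
        raise ValueError("all map sets must have the same number of replicates")
    n_maps = lengths.pop()
    if n_maps < 1:
        raise ValueError("empty map sets")
    if tree is None:
        tree = maps_by_model[oum_ids[0]][0].tree
    y = np.asarray(sdi, dtype=float)

    fits = {}
    base = {}
    for mid in ("BM1", "OU1"):
        fit = OUModel(y, model=mid, tree=tree).fit()
        fits[mid] = fit
        base[mid] = fit.aicc

    models = ["BM1", "OU1"] + oum_ids
    rows = []
    kept_idx = []
    for j in range(n_maps):
        row = dict(base)
        ok = True
        for mid in oum_ids:
            try:
                f = OUModel(y, model="OUM", smap=maps_by_model[mid][j]).fit()
                row[mid] = f.aicc
                if j == 0:
                    fits[mid] = f
            except (RuntimeError, ValueError, np.linalg.LinAlgError) as exc:
                warnings.warn(f"map {j} dropped: {mid} fit failed ({exc})")
                ok = False
                break
        if ok:
            rows.append([row[m] for m in models])
            kept_idx.append(j)
    n_dropped = n_maps - len(rows)
    if n_dropped > 0.10 * n_maps:
        raise RuntimeError(
            f"{n_dropped}/{n_maps} maps failed to fit; data or maps look pathological"
        )
    A = pd.DataFrame(rows, columns=models, index=kept_idx)
    Wts = A.apply(lambda r: pd.Series(aicc_weights(r.values), index=models), axis=1)
    mean_aicc = A.mean(axis=0)
    delta = mean_aicc - mean_aicc.min()
    mean_w = Wts.mean(axis=0)
    best = str(mean_w.idxmax())
    return ModelComparison(
        models=models,
        per_map_aicc=A,
        per_map_weights=Wts,
        mean_aicc=mean_aicc,
        delta_aicc=delta,
        mean_weights=mean_w,
        best_model=best,
        n_maps=len(rows),
        n_dropped=n_dropped,
        fits=fits,
    )


# ---------------------------------------------------------------------------
# Parametric bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapCI:
    """Percentile bootstrap intervals for the parameters of an OU fit."""

    params: pd.DataFrame  # index: parameter, columns: point, lower, upper
    n_reps: int
    n_failed: int
    seed: int = None
    draws: pd.DataFrame = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [f"Parametric bootstrap ({self.n_reps} replicates kept, "
                 f"{self.n_failed} failed)"]
        lines.append(self.params.round(4).to_string())
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "n_failed": self.n_failed,
            "seed": self.seed,
            "params": {
                name: {
                    "point": float(row["point"]),
                    "lower_2.5": float(row["lower"]),
                    "upper_97.5": float(row["upper"]),
                }
                for name, row in self.params.iterrows()
            },
        }


def parametric_bootstrap(fit: OUFitResult, n_reps: int = 1000, seed=None,
                         keep_draws: bool = False) -> BootstrapCI:
    """Percentile CIs by simulating from the fitted Gaussian and refitting.

    Each replicate draws a trait vector from N(W theta, sigma^2 V0), refits
    the same model on the same map, and records (theta, alpha, sigma^2).
    Replicates whose refit fails are dropped; more than 20% failures is an
    error.  Reproducible given ``seed``.
    """
    model = fit._model
    if model is None:
        raise ValueError("fit does not carry its model; refit before bootstrapping")
    rng = np.random.default_rng(seed)
    mu = fit.expected_means()
    V = fit.covariance()
    Lc = np.linalg.cholesky(V + 1e-12 * float(np.mean(np.diag(V))) * np.eye(fit.n))
    names = [f"theta_{r}" for r in fit.regimes] + ["alpha", "sigma2"]
    draws = []
    failed = 0
    for _ in range(n_reps):
        y_star = mu + Lc @ rng.standard_normal(fit.n)
        m = OUModel(y_star, model=fit.model_id, smap=model.smap, tree=model.tree)
        try:
            f = m.fit(alpha_init=fit.alpha if fit.model_id != "BM1" else None)
            draws.append(list(f.theta) + [f.alpha, f.sigma2])
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            failed += 1
    if failed > 0.20 * n_reps:
        raise RuntimeError(f"{failed}/{n_reps} bootstrap replicates failed")
    D = pd.DataFrame(draws, columns=names)
    point = list(fit.theta) + [fit.alpha, fit.sigma2]
    lo = D.quantile(0.025)
    hi = D.quantile(0.975)
    params = pd.DataFrame(
        {"point": point, "lower": [lo[c] for c in names], "upper": [hi[c] for c in names]},
        index=names,
    )
    return BootstrapCI(params=params, n_reps=len(D), n_failed=failed, seed=seed,
                       draws=D if keep_draws else None)


# ---------------------------------------------------------------------------
# Brownian ancestral states
# ---------------------------------------------------------------------------


def bm_ancestral_states(tree: PhyloTree, trait) -> pd.DataFrame:
    """Joint maximum-likelihood Brownian ancestral states with standard errors.

    Solves the harmonic system in which each internal value is the
    inverse-branch-length weighted mean of its neighbours; the root estimate
    equals the GLS phylogenetic mean.  Standard errors come from the inverse
    curvature scaled by the ML Brownian rate estimated from the tips.
    Returns a DataFrame indexed by internal node id with columns
    ``estimate`` and ``se``.
    """
    y = np.asarray(trait, dtype=float)
    n, m = tree.n_tips, tree.n_nodes - tree.n_tips
    if len(y) != n:
        raise ValueError("trait length does not match tip count")
    internal = list(range(n, tree.n_nodes))
    iidx = {v: i for i, v in enumerate(internal)}
    L_II = np.zeros((m, m))
    b = np.zeros(m)
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        p = tree.parent[v]
        w = 1.0 / max(tree.lengths[v], 1e-12)
        pi = iidx[p]
        L_II[pi, pi] += w
        if v < n:
            b[pi] += w * y[v]
        else:
            vi = iidx[v]
            L_II[vi, vi] += w
            L_II[pi, vi] -= w
            L_II[vi, pi] -= w
    cho = linalg.cho_factor(L_II, lower=True)
    est = linalg.cho_solve(cho, b)
    # ML Brownian rate from tips (GLS mean profiled out)
    C = tree.vcv()
    choC = linalg.cho_factor(C, lower=True)
    one = np.ones(n)
    Ci1 = linalg.cho_solve(choC, one)
    mu = float(y @ Ci1 / (one @ Ci1))
    r = y - mu
    sigma2 = float(r @ linalg.cho_solve(choC, r)) / n
    cov = linalg.cho_solve(cho, np.eye(m))
    se = np.sqrt(sigma2 * np.diag(cov))
    return pd.DataFrame({"estimate": est, "se": se}, index=internal)
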