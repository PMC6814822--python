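"""Phylogenetic reduced major axis (RMA) regression and the Rensch's-rule test.

Rensch's rule states that male-biased sexual size dimorphism increases with
body size (hyperallometry).  The standard test regresses ln male mass (y) on
ln female mass (x) by reduced major axis — a line-fitting procedure
symmetric in x and y with slope ``b = sign(s_xy) * sqrt(s_yy / s_xx)`` — and
asks whether the slope differs from 1.  Slopes above 1 indicate a positive
Rensch trend, below 1 a negative trend.

Phylogenetic non-independence is handled by estimating the evolutionary
(co)variances under a bivariate Brownian model whose residual correlation
structure is the lambda-transformed tree covariance; Pagel's lambda is
estimated simultaneously by maximum likelihood.  The slope test follows
Clarke (1980): the statistic is computed on the log-slope scale and referred
to a t distribution with effective degrees of freedom
``df = 2 + (n - 2) / (1 + r^2 / 2)`` (generally non-integer).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .tree import PhyloTree, lambda_transform, prune_to_taxa

__all__ = ["PhyloRMA", "RMAResult", "classify_rensch", "rma_by_clade"]


@dataclass
class RMAResult:
    """Fitted phylogenetic RMA regression with the slope-vs-b0 test.

    All quantities are on the natural-log mass scale.  ``df`` is the Clarke
    effective degrees of freedom and is generally non-integer.
    """

    slope: float
    se: float
    intercept: float
    lam: float
    r2: float
    n: int
    clade: str = "all"
    loglik: float = float("nan")
    b0: float = 1.0
    T: float = field(default=float("nan"))
    df: float = field(default=float("nan"))
    pvalue: float = field(default=float("nan"))
    means: tuple = (float("nan"), float("nan"))
    evo_cov: tuple = (float("nan"), float("nan"), float("nan"))  # s_xx, s_yy, s_xy

    def test_slope(self, b0: float = 1.0):
        """Two-sided test of the RMA slope against ``b0`` (log-slope scale).

        Returns ``(T, df, P)`` and stores them on the result.  ``T = 0`` and
        ``P = 1`` when the estimated slope equals ``b0`` exactly.
        """
        if b0 > 0 and self.slope <= 0:
            raise ValueError(
                f"log-scale slope test undefined for slope {self.slope} <= 0 with b0 > 0"
            )
        self.b0 = b0
        se_log = math.sqrt(max(1.0 - self.r2, 0.0) / (self.n - 2))
        if se_log == 0.0:
            self.T = 0.0 if math.isclose(self.slope, b0) else math.inf
        else:
            self.T = abs(math.log(abs(self.slope)) - math.log(abs(b0))) / se_log
        self.df = 2.0 + (self.n - 2) / (1.0 + self.r2 / 2.0)
        self.pvalue = 2.0 * stats.t.sf(self.T, self.df)
        return self.T, self.df, self.pvalue

    @property
    def rensch(self) -> str:
        """Rensch's-rule call at alpha = 0.05: 'positive', 'negative', or 'none'."""
        return classify_rensch(self)

    def summary(self) -> str:
        if math.isnan(self.T):
            self.test_slope(self.b0)
        lines = [
            f"Phylogenetic RMA regression — clade: {self.clade} (n = {self.n})",
            f"  slope     {self.slope:8.4f} ± {self.se:.4f}   (H0: slope = {self.b0:g})",
            f"  intercept {self.intercept:8.4f}",
            f"  lambda    {self.lam:8.4f}",
            f"  R^2       {self.r2:8.4f}",
            f"  T = {self.T:.3f},  df = {self.df:.2f},  P = {self.pvalue:.4g}",
            f"  Rensch's rule: {self.rensch}",
        ]
        return "\n".join(lines)

    def to_row(self) -> dict:
        if math.isnan(self.T):
            self.test_slope(self.b0)
        return {
            "clade": self.clade,
            "n": self.n,
            "slope": self.slope,
            "se": self.se,
            "lambda": self.lam,
            "r2": self.r2,
            "T": self.T,
            "df": self.df,
            "P": self.pvalue,
            "rensch_call": self.rensch,
        }


def classify_rensch(result: RMAResult, alpha: float = 0.05) -> str:
    """Classify a fitted slope as a positive/negative/absent Rensch trend."""
    if math.isnan(result.T):
        result.test_slope(result.b0)
    if result.pvalue < alpha and result.slope > result.b0:
        return "positive"
    if result.pvalue < alpha and result.slope < result.b0:
        return "negative"
    return "none"


class PhyloRMA:
    """Phylogenetic RMA regression model of y on x under lambda-transformed
    Brownian covariance.

    Parameters
    ----------
    tree : PhyloTree
        Tree whose tips match the observations.
    x, y : arrays, aligned with ``tree.tip_labels``
        Typically x = ln female mass, y = ln male mass.
    clade : str
        Label carried into the result.
    """

    def __init__(self, tree: PhyloTree, x, y, clade: str = "all"):
        self.tree = tree
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.clade = clade
        n = tree.n_tips
        if len(self.x) != n or len(self.y) != n:
            raise ValueError(
                f"trait vectors (len {len(self.x)}, {len(self.y)}) do not match "
                f"the {n} tree tips"
            )
        if n < 3:
            raise ValueError("phylogenetic RMA requires at least 3 species")
        self.C = tree.vcv()

    @classmethod
    def from_table(cls, tree: PhyloTree, table, clade: str = "all"):
        """Build from a TraitTable: x = ln female mass, y = ln male mass."""
        lx, ly = table.log_masses(order=tree.tip_labels)
        return cls(tree, lx, ly, clade=clade)

    # -- likelihood ----------------------------------------------------------

    def _profile(self, lam: float):
        """GLS means, residual cross-products, and profile lnL at fixed lambda."""
        n = self.tree.n_tips
        C = lambda_transform(self.C, lam)
        try:
            cho = linalg.cho_factor(C, lower=True)
        except linalg.LinAlgError:
            return None
        one = np.ones(n)
        Y = np.column_stack([self.x, self.y])
        Ci1 = linalg.cho_solve(cho, one)
        denom = one @ Ci1
        a = (Y.T @ Ci1) / denom  # GLS phylogenetic means (a_x, a_y)
        E = Y - np.outer(one, a)
        CiE = linalg.cho_solve(cho, E)
        S = E.T @ CiE  # residual cross-products
        R = S / n  # ML rate matrix
        sign, logdet_R = np.linalg.slogdet(R)
        if sign <= 0:
            # perfectly correlated (or degenerate) traits: the bivariate
            # Gaussian likelihood is unbounded; slope/intercept remain defined
            return a, S, math.inf
        logdet_C = 2.0 * np.sum(np.log(np.diag(cho[0])))
        p = 2
        lnL = -0.5 * (n * p * (math.log(2 * math.pi) + 1) + p * logdet_C + n * logdet_R)
        return a, S, lnL

    def loglik(self, lam: float) -> float:
        out = self._profile(lam)
        return -math.inf if out is None else out[2]

    def fit(self, fix_lambda: float | None = None, b0: float = 1.0) -> RMAResult:
        """Estimate lambda by ML (unless fixed) and return the RMA fit.

        Lambda is maximized over [0, 1] by bounded scalar search on two
        sub-intervals plus endpoint checks, which avoids boundary traps.
        """
        if fix_lambda is not None:
            lam = float(fix_lambda)
            if not 0.0 <= lam <= 1.0:
                raise ValueError("lambda must be in [0, 1]")
        else:
            cands = [0.0, 0.5, 1.0]
            for lo, hi in ((0.0, 0.5), (0.5, 1.0)):
                res = optimize.minimize_scalar(
                    lambda l: -self.loglik(l),
                    bounds=(lo, hi),
                    method="bounded",
                    options={"xatol": 1e-6},
                )
                cands.append(float(res.x))
            lam = max(cands, key=self.loglik)
        out = self._profile(lam)
        if out is None:
            raise ValueError("singular covariance; cannot fit phylogenetic RMA")
        a, S, lnL = out
        n = self.tree.n_tips
        s = S / (n - 1)  # evolutionary (co)variances
        s_xx, s_yy, s_xy = s[0, 0], s[1, 1], s[0, 1]
        if s_xx <= 0:
            raise ValueError("degenerate x variable (zero evolutionary variance)")
        if s_yy <= 0:
            raise ValueError("degenerate y variable (zero evolutionary variance)")
        slope = math.copysign(math.sqrt(s_yy / s_xx), s_xy if s_xy != 0 else 1.0)
        r2 = (s_xy * s_xy) / (s_xx * s_yy)
        se = abs(slope) * math.sqrt(max(1.0 - r2, 0.0) / (n - 2))
        res = RMAResult(
            slope=slope,
            se=se,
            intercept=a[1] - slope * a[0],
            lam=lam,
            r2=min(r2, 1.0),
            n=n,
            clade=self.clade,
            loglik=lnL,
            means=(a[0], a[1]),
            evo_cov=(s_xx, s_yy, s_xy),
        )
        res.test_slope(b0)
        return res


def rma_by_clade(tree: PhyloTree, table, clades: dict, b0: float = 1.0,
                 min_n: int = 3) -> list[RMAResult]:
    """Global RMA fit plus one fit per clade.

    ``clades`` maps species name -> clade label; every analyzed species must
    appear.  Clades with fewer than ``min_n`` species are skipped with a
    warning.  Per-clade degeneracies (e.g. identical masses) are reported as
    warnings and the remaining fits still returned.  The global fit is
    labelled ``"all"`` and comes first; clades follow in sorted order.
    """
    species = [s for s in tree.tip_labels]
    missing = [s for s in species if s not in clades]
    if missing:
        raise ValueError(f"species without a clade assignment: {missing[:5]}...")
    results = [PhyloRMA.from_table(tree, table, clade="all").fit(b0=b0)]
    labels = sorted(set(clades[s] for s in species))
    for lab in labels:
        members = [s for s in species if clades[s] == lab]
        if len(members) < min_n:
            warnings.warn(
                f"clade {lab!r} skipped: only {len(members)} species (< {min_n})"
            )
            continue
        subtree, _ = prune_to_taxa(tree, members)
        try:
            results.append(PhyloRMA.from_table(subtree, table, clade=lab).fit(b0=b0))
        except ValueError as exc:
            warnings.warn(f"clade {lab!r} could not be fit: {exc}")
    return results


def results_table(results: list[RMAResult]) -> pd.DataFrame:
    """Tabulate RMA fits in the standard column layout."""
    return pd.DataFrame([r.to_row() for r in results])
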