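"""Synthetic data generation: trees, regime histories, SDI values, tables.

Every stage of the analysis can be exercised without external data:
pure-birth (Yule) trees rescaled to a chosen depth; discrete regimes evolved
by exact Gillespie simulation of a continuous-time Markov chain down the
tree (yielding both the true history and the tip states); SDI drawn from the
exact multivariate normal implied by a BM/OU(M) model on the mapped tree;
and full species tables in which female masses evolve by Brownian motion on
the ln-gram scale and male masses are back-computed from the SDI so that the
dimorphism index round-trips exactly.

``paper_like_recipe`` freezes a study-shaped configuration: 166 species, a
60-Myr-deep tree, six combined social-x-diet regimes with mostly male-biased
optima (solitary-carnivory highest), a short phylogenetic half-life relative
to tree depth, and rare regime transitions from a solitary-carnivorous root.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .tree import PhyloTree, SimmapTree
from .traits import TraitTable, SpeciesRecord, COMBINED_REGIMES
from .markov import MkModel, build_q
from .ou import ou_weight_matrix, ou_vcv

__all__ = [
    "SimulationRecipe",
    "simulate_tree",
    "simulate_regimes",
    "simulate_trait",
    "simulate_species_table",
    "paper_like_recipe",
    "generate_dataset",
]


@dataclass
class SimulationRecipe:
    """Frozen description of one synthetic dataset."""

    n_tips: int = 166
    depth: float = 60.0  # Myr
    alphabet: tuple = COMBINED_REGIMES
    q_rate: float = 0.003  # ER transition rate, events/Myr (rare transitions)
    root_state: str = "solitary_carnivory"
    trait_model: str = "OUM"
    alpha: float = math.log(2.0) / 3.16  # 1/Myr (half-life 3.16 Myr)
    sigma2: float = 2.0 * (math.log(2.0) / 3.16) * 100.0  # stationary SD 10%
    theta: dict = field(default_factory=lambda: {
        "solitary_carnivory": 50.0,
        "solitary_omnivory": 33.0,
        "solitary_other": 6.0,
        "group_carnivory": 15.0,
        "group_omnivory": 9.0,
        "group_other": 17.0,
    })
    bm_root: float = 20.0  # used when trait_model == "BM1"
    female_root_ln_g: float = math.log(5000.0)
    female_bm_rate: float = 0.02  # (ln g)^2 / Myr
    planted_shifts: tuple = ()  # ((branch_id, pos, theta), ...)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["alphabet"] = list(self.alphabet)
        d["planted_shifts"] = [list(s) for s in self.planted_shifts]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationRecipe":
        d = dict(d)
        if "alphabet" in d:
            d["alphabet"] = tuple(d["alphabet"])
        if "planted_shifts" in d:
            d["planted_shifts"] = tuple(tuple(s) for s in d["planted_shifts"])
        return cls(**d)


def paper_like_recipe() -> SimulationRecipe:
    """The default study-shaped recipe (see module docstring)."""
    return SimulationRecipe()


# ---------------------------------------------------------------------------


def simulate_tree(n_tips: int, depth: float, rng=None, seed=None) -> PhyloTree:
    """Pure-birth (Yule) tree with ``n_tips`` tips, rescaled to ``depth`` Myr.

    Ultrametric by construction; tips are labelled ``t1..tn``.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    if rng is None:
        rng = np.random.default_rng(seed)
    # forward simulation from a crown split at time 0, unit birth rate
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=int)
    node_time = np.zeros(n_nodes)
    next_internal = n_tips  # internal ids n_tips .. 2n-2
    root = next_internal
    next_internal += 1
    # active lineages carry a pending node id drawn from the tip range lazily;
    # represent each active lineage by (parent_id); assign ids at split/stop
    active_parents = [root, root]
    t = 0.0
    next_tip = 0
    while len(active_parents) < n_tips:
        k = len(active_parents)
        t += rng.exponential(1.0 / k)
        i = int(rng.integers(k))
        v = next_internal
        next_internal += 1
        parent[v] = active_parents[i]
        node_time[v] = t
        active_parents[i] = v
        active_parents.append(v)
    t += rng.exponential(1.0 / n_tips)
    for p in active_parents:
        parent[next_tip] = p
        node_time[next_tip] = t
        next_tip += 1
    scale = depth / t
    node_time *= scale
    lengths = np.zeros(n_nodes)
    for v in range(n_nodes):
        if parent[v] >= 0:
            lengths[v] = node_time[v] - node_time[parent[v]]
    labels = [f"t{i + 1}" for i in range(n_tips)]
    return PhyloTree(parent, lengths, labels)


def simulate_regimes(tree: PhyloTree, Q: np.ndarray, alphabet, root_state,
                     rng=None, seed=None) -> SimmapTree:
    """Exact Gillespie simulation of the regime Markov chain down the tree.

    Returns the true history as a :class:`SimmapTree`; tip states are
    available via ``.tip_states()``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    alphabet = tuple(alphabet)
    Q = np.asarray(Q, dtype=float)
    k = len(alphabet)
    ridx = {s: i for i, s in enumerate(alphabet)}
    if root_state not in ridx:
        raise ValueError(f"root state {root_state!r} not in alphabet")
    segments: list = [None] * tree.n_nodes
    state_at = np.zeros(tree.n_nodes, dtype=int)
    state_at[tree.root] = ridx[root_state]
    segments[tree.root] = [(root_state, 0.0)]
    for v in tree.preorder[1:]:
        s = int(state_at[tree.parent[v]])
        remaining = float(tree.lengths[v])
        segs = []
        if remaining == 0.0:
            segs = [(alphabet[s], 0.0)]
        while remaining > 0.0:
            rate = -Q[s, s]
            wait = math.inf if rate <= 0 else rng.exponential(1.0 / rate)
            if wait >= remaining:
                segs.append((alphabet[s], remaining))
                break
            segs.append((alphabet[s], wait))
            remaining -= wait
            probs = Q[s].copy()
            probs[s] = 0.0
            probs = np.clip(probs, 0.0, None)
            probs /= probs.sum()
            s = int(rng.choice(k, p=probs))
        segments[v] = segs
        state_at[v] = s
    return SimmapTree(tree, segments, alphabet=alphabet)


def simulate_trait(smap: SimmapTree, model: str, alpha: float, sigma2: float,
                   theta=None, bm_root: float = 0.0, rng=None, seed=None) -> np.ndarray:
    """One exact draw of tip values from the Gaussian implied by the model.

    ``theta`` maps regime -> optimum for OUM (a scalar for OU1); BM1 uses
    ``bm_root`` as the ancestral mean.  Values are aligned with
    ``smap.tree.tip_labels``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    tree = smap.tree
    n = tree.n_tips
    if model == "BM1":
        mu = np.full(n, float(bm_root))
        V = sigma2 * tree.vcv()
    elif model == "OU1":
        mu = np.full(n, float(theta))
        V = ou_vcv(tree, alpha, sigma2)
    elif model == "OUM":
        W, regimes = ou_weight_matrix(smap, alpha)
        th = np.array([theta[r] for r in regimes], dtype=float)
        mu = W @ th
        V = ou_vcv(tree, alpha, sigma2)
    else:
        raise ValueError(f"unknown trait model {model!r}")
    Lc = np.linalg.cholesky(V + 1e-12 * float(np.mean(np.diag(V))) * np.eye(n))
    return mu + Lc @ rng.standard_normal(n)


_DECODE_SOCIAL = {"solitary": "territorial_solitary", "group": "group_living"}
_DECODE_DIET = {"carnivory": "carnivory", "omnivory": "omnivory", "other": "insectivory"}


def _decode_regime(regime: str):
    social_key, diet_key = regime.split("_", 1)
    return _DECODE_SOCIAL[social_key], _DECODE_DIET[diet_key]


def simulate_species_table(smap: SimmapTree, recipe: SimulationRecipe,
                           rng=None, seed=None, max_redraws: int = 50):
    """Full species table consistent with a combined-regime map.

    Female masses evolve by Brownian motion on ln grams; the SDI vector is
    drawn from the trait model; male mass is ``female * (1 + SDI/100)`` for
    male-biased species and ``female / (1 + |SDI|/100)`` for female-biased
    ones, so that the dimorphism index recomputed from the masses equals the
    generated SDI exactly.  Draws containing SDI <= -100 are redrawn.
    Returns ``(table, sdi)``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    tree = smap.tree
    n = tree.n_tips
    # Brownian ln female mass down the tree
    val = np.zeros(tree.n_nodes)
    val[tree.root] = recipe.female_root_ln_g
    for v in tree.preorder[1:]:
        sd = math.sqrt(recipe.female_bm_rate * tree.lengths[v])
        val[v] = val[tree.parent[v]] + rng.normal(0.0, sd)
    female = np.exp(val[:n])
    for attempt in range(max_redraws):
        sdi = simulate_trait(smap, recipe.trait_model, recipe.alpha, recipe.sigma2,
                             theta=recipe.theta, bm_root=recipe.bm_root, rng=rng)
        if np.all(sdi > -100.0):
            break
    else:
        raise RuntimeError("could not draw an SDI vector above -100% "
                           f"in {max_redraws} attempts")
    male = np.where(sdi >= 0, female * (1.0 + sdi / 100.0),
                    female / (1.0 + np.abs(sdi) / 100.0))
    states = smap.tip_states()
    records = []
    for i, lab in enumerate(tree.tip_labels):
        social, diet = _decode_regime(states[lab])
        records.append(SpeciesRecord(
            species=lab,
            male_mass_g=float(male[i]),
            female_mass_g=float(female[i]),
            social_system=social,
            diet=diet,
        ))
    return TraitTable(records), sdi


def generate_dataset(recipe: SimulationRecipe, seed=None):
    """Tree + true regime history + species table from one recipe and seed.

    Returns ``(tree, smap, table, sdi)``; all randomness flows from ``seed``.
    """
    rng = np.random.default_rng(seed)
    tree = simulate_tree(recipe.n_tips, recipe.depth, rng=rng)
    Q = build_q("ER", [recipe.q_rate], len(recipe.alphabet))
    smap = simulate_regimes(tree, Q, recipe.alphabet, recipe.root_state, rng=rng)
    table, sdi = simulate_species_table(smap, recipe, rng=rng)
    return tree, smap, table, sdi
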