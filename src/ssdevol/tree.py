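"""Phylogenetic tree containers, file I/O, and covariance utilities.

Trees are stored in a flat array representation: nodes are integer ids,
tips occupy ids ``0 .. n_tips-1`` (in tip-label order of construction),
internal nodes follow, and every non-root node carries the length of the
branch above it in millions of years (Myr).

Two containers are provided:

``PhyloTree``
    a rooted tree with branch lengths; the substrate for all covariance
    computations (Brownian VCV, Pagel's lambda transform, OU kernels).

``SimmapTree``
    a ``PhyloTree`` whose every branch carries an ordered piecewise-constant
    regime history (a stochastic character map).  Segments are stored
    rootward-to-tipward; this convention is enforced by the parser and
    writer because interoperating dialects do not declare it.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "SimmapTree",
    "TreeFormatError",
    "read_tree",
    "read_simmap",
    "write_simmap",
    "phylo_vcv",
    "lambda_transform",
    "prune_to_taxa",
]


class TreeFormatError(ValueError):
    """Raised for malformed Newick/NEXUS/simmap input."""


class PhyloTree:
    """Rooted phylogenetic tree with branch lengths in Myr.

    Parameters
    ----------
    parent : array of int
        ``parent[i]`` is the parent node id of node ``i`` (``-1`` for the
        root).  Tips must be ids ``0 .. n_tips-1``.
    lengths : array of float
        ``lengths[i]`` is the length of the branch above node ``i``
        (ignored for the root); all lengths must be finite and >= 0.
    tip_labels : sequence of str
        Labels of tips ``0 .. n_tips-1``; unique and non-empty.
    """

    def __init__(self, parent, lengths, tip_labels):
        self.parent = np.asarray(parent, dtype=int)
        self.lengths = np.asarray(lengths, dtype=float)
        self.tip_labels = [str(x) for x in tip_labels]
        self.n_nodes = len(self.parent)
        self.n_tips = len(self.tip_labels)
        self._validate()
        # children lists and traversal orders
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                self.children[p].append(i)
        self.root = int(np.flatnonzero(self.parent < 0)[0])
        self.preorder = self._preorder()
        self.postorder = self.preorder[::-1]
        self.lengths = self.lengths.copy()
        self.lengths[self.root] = 0.0
        # node depths: time from the root
        self.depths = np.zeros(self.n_nodes)
        for v in self.preorder[1:]:
            self.depths[v] = self.depths[self.parent[v]] + self.lengths[v]
        self._tip_index = {lab: i for i, lab in enumerate(self.tip_labels)}

    # -- construction checks ------------------------------------------------

    def _validate(self):
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeFormatError(f"tree must have exactly one root, found {len(roots)}")
        if len(self.lengths) != self.n_nodes:
            raise TreeFormatError("parent and length arrays differ in size")
        if self.n_tips < 1 or self.n_tips > self.n_nodes:
            raise TreeFormatError("invalid tip count")
        if len(set(self.tip_labels)) != self.n_tips or any(
            not lab for lab in self.tip_labels
        ):
            raise TreeFormatError("tip labels must be unique and non-empty")
        nonroot = self.parent >= 0
        if not np.all(np.isfinite(self.lengths[nonroot])):
            raise TreeFormatError("branch lengths must be finite")
        if np.any(self.lengths[nonroot] < 0):
            raise TreeFormatError("branch lengths must be non-negative")

    def _preorder(self):
        root = int(np.flatnonzero(self.parent < 0)[0])
        order = []
        stack = [root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        if len(order) != self.n_nodes:
            raise TreeFormatError("tree contains disconnected nodes or a cycle")
        return np.array(order, dtype=int)

    # -- basic queries -------------------------------------------------------

    @property
    def depth(self) -> float:
        """Maximum root-to-tip depth (tree height, Myr)."""
        return float(self.depths[: self.n_tips].max())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = self.depths[: self.n_tips]
        return bool(np.ptp(d) <= rel_tol * max(d.max(), 1e-300))

    def tip_index(self, label: str) -> int:
        return self._tip_index[label]

    def branch_ids(self):
        """Ids of all non-root nodes, i.e. the branches (branch = node above which it hangs)."""
        return [int(v) for v in self.preorder if v != self.root]

    # -- covariance ----------------------------------------------------------

    def vcv(self) -> np.ndarray:
        """Brownian-motion covariance structure: C[i,j] = depth of MRCA(i,j)."""
        n = self.n_tips
        C = np.zeros((n, n))
        # tip sets, assembled in postorder
        tipsets: dict[int, np.ndarray] = {}
        for v in self.postorder:
            if v < n:
                tipsets[v] = np.array([v])
                continue
            kids = self.children[v]
            sets = [tipsets.pop(k) for k in kids]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    C[np.ix_(sets[a], sets[b])] = self.depths[v]
                    C[np.ix_(sets[b], sets[a])] = self.depths[v]
            tipsets[v] = np.concatenate(sets)
        np.fill_diagonal(C, self.depths[:n])
        return C

    def patristic(self) -> np.ndarray:
        """Pairwise tip-to-tip path lengths."""
        C = self.vcv()
        d = np.diag(C)
        return d[:, None] + d[None, :] - 2.0 * C

    # -- serialization -------------------------------------------------------

    def to_newick(self) -> str:
        def rec(v):
            if v < self.n_tips:
                core = _quote_label(self.tip_labels[v])
            else:
                core = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
            if v == self.root:
                return core
            return f"{core}:{self.lengths[v]:.17g}"

        return rec(self.root) + ";"

    def __repr__(self):
        return f"<PhyloTree {self.n_tips} tips, depth {self.depth:.4g} Myr>"


def _quote_label(lab: str) -> str:
    if any(c in lab for c in "(),:;[]{} '\t\n"):
        return "'" + lab.replace("'", "''") + "'"
    return lab


# ---------------------------------------------------------------------------
# Newick / NEXUS input via dendropy
# ---------------------------------------------------------------------------


def _from_dendropy(dtree: "dendropy.Tree") -> PhyloTree:
    nodes = list(dtree.preorder_node_iter())
    tips = [nd for nd in nodes if nd.is_leaf()]
    internals = [nd for nd in nodes if not nd.is_leaf()]
    labels = []
    for nd in tips:
        lab = nd.taxon.label if nd.taxon is not None else nd.label
        if not lab:
            raise TreeFormatError("tip without a label")
        labels.append(lab)
    ids = {id(nd): i for i, nd in enumerate(tips)}
    ids.update({id(nd): len(tips) + i for i, nd in enumerate(internals)})
    n = len(nodes)
    parent = np.full(n, -1, dtype=int)
    lengths = np.zeros(n)
    for nd in nodes:
        i = ids[id(nd)]
        if nd.parent_node is not None:
            parent[i] = ids[id(nd.parent_node)]
            if nd.edge.length is None:
                who = labels[i] if i < len(tips) else f"internal node {i}"
                raise TreeFormatError(f"missing branch length on edge above {who}")
            lengths[i] = float(nd.edge.length)
    return PhyloTree(parent, lengths, labels)


def read_tree(source: str, fmt: str = "newick") -> PhyloTree:
    """Read a rooted tree with branch lengths from Newick or NEXUS text or a file path.

    Every non-root edge must carry a branch length; a missing length is a
    hard error (silently assuming zero would corrupt all covariances).
    """
    if fmt not in ("newick", "nexus"):
        raise ValueError(f"format must be 'newick' or 'nexus', got {fmt!r}")
    text = source
    if "(" not in source and ";" not in source:
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    if not text.strip():
        raise TreeFormatError("empty tree input")
    if fmt == "newick" and not text.rstrip().endswith(";"):
        raise TreeFormatError("truncated newick input: missing terminal ';'")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema=fmt, suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises many error types
        raise TreeFormatError(f"could not parse {fmt} input: {exc}") from exc
    return _from_dendropy(dtree)


# ---------------------------------------------------------------------------
# Simmap trees
# ---------------------------------------------------------------------------


@dataclass
class SimmapTree:
    """A tree whose branches carry piecewise-constant regime histories.

    ``segments[v]`` is the ordered (rootward -> tipward) list of
    ``(state, duration_Myr)`` pairs on the branch above node ``v``; the root
    carries a single zero-duration segment recording the root state.
    """

    tree: PhyloTree
    segments: list  # list over node ids of list[(state, float)]
    alphabet: tuple = field(default=None)

    def __post_init__(self):
        if self.alphabet is None:
            states = {s for segs in self.segments for s, _ in segs}
            self.alphabet = tuple(sorted(states))
        self.validate()

    def validate(self):
        t = self.tree
        if len(self.segments) != t.n_nodes:
            raise ValueError("one segment list required per node")
        alpha = set(self.alphabet)
        for v in range(t.n_nodes):
            segs = self.segments[v]
            if not segs:
                raise ValueError(f"empty segment list on branch above node {v}")
            for s, d in segs:
                if s not in alpha:
                    raise ValueError(f"state {s!r} not in regime alphabet {sorted(alpha)}")
                if d < 0:
                    raise ValueError("negative segment duration")
            bl = 0.0 if v == t.root else t.lengths[v]
            tot = sum(d for _, d in segs)
            if abs(tot - bl) > 1e-9 * max(bl, 1.0):
                raise ValueError(
                    f"segment durations on branch above node {v} sum to {tot}, "
                    f"branch length is {bl}"
                )
        for v in range(t.n_nodes):
            if v == t.root:
                continue
            if self.segments[v][0][0] != self.segments[t.parent[v]][-1][0]:
                raise ValueError(
                    f"history discontinuity at node {t.parent[v]} -> {v}: "
                    f"{self.segments[t.parent[v]][-1][0]!r} != {self.segments[v][0][0]!r}"
                )

    @property
    def root_state(self):
        return self.segments[self.tree.root][0][0]

    def node_states(self) -> list:
        """State at each node (end of the branch above it; root = root state)."""
        return [segs[-1][0] for segs in self.segments]

    def tip_states(self) -> dict:
        ns = self.node_states()
        return {lab: ns[i] for i, lab in enumerate(self.tree.tip_labels)}

    def transition_counts(self) -> dict:
        """Number of state-change events per ordered state pair on this map."""
        counts: dict[tuple, int] = {}
        for v in range(self.tree.n_nodes):
            segs = self.segments[v]
            for (s1, _), (s2, _) in zip(segs, segs[1:]):
                if s1 != s2:
                    counts[(s1, s2)] = counts.get((s1, s2), 0) + 1
        return counts

    def n_transitions(self) -> int:
        return sum(self.transition_counts().values())

    def __repr__(self):
        return (
            f"<SimmapTree {self.tree.n_tips} tips, {len(self.alphabet)} states, "
            f"{self.n_transitions()} transitions>"
        )


# -- simmap dialect parser ---------------------------------------------------
#
# Branch annotations have the form  {state,dur:state,dur:...}  in place of a
# plain branch length; segment order is rootward -> tipward.


class _SimmapLexer:
    def __init__(self, text):
        self.text = text
        self.pos = 0

    def peek(self):
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def next(self):
        c = self.peek()
        self.pos += 1
        return c

    def skip_ws(self):
        while self.peek() in " \t\r\n":
            self.pos += 1

    def error(self, msg):
        raise TreeFormatError(f"simmap parse error at position {self.pos}: {msg}")


def _parse_simmap_label(lx: _SimmapLexer) -> str:
    lx.skip_ws()
    if lx.peek() == "'":
        lx.next()
        out = []
        while True:
            c = lx.next()
            if c == "":
                lx.error("unterminated quoted label")
            if c == "'":
                if lx.peek() == "'":
                    lx.next()
                    out.append("'")
                else:
                    break
            else:
                out.append(c)
        return "".join(out)
    out = []
    while lx.peek() and lx.peek() not in "(),:;{}[]":
        out.append(lx.next())
    return "".join(out).strip()


def _parse_simmap_segments(lx: _SimmapLexer) -> list:
    # at '{'
    lx.next()
    segs = []
    while True:
        state = []
        while lx.peek() and lx.peek() not in ",":
            state.append(lx.next())
        if lx.peek() != ",":
            lx.error("expected ',' between state and duration")
        lx.next()
        num = []
        while lx.peek() and lx.peek() not in ":}":
            num.append(lx.next())
        try:
            dur = float("".join(num))
        except ValueError:
            lx.error(f"bad duration {''.join(num)!r}")
        segs.append(("".join(state).strip(), dur))
        c = lx.next()
        if c == "}":
            return segs
        if c != ":":
            lx.error("expected ':' or '}' after segment")


def read_simmap(text: str, alphabet=None) -> SimmapTree:
    """Parse a simmap-annotated Newick string into a :class:`SimmapTree`.

    The annotation on each branch is ``{state,duration:state,duration:...}``
    listed rootward to tipward; durations must sum to the branch length
    implied by the segments themselves (the dialect carries no separate
    length). Continuity between parent and child branches is validated.
    """
    if "(" not in text:
        with open(text, encoding="utf-8") as fh:
            text = fh.read()
    lx = _SimmapLexer(text)
    # recursive-descent into a temporary nested structure
    def parse_clade():
        lx.skip_ws()
        children = []
        label = ""
        if lx.peek() == "(":
            lx.next()
            while True:
                children.append(parse_clade())
                lx.skip_ws()
                c = lx.next()
                if c == ")":
                    break
                if c != ",":
                    lx.error("expected ',' or ')'")
            label = _parse_simmap_label(lx)
        else:
            label = _parse_simmap_label(lx)
            if not label:
                lx.error("expected a tip label")
        segs = None
        lx.skip_ws()
        if lx.peek() == ":":
            lx.next()
            lx.skip_ws()
        if lx.peek() == "{":
            segs = _parse_simmap_segments(lx)
        return {"label": label, "children": children, "segs": segs}

    top = parse_clade()
    lx.skip_ws()
    if lx.next() != ";":
        lx.error("missing terminal ';'")

    # flatten: tips first
    tips, internals = [], []

    def collect(nd):
        if nd["children"]:
            for c in nd["children"]:
                collect(c)
            internals.append(nd)
        else:
            tips.append(nd)

    collect(top)
    ids = {id(nd): i for i, nd in enumerate(tips)}
    ids.update({id(nd): len(tips) + i for i, nd in enumerate(internals)})
    n = len(tips) + len(internals)
    parent = np.full(n, -1, dtype=int)
    lengths = np.zeros(n)
    segments: list = [None] * n

    def wire(nd):
        i = ids[id(nd)]
        for c in nd["children"]:
            parent[ids[id(c)]] = i
            wire(c)
        if nd is top:
            if nd["segs"] is not None:
                raise TreeFormatError("root must not carry a segment annotation")
        else:
            if nd["segs"] is None:
                raise TreeFormatError(
                    f"branch above {nd['label'] or 'internal node'} lacks a "
                    "{state,duration} annotation"
                )
            segments[i] = list(nd["segs"])
            lengths[i] = sum(d for _, d in nd["segs"])

    wire(top)
    tree = PhyloTree(parent, lengths, [nd["label"] for nd in tips])
    root = tree.root
    # root carries the starting state of its children as a zero-duration segment
    child0 = tree.children[root][0]
    segments[root] = [(segments[child0][0][0], 0.0)]
    return SimmapTree(tree, segments, alphabet=tuple(alphabet) if alphabet else None)


def write_simmap(smap: SimmapTree) -> str:
    """Serialize a :class:`SimmapTree` in the simmap-annotated Newick dialect."""
    t = smap.tree

    def rec(v):
        if v < t.n_tips:
            core = _quote_label(t.tip_labels[v])
        else:
            core = "(" + ",".join(rec(c) for c in t.children[v]) + ")"
        if v == t.root:
            return core
        ann = ":".join(f"{s},{d:.17g}" for s, d in smap.segments[v])
        return core + ":{" + ann + "}"

    return rec(t.root) + ";"


# ---------------------------------------------------------------------------
# Covariance utilities
# ---------------------------------------------------------------------------


def phylo_vcv(tree: PhyloTree) -> np.ndarray:
    """Brownian phylogenetic covariance matrix (shared path length to the MRCA)."""
    return tree.vcv()


def lambda_transform(C: np.ndarray, lam: float, allow_above_one: bool = False) -> np.ndarray:
    """Pagel's lambda transform: scale off-diagonal covariances by ``lam``.

    ``lam`` must lie in [0, 1] unless ``allow_above_one`` is set (values
    above 1 can make the matrix indefinite and are off by default).
    """
    hi = math.inf if allow_above_one else 1.0
    if not (0.0 <= lam <= hi):
        raise ValueError(f"lambda must be in [0, {hi}], got {lam}")
    C = np.asarray(C, dtype=float)
    out = C * lam
    np.fill_diagonal(out, np.diag(C))
    return out


def prune_to_taxa(tree: PhyloTree, names) -> tuple:
    """Restrict a tree to the given tip names.

    Returns ``(subtree, dropped)`` where ``subtree`` is the induced tree on
    the kept tips (degree-2 internal nodes suppressed, lengths summed, rooted
    at the MRCA of the kept taxa) and ``dropped`` lists tips of the input
    that were removed.
    """
    names = list(names)
    keep = [n for n in names if n in tree._tip_index]
    missing = sorted(set(names) - set(keep))
    if missing:
        raise ValueError(f"taxa not in tree: {missing}")
    if not keep:
        raise ValueError("no taxa to keep")
    dropped = sorted(set(tree.tip_labels) - set(keep))
    keep_ids = set(tree.tip_index(n) for n in keep)

    # number of kept tips below each node
    cnt = np.zeros(tree.n_nodes, dtype=int)
    for v in tree.postorder:
        if v < tree.n_tips:
            cnt[v] = 1 if v in keep_ids else 0
        else:
            cnt[v] = sum(cnt[c] for c in tree.children[v])

    # new root: deepest node with all kept tips below it
    new_root = tree.root
    total = cnt[tree.root]
    while True:
        nz = [c for c in tree.children[new_root] if cnt[c] > 0]
        if len(nz) == 1 and cnt[nz[0]] == total and nz[0] >= tree.n_tips:
            new_root = nz[0]
        else:
            break

    tips_out: list[str] = []
    recs: list[tuple[int, float]] = []  # (parent index in recs/-1, length)

    def build(v, acc_len, parent_idx):
        # descend, accumulating lengths through suppressed degree-1 nodes
        while True:
            if v < tree.n_tips:
                recs.append((parent_idx, acc_len))
                tips_out.append(tree.tip_labels[v])
                return ("tip", len(recs) - 1)
            nz = [c for c in tree.children[v] if cnt[c] > 0]
            if len(nz) == 1:
                acc_len += tree.lengths[nz[0]]
                v = nz[0]
                continue
            recs.append((parent_idx, acc_len))
            my = len(recs) - 1
            for c in nz:
                build(c, tree.lengths[c], my)
            return ("internal", my)

    if len(keep) == 1:
        # degenerate: single-tip "tree"
        tid = tree.tip_index(keep[0])
        return PhyloTree([-1], [0.0], [tree.tip_labels[tid]]), dropped

    build(new_root, 0.0, -1)
    # renumber: tips first in order encountered
    is_tip = [lab is not None for lab in _tip_flags(recs, tips_out)]
    n_t = len(tips_out)
    tip_seen = 0
    int_seen = 0
    newid = {}
    for i, tipflag in enumerate(is_tip):
        if tipflag:
            newid[i] = tip_seen
            tip_seen += 1
        else:
            newid[i] = n_t + int_seen
            int_seen += 1
    n = len(recs)
    parent = np.full(n, -1, dtype=int)
    lengths = np.zeros(n)
    for i, (p, ln) in enumerate(recs):
        parent[newid[i]] = newid[p] if p >= 0 else -1
        lengths[newid[i]] = ln
    return PhyloTree(parent, lengths, tips_out), dropped


def _tip_flags(recs, tips_out):
    """Mark which rec indices are tips (they were appended in tandem)."""
    flags = [None] * len(recs)
    ti = 0
    # tips were appended to tips_out exactly when a 'tip' rec was appended;
    # replay: a rec is a tip iff no other rec names it as parent
    has_child = set(p for p, _ in recs if p >= 0)
    for i in range(len(recs)):
        if i not in has_child:
            flags[i] = tips_out[ti]
            ti += 1
    return flags


def normalize_label(label: str) -> str:
    """Canonical tip-label form for tree/table matching (spaces -> underscores)."""
    return "_".join(str(label).strip().split())
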