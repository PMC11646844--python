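"""Poisson-tree-process delimitation of clonal families on a rooted tree.

The model: a delimitation selects a connected, root-containing subtree G of
internal nodes, the "speciation" part of the tree, on which branching
reflects the historical diversification between clonal families (the
species-delimitation analogue of between-species branching). Every edge
whose parent lies in G is a speciation edge; each child hanging off G roots
one coalescent subtree, whose internal edges reflect somatic-hypermutation
branching within one family. Branch lengths in each class are modelled as
exponential; rates are fitted by maximum likelihood (rate = n / sum of
lengths). The delimitation minimising AIC = 2k - 2 log L is returned.

Two modes: ``single_rate`` pools all coalescent edges into one exponential
fit (two rates total), ``multi_rate`` fits one rate per coalescent subtree
(allowing rate variation between families). The null model (G empty) pools
every edge into a single fit and assigns all leaves to one family. Leaves
attached directly to G are singleton families; their zero-edge subtrees
contribute no likelihood term.

The search is exhaustive when the number of delimitations is small and a
greedy grow/shrink hill-climb over the speciation frontier (with optional
random restarts) otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .partition import Partition
from .trees import PhyloTree, midpoint_root

DEFAULT_MIN_BRANCH_LENGTH = 1e-9
DEFAULT_EXHAUSTIVE_LIMIT = 100_000


def exponential_fit(
    lengths, min_branch_length: float = DEFAULT_MIN_BRANCH_LENGTH
) -> tuple[float, float]:
    """ML exponential fit to branch lengths: rate = n / sum, loglik = n (ln rate - 1).

    Lengths below ``min_branch_length`` are floored to it first, so
    zero-length branches cannot blow up the rate.
    """
    lengths = np.asarray(list(lengths), dtype=float)
    if lengths.size == 0:
        raise ValueError("cannot fit an exponential to an empty set of branch lengths")
    lengths = np.maximum(lengths, min_branch_length)
    total = float(lengths.sum())
    n = lengths.size
    rate = n / total
    loglik = n * (math.log(rate) - 1.0)
    return rate, loglik


class TreeIndex:
    """Flat postorder view of a rooted binary tree, for fast rescoring.

    Node i stores its parent, the length of the edge above it (None at the
    root) and the set of nodes strictly below it. Indices follow postorder.
    """

    def __init__(self, tree: PhyloTree):
        if len(tree.children) != 2:
            raise ValueError("PTP delimitation requires a rooted binary tree")
        nodes = list(tree.postorder(include_self=True))
        if sum(1 for n in nodes if n.is_tip()) < 2:
            raise ValueError("tree must have at least 2 leaves")
        if any(len(n.children) != 2 for n in nodes if not n.is_tip()):
            raise ValueError("PTP delimitation requires a strictly binary tree")
        self.nodes = nodes
        index = {id(n): i for i, n in enumerate(nodes)}
        n = len(nodes)
        self.parent = np.full(n, -1, dtype=int)
        self.length = np.zeros(n)
        self.is_leaf = np.zeros(n, dtype=bool)
        self.leaf_name: list[str | None] = [None] * n
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i, node in enumerate(nodes):
            self.is_leaf[i] = node.is_tip()
            self.leaf_name[i] = node.name if node.is_tip() else None
            if node.parent is not None and id(node.parent) in index:
                self.parent[i] = index[id(node.parent)]
                self.length[i] = float(node.length or 0.0)
            for child in node.children:
                self.children[i].append(index[id(child)])
        self.root = index[id(tree)]
        # nodes strictly below i, and leaf names per clade
        self.descendants: list[np.ndarray] = [np.empty(0, dtype=int)] * n
        self.clade_leaves: list[list[str]] = [[] for _ in range(n)]
        for i in range(n):  # postorder: children precede parents
            if self.is_leaf[i]:
                self.clade_leaves[i] = [self.leaf_name[i]]
            else:
                parts = [self.descendants[c] for c in self.children[i]]
                parts.append(np.asarray(self.children[i], dtype=int))
                self.descendants[i] = np.concatenate(parts)
                self.clade_leaves[i] = [
                    name for c in self.children[i] for name in self.clade_leaves[c]
                ]
        self.internal = np.flatnonzero(~self.is_leaf)
        self.n_edges = n - 1

    def count_delimitations(self) -> int:
        """Number of root-containing connected subtrees of internal nodes (+ null)."""
        f = np.ones(len(self.nodes), dtype=object)
        for i in range(len(self.nodes)):
            if not self.is_leaf[i]:
                prod = 1
                for c in self.children[i]:
                    prod *= f[c]
                f[i] = 1 + prod
        return int(f[self.root])


@dataclass(frozen=True)
class Delimitation:
    """A speciation/coalescent split: the speciation node set G (possibly empty)."""

    index: TreeIndex
    speciation_nodes: frozenset[int]

    def __post_init__(self) -> None:
        S = self.speciation_nodes
        idx = self.index
        if S:
            if idx.root not in S:
                raise ValueError("nonempty speciation set must contain the root")
            for v in S:
                if idx.is_leaf[v]:
                    raise ValueError("speciation nodes must be internal")
                p = idx.parent[v]
                if p >= 0 and p not in S:
                    raise ValueError("speciation set must be parent-closed (connected)")

    @property
    def coalescent_roots(self) -> list[int]:
        """Children hanging off G, each rooting one coalescent subtree.

        For the null model (G empty) the tree root is the single subtree.
        Zero-edge subtrees (leaves attached directly to G) are included here
        and become singleton families.
        """
        idx = self.index
        S = self.speciation_nodes
        if not S:
            return [idx.root]
        return [
            c for v in sorted(S) for c in idx.children[v] if c not in S
        ]

    @property
    def n_families(self) -> int:
        return len(self.coalescent_roots)

    def families(self) -> list[list[str]]:
        """Leaf-label families implied by the delimitation."""
        idx = self.index
        return [idx.clade_leaves[c] for c in self.coalescent_roots]

    def speciation_edge_lengths(self) -> np.ndarray:
        idx = self.index
        S = self.speciation_nodes
        edges = [
            c for v in S for c in idx.children[v]
        ]  # every edge whose parent is in G
        return idx.length[np.asarray(edges, dtype=int)] if edges else np.empty(0)

    def coalescent_edge_lengths(self) -> list[np.ndarray]:
        """Per-subtree edge lengths (edges strictly below each coalescent root)."""
        idx = self.index
        out = []
        for c in self.coalescent_roots:
            out.append(idx.length[idx.descendants[c]])
        return out


@dataclass(frozen=True)
class DelimitationScore:
    loglik: float
    k: int
    aic: float
    rates: dict = field(hash=False)
    mode: str = "single_rate"


def score_delimitation(
    d: Delimitation,
    mode: str = "single_rate",
    min_branch_length: float = DEFAULT_MIN_BRANCH_LENGTH,
) -> DelimitationScore:
    """AIC-score a delimitation.

    ``single_rate``: one exponential fit to the speciation edges plus one
    pooled fit to all coalescent edges. ``multi_rate``: one fit per
    coalescent subtree. k counts the fitted rates. Empty (zero-edge)
    coalescent subtrees contribute no term.
    """
    if mode not in ("single_rate", "multi_rate"):
        raise ValueError(f"unknown mode {mode!r}")
    if d.index.n_edges == 0:
        raise ValueError("tree has no edges to fit")
    spec_edges = d.speciation_edge_lengths()
    coal = [lens for lens in d.coalescent_edge_lengths() if lens.size > 0]

    loglik = 0.0
    k = 0
    rates: dict = {}
    if spec_edges.size > 0:
        rate, ll = exponential_fit(spec_edges, min_branch_length)
        loglik += ll
        k += 1
        rates["speciation"] = rate
    if coal:
        if mode == "single_rate":
            pooled = np.concatenate(coal)
            rate, ll = exponential_fit(pooled, min_branch_length)
            loglik += ll
            k += 1
            rates["coalescent"] = rate
        else:
            coal_rates = []
            for lens in coal:
                rate, ll = exponential_fit(lens, min_branch_length)
                loglik += ll
                k += 1
                coal_rates.append(rate)
            rates["coalescent"] = coal_rates
    aic = 2.0 * k - 2.0 * loglik
    return DelimitationScore(loglik=loglik, k=k, aic=aic, rates=rates, mode=mode)


def enumerate_delimitations(
    tree_or_index: PhyloTree | TreeIndex, max_count: int = DEFAULT_EXHAUSTIVE_LIMIT
) -> list[Delimitation]:
    """Every root-containing connected subtree of internal nodes, incl. the null model.

    Errors out if the count exceeds ``max_count`` (the space grows roughly
    exponentially in tree size; use :func:`search_delimitation` instead).
    """
    idx = (
        tree_or_index
        if isinstance(tree_or_index, TreeIndex)
        else TreeIndex(tree_or_index)
    )
    total = idx.count_delimitations()
    if total > max_count:
        raise ValueError(f"{total} delimitations exceed max_count={max_count}")

    def options(v: int) -> list[frozenset[int]]:
        """Connected subtrees of the clade at v that contain v (or are empty)."""
        if idx.is_leaf[v]:
            return [frozenset()]
        subsets = [frozenset()]
        child_opts = [options(c) for c in idx.children[v]]
        lefts, rights = child_opts
        for sl in lefts:
            for sr in rights:
                subsets.append(sl | sr | {v})
        return subsets

    return [Delimitation(idx, s) for s in options(idx.root)]


def _score_key(d: Delimitation, score: DelimitationScore) -> tuple:
    # AIC, then fewer families, then smallest speciation node set
    return (score.aic, d.n_families, tuple(sorted(d.speciation_nodes)))


def _legal_grow(idx: TreeIndex, S: frozenset[int]) -> list[int]:
    if not S:
        return [idx.root] if not idx.is_leaf[idx.root] else []
    return [
        c
        for v in S
        for c in idx.children[v]
        if c not in S and not idx.is_leaf[c]
    ]


def _legal_shrink(idx: TreeIndex, S: frozenset[int]) -> list[int]:
    return [v for v in S if not any(c in S for c in idx.children[v])]


def search_delimitation(
    tree: PhyloTree | TreeIndex,
    mode: str = "single_rate",
    restarts: int = 1,
    seed: int = 0,
    min_branch_length: float = DEFAULT_MIN_BRANCH_LENGTH,
    exhaustive_limit: int = DEFAULT_EXHAUSTIVE_LIMIT,
) -> tuple[Delimitation, DelimitationScore]:
    """Find the minimum-AIC delimitation.

    Exhaustive when the number of delimitations is at most
    ``exhaustive_limit``; otherwise greedy hill-climbing over single-node
    grow/shrink moves of the speciation frontier, restarted from the null
    model and, for ``restarts > 1``, from random root-containing subtrees.
    AIC ties favour fewer families, then the smaller speciation set.
    """
    idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)

    if idx.count_delimitations() <= exhaustive_limit:
        best = None
        for d in enumerate_delimitations(idx, exhaustive_limit):
            score = score_delimitation(d, mode, min_branch_length)
            key = _score_key(d, score)
            if best is None or key < best[0]:
                best = (key, d, score)
        return best[1], best[2]

    rng = np.random.default_rng(seed)
    starts: list[frozenset[int]] = [frozenset()]
    starts.extend(_height_threshold_starts(idx, mode, min_branch_length))
    for _ in range(max(0, restarts - 1)):
        starts.append(_random_subtree(idx, rng))
    best = None
    for S in starts:
        d = Delimitation(idx, S)
        score = score_delimitation(d, mode, min_branch_length)
        key = _score_key(d, score)
        while True:
            candidates = []
            for v in _legal_grow(idx, S):
                candidates.append(S | {v})
            for v in _legal_shrink(idx, S):
                candidates.append(S - {v})
            improved = None
            for cand in candidates:
                cd = Delimitation(idx, frozenset(cand))
                cs = score_delimitation(cd, mode, min_branch_length)
                ck = _score_key(cd, cs)
                if ck < key and (improved is None or ck < improved[0]):
                    improved = (ck, cd, cs)
            if improved is None:
                break
            key, d, score = improved
            S = d.speciation_nodes
        if best is None or key < best[0]:
            best = (key, d, score)
    return best[1], best[2]


def _height_threshold_starts(
    idx: TreeIndex, mode: str, min_branch_length: float
) -> list[frozenset[int]]:
    """Deterministic hill-climb seed: cut the tree at a clade-height threshold.

    Speciation/coalescent transitions tend to separate deep backbone nodes
    from shallow within-family clades, so the best delimitation of the form
    S_t = {internal v : clade height of v > t} is usually close to the
    optimum. All n candidate thresholds are scored; the best is returned.
    """
    n = len(idx.nodes)
    height = np.zeros(n)
    for i in range(n):  # postorder: children first
        if not idx.is_leaf[i]:
            height[i] = max(height[c] + idx.length[c] for c in idx.children[i])
    internal_heights = sorted(set(height[~idx.is_leaf]))
    best = None
    for t in internal_heights:
        S = frozenset(int(v) for v in np.flatnonzero(~idx.is_leaf & (height > t)))
        if S and idx.root not in S:
            continue
        d = Delimitation(idx, S)
        s = score_delimitation(d, mode, min_branch_length)
        key = _score_key(d, s)
        if best is None or key < best[0]:
            best = (key, S)
    return [best[1]] if best is not None else []


def _random_subtree(idx: TreeIndex, rng: np.random.Generator) -> frozenset[int]:
    """Random root-containing connected subtree of internal nodes (top-down coin flips)."""
    if idx.is_leaf[idx.root]:
        return frozenset()
    S = {idx.root}
    stack = [c for c in idx.children[idx.root] if not idx.is_leaf[c]]
    while stack:
        v = stack.pop()
        if rng.random() < 0.5:
            S.add(v)
            stack.extend(c for c in idx.children[v] if not idx.is_leaf[c])
    return frozenset(S)


def delimit_clones(
    tree: PhyloTree,
    mode: str = "single_rate",
    min_branch_length: float = DEFAULT_MIN_BRANCH_LENGTH,
    restarts: int = 1,
    seed: int = 0,
    exhaustive_limit: int = DEFAULT_EXHAUSTIVE_LIMIT,
) -> tuple[Partition, DelimitationScore]:
    """Delimit clonal families on a tree; returns (partition, fit report).

    Unrooted input (trifurcating root) is midpoint-rooted first, with a
    warning. Each coalescent subtree's leaves become one family; leaves
    attached directly to the speciation subtree become singletons.
    """
    if len(tree.children) != 2:
        warnings.warn("input tree is unrooted; applying midpoint rooting")
        tree = midpoint_root(tree)
    d, score = search_delimitation(
        tree,
        mode=mode,
        restarts=restarts,
        seed=seed,
        min_branch_length=min_branch_length,
        exhaustive_limit=exhaustive_limit,
    )
    assignment = {}
    for i, members in enumerate(d.families()):
        for name in members:
            assignment[name] = f"ptp{i + 1}"
    return Partition(assignment), score
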