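"""Distance, parsimony and resampling machinery.

Implements the tree-building toolkit the pipeline relies on: Jukes-Cantor
distances, Saitou-Nei neighbor-joining with deterministic tie-breaking,
nonparametric bootstrap support, Fitch parsimony lengths, NNI hill-climbing,
the incongruence length difference (ILD) partition-homogeneity test, and a
Kishino-Hasegawa-style topology-constraint test with RELL resampling.

Searches are deliberately modest (NJ starting tree + NNI refinement): the
data this package targets are strongly structured (deeply divergent genome
clades), where clade delimitation does not require full heuristic searches.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .seqs import Alignment, p_distance
from .trees import Node, Tree

log = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix", "jc69_distance", "jc_matrix", "nj_build",
    "bootstrap_support", "FitchEngine", "fitch_length", "nni_search",
    "ild_test", "kh_constraint_test",
]

SATURATION_P = 0.75


# ---------------------------------------------------------------------------
# distances

@dataclass
class DistanceMatrix:
    names: list[str]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.names)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(self.matrix)
        if not np.array_equal(self.matrix[finite & finite.T],
                              self.matrix.T[finite & finite.T]) and \
           not np.allclose(np.where(finite, self.matrix, 0.0),
                           np.where(finite.T, self.matrix.T, 0.0)):
            raise ValueError("matrix must be symmetric")
        if (self.matrix[finite] < 0).any():
            raise ValueError("distances must be non-negative")

    @property
    def saturated(self) -> np.ndarray:
        """Boolean mask of entries flagged as saturated (infinite)."""
        return ~np.isfinite(self.matrix)

    def capped(self, factor: float = 1.25) -> "DistanceMatrix":
        """Replace saturated entries by factor x the largest finite entry."""
        if not self.saturated.any():
            return self
        m = self.matrix.copy()
        cap = np.nanmax(m[np.isfinite(m)]) * factor
        m[~np.isfinite(m)] = cap
        return DistanceMatrix(self.names, m)


def jc69_distance(a: str, b: str) -> float:
    """Jukes-Cantor corrected distance d = -(3/4) ln(1 - (4/3)p).

    Gap/N sites are dropped pairwise. Saturated pairs (p >= 3/4, outside the
    domain of the correction) return ``inf``; a pair with no comparable
    sites raises ``ValueError``.
    """
    p = p_distance(a, b)
    if p >= SATURATION_P:
        return math.inf
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc_matrix(aln: Alignment) -> DistanceMatrix:
    codes = aln.codes
    single = np.isin(codes, (1, 2, 4, 8))
    n = len(aln)
    m = np.zeros((n, n))
    for i in range(n):
        both = single[i] & single[i + 1:]
        valid = both.sum(axis=1)
        if (valid == 0).any():
            j = int(np.argmax(valid == 0)) + i + 1
            raise ValueError(
                f"no comparable sites between {aln.names[i]} and {aln.names[j]}")
        mism = (both & (codes[i] != codes[i + 1:])).sum(axis=1)
        p = mism / valid
        with np.errstate(invalid="ignore"):
            d = np.where(p >= SATURATION_P, np.inf,
                         -0.75 * np.log1p(-4.0 * np.minimum(p, SATURATION_P - 1e-12) / 3.0))
        m[i, i + 1:] = d
        m[i + 1:, i] = d
    return DistanceMatrix(aln.names, m)


# ---------------------------------------------------------------------------
# neighbor joining

def nj_build(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining.

    Deterministic: ties in the Q criterion are broken by the
    lexicographically smallest (sorted) pair of cluster labels, where a
    cluster is labelled by its smallest member taxon. Negative branch
    lengths are clamped to zero (with a log notice).
    """
    if len(dm.names) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.isfinite(dm.matrix).all():
        raise ValueError("distance matrix contains saturated entries; "
                         "call .capped() first")
    D = dm.matrix.copy()
    nodes = [Node(name) for name in dm.names]
    labels = list(dm.names)

    def clamp(x: float, context: str) -> float:
        if x < 0:
            log.info("negative branch length %.4g clamped to 0 (%s)", x, context)
            return 0.0
        return x

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=1e-9, atol=1e-12))
        best = min((tuple(sorted((labels[i], labels[j]))), i, j)
                   for i, j in ties if i < j)
        _, i, j = best
        li = clamp(D[i, j] / 2 + (r[i] - r[j]) / (2 * (n - 2)), labels[i])
        lj = clamp(D[i, j] - (D[i, j] / 2 + (r[i] - r[j]) / (2 * (n - 2))),
                   labels[j])
        parent = Node()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add(nodes[i])
        parent.add(nodes[j])
        dnew = (D[i, :] + D[j, :] - D[i, j]) / 2
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.empty((n - 1, n - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]

    root = Node()
    if len(nodes) == 3:
        d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
        lens = [(d01 + d02 - d12) / 2,
                (d01 + d12 - d02) / 2,
                (d02 + d12 - d01) / 2]
        for node, ln, lab in zip(nodes, lens, labels):
            node.length = clamp(ln, lab)
            root.add(node)
    else:  # pragma: no cover - unreachable given the >=3 precondition
        raise AssertionError
    return Tree(root)


def nj_from_alignment(aln: Alignment) -> Tree:
    return nj_build(jc_matrix(aln).capped())


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap_support(aln: Alignment, n_reps: int = 100, seed: int = 0,
                      builder=None) -> Tree:
    """Attach column-resampling bootstrap support to the point-estimate tree.

    Support is the percentage of replicate trees containing each internal
    bipartition of the point tree. The default builder is JC + NJ, for
    which replicate distances are computed by weighting site counts
    (equivalent to resampling columns with replacement).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    point = builder(aln) if builder is not None else nj_from_alignment(aln)
    target = point.bipartitions()
    counts = {bip: 0 for bip in target}

    if builder is None and len(aln) >= 3:
        codes = aln.codes
        single = np.isin(codes, (1, 2, 4, 8))
        n, L = codes.shape
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        both = np.array([single[i] & single[j] for i, j in pairs],
                        dtype=np.float64)
        mism = np.array([(single[i] & single[j]) & (codes[i] != codes[j])
                         for i, j in pairs], dtype=np.float64)
        W = rng.multinomial(L, np.full(L, 1.0 / L),
                            size=n_reps).T.astype(np.float64)
        valid_c = both @ W
        mism_c = mism @ W
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(valid_c > 0, mism_c / np.maximum(valid_c, 1), SATURATION_P)
        d = np.where(p >= SATURATION_P, np.inf,
                     -0.75 * np.log1p(-4.0 * np.minimum(p, SATURATION_P - 1e-12) / 3.0))
        for rep in range(n_reps):
            m = np.zeros((n, n))
            for (i, j), dij in zip(pairs, d[:, rep]):
                m[i, j] = m[j, i] = dij
            rep_tree = nj_build(DistanceMatrix(aln.names, m).capped())
            for bip in rep_tree.bipartitions():
                if bip in counts:
                    counts[bip] += 1
    else:
        L = aln.n_columns
        for _ in range(n_reps):
            cols = rng.integers(0, L, size=L)
            rep_tree = builder(aln.take_columns(cols))
            for bip in rep_tree.bipartitions():
                if bip in counts:
                    counts[bip] += 1

    for bip, node in target.items():
        node.support = 100.0 * counts[bip] / n_reps
    return point


# ---------------------------------------------------------------------------
# Fitch parsimony

class FitchEngine:
    """Vectorized Fitch length evaluation with site-pattern compression."""

    def __init__(self, aln: Alignment):
        self.aln = aln
        self._row = {name: i for i, name in enumerate(aln.names)}
        patterns, inverse, weights = np.unique(
            aln.codes, axis=1, return_inverse=True, return_counts=True)
        self.patterns = patterns  # (taxa, n_patterns)
        self.weights = weights.astype(np.int64)
        self._inverse = inverse

    def _changes(self, tree: Tree, columns: np.ndarray) -> np.ndarray:
        masks: dict[int, np.ndarray] = {}
        changes = np.zeros(columns.shape[1], dtype=np.int64)
        for node in tree.postorder():
            if node.is_leaf:
                try:
                    masks[id(node)] = columns[self._row[node.name]]
                except KeyError:
                    raise KeyError(f"leaf {node.name!r} missing from alignment")
                continue
            cur = None
            for child in node.children:
                m = masks.pop(id(child))
                if cur is None:
                    cur = m
                else:
                    inter = cur & m
                    zero = inter == 0
                    changes += zero
                    cur = np.where(zero, cur | m, inter)
            masks[id(node)] = cur
        return changes

    def length(self, tree: Tree) -> int:
        return int(self._changes(tree, self.patterns) @ self.weights)

    def site_lengths(self, tree: Tree) -> np.ndarray:
        """Per-alignment-column Fitch changes."""
        return self._changes(tree, self.patterns)[self._inverse]


def fitch_length(tree: Tree, aln: Alignment) -> int:
    """Fitch parsimony length; gaps/N are missing data (no cost)."""
    return FitchEngine(aln).length(tree)


# ---------------------------------------------------------------------------
# NNI hill climbing

def _is_monophyletic(tree: Tree, group: frozenset) -> bool:
    all_leaves = frozenset(tree.leaf_names())
    if not group <= all_leaves:
        return False
    target = {group, all_leaves - group}
    below: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.name])
        else:
            below[id(node)] = frozenset().union(
                *(below[id(c)] for c in node.children))
        if below[id(node)] in target:
            return True
    return False


def _swap(p: Node, c: Node, s: Node, x: Node) -> None:
    p.children[p.children.index(s)] = x
    c.children[c.children.index(x)] = s
    x.parent, s.parent = p, c


def nni_search(tree: Tree, engine: FitchEngine,
               constraint: frozenset | None = None,
               max_rounds: int = 100) -> Tree:
    """First-improvement NNI hill climb on Fitch length.

    If ``constraint`` is given, only moves preserving monophyly of that
    leaf set are accepted (the input tree must already satisfy it).
    """
    tree = tree.copy()
    best = engine.length(tree)
    for _ in range(max_rounds):
        improved = False
        internal = [n for n in tree.postorder()
                    if not n.is_leaf and n.parent is not None]
        for c in internal:
            p = c.parent
            for s in list(p.children):
                if improved:
                    break
                if s is c:
                    continue
                for x in list(c.children):
                    _swap(p, c, s, x)
                    ok = constraint is None or _is_monophyletic(tree, constraint)
                    score = engine.length(tree) if ok else None
                    if ok and score < best:
                        best = score
                        improved = True
                        break
                    _swap(p, c, x, s)  # revert
            if improved:
                break
        if not improved:
            break
    return tree


# ---------------------------------------------------------------------------
# ILD partition-homogeneity test

def _search_length(aln: Alignment) -> int:
    tree = nj_build(jc_matrix(aln).capped())
    engine = FitchEngine(aln)
    return engine.length(nni_search(tree, engine))


def ild_test(aln1: Alignment, aln2: Alignment, n_reps: int = 100,
             seed: int = 0) -> tuple[int, float]:
    """Incongruence length difference test (Farris et al. style).

    The statistic is L(combined) - [L(p1) + L(p2)], with lengths taken from
    NJ trees refined by NNI. The null distribution reassigns characters at
    random to partitions of the original sizes. Returns (statistic,
    p-value) with a +1/+1 continuity correction.
    """
    if n_reps < 10:
        raise ValueError("n_reps must be >= 10")
    shared = sorted(set(aln1.names) & set(aln2.names))
    if len(shared) < 4:
        raise ValueError("partitions must share at least 4 taxa")
    a1, a2 = aln1.subset(shared), aln2.subset(shared)
    combined = a1.concat(a2)
    observed = _search_length(combined) - (_search_length(a1) + _search_length(a2))

    rng = np.random.default_rng(seed)
    n1 = a1.n_columns
    total = combined.n_columns
    exceed = 0
    for _ in range(n_reps):
        perm = rng.permutation(total)
        p1 = combined.take_columns(perm[:n1])
        p2 = combined.take_columns(perm[n1:])
        null = _search_length(combined) - (_search_length(p1) + _search_length(p2))
        if null >= observed:
            exceed += 1
    return observed, (exceed + 1) / (n_reps + 1)


# ---------------------------------------------------------------------------
# KH-style constraint test (RELL)

def _attach_group(backbone: Tree, group_tree: Node) -> list[Tree]:
    """All trees formed by inserting ``group_tree`` on each backbone edge."""
    out = []
    edges = [n for n in backbone.postorder() if n.parent is not None]
    for k, _ in enumerate(edges):
        cand = backbone.copy()
        cand_edges = [n for n in cand.postorder() if n.parent is not None]
        child = cand_edges[k]
        parent = child.parent
        mid = Node(length=child.length / 2)
        parent.children[parent.children.index(child)] = mid
        mid.parent = parent
        child.length /= 2
        mid.add(child)

        def clone(node: Node) -> Node:
            new = Node(node.name, node.length, node.support)
            for ch in node.children:
                new.add(clone(ch))
            return new

        mid.add(clone(group_tree))
        out.append(Tree(cand.root))
    return out


def _group_subtree(aln: Alignment, group: list[str]) -> Node:
    if len(group) == 1:
        return Node(group[0], length=0.0)
    if len(group) == 2:
        d = jc69_distance(aln.row(group[0]), aln.row(group[1]))
        d = d if math.isfinite(d) else 1.0
        root = Node()
        root.add(Node(group[0], length=d / 2))
        root.add(Node(group[1], length=d / 2))
        return root
    sub = nj_from_alignment(aln.subset(group))
    return sub.root


def kh_constraint_test(aln: Alignment, group: frozenset | set,
                       tree: Tree | None = None, n_rell: int = 1000,
                       seed: int = 0) -> tuple[int, float]:
    """Kishino-Hasegawa-style parsimony test of a monophyly constraint.

    Finds the best tree forcing ``group`` monophyletic (NJ-based placement
    plus constraint-respecting NNI), then compares per-site Fitch lengths
    against the unconstrained tree by RELL resampling. Returns
    (length difference, two-sided p-value).
    """
    group = frozenset(group)
    taxa = set(aln.names)
    if not group <= taxa or not 2 <= len(group) <= len(taxa) - 2:
        raise ValueError("constraint group must be a proper subset "
                         "(>=2 members, >=2 non-members) of the taxa")
    engine = FitchEngine(aln)
    if tree is None:
        tree = nni_search(nj_from_alignment(aln), engine)
    if _is_monophyletic(tree, group):
        return 0, 1.0

    backbone = tree.restrict(taxa - group)
    group_tree = _group_subtree(aln, sorted(group))
    candidates = _attach_group(backbone, group_tree)
    start = min(candidates, key=engine.length)
    constrained = nni_search(start, engine, constraint=group)

    s_con = engine.site_lengths(constrained)
    s_un = engine.site_lengths(tree)
    d = (s_con - s_un).astype(np.float64)
    delta = int(d.sum())
    if not d.any():
        return 0, 1.0
    rng = np.random.default_rng(seed)
    L = d.size
    W = rng.multinomial(L, np.full(L, 1.0 / L), size=n_rell)
    boot = W @ d
    centered = np.abs(boot - boot.mean())
    p = float((centered >= abs(delta)).mean())
    return delta, p
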