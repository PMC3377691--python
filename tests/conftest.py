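import itertools

import numpy as np
import pytest

from homoeosort.seqs import Alignment
from homoeosort.trees import parse_newick


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def evolve_on_tree(newick: str, n_sites: int, rng,
                   multiple_hits: bool = False) -> Alignment:
    """Simulate a JC alignment along a tree (test utility)."""
    tree = parse_newick(newick)
    seqs = {}
    root_seq = rng.integers(0, 4, n_sites)

    def walk(node, seq):
        p = node.length
        if multiple_hits:
            p = 0.75 * (1 - np.exp(-4 * node.length / 3))
        hit = rng.random(n_sites) < p
        new = seq.copy()
        shift = rng.integers(1, 4, n_sites)
        new[hit] = (new[hit] + shift[hit]) % 4
        if node.is_leaf:
            seqs[node.name] = "".join("ACGT"[b] for b in new)
        for child in node.children:
            walk(child, new)

    for child in tree.root.children:
        walk(child, root_seq)
    names = sorted(seqs)
    return Alignment(names, [seqs[n] for n in names])


def brute_force_fitch(tree, aln: Alignment) -> int:
    """Exhaustive minimum over all internal-state labelings (oracle)."""
    internal = [nd for nd in tree.postorder() if not nd.is_leaf]
    row = {nm: i for i, nm in enumerate(aln.names)}
    codes = aln.codes
    total = 0
    for col in range(aln.n_columns):
        best = None
        for assign in itertools.product((1, 2, 4, 8), repeat=len(internal)):
            amap = {id(nd): st for nd, st in zip(internal, assign)}
            cost = 0
            for nd in tree.postorder():
                if nd.parent is None:
                    continue
                state = (amap[id(nd)] if not nd.is_leaf
                         else int(codes[row[nd.name], col]))
                if state in (1, 2, 4, 8) and not state & amap[id(nd.parent)]:
                    cost += 1
            best = cost if best is None else min(best, cost)
        total += best
    return total


def random_binary_tree(n_leaves: int, rng):
    """Random unrooted binary tree with positive branch lengths."""
    from homoeosort.trees import Node, Tree

    root = Node()
    for i in range(3):
        root.add(Node(f"t{i}", length=float(rng.uniform(0.05, 1.0))))
    for i in range(3, n_leaves):
        edges = [nd for nd in Tree(root).postorder() if nd.parent is not None]
        target = edges[rng.integers(len(edges))]
        parent = target.parent
        mid = Node()
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        split = target.length * float(rng.uniform(0.2, 0.8))
        mid.length = target.length - split
        target.length = split
        target.parent = None
        mid.add(target)
        mid.add(Node(f"t{i}", length=float(rng.uniform(0.05, 1.0))))
    return Tree(root)
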