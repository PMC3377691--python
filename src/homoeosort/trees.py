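"""Lightweight rooted/unrooted tree structure used across the package.

Trees are stored rooted (the root of an "unrooted" tree is simply an
arbitrary basal node, usually a trifurcation left by neighbor-joining).
Topological comparisons go through bipartitions, which are invariant to
the choice of that basal node.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import dendropy

__all__ = [
    "Node",
    "Tree",
    "parse_newick",
    "robinson_foulds",
]


class Node:
    __slots__ = ("name", "children", "parent", "length", "support")

    def __init__(self, name: str | None = None, length: float = 0.0,
                 support: float | None = None):
        self.name = name
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length
        self.support = support

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, n_children={len(self.children)})"


class Tree:
    def __init__(self, root: Node):
        self.root = root

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def find(self, name: str) -> Node:
        for node in self.postorder():
            if node.name == name:
                return node
        raise KeyError(name)

    # -- copying -----------------------------------------------------------
    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.length, node.support)
            for child in node.children:
                new.add(clone(child))
            return new

        return Tree(clone(self.root))

    # -- serialization -----------------------------------------------------
    def newick(self, support_as_label: bool = True,
               lengths: bool = True) -> str:
        def emit(node: Node) -> str:
            if node.is_leaf:
                body = node.name or ""
            else:
                body = "(" + ",".join(emit(c) for c in node.children) + ")"
                if support_as_label and node.support is not None:
                    body += f"{node.support:g}"
                elif node.name:
                    body += node.name
            if lengths and node.parent is not None:
                body += f":{node.length:g}"
            return body

        return emit(self.root) + ";"

    # -- topology ----------------------------------------------------------
    def bipartitions(self) -> dict[frozenset, Node]:
        """Non-trivial bipartitions as canonical leaf-name sets.

        Each internal edge (parent, child) maps the leaf set under ``child``;
        the side not containing the lexicographically smallest leaf is used
        as the canonical representative, so the encoding does not depend on
        where the tree is rooted.
        """
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        below: dict[int, frozenset] = {}
        out: dict[frozenset, Node] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
            else:
                side = frozenset().union(*(below[id(c)] for c in node.children))
                below[id(node)] = side
                if node.parent is None:
                    continue
                if len(side) < 2 or len(all_leaves - side) < 2:
                    continue
                canon = side if anchor not in side else all_leaves - side
                out[canon] = node
        return out

    # -- metrics -----------------------------------------------------------
    def patristic_distances(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf path lengths, keyed by sorted name pairs."""
        dists: dict[tuple[str, str], float] = {}
        below: dict[int, dict[str, float]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = {node.name: 0.0}
                continue
            merged: dict[str, float] = {}
            kids = [{k: v + c.length for k, v in below[id(c)].items()}
                    for c in node.children]
            for i in range(len(kids)):
                for j in range(i + 1, len(kids)):
                    for a, da in kids[i].items():
                        for b, db in kids[j].items():
                            key = (a, b) if a < b else (b, a)
                            dists[key] = da + db
                for k, v in kids[i].items():
                    merged[k] = v
            below[id(node)] = merged
        return dists

    def total_length(self) -> float:
        return sum(n.length for n in self.postorder() if n.parent is not None)

    # -- manipulation ------------------------------------------------------
    def restrict(self, keep: Iterable[str]) -> "Tree":
        """Prune to a leaf subset, suppressing degree-2 nodes."""
        keep = set(keep)
        tree = self.copy()

        def prune(node: Node) -> Node | None:
            if node.is_leaf:
                return node if node.name in keep else None
            new_children = [c for c in (prune(ch) for ch in node.children)
                            if c is not None]
            if not new_children:
                return None
            if len(new_children) == 1:
                child = new_children[0]
                child.length += node.length
                return child
            node.children = []
            for c in new_children:
                node.add(c)
            return node

        new_root = prune(tree.root)
        if new_root is None:
            raise ValueError("restriction removed every leaf")
        new_root.parent = None
        new_root.length = 0.0
        return Tree(new_root)

    def midpoint_root(self) -> "Tree":
        """Reroot at the midpoint of the longest leaf-to-leaf path.

        Deterministic: ties are broken by the sorted name pair.
        """
        dists = self.patristic_distances()
        (a, b), dmax = max(dists.items(), key=lambda kv: (kv[1], kv[0]))
        # walk from a towards b, find edge containing the midpoint
        tree = self.copy()
        parent_map = {id(n): n.parent for n in tree.postorder()}
        na, nb = tree.find(a), tree.find(b)
        path_a = []
        node = na
        while node is not None:
            path_a.append(node)
            node = parent_map[id(node)]
        anc_index = {id(n): i for i, n in enumerate(path_a)}
        node, path_b = nb, []
        while id(node) not in anc_index:
            path_b.append(node)
            node = parent_map[id(node)]
        mrca = node
        path = path_a[:anc_index[id(mrca)]] + [mrca] + list(reversed(path_b))
        # distance travelled from a along the path; find midpoint edge
        half = dmax / 2.0
        travelled = 0.0
        for i in range(len(path) - 1):
            u, v = path[i], path[i + 1]
            # edge length between u and v (one is the parent of the other)
            edge = v.length if v.parent is u else u.length
            if travelled + edge >= half or i == len(path) - 2:
                child = v if v.parent is u else u
                # frac: distance from u (walk direction) to the midpoint
                frac = min(max(half - travelled, 0.0), edge)
                offset = edge - frac if child is v else frac
                return _reroot_on_edge(tree, child, offset)
            travelled += edge
        raise AssertionError("midpoint not found")  # pragma: no cover

    def ladderize(self) -> None:
        """Sort children by (subtree size, smallest leaf name), in place."""
        sizes: dict[int, tuple[int, str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                sizes[id(node)] = (1, node.name)
            else:
                subs = [sizes[id(c)] for c in node.children]
                sizes[id(node)] = (sum(s[0] for s in subs),
                                   min(s[1] for s in subs))
            node.children.sort(key=lambda c: sizes[id(c)])


def _reroot_on_edge(tree: Tree, child: Node, offset_from_child: float) -> Tree:
    """Place a new root on the edge above ``child``, ``offset`` up from it."""
    old_parent = child.parent
    if old_parent is None:
        return tree
    edge_len = child.length
    offset = min(max(offset_from_child, 0.0), edge_len)
    new_root = Node()
    # detach child
    old_parent.children.remove(child)
    child.parent = None
    child.length = offset
    new_root.add(child)
    # invert the path from old_parent up to the old root; edge supports
    # travel with their bipartition (stored on the lower node of each edge)
    carry_len = edge_len - offset
    carry_support = child.support
    node, prev = old_parent, new_root
    while node is not None:
        parent = node.parent
        if parent is not None:
            parent.children.remove(node)
        node.parent = None
        this_len, this_support = node.length, node.support
        node.length = carry_len
        node.support = carry_support
        prev.add(node)
        carry_len, carry_support = this_len, this_support
        prev = node
        node = parent
    # suppress a leftover degree-1 old root
    _suppress_unary(new_root)
    return Tree(new_root)


def _suppress_unary(root: Node) -> None:
    stack = [root]
    while stack:
        node = stack.pop()
        for child in list(node.children):
            while len(child.children) == 1:
                grand = child.children[0]
                grand.length += child.length
                grand.parent = node
                node.children[node.children.index(child)] = grand
                child = grand
            stack.append(child)


def parse_newick(text: str) -> Tree:
    """Parse a Newick string (internal node labels read as support)."""
    dt = dendropy.Tree.get(data=text, schema="newick",
                           suppress_internal_node_taxa=True)

    def convert(dnode) -> Node:
        name = dnode.taxon.label if dnode.taxon is not None else None
        node = Node(name=name,
                    length=dnode.edge.length or 0.0)
        if dnode.label is not None and not dnode.is_leaf():
            try:
                node.support = float(dnode.label)
            except ValueError:
                node.name = dnode.label
        for child in dnode.child_nodes():
            node.add(convert(child))
        return node

    return Tree(convert(dt.seed_node))


def robinson_foulds(t1: Tree, t2: Tree) -> int:
    """Symmetric bipartition distance on the shared leaf set."""
    shared = set(t1.leaf_names()) & set(t2.leaf_names())
    if len(shared) < 4:
        raise ValueError("need >= 4 shared taxa for a meaningful RF distance")
    b1 = set(t1.restrict(shared).bipartitions())
    b2 = set(t2.restrict(shared).bipartitions())
    return len(b1 ^ b2)
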