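"""Phylogenetic trees: Newick I/O, rerooting, and normalized RF distance.

The tree structure is deliberately small: parent/child-linked nodes with
branch lengths, a ``rooted`` flag (rooted trees have a degree-2 root,
unrooted trees a basal multifurcation), and edges identified by the leaf
bipartition (split) they induce — a representation that is stable under
rerooting and shared with the rooting module's reports.
"""

from __future__ import annotations


import dendropy

__all__ = ["Node", "PhyloTree", "parse_newick", "write_newick", "normalized_rf"]


class Node:
    __slots__ = ("children", "parent", "length", "label")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length  # length of the edge above this node
        self.label = label

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Rooted or unrooted tree over uniquely labeled leaves.

    Every non-root node owns the edge to its parent (``node.length``); for
    a rooted tree the root has exactly two children, for an unrooted tree
    three or more.  Edge identifiers are canonical splits: the frozenset of
    leaf labels on the side *not* containing the reference (lexicographically
    smallest) leaf.
    """

    def __init__(self, root: Node, rooted: bool):
        self.root = root
        self.rooted = rooted
        labels = [n.label for n in self.leaves()]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels")
        if any(lbl is None or lbl == "" for lbl in labels):
            raise ValueError("unlabeled leaf")

    # -- traversal ----------------------------------------------------------
    def postorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                out.append(node)
            else:
                stack.append((node, True))
                for ch in node.children:
                    stack.append((ch, False))
        return out

    def preorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return sorted(n.label for n in self.leaves())

    def total_length(self) -> float:
        return sum(n.length for n in self.postorder() if n is not self.root)

    def copy(self) -> "PhyloTree":
        def clone(n: Node) -> Node:
            c = Node(n.label, n.length)
            for ch in n.children:
                c.add(clone(ch))
            return c
        return PhyloTree(clone(self.root), self.rooted)

    # -- splits and edges ---------------------------------------------------
    def _reference_leaf(self) -> str:
        return min(n.label for n in self.leaves())

    def canonical_split(self, leafset: frozenset) -> frozenset:
        """Canonicalize a bipartition side to the one without the reference leaf."""
        all_leaves = frozenset(n.label for n in self.leaves())
        ref = self._reference_leaf()
        return all_leaves - leafset if ref in leafset else leafset

    def edge_splits(self) -> dict[frozenset, Node]:
        """Map canonical split -> child node owning that edge.

        In a rooted tree the two root-adjacent edges induce the same split;
        the first-encountered child is kept (they are the same unrooted edge).
        """
        below: dict[int, frozenset] = {}
        out: dict[frozenset, Node] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children))
            if node is not self.root:
                key = self.canonical_split(below[id(node)])
                out.setdefault(key, node)
        return out

    def splits(self, nontrivial_only: bool = True) -> set[frozenset]:
        n_leaves = len(self.leaves())
        out = set()
        for split in self.edge_splits():
            if nontrivial_only and not 1 < len(split) < n_leaves - 1:
                continue
            out.add(split)
        return out

    # -- rerooting ----------------------------------------------------------
    def _adjacency(self) -> dict:
        """Undirected view with the degree-2 root (if any) dissolved."""
        adj: dict[int, list] = {}
        nodes: dict[int, Node] = {}

        def link(a: Node, b: Node, length: float):
            adj.setdefault(id(a), []).append((id(b), length))
            adj.setdefault(id(b), []).append((id(a), length))
            nodes[id(a)] = a
            nodes[id(b)] = b

        for node in self.postorder():
            for ch in node.children:
                link(node, ch, ch.length)
        if self.rooted and len(self.root.children) == 2:
            a, b = self.root.children
            # dissolve root: a - b with summed length
            adj[id(a)] = [(x, l) for x, l in adj[id(a)] if x != id(self.root)]
            adj[id(b)] = [(x, l) for x, l in adj[id(b)] if x != id(self.root)]
            adj[id(a)].append((id(b), a.length + b.length))
            adj[id(b)].append((id(a), a.length + b.length))
            del adj[id(self.root)]
            nodes.pop(id(self.root), None)
        return adj, nodes

    def unrooted(self) -> "PhyloTree":
        """The unrooted version of this tree (root dissolved)."""
        if not self.rooted:
            return self.copy()
        adj, nodes = self._adjacency()
        # rebuild from an arbitrary internal node
        start = next(i for i in adj if not nodes[i].is_leaf)
        return PhyloTree(_rebuild(adj, nodes, start), rooted=False)

    def reroot_on_edge(self, split: frozenset, fraction: float = 0.5) -> "PhyloTree":
        """Root on the edge identified by ``split``.

        The edge of length L is subdivided into ``fraction * L`` (on the side
        of the canonical split, i.e. away from the reference leaf) and
        ``(1 - fraction) * L``.  A previous degree-2 root is dissolved first.
        """
        if not 0 <= fraction <= 1:
            raise ValueError("fraction must lie in [0, 1]")
        split = frozenset(split)
        all_labels = frozenset(n.label for n in self.leaves())
        if not split <= all_labels:
            raise KeyError(f"unknown leaves in split: "
                           f"{sorted(split - all_labels)}")
        split = self.canonical_split(split)
        adj, nodes = self._adjacency()
        target = None
        for i in list(adj):
            for j, length in adj[i]:
                side = _leafset_beyond(adj, nodes, i, j)
                if self.canonical_split(side) == split:
                    target = (i, j, length)
                    break
            if target:
                break
        if target is None:
            raise KeyError(f"no edge with split {sorted(split)}")
        i, j, length = target
        side_j = _leafset_beyond(adj, nodes, i, j)
        # place fraction*L on the canonical-split side
        lj = fraction * length if self.canonical_split(side_j) == side_j else (1 - fraction) * length
        li = length - lj
        root = Node()
        rid = id(root)
        nodes[rid] = root
        adj[i] = [(x, l) for x, l in adj[i] if x != j] + [(rid, li)]
        adj[j] = [(x, l) for x, l in adj[j] if x != i] + [(rid, lj)]
        adj[rid] = [(i, li), (j, lj)]
        return PhyloTree(_rebuild(adj, nodes, rid), rooted=True)

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Patristic distance between every leaf pair."""
        adj, nodes = self._adjacency()
        leaves = {i: nodes[i].label for i in adj if nodes[i].is_leaf}
        out = {}
        for src, src_label in leaves.items():
            dist = {src: 0.0}
            stack = [src]
            while stack:
                u = stack.pop()
                for v, l in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + l
                        stack.append(v)
            for dst, dst_label in leaves.items():
                if src_label < dst_label:
                    out[(src_label, dst_label)] = dist[dst]
        return out

    def __repr__(self):
        kind = "rooted" if self.rooted else "unrooted"
        return f"<PhyloTree {kind}, {len(self.leaves())} leaves>"


def _leafset_beyond(adj, nodes, i, j) -> frozenset:
    """Labels of leaves reachable from j without passing through i."""
    seen = {i, j}
    stack = [j]
    out = set()
    while stack:
        u = stack.pop()
        if nodes[u].is_leaf:
            out.add(nodes[u].label)
        for v, _ in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return frozenset(out)


def _rebuild(adj, nodes, start) -> Node:
    """Materialize parent/child links from an adjacency view, rooted at start."""
    old = nodes[start]
    root = Node(old.label if old.is_leaf else None)
    stack = [(start, None, root)]
    while stack:
        u, came_from, new_u = stack.pop()
        for v, length in adj[u]:
            if v == came_from:
                continue
            old_v = nodes[v]
            new_v = Node(old_v.label if old_v.is_leaf else None, length)
            new_u.add(new_v)
            stack.append((v, u, new_v))
    return root


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string; rootedness is inferred from the basal degree
    (two children at the base means rooted)."""
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True,
                                  preserve_underscores=True)
    except Exception as exc:
        raise ValueError(f"newick parse error: {exc}") from exc

    def convert(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else None
        node = Node(label, dnode.edge.length if dnode.edge.length is not None else 0.0)
        for ch in dnode.child_nodes():
            node.add(convert(ch))
        return node

    root = convert(dtree.seed_node)
    root.length = 0.0
    return PhyloTree(root, rooted=len(root.children) == 2)


def write_newick(tree: PhyloTree, annotations: dict | None = None) -> str:
    """Serialize to Newick with 10 significant digits.

    ``annotations`` maps canonical splits to comment strings attached to the
    corresponding branch, e.g. ``{split: "&rootstrap=0.99"}``.
    """
    ann = annotations or {}
    split_of: dict[int, frozenset] = {}
    if ann:
        for split, node in tree.edge_splits().items():
            split_of[id(node)] = split

    def fmt(node: Node) -> str:
        if node.is_leaf:
            body = node.label
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
        if node.parent is None:
            return body
        tag = ""
        key = split_of.get(id(node))
        if key is not None and key in ann:
            tag = f"[{ann[key]}]"
        return f"{body}:{node.length:.10g}{tag}"

    return fmt(tree.root) + ";"


def normalized_rf(a: PhyloTree, b: PhyloTree) -> float:
    """Robinson–Foulds split distance normalized by its maximum.

    Rooted inputs are unrooted first.  The distance is the number of
    non-trivial splits present in exactly one tree, divided by the total
    number of internal (split-inducing) edges of both trees — 0 for
    identical topologies, 1 when no split is shared.
    """
    if a.leaf_labels() != b.leaf_labels():
        raise ValueError("trees must share an identical leaf set")
    sa = a.unrooted().splits() if a.rooted else a.splits()
    sb = b.unrooted().splits() if b.rooted else b.splits()
    denom = len(sa) + len(sb)
    if denom == 0:
        return 0.0
    return len(sa.symmetric_difference(sb)) / denom
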