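"""Rooted phylogenetic trees: Newick I/O, rooting, pruning, queries.

The tree type here (:class:`LabeledTree`) is the carrier for both species
trees and gene ("protein") trees throughout the package.  Parsing is
delegated to dendropy; the structural operations (midpoint and outgroup
rooting, pruning, MRCA) are implemented directly on the lightweight node
structure because downstream reconciliation needs stable post-order
indexing and exactly specified tie-breaking.
"""

from __future__ import annotations

import io
import random
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import dendropy

__all__ = [
    "TreeError",
    "NewickParseError",
    "Node",
    "LabeledTree",
    "TreeIndex",
    "parse_newick",
    "parse_newick_list",
    "read_trees",
    "write_newick",
    "midpoint_root",
    "outgroup_root",
    "prune_to",
    "mrca",
    "resolve_polytomies",
    "read_tsv_map",
    "write_tsv_map",
    "default_leafmap",
]


class TreeError(ValueError):
    """Raised for structurally invalid trees or invalid tree operations."""


class NewickParseError(TreeError):
    """Malformed Newick input; ``offset`` is the best-known character offset."""

    def __init__(self, message: str, offset: Optional[int] = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at character offset {offset})"
        super().__init__(message)


@dataclass
class Node:
    """A tree node; leaves have a nonempty unique ``label`` and no children."""

    label: str = ""
    length: Optional[float] = None
    children: list["Node"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        # iterative: gene trees from simulations can be deep
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                yield node
            else:
                stack.append((node, True))
                for ch in reversed(node.children):
                    stack.append((ch, False))

    def copy(self) -> "Node":
        new = Node(self.label, self.length)
        new.children = [c.copy() for c in self.children]
        return new


class LabeledTree:
    """A rooted tree with uniquely labeled leaves.

    Instances are treated as immutable by all public operations: rooting
    and pruning return new trees.
    """

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    def _validate(self) -> None:
        seen: set[str] = set()
        for node in self.root.postorder():
            if node.is_leaf():
                if not node.label:
                    raise TreeError("leaf with empty label")
                if node.label in seen:
                    raise TreeError(f"duplicate leaf label {node.label!r}")
                seen.add(node.label)
            if node.length is not None and node.length < 0:
                raise TreeError(f"negative branch length on {node.label or '<internal>'}")

    # -- queries ---------------------------------------------------------

    def postorder(self) -> list[Node]:
        return list(self.root.postorder())

    def leaves(self) -> list[Node]:
        return [n for n in self.root.postorder() if n.is_leaf()]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def n_leaves(self) -> int:
        return len(self.leaves())

    def is_binary(self) -> bool:
        return all(n.is_leaf() or len(n.children) == 2 for n in self.root.postorder())

    def has_lengths(self) -> bool:
        """True when every non-root edge carries a branch length."""
        return all(n.length is not None for n in self.root.postorder() if n is not self.root)

    def copy(self) -> "LabeledTree":
        return LabeledTree(self.root.copy())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"LabeledTree({write_newick(self)!r})"


class TreeIndex:
    """Post-order array view of a tree, for O(1) ancestry queries.

    Built once per tree by the reconciliation and origin-inference code;
    node identity across replicates is the stable post-order index.
    """

    def __init__(self, tree: LabeledTree):
        self.tree = tree
        self.nodes: list[Node] = tree.postorder()
        self.index: dict[int, int] = {id(n): i for i, n in enumerate(self.nodes)}
        n = len(self.nodes)
        self.parent = [-1] * n
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i, node in enumerate(self.nodes):
            for ch in node.children:
                j = self.index[id(ch)]
                self.parent[j] = i
                self.children[i].append(j)
        self.root = self.index[id(tree.root)]
        # pre-order intervals + depth (edge count from root)
        self.tin = [0] * n
        self.tout = [0] * n
        self.depth = [0] * n
        clock = 0
        stack = [(self.root, False)]
        while stack:
            i, done = stack.pop()
            if done:
                self.tout[i] = clock
                continue
            self.tin[i] = clock
            clock += 1
            stack.append((i, True))
            for j in reversed(self.children[i]):
                self.depth[j] = self.depth[i] + 1
                stack.append((j, False))
        self.leaf_index: dict[str, int] = {
            node.label: i for i, node in enumerate(self.nodes) if node.is_leaf()
        }

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    def is_ancestor(self, a: int, b: int) -> bool:
        """True when a is an ancestor of b (or a == b)."""
        return self.tin[a] <= self.tin[b] and self.tout[b] <= self.tout[a]

    def comparable(self, a: int, b: int) -> bool:
        return self.is_ancestor(a, b) or self.is_ancestor(b, a)

    def leaves_under(self, i: int) -> list[int]:
        return [j for j in range(len(self.nodes)) if self.is_leaf(j) and self.is_ancestor(i, j)]

    def name(self, i: int) -> str:
        """Human-readable, unique node name.

        A labeled node uses its label; an internal node is named
        ``mrca(a,b)`` from the smallest leaf label in each child subtree,
        a pair whose MRCA is exactly this node.
        """
        node = self.nodes[i]
        if node.label:
            return node.label
        reps = sorted(
            min(self.nodes[j].label for j in self.leaves_under(c))
            for c in self.children[i]
        )
        return f"mrca({reps[0]},{reps[-1]})"


# -- Newick I/O ----------------------------------------------------------


def _check_balanced(text: str) -> None:
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError("unbalanced ')'", offset=pos)
        elif ch == ";" and depth != 0:
            raise NewickParseError("';' inside unbalanced parentheses", offset=pos)
    if depth != 0:
        raise NewickParseError("unbalanced '(': missing closing parenthesis", offset=len(text))


def _from_dendropy(dnode) -> Node:
    label = ""
    if dnode.taxon is not None and dnode.taxon.label:
        label = dnode.taxon.label
    elif dnode.label:
        label = dnode.label
    node = Node(label=label, length=dnode.edge.length)
    node.children = [_from_dendropy(c) for c in dnode.child_nodes()]
    return node


def parse_newick(text: str) -> LabeledTree:
    """Parse a single ``;``-terminated Newick statement.

    Square-bracket comments are stripped; quoted labels and underscores are
    handled per Newick convention (underscores are preserved verbatim).
    """
    stripped = text.strip()
    if not stripped:
        raise NewickParseError("empty input", offset=0)
    if not stripped.endswith(";"):
        raise NewickParseError("missing terminating ';'", offset=len(text))
    _check_balanced(stripped)
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}", offset=0) from None
    root = _from_dendropy(dtree.seed_node)
    # duplicate-leaf check with a useful offset
    seen: dict[str, int] = {}
    for node in root.postorder():
        if node.is_leaf():
            if node.label in seen:
                off = stripped.find(node.label, seen[node.label] + len(node.label))
                raise NewickParseError(
                    f"duplicate leaf label {node.label!r}", offset=max(off, 0)
                )
            seen[node.label] = stripped.find(node.label)
    return LabeledTree(root)


def parse_newick_list(text: str) -> list[LabeledTree]:
    """Parse a ``;``-separated multi-tree string."""
    trees = []
    buf = ""
    for chunk in text.split(";"):
        buf += chunk
        if buf.strip():
            trees.append(parse_newick(buf.strip() + ";"))
        buf = ""
    return trees


def read_trees(path) -> list[LabeledTree]:
    with io.open(path, "r", encoding="utf-8") as fh:
        return parse_newick_list(fh.read())


_NEEDS_QUOTE = set(" ()[]{}:;,'\t\n")


def _fmt_label(label: str) -> str:
    if any(ch in _NEEDS_QUOTE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _fmt_length(x: float) -> str:
    return repr(x) if isinstance(x, float) else str(x)


def write_newick(tree: LabeledTree) -> str:
    """Serialize so that ``parse_newick(write_newick(t))`` round-trips."""

    def emit(node: Node) -> str:
        if node.is_leaf():
            s = _fmt_label(node.label)
        else:
            s = "(" + ",".join(emit(c) for c in node.children) + ")"
            if node.label:
                s += _fmt_label(node.label)
        if node.length is not None:
            s += ":" + _fmt_length(node.length)
        return s

    return emit(tree.root) + ";"


# -- unrooted adjacency view (shared by the rooting operations) ----------


def _adjacency(tree: LabeledTree):
    """Undirected edge map with the root suppressed when it is degree-2.

    Returns (adj, nodes) where adj maps id(node) -> list of (neighbor,
    length-or-None).  Node objects are reused; lengths of the two root
    edges are summed on suppression (None + x treated as missing only if
    both are None results in None; otherwise missing counts as 0).
    """
    adj: dict[int, list[tuple[Node, Optional[float]]]] = {}
    obj: dict[int, Node] = {}

    def add(a: Node, b: Node, ln: Optional[float]) -> None:
        adj.setdefault(id(a), []).append((b, ln))
        adj.setdefault(id(b), []).append((a, ln))
        obj[id(a)] = a
        obj[id(b)] = b

    for node in tree.root.postorder():
        for ch in node.children:
            add(node, ch, ch.length)
    root = tree.root
    if len(root.children) == 2:
        a, b = root.children
        ln: Optional[float]
        if a.length is None and b.length is None:
            ln = None
        else:
            ln = (a.length or 0.0) + (b.length or 0.0)
        adj[id(a)] = [(n, l) for n, l in adj[id(a)] if n is not root] + [(b, ln)]
        adj[id(b)] = [(n, l) for n, l in adj[id(b)] if n is not root] + [(a, ln)]
        del adj[id(root)]
        obj.pop(id(root), None)
    return adj, obj


def _orient(adj, node: Node, exclude: Optional[Node], length: Optional[float]) -> Node:
    new = Node(label=node.label if node.children or node.is_leaf() else "", length=length)
    new.label = node.label
    kids = []
    for nb, ln in adj[id(node)]:
        if exclude is not None and nb is exclude:
            continue
        kids.append(_orient(adj, nb, node, ln))
    new.children = kids
    return new


def _reroot_on_edge(adj, u: Node, v: Node, edge_len: Optional[float],
                    dist_from_u: Optional[float]) -> LabeledTree:
    root = Node()
    if edge_len is None:
        lu = lv = None
    else:
        lu = dist_from_u
        lv = edge_len - dist_from_u
    side_u = _orient(adj, u, v, lu)
    side_v = _orient(adj, v, u, lv)
    root.children = [side_u, side_v]
    return LabeledTree(root)


def _leaf_paths(adj, start: Node):
    """BFS from a leaf: returns (dist, prev) keyed by id(node)."""
    dist = {id(start): 0.0}
    prev: dict[int, Node] = {}
    queue = [start]
    while queue:
        cur = queue.pop()
        for nb, ln in adj[id(cur)]:
            if id(nb) in dist:
                continue
            if ln is None:
                raise TreeError("midpoint rooting requires branch lengths on all edges")
            dist[id(nb)] = dist[id(cur)] + ln
            prev[id(nb)] = cur
            queue.append(nb)
    return dist, prev


def midpoint_root(tree: LabeledTree) -> LabeledTree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Ties between equally long paths are broken by the lexicographic order
    of the (sorted) endpoint-label pair.
    """
    if tree.n_leaves() < 2:
        raise TreeError("midpoint rooting needs at least 2 leaves")
    adj, _ = _adjacency(tree)
    leaves = tree.leaves()
    paths = {leaf.label: _leaf_paths(adj, leaf) for leaf in leaves}
    best: Optional[tuple[str, str]] = None
    best_d = -1.0
    for a in leaves:
        da, _ = paths[a.label]
        for b in leaves:
            if a.label >= b.label:
                continue
            d = da[id(b)]
            pair = (a.label, b.label)
            if d > best_d + 1e-12 or (abs(d - best_d) <= 1e-12 and pair < best):
                best_d, best = d, pair
    assert best is not None
    a_lab, b_lab = best
    leaf_by_label = {l.label: l for l in leaves}
    a, b = leaf_by_label[a_lab], leaf_by_label[b_lab]
    dist, prev = paths[a.label]
    # walk b -> a, then reverse to get path a -> b
    path = [b]
    while path[-1] is not a:
        path.append(prev[id(path[-1])])
    path.reverse()
    half = best_d / 2.0
    cum = 0.0
    for u, v in zip(path, path[1:]):
        ln = next(l for nb, l in adj[id(u)] if nb is v)
        if cum + ln >= half - 1e-12:
            return _reroot_on_edge(adj, u, v, ln, max(half - cum, 0.0))
        cum += ln
    raise AssertionError("midpoint not found on path")  # pragma: no cover


def outgroup_root(tree: LabeledTree, outgroup: Iterable[str]) -> LabeledTree:
    """Root on the edge separating ``outgroup`` from all remaining leaves."""
    og = set(outgroup)
    labels = set(tree.leaf_labels())
    unknown = og - labels
    if unknown:
        raise TreeError(f"unknown outgroup labels: {sorted(unknown)}")
    if not og or og == labels:
        raise TreeError("outgroup must be a nonempty proper subset of the leaves")
    adj, obj = _adjacency(tree)

    def side_leaves(u: Node, v: Node) -> set[str]:
        # leaves reachable from v when the edge (u, v) is cut
        out: set[str] = set()
        stack = [(v, u)]
        while stack:
            cur, prev_n = stack.pop()
            if not [nb for nb, _ in adj[id(cur)] if nb is not prev_n]:
                out.add(cur.label)
            for nb, _ in adj[id(cur)]:
                if nb is not prev_n:
                    stack.append((nb, cur))
        return out

    edges = []
    for nid, nbrs in adj.items():
        for nb, ln in nbrs:
            if id(obj[nid]) < id(nb):
                edges.append((obj[nid], nb, ln))
    smallest_superset: Optional[set[str]] = None
    for u, v, ln in edges:
        for x, y in ((u, v), (v, u)):
            side = side_leaves(x, y)
            if side == og:
                mid = None if ln is None else ln / 2.0
                return _reroot_on_edge(adj, x, y, ln, mid)
            if og <= side and (smallest_superset is None or len(side) < len(smallest_superset)):
                smallest_superset = side
    raise TreeError(
        "outgroup is not monophyletic under any rooting: requested "
        f"{sorted(og)} | {sorted(labels - og)}; smallest containing clade is "
        f"{sorted(smallest_superset or labels)}"
    )


def prune_to(tree: LabeledTree, keep: Iterable[str]) -> LabeledTree:
    """Restrict to ``keep`` leaves, suppressing unary nodes (lengths summed)."""
    keep_set = set(keep)
    labels = set(tree.leaf_labels())
    unknown = keep_set - labels
    if unknown:
        raise TreeError(f"unknown labels in keep set: {sorted(unknown)}")
    if not keep_set:
        raise TreeError("keep set is empty")

    def rebuild(node: Node) -> Optional[Node]:
        if node.is_leaf():
            return Node(node.label, node.length) if node.label in keep_set else None
        kids = [k for k in (rebuild(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            child = kids[0]
            if node.length is None and child.length is None:
                child.length = None
            else:
                child.length = (node.length or 0.0) + (child.length or 0.0)
            return child
        new = Node(node.label, node.length)
        new.children = kids
        return new

    root = rebuild(tree.root)
    assert root is not None
    root.length = None
    return LabeledTree(root)


def mrca(tree: LabeledTree, labels: Iterable[str]) -> Node:
    """Most recent common ancestor of the given leaf labels."""
    want = set(labels)
    if not want:
        raise TreeError("mrca of an empty label set")
    unknown = want - set(tree.leaf_labels())
    if unknown:
        raise TreeError(f"unknown labels: {sorted(unknown)}")
    best: Optional[Node] = None

    def walk(node: Node) -> set[str]:
        nonlocal best
        if node.is_leaf():
            got = {node.label} & want
        else:
            got = set()
            for c in node.children:
                got |= walk(c)
        if got == want and best is None:
            best = node
        return got

    walk(tree.root)
    assert best is not None
    return best


def resolve_polytomies(tree: LabeledTree, seed: int) -> LabeledTree:
    """Randomly resolve multifurcations into binary nodes (zero-length edges).

    Reconciliation rejects non-binary trees by default; this is the opt-in
    seeded resolution for inputs with collapsed nodes.
    """
    rng = random.Random(seed)
    new = tree.copy()
    for node in new.postorder():
        while len(node.children) > 2:
            i, j = sorted(rng.sample(range(len(node.children)), 2))
            b = node.children.pop(j)
            a = node.children.pop(i)
            joint = Node(label="", length=0.0)
            joint.children = [a, b]
            node.children.append(joint)
    return LabeledTree(new.root)


# -- 2-column TSV maps (leaf -> species, species -> group) ---------------


def read_tsv_map(path) -> dict[str, str]:
    """Read a 2-column tab-separated map; '#' starts a comment line."""
    out: dict[str, str] = {}
    with io.open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            out[parts[0]] = parts[1]
    return out


def write_tsv_map(path, mapping: dict[str, str], header: str = "") -> None:
    with io.open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        for k, v in mapping.items():
            fh.write(f"{k}\t{v}\n")


def default_leafmap(gene_tree: LabeledTree) -> dict[str, str]:
    """Leaf-to-species map by the ``species|gene_id`` label convention.

    Labels without a ``|`` map to themselves (single-copy genes named by
    their genome).
    """
    out = {}
    for lab in gene_tree.leaf_labels():
        out[lab] = lab.split("|", 1)[0]
    return out
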