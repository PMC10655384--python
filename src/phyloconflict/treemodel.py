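"""Core tree data model: newick I/O, rooting, and clade/bipartition machinery.

Trees are stored as rooted node structures even when they represent unrooted
phylogenies; the ``rooted`` flag records which interpretation is
authoritative. An unrooted tree is conventionally held as
rooted-at-an-arbitrary-trifurcation.

Branch support lives on internal nodes (the support of the edge above the
node). Values parsed on a 0-1 scale are normalized to 0-100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

__all__ = [
    "Tree",
    "Node",
    "Clade",
    "TaxonMap",
    "NewickParseError",
    "TreeValidationError",
    "NotRootableError",
    "NonMonophyleticOutgroupError",
    "parse_newick",
    "read_newick_file",
    "write_newick",
    "write_newick_file",
    "reroot_on_outgroup",
    "clades_of",
    "restrict",
    "clades_conflict",
    "tip_to_tip_depth",
    "root_to_tip_depth",
]


class NewickParseError(ValueError):
    """Malformed newick. Carries the character offset of the failure."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class TreeValidationError(ValueError):
    """Structural invariant violated (duplicate leaves, bad support, ...)."""


class NotRootableError(ValueError):
    """No outgroup taxon present in the tree."""


class NonMonophyleticOutgroupError(ValueError):
    """Outgroup taxa present but not separable from the ingroup by one edge."""


class Node:
    """A tree node. ``length`` and ``support`` describe the edge above it."""

    __slots__ = ("label", "length", "support", "children", "parent")

    def __init__(
        self,
        label: Optional[str] = None,
        length: Optional[float] = None,
        support: Optional[float] = None,
    ):
        self.label = label
        self.length = length
        self.support = support
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        out = list(self.preorder())
        return reversed(out)

    def leaves(self) -> list["Node"]:
        return [n for n in self.preorder() if n.is_leaf]

    def copy(self) -> "Node":
        new = Node(self.label, self.length, self.support)
        for child in self.children:
            new.add_child(child.copy())
        return new


class Tree:
    """Phylogeny with branch lengths, numeric support, and a rooted flag."""

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted
        self.validate()

    # -- structure ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def taxa(self) -> frozenset[str]:
        return frozenset(leaf.label for leaf in self.leaves())

    def internal_nodes(self, exclude_root: bool = True) -> list[Node]:
        out = [n for n in self.preorder() if not n.is_leaf]
        if exclude_root:
            out = [n for n in out if n is not self.root]
        return out

    def copy(self) -> "Tree":
        return Tree(self.root.copy(), rooted=self.rooted)

    def validate(self) -> None:
        labels = [leaf.label for leaf in self.leaves()]
        if any(not lab for lab in labels):
            raise TreeValidationError("empty or missing leaf label")
        dupes = {lab for lab in labels if labels.count(lab) > 1}
        if dupes:
            raise TreeValidationError(
                f"duplicate leaf labels: {sorted(dupes)}"
            )
        for node in self.preorder():
            if node.length is not None and node.length < 0:
                raise TreeValidationError(
                    f"negative branch length {node.length}"
                )
            if node.support is not None and not (0 <= node.support <= 100):
                raise TreeValidationError(
                    f"support {node.support} outside [0, 100]"
                )

    # -- clades ------------------------------------------------------------

    def cluster_map(self) -> dict[int, frozenset[str]]:
        """id(node) -> descendant taxon set, for every node."""
        clusters: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                clusters[id(node)] = frozenset([node.label])
            else:
                clusters[id(node)] = frozenset().union(
                    *(clusters[id(c)] for c in node.children)
                )
        return clusters

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "rooted" if self.rooted else "unrooted"
        return f"<Tree {kind}, {len(self.leaves())} leaves>"


@dataclass(frozen=True)
class Clade:
    """A taxon set cut out by a tree edge, with the edge's support."""

    taxa: frozenset[str]
    support: Optional[float] = field(default=None, compare=False, hash=False)

    def __post_init__(self):
        if not isinstance(self.taxa, frozenset):
            object.__setattr__(self, "taxa", frozenset(self.taxa))
        if not self.taxa:
            raise ValueError("empty clade")

    def is_trivial(self, universe: Iterable[str]) -> bool:
        universe = frozenset(universe)
        return len(self.taxa) <= 1 or self.taxa >= universe

    def sort_key(self) -> tuple:
        return tuple(sorted(self.taxa))


class TaxonMap:
    """Many-to-one accession-label -> taxon-label map; identity by default."""

    def __init__(self, mapping: Optional[dict[str, str]] = None):
        self._mapping = dict(mapping or {})

    def __call__(self, label: str) -> str:
        return self._mapping.get(label, label)

    def map_set(self, labels: Iterable[str]) -> frozenset[str]:
        return frozenset(self(lab) for lab in labels)

    @classmethod
    def from_tsv(cls, path) -> "TaxonMap":
        mapping = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"bad taxon-map line: {line!r}")
                mapping[parts[0]] = parts[1]
        return cls(mapping)


# ---------------------------------------------------------------------------
# newick parsing


def _tokenize_label(text: str, pos: int) -> tuple[str, int]:
    """Read an (optionally quoted) label starting at pos."""
    if pos < len(text) and text[pos] == "'":
        end = pos + 1
        out = []
        while end < len(text):
            if text[end] == "'":
                if end + 1 < len(text) and text[end + 1] == "'":
                    out.append("'")
                    end += 2
                    continue
                return "".join(out), end + 1
            out.append(text[end])
            end += 1
        raise NewickParseError("unterminated quoted label", pos)
    end = pos
    while end < len(text) and text[end] not in "(),:;[":
        end += 1
    return text[pos:end].strip(), end


def _skip_comment(text: str, pos: int) -> tuple[Optional[str], int]:
    """Skip a [...] comment; return its content."""
    if pos >= len(text) or text[pos] != "[":
        return None, pos
    end = text.find("]", pos)
    if end == -1:
        raise NewickParseError("unterminated comment", pos)
    return text[pos + 1 : end], end + 1


def parse_newick(text: str, support_in_comments: bool = False) -> Tree:
    """Parse one newick string into a :class:`Tree`.

    Purely numeric internal-node labels are read as branch support.
    Supports on a 0-1 scale are rescaled to 0-100 (decided globally: if
    every parsed support is <= 1, all are multiplied by 100).

    With ``support_in_comments``, a numeric ``[...]`` comment after the
    branch length is read as support instead (MrBayes/BEAST-like exports).

    Raises :class:`NewickParseError` with a character offset on malformed
    input and :class:`TreeValidationError` on duplicate leaf labels.
    """
    text = text.strip()
    if not text:
        raise NewickParseError("empty input", 0)
    pos = 0
    root = Node()
    node = root
    opened = 0
    saw_semicolon = False
    internal_numeric_labels: list[Node] = []

    def finish_node(n: Node, p: int) -> int:
        """Consume optional label, :length, and comments after a node."""
        label, p = _tokenize_label(text, p)
        if label:
            if n.is_leaf:
                n.label = label
            else:
                try:
                    n.support = float(label)
                    internal_numeric_labels.append(n)
                except ValueError:
                    n.label = label
        comment, p = _skip_comment(text, p)
        if comment is not None and support_in_comments and not n.is_leaf:
            try:
                n.support = float(comment)
                internal_numeric_labels.append(n)
            except ValueError:
                pass
        if p < len(text) and text[p] == ":":
            p += 1
            end = p
            while end < len(text) and text[end] not in "(),;[":
                end += 1
            token = text[p:end].strip()
            try:
                n.length = float(token)
            except ValueError:
                raise NewickParseError(
                    f"bad branch length {token!r}", p
                ) from None
            p = end
            comment, p = _skip_comment(text, p)
            if comment is not None and support_in_comments and not n.is_leaf:
                try:
                    n.support = float(comment)
                    internal_numeric_labels.append(n)
                except ValueError:
                    pass
        return p

    if text[pos] != "(":
        raise NewickParseError("expected '('", pos)
    node = root
    pos += 1
    opened = 1
    current = root.add_child(Node())
    # descend immediately if a subtree opens
    while pos < len(text):
        ch = text[pos]
        if ch == "(":
            opened += 1
            current = current.add_child(Node())
            pos += 1
        elif ch == ",":
            if current.is_leaf and current.label is None:
                raise NewickParseError("empty subtree element", pos)
            parent = current.parent
            if parent is None:
                raise NewickParseError("unexpected ','", pos)
            pos += 1
            current = parent.add_child(Node())
        elif ch == ")":
            if current.is_leaf and current.label is None:
                raise NewickParseError("empty subtree element", pos)
            opened -= 1
            if opened < 0:
                raise NewickParseError("unbalanced ')'", pos)
            current = current.parent
            if current is None:
                raise NewickParseError("unbalanced ')'", pos)
            pos += 1
            pos = finish_node(current, pos)
        elif ch == ";":
            saw_semicolon = True
            pos += 1
            break
        elif ch.isspace():
            pos += 1
        else:
            pos = finish_node(current, pos)
            if pos < len(text) and text[pos] not in "(),;":
                raise NewickParseError(
                    f"unexpected character {text[pos]!r}", pos
                )
    if opened != 0:
        raise NewickParseError("unbalanced parentheses", len(text) - 1)
    if not saw_semicolon:
        raise NewickParseError("missing ';'", len(text) - 1)
    if pos < len(text) and text[pos:].strip():
        raise NewickParseError("trailing characters after ';'", pos)

    supports = [n.support for n in internal_numeric_labels if n.support is not None]
    if supports and max(supports) <= 1.0:
        for n in internal_numeric_labels:
            if n.support is not None:
                n.support = n.support * 100.0
    # a bifurcating top level reads as rooted; trifurcation+ as unrooted
    rooted = len(root.children) == 2
    return Tree(root, rooted=rooted)


def read_newick_file(path, **kwargs) -> list[Tree]:
    """Read a one-tree-per-line newick file."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(parse_newick(line, **kwargs))
    return trees


def _format_length(x: float) -> str:
    return format(x, ".10g")


def _format_support(x: float) -> str:
    if float(x).is_integer():
        return str(int(x))
    return format(x, ".10g")


def _node_to_newick(node: Node, parts: list[str]) -> None:
    if node.is_leaf:
        label = node.label or ""
        if any(c in label for c in "(),:;[] '"):
            label = "'" + label.replace("'", "''") + "'"
        parts.append(label)
    else:
        parts.append("(")
        for i, child in enumerate(node.children):
            if i:
                parts.append(",")
            _node_to_newick(child, parts)
        parts.append(")")
        if node.support is not None:
            parts.append(_format_support(node.support))
        elif node.label:
            parts.append(node.label)
    if node.length is not None:
        parts.append(":" + _format_length(node.length))


def write_newick(tree: Tree) -> str:
    """Serialize to newick; ``parse_newick(write_newick(t))`` is isomorphic
    to ``t`` (topology, lengths to 10 significant digits, supports)."""
    parts: list[str] = []
    _node_to_newick(tree.root, parts)
    parts.append(";")
    return "".join(parts)


def write_newick_file(trees: Iterable[Tree], path) -> None:
    with open(path, "w") as fh:
        for tree in trees:
            fh.write(write_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# rooting


def _unroot_inplace(root: Node) -> Node:
    """Turn a degree-2 root into a trifurcation by merging its two edges.

    The second root child is grafted onto the first (if the first is
    internal), or vice versa; edge lengths are summed and the support of
    the root edge is kept.
    """
    if len(root.children) != 2:
        return root
    a, b = root.children
    keep, move = (a, b) if not a.is_leaf else (b, a)
    if keep.is_leaf:
        # two-leaf tree: nothing to unroot
        return root
    total = None
    if keep.length is not None or move.length is not None:
        total = (keep.length or 0.0) + (move.length or 0.0)
    move.length = total
    if move.support is None and not move.is_leaf:
        move.support = keep.support
    keep.children.append(move)
    move.parent = keep
    keep.parent = None
    keep.length = None
    keep.support = None
    return keep


def _reroot_at_edge(tree: Tree, child: Node, fraction: float = 0.5) -> Tree:
    """Reroot so the new root bisects the edge above ``child``.

    ``fraction`` is the portion of the edge assigned to the child side.
    """
    if child.parent is None:
        raise ValueError("cannot reroot on the root's (non-existent) edge")
    length = child.length
    support = child.support

    # Reverse parent pointers from child's parent up to the old root.
    path = []
    node = child.parent
    while node is not None:
        path.append(node)
        node = node.parent

    new_root = Node()
    if length is not None:
        child_len = length * fraction
        parent_len = length - child_len
    else:
        child_len = parent_len = None

    old_parent = child.parent
    old_parent.children.remove(child)

    # Flip edges along the path: each node on the path becomes a child of
    # its former child, inheriting the edge (length/support) that used to
    # point rootward from it.
    prev = None
    prev_len = parent_len
    prev_sup = support
    for node in path:
        nxt_len = node.length
        nxt_sup = node.support
        node.length = prev_len
        node.support = prev_sup
        if prev is not None:
            node.children.remove(prev)
            prev.add_child(node)
        prev = node
        prev_len = nxt_len
        prev_sup = nxt_sup

    new_root.add_child(child)
    child.length = child_len
    new_root.add_child(old_parent)

    # suppress any unary node left where the old root was
    for node in list(new_root.preorder()):
        if not node.is_leaf and len(node.children) == 1 and node is not new_root:
            only = node.children[0]
            if node.length is not None and only.length is not None:
                only.length += node.length
            elif node.length is not None:
                only.length = node.length
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx] = only
            only.parent = parent
    return Tree(new_root, rooted=True)


def reroot_on_outgroup(tree: Tree, outgroups: Iterable[str]) -> Tree:
    """Root ``tree`` on the edge separating the present outgroup taxa from
    the ingroup.

    The new root bisects that edge (half the length on either side), so the
    multiset of tip-to-tip path lengths is preserved and the operation is
    idempotent. A single present outgroup leaf roots on its pendant edge.

    Raises :class:`NotRootableError` if no outgroup taxon is present and
    :class:`NonMonophyleticOutgroupError` if the present outgroups are not
    separable from the ingroup by a single edge.
    """
    outgroups = frozenset(outgroups)
    work = tree.copy()
    taxa = work.taxa()
    present = taxa & outgroups
    if not present:
        raise NotRootableError(f"no outgroup of {sorted(outgroups)} present")
    if present == taxa:
        raise NotRootableError("tree consists only of outgroup taxa")

    root = _unroot_inplace(work.root)
    work = Tree(root, rooted=False)
    clusters = work.cluster_map()
    target = None
    for node in work.preorder():
        if node is work.root:
            continue
        below = clusters[id(node)]
        if below == present or below == taxa - present:
            target = node
            break
    if target is None:
        raise NonMonophyleticOutgroupError(
            "present outgroup taxa are not separable from the ingroup"
        )
    rooted = _reroot_at_edge(work, target)
    # orient with the outgroup clade first for stable output
    first = rooted.root.children[0]
    if rooted.cluster_map()[id(first)] != present:
        rooted.root.children.reverse()
    return rooted


# ---------------------------------------------------------------------------
# clades


def clades_of(tree: Tree, taxon_map: Optional[TaxonMap] = None) -> set[Clade]:
    """Non-trivial clades of a rooted tree, one per internal non-root node,
    each carrying that node's support."""
    if not tree.rooted:
        raise ValueError("clades_of requires a rooted tree")
    taxon_map = taxon_map or TaxonMap()
    clusters = tree.cluster_map()
    universe = taxon_map.map_set(tree.taxa())
    out: set[Clade] = set()
    for node in tree.internal_nodes(exclude_root=True):
        taxa = taxon_map.map_set(clusters[id(node)])
        clade = Clade(taxa, support=node.support)
        if not clade.is_trivial(universe):
            out.add(clade)
    return out


def restrict(clade: Clade, taxa: Iterable[str]) -> Optional[Clade]:
    """Intersect the clade with ``taxa``; support carried through.
    Returns None for an empty intersection."""
    inter = clade.taxa & frozenset(taxa)
    if not inter:
        return None
    return Clade(inter, support=clade.support)


def clades_conflict(x: Clade, y: Clade) -> bool:
    """Rooted-compatibility test: clades conflict iff they are neither
    nested nor disjoint (x∩y, x∖y, y∖x all non-empty)."""
    return bool(x.taxa & y.taxa) and bool(x.taxa - y.taxa) and bool(y.taxa - x.taxa)


# ---------------------------------------------------------------------------
# depth


def _farthest_leaf(tree: Tree, start: Node) -> tuple[Node, float]:
    # adjacency over the (undirected) tree with edge lengths
    dist = {id(start): 0.0}
    best = (start, 0.0)
    stack = [start]
    while stack:
        node = stack.pop()
        d = dist[id(node)]
        neighbors = list(node.children)
        if node.parent is not None:
            neighbors.append(node.parent)
        for nb in neighbors:
            if id(nb) in dist:
                continue
            edge = nb.length if nb.parent is node else node.length
            if edge is None:
                raise ValueError("missing branch length")
            dist[id(nb)] = d + edge
            stack.append(nb)
            if nb.is_leaf and dist[id(nb)] > best[1]:
                best = (nb, dist[id(nb)])
    return best


def tip_to_tip_depth(tree: Tree) -> float:
    """Maximum path length between any two leaves (the tree diameter).

    Requires branch lengths on every non-root edge.
    """
    leaves = tree.leaves()
    if len(leaves) < 2:
        return 0.0
    for node in tree.preorder():
        if node is not tree.root and node.length is None:
            raise ValueError("missing branch length")
    far, _ = _farthest_leaf(tree, leaves[0])
    _, diameter = _farthest_leaf(tree, far)
    return diameter


def root_to_tip_depth(tree: Tree) -> float:
    """Maximum root-to-leaf path length (alternative depth for rooted trees)."""
    depth = {id(tree.root): 0.0}
    best = 0.0
    for node in tree.preorder():
        if node is tree.root:
            continue
        if node.length is None:
            raise ValueError("missing branch length")
        depth[id(node)] = depth[id(node.parent)] + node.length
        if node.is_leaf:
            best = max(best, depth[id(node)])
    return best


def topology_signature(tree: Tree) -> frozenset[tuple[str, ...]]:
    """Label-based rooted topology key: the set of non-trivial clusters.

    Two rooted trees on the same taxa are topologically identical iff their
    signatures are equal.
    """
    clusters = tree.cluster_map()
    taxa = tree.taxa()
    out = set()
    for node in tree.internal_nodes(exclude_root=False):
        c = clusters[id(node)]
        if 1 < len(c):
            out.add(tuple(sorted(c)))
    out.add(tuple(sorted(taxa)))
    return frozenset(out)


def trees_isomorphic(a: Tree, b: Tree) -> bool:
    """Topology + labels equality for rooted representations."""
    return topology_signature(a) == topology_signature(b)
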