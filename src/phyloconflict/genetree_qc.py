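"""Gene-tree sanitation: branch-length outliers, low-support collapse,
leaf pruning, and outgroup-availability filtering."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .treemodel import (
    NonMonophyleticOutgroupError,
    NotRootableError,
    Node,
    Tree,
    reroot_on_outgroup,
    root_to_tip_depth,
    tip_to_tip_depth,
)

__all__ = [
    "OutlierThresholds",
    "FlaggedBranch",
    "detect_branch_outliers",
    "collapse_low_support",
    "prune_leaves",
    "filter_trees_with_outgroup",
]


@dataclass(frozen=True)
class OutlierThresholds:
    """Branch-length flag thresholds, as fractions of total tree depth,
    plus the support-collapse cutoff."""

    terminal_fraction: float = 0.25
    internal_fraction: float = 0.50
    outgroup_fraction: float = 0.75
    collapse_support: float = 33.0
    outgroups: frozenset[str] = frozenset()

    def __post_init__(self):
        for name in ("terminal_fraction", "internal_fraction", "outgroup_fraction"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if not (0 <= self.collapse_support <= 100):
            raise ValueError("collapse_support must be in [0, 100]")
        if not isinstance(self.outgroups, frozenset):
            object.__setattr__(self, "outgroups", frozenset(self.outgroups))


@dataclass(frozen=True)
class FlaggedBranch:
    branch_id: int
    branch_class: str  # terminal | internal | outgroup
    length: float
    depth_fraction: float
    leaf: Optional[str] = None  # set for pendant edges


def detect_branch_outliers(
    tree: Tree,
    cfg: OutlierThresholds = OutlierThresholds(),
    depth_mode: str = "tip_to_tip",
) -> list[FlaggedBranch]:
    """Flag branches longer than a class-specific fraction of tree depth.

    Classes: ``terminal`` (pendant edge of an ingroup leaf), ``outgroup``
    (pendant edge of an outgroup leaf, or any edge whose far side contains
    only outgroup taxa), else ``internal``. The outgroup class takes
    precedence when both apply. Depth defaults to the maximum tip-to-tip
    path length; ``depth_mode="root_to_tip"`` uses the rooted alternative.
    """
    if depth_mode == "tip_to_tip":
        depth = tip_to_tip_depth(tree)
    elif depth_mode == "root_to_tip":
        depth = root_to_tip_depth(tree)
    else:
        raise ValueError(f"unknown depth_mode {depth_mode!r}")
    if depth == 0:
        raise ValueError("degenerate tree: zero depth")

    clusters = tree.cluster_map()
    taxa = tree.taxa()
    outgroups = cfg.outgroups & taxa
    flagged = []
    for branch_id, node in enumerate(tree.preorder()):
        if node is tree.root or node.length is None:
            continue
        below = clusters[id(node)]
        above = taxa - below
        if outgroups and (below <= outgroups or above <= outgroups):
            cls = "outgroup"
            frac_limit = cfg.outgroup_fraction
        elif node.is_leaf:
            cls = "terminal"
            frac_limit = cfg.terminal_fraction
        else:
            cls = "internal"
            frac_limit = cfg.internal_fraction
        if node.length > frac_limit * depth:
            flagged.append(
                FlaggedBranch(
                    branch_id=branch_id,
                    branch_class=cls,
                    length=node.length,
                    depth_fraction=node.length / depth,
                    leaf=node.label if node.is_leaf else None,
                )
            )
    return flagged


def collapse_low_support(
    tree: Tree, cfg: OutlierThresholds = OutlierThresholds()
) -> Tree:
    """Contract every internal branch with support strictly below the
    cutoff into a polytomy. Absent support counts as 0 (collapsible); the
    contracted edge's length is discarded. Leaves are never removed."""
    out = tree.copy()
    changed = True
    while changed:
        changed = False
        for node in list(out.preorder()):
            if node.is_leaf or node is out.root or node.parent is None:
                continue
            support = node.support if node.support is not None else 0.0
            if support < cfg.collapse_support:
                parent = node.parent
                idx = parent.children.index(node)
                parent.children[idx : idx + 1] = node.children
                for child in node.children:
                    child.parent = parent
                changed = True
    return Tree(out.root, rooted=tree.rooted)


def prune_leaves(
    tree: Tree, leaves: Iterable[str], min_remaining: int = 3
) -> Tree:
    """Remove the listed leaves; suppress resulting unary nodes, summing
    branch lengths so surviving pairwise path lengths are unchanged.

    Errors if a listed leaf is absent or fewer than ``min_remaining``
    leaves would remain (lower it to 2 to allow two-leaf results).
    """
    drop = frozenset(leaves)
    taxa = tree.taxa()
    missing = drop - taxa
    if missing:
        raise ValueError(f"leaves not in tree: {sorted(missing)}")
    if len(taxa - drop) < min_remaining:
        raise ValueError(
            f"pruning would leave fewer than {min_remaining} leaves"
        )
    if not drop:
        return tree.copy()

    out = tree.copy()
    for leaf in [n for n in out.leaves() if n.label in drop]:
        leaf.parent.children.remove(leaf)
    # iteratively remove childless internals and suppress unary nodes
    changed = True
    root = out.root
    while changed:
        changed = False
        for node in list(root.preorder()):
            if node.is_leaf and node.label is None:
                node.parent.children.remove(node)
                changed = True
            elif not node.is_leaf and len(node.children) == 1:
                only = node.children[0]
                if node is root:
                    only.parent = None
                    if only.length is not None and node.length is not None:
                        only.length += node.length
                    root = only
                else:
                    if only.length is not None and node.length is not None:
                        only.length += node.length
                    elif node.length is not None:
                        only.length = node.length
                    idx = node.parent.children.index(node)
                    node.parent.children[idx] = only
                    only.parent = node.parent
                changed = True
    root.length = None  # a root carries no edge
    return Tree(root, rooted=tree.rooted)


@dataclass(frozen=True)
class ExcludedTree:
    index: int
    reason: str  # no_outgroup | non_monophyletic_outgroup


def filter_trees_with_outgroup(
    trees: Sequence[Tree], outgroups: Iterable[str]
) -> tuple[list[Tree], list[ExcludedTree]]:
    """Root each tree that contains at least one outgroup taxon; return the
    rooted subset plus the excluded trees with reasons."""
    outgroups = frozenset(outgroups)
    rooted, excluded = [], []
    for i, tree in enumerate(trees):
        try:
            rooted.append(reroot_on_outgroup(tree, outgroups))
        except NotRootableError:
            excluded.append(ExcludedTree(index=i, reason="no_outgroup"))
        except NonMonophyleticOutgroupError:
            excluded.append(
                ExcludedTree(index=i, reason="non_monophyletic_outgroup")
            )
    return rooted, excluded
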