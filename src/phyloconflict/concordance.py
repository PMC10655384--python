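"""Per-node concordance/conflict tallies of rooted gene trees against a
rooted species tree.

For each internal species-tree node the gene trees are classified four
ways: concordant, conflicting-with-the-top-alternative, other conflict, or
uninformative (missing taxa or support below the cutoff). Classification
works on taxon-restricted clades so gene trees with missing taxa still
contribute wherever they are informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .treemodel import (
    Clade,
    TaxonMap,
    Tree,
    clades_conflict,
    clades_of,
    restrict,
)

__all__ = [
    "ConcordanceConfig",
    "Classification",
    "NodeConcordance",
    "classify_gene_tree",
    "summarize_concordance",
    "pie_fractions",
    "annotate_species_tree",
]


@dataclass(frozen=True)
class ConcordanceConfig:
    """``min_support``: gene-tree clades below this support are ignored
    (they can neither support nor conflict); ``taxon_map`` folds accession
    labels onto species-tree tips before comparison."""

    min_support: float = 50.0
    taxon_map: TaxonMap = field(default_factory=TaxonMap)

    def __post_init__(self):
        if not (0 <= self.min_support <= 100):
            raise ValueError("min_support must be in [0, 100]")


@dataclass(frozen=True)
class Classification:
    kind: str  # concordant | conflict | uninformative
    conflicting_clade: Optional[Clade] = None


def _passes(support: Optional[float], min_support: float) -> bool:
    return (support if support is not None else 0.0) >= min_support


def _classify_against(
    species_clade: Clade,
    gene_taxa: frozenset[str],
    candidates: Sequence[Clade],
) -> Classification:
    r = restrict(species_clade, gene_taxa)
    if r is None or len(r.taxa) < 2 or len(gene_taxa - r.taxa) < 1:
        return Classification("uninformative")
    for clade in candidates:
        if clade.taxa == r.taxa:
            return Classification("concordant")
    conflicting = [c for c in candidates if clades_conflict(c, r)]
    if conflicting:
        best = min(
            conflicting,
            key=lambda c: (
                len(c.taxa ^ r.taxa),
                -(c.support if c.support is not None else 0.0),
                c.sort_key(),
            ),
        )
        return Classification("conflict", conflicting_clade=best)
    return Classification("uninformative")


def _gene_tree_candidates(
    gene_tree: Tree, cfg: ConcordanceConfig
) -> tuple[frozenset[str], list[Clade]]:
    """Mapped taxon set and support-passing clades of one rooted gene tree."""
    if not gene_tree.rooted:
        raise ValueError("concordance requires rooted gene trees")
    gene_taxa = cfg.taxon_map.map_set(gene_tree.taxa())
    candidates = [
        c
        for c in clades_of(gene_tree, taxon_map=cfg.taxon_map)
        if _passes(c.support, cfg.min_support)
    ]
    return gene_taxa, candidates


def classify_gene_tree(
    species_clade: Clade,
    gene_tree: Tree,
    cfg: ConcordanceConfig = ConcordanceConfig(),
) -> Classification:
    """Classify one rooted gene tree against one species-tree clade.

    Let R be the species clade restricted to the gene tree's (mapped)
    taxa. The tree is uninformative if R keeps fewer than 2 taxa or no
    taxon outside R remains. It is concordant if some gene-tree clade with
    support >= min_support equals R; conflicting if some such clade
    conflicts with R (reporting, among qualifying clades, the one with the
    smallest symmetric difference to R; ties broken by higher support then
    lexicographic taxon set); otherwise uninformative.
    """
    gene_taxa, candidates = _gene_tree_candidates(gene_tree, cfg)
    return _classify_against(species_clade, gene_taxa, candidates)


@dataclass
class NodeConcordance:
    """Four-way gene-tree tally for one species-tree node."""

    node_id: int
    clade: frozenset[str]
    concordant: int = 0
    top_alternative: Optional[frozenset[str]] = None
    top_alternative_count: int = 0
    other_conflict: int = 0
    uninformative: int = 0
    total: int = 0

    @property
    def conflicting(self) -> int:
        return self.top_alternative_count + self.other_conflict

    def check(self) -> None:
        s = (
            self.concordant
            + self.top_alternative_count
            + self.other_conflict
            + self.uninformative
        )
        if s != self.total:
            raise AssertionError(
                f"node {self.node_id}: counts {s} != total {self.total}"
            )


def species_tree_clades(
    species_tree: Tree, taxon_map: Optional[TaxonMap] = None
) -> list[tuple[int, Clade]]:
    """Stable (node_id, clade) pairs for internal non-root nodes, in
    preorder; node ids are preorder positions in the species tree."""
    if not species_tree.rooted:
        raise ValueError("species tree must be rooted")
    taxon_map = taxon_map or TaxonMap()
    clusters = species_tree.cluster_map()
    universe = taxon_map.map_set(species_tree.taxa())
    out = []
    for node_id, node in enumerate(species_tree.preorder()):
        if node.is_leaf or node is species_tree.root:
            continue
        taxa = taxon_map.map_set(clusters[id(node)])
        clade = Clade(taxa, support=node.support)
        if not clade.is_trivial(universe):
            out.append((node_id, clade))
    return out


def summarize_concordance(
    species_tree: Tree,
    gene_trees: Sequence[Tree],
    cfg: ConcordanceConfig = ConcordanceConfig(),
) -> list[NodeConcordance]:
    """Tally every rooted gene tree against every internal species-tree
    node. The top alternative is the modal conflicting clade (ties broken
    by lexicographically smallest taxon set, deterministically)."""
    if not gene_trees:
        raise ValueError("no gene trees supplied")
    prepared = [_gene_tree_candidates(gt, cfg) for gt in gene_trees]
    results = []
    for node_id, clade in species_tree_clades(species_tree, cfg.taxon_map):
        nc = NodeConcordance(node_id=node_id, clade=clade.taxa, total=len(gene_trees))
        conflict_counts: dict[frozenset[str], int] = {}
        for gene_taxa, candidates in prepared:
            cls = _classify_against(clade, gene_taxa, candidates)
            if cls.kind == "concordant":
                nc.concordant += 1
            elif cls.kind == "conflict":
                key = cls.conflicting_clade.taxa
                conflict_counts[key] = conflict_counts.get(key, 0) + 1
            else:
                nc.uninformative += 1
        if conflict_counts:
            top = min(
                conflict_counts.items(),
                key=lambda kv: (-kv[1], tuple(sorted(kv[0]))),
            )
            nc.top_alternative, nc.top_alternative_count = top[0], top[1]
            nc.other_conflict = sum(conflict_counts.values()) - top[1]
        nc.check()
        results.append(nc)
    return results


def pie_fractions(nc: NodeConcordance) -> tuple[float, float, float, float]:
    """(concordant, top-alternative, other-conflict, uninformative) / total."""
    if nc.total <= 0:
        raise ValueError("total must be positive")
    t = nc.total
    return (
        nc.concordant / t,
        nc.top_alternative_count / t,
        nc.other_conflict / t,
        nc.uninformative / t,
    )


def annotate_species_tree(species_tree: Tree, results: Sequence[NodeConcordance]) -> Tree:
    """Copy of the species tree with 'concordant/conflicting' node labels."""
    out = species_tree.copy()
    by_id = {nc.node_id: nc for nc in results}
    for node_id, node in enumerate(out.preorder()):
        if node_id in by_id and not node.is_leaf:
            nc = by_id[node_id]
            node.support = None
            node.label = f"{nc.concordant}/{nc.conflicting}"
    return out


def concordance_table_rows(results: Sequence[NodeConcordance]) -> list[dict]:
    rows = []
    for nc in results:
        rows.append(
            {
                "node_id": nc.node_id,
                "clade": ",".join(sorted(nc.clade)),
                "concordant": nc.concordant,
                "top_alternative_count": nc.top_alternative_count,
                "other_conflict": nc.other_conflict,
                "uninformative": nc.uninformative,
                "total": nc.total,
                "top_alternative": ",".join(sorted(nc.top_alternative))
                if nc.top_alternative
                else "",
            }
        )
    return rows
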