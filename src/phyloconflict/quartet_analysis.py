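"""Relative quartet-topology frequencies around focal branches and
per-group monophyly classification across gene trees."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .treemodel import Tree

__all__ = [
    "CladeQuartet",
    "QuartetFrequencies",
    "quartet_vote",
    "quartet_frequencies",
    "flag_polytomy",
    "monophyly_classify",
    "monophyly_matrix",
    "MONOPHYLY_CATEGORIES",
]

MONOPHYLY_CATEGORIES = (
    "strong_support",
    "weak_support",
    "weak_reject",
    "strong_reject",
    "no_data",
)


@dataclass(frozen=True)
class CladeQuartet:
    """Four named, disjoint taxon groups; T1 = G1G2|G3G4 is the
    species-tree resolution, T2 = G1G3|G2G4, T3 = G1G4|G2G3."""

    g1: frozenset[str]
    g2: frozenset[str]
    g3: frozenset[str]
    g4: frozenset[str]
    names: tuple[str, str, str, str] = ("G1", "G2", "G3", "G4")

    def __post_init__(self):
        groups = [frozenset(g) for g in (self.g1, self.g2, self.g3, self.g4)]
        for name, g in zip("g1 g2 g3 g4".split(), groups):
            if not g:
                raise ValueError(f"{name} is empty")
            object.__setattr__(self, name, g)
        for (i, a), (j, b) in itertools.combinations(enumerate(groups), 2):
            if a & b:
                raise ValueError(
                    f"groups {i + 1} and {j + 1} overlap: {sorted(a & b)}"
                )

    @property
    def groups(self) -> tuple[frozenset[str], ...]:
        return (self.g1, self.g2, self.g3, self.g4)


@dataclass
class QuartetFrequencies:
    counts: tuple[int, int, int]
    n_voting: int
    n_abstaining: int

    @property
    def frequencies(self) -> tuple[float, float, float]:
        if self.n_voting == 0:
            raise ValueError("no voting trees")
        return tuple(c / self.n_voting for c in self.counts)


def _induced_quartet_topology(
    clusters: Sequence[frozenset[str]], a: str, b: str, c: str, d: str
) -> Optional[int]:
    """Unrooted topology of four leaves: 1 for ab|cd, 2 for ac|bd,
    3 for ad|bc, None if unresolved (no edge splits them 2|2).

    ``clusters`` are the descendant-leaf sets of every node under an
    arbitrary rooting; rooting does not change the induced unrooted
    quartet.
    """
    four = (a, b, c, d)
    for cl in clusters:
        inside = [x for x in four if x in cl]
        if len(inside) == 2:
            pair = frozenset(inside)
            if pair == frozenset((a, b)) or pair == frozenset((c, d)):
                return 1
            if pair == frozenset((a, c)) or pair == frozenset((b, d)):
                return 2
            return 3
    return None


def quartet_vote(
    gene_tree: Tree,
    q: CladeQuartet,
    max_combinations: int = 500,
    seed: int = 0,
) -> Optional[int]:
    """Vote of one gene tree: 1, 2, or 3, or None (abstain).

    Abstains when a group has no representative in the tree. Otherwise all
    one-leaf-per-group combinations are enumerated (or ``max_combinations``
    sampled with a fixed seed when there are more), each induced unrooted
    quartet topology is read, and the majority topology wins; an exact tie
    for the top count abstains. Votes are computed on unrooted quartets,
    so the result is invariant to the gene tree's rooting.
    """
    taxa = gene_tree.taxa()
    reps = [sorted(g & taxa) for g in q.groups]
    if any(not r for r in reps):
        return None
    n_comb = 1
    for r in reps:
        n_comb *= len(r)
    if n_comb <= max_combinations:
        combos = list(itertools.product(*reps))
    else:
        rng = np.random.default_rng(seed)
        combos = [
            tuple(r[rng.integers(len(r))] for r in reps)
            for _ in range(max_combinations)
        ]
    clusters = list(gene_tree.cluster_map().values())
    tally = [0, 0, 0]
    for a, b, c, d in combos:
        topo = _induced_quartet_topology(clusters, a, b, c, d)
        if topo is not None:
            tally[topo - 1] += 1
    best = max(tally)
    if best == 0 or tally.count(best) > 1:
        return None
    return tally.index(best) + 1


def quartet_frequencies(
    gene_trees: Sequence[Tree],
    q: CladeQuartet,
    max_combinations: int = 500,
    seed: int = 0,
) -> QuartetFrequencies:
    """Counts and relative frequencies of the three resolutions over the
    non-abstaining gene trees."""
    counts = [0, 0, 0]
    abstain = 0
    for tree in gene_trees:
        vote = quartet_vote(tree, q, max_combinations=max_combinations, seed=seed)
        if vote is None:
            abstain += 1
        else:
            counts[vote - 1] += 1
    if sum(counts) == 0:
        raise ValueError("zero voting trees for this quartet")
    return QuartetFrequencies(
        counts=tuple(counts), n_voting=sum(counts), n_abstaining=abstain
    )


def flag_polytomy(
    freqs: QuartetFrequencies, epsilon: float = 0.05
) -> tuple[bool, Optional[int]]:
    """(polytomy?, dominant topology id or None).

    Dominant = argmax frequency provided it reaches 1/3; polytomy is
    flagged iff all three frequencies lie within +/- epsilon of 1/3. Both
    can hold at once and both are reported.
    """
    f = freqs.frequencies
    polytomy = all(abs(x - 1 / 3) <= epsilon for x in f)
    fmax = max(f)
    dominant = f.index(fmax) + 1 if fmax >= 1 / 3 else None
    return polytomy, dominant


# ---------------------------------------------------------------------------
# monophyly


def _split_conflicts_group(
    side: frozenset[str], group: frozenset[str], present: frozenset[str]
) -> bool:
    """Unrooted incompatibility of bipartition side|rest with group|rest:
    all four intersections non-empty."""
    other = present - side
    non_group = present - group
    return bool(
        (side & group)
        and (side & non_group)
        and (other & group)
        and (other & non_group)
    )


def monophyly_classify(
    gene_tree: Tree, group: Iterable[str], strong_threshold: float = 75.0
) -> str:
    """One of strong_support / weak_support / weak_reject / strong_reject /
    no_data for a named taxon group in one gene tree.

    Monophyly is judged in the unrooted sense: the group (restricted to
    the taxa present) is monophyletic iff some edge bipartition has
    exactly the present group members on one side. With fewer than two
    group members, or no non-group taxon, present the tree is no_data.
    """
    group = frozenset(group)
    present = gene_tree.taxa()
    g = group & present
    if len(g) < 2 or not (present - g):
        return "no_data"
    clusters = gene_tree.cluster_map()
    mono_edges = [
        node
        for node in gene_tree.preorder()
        if node is not gene_tree.root
        and (clusters[id(node)] == g or present - clusters[id(node)] == g)
    ]
    if mono_edges:
        support = max(
            (n.support for n in mono_edges if n.support is not None),
            default=0.0,
        )
        return "strong_support" if support >= strong_threshold else "weak_support"
    # not monophyletic: strong iff a well-supported bipartition conflicts
    for node in gene_tree.preorder():
        if node is gene_tree.root or node.is_leaf:
            continue
        support = node.support if node.support is not None else 0.0
        if support >= strong_threshold and _split_conflicts_group(
            clusters[id(node)], g, present
        ):
            return "strong_reject"
    return "weak_reject"


def monophyly_matrix(
    gene_trees: Sequence[Tree],
    groups: Mapping[str, Iterable[str]],
    strong_threshold: float = 75.0,
) -> dict[str, list[str]]:
    """group name -> per-gene-tree category list (one entry per tree)."""
    return {
        name: [
            monophyly_classify(t, taxa, strong_threshold=strong_threshold)
            for t in gene_trees
        ]
        for name, taxa in groups.items()
    }


def monophyly_totals(matrix: Mapping[str, Sequence[str]]) -> dict[str, dict[str, int]]:
    return {
        name: {cat: cats.count(cat) for cat in MONOPHYLY_CATEGORIES}
        for name, cats in matrix.items()
    }
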