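"""Synthetic inputs: multispecies-coalescent gene trees on a known species
tree (with taxon dropout and support noise) and toy codon fixtures with
planted, exactly assertable properties.

Species-tree branch lengths are in coalescent units. Within a species-tree
branch carrying k gene lineages, coalescences occur at rate k(k-1)/2 with
exponential waiting times; lineages surviving to the root branch coalesce
freely. With one sampled lineage per species, the probability that a
quartet around an internal branch of length t matches the species tree is
1 - (2/3)e^(-t), the other two resolutions (1/3)e^(-t) each.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .codon_align import Alignment
from .treemodel import Node, Tree, parse_newick

__all__ = [
    "SpeciesTreeModel",
    "SimConfig",
    "simulate_msc_gene_tree",
    "simulate_gene_tree_set",
    "expected_quartet_freqs",
    "make_anomaly_scenario",
    "make_balanced_quartet_model",
    "make_toy_gene_fixtures",
    "ToyGeneFixtures",
]

SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

_CODON_TABLE = None


def _codon_table() -> dict[str, str]:
    global _CODON_TABLE
    if _CODON_TABLE is None:
        from Bio.Seq import Seq

        _CODON_TABLE = {c: str(Seq(c).translate()) for c in SENSE_CODONS}
    return _CODON_TABLE


@dataclass
class SpeciesTreeModel:
    """Rooted binary species tree with coalescent-unit branch lengths."""

    tree: Tree

    def __post_init__(self):
        if not self.tree.rooted:
            raise ValueError("species tree model must be rooted")
        for node in self.tree.preorder():
            if node is self.tree.root:
                continue
            if node.length is None or node.length <= 0:
                raise ValueError("model branch lengths must be positive")
            if not node.is_leaf and len(node.children) != 2:
                raise ValueError("model must be binary")
        if len(self.tree.root.children) != 2:
            raise ValueError("model must be binary")

    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTreeModel":
        return cls(parse_newick(text))

    def taxa(self) -> frozenset[str]:
        return self.tree.taxa()


@dataclass(frozen=True)
class SimConfig:
    """Gene-tree set simulation settings. A fixed seed gives bit-identical
    output."""

    n_trees: int = 100
    dropout: float = 0.0
    support: tuple[float, float] = (100.0, 100.0)  # (lo, hi); lo == hi -> constant
    seed: int = 0
    length_scale: float = 1.0  # substitutions per coalescent unit

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        lo, hi = self.support
        if not (0 <= lo <= hi <= 100):
            raise ValueError("support range must satisfy 0 <= lo <= hi <= 100")
        if self.length_scale <= 0:
            raise ValueError("length_scale must be positive")


@dataclass
class _Lineage:
    node: Node
    time: float  # absolute time (coalescent units above the tips)


def _coalesce_in_branch(
    lineages: list[_Lineage],
    start: float,
    duration: float,
    rng: np.random.Generator,
) -> list[_Lineage]:
    """Coalesce within one species-tree branch spanning
    [start, start + duration]; ``duration`` may be inf. Lineage times below
    ``start`` are allowed (they entered in descendant branches) and yield
    branch lengths spanning the species boundary."""
    lineages = list(lineages)
    t = max([start] + [lin.time for lin in lineages])
    while len(lineages) >= 2:
        k = len(lineages)
        wait = rng.exponential(1.0 / (k * (k - 1) / 2.0))
        if t + wait - start > duration:
            break
        t += wait
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[int(i)], lineages[int(j)]
        parent = Node()
        for lin in (a, b):
            lin.node.length = t - lin.time
            parent.add_child(lin.node)
        lineages = [lin for n, lin in enumerate(lineages) if n not in (int(i), int(j))]
        lineages.append(_Lineage(parent, t))
    return lineages


def simulate_msc_gene_tree(
    model: SpeciesTreeModel, rng: np.random.Generator
) -> Tree:
    """Draw one gene tree under the multispecies coalescent.

    One lineage is sampled per species. Species-tree node times are taken
    as maximum distance above the tips, so ultrametric models behave as
    time trees. Gene-tree branch lengths come out in coalescent units.
    """
    stree = model.tree
    # node ages (time above tips)
    age: dict[int, float] = {}
    for node in stree.postorder():
        if node.is_leaf:
            age[id(node)] = 0.0
        else:
            age[id(node)] = max(
                age[id(c)] + (c.length or 0.0) for c in node.children
            )
    pending: dict[int, list[_Lineage]] = {}
    for node in stree.postorder():
        if node.is_leaf:
            lineages = [_Lineage(Node(label=node.label), 0.0)]
        else:
            lineages = []
            for child in node.children:
                lineages.extend(pending[id(child)])
        duration = math.inf if node is stree.root else node.length
        pending[id(node)] = _coalesce_in_branch(
            lineages, age[id(node)], duration, rng
        )
    (root_lineage,) = pending[id(stree.root)]
    root = root_lineage.node
    root.length = None
    return Tree(root, rooted=True)


def _assign_supports(tree: Tree, support: tuple[float, float], rng) -> None:
    lo, hi = support
    for node in tree.internal_nodes(exclude_root=True):
        node.support = lo if lo == hi else float(rng.uniform(lo, hi))


def simulate_gene_tree_set(model: SpeciesTreeModel, cfg: SimConfig) -> list[Tree]:
    """n independent MSC gene trees with per-leaf dropout and supports.

    Each leaf is independently dropped with probability ``dropout``; draws
    leaving fewer than 3 leaves are redrawn wholesale. Branch lengths are
    multiplied by ``length_scale``.
    """
    from .genetree_qc import prune_leaves

    rng = np.random.default_rng(cfg.seed)
    taxa = sorted(model.taxa())
    out = []
    while len(out) < cfg.n_trees:
        tree = simulate_msc_gene_tree(model, rng)
        drop = [t for t in taxa if rng.random() < cfg.dropout]
        if len(taxa) - len(drop) < 3:
            continue
        if drop:
            tree = prune_leaves(tree, drop)
        if cfg.length_scale != 1.0:
            for node in tree.preorder():
                if node.length is not None:
                    node.length *= cfg.length_scale
        _assign_supports(tree, cfg.support, rng)
        out.append(tree)
    return out


def expected_quartet_freqs(t: float) -> tuple[float, float, float]:
    """Closed-form MSC quartet resolution probabilities around an internal
    branch of ``t`` coalescent units: (1 - (2/3)e^-t, (1/3)e^-t, (1/3)e^-t)."""
    if t < 0:
        raise ValueError("t must be non-negative")
    minor = math.exp(-t) / 3.0
    return (1.0 - 2.0 * minor, minor, minor)


def make_anomaly_scenario(x: float, y: float) -> SpeciesTreeModel:
    """Rooted caterpillar (((A,B),C),D) with internal branches x (tipward,
    above the (A,B) node) and y (rootward, above the ((A,B),C) node),
    pendant lengths chosen to make the model ultrametric.

    For small x and y this sits in the anomaly zone: the modal gene-tree
    topology differs from the species topology.
    """
    if x <= 0 or y <= 0:
        raise ValueError("x and y must be positive")
    h = 1.0
    return SpeciesTreeModel.from_newick(
        f"(((A:{h},B:{h}):{x},C:{h + x}):{y},D:{h + x + y});"
    )


def make_balanced_quartet_model(t: float, pendant: float = 1.0) -> SpeciesTreeModel:
    """Rooted balanced quartet ((A,B),(C,D)) whose internal branches sum to
    ``t`` coalescent units between the two cherries."""
    if t <= 0:
        raise ValueError("t must be positive")
    half = t / 2.0
    return SpeciesTreeModel.from_newick(
        f"((A:{pendant},B:{pendant}):{half},"
        f"(C:{pendant + 0.0},D:{pendant}):{half});"
    )


# ---------------------------------------------------------------------------
# toy codon fixtures with planted truths


@dataclass
class ToyGeneFixtures:
    """Per-gene fixtures plus a manifest of exactly planted properties.

    ``manifest[gene]`` records: target_length (aa), short_samples (planted
    strictly below 25% of target), n_stop_codons, low_occupancy_codon_columns
    (0-based protein-alignment columns planted strictly below 50% row
    occupancy).
    """

    proteins: dict[str, dict[str, str]]  # gene -> sample -> unaligned protein
    cds: dict[str, dict[str, str]]  # gene -> sample -> unaligned CDS
    protein_alignments: dict[str, Alignment]
    target_lengths: dict[str, int]
    manifest: dict[str, dict]


def make_toy_gene_fixtures(
    genes: int = 3,
    samples: int = 4,
    target_length: int = 40,
    n_short: int = 1,
    n_stops: int = 2,
    n_low_occupancy_columns: int = 2,
    seed: int = 0,
) -> ToyGeneFixtures:
    """Build per-gene protein + CDS fixtures with exact planted counts.

    Per gene: ``n_short`` samples get sequences strictly below 25% of the
    target length; ``n_stops`` internal stop codons are planted across the
    full-length sequences; the protein alignment carries
    ``n_low_occupancy_columns`` inserted columns occupied by exactly one
    row (low occupancy for >= 3 rows). Everything is recorded in the
    manifest so filter outputs can be asserted exactly.
    """
    if samples < 2:
        raise ValueError("need at least 2 samples")
    if n_short >= samples:
        raise ValueError("n_short must leave at least one full-length sample")
    rng = np.random.default_rng(seed)
    table = _codon_table()
    gene_names = [f"g{i + 1}" for i in range(genes)]
    sample_names = [f"s{i + 1}" for i in range(samples)]
    short_len = max(1, int(math.floor(0.25 * target_length)) - 1)

    proteins: dict[str, dict[str, str]] = {}
    cds: dict[str, dict[str, str]] = {}
    alignments: dict[str, Alignment] = {}
    target_lengths: dict[str, int] = {}
    manifest: dict[str, dict] = {}

    for gene in gene_names:
        gene_prot: dict[str, str] = {}
        gene_cds: dict[str, str] = {}
        short_samples = sample_names[:n_short]
        for sample in sample_names:
            n_res = short_len if sample in short_samples else target_length
            codons = [
                SENSE_CODONS[int(rng.integers(len(SENSE_CODONS)))]
                for _ in range(n_res)
            ]
            gene_cds[sample] = "".join(codons)
            gene_prot[sample] = "".join(table[c] for c in codons)

        # plant internal stop codons in full-length sequences, round-robin
        full = [s for s in sample_names if s not in short_samples]
        stop_positions = []
        for k in range(n_stops):
            sample = full[k % len(full)]
            pos = 1 + (k // len(full))  # internal, deterministic
            if pos >= target_length - 1:
                raise ValueError("too many stops for the target length")
            seq = gene_cds[sample]
            gene_cds[sample] = seq[: 3 * pos] + "TAA" + seq[3 * pos + 3 :]
            p = gene_prot[sample]
            gene_prot[sample] = p[:pos] + "*" + p[pos + 1 :]
            stop_positions.append((sample, pos))

        # protein "alignment" of the full-length rows: identical lengths,
        # plus planted single-occupancy columns
        aln_rows = {s: list(gene_prot[s]) for s in full}
        width = target_length
        low_cols = []
        for k in range(n_low_occupancy_columns):
            col = min(2 + 2 * k, width)
            owner = full[k % len(full)]
            for s in full:
                aln_rows[s].insert(col, "A" if s == owner else "-")
            width += 1
            low_cols.append(col)
        alignment = Alignment(
            names=list(full),
            rows=["".join(aln_rows[s]) for s in full],
            alphabet="aa",
        )
        # keep CDS consistent with the alignment rows (owner rows gained a residue)
        for k, col in enumerate(low_cols):
            owner = full[k % len(full)]
            # residue 'A' was inserted at protein position = number of
            # residues before col in the owner row
            row = alignment.row(owner)
            res_index = sum(1 for c in row[:col] if c != "-")
            seq = gene_cds[owner]
            gene_cds[owner] = seq[: 3 * res_index] + "GCT" + seq[3 * res_index :]
            p = gene_prot[owner]
            gene_prot[owner] = p[:res_index] + "A" + p[res_index:]

        proteins[gene] = gene_prot
        cds[gene] = gene_cds
        alignments[gene] = alignment
        target_lengths[gene] = target_length
        manifest[gene] = {
            "target_length": target_length,
            "short_samples": list(short_samples),
            "short_length": short_len,
            "n_stop_codons": n_stops,
            "stop_positions": stop_positions,
            "low_occupancy_columns": low_cols,
        }
    return ToyGeneFixtures(
        proteins=proteins,
        cds=cds,
        protein_alignments=alignments,
        target_lengths=target_lengths,
        manifest=manifest,
    )
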