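"""Configuration-driven driver chaining all stages end-to-end.

Alignment and tree inference are external hand-off points: the pipeline
consumes aligned proteins (plus unaligned CDS) and pre-built gene trees,
and never shells out to inference binaries. Every filter decision is
logged with its rule and threshold, and a consolidated JSON-able report
tracks counts through each stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import codon_align as ca
from . import concordance as cc
from . import genetree_qc as gq
from . import quartet_analysis as qa
from . import seq_qc as sq
from . import supermatrix as sm
from .treemodel import TaxonMap, parse_newick, read_newick_file, write_newick

logger = logging.getLogger("phyloconflict")

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; message names the stage and offending record."""


@dataclass
class RunConfig:
    """All inputs, outputs, and thresholds for one pipeline run."""

    # inputs
    protein_alignment_dir: Optional[str] = None  # per-gene <gene>.faa
    cds_dir: Optional[str] = None  # per-gene <gene>.fna (unaligned)
    target_lengths_tsv: Optional[str] = None  # gene<TAB>length (aa)
    gene_trees: Optional[str] = None  # one newick per line
    species_tree: Optional[str] = None  # newick
    outgroups: tuple[str, ...] = ()
    taxon_map_tsv: Optional[str] = None
    genus_groups: dict[str, list[str]] = field(default_factory=dict)
    # thresholds (module defaults)
    min_length_fraction: float = 0.25
    min_sequences_per_gene: int = 15
    trim_min_fraction: float = 0.5
    trim_mode: str = "auto"
    terminal_fraction: float = 0.25
    internal_fraction: float = 0.50
    outgroup_fraction: float = 0.75
    collapse_support: float = 33.0
    min_support: float = 50.0
    strong_threshold: float = 75.0
    seed: int = 0
    # output
    out_dir: str = "pipeline_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "outgroups" in raw:
            raw["outgroups"] = tuple(raw["outgroups"])
        return cls(**raw)


def _read_target_lengths(path) -> dict[str, int]:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, length = line.split("\t")[:2]
            out[gene] = int(length)
    return out


def _stage(name: str):
    logger.info("stage: %s", name)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute seq_qc -> codon threading/trimming -> gene-tree QC ->
    rooting -> concordance (+ quartets/monophyly) -> supermatrix.

    Returns the consolidated report (also written to ``report.json``).
    Stages whose inputs are not configured are skipped and noted.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": [], "counts": {}}
    taxon_map = (
        TaxonMap.from_tsv(cfg.taxon_map_tsv) if cfg.taxon_map_tsv else TaxonMap()
    )

    trimmed: dict[str, ca.Alignment] = {}
    if cfg.protein_alignment_dir:
        _stage("seq_qc")
        if not cfg.target_lengths_tsv:
            raise PipelineError("seq_qc: target_lengths_tsv is required")
        targets = _read_target_lengths(cfg.target_lengths_tsv)
        fcfg = sq.FilterConfig(
            min_length_fraction=cfg.min_length_fraction,
            min_sequences_per_gene=cfg.min_sequences_per_gene,
        )
        prot_dir = Path(cfg.protein_alignment_dir)
        genes: dict[str, dict[str, str]] = {}
        for path in sorted(prot_dir.glob("*.faa")):
            genes[path.stem] = ca.read_fasta_dict(path)
        if not genes:
            raise PipelineError(f"seq_qc: no .faa files in {prot_dir}")
        unknown = set(genes) - set(targets)
        if unknown:
            raise PipelineError(
                f"seq_qc: genes without target lengths: {sorted(unknown)}"
            )
        recovery = sq.build_recovery_matrix(genes, targets)
        recovery.to_tsv(out_dir / "recovery_matrix.tsv")

        filter_rows = []
        retained_genes: dict[str, dict[str, str]] = {}
        n_removed_seqs = 0
        for gene, seqs in genes.items():
            retained, removed = sq.filter_short_sequences(seqs, targets[gene], fcfg)
            n_removed_seqs += len(removed)
            for row in sq.filter_report_rows(gene, targets[gene], retained, removed):
                row["rule"] = f"length < {cfg.min_length_fraction} * target"
                filter_rows.append(row)
            if retained:
                retained_genes[gene] = retained
        kept_genes, dropped_genes = sq.drop_sparse_genes(retained_genes, fcfg)
        pd.DataFrame(filter_rows).to_csv(
            out_dir / "sequence_filter_report.tsv", sep="\t", index=False
        )
        report["counts"]["input_genes"] = len(genes)
        report["counts"]["sequences_removed_short"] = n_removed_seqs
        report["counts"]["genes_dropped_sparse"] = len(dropped_genes)
        report["counts"]["genes_after_seq_qc"] = len(kept_genes)
        report["stages"].append("seq_qc")
        logger.info(
            "seq_qc: removed %d short sequences; dropped %d sparse genes",
            n_removed_seqs,
            len(dropped_genes),
        )

        _stage("codon_align")
        if not cfg.cds_dir:
            raise PipelineError("codon_align: cds_dir is required")
        cds_dir = Path(cfg.cds_dir)
        thread_errors = []
        trim_rows = []
        for gene, seqs in kept_genes.items():
            masked = {s: ca.mask_stop_codons(v) for s, v in seqs.items()}
            prot_aln = ca.Alignment.from_dict(masked, alphabet="aa")
            cds_path = cds_dir / f"{gene}.fna"
            if not cds_path.exists():
                raise PipelineError(f"codon_align: missing CDS file {cds_path}")
            cds = ca.read_fasta_dict(cds_path)
            cds = {s: v for s, v in cds.items() if s in masked}
            codon_aln, errs = ca.thread_codons(prot_aln, cds)
            thread_errors.extend((gene, str(e)) for e in errs)
            trimmed_aln, kept_cols = ca.trim_low_occupancy_columns(
                codon_aln, min_fraction=cfg.trim_min_fraction, mode=cfg.trim_mode
            )
            for row in ca.trim_report_rows(kept_cols, codon_aln.n_columns):
                row["gene"] = gene
                trim_rows.append(row)
            trimmed[gene] = trimmed_aln
            ca.write_fasta(trimmed_aln.to_dict(), out_dir / f"{gene}.trimmed.fna")
        pd.DataFrame(trim_rows).to_csv(
            out_dir / "trim_report.tsv", sep="\t", index=False
        )
        report["counts"]["threading_errors"] = len(thread_errors)
        report["counts"]["genes_threaded"] = len(trimmed)
        report["stages"].append("codon_align")

    rooted: list = []
    if cfg.gene_trees:
        _stage("genetree_qc")
        trees = read_newick_file(cfg.gene_trees)
        if not trees:
            raise PipelineError(f"genetree_qc: no trees in {cfg.gene_trees}")
        thresholds = gq.OutlierThresholds(
            terminal_fraction=cfg.terminal_fraction,
            internal_fraction=cfg.internal_fraction,
            outgroup_fraction=cfg.outgroup_fraction,
            collapse_support=cfg.collapse_support,
            outgroups=frozenset(cfg.outgroups),
        )
        outlier_rows = []
        for i, tree in enumerate(trees):
            try:
                for fb in gq.detect_branch_outliers(tree, thresholds):
                    outlier_rows.append(
                        {
                            "tree": i,
                            "branch_id": fb.branch_id,
                            "class": fb.branch_class,
                            "length": fb.length,
                            "depth_fraction": fb.depth_fraction,
                            "leaf": fb.leaf or "",
                        }
                    )
            except ValueError as exc:
                raise PipelineError(f"genetree_qc: tree {i}: {exc}") from exc
        pd.DataFrame(outlier_rows).to_csv(
            out_dir / "branch_outliers.tsv", sep="\t", index=False
        )
        collapsed = [gq.collapse_low_support(t, thresholds) for t in trees]
        report["counts"]["input_gene_trees"] = len(trees)
        report["counts"]["trees_with_outlier_branches"] = len(
            {r["tree"] for r in outlier_rows}
        )
        report["stages"].append("genetree_qc")

        _stage("rooting")
        if cfg.outgroups:
            rooted, excluded = gq.filter_trees_with_outgroup(
                collapsed, cfg.outgroups
            )
            pd.DataFrame(
                [{"tree": e.index, "reason": e.reason} for e in excluded]
            ).to_csv(out_dir / "rooting_exclusions.tsv", sep="\t", index=False)
            with open(out_dir / "rooted_gene_trees.nwk", "w") as fh:
                for t in rooted:
                    fh.write(write_newick(t) + "\n")
            report["counts"]["rooted_gene_trees"] = len(rooted)
            report["counts"]["trees_excluded_rooting"] = len(excluded)
            report["stages"].append("rooting")

    if cfg.species_tree and rooted:
        _stage("concordance")
        species_path = Path(cfg.species_tree)
        if not species_path.exists():
            raise PipelineError(
                f"concordance: species tree file not found: {species_path}"
            )
        species = parse_newick(species_path.read_text().strip())
        if not species.rooted:
            try:
                from .treemodel import reroot_on_outgroup

                species = reroot_on_outgroup(species, cfg.outgroups)
            except ValueError as exc:
                raise PipelineError(f"concordance: species tree: {exc}") from exc
        ccfg = cc.ConcordanceConfig(
            min_support=cfg.min_support, taxon_map=taxon_map
        )
        results = cc.summarize_concordance(species, rooted, ccfg)
        pd.DataFrame(cc.concordance_table_rows(results)).to_csv(
            out_dir / "concordance.tsv", sep="\t", index=False
        )
        annotated = cc.annotate_species_tree(species, results)
        (out_dir / "species_tree_annotated.nwk").write_text(
            write_newick(annotated) + "\n"
        )
        report["counts"]["species_tree_nodes"] = len(results)
        report["concordance"] = {
            str(nc.node_id): [
                nc.concordant,
                nc.top_alternative_count,
                nc.other_conflict,
                nc.uninformative,
            ]
            for nc in results
        }
        report["stages"].append("concordance")
    elif cfg.species_tree and not cfg.gene_trees:
        raise PipelineError("concordance: species tree given but no gene trees")

    if cfg.genus_groups and cfg.gene_trees:
        _stage("monophyly")
        matrix = qa.monophyly_matrix(
            rooted or read_newick_file(cfg.gene_trees),
            {k: frozenset(v) for k, v in cfg.genus_groups.items()},
            strong_threshold=cfg.strong_threshold,
        )
        totals = qa.monophyly_totals(matrix)
        pd.DataFrame(totals).T.to_csv(out_dir / "monophyly.tsv", sep="\t")
        report["monophyly"] = totals
        report["stages"].append("monophyly")

    if trimmed:
        _stage("supermatrix")
        samples = sorted({s for aln in trimmed.values() for s in aln.names})
        matrix, scheme = sm.concatenate(dict(sorted(trimmed.items())), samples)
        ca.write_fasta(matrix.to_dict(), out_dir / "supermatrix.fasta")
        (out_dir / "partitions.txt").write_text(sm.write_partition_file(scheme))
        stats = sm.matrix_stats(matrix)
        pd.DataFrame(
            [
                {
                    "n_samples": stats.n_samples,
                    "n_columns": stats.n_columns,
                    "variable_sites": stats.variable_sites,
                    "gap_percent": round(stats.gap_percent, 6),
                }
            ]
        ).to_csv(out_dir / "matrix_stats.tsv", sep="\t", index=False)
        report["matrix_stats"] = {
            "n_samples": stats.n_samples,
            "n_columns": stats.n_columns,
            "variable_sites": stats.variable_sites,
            "gap_percent": round(stats.gap_percent, 6),
        }
        report["stages"].append("supermatrix")

    report_text = json.dumps(report, indent=2, sort_keys=True)
    (out_dir / "report.json").write_text(report_text + "\n")
    return report
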