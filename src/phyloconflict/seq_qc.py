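"""Target-recovery accounting and post-assembly sequence/gene filters.

Lengths are always counted on ungapped residues so that filtering is
invariant to alignment state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

__all__ = [
    "FilterConfig",
    "RecoveryMatrix",
    "build_recovery_matrix",
    "filter_short_sequences",
    "drop_sparse_genes",
    "build_chimeric_target",
    "ungapped_length",
]

GAP_CHARS = "-?"


def ungapped_length(seq: str) -> int:
    return sum(1 for c in seq if c not in GAP_CHARS)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the short-sequence and sparse-gene filters.

    A sequence is removed iff its ungapped length is strictly below
    ``min_length_fraction`` of the target length; a gene is dropped iff it
    holds strictly fewer than ``min_sequences_per_gene`` sequences.
    """

    min_length_fraction: float = 0.25
    min_sequences_per_gene: int = 15

    def __post_init__(self):
        if not (0 < self.min_length_fraction <= 1):
            raise ValueError("min_length_fraction must be in (0, 1]")
        if self.min_sequences_per_gene < 2:
            raise ValueError("min_sequences_per_gene must be >= 2")


@dataclass
class RecoveryMatrix:
    """Samples x genes recovered-fraction table plus per-sample gene counts."""

    fractions: pd.DataFrame  # index: samples, columns: genes
    gene_counts: pd.Series  # index: samples

    def to_tsv(self, path) -> None:
        self.fractions.to_csv(path, sep="\t", float_format="%.6g")


def build_recovery_matrix(
    per_gene_sequences: Mapping[str, Mapping[str, str]],
    target_lengths: Mapping[str, int],
) -> RecoveryMatrix:
    """Recovered fraction = ungapped sequence length / target length.

    A fraction of 0 means the gene is absent for that sample; per-sample
    gene counts tally genes with fraction > 0.
    """
    unknown = set(per_gene_sequences) - set(target_lengths)
    if unknown:
        raise KeyError(
            f"genes without a target length: {sorted(unknown)}"
        )
    for gene, tl in target_lengths.items():
        if tl <= 0:
            raise ValueError(f"non-positive target length for gene {gene!r}")
    genes = sorted(per_gene_sequences)
    samples = sorted({s for g in genes for s in per_gene_sequences[g]})
    frame = pd.DataFrame(0.0, index=samples, columns=genes)
    for gene in genes:
        tl = target_lengths[gene]
        for sample, seq in per_gene_sequences[gene].items():
            frame.loc[sample, gene] = ungapped_length(seq) / tl
    counts = (frame > 0).sum(axis=1) if genes else pd.Series(dtype=int)
    return RecoveryMatrix(fractions=frame, gene_counts=counts)


def filter_short_sequences(
    gene_sequences: Mapping[str, str],
    target_length: int,
    cfg: FilterConfig = FilterConfig(),
) -> tuple[dict[str, str], dict[str, str]]:
    """Split sequences of one gene into (retained, removed).

    Removal rule: ungapped length < min_length_fraction * target_length,
    strictly — a sequence at exactly the threshold is retained.
    """
    if target_length <= 0:
        raise ValueError("target_length must be positive")
    cutoff = cfg.min_length_fraction * target_length
    retained, removed = {}, {}
    for sample, seq in gene_sequences.items():
        if ungapped_length(seq) < cutoff:
            removed[sample] = seq
        else:
            retained[sample] = seq
    return retained, removed


def drop_sparse_genes(
    genes: Mapping[str, Mapping[str, str]],
    cfg: FilterConfig = FilterConfig(),
) -> tuple[dict[str, Mapping[str, str]], dict[str, Mapping[str, str]]]:
    """Split genes into (retained, dropped) by sequence count.

    A gene is dropped iff it contains < min_sequences_per_gene sequences.
    """
    retained, dropped = {}, {}
    for gene, seqs in genes.items():
        if len(seqs) < cfg.min_sequences_per_gene:
            dropped[gene] = seqs
        else:
            retained[gene] = seqs
    return retained, dropped


def build_chimeric_target(ref_a: str, ref_b: str) -> str:
    """Merge two aligned reference sequences into one gap-free chimera.

    Inputs are the two rows of a pairwise alignment (equal length). Per
    column the residue of ``ref_a`` is emitted when present, else that of
    ``ref_b``; columns gapped in both are skipped. The preference for
    ``ref_a`` is arbitrary but deterministic.
    """
    if len(ref_a) != len(ref_b):
        raise ValueError(
            f"aligned references differ in length ({len(ref_a)} vs {len(ref_b)})"
        )
    out = []
    for a, b in zip(ref_a, ref_b):
        if a not in GAP_CHARS:
            out.append(a)
        elif b not in GAP_CHARS:
            out.append(b)
    return "".join(out)


def filter_report_rows(
    gene: str,
    target_length: int,
    retained: Mapping[str, str],
    removed: Mapping[str, str],
) -> list[dict]:
    """Rows for the TSV filter report (gene, sample, length, target, action)."""
    rows = []
    for action, bucket in (("retained", retained), ("removed", removed)):
        for sample in sorted(bucket):
            rows.append(
                {
                    "gene": gene,
                    "sample": sample,
                    "length": ungapped_length(bucket[sample]),
                    "target_length": target_length,
                    "action": action,
                }
            )
    return rows
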