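"""Concatenation of gene alignments into a partitioned supermatrix, plus
matrix statistics and RAxML-style partition output."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .codon_align import Alignment

__all__ = [
    "Partition",
    "PartitionScheme",
    "MatrixStats",
    "concatenate",
    "de_concatenate",
    "matrix_stats",
    "write_partition_file",
]

GAP_CHARS = frozenset("-?")
DNA_UNAMBIGUOUS = frozenset("ACGTU")
AA_UNAMBIGUOUS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class Partition:
    """1-based inclusive column range with optional codon stride."""

    name: str
    gene: str
    codon_position: Optional[int]  # 1..3, or None for an unstrided block
    start: int
    end: int
    stride: int = 1

    def columns(self) -> range:
        # 0-based column indices covered by this partition
        return range(self.start - 1, self.end, self.stride)


@dataclass
class PartitionScheme:
    partitions: list[Partition]
    gene_spans: dict[str, tuple[int, int]]  # gene -> (start, end), 1-based

    def validate(self, n_columns: int) -> None:
        seen = np.zeros(n_columns, dtype=int)
        for p in self.partitions:
            for col in p.columns():
                seen[col] += 1
        if not (seen == 1).all():
            bad = np.flatnonzero(seen != 1)[:5] + 1
            raise ValueError(
                f"partition scheme does not tile columns exactly once "
                f"(first offenders, 1-based: {bad.tolist()})"
            )


@dataclass(frozen=True)
class MatrixStats:
    n_samples: int
    n_columns: int
    variable_sites: int
    gap_percent: float


def concatenate(
    alignments: Mapping[str, Alignment],
    samples: Sequence[str],
) -> tuple[Alignment, PartitionScheme]:
    """Concatenate per-gene alignments over an ordered sample universe.

    Samples absent from a gene are filled with '-' across that gene's
    columns. Columns are laid out gene by gene in the mapping's key order
    (sort the mapping first for a canonical layout). Each gene whose width
    is divisible by 3 contributes three codon-position partitions with
    stride 3; other widths contribute one unstrided partition.
    """
    samples = list(samples)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample labels in universe")
    rows = {s: [] for s in samples}
    partitions: list[Partition] = []
    gene_spans: dict[str, tuple[int, int]] = {}
    offset = 0
    for gene, aln in alignments.items():
        extra = set(aln.names) - set(samples)
        if extra:
            raise ValueError(
                f"gene {gene!r} has labels outside the sample universe: "
                f"{sorted(extra)}"
            )
        width = aln.n_columns
        seqs = aln.to_dict()
        blank = "-" * width
        for s in samples:
            rows[s].append(seqs.get(s, blank))
        start, end = offset + 1, offset + width
        gene_spans[gene] = (start, end)
        if width % 3 == 0 and width > 0:
            for pos in (1, 2, 3):
                partitions.append(
                    Partition(
                        name=f"{gene}_codon{pos}",
                        gene=gene,
                        codon_position=pos,
                        start=start + pos - 1,
                        end=end,
                        stride=3,
                    )
                )
        elif width > 0:
            partitions.append(
                Partition(
                    name=gene, gene=gene, codon_position=None, start=start, end=end
                )
            )
        offset = end
    matrix = Alignment(
        names=samples,
        rows=["".join(rows[s]) for s in samples],
        alphabet=next(iter(alignments.values())).alphabet if alignments else "nt",
    )
    scheme = PartitionScheme(partitions=partitions, gene_spans=gene_spans)
    if matrix.n_columns:
        scheme.validate(matrix.n_columns)
    return matrix, scheme


def de_concatenate(
    matrix: Alignment, scheme: PartitionScheme
) -> dict[str, Alignment]:
    """Slice the supermatrix back into per-gene alignments (absent samples
    appear as all-gap rows)."""
    out = {}
    for gene, (start, end) in scheme.gene_spans.items():
        rows = [r[start - 1 : end] for r in matrix.rows]
        out[gene] = Alignment(list(matrix.names), rows, matrix.alphabet)
    return out


def matrix_stats(
    alignment: Alignment, count_ambiguous: bool = False
) -> MatrixStats:
    """Sample/column counts, variable sites, and gap percentage.

    A variable site is a column with >= 2 distinct unambiguous residues;
    gaps ('-', '?') never count and, unless ``count_ambiguous``, neither do
    ambiguity codes (anything outside ACGTU for nucleotide data, outside
    the 20 standard letters for amino acids). Gap percent counts '-'/'?'
    cells over all cells.
    """
    if alignment.n_rows == 0 or alignment.n_columns == 0:
        raise ValueError("empty alignment")
    arr = np.frombuffer(
        "".join(r.upper() for r in alignment.rows).encode("ascii"), dtype="S1"
    ).reshape(alignment.n_rows, alignment.n_columns)
    gap_mask = (arr == b"-") | (arr == b"?")
    gap_percent = float(100.0 * gap_mask.sum() / arr.size)

    if count_ambiguous:
        valid = ~gap_mask
    else:
        residues = (
            DNA_UNAMBIGUOUS if alignment.alphabet == "nt" else AA_UNAMBIGUOUS
        )
        valid = np.isin(arr, [c.encode() for c in sorted(residues)])
    # count distinct valid residues per column
    variable = 0
    codes = np.where(valid, arr.view(np.uint8), 0)
    for col in range(alignment.n_columns):
        col_codes = codes[:, col]
        distinct = np.unique(col_codes[col_codes != 0])
        if distinct.size >= 2:
            variable += 1
    return MatrixStats(
        n_samples=alignment.n_rows,
        n_columns=alignment.n_columns,
        variable_sites=variable,
        gap_percent=gap_percent,
    )


def write_partition_file(scheme: PartitionScheme, datatype: str = "DNA") -> str:
    """RAxML-format partition text: ``DNA, name = start-end\\3`` per line.

    Output is byte-stable across runs for the same scheme.
    """
    lines = []
    for p in scheme.partitions:
        suffix = f"\\{p.stride}" if p.stride != 1 else ""
        lines.append(f"{datatype}, {p.name} = {p.start}-{p.end}{suffix}")
    return "\n".join(lines) + ("\n" if lines else "")
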