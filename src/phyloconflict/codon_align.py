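"""Stop-codon masking, protein-guided codon threading, and occupancy trimming."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

__all__ = [
    "Alignment",
    "ThreadingError",
    "mask_stop_codons",
    "thread_codons",
    "trim_low_occupancy_columns",
    "read_fasta",
    "write_fasta",
]

GAP_CHARS = {"-", "?"}
STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class Alignment:
    """Ordered multiple sequence alignment.

    ``alphabet`` is "aa" or "nt"; all rows must have equal length and
    nucleotide codon alignments a length divisible by 3.
    """

    names: list[str]
    rows: list[str]
    alphabet: str = "nt"

    def __post_init__(self):
        if len(self.names) != len(self.rows):
            raise ValueError("names/rows length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate row labels")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"unequal row lengths: {sorted(widths)}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, name: str) -> str:
        return self.rows[self.names.index(name)]

    def items(self):
        return zip(self.names, self.rows)

    @classmethod
    def from_dict(cls, seqs: Mapping[str, str], alphabet: str = "nt") -> "Alignment":
        names = list(seqs)
        return cls(names=names, rows=[seqs[n] for n in names], alphabet=alphabet)

    def to_dict(self) -> dict[str, str]:
        return dict(self.items())


class ThreadingError(ValueError):
    """CDS/protein length mismatch for one row."""

    def __init__(self, sample: str, cds_len: int, protein_len: int):
        super().__init__(
            f"sample {sample!r}: ungapped CDS length {cds_len} does not match "
            f"3 x ungapped protein length {protein_len}"
        )
        self.sample = sample
        self.cds_len = cds_len
        self.protein_len = protein_len


def mask_stop_codons(protein: str) -> str:
    """Replace every '*' with 'X'; length unchanged."""
    return protein.replace("*", "X")


def _ungapped(seq: str) -> str:
    return "".join(c for c in seq if c not in GAP_CHARS)


def thread_codons(
    protein_alignment: Alignment,
    cds: Mapping[str, str],
) -> tuple[Alignment, list[ThreadingError]]:
    """Map unaligned CDS onto a protein alignment, codon per residue.

    Each amino-acid column becomes one codon column ('-' -> '---'), so the
    output has 3x the protein alignment's columns. A terminal stop codon in
    the CDS is stripped first when the protein row lacks a terminal '*'/'X'
    (pal2nal-like tolerance for the common off-by-one-codon mismatch).

    Rows whose CDS length still mismatches are excluded and reported in the
    returned error list; the remaining rows proceed.
    """
    if protein_alignment.alphabet != "aa":
        raise ValueError("protein_alignment must have alphabet 'aa'")
    out_names: list[str] = []
    out_rows: list[str] = []
    errors: list[ThreadingError] = []
    for name, prot_row in protein_alignment.items():
        if name not in cds:
            errors.append(ThreadingError(name, 0, len(_ungapped(prot_row))))
            continue
        nt = _ungapped(cds[name]).upper()
        residues = _ungapped(prot_row)
        if (
            len(nt) == 3 * len(residues) + 3
            and nt[-3:] in STOP_CODONS
            and (not residues or residues[-1] not in "*X")
        ):
            nt = nt[:-3]
        if len(nt) != 3 * len(residues):
            errors.append(ThreadingError(name, len(nt), len(residues)))
            continue
        codons = iter(nt[i : i + 3] for i in range(0, len(nt), 3))
        threaded = []
        for aa in prot_row:
            if aa in GAP_CHARS:
                threaded.append("---")
            else:
                threaded.append(next(codons))
        out_names.append(name)
        out_rows.append("".join(threaded))
    return Alignment(out_names, out_rows, alphabet="nt"), errors


def _column_occupancy(rows: list[str], col: int) -> float:
    occupied = sum(1 for r in rows if r[col] not in GAP_CHARS)
    return occupied / len(rows)


def _codon_occupancy(rows: list[str], start: int) -> float:
    # a row occupies a codon triple if any of its three cells is a residue
    occupied = sum(
        1
        for r in rows
        if any(r[start + k] not in GAP_CHARS for k in range(3))
    )
    return occupied / len(rows)


def trim_low_occupancy_columns(
    alignment: Alignment,
    min_fraction: float = 0.5,
    mode: str = "auto",
) -> tuple[Alignment, list[int]]:
    """Remove columns represented by fewer than ``min_fraction`` of rows.

    Removal is strict: a column at exactly the threshold is kept. Only '-'
    and '?' count as gaps; ambiguity codes ('N', 'X') count as occupied.

    ``mode``:
      * ``"codon"``  - occupancy judged per codon triple, triples removed
        atomically (preserves reading frame);
      * ``"column"`` - plain per-column trimming;
      * ``"auto"``   - codon mode for nucleotide alignments whose width is
        divisible by 3, column mode otherwise.

    Returns the trimmed alignment and the kept original column indices
    (new coordinate -> old coordinate).
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    if mode not in ("auto", "codon", "column"):
        raise ValueError(f"unknown trim mode {mode!r}")
    if mode == "auto":
        mode = (
            "codon"
            if alignment.alphabet == "nt" and alignment.n_columns % 3 == 0
            else "column"
        )
    if alignment.n_rows == 0 or alignment.n_columns == 0:
        return alignment, list(range(alignment.n_columns))

    rows = alignment.rows
    kept: list[int] = []
    if mode == "codon":
        if alignment.n_columns % 3 != 0:
            raise ValueError("codon-mode trimming needs width divisible by 3")
        for start in range(0, alignment.n_columns, 3):
            if _codon_occupancy(rows, start) >= min_fraction:
                kept.extend((start, start + 1, start + 2))
    else:
        for col in range(alignment.n_columns):
            if _column_occupancy(rows, col) >= min_fraction:
                kept.append(col)
    new_rows = ["".join(r[c] for c in kept) for r in rows]
    return Alignment(list(alignment.names), new_rows, alignment.alphabet), kept


def trim_report_rows(kept: list[int], n_columns: int) -> list[dict]:
    """Rows for the TSV trim report: contiguous old-column ranges + action."""
    kept_set = set(kept)
    rows = []
    start = 0
    while start < n_columns:
        action = "kept" if start in kept_set else "removed"
        end = start
        while end + 1 < n_columns and ((end + 1) in kept_set) == (start in kept_set):
            end += 1
        rows.append({"start": start + 1, "end": end + 1, "action": action})
        start = end + 1
    return rows


# ---------------------------------------------------------------------------
# FASTA I/O (thin wrappers; Biopython backs the parsing)


def read_fasta(path, alphabet: str = "nt") -> Alignment:
    from Bio import SeqIO

    names, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        rows.append(str(rec.seq))
    return Alignment(names, rows, alphabet=alphabet)


def read_fasta_dict(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs, path) -> None:
    """Write a mapping or Alignment to FASTA (60-column wrap)."""
    items = seqs.items() if hasattr(seqs, "items") else seqs
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
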