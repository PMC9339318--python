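"""Per-element multi-species alignments and their text-format I/O.

One genomic element (CNEE or gene) is one aligned multi-FASTA file whose
record ids are tip names. Coordinates follow BED conventions (0-based,
half-open). ``N`` and ``-`` are treated as missing data throughout;
soft-masked lowercase input is uppercased on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentTreeMismatchError, DataError
from .trees import Phylogeny

__all__ = ["ElementAlignment", "PatternData", "encode_patterns",
           "read_element_fasta", "write_element_fasta", "read_bed", "write_bed"]

NUC_ORDER = "ACGT"
_CODE = {c: i for i, c in enumerate(NUC_ORDER)}
MISSING = 4  # anything not A/C/G/T marginalizes to an all-ones partial


@dataclass
class ElementAlignment:
    """Gap/ambiguity-aware alignment of one element across species."""

    id: str
    seqs: dict[str, str]
    chrom: str | None = None
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if not self.seqs:
            raise DataError(f"{self.id}: alignment has no sequences")
        self.seqs = {name: seq.upper() for name, seq in self.seqs.items()}
        lengths = {len(s) for s in self.seqs.values()}
        if len(lengths) != 1:
            raise DataError(f"{self.id}: unequal sequence lengths {sorted(lengths)}")
        if self.length < 1:
            raise DataError(f"{self.id}: empty alignment")

    @property
    def length(self) -> int:
        return len(next(iter(self.seqs.values())))

    @property
    def taxa(self) -> list[str]:
        return list(self.seqs)

    def column(self, i: int) -> dict[str, str]:
        return {name: seq[i] for name, seq in self.seqs.items()}

    def slice(self, start: int, end: int) -> "ElementAlignment":
        return ElementAlignment(
            self.id, {n: s[start:end] for n, s in self.seqs.items()},
            self.chrom, None if self.start is None else self.start + start,
            None if self.start is None else self.start + end)


@dataclass
class PatternData:
    """Column patterns of an alignment in tree node order.

    ``codes`` has shape (n_nodes, n_patterns) with 0..3 = A,C,G,T and 4 =
    missing (internal nodes and absent taxa are all-missing). ``counts``
    gives each pattern's multiplicity; ``pattern_of_column`` maps original
    columns back to patterns.
    """

    codes: np.ndarray
    counts: np.ndarray
    pattern_of_column: np.ndarray
    n_columns: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_columns = int(self.pattern_of_column.size)


def encode_patterns(aln: ElementAlignment, tree: Phylogeny,
                    require_all_tips: bool = False) -> PatternData:
    """Compress alignment columns to unique site patterns over tree nodes."""
    tip_names = set(tree.tip_names)
    extra = set(aln.taxa) - tip_names
    if extra:
        raise AlignmentTreeMismatchError(
            f"{aln.id}: taxa absent from tree: {sorted(extra)}")
    if require_all_tips and tip_names - set(aln.taxa):
        raise AlignmentTreeMismatchError(
            f"{aln.id}: taxa missing: {sorted(tip_names - set(aln.taxa))}")
    n_cols = aln.length
    cols = np.full((tree.n_nodes, n_cols), MISSING, dtype=np.int8)
    for name, seq in aln.seqs.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        row = np.full(n_cols, MISSING, dtype=np.int8)
        for base, code in _CODE.items():
            row[arr == ord(base)] = code
        cols[tree.tip_index(name)] = row
    uniq, inverse, counts = np.unique(cols.T, axis=0, return_inverse=True,
                                      return_counts=True)
    return PatternData(codes=uniq.T, counts=counts.astype(float),
                       pattern_of_column=inverse.astype(np.int64))


# -- FASTA ---------------------------------------------------------------


def read_element_fasta(path, element_id: str | None = None,
                       chrom=None, start=None, end=None) -> ElementAlignment:
    path = Path(path)
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise DataError(f"{path}: no FASTA records")
    return ElementAlignment(element_id or path.stem, seqs, chrom, start, end)


def write_element_fasta(aln: ElementAlignment, path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in aln.seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# -- BED -----------------------------------------------------------------


def read_bed(path) -> list[tuple]:
    """Read BED3+ records as (chrom, start, end, name?, score?, strand?)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise DataError(f"malformed BED interval {chrom}:{start}-{end}")
            out.append(tuple([chrom, start, end] + parts[3:6]))
    return out


def write_bed(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write("\t".join(str(x) for x in rec) + "\n")
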