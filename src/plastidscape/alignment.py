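"""Per-gene multiple alignments and FASTA round-trips.

A :class:`GeneAlignment` is the in-memory container shared by the
variability statistics, the substitution-rate estimators and the tree
builders: an ordered set of equal-length rows over ``A C G T N -``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["GeneAlignment"]

VALID_CHARS = set("ACGTN-")


@dataclass
class GeneAlignment:
    """A multiple alignment of one gene across taxa.

    Parameters
    ----------
    gene_name : str
        Identifier of the locus.
    taxa : list of str
        Unique row identifiers, in order.
    rows : list of str
        Aligned sequences, all the same length, over ``A C G T N -``.
    """

    gene_name: str
    taxa: list[str] = field(default_factory=list)
    rows: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows must have equal length")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon ids must be unique")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows of unequal length in {self.gene_name}: {sorted(lengths)}")
        self.rows = [r.upper() for r in self.rows]
        for t, r in zip(self.taxa, self.rows):
            bad = set(r) - VALID_CHARS
            if bad:
                raise ValueError(f"invalid characters {sorted(bad)} in row {t}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def aligned_length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def subset(self, taxa: Iterable[str]) -> "GeneAlignment":
        taxa = list(taxa)
        return GeneAlignment(self.gene_name, taxa, [self.row(t) for t in taxa])

    def slice_columns(self, start: int, end: int) -> "GeneAlignment":
        return GeneAlignment(self.gene_name, list(self.taxa), [r[start:end] for r in self.rows])

    # ---------------------------------------------------------------- I/O
    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(r), id=t, description="") for t, r in zip(self.taxa, self.rows)
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path, gene_name: str | None = None) -> "GeneAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        name = gene_name or Path(path).stem
        return cls(name, [r.id for r in records], [str(r.seq).upper() for r in records])

    @staticmethod
    def concatenate(alignments: list["GeneAlignment"], name: str = "concat") -> "GeneAlignment":
        """Concatenate alignments sharing a taxon set, in the given order."""
        if not alignments:
            raise ValueError("nothing to concatenate")
        taxa = list(alignments[0].taxa)
        for aln in alignments[1:]:
            if set(aln.taxa) != set(taxa):
                raise ValueError(f"taxon set mismatch at {aln.gene_name}")
        rows = ["".join(aln.row(t) for aln in alignments) for t in taxa]
        return GeneAlignment(name, taxa, rows)
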