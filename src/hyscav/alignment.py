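"""Codon-aware alignment container with 1-based column addressing."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import codon_at


@dataclass
class CodonAlignment:
    """Aligned protein-coding nucleotide sequences.

    Rows are keyed by sequence id; all rows have equal length divisible
    by 3.  Codon columns are addressed 1-based throughout the package.
    """

    sequences: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        if lengths and next(iter(lengths)) % 3:
            raise ValueError("alignment length not divisible by 3")
        self.sequences = {k: v.upper() for k, v in self.sequences.items()}

    @property
    def n_rows(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        """Number of codon columns."""
        if not self.sequences:
            return 0
        return len(next(iter(self.sequences.values()))) // 3

    def ids(self) -> List[str]:
        return list(self.sequences)

    def codon(self, row_id: str, column: int) -> str:
        return codon_at(self.sequences[row_id], column)

    def column_codons(self, column: int) -> Dict[str, str]:
        return {rid: self.codon(rid, column) for rid in self.sequences}

    def iter_columns(self) -> Iterator[Tuple[int, Dict[str, str]]]:
        for col in range(1, self.n_columns + 1):
            yield col, self.column_codons(col)

    def subset_columns(self, columns: List[int]) -> "CodonAlignment":
        """New alignment keeping the given 1-based codon columns, in order."""
        rows = {
            rid: "".join(codon_at(seq, c) for c in columns)
            for rid, seq in self.sequences.items()
        }
        return CodonAlignment(rows)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "CodonAlignment":
        records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
        if not records:
            raise ValueError(f"no sequences found in {path}")
        return cls(records)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=rid, description="") for rid, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")
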