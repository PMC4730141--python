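"""Genetic codes and codon utilities.

Two codes are provided: the standard bacterial/nuclear code, and an
"opal-as-Sec" variant in which the opal codon TGA is decoded as
selenocysteine (single-letter U) instead of terminating translation.
Selenoproteins such as the [NiFeSe] hydrogenase large subunit use the
latter: an in-frame TGA is read through when a SECIS element is present
downstream, so under the Sec code TGA is a sense codon and only TAA/TAG
terminate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterator, Tuple

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

#: single-letter code for selenocysteine
SELENOCYSTEINE = "U"

OPAL = "TGA"


def _standard_table() -> Dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[1]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


@dataclass(frozen=True)
class GeneticCode:
    """A 64-codon translation table with an explicit stop set.

    ``readthrough_mode`` is either ``"standard"`` (stops TAA/TAG/TGA) or
    ``"opal_as_Sec"`` (TGA decodes to U; stops TAA/TAG only).
    """

    name: str
    codon_to_aa: Dict[str, str] = field(repr=False)
    readthrough_mode: str = "standard"

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(f"genetic code must cover all 64 codons, got {len(self.codon_to_aa)}")

    @property
    def stop_codons(self) -> FrozenSet[str]:
        return frozenset(c for c, aa in self.codon_to_aa.items() if aa == "*")

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[codon.upper()] == "*"

    def is_sense(self, codon: str) -> bool:
        codon = codon.upper()
        return codon in self.codon_to_aa and self.codon_to_aa[codon] != "*"

    def translate_codon(self, codon: str) -> str:
        return self.codon_to_aa[codon.upper()]

    def sense_codons(self) -> Tuple[str, ...]:
        return tuple(sorted(c for c in self.codon_to_aa if not self.is_stop(c)))


def standard_code() -> GeneticCode:
    return GeneticCode(name="standard", codon_to_aa=_standard_table())


def opal_sec_code() -> GeneticCode:
    """Standard code with TGA reassigned to selenocysteine (U)."""
    mapping = _standard_table()
    mapping[OPAL] = SELENOCYSTEINE
    return GeneticCode(name="opal_as_Sec", codon_to_aa=mapping, readthrough_mode="opal_as_Sec")


def get_code(name: str) -> GeneticCode:
    if name in ("standard", "std"):
        return standard_code()
    if name in ("opal_as_Sec", "opal_sec", "sec"):
        return opal_sec_code()
    raise ValueError(f"unknown genetic code {name!r}")


def iter_codons(sequence: str) -> Iterator[str]:
    """Yield successive in-frame codons; the length must be divisible by 3."""
    seq = sequence.upper()
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    for i in range(0, len(seq), 3):
        yield seq[i : i + 3]


def codon_at(sequence: str, column: int) -> str:
    """Return the codon at 1-based codon column ``column``."""
    if column < 1:
        raise IndexError(f"codon columns are 1-based, got {column}")
    start = (column - 1) * 3
    codon = sequence[start : start + 3].upper()
    if len(codon) != 3:
        raise IndexError(f"column {column} beyond end of sequence")
    return codon


def translate(sequence: str, code: GeneticCode, to_stop: bool = True) -> str:
    """Translate a CDS; stops render as '*' unless ``to_stop`` truncates there."""
    out = []
    for codon in iter_codons(sequence):
        aa = code.translate_codon(codon)
        if aa == "*" and to_stop:
            break
        out.append(aa)
    return "".join(out)
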