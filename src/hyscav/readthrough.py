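"""Opal-codon readthrough translation and SECIS-like stem-loop scanning.

Selenoprotein coding sequences carry an in-frame TGA (opal) codon that
is decoded as selenocysteine (U) rather than terminating translation,
provided a SECIS stem-loop element follows in the mRNA.  In genome
annotations such genes appear truncated at the opal codon; reading
through it as Sec recovers the full-length protein ending at the second
stop codon.

The SECIS scan here is a minimal hairpin maximizer (perfect stems,
Watson-Crick plus G-U wobble pairs, no bulges), not a thermodynamic
folder: it scores candidate stem-loop geometries by stem length and is
intended as a transparent, testable heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .genetics import OPAL, SELENOCYSTEINE, iter_codons, standard_code

STANDARD_STOPS = frozenset({"TAA", "TAG", "TGA"})

#: allowed stem pairs on DNA alphabet (RNA G-U wobble = DNA G-T)
_PAIRS = frozenset({("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")})


@dataclass(frozen=True)
class ReadthroughResult:
    """Opal readthrough of one CDS.

    Positions are 1-based codon indices.  ``standard_protein`` is the
    annotated product ending just before the opal codon;
    ``extended_protein`` decodes the opal codon as U and runs to the
    codon before the second stop.
    """

    opal_position: int
    standard_protein: str
    extended_protein: str
    second_stop_position: Optional[int]


def find_opal_readthrough(cds: str) -> Optional[ReadthroughResult]:
    """Detect and translate an in-frame opal (TGA) readthrough candidate.

    The first in-frame TGA that is followed downstream (in frame) by
    another stop codon is reported; translation uses the standard code
    before and after the opal position, with U at the opal codon.
    Returns None when there is no in-frame TGA before the terminal stop,
    or when a TAA/TAG stop precedes every TGA (the ORF genuinely ends).
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    code = standard_code()
    codons = list(iter_codons(cds))
    if not codons or code.is_stop(codons[0]):
        raise ValueError("CDS must start with a sense codon")

    opal_idx: Optional[int] = None
    for i, codon in enumerate(codons):
        if codon == OPAL:
            opal_idx = i
            break
        if codon in STANDARD_STOPS:
            return None  # ordinary termination before any opal codon
    if opal_idx is None:
        return None

    second_stop: Optional[int] = None
    for j in range(opal_idx + 1, len(codons)):
        if codons[j] in STANDARD_STOPS:
            second_stop = j
            break

    standard_protein = "".join(code.translate_codon(c) for c in codons[:opal_idx])
    end = second_stop if second_stop is not None else len(codons)
    extended = []
    for k in range(end):
        extended.append(SELENOCYSTEINE if k == opal_idx else code.translate_codon(codons[k]))
    return ReadthroughResult(
        opal_position=opal_idx + 1,
        standard_protein=standard_protein,
        extended_protein="".join(extended),
        second_stop_position=None if second_stop is None else second_stop + 1,
    )


@dataclass(frozen=True)
class StemLoopCandidate:
    """A perfect hairpin: stem of ``stem_length`` pairs around a loop.

    ``window_start``/``window_end`` are 1-based inclusive nucleotide
    coordinates of the hairpin within the scanned window;
    ``pairing_score`` counts the Watson-Crick/GU pairs (equals
    stem_length for the perfect stems scored here).
    """

    window_start: int
    window_end: int
    stem_length: int
    loop_length: int
    pairing_score: int


def _pairs(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


def scan_secis(
    window: str,
    min_stem: int = 6,
    min_loop: int = 3,
    max_loop: int = 8,
) -> Optional[StemLoopCandidate]:
    """Best perfect-stem hairpin in a nucleotide window, or None.

    All (start, stem, loop) geometries with fully complementary stems
    (Watson-Crick and G-U) and loop length within [min_loop, max_loop]
    are enumerated; the candidate maximizing the pairing score (stem
    length) wins, with ties broken by smaller start then longer stem
    (longer stems at equal score cannot occur for perfect stems, so the
    effective tie-break is the leftmost geometry).
    """
    seq = window.upper().replace("U", "T")
    n = len(seq)
    if min_stem < 1 or min_loop < 3:
        raise ValueError("min_stem >= 1 and min_loop >= 3 required")
    best: Optional[StemLoopCandidate] = None
    # hairpin at 0-based start with stem s and loop l spans 2s + l bases;
    # base start+i pairs with base start + 2s + l - 1 - i
    for start in range(n):
        for loop in range(min_loop, max_loop + 1):
            max_stem = (n - start - loop) // 2
            for stem_len in range(max_stem, min_stem - 1, -1):
                if not all(
                    _pairs(seq[start + i], seq[start + 2 * stem_len + loop - 1 - i])
                    for i in range(stem_len)
                ):
                    continue
                cand = StemLoopCandidate(
                    window_start=start + 1,
                    window_end=start + 2 * stem_len + loop,
                    stem_length=stem_len,
                    loop_length=loop,
                    pairing_score=stem_len,
                )
                if best is None or (
                    -cand.pairing_score,
                    cand.window_start,
                    -cand.stem_length,
                    cand.loop_length,
                ) < (-best.pairing_score, best.window_start, -best.stem_length, best.loop_length):
                    best = cand
                break  # shorter stems at this (start, loop) score lower
    return best
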