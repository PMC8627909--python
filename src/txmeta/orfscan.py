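"""Six-frame ORF prediction and translation.

Only complete ORFs (ATG start codon to the first in-frame stop) are
reported by default; a contig is considered protein-coding when it carries
at least one ORF encoding 30 or more amino-acid residues, the threshold
applied when selecting proteins from meta-assembly contigs. For each
(frame, stop) pair only the leftmost ATG is reported, so nested calls
sharing a stop codon collapse to the longest one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from Bio.Data import CodonTable

from .seqio import Contig, revcomp

__all__ = ["OrfCall", "translate", "find_orfs", "longest_orf"]

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    _CODON_TO_AA[_stop] = "*"

_FRAME_ORDER = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class OrfCall:
    """A complete open reading frame on a contig.

    ``start``/``end`` are 0-based half-open coordinates on the forward
    strand of the contig regardless of frame sign; ``end - start`` is a
    multiple of 3 and spans the stop codon. ``protein`` excludes the
    terminal stop symbol, so ``aa_length == (end - start) // 3 - 1``.
    """

    contig_id: str
    frame: int
    start: int
    end: int
    aa_length: int
    protein: str


def translate(seq: str) -> str:
    """Translate a nucleotide string with the standard genetic code.

    Codons containing any character outside {A,C,G,T} yield ``'X'``; stop
    codons yield ``'*'``. The length must be a multiple of 3.
    """
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    seq = seq.upper()
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        out.append(_CODON_TO_AA.get(codon, "X"))
    return "".join(out)


def _orfs_one_strand(
    seq: str, offset: int, include_partial: bool
) -> Iterator[tuple[int, int, bool]]:
    """Yield (start, end, complete) of ORFs in reading frame ``offset`` of
    ``seq``, leftmost ATG per stop codon."""
    n = len(seq)
    start: int | None = None
    last = offset
    for i in range(offset, n - 2, 3):
        codon = seq[i : i + 3]
        last = i + 3
        if codon in ("TAA", "TAG", "TGA"):
            if start is not None:
                yield start, i + 3, True
            start = None
        elif start is None and codon == "ATG":
            start = i
    if include_partial and start is not None:
        yield start, last, False


def find_orfs(contig: Contig, min_aa: int = 30, include_partial: bool = False) -> list[OrfCall]:
    """Find every complete ORF in all six frames with >= ``min_aa`` residues.

    Reverse-strand ORFs are reported in forward-strand coordinates. The
    result is sorted by (start, frame) with frame order +1,+2,+3,-1,-2,-3.
    With ``include_partial`` ORFs running off the contig end without an
    in-frame stop are also reported (their span excludes any stop codon).
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = contig.sequence
    n = len(seq)
    rc = revcomp(seq)
    calls: list[OrfCall] = []
    for offset in range(3):
        for s, e, complete in _orfs_one_strand(seq, offset, include_partial):
            aa = (e - s) // 3 - 1 if complete else (e - s) // 3
            if aa >= min_aa:
                pe = e - 3 if complete else e
                calls.append(
                    OrfCall(contig.id, offset + 1, s, e, aa, translate(seq[s:pe]))
                )
        for s, e, complete in _orfs_one_strand(rc, offset, include_partial):
            aa = (e - s) // 3 - 1 if complete else (e - s) // 3
            if aa >= min_aa:
                pe = e - 3 if complete else e
                calls.append(
                    OrfCall(contig.id, -(offset + 1), n - e, n - s, aa, translate(rc[s:pe]))
                )
    calls.sort(key=lambda c: (c.start, _FRAME_ORDER.index(c.frame)))
    return calls


def longest_orf(contig: Contig, min_aa: int = 1) -> OrfCall | None:
    """The ORF with the most residues, or None if no ORF reaches ``min_aa``.

    Ties go to the smallest start, then frame order +1,+2,+3,-1,-2,-3.
    """
    calls = find_orfs(contig, min_aa=min_aa)
    if not calls:
        return None
    return min(calls, key=lambda c: (-c.aa_length, c.start, _FRAME_ORDER.index(c.frame)))


def orf_table(calls: list[OrfCall]) -> str:
    """ORF calls as a TSV table (contig_id, frame, start, end, aa_length)."""
    lines = ["contig_id\tframe\tstart\tend\taa_length"]
    for c in calls:
        lines.append(f"{c.contig_id}\t{c.frame:+d}\t{c.start}\t{c.end}\t{c.aa_length}")
    return "\n".join(lines) + "\n"
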