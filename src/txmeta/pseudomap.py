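"""k-mer pseudo-alignment: the read mapping-rate quality metric.

Emulates how pseudo-aligners decide read/transcript compatibility: a read
is mapped when the contig-id sets of its canonical k-mers (absent k-mers
skipped) have a non-empty intersection and at least ``min_frac`` of its
k-mers are present in the index. Only the mapped/unmapped decision is
needed for the metric, so no De Bruijn equivalence-class machinery is
built and no abundances are estimated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .seqio import Assembly, ReadRecord, revcomp

__all__ = ["KmerIndex", "MapRateReport", "build_index", "map_rate", "canonical_kmers"]


def canonical_kmers(seq: str, k: int) -> list[str]:
    """Canonical (lexicographic min of k-mer and reverse complement)
    k-mers of ``seq``, skipping any containing N."""
    out = []
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        rc = revcomp(kmer)
        out.append(kmer if kmer <= rc else rc)
    return out


@dataclass
class KmerIndex:
    """Canonical k-mer -> set of contig ids."""

    k: int
    table: dict[str, set[str]] = field(default_factory=dict)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.table

    def __len__(self) -> int:
        return len(self.table)

    def add_contigs(self, contigs: Iterable) -> None:
        for c in contigs:
            for kmer in canonical_kmers(c.sequence, self.k):
                self.table.setdefault(kmer, set()).add(c.id)


def build_index(assembly: Assembly, k: int = 31) -> KmerIndex:
    """Index all canonical k-mers of all contigs. ``k`` must be odd (a
    canonical odd-length k-mer can never equal its own reverse complement)
    and within [11, 63]."""
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if not 11 <= k <= 63:
        raise ValueError("k must be in [11, 63]")
    index = KmerIndex(k=k)
    index.add_contigs(assembly)
    return index


@dataclass(frozen=True)
class MapRateReport:
    n_reads: int
    n_mapped: int

    @property
    def pct_mapped(self) -> float:
        if self.n_reads == 0:
            return 0.0
        return round(100.0 * self.n_mapped / self.n_reads, 2)

    def to_json(self) -> str:
        return json.dumps(
            {"n_reads": self.n_reads, "n_mapped": self.n_mapped, "pct_mapped": self.pct_mapped},
            indent=2,
        )


def _read_is_mapped(read: ReadRecord, index: KmerIndex, min_frac: float) -> bool:
    kmers = canonical_kmers(read.sequence, index.k)
    if not kmers:  # read shorter than k
        return False
    present = [km for km in kmers if km in index.table]
    if len(present) < min_frac * len(kmers) or not present:
        return False
    compat: set[str] | None = None
    for km in present:
        ids = index.table[km]
        compat = set(ids) if compat is None else compat & ids
        if not compat:
            return False
    return bool(compat)


def map_rate(
    reads: Sequence[ReadRecord], index: KmerIndex, min_frac: float = 0.5
) -> MapRateReport:
    """Fraction of reads pseudo-aligning to the indexed assembly.

    Reads shorter than k count as unmapped. ``min_frac`` is the minimum
    fraction of a read's k-mers that must be present in the index; 0.5 by
    default to tolerate indel-rich single-end reads.
    """
    n_mapped = sum(1 for r in reads if _read_is_mapped(r, index, min_frac))
    return MapRateReport(n_reads=len(reads), n_mapped=n_mapped)
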