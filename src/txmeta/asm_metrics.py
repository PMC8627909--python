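"""Contig-length statistics and reference-CDS recovery metrics.

Covers five of the seven assembly-quality parameters: N50, median contig
length, percentage of contigs with homology to a known CDS, number of CDS
detected, and number of CDS with at least 95 % of their length covered by
aligned contigs. Homology search is a seed-and-extend ungapped local
aligner: exact shared k-mers anchor diagonals, along which maximal-scoring
ungapped segments (+1 match / -2 mismatch) are extracted; hits below the
identity cut-off or shorter than the seed length are dropped.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from .seqio import Assembly, Contig, revcomp

__all__ = [
    "AssemblyStats",
    "AlignmentHit",
    "CdsCoverageReport",
    "n50",
    "summarize_lengths",
    "length_stats",
    "local_align",
    "cds_recovery",
]


# ---------------------------------------------------------------------------
# length statistics


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    total_len: int
    mean_len: float  # one decimal place
    median_len: float
    max_len: int
    n50: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def n50(lengths: Sequence[int]) -> int:
    """Contig length at which the longest-first cumulative sum first
    reaches half the total assembly length."""
    if not lengths:
        raise ValueError("n50 of an empty length set is undefined")
    total = sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if 2 * acc >= total:
            return length
    raise AssertionError("unreachable")


def _round1(x: float | Decimal) -> float:
    return float(Decimal(x).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_lengths(lengths: Sequence[int]) -> AssemblyStats:
    """Length statistics from a contig-length multiset.

    The mean is reported to one decimal (half-away-from-zero); the median
    of an even count is the arithmetic mean of the two central values.
    """
    if not lengths:
        raise ValueError("cannot summarize an empty assembly")
    total = sum(lengths)
    return AssemblyStats(
        n_contigs=len(lengths),
        total_len=total,
        mean_len=_round1(Decimal(total) / Decimal(len(lengths))),
        median_len=float(statistics.median(lengths)),
        max_len=max(lengths),
        n50=n50(lengths),
    )


def length_stats(assembly: Assembly) -> AssemblyStats:
    """:func:`summarize_lengths` over an assembly's contigs."""
    if len(assembly) == 0:
        raise ValueError(f"assembly {assembly.label!r} is empty")
    return summarize_lengths(assembly.lengths)


# ---------------------------------------------------------------------------
# seed-and-extend ungapped local alignment

_MATCH = 1
_MISMATCH = -2


@dataclass(frozen=True)
class AlignmentHit:
    """An ungapped local alignment of a contig to a reference CDS.

    Spans are 0-based half-open; ``contig_start``/``contig_end`` are on the
    forward strand of the contig, ``strand`` records which contig strand
    aligned to the CDS.
    """

    contig_id: str
    cds_id: str
    identity: float
    cds_start: int
    cds_end: int
    contig_start: int
    contig_end: int
    strand: str


def _max_scoring_segments(matches: list[bool]) -> list[tuple[int, int]]:
    """Maximal-scoring disjoint segments of a +1/-2 match profile.

    Greedy linear scan: each segment starts on a match, extends while the
    running score stays non-negative, and is emitted at its best-scoring
    endpoint (so segments start and end on matches).
    """
    segs: list[tuple[int, int]] = []
    i = 0
    n = len(matches)
    while i < n:
        if not matches[i]:
            i += 1
            continue
        score = 0
        best = 0
        best_end = i
        j = i
        while j < n:
            score += _MATCH if matches[j] else _MISMATCH
            if score < 0:
                break
            if score > best:
                best = score
                best_end = j
            j += 1
        segs.append((i, best_end + 1))
        i = best_end + 1
    return segs


def _diagonal_hits(
    qseq: str,
    tseq: str,
    diagonals: set[int],
    k: int,
    min_identity: float,
) -> list[tuple[int, int, int, int, float]]:
    """Hits (q_start, q_end, t_start, t_end, identity) along seeded diagonals."""
    out = []
    for d in diagonals:  # diagonal d: q_pos = t_pos + d
        q0 = max(0, d)
        t0 = q0 - d
        span = min(len(qseq) - q0, len(tseq) - t0)
        if span < k:
            continue
        matches = [qseq[q0 + i] == tseq[t0 + i] for i in range(span)]
        for s, e in _max_scoring_segments(matches):
            length = e - s
            if length < k:
                continue
            ident = sum(matches[s:e]) / length
            if ident >= min_identity:
                out.append((q0 + s, q0 + e, t0 + s, t0 + e, ident))
    return out


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            idx.setdefault(kmer, []).append(i)
    return idx


def local_align(
    query: Contig,
    target: str,
    cds_id: str = "target",
    k: int = 31,
    min_identity: float = 0.70,
) -> list[AlignmentHit]:
    """Align a contig to one CDS sequence on both strands.

    Exact shared ``k``-mers anchor diagonals; each seeded diagonal is
    scanned for maximal ungapped segments scored +1/-2, and segments below
    ``min_identity`` or shorter than ``k`` are discarded. Overlapping
    segments on the same diagonal are inherently merged by the scan.
    """
    if k < 11:
        raise ValueError("seed length k must be >= 11")
    tidx = _kmer_positions(target, k)
    hits: list[AlignmentHit] = []
    n = len(query.sequence)
    for strand, qseq in (("+", query.sequence), ("-", revcomp(query.sequence))):
        diagonals: set[int] = set()
        for qpos_idx in range(len(qseq) - k + 1):
            kmer = qseq[qpos_idx : qpos_idx + k]
            if "N" in kmer:
                continue
            for tpos in tidx.get(kmer, ()):
                diagonals.add(qpos_idx - tpos)
        for qs, qe, ts, te, ident in _diagonal_hits(qseq, target, diagonals, k, min_identity):
            if strand == "+":
                cs, ce = qs, qe
            else:
                cs, ce = n - qe, n - qs
            hits.append(AlignmentHit(query.id, cds_id, ident, ts, te, cs, ce, strand))
    hits.sort(key=lambda h: (h.cds_start, h.cds_end, h.strand))
    return hits


# ---------------------------------------------------------------------------
# CDS recovery


@dataclass
class CdsCoverageReport:
    """Per-CDS coverage by aligned contigs.

    ``coverage`` maps detected CDS ids to the fraction of their length
    covered by the union of qualifying hit spans; ``full95`` holds those
    with coverage >= 0.95 ("at least 95 %" is inclusive).
    """

    coverage: dict[str, float]
    detected: set[str]
    full95: set[str]
    pct_contigs_with_hit: float
    n_contigs: int

    @property
    def n_detected(self) -> int:
        return len(self.detected)

    @property
    def n_full95(self) -> int:
        return len(self.full95)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_detected": self.n_detected,
                "n_full95": self.n_full95,
                "pct_contigs_with_hit": self.pct_contigs_with_hit,
                "n_contigs": self.n_contigs,
            },
            indent=2,
        )


def _union_length(spans: list[tuple[int, int]]) -> int:
    total = 0
    end = -1
    for s, e in sorted(spans):
        if s > end:
            total += e - s
            end = e
        elif e > end:
            total += e - end
            end = e
    return total


def cds_recovery(
    assembly: Assembly,
    reference: Mapping[str, str],
    k: int = 31,
    min_identity: float = 0.70,
    union_coverage: bool = True,
) -> CdsCoverageReport:
    """Score recovery of a reference CDS set by an assembly.

    Coverage per CDS is the union of qualifying hit spans over all contigs
    divided by the CDS length (with ``union_coverage=False``, the single
    best contig's covered span instead). Also reports the percentage of
    contigs with at least one qualifying hit.
    """
    if not reference:
        raise ValueError("reference CDS set is empty")
    # one shared k-mer index over all CDS: kmer -> [(cds_id, pos)]
    tidx: dict[str, list[tuple[str, int]]] = {}
    for cid, seq in reference.items():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" not in kmer:
                tidx.setdefault(kmer, []).append((cid, i))

    spans: dict[str, list[tuple[int, int]]] = {}
    per_contig_best: dict[str, dict[str, int]] = {}
    contigs_with_hit = 0
    for contig in assembly:
        n = len(contig.sequence)
        found = False
        for strand, qseq in (("+", contig.sequence), ("-", revcomp(contig.sequence))):
            diag: dict[str, set[int]] = {}
            for qpos in range(len(qseq) - k + 1):
                kmer = qseq[qpos : qpos + k]
                if "N" in kmer:
                    continue
                for cid, tpos in tidx.get(kmer, ()):
                    diag.setdefault(cid, set()).add(qpos - tpos)
            for cid, dset in diag.items():
                res = _diagonal_hits(qseq, reference[cid], dset, k, min_identity)
                for qs, qe, ts, te, ident in res:
                    found = True
                    if union_coverage:
                        spans.setdefault(cid, []).append((ts, te))
                    else:
                        best = per_contig_best.setdefault(cid, {})
                        best[contig.id] = max(best.get(contig.id, 0), te - ts)
                        spans.setdefault(cid, []).append((ts, te))
        if found:
            contigs_with_hit += 1

    coverage: dict[str, float] = {}
    for cid, sp in spans.items():
        if union_coverage:
            coverage[cid] = _union_length(sp) / len(reference[cid])
        else:
            coverage[cid] = max(per_contig_best[cid].values()) / len(reference[cid])
    detected = set(coverage)
    full95 = {cid for cid, cov in coverage.items() if cov >= 0.95}
    pct = 100.0 * contigs_with_hit / len(assembly) if len(assembly) else 0.0
    return CdsCoverageReport(
        coverage=coverage,
        detected=detected,
        full95=full95,
        pct_contigs_with_hit=round(pct, 1),
        n_contigs=len(assembly),
    )
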