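"""Synthetic transcriptomes, redundant multi-source assemblies and
IonTorrent-like read libraries, with full ground-truth provenance.

The generator emulates the data shapes of a single-end IonTorrent RNA-seq
experiment assembled with several tools: a set of ORF-bearing transcripts;
per-tool assemblies containing full-length and fragmented contigs with
substitution errors plus planted substring duplicates (the redundancy the
dedup stage must remove); and variable-length (50-270 nt) reads with
per-base qualities, including a tunable low-quality fraction for filter
testing. Every contig and read is traceable to its source transcript
through :class:`SynthTruth`, and every generator is byte-deterministic
under a fixed seed.

What it does not emulate: IonTorrent homopolymer indels, expression-level
variation, splice isoforms, or assembler-specific artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .seqio import Assembly, Contig, ReadRecord, revcomp

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "simulate_transcripts",
    "simulate_assemblies",
    "simulate_reads",
]

_BASES = np.array(list("ACGT"))

# fixed per-generator seed offsets: each generator draws from its own
# stream so modules can run independently yet reproducibly
_OFFSET_TRANSCRIPTS = 0
_OFFSET_ASSEMBLIES = 1
_OFFSET_READS = 2

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic experiment.

    Defaults describe a small but realistic single-end IonTorrent-style
    experiment: 200 transcripts of 300-3000 nt at 44 % GC, four assemblies
    (one per assembler), 30 % planted redundancy, 30 % fragmented contigs,
    1 % substitution noise in contigs and reads, and 10 000 reads of
    50-270 nt of which 10 % are low-quality.
    """

    n_transcripts: int = 200
    length_range: tuple[int, int] = (300, 3000)
    gc: float = 0.44
    n_assemblies: int = 4
    redundancy_rate: float = 0.3
    fragmentation_rate: float = 0.3
    sub_error_rate: float = 0.01
    n_reads: int = 10_000
    read_length_range: tuple[int, int] = (50, 270)
    read_error_rate: float = 0.01
    low_quality_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("redundancy_rate", "fragmentation_rate", "sub_error_rate",
                     "read_error_rate", "low_quality_fraction", "gc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("length_range", "read_length_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must be positive and ordered")


@dataclass
class SynthTruth:
    """Ground-truth provenance for everything the generators emit.

    ``contig_provenance`` maps contig id -> (transcript_id, (start, end) on
    the transcript, is_planted_duplicate, container_contig_id or None);
    ``read_provenance`` maps read id -> (transcript_id, (start, end),
    strand).
    """

    transcripts: dict[str, str] = field(default_factory=dict)
    contig_provenance: dict[str, tuple] = field(default_factory=dict)
    read_provenance: dict[str, tuple] = field(default_factory=dict)

    def planted_duplicates(self, assembly_label: str | None = None) -> set[str]:
        """Ids of planted substring-duplicate contigs (optionally within
        one assembly, whose contig ids start with ``<label>_``)."""
        out = set()
        for cid, (_, _, planted, _) in self.contig_provenance.items():
            if planted and (assembly_label is None or cid.startswith(assembly_label + "_")):
                out.add(cid)
        return out


def _rng(config: SynthConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng((config.seed + offset) % (2**31))


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _random_codons(rng: np.random.Generator, n: int, gc: float) -> str:
    """n random non-stop codons."""
    out = []
    while len(out) < n:
        codon = _random_seq(rng, 3, gc)
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def simulate_transcripts(config: SynthConfig) -> tuple[list[Contig], SynthTruth]:
    """Generate transcripts, each guaranteed to carry a complete ORF of at
    least 30 codons (so ORF scanning and coding-only filtering have
    signal). Deterministic for a fixed seed."""
    lo, hi = config.length_range
    min_orf_nt = 30 * 3 + 6  # ATG + 30 codons + stop
    if lo < min_orf_nt:
        raise ValueError(
            f"minimum transcript length {lo} cannot hold a 30-codon ORF ({min_orf_nt} nt)"
        )
    rng = _rng(config, _OFFSET_TRANSCRIPTS)
    truth = SynthTruth()
    transcripts: list[Contig] = []
    for i in range(config.n_transcripts):
        length = int(rng.integers(lo, hi + 1))
        # ORF length uniform between 30 codons and nearly the whole
        # transcript, flanked by random UTRs
        orf_nt_max = (length - 6) // 3 * 3
        orf_codons = int(rng.integers(30, max(31, orf_nt_max // 3 - 1)))
        orf = "ATG" + _random_codons(rng, orf_codons, config.gc) + "TAA"
        utr_total = length - len(orf)
        utr5 = int(rng.integers(0, utr_total + 1))
        seq = (
            _random_seq(rng, utr5, config.gc)
            + orf
            + _random_seq(rng, utr_total - utr5, config.gc)
        )
        tid = f"t{i:04d}"
        truth.transcripts[tid] = seq
        transcripts.append(Contig(tid, seq, source_label="transcripts"))
    return transcripts, truth


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for pos in hits:
        cur = arr[pos].decode()
        choices = [b for b in "ACGT" if b != cur]
        arr[pos] = rng.choice(choices).encode()
    return arr.tobytes().decode()


def simulate_assemblies(
    transcripts: Sequence[Contig],
    config: SynthConfig,
    truth: SynthTruth | None = None,
) -> tuple[list[Assembly], SynthTruth]:
    """Generate ``n_assemblies`` assemblies of the transcript set.

    Each assembly represents every transcript by one contig — full-length,
    or (with probability ``fragmentation_rate``) a fragment of 40-80 % of
    the transcript — mutated at ``sub_error_rate``. It then plants
    ``floor(redundancy_rate * n_base_contigs)`` extra contigs that are
    exact proper substrings of randomly chosen existing contigs (copied
    after mutation, so they remain exact even with noise). Planted
    duplicates are at least 200 nt where the container allows, long enough
    that coincidental containment between unrelated contigs cannot occur.
    """
    if not transcripts:
        raise ValueError("no transcripts to assemble")
    truth = truth if truth is not None else SynthTruth()
    rng = _rng(config, _OFFSET_ASSEMBLIES)
    assemblies: list[Assembly] = []
    for a in range(config.n_assemblies):
        label = f"asm{a + 1}"
        contigs: list[Contig] = []
        for t in transcripts:
            seq = t.sequence
            span = (0, len(seq))
            if rng.random() < config.fragmentation_rate:
                frac = rng.uniform(0.4, 0.8)
                flen = max(50, int(len(seq) * frac))
                start = int(rng.integers(0, len(seq) - flen + 1))
                span = (start, start + flen)
                seq = seq[start : start + flen]
            seq = _mutate(rng, seq, config.sub_error_rate)
            cid = f"{label}_c{len(contigs):05d}"
            contigs.append(Contig(cid, seq, source_label=label))
            truth.contig_provenance[cid] = (t.id, span, False, None)
        n_planted = int(config.redundancy_rate * len(contigs))
        base = list(contigs)
        for j in range(n_planted):
            container = base[int(rng.integers(0, len(base)))]
            clen = len(container.sequence)
            lo = min(200, clen - 1)
            dup_len = int(rng.integers(lo, clen))  # proper substring
            start = int(rng.integers(0, clen - dup_len + 1))
            dup_seq = container.sequence[start : start + dup_len]
            cid = f"{label}_d{j:05d}"
            src = truth.contig_provenance[container.id][0]
            contigs.append(Contig(cid, dup_seq, source_label=label))
            truth.contig_provenance[cid] = (src, None, True, container.id)
        assemblies.append(Assembly(label=label, contigs=contigs))
    return assemblies, truth


def simulate_reads(
    transcripts: Sequence[Contig],
    config: SynthConfig,
    truth: SynthTruth | None = None,
) -> tuple[list[ReadRecord], SynthTruth]:
    """Generate single-end reads of uniform length in ``read_length_range``
    (capped by the transcript), uniform strand, substitution errors at
    ``read_error_rate``, and qualities with mean >= 20 except for a
    ``low_quality_fraction`` of deliberately poor reads."""
    if not transcripts:
        raise ValueError("no transcripts to sample reads from")
    truth = truth if truth is not None else SynthTruth()
    rng = _rng(config, _OFFSET_READS)
    lengths = np.array([len(t) for t in transcripts], dtype=float)
    weights = lengths / lengths.sum()
    lo, hi = config.read_length_range
    reads: list[ReadRecord] = []
    for i in range(config.n_reads):
        t = transcripts[int(rng.choice(len(transcripts), p=weights))]
        rlen = min(int(rng.integers(lo, hi + 1)), len(t))
        start = int(rng.integers(0, len(t) - rlen + 1))
        frag = t.sequence[start : start + rlen]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = revcomp(frag)
        frag = _mutate(rng, frag, config.read_error_rate)
        if rng.random() < config.low_quality_fraction:
            quals = tuple(int(q) for q in rng.integers(2, 16, size=rlen))  # mean < 20
        else:
            quals = tuple(int(q) for q in rng.integers(25, 41, size=rlen))  # mean >= 20
        rid = f"r{i:06d}"
        reads.append(ReadRecord(rid, frag, quals))
        truth.read_provenance[rid] = (t.id, (start, start + rlen), strand)
    return reads, truth
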