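"""Sequence I/O: contigs, assemblies, reads, and read filtering.

FASTA and FASTQ parsing is delegated to Biopython; this module wraps the
records in the lightweight containers the rest of the toolkit operates on
and applies the quality/length read filter used throughout the pipeline
(reads with mean Phred quality below 20 or length outside [50, 270] are
discarded; all three boundaries are inclusive on the keep side).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

__all__ = [
    "Contig",
    "Assembly",
    "ReadRecord",
    "FilterStats",
    "FastaFormatError",
    "FastqFormatError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "filter_reads",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC ambiguity codes other than N are collapsed to N so that downstream
# k-mer machinery works on a closed {A,C,G,T,N} alphabet.
_AMBIGUOUS = str.maketrans({c: "N" for c in "RYSWKMBDHVU"})


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def _clean_sequence(raw: str) -> str:
    return raw.upper().translate(_AMBIGUOUS)


class FastaFormatError(ValueError):
    """Malformed FASTA input (stray sequence, duplicate ids, ...)."""


class FastqFormatError(ValueError):
    """Malformed FASTQ input (truncated record, length mismatch, ...)."""


@dataclass(frozen=True)
class Contig:
    """A contiguous assembled nucleotide sequence.

    Attributes
    ----------
    id : str
        Unique identifier within its assembly.
    sequence : str
        Uppercase nucleotide string over {A,C,G,T,N}; length >= 1.
    source_label : str
        Name of the assembly the contig originates from.
    """

    id: str
    sequence: str
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Assembly:
    """An ordered collection of contigs under a common label."""

    label: str
    contigs: list[Contig] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("assembly label must be non-empty")
        seen: set[str] = set()
        for c in self.contigs:
            if c.id in seen:
                raise ValueError(f"duplicate contig id {c.id!r} in assembly {self.label!r}")
            seen.add(c.id)

    def __len__(self) -> int:
        return len(self.contigs)

    def __iter__(self) -> Iterator[Contig]:
        return iter(self.contigs)

    @property
    def lengths(self) -> list[int]:
        return [len(c) for c in self.contigs]

    def total_length(self) -> int:
        return sum(self.lengths)


@dataclass(frozen=True)
class ReadRecord:
    """A single-end sequencing read with per-base Phred qualities."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def mean_quality(self) -> float:
        """Arithmetic mean of the per-base Phred scores."""
        if not self.qualities:
            return 0.0
        return sum(self.qualities) / len(self.qualities)


def read_fasta(path: str | Path, label: str | None = None) -> Assembly:
    """Read a (possibly multi-line) FASTA file into an :class:`Assembly`.

    The header token up to the first whitespace becomes the contig id;
    sequences are uppercased and non-N ambiguity codes mapped to N.
    """
    path = Path(path)
    label = label if label is not None else path.stem
    contigs: list[Contig] = []
    seen: set[str] = set()
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seen:
                raise FastaFormatError(f"{path}: duplicate contig id {rec.id!r}")
            seen.add(rec.id)
            contigs.append(Contig(rec.id, _clean_sequence(str(rec.seq)), source_label=label))
    except ValueError as exc:
        if isinstance(exc, FastaFormatError):
            raise
        raise FastaFormatError(f"{path}: {exc}") from exc
    return Assembly(label=label, contigs=contigs)


def write_fasta(assembly: Assembly | Iterable[Contig], path: str | Path, wrap: int = 60) -> None:
    """Write contigs as FASTA; ``wrap=0`` disables line wrapping."""
    if wrap < 0:
        raise ValueError("wrap must be >= 0")
    contigs = assembly.contigs if isinstance(assembly, Assembly) else list(assembly)
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n")
            if wrap == 0:
                fh.write(c.sequence + "\n")
            else:
                for i in range(0, len(c.sequence), wrap):
                    fh.write(c.sequence[i : i + wrap] + "\n")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Read 4-line FASTQ (Phred+33) into :class:`ReadRecord` objects."""
    path = Path(path)
    reads: list[ReadRecord] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = tuple(rec.letter_annotations["phred_quality"])
            reads.append(ReadRecord(rec.id, _clean_sequence(str(rec.seq)), quals))
    except ValueError as exc:
        raise FastqFormatError(f"{path}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    """Write reads as 4-line Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


@dataclass
class FilterStats:
    """Bookkeeping for :func:`filter_reads`; reasons are mutually exclusive."""

    n_input: int = 0
    n_kept: int = 0
    n_too_short: int = 0
    n_too_long: int = 0
    n_low_quality: int = 0

    @property
    def n_removed(self) -> int:
        return self.n_too_short + self.n_too_long + self.n_low_quality

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_kept": self.n_kept,
                "n_removed": self.n_removed,
                "n_too_short": self.n_too_short,
                "n_too_long": self.n_too_long,
                "n_low_quality": self.n_low_quality,
            },
            indent=2,
        )


def filter_reads(
    reads: Sequence[ReadRecord],
    min_mean_quality: float = 20.0,
    min_len: int = 50,
    max_len: int = 270,
) -> tuple[list[ReadRecord], FilterStats]:
    """Keep reads with mean quality >= ``min_mean_quality`` and length in
    ``[min_len, max_len]``.

    Boundary values pass: a 50 nt or 270 nt read, or one with mean quality
    exactly 20, is kept. When a read fails both the length and the quality
    check, the length reason is recorded (one reason per read, so the reason
    counts plus ``n_kept`` always sum to ``n_input``).
    """
    if min_mean_quality <= 0 or min_len <= 0 or max_len <= 0:
        raise ValueError("thresholds must be positive")
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    stats = FilterStats(n_input=len(reads))
    kept: list[ReadRecord] = []
    for r in reads:
        if len(r) < min_len:
            stats.n_too_short += 1
        elif len(r) > max_len:
            stats.n_too_long += 1
        elif r.mean_quality() < min_mean_quality:
            stats.n_low_quality += 1
        else:
            kept.append(r)
            stats.n_kept += 1
    return kept, stats
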