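"""End-to-end orchestration: meta-assembly construction and multi-metric
assembly evaluation, shared by the CLI and the examples."""

from __future__ import annotations

from typing import Mapping, Sequence

from .asm_metrics import cds_recovery, length_stats
from .dedup import RedundancyReport, merge_assemblies, remove_redundant
from .pseudomap import build_index, map_rate
from .ranker import (
    MetricMatrix,
    OverlapReport,
    RankResult,
    normalize,
    overlap_sets,
    rank_assemblies,
)
from .seqio import Assembly, ReadRecord

__all__ = ["make_meta_assembly", "evaluate_assemblies"]


def make_meta_assembly(
    assemblies: Sequence[Assembly],
    label: str = "meta",
    consider_revcomp: bool = True,
    coding_only: bool = False,
    min_aa: int = 30,
) -> tuple[Assembly, RedundancyReport]:
    """Concatenate assemblies and remove substring-redundant contigs."""
    merged = merge_assemblies(assemblies, label=label)
    return remove_redundant(
        merged, consider_revcomp=consider_revcomp, coding_only=coding_only, min_aa=min_aa
    )


def evaluate_assemblies(
    assemblies: Sequence[Assembly],
    reference_cds: Mapping[str, str] | None = None,
    markers: Mapping[str, str] | None = None,
    reads: Sequence[ReadRecord] | None = None,
    k: int = 31,
    min_identity: float = 0.70,
    min_frac: float = 0.5,
) -> tuple[MetricMatrix, RankResult, OverlapReport | None]:
    """Compute the available quality metrics per assembly, normalize, rank,
    and decompose the overlap of detected-CDS sets.

    Metrics whose inputs are missing (no reference CDS, no markers, no
    reads) are dropped from the panel. Marker recovery counts markers that
    are detected at all (complete, coverage >= 0.95, plus fragmented ones
    below that), scored through the same CDS-coverage engine.
    """
    if not assemblies:
        raise ValueError("no assemblies to evaluate")
    values: dict[str, dict[str, float]] = {}
    detected_sets: dict[str, set] = {}
    for asm in assemblies:
        stats = length_stats(asm)
        row: dict[str, float] = {"n50": stats.n50, "median_len": stats.median_len}
        if markers:
            mrep = cds_recovery(asm, markers, k=k, min_identity=min_identity)
            row["markers_recovered"] = mrep.n_detected  # complete + fragmented
        if reference_cds:
            crep = cds_recovery(asm, reference_cds, k=k, min_identity=min_identity)
            row["pct_contigs_with_hit"] = crep.pct_contigs_with_hit
            row["n_cds_detected"] = crep.n_detected
            row["n_cds_full95"] = crep.n_full95
            detected_sets[asm.label] = set(crep.detected)
        if reads is not None:
            index = build_index(asm, k=k)
            row["pct_reads_mapped"] = map_rate(reads, index, min_frac=min_frac).pct_mapped
        values[asm.label] = row

    matrix = MetricMatrix.from_dict(values)
    matrix = normalize(matrix)
    ranking = rank_assemblies(matrix)
    overlap = None
    if detected_sets and 1 <= len(detected_sets) <= 6:
        overlap = overlap_sets(detected_sets)
    return matrix, ranking, overlap
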