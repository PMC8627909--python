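"""Metric normalization, assembly ranking, and CDS-list overlap counts.

Each quality metric is min-max scaled across the k assemblies so it takes
a value in [0, 1]: N_ij = (R_ij - min V_i) / (max V_i - min V_i), where
V_i collects metric i over all assemblies (flipped to 1 - that value for
lower-is-better metrics). The normalized metrics are summed per assembly
and assemblies are ranked by decreasing sum; the top assembly is the best
by the combined criterion. Rankings are invariant under any increasing
affine transform of a raw metric column, which is the point of the
scaling: metrics on wildly different scales contribute equally.

The default metric panel (in the conventional order) is: N50; median
contig length; marker-gene recovery count; % contigs with CDS homology;
number of reference CDS detected; number of CDS >= 95 % covered; % reads
mapped. All are higher-is-better.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "DEFAULT_METRICS",
    "MetricMatrix",
    "RankResult",
    "OverlapReport",
    "normalize",
    "rank_assemblies",
    "overlap_sets",
]

DEFAULT_METRICS = (
    "n50",
    "median_len",
    "markers_recovered",
    "pct_contigs_with_hit",
    "n_cds_detected",
    "n_cds_full95",
    "pct_reads_mapped",
)


@dataclass
class MetricMatrix:
    """Raw and normalized quality metrics for k assemblies.

    ``raw`` is assemblies x metrics; ``direction[m]`` is True when higher
    raw values of metric ``m`` are better (the default for every metric in
    the standard panel).
    """

    raw: pd.DataFrame
    direction: dict[str, bool] = field(default_factory=dict)
    normalized: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for m in self.raw.columns:
            self.direction.setdefault(m, True)

    @property
    def assembly_labels(self) -> list[str]:
        return list(self.raw.index)

    @property
    def metric_names(self) -> list[str]:
        return list(self.raw.columns)

    @classmethod
    def from_dict(
        cls,
        values: Mapping[str, Mapping[str, float]],
        metric_names: Sequence[str] | None = None,
        direction: Mapping[str, bool] | None = None,
    ) -> "MetricMatrix":
        """Build from {assembly_label: {metric: value}}."""
        raw = pd.DataFrame.from_dict(values, orient="index")
        if metric_names is not None:
            raw = raw[list(metric_names)]
        return cls(raw=raw, direction=dict(direction or {}))

    def to_tsv(self, path) -> None:
        self.raw.to_csv(path, sep="\t", index_label="assembly")


def normalize(matrix: MetricMatrix) -> MetricMatrix:
    """Min-max scale every metric column into [0, 1].

    Non-degenerate columns attain both 0 (worst assembly) and 1 (best);
    a degenerate column (all values equal) carries no ranking information
    and is set to 1.0 for every assembly, which shifts all sums equally.
    """
    raw = matrix.raw
    for m in raw.columns:
        for label in raw.index:
            v = raw.at[label, m]
            if not math.isfinite(v):
                raise ValueError(f"non-finite raw value for metric {m!r}, assembly {label!r}")
    norm = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for m in raw.columns:
        col = raw[m].astype(float)
        lo, hi = col.min(), col.max()
        if hi == lo:
            norm[m] = 1.0
        else:
            scaled = (col - lo) / (hi - lo)
            norm[m] = scaled if matrix.direction.get(m, True) else 1.0 - scaled
    return MetricMatrix(raw=raw, direction=dict(matrix.direction), normalized=norm)


@dataclass
class RankResult:
    """Summed normalized metrics and the resulting quality order."""

    sums: dict[str, float]
    order: list[str]

    @property
    def best(self) -> str:
        return self.order[0]

    def to_json(self) -> str:
        return json.dumps(
            {"order": self.order, "sums": {k: round(v, 4) for k, v in self.sums.items()}},
            indent=2,
        )


def rank_assemblies(matrix: MetricMatrix) -> RankResult:
    """Sum normalized metrics per assembly and sort by decreasing sum.

    Ties are broken by lexicographic label order. The first label is the
    assembly judged highest quality by the combined criterion.
    """
    if matrix.normalized is None:
        raise ValueError("matrix not normalized; call normalize() first")
    sums = {label: float(matrix.normalized.loc[label].sum()) for label in matrix.normalized.index}
    order = sorted(sums, key=lambda lab: (-sums[lab], lab))
    return RankResult(sums=sums, order=order)


@dataclass
class OverlapReport:
    """Exclusive-region counts of m sets (a numeric Venn diagram).

    ``region_counts`` maps each non-empty subset of labels (as a frozenset)
    to the number of items belonging to exactly that subset; the counts
    sum to the size of the union.
    """

    set_labels: list[str]
    region_counts: dict[frozenset, int]

    @property
    def union_size(self) -> int:
        return sum(self.region_counts.values())

    def in_all(self) -> int:
        return self.region_counts.get(frozenset(self.set_labels), 0)

    def in_exactly_one(self) -> int:
        return sum(
            c for region, c in self.region_counts.items() if len(region) == 1
        )

    def pairwise_intersections(self) -> dict[tuple[str, str], int]:
        """|A ∩ B| for every label pair (not exclusive regions)."""
        out = {}
        for a, b in combinations(sorted(self.set_labels), 2):
            out[(a, b)] = sum(
                c for region, c in self.region_counts.items() if a in region and b in region
            )
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "set_labels": sorted(self.set_labels),
                "union_size": self.union_size,
                "in_all": self.in_all(),
                "in_exactly_one": self.in_exactly_one(),
                "regions": {
                    "&".join(sorted(region)): c
                    for region, c in sorted(
                        self.region_counts.items(), key=lambda kv: sorted(kv[0])
                    )
                },
            },
            indent=2,
        )


def overlap_sets(lists: Mapping[str, set]) -> OverlapReport:
    """Exclusive-region counts for 1-6 sets of ids.

    Every item in the union is assigned to the region of exactly the sets
    containing it, so region counts are a partition of the union.
    """
    if not 1 <= len(lists) <= 6:
        raise ValueError("overlap_sets supports 1 to 6 sets; use a table for more")
    labels = list(lists)
    universe = set().union(*lists.values())
    counts: dict[frozenset, int] = {}
    for item in universe:
        region = frozenset(lab for lab in labels if item in lists[lab])
        counts[region] = counts.get(region, 0) + 1
    return OverlapReport(set_labels=labels, region_counts=counts)


def venn_figure(report: OverlapReport, path) -> None:
    """Draw a 2- or 3-set Venn diagram with region counts (matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    m = len(report.set_labels)
    if m not in (2, 3):
        raise ValueError("venn figures supported for 2 or 3 sets")
    labels = sorted(report.set_labels)
    centers = {2: [(-0.4, 0), (0.4, 0)], 3: [(-0.4, -0.25), (0.4, -0.25), (0, 0.45)]}[m]
    fig, ax = plt.subplots(figsize=(5, 5))
    for (x, y), lab in zip(centers, labels):
        ax.add_patch(Circle((x, y), 0.75, alpha=0.3))
        ax.annotate(lab, (x, y + 0.8), ha="center")
    # region label positions: centroid of member circles pushed outward
    for region, count in report.region_counts.items():
        xs = [c for c, lab in zip(centers, labels) if lab in region]
        x = sum(p[0] for p in xs) / len(xs)
        y = sum(p[1] for p in xs) / len(xs)
        ax.annotate(str(count), (x, y), ha="center", va="center")
    ax.set_xlim(-1.6, 1.6)
    ax.set_ylim(-1.6, 1.6)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=150)
    plt.close(fig)
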