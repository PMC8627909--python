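"""Decompose which assemblies detect which reference CDS.

Scores each assembly's CDS recovery and counts, for every subset of
assemblies, how many CDS are detected by exactly that subset — the
numbers behind a Venn diagram of CDS lists.
"""

from txmeta import (
    Assembly,
    Contig,
    SynthConfig,
    cds_recovery,
    overlap_sets,
    simulate_transcripts,
)

cfg = SynthConfig(n_transcripts=40, seed=31)
transcripts, truth = simulate_transcripts(cfg)
reference = {t.id: t.sequence for t in transcripts}

# Each "assembler" recovers a different, overlapping slice of the
# transcriptome, as real tools do.
slices = {"asm1": transcripts[:25], "asm2": transcripts[15:35], "asm3": transcripts[20:]}
assemblies = [
    Assembly(label, [Contig(f"{label}_{t.id}", t.sequence) for t in ts])
    for label, ts in slices.items()
]

detected = {}
for asm in assemblies:
    report = cds_recovery(asm, reference)
    detected[asm.label] = report.detected
    print(f"{asm.label}: {report.n_detected} CDS detected, "
          f"{report.n_full95} covered >= 95 %")

overlap = overlap_sets(detected)
print(f"\nunion of detected CDS: {overlap.union_size}")
print(f"detected by all {len(detected)} assemblies: {overlap.in_all()}")
print(f"detected by exactly one assembly: {overlap.in_exactly_one()}")
for region, count in sorted(overlap.region_counts.items(), key=lambda kv: sorted(kv[0])):
    print(f"  {' & '.join(sorted(region))}: {count}")
# Region counts partition the union: their sum equals the union size.
# Large single-assembly regions mean the assemblers complement each other,
# which is the motivation for merging them into a meta-assembly.
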