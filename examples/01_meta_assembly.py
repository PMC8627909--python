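"""Build a meta-assembly: merge four redundant assemblies and remove every
contig that is a substring of another.

Simulates four assemblies of the same 60-transcript sample (30 % planted
substring duplicates each), concatenates them, and reduces redundancy.
"""

from txmeta import SynthConfig, make_meta_assembly, simulate_assemblies, simulate_transcripts

cfg = SynthConfig(n_transcripts=60, n_assemblies=4, redundancy_rate=0.3, seed=7)
transcripts, truth = simulate_transcripts(cfg)
assemblies, truth = simulate_assemblies(transcripts, cfg, truth)

meta, report = make_meta_assembly(assemblies)

print(f"input contigs (4 assemblies): {report.n_before}")
print(f"non-redundant meta-assembly:  {report.n_after} contigs")
print(f"retention: {report.reduction_pct} % of the input")
# Retention well below 100 % shows how much the assemblies duplicate each
# other: every removed contig was wholly contained in a retained one
# (forward or reverse complement), so no sequence information is lost.
some_removed = list(report.removed.items())[:3]
for removed, container in some_removed:
    print(f"  removed {removed}  (contained in {container})")
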