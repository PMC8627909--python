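"""Filter an IonTorrent-like read library and pseudo-map it back.

Reads with mean Phred quality below 20 or length outside [50, 270] nt are
removed; surviving reads are assigned to the assembly by canonical 31-mer
compatibility (a read maps when its k-mers agree on at least one contig
and at least half of them are present in the index).
"""

from txmeta import (
    Assembly,
    Contig,
    SynthConfig,
    build_index,
    filter_reads,
    map_rate,
    simulate_reads,
    simulate_transcripts,
)

cfg = SynthConfig(n_transcripts=40, n_reads=4000, low_quality_fraction=0.15, seed=3)
transcripts, truth = simulate_transcripts(cfg)
reads, truth = simulate_reads(transcripts, cfg, truth)

kept, stats = filter_reads(reads)
print(f"reads in: {stats.n_input}, kept: {stats.n_kept} "
      f"(low quality: {stats.n_low_quality}, short: {stats.n_too_short}, "
      f"long: {stats.n_too_long})")

assembly = Assembly("tx", [Contig(t.id, t.sequence) for t in transcripts])
index = build_index(assembly, k=31)
report = map_rate(kept, index, min_frac=0.5)
print(f"pseudo-mapped: {report.n_mapped}/{report.n_reads} = {report.pct_mapped} %")
# Mapping against the true transcripts, only reads whose 1 % substitution
# errors destroy too many of their 31-mers fail; the rate is the library-
# usage quality metric of the ranking panel.
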