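# Methods

## Pipeline model

`txmeta` models the meta-assembly strategy for short-read transcriptome
reconstruction: several de novo assemblies of the same read libraries are
concatenated and the union is reduced by **substring redundancy removal** —
every contig whose sequence occurs as a substring of another contig in the
set is deleted. Reverse-complement containment counts as redundancy by
default because de novo contigs are strand-ambiguous; the check can be
switched off (`consider_revcomp=False`) to obtain pure forward-strand
semantics. Among identical sequences exactly one survives (smallest id).
The operation is idempotent, and because candidates are processed
longest-first with deterministic tie-breaks, the retained *sequence set*
does not depend on input order; the retained contigs are emitted in input
order.

### Redundancy-removal algorithm

Contigs are sorted by decreasing length (ties by id) and inserted into the
retained set one at a time. A candidate is checked for containment by
looking up its first 21-mer in a position index over all 21-mers of the
retained contigs; any true containment must place that anchor at an
indexed position, so each candidate is verified by direct string
comparison at only those positions. Candidates shorter than 21 nt fall
back to a linear scan. This keeps the common case near linear in total
sequence length, versus the quadratic all-pairs scan the test suite uses
as an oracle (they agree exactly on randomized instances up to 500
contigs). When a removed contig fits inside several retained ones, the
longest container (ties: smallest id) is reported. The position index
trades memory for speed (one entry per retained base); for desk-scale and
synthetic workloads this is a few hundred MB at most.

An optional *coding-only* mode drops contigs lacking a complete ORF of
≥ `min_aa` residues before deduplication, reproducing pipelines that
consider only ORF-bearing contigs. It is off by default so the core
operation stays purely sequence-based.

## Read filtering

Reads with arithmetic mean Phred quality below 20 or length below 50 nt or
above 270 nt are removed; all boundaries are inclusive on the keep side
(length 50, length 270 and mean exactly 20 pass), reading "below"/"above"
strictly. The mean is taken in Phred space, not error-probability space,
matching the default behaviour of the common read-filtering tools whose
output this models. When a read fails both length and quality, the length
reason is recorded, so reason counts and kept reads always partition the
input.

## ORF calling

Complete ORFs only — ATG to the first in-frame stop — in all six frames,
with reverse-strand calls mapped to forward-strand coordinates; a
30-residue minimum (excluding the stop) is the default threshold for
calling a contig protein-coding. For each (frame, stop) pair only the
leftmost ATG is reported, avoiding quadratic nested calls. Partial ORFs
running off the contig end can be included with `include_partial=True`.
Codons containing N translate to X; the codon table is the standard
genetic code.

## CDS recovery and the aligner

Homology of contigs to a reference CDS set is established by a
seed-and-extend **ungapped** aligner: exact shared k-mers (default k = 31)
anchor query/target diagonals; along each seeded diagonal the match/mismatch
profile is scanned for maximal-scoring segments under +1/−2 scoring (a
greedy linear scan that extends while the running score stays non-negative
and cuts each segment at its best-scoring endpoint — equivalent in effect
to X-drop extension with the drop at the score floor, and deterministic).
Segments shorter than k or below 70 % identity are discarded. Both strands
are searched. The k = 31 / 0.70 defaults are deliberate stand-ins for the
unspecified internals of external homology tools; they are strict enough
that unrelated random sequences essentially never hit (a shared 31-mer is
required) and loose enough to tolerate a few percent substitution noise.

Per-CDS coverage is the union of qualifying hit spans across all contigs
divided by CDS length ("covered with aligned contigs" is plural);
`union_coverage=False` scores only the single best contig. A CDS is
*detected* if it has any qualifying hit and *fully recovered* if coverage
≥ 0.95 (inclusive). Gapped alignment is out of scope: for same-species CDS
recovery with substitution-dominated noise, ungapped segments recover
coverage accurately, and the simple model keeps the brute-force oracle
tractable.

Marker-gene recovery (the completeness slot occupied by BUSCO-style
benchmarks in the seven-metric panel) is scored generically through the
same engine: any marker FASTA can be supplied, a marker counts as
*complete* at coverage ≥ 0.95 and *fragmented* when detected below that,
and the panel metric is the detected count (complete + fragmented). The
HMM machinery of real marker tools is intentionally not reproduced; the
slot in the ranking is what matters.

## Pseudo-alignment mapping rate

A read maps to the assembly when (a) the contig-id sets of its canonical
31-mers — k-mers absent from the index are skipped — have a non-empty
intersection, and (b) at least `min_frac` (default 0.5) of its k-mers are
present in the index. Reads shorter than k never map. This compatibility
rule reproduces the mapped/unmapped decision of pseudo-aligners without a
De Bruijn equivalence-class structure, which the percentage metric does
not need. `min_frac = 0.5` tolerates the error rates of variable-length
single-end reads; k is odd so a canonical k-mer can never be its own
reverse complement. The mapping rate is computed on post-filter reads.

## Normalization and ranking

Metric *i* over the *k* assemblies forms the vector `V_i`; each raw value
is scaled to `(R_ij − min V_i)/(max V_i − min V_i)` (flipped as
`1 − (...)` for lower-is-better metrics; all seven defaults are
higher-is-better). A degenerate column (`max = min`) carries no ranking
information and is set to 1.0 for every assembly — a constant offset
cannot change the order, and 1.0 avoids penalizing all assemblies on an
uninformative metric. Non-degenerate columns always attain both 0 and 1.
Sums are compared in decreasing order with lexicographic tie-breaks.
Metrics whose inputs are unavailable (no reference, no reads) are dropped
from the panel with a warning rather than imputed.

CDS-list overlaps are decomposed into exclusive regions (the numbers
behind a Venn diagram) for up to 6 sets by direct membership tallying;
region counts partition the union. Figures are drawn with plain matplotlib
circles for 2–3 sets; beyond that the tabular/JSON output is the intended
interface.

## Synthetic data

The generator emulates the shapes of a single-end IonTorrent RNA-seq
experiment, not its full error physics:

- **Transcripts**: uniform lengths in 300–3000 nt at 44 % GC (typical of
  cereal transcripts), each carrying a planted complete ORF of ≥ 30 codons
  so ORF-based stages always have signal. Infeasibly short length ranges
  (< 96 nt) are rejected.
- **Assemblies**: 4 by default (one per assembler in the modeled design).
  Each represents every transcript by one contig — full-length or, with
  probability `fragmentation_rate` = 0.3, a 40–80 % fragment — with
  substitutions at `sub_error_rate` = 0.01. Then `⌊redundancy_rate × n⌋`
  duplicates are planted as **exact proper substrings** of randomly chosen
  contigs (copied after mutation, so dedup ground truth stays exact even
  with noise), at least 200 nt where the container allows — long enough
  that coincidental containment between unrelated random contigs does not
  occur. `redundancy_rate` = 0.3 by default.
- **Reads**: lengths uniform in 50–270 nt (the filter's window), uniform
  strand, substitutions at 0.01 per base; per-base qualities drawn from
  25–40 for normal reads and 2–15 for a `low_quality_fraction` = 0.1 of
  reads, so the quality filter has a known target.

Each generator draws from its own RNG stream (`seed` plus a fixed
per-generator offset), so outputs are byte-identical under a fixed seed
even when generators run independently. Not emulated: homopolymer indels
(the dominant IonTorrent error mode), expression-level variation, splice
isoforms, chimeras, or assembler-specific artifacts. Consequently, passing
tests demonstrate the correctness of the algorithms under
substitution-dominated noise with exact planted redundancy — they do not
certify behaviour on indel-rich real libraries, where the ungapped aligner
and the k-mer mapping rule will both undercount.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run synthetic experiments of
60–100 transcripts, 2–4 assemblies (a few hundred contigs) and 5 000–10 000
reads — large enough that every code path (fragmentation, planted
redundancy, both strands, filter rejections) is exercised and the oracle
comparisons are exhaustive, while a full run stays in the minutes range on
one core. Retention percentages are rounded half-away-from-zero to one
decimal; mapping percentages to two decimals; mean contig length to one
decimal. Degenerate inputs (empty assemblies, empty read sets, k-mer-free
reads, single-assembly normalization) are defined explicitly rather than
left to fall through: statistics of an empty assembly raise, an empty read
set maps at 0.0 %, and a single assembly normalizes to all-ones.

## Known limitations

- Near-identical but non-substring contigs (one mismatch anywhere) are
  *not* redundant by the substring definition and are retained; clustering
  is deliberately out of scope.
- The aligner is ungapped; a single indel splits hits and lowers coverage.
- The anchor index keys the first 21-mer of each candidate; sequences are
  treated case-insensitively but N-containing anchors are looked up
  literally (N never matches ACGT), which only makes containment checks
  conservative for N-rich contigs.
- Protein-space redundancy (different nucleotide sequences encoding the
  same protein) is not considered.
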