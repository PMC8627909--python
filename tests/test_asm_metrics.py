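"""asm_metrics: N50/length statistics, the seeded ungapped aligner, and
reference-CDS recovery."""

import random
import statistics

import pytest
from hypothesis import given
from hypothesis import strategies as st

from txmeta.asm_metrics import (
    cds_recovery,
    length_stats,
    local_align,
    n50,
    summarize_lengths,
)
from txmeta.seqio import Assembly, Contig, revcomp

# --- N50 and length statistics -------------------------------------------


def oracle_n50(lengths):
    total = sum(lengths)
    acc = 0
    for x in sorted(lengths, reverse=True):
        acc += x
        if acc * 2 >= total:
            return x


class TestN50:
    @pytest.mark.parametrize(
        "lengths,expected",
        [((6, 5, 4, 3, 2), 5), ((7,), 7), ((3, 3, 3, 3), 3), ((1, 1, 10), 10)],
    )
    def test_examples(self, lengths, expected):
        assert n50(lengths) == expected

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            n50([])

    @given(st.lists(st.integers(1, 5000), min_size=1, max_size=200))
    def test_matches_oracle_and_dominates_median(self, lengths):
        val = n50(lengths)
        assert val == oracle_n50(lengths)
        assert val >= statistics.median(lengths)


class TestLengthStats:
    def test_alm_scale_mean(self):
        # aggregate identity: 68 414 contigs totalling 46 440 750 nt
        lengths = [678] * 68413 + [46_440_750 - 678 * 68413]
        st_ = summarize_lengths(lengths)
        assert st_.n_contigs == 68_414
        assert st_.total_len == 46_440_750
        assert st_.mean_len == 678.8

    def test_even_count_median(self):
        assert summarize_lengths([1, 2, 3, 4]).median_len == 2.5

    def test_fields_match_naive_recomputation(self, rng):
        for _ in range(20):
            lengths = [rng.randint(1, 3000) for _ in range(rng.randint(1, 150))]
            s = summarize_lengths(lengths)
            assert s.total_len == sum(lengths)
            assert s.max_len == max(lengths)
            assert s.median_len == statistics.median(lengths)
            assert s.n50 == oracle_n50(lengths)
            assert abs(s.mean_len - sum(lengths) / len(lengths)) <= 0.05
            assert s.max_len >= s.n50 >= s.median_len

    def test_assembly_wrapper_and_empty(self):
        asm = Assembly("a", [Contig("c", "ACGT" * 5)])
        assert length_stats(asm).n50 == 20
        with pytest.raises(ValueError):
            length_stats(Assembly("e", []))


# --- local alignment ------------------------------------------------------


def _dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestLocalAlign:
    def test_identical_full_span(self, rng):
        seq = _dna(rng, 400)
        hits = local_align(Contig("q", seq), seq, k=31)
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) == 1
        h = plus[0]
        assert (h.cds_start, h.cds_end) == (0, 400)
        assert (h.contig_start, h.contig_end) == (0, 400)
        assert h.identity == 1.0

    def test_no_shared_kmer_no_hits(self, rng):
        q = _dna(rng, 200)
        t = _dna(rng, 200)
        qk = {q[i : i + 31] for i in range(len(q) - 30)} | {
            revcomp(q)[i : i + 31] for i in range(len(q) - 30)
        }
        tk = {t[i : i + 31] for i in range(len(t) - 30)}
        assert qk.isdisjoint(tk)  # construction check
        assert local_align(Contig("q", q), t, k=31) == []

    def test_planted_insert_recovered(self, rng):
        q = _dna(rng, 200)
        target = _dna(rng, 150) + q + _dna(rng, 150)
        hits = local_align(Contig("q", q), target, k=31)
        best = max(hits, key=lambda h: h.cds_end - h.cds_start)
        assert best.cds_end - best.cds_start >= 200
        assert best.identity == 1.0
        assert (best.cds_start, best.cds_end) == (150, 350)

    def test_strand_symmetry(self, rng):
        target = _dna(rng, 500)
        q = target[100:300]
        fwd = local_align(Contig("q", q), target, k=31)
        rev = local_align(Contig("q", revcomp(q)), target, k=31)
        assert {(h.cds_start, h.cds_end) for h in fwd} == {
            (h.cds_start, h.cds_end) for h in rev
        }
        assert {h.strand for h in fwd} == {"+"} and {h.strand for h in rev} == {"-"}

    def test_mismatches_lower_identity(self, rng):
        t = _dna(rng, 300)
        q = list(t)
        # plant 6 well-separated substitutions (2 %)
        for pos in range(25, 300, 50):
            q[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[pos]]
        hits = local_align(Contig("q", "".join(q)), t, k=31, min_identity=0.9)
        assert hits
        total_matches = sum(
            round(h.identity * (h.cds_end - h.cds_start)) for h in hits if h.strand == "+"
        )
        assert total_matches <= 294  # cannot exceed true match count

    def test_k_below_11_rejected(self):
        with pytest.raises(ValueError):
            local_align(Contig("q", "ACGT" * 20), "ACGT" * 20, k=9)


# --- CDS recovery ---------------------------------------------------------


@pytest.fixture
def reference(rng):
    return {f"cds{i}": _dna(rng, rng.randint(300, 900)) for i in range(8)}


class TestCdsRecovery:
    def test_identity_assembly_full_recovery(self, reference):
        asm = Assembly("a", [Contig(f"c_{k}", v) for k, v in reference.items()])
        rep = cds_recovery(asm, reference)
        assert rep.detected == set(reference)
        assert rep.full95 == set(reference)
        assert rep.pct_contigs_with_hit == 100.0

    def test_90pct_contig_detected_not_full95(self, reference):
        cid = sorted(reference)[0]
        seq = reference[cid]
        asm = Assembly("a", [Contig("part", seq[: int(len(seq) * 0.9)])])
        rep = cds_recovery(asm, reference)
        assert rep.detected == {cid}
        assert rep.full95 == set()
        assert 0.88 <= rep.coverage[cid] <= 0.92

    def test_empty_assembly_all_zero(self, reference):
        rep = cds_recovery(Assembly("a", []), reference)
        assert rep.n_detected == rep.n_full95 == 0
        assert rep.pct_contigs_with_hit == 0.0

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError):
            cds_recovery(Assembly("a", [Contig("c", "ACGT" * 20)]), {})

    def test_union_coverage_across_contigs(self, reference):
        cid = sorted(reference)[0]
        seq = reference[cid]
        half = len(seq) // 2
        # two overlapping halves jointly cover the full CDS
        asm = Assembly(
            "a",
            [Contig("left", seq[: half + 40]), Contig("right", seq[half - 40 :])],
        )
        rep = cds_recovery(asm, reference)
        assert rep.coverage[cid] == 1.0
        assert cid in rep.full95

    def test_monotonicity_adding_contigs(self, reference, rng):
        cid = sorted(reference)[0]
        seq = reference[cid]
        base = Assembly("a", [Contig("c0", seq[:200])])
        bigger = Assembly("a", [Contig("c0", seq[:200]), Contig("c1", seq[150:400])])
        r1 = cds_recovery(base, reference)
        r2 = cds_recovery(bigger, reference)
        for k in r1.coverage:
            assert r2.coverage.get(k, 0) >= r1.coverage[k]
        assert r1.detected <= r2.detected
        assert r1.full95 <= r2.full95
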