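"""dedup: merging, substring-redundancy removal vs a quadratic oracle,
and the retention-percentage arithmetic."""

import random

import pytest

from txmeta.dedup import merge_assemblies, reduction_percent, remove_redundant
from txmeta.seqio import Assembly, Contig, revcomp

# --- quadratic all-pairs oracle ------------------------------------------


def oracle_retained(contigs, consider_revcomp=True):
    """Ids surviving redundancy removal, by checking every pair directly.

    A contig is removed iff its sequence (or reverse complement, when
    enabled) is a substring of a *surviving* contig; identical sequences
    keep the lexicographically smallest id. Processing longest-first (ties
    by id) makes the survivor set well-defined.
    """
    order = sorted(contigs, key=lambda c: (-len(c.sequence), c.id))
    kept = []
    for c in order:
        contained = any(
            c.sequence in k.sequence
            or (consider_revcomp and revcomp(c.sequence) in k.sequence)
            for k in kept
        )
        if not contained:
            kept.append(c)
    return {c.id for c in kept}


def random_instance(rng: random.Random, n_base: int, n_planted: int):
    contigs = []
    for i in range(n_base):
        length = rng.randint(50, 2000)
        contigs.append(Contig(f"b{i:03d}", "".join(rng.choice("ACGT") for _ in range(length))))
    for j in range(n_planted):
        src = rng.choice(contigs[:n_base])
        sub_len = rng.randint(20, len(src.sequence))
        start = rng.randint(0, len(src.sequence) - sub_len)
        sub = src.sequence[start : start + sub_len]
        if rng.random() < 0.5:
            sub = revcomp(sub)
        contigs.append(Contig(f"p{j:03d}", sub))
    rng.shuffle(contigs)
    return contigs


# --- merge ----------------------------------------------------------------


def test_merge_concatenates_and_prefixes():
    a = Assembly("x", [Contig(f"c{i}", "ACGTACGT") for i in range(3)])
    b = Assembly("y", [Contig(f"c{i}", "TTTTGGGG") for i in range(4)])
    merged = merge_assemblies([a, b])
    assert len(merged) == 7
    assert merged.contigs[0].id == "x|c0"
    assert merged.contigs[3].source_label == "y"


def test_merge_single_assembly_identity():
    a = Assembly("x", [Contig("c0", "ACGT"), Contig("c1", "GGCC")])
    merged = merge_assemblies([a])
    assert [(c.id, c.sequence) for c in merged] == [("x|c0", "ACGT"), ("x|c1", "GGCC")]


def test_merge_collision_raises():
    a = Assembly("x", [Contig("c0", "ACGT")])
    with pytest.raises(ValueError, match="collision"):
        merge_assemblies([a, a])


def test_merge_count_is_sum(rng):
    sizes = (3, 11, 5, 8)
    asms = [
        Assembly(f"a{i}", [Contig(f"c{j}", "ACGT" * 10) for j in range(n)])
        for i, n in enumerate(sizes)
    ]
    assert len(merge_assemblies(asms)) == sum(sizes)


# --- remove_redundant -----------------------------------------------------


def test_substring_removed():
    asm = Assembly("t", [Contig("A", "ATGCAT"), Contig("B", "GCA")])
    nr, rep = remove_redundant(asm)
    assert rep.retained == {"A"} and rep.removed == {"B": "A"}


def test_identical_pair_keeps_smaller_id():
    asm = Assembly("t", [Contig("B", "ACGT" * 10), Contig("A", "ACGT" * 10)])
    nr, rep = remove_redundant(asm)
    assert rep.retained == {"A"} and rep.removed == {"B": "A"}


def test_revcomp_containment_configurable():
    asm = Assembly("t", [Contig("A", "AAATTTGGG"), Contig("B", revcomp("ATTTGG"))])
    _, rep_on = remove_redundant(asm, consider_revcomp=True)
    _, rep_off = remove_redundant(asm, consider_revcomp=False)
    assert rep_on.removed == {"B": "A"}
    assert rep_off.removed == {}


def test_container_is_longest_with_smallest_id():
    asm = Assembly(
        "t",
        [
            Contig("long", "AAATGCATGCTTTTTTTT"),
            Contig("mid", "ATGCATGCTT"),
            Contig("z", "TGCATG"),
        ],
    )
    _, rep = remove_redundant(asm)
    assert rep.removed["z"] == "long"


def test_short_contig_fallback_below_anchor_k():
    # candidate shorter than the anchor k-mer exercises the linear path
    asm = Assembly("t", [Contig("A", "ACGT" * 30), Contig("B", "CGTA")])
    _, rep = remove_redundant(asm)
    assert rep.removed == {"B": "A"}


def test_matches_oracle_on_random_instances(rng):
    for trial in range(20):
        contigs = random_instance(rng, n_base=rng.randint(5, 40), n_planted=rng.randint(0, 25))
        asm = Assembly("t", contigs)
        nr, rep = remove_redundant(asm)
        assert rep.retained == oracle_retained(contigs)
        assert rep.n_before == len(contigs)
        assert rep.n_after == len(rep.retained)
        # every removed contig really is contained in its reported container
        by_id = {c.id: c.sequence for c in contigs}
        for rid, container in rep.removed.items():
            assert container in rep.retained
            assert (
                by_id[rid] in by_id[container] or revcomp(by_id[rid]) in by_id[container]
            )


def test_idempotence(rng):
    contigs = random_instance(rng, 30, 20)
    asm = Assembly("t", contigs)
    once, rep1 = remove_redundant(asm)
    twice, rep2 = remove_redundant(once)
    assert [(c.id, c.sequence) for c in twice] == [(c.id, c.sequence) for c in once]
    assert rep2.removed == {}


def test_order_insensitivity(rng):
    contigs = random_instance(rng, 25, 15)
    asm1 = Assembly("t", list(contigs))
    shuffled = list(contigs)
    rng.shuffle(shuffled)
    asm2 = Assembly("t", shuffled)
    _, rep1 = remove_redundant(asm1)
    _, rep2 = remove_redundant(asm2)
    assert rep1.retained == rep2.retained


def test_retained_output_preserves_input_order(rng):
    contigs = random_instance(rng, 20, 10)
    asm = Assembly("t", contigs)
    nr, rep = remove_redundant(asm)
    expected = [c.id for c in contigs if c.id in rep.retained]
    assert [c.id for c in nr] == expected


def test_coding_only_drops_orf_free_contigs():
    coding = "ATG" + "GCT" * 40 + "TAA"
    asm = Assembly("t", [Contig("orf", coding), Contig("junk", "CCCCCCCACC" * 30)])
    nr, rep = remove_redundant(asm, coding_only=True, min_aa=30)
    assert rep.retained == {"orf"}
    assert rep.removed["junk"] == "-"


# --- reduction_percent ----------------------------------------------------


@pytest.mark.parametrize(
    "before,after,pct",
    [
        (169232, 68414, 40.4),
        (133070, 32466, 24.4),
        (1000, 1000, 100.0),
        (1000, 0, 0.0),
        (1000, 245, 24.5),
        (200, 49, 24.5),  # 24.5 exactly: half-away rounding
    ],
)
def test_reduction_percent(before, after, pct):
    assert reduction_percent(before, after) == pct


def test_reduction_percent_invalid():
    with pytest.raises(ValueError):
        reduction_percent(0, 0)
    with pytest.raises(ValueError):
        reduction_percent(10, 11)
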