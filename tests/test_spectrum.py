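"""Mutation classification, junction repeats and QP perfection."""

import numpy as np
import pytest

from fluctspec import (
    GeneReference,
    QuasiPalindrome,
    RegionAnnotation,
    assign_region,
    classify_variant,
    junction_repeat,
    qp_perfection,
    revcomp,
    sbs_type,
    tabulate,
)
from fluctspec.spectrum import SBS_TYPES, insertion_junction
from fluctspec.varcall import VariantCall, apply_variants

from conftest import random_dna


# ---------------------------------------------------------------- junction_repeat

def brute_junction(seq, s, e):
    """Character-by-character homology scan, independent of the implementation."""
    n = len(seq)
    f = 0
    while s + f <= n and e + f < n and seq[s - 1 + f] == seq[e + f]:
        f += 1
    b = 0
    while s - 1 - b >= 1 and seq[s - 2 - b] == seq[e - 1 - b]:
        b += 1
    return f, b


def test_junction_repeat_planted():
    # deleting positions 1-4 of ACGTACGT leaves ACGT: 4 bp forward homology
    j = junction_repeat("ACGTACGT", 1, 4)
    assert j.forward_len == 4 and j.total_len == 4 and j.repeat_seq == "ACGT"


def test_junction_repeat_none():
    j = junction_repeat("AAACCCGGG", 4, 6)
    assert j.total_len == 0 and j.repeat_seq == ""


def test_junction_repeat_out_of_range():
    with pytest.raises(ValueError):
        junction_repeat("ACGT", 2, 9)


def test_junction_repeat_matches_bruteforce(rng):
    for _ in range(1000):
        seq = random_dna(rng, 200)
        s = int(rng.integers(1, 180))
        e = int(rng.integers(s, min(s + 40, 200)))
        j = junction_repeat(seq, s, e)
        f, b = brute_junction(seq, s, e)
        assert (j.forward_len, j.backward_len) == (f, b)
        # the repeat substring re-extracts identically at both junction flanks
        if j.forward_len:
            assert seq[s - 1 : s - 1 + j.forward_len] == seq[e : e + j.forward_len]


def test_junction_invariant_under_equivalent_placement(rng):
    # shifting the deletion within its shift range must not change total_len
    from fluctspec.varcall import normalize_indel

    for _ in range(50):
        seq = "".join(rng.choice(list("ACG"), size=120))
        s = int(rng.integers(10, 100))
        size = int(rng.integers(5, 12))
        call = normalize_indel(
            VariantCall("deletion", (s, s + size - 1), seq[s - 1 : s - 1 + size], ""), seq
        )
        totals = {
            junction_repeat(seq, p, p + size - 1).total_len
            for p in range(call.shift_range[0], call.shift_range[1] + 1)
        }
        assert len(totals) == 1


# ---------------------------------------------------------------- sbs_type

@pytest.mark.parametrize(
    "ref,alt,expected",
    [("A", "T", "AT>TA"), ("T", "A", "AT>TA"), ("C", "G", "CG>GC"), ("G", "C", "CG>GC")],
)
def test_sbs_type_complement_collapse(ref, alt, expected):
    assert sbs_type(VariantCall("substitution", (1, 1), ref, alt)) == expected


def test_sbs_type_all_twelve_collapse_to_six():
    seen = {}
    for ref in "ACGT":
        for alt in "ACGT":
            if ref == alt:
                continue
            t = sbs_type(VariantCall("substitution", (1, 1), ref, alt))
            seen.setdefault(t, []).append((ref, alt))
    assert set(seen) == set(SBS_TYPES)
    assert all(len(v) == 2 for v in seen.values())


def test_sbs_type_rejects_non_sbs():
    with pytest.raises(ValueError):
        sbs_type(VariantCall("deletion", (1, 3), "ACG", ""))


# ---------------------------------------------------------------- assign_region

def _two_region_ref(seq):
    return GeneReference(
        "g", seq,
        regions=[
            RegionAnnotation("5prime_GC", 1, len(seq) // 2),
            RegionAnnotation("3prime_native", len(seq) // 2 + 1, len(seq)),
        ],
    )


def test_assign_region_by_start(rng):
    ref = _two_region_ref(random_dna(rng, 100))
    v = VariantCall("substitution", (10, 10), ref.sequence[9], "A" if ref.sequence[9] != "A" else "C")
    assert assign_region(v, ref) == "5prime_GC"


def test_boundary_spanning_uses_start_rule(rng):
    ref = _two_region_ref(random_dna(rng, 100))
    v = VariantCall("deletion", (48, 55), ref.sequence[47:55], "")
    assert assign_region(v, ref) == "5prime_GC"


def test_assign_region_matches_membership_oracle(rng):
    ref = _two_region_ref(random_dna(rng, 100))
    for _ in range(100):
        p = int(rng.integers(1, 101))
        v = VariantCall("substitution", (p, p), "A", "C")
        expected = "5prime_GC" if p <= 50 else "3prime_native"
        assert assign_region(v, ref) == expected


# ---------------------------------------------------------------- qp_perfection

def _qp_ref(left, loop, right, pad="ATAT"):
    seq = pad + left + loop + right + pad
    off = len(pad)
    return (
        GeneReference("qp", seq, fork_direction="leftward-origin"),
        QuasiPalindrome(
            left_arm=(off + 1, off + len(left)),
            right_arm=(off + len(left) + len(loop) + 1, off + len(left) + len(loop) + len(right)),
            loop_len=len(loop),
        ),
    )


def test_perfecting_insertion_detected():
    # right arm GA-GTC is revcomp(GACTTC)=GAAGTC missing one A
    ref, qp = _qp_ref("GACTTC", "AAA", "GAGTC")
    pos = qp.right_arm[0] + 1  # insert the missing base after "GA"
    call = qp_perfection(VariantCall("insertion", (pos, pos + 1), "", "A"), ref, qp)
    assert call.perfected and call.templated_arm == "left"


def test_breaking_a_perfect_palindrome_is_not_perfection():
    ref, qp = _qp_ref("GACTTC", "AAA", "GAAGTC")
    pos = qp.right_arm[0]
    call = qp_perfection(VariantCall("insertion", (pos, pos + 1), "", "T"), ref, qp)
    assert not call.perfected


def test_variant_outside_footprint_rejected():
    ref, qp = _qp_ref("GACTTC", "AAA", "GAGTC")
    with pytest.raises(ValueError):
        qp_perfection(VariantCall("substitution", (1, 1), "A", "C"), ref, qp)


def test_qp_perfection_matches_revcomp_oracle(rng):
    # random QPs with a planted 1-3 bp arm gap; the correcting insertion must
    # be judged by direct revcomp comparison of the mutant footprint
    for _ in range(50):
        arm = int(rng.integers(5, 10))
        loop_len = int(rng.integers(1, 5))
        left = random_dna(rng, arm)
        loop = random_dna(rng, loop_len)
        gap = int(rng.integers(1, 4))
        cut = int(rng.integers(0, arm - gap + 1))
        perfect = revcomp(left)
        right = perfect[:cut] + perfect[cut + gap :]
        ref, qp = _qp_ref(left, loop, right)
        pos = qp.right_arm[0] - 1 + cut
        ins = VariantCall("insertion", (pos, pos + 1), "", perfect[cut : cut + gap])
        got = qp_perfection(ins, ref, qp)
        # oracle: apply and compare arms directly
        mut = apply_variants(ref.sequence, [ins])
        lo = qp.left_arm[0] - 1
        footprint = mut[lo : lo + 2 * arm + loop_len]
        assert got.perfected == (footprint[:arm] == revcomp(footprint[-arm:]))
        assert got.perfected


def test_strand_inference_follows_fork_and_arm():
    ref, qp = _qp_ref("GACTTC", "AAA", "GAGTC")  # leftward-origin fork
    pos = qp.right_arm[0] + 1
    call = qp_perfection(VariantCall("insertion", (pos, pos + 1), "", "A"), ref, qp)
    # variant touched the right arm -> left arm templated -> lagging under a
    # rightward-moving fork (origin on the left)
    assert call.templated_arm == "left" and call.initiating_strand == "lagging"
    call2 = qp_perfection(
        VariantCall("insertion", (pos, pos + 1), "", "A"), ref, qp,
        fork_direction="rightward-origin",
    )
    assert call2.initiating_strand == "leading"


def test_unknown_fork_gives_unknown_strand():
    ref, qp = _qp_ref("GACTTC", "AAA", "GAGTC")
    pos = qp.right_arm[0] + 1
    call = qp_perfection(
        VariantCall("insertion", (pos, pos + 1), "", "A"), ref, qp,
        fork_direction="unknown",
    )
    assert call.initiating_strand == "unknown"


# ---------------------------------------------------------------- classify_variant

def test_substitution_classified_sbs(reporter):
    ref, _, _ = reporter
    base = ref.sequence[9]
    alt = "T" if base != "T" else "G"
    rec = classify_variant(VariantCall("substitution", (10, 10), base, alt), ref)
    assert rec.mclass == "SBS" and rec.sbs is not None
    assert rec.region == "5prime_GC"


def test_slippage_deletion_classified_with_junction(reporter):
    # the planted 4 bp repeats separated by 19 bp: deleting one copy plus the
    # spacer is the 23 bp slippage product with >= 4 bp junction homology
    ref, pair, _ = reporter
    s, e = pair.left_start, pair.right_start - 1
    assert e - s + 1 == 23
    rec = classify_variant(
        VariantCall("deletion", (s, e), ref.sequence[s - 1 : e], ""), ref
    )
    assert rec.mclass == "DEL_GE5"
    assert rec.junction.total_len >= 4
    assert rec.flanked_by_repeats


def test_qp_insertion_takes_precedence_over_small_indel(reporter):
    # a 2 bp insertion perfecting the planted QP must be QP_TEMPLATED,
    # never INDEL_LT5
    from fluctspec.simulate import perfecting_insertion

    ref, _, qp = reporter
    ins = perfecting_insertion(ref.sequence, qp)
    assert ins is not None and len(ins.alt_allele) == 2
    rec = classify_variant(ins, ref, qp_registry=[qp])
    assert rec.mclass == "QP_TEMPLATED"
    assert rec.qpcall.perfected
    rec_no_registry = classify_variant(ins, ref)
    assert rec_no_registry.mclass == "INDEL_LT5"


def test_duplication_flagged(reporter):
    ref, pair, _ = reporter
    s, e = pair.left_start, pair.right_start - 1
    segment = ref.sequence[s - 1 : e]
    rec = classify_variant(VariantCall("insertion", (e, e + 1), "", segment), ref)
    assert rec.mclass == "INS_GE5" and rec.is_duplication


@pytest.mark.parametrize("size,expected", [(4, "INDEL_LT5"), (5, "DEL_GE5")])
def test_size_boundary_five_bp(reporter, size, expected):
    ref, _, _ = reporter
    s = 700
    rec = classify_variant(
        VariantCall("deletion", (s, s + size - 1), ref.sequence[s - 1 : s - 1 + size], ""),
        ref,
    )
    assert rec.mclass == expected


def test_every_record_gets_exactly_one_class(reporter, rng):
    ref, pair, qp = reporter
    from fluctspec.simulate import ProcessMixture, simulate_mutant_cohort

    mix = ProcessMixture(
        weights={"slippage_deletion": 0.4, "sbs": 0.3, "small_indel": 0.2, "qp_insertion": 0.1}
    )
    cohort = simulate_mutant_cohort(ref, mix, 50, seed=5, qp_registry=[qp])
    from fluctspec.spectrum import CLASS_LABELS

    for m in cohort:
        rec = classify_variant(m.variant, ref, qp_registry=[qp])
        assert rec.mclass in CLASS_LABELS


# ---------------------------------------------------------------- tabulate

def test_tabulate_empty():
    table = tabulate([])
    assert table.total == 0 and table.class_counts.sum() == 0


def test_tabulate_counts(reporter):
    ref, pair, _ = reporter
    recs = []
    for p in (10, 20, 30):
        b = ref.sequence[p - 1]
        alt = "T" if b != "T" else "G"
        recs.append(classify_variant(VariantCall("substitution", (p, p), b, alt), ref))
    s, e = pair.left_start, pair.right_start - 1
    recs.append(
        classify_variant(VariantCall("deletion", (s, e), ref.sequence[s - 1 : e], ""), ref)
    )
    table = tabulate(recs)
    assert table.class_counts["SBS"] == 3
    assert table.class_counts["DEL_GE5"] == 1
    assert table.total == 4
    assert table.class_counts.sum() == len(recs)
    assert table.sbs_counts.sum() == 3


def test_insertion_junction_detects_tandem_copy():
    #      123456789
    seq = "AACGTACGTT"
    j = insertion_junction(seq, 9, "ACGT")  # insert ACGT after pos 9? backward match
    assert j.total_len >= 4
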