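"""Mutation classification and spectrum tabulation.

Classes follow the reporter-gene rate-table scheme:

* ``SBS`` — single-base substitution, with one of six strand-collapsed types;
* ``DEL_GE5`` / ``INS_GE5`` — deletions / insertions of at least 5 bp, the
  polymerase-slippage size class; insertions that tandem-copy an adjacent
  reference segment are flagged as duplications;
* ``INDEL_LT5`` — insertions/deletions of 1-4 bp;
* ``QP_TEMPLATED`` — an insertion (or complex change) converting a
  quasi-palindrome into a perfect palindrome, the template-switch signature;
  takes precedence over the size classes so such events are never counted
  as small indels;
* ``COMPLEX`` / ``OTHER`` — everything else.

Deletion endpoints are scored for junction direct-repeat homology over every
equivalent placement of the deletion; the maximal total homology is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .refseq import GeneReference, QuasiPalindrome, complement, revcomp
from .varcall import VariantCall, apply_variants

__all__ = [
    "CLASS_LABELS",
    "SBS_TYPES",
    "JunctionRepeat",
    "QPCall",
    "MutationRecord",
    "SpectrumTable",
    "junction_repeat",
    "insertion_junction",
    "classify_variant",
    "qp_perfection",
    "assign_region",
    "sbs_type",
    "tabulate",
    "DEFAULT_STRAND_MAP",
]

logger = logging.getLogger(__name__)

CLASS_LABELS = (
    "SBS",
    "INDEL_LT5",
    "DEL_GE5",
    "INS_GE5",
    "QP_TEMPLATED",
    "COMPLEX",
    "OTHER",
)

#: six complementary-collapsed substitution types
SBS_TYPES = ("AT>TA", "AT>GC", "AT>CG", "CG>GC", "CG>AT", "CG>TA")

#: junction homology length at which a deletion is flagged "flanked by direct
#: repeats" (reported attribute; does not gate the size class)
DEFAULT_REPEAT_FLAG_MIN = 4

#: (templated_arm, fork_direction) -> initiating strand.  With the origin on
#: the left the fork moves rightward through the gene; a right-arm-templated
#: correction under a rightward-moving fork is called a leading-strand-
#: initiated switch.  Configurable: the mapping is a convention.
DEFAULT_STRAND_MAP = {
    ("right", "leftward-origin"): "leading",
    ("left", "leftward-origin"): "lagging",
    ("right", "rightward-origin"): "lagging",
    ("left", "rightward-origin"): "leading",
}


@dataclass(frozen=True)
class JunctionRepeat:
    """Direct-repeat homology at the two endpoints of a deletion.

    ``forward_len`` bases immediately downstream of both endpoints match;
    ``backward_len`` bases immediately upstream match.  Their sum is the
    length of the repeat that makes the deletion placement-ambiguous.
    """

    forward_len: int
    backward_len: int
    repeat_seq: str

    @property
    def total_len(self) -> int:
        return self.forward_len + self.backward_len


@dataclass(frozen=True)
class QPCall:
    qp: QuasiPalindrome
    perfected: bool
    templated_arm: str  # left | right | unknown
    initiating_strand: str  # leading | lagging | unknown


@dataclass
class MutationRecord:
    variant: VariantCall
    mclass: str
    junction: JunctionRepeat | None = None
    qpcall: QPCall | None = None
    region: str = "unannotated"
    sbs: str | None = None
    is_duplication: bool = False
    flanked_by_repeats: bool = False

    def __post_init__(self):
        if self.mclass not in CLASS_LABELS:
            raise ValueError(f"unknown class {self.mclass!r}")


def junction_repeat(ref: GeneReference | str, del_start: int, del_end: int) -> JunctionRepeat:
    """Homology between the flanks of the deletion removing ref[del_start..del_end].

    forward_len = max k >= 0 with ref[del_start..del_start+k-1] ==
    ref[del_end+1..del_end+k]; backward_len is the analogous upstream match.
    """
    seq = ref.sequence if isinstance(ref, GeneReference) else str(ref)
    n = len(seq)
    if not (1 <= del_start <= del_end <= n):
        raise ValueError(f"deletion [{del_start}, {del_end}] outside [1, {n}]")
    f = 0
    while del_start - 1 + f < n and del_end + f < n and seq[del_start - 1 + f] == seq[del_end + f]:
        f += 1
    b = 0
    while del_start - 2 - b >= 0 and seq[del_start - 2 - b] == seq[del_end - 1 - b]:
        b += 1
    repeat = seq[del_start - 1 - b : del_start - 1 + f]
    return JunctionRepeat(forward_len=f, backward_len=b, repeat_seq=repeat)


def insertion_junction(ref: str, pos: int, alt: str) -> JunctionRepeat:
    """Homology between an inserted string and the reference flanks.

    ``pos`` is the left-flank reference position (insertion between pos and
    pos+1).  forward_len: longest prefix of alt matching the reference just
    downstream; backward_len: longest suffix matching just upstream.
    """
    n = len(ref)
    f = 0
    while f < len(alt) and pos + f < n and alt[f] == ref[pos + f]:
        f += 1
    b = 0
    while b < len(alt) and pos - 1 - b >= 0 and alt[-1 - b] == ref[pos - 1 - b]:
        b += 1
    repeat = (ref[pos - b : pos] if b else "") + alt[:f]
    return JunctionRepeat(forward_len=f, backward_len=b, repeat_seq=repeat)


def sbs_type(variant: VariantCall) -> str:
    """Collapse a substitution onto one of the six strand-symmetric types."""
    if variant.kind != "substitution":
        raise ValueError("sbs_type requires a substitution call")
    ref_b, alt_b = variant.ref_allele, variant.alt_allele
    if ref_b in "TG":  # normalize to the A/C representative
        ref_b, alt_b = complement(ref_b), complement(alt_b)
    pair = {"A": "AT", "C": "CG"}[ref_b]
    return f"{pair}>{alt_b}{complement(alt_b)}"


def assign_region(
    variant: VariantCall, ref: GeneReference, default: str = "unannotated"
) -> str:
    """Region label by the leftmost variant start position."""
    pos = variant.shift_range[0] if variant.shift_range else variant.ref_interval[0]
    pos = max(pos, 1)
    end = variant.ref_interval[1]
    label = ref.region_of(pos, default)
    if end > pos and ref.region_of(min(end, len(ref)), default) != label:
        logger.warning(
            "variant [%d, %d] spans a region boundary; assigned %r by start rule",
            pos,
            end,
            label,
        )
    return label


def qp_perfection(
    variant: VariantCall,
    ref: GeneReference | str,
    qp: QuasiPalindrome,
    fork_direction: str | None = None,
    strand_map: dict | None = None,
) -> QPCall:
    """Does applying ``variant`` convert ``qp`` into a perfect palindrome?

    The variant is applied to the QP footprint; the mutant footprint is
    perfect when, keeping the loop length fixed, its two arms are exact
    reverse complements.  The templated arm is the arm whose sequence the
    variant did not touch (it supplied the corrective template).
    """
    seq = ref.sequence if isinstance(ref, GeneReference) else str(ref)
    if fork_direction is None:
        fork_direction = ref.fork_direction if isinstance(ref, GeneReference) else "unknown"
    fp_lo, fp_hi = qp.footprint
    v_lo = variant.ref_interval[0]
    v_hi = max(variant.ref_interval)
    if v_hi < fp_lo or v_lo > fp_hi:
        raise ValueError("variant outside the QP footprint")

    local = apply_variants(seq, [variant])[fp_lo - 1 : fp_hi + (
        len(variant.alt_allele) - len(variant.ref_allele)
    )]
    n = len(local)
    arm = (n - qp.loop_len) // 2
    perfected = (
        (n - qp.loop_len) % 2 == 0
        and arm >= 1
        and local[:arm] == revcomp(local[n - arm :])
    )

    la_lo, la_hi = qp.left_arm
    ra_lo, ra_hi = qp.right_arm
    touches_left = v_lo <= la_hi and v_hi >= la_lo
    touches_right = v_lo <= ra_hi and v_hi >= ra_lo
    if touches_left and not touches_right:
        templated = "right"
    elif touches_right and not touches_left:
        templated = "left"
    else:
        templated = "unknown"

    strand_map = DEFAULT_STRAND_MAP if strand_map is None else strand_map
    strand = strand_map.get((templated, fork_direction), "unknown")
    return QPCall(qp=qp, perfected=perfected, templated_arm=templated, initiating_strand=strand)


def _best_junction_deletion(seq: str, call: VariantCall) -> JunctionRepeat:
    """Maximal junction homology over every equivalent deletion placement."""
    size = call.size
    lo, hi = call.shift_range or (call.ref_interval[0], call.ref_interval[0])
    best = None
    for s in range(lo, hi + 1):
        j = junction_repeat(seq, s, s + size - 1)
        if best is None or j.total_len > best.total_len:
            best = j
    return best


def _best_junction_insertion(seq: str, call: VariantCall) -> JunctionRepeat:
    lo, hi = call.shift_range or (call.ref_interval[0], call.ref_interval[0])
    alt = call.alt_allele
    best = None
    # rotate the allele as the anchor moves right
    for p in range(lo, hi + 1):
        shifted = alt
        for q in range(lo, p):  # rotate left->right
            shifted = shifted[1:] + seq[q]
        j = insertion_junction(seq, p, shifted)
        if best is None or j.total_len > best.total_len:
            best = j
    return best


def _is_duplication(seq: str, call: VariantCall) -> bool:
    """Tandem test over both flanks at every equivalent placement."""
    L = len(call.alt_allele)
    lo, hi = call.shift_range or (call.ref_interval[0], call.ref_interval[0])
    alt = call.alt_allele
    for p in range(lo, hi + 1):
        if p - L >= 0 and seq[p - L : p] == alt:
            return True
        if p + L <= len(seq) and seq[p : p + L] == alt:
            return True
        if p < hi:
            alt = alt[1:] + seq[p]
    return False


def classify_variant(
    variant: VariantCall,
    ref: GeneReference,
    qp_registry: list[QuasiPalindrome] | None = None,
    repeat_flag_min: int = DEFAULT_REPEAT_FLAG_MIN,
    strand_map: dict | None = None,
) -> MutationRecord:
    """Assign the mutation class and its descriptors.

    Precedence: (1) QP_TEMPLATED for an insertion/complex call perfecting a
    registered quasi-palindrome; (2) SBS; (3) indels >= 5 bp; (4) indels
    < 5 bp; (5) COMPLEX.  Indels get junction analysis over the whole
    shift range, reporting the maximal total homology.
    """
    seq = ref.sequence
    region = assign_region(variant, ref)

    if variant.kind in ("insertion", "complex") and qp_registry:
        v_lo, v_hi = variant.ref_interval[0], max(variant.ref_interval)
        for qp in qp_registry:
            fp_lo, fp_hi = qp.footprint
            if v_hi < fp_lo or v_lo > fp_hi:
                continue
            call = qp_perfection(variant, ref, qp, strand_map=strand_map)
            if call.perfected:
                return MutationRecord(
                    variant=variant, mclass="QP_TEMPLATED", qpcall=call, region=region
                )

    if variant.kind == "substitution":
        return MutationRecord(
            variant=variant, mclass="SBS", region=region, sbs=sbs_type(variant)
        )

    if variant.kind in ("deletion", "insertion"):
        size = variant.size
        if variant.kind == "deletion":
            junction = _best_junction_deletion(seq, variant)
            dup = False
        else:
            junction = _best_junction_insertion(seq, variant)
            dup = _is_duplication(seq, variant)
        label = (
            ("DEL_GE5" if variant.kind == "deletion" else "INS_GE5")
            if size >= 5
            else "INDEL_LT5"
        )
        return MutationRecord(
            variant=variant,
            mclass=label,
            junction=junction,
            region=region,
            is_duplication=dup,
            flanked_by_repeats=junction.total_len >= repeat_flag_min,
        )

    return MutationRecord(variant=variant, mclass="COMPLEX", region=region)


@dataclass
class SpectrumTable:
    """Counts per class, per region, per SBS type, and deletion:duplication."""

    class_counts: pd.Series
    region_counts: pd.DataFrame
    sbs_counts: pd.Series
    n_deletions: int
    n_duplications: int

    @property
    def total(self) -> int:
        return int(self.class_counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return self.class_counts.rename("count").to_frame()


def tabulate(records: list[MutationRecord]) -> SpectrumTable:
    """Aggregate classified records into a spectrum table."""
    class_counts = pd.Series(0, index=list(CLASS_LABELS), dtype=int)
    sbs_counts = pd.Series(0, index=list(SBS_TYPES), dtype=int)
    regions = sorted({r.region for r in records}) or ["unannotated"]
    region_counts = pd.DataFrame(0, index=list(CLASS_LABELS), columns=regions, dtype=int)
    n_del = n_dup = 0
    for rec in records:
        class_counts[rec.mclass] += 1
        region_counts.loc[rec.mclass, rec.region] += 1
        if rec.sbs is not None:
            sbs_counts[rec.sbs] += 1
        if rec.mclass == "DEL_GE5":
            n_del += 1
        if rec.mclass == "INS_GE5" and rec.is_duplication:
            n_dup += 1
    return SpectrumTable(
        class_counts=class_counts,
        region_counts=region_counts,
        sbs_counts=sbs_counts,
        n_deletions=n_del,
        n_duplications=n_dup,
    )


def records_to_frame(records: list[MutationRecord], gene: str = "") -> pd.DataFrame:
    """One row per mutation: the records TSV layout."""
    rows = []
    for rec in records:
        v = rec.variant
        rows.append(
            {
                "gene": gene,
                "kind": v.kind,
                "start": v.ref_interval[0],
                "end": v.ref_interval[1],
                "ref": v.ref_allele or ".",
                "alt": v.alt_allele or ".",
                "class": rec.mclass,
                "junction_forward": rec.junction.forward_len if rec.junction else "",
                "junction_backward": rec.junction.backward_len if rec.junction else "",
                "junction_total": rec.junction.total_len if rec.junction else "",
                "repeat_seq": rec.junction.repeat_seq if rec.junction else "",
                "flanked_by_repeats": rec.flanked_by_repeats,
                "is_duplication": rec.is_duplication,
                "qp_perfected": rec.qpcall.perfected if rec.qpcall else "",
                "qp_templated_arm": rec.qpcall.templated_arm if rec.qpcall else "",
                "qp_initiating_strand": rec.qpcall.initiating_strand if rec.qpcall else "",
                "region": rec.region,
                "sbs_type": rec.sbs or "",
            }
        )
    return pd.DataFrame(rows)
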