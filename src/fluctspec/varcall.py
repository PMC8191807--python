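"""Pairwise alignment of mutant alleles and normalized variant extraction.

A sequenced mutant allele is compared to its reference by one optimal global
alignment under fixed, documented scoring, and the differences are reduced to
normalized variant calls.  Because slippage deletions sit between direct
repeats, their placement on the reference is ambiguous; calls are left-aligned
(the VCF convention) but carry the full ``shift_range`` of equivalent
placements, which the junction-repeat analysis needs.

Scoring constants (bit-exact reproducibility): match +1, mismatch -2,
gap open -5, gap extend -1; a gap of length L scores -5 - (L-1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd
from Bio import Align, SeqIO

__all__ = [
    "VariantCall",
    "align_pair",
    "extract_variants",
    "normalize_indel",
    "call_variants",
    "apply_variants",
    "load_mutants_fasta",
    "read_variant_table",
    "write_variant_table",
    "MATCH_SCORE",
    "MISMATCH_SCORE",
    "GAP_OPEN",
    "GAP_EXTEND",
    "DEFAULT_MERGE_WINDOW",
]

MATCH_SCORE = 1
MISMATCH_SCORE = -2
GAP_OPEN = -5
GAP_EXTEND = -1
DEFAULT_MERGE_WINDOW = 10


@dataclass(frozen=True)
class VariantCall:
    """One normalized difference between mutant and reference.

    ``ref_interval`` is 1-based inclusive on the reference.  For an insertion
    it is the flanking pair ``(p, p+1)``: the alt bases sit between reference
    positions p and p+1 (p may be 0 for an insertion before the first base).
    ``shift_range`` is the interval of equivalent anchor positions: for a
    deletion, all possible start positions; for an insertion, all possible
    left-flank positions p.  Width 1 means the placement is unambiguous.
    """

    kind: str  # substitution | insertion | deletion | complex
    ref_interval: tuple[int, int]
    ref_allele: str
    alt_allele: str
    shift_range: tuple[int, int] | None = None

    def __post_init__(self):
        if self.kind == "substitution" and not (
            len(self.ref_allele) == len(self.alt_allele) == 1
        ):
            raise ValueError("substitution must have single-base alleles")
        if self.kind == "deletion" and self.alt_allele:
            raise ValueError("deletion must have empty alt allele")
        if self.kind == "insertion" and self.ref_allele:
            raise ValueError("insertion must have empty ref allele")

    @property
    def start(self) -> int:
        return self.ref_interval[0]

    @property
    def size(self) -> int:
        """Event size in bp (indels: inserted/deleted length; SBS: 1)."""
        if self.kind == "insertion":
            return len(self.alt_allele)
        if self.kind == "deletion":
            return len(self.ref_allele)
        return max(len(self.ref_allele), len(self.alt_allele))


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def align_pair(ref: str, mutant: str):
    """One optimal global alignment of mutant against reference.

    Returns a Bio.Align.Alignment.  Ties between co-optimal alignments are
    broken by the aligner's deterministic first traceback, so repeated runs
    are bit-identical.  A length ratio above 2 is rejected as a wrong-gene /
    failed-read input.
    """
    if not ref or not mutant:
        raise ValueError("both sequences must be non-empty")
    ratio = max(len(ref), len(mutant)) / min(len(ref), len(mutant))
    if ratio > 2:
        raise ValueError(
            f"sequence length ratio {ratio:.2f} > 2; mutant does not look like "
            "an allele of this reference"
        )
    return _make_aligner().align(ref, mutant)[0]


def extract_variants(alignment, merge_window: int = DEFAULT_MERGE_WINDOW) -> list[VariantCall]:
    """Reduce an alignment to variant calls.

    Maximal runs of difference columns become calls; calls separated by at
    most ``merge_window`` matching reference bases merge into one complex
    call (the merged alleles include the intervening matched bases).
    """
    ref_row = alignment[0]
    alt_row = alignment[1]
    # raw difference segments: [ref_start, ref_end, ref_str, alt_str]; a pure
    # insertion after reference position p has ref_start = p+1, ref_end = p.
    events: list[list] = []
    rpos = 0  # 1-based position of last consumed ref base
    current: list | None = None
    for rc, ac in zip(ref_row, alt_row):
        if rc != "-":
            rpos += 1
        if rc == ac:
            current = None
            continue
        if current is None:
            current = [rpos if rc != "-" else rpos + 1, rpos - 1, "", ""]
            events.append(current)
        if rc != "-":
            current[1] = rpos
            current[2] += rc
        if ac != "-":
            current[3] += ac

    # merge events closer than merge_window on the reference
    ref_seq = str(alignment.target)
    merged: list[list] = []
    for ev in events:
        if merged:
            prev = merged[-1]
            gap = ev[0] - prev[1] - 1
            if gap <= merge_window:
                between = ref_seq[prev[1] : ev[0] - 1]
                prev[1] = max(prev[1], ev[1])
                prev[2] = prev[2] + between + ev[2]
                prev[3] = prev[3] + between + ev[3]
                continue
        merged.append(ev)

    calls = []
    for start, end, ref_str, alt_str in merged:
        if ref_str and alt_str and len(ref_str) == len(alt_str) == 1:
            kind = "substitution"
            interval = (start, end)
        elif ref_str and not alt_str:
            kind = "deletion"
            interval = (start, end)
        elif alt_str and not ref_str:
            kind = "insertion"
            interval = (start - 1, start)  # flanking pair
        else:
            kind = "complex"
            interval = (start, end)
        calls.append(
            VariantCall(
                kind=kind,
                ref_interval=interval,
                ref_allele=ref_str,
                alt_allele=alt_str,
                shift_range=None,
            )
        )
    return calls


def normalize_indel(call: VariantCall, ref: str) -> VariantCall:
    """Left-align an indel and record all equivalent placements.

    The returned call is placed at the leftmost equivalent position;
    ``shift_range`` spans every anchor position producing the identical
    mutant sequence.  Idempotent; non-indels are returned unchanged.
    """
    if call.kind == "deletion":
        s, e = call.ref_interval
        size = e - s + 1
        lo = s
        while lo > 1 and ref[lo - 2] == ref[lo - 2 + size]:
            lo -= 1
        hi = s
        while hi + size <= len(ref) and ref[hi - 1] == ref[hi - 1 + size]:
            hi += 1
        return replace(
            call,
            ref_interval=(lo, lo + size - 1),
            ref_allele=ref[lo - 1 : lo - 1 + size],
            shift_range=(lo, hi),
        )
    if call.kind == "insertion":
        p = call.ref_interval[0]
        alt = call.alt_allele
        lo, alt_lo = p, alt
        while lo > 0 and ref[lo - 1] == alt_lo[-1]:
            alt_lo = ref[lo - 1] + alt_lo[:-1]
            lo -= 1
        hi, alt_hi = p, alt
        while hi < len(ref) and ref[hi] == alt_hi[0]:
            alt_hi = alt_hi[1:] + ref[hi]
            hi += 1
        return replace(
            call,
            ref_interval=(lo, lo + 1),
            alt_allele=alt_lo,
            shift_range=(lo, hi),
        )
    return call


def call_variants(
    ref: str, mutant: str, merge_window: int = DEFAULT_MERGE_WINDOW
) -> list[VariantCall]:
    """Align, extract and normalize: the full mutant -> calls pipeline."""
    aln = align_pair(ref, mutant)
    return [normalize_indel(c, ref) for c in extract_variants(aln, merge_window)]


def apply_variants(ref: str, calls: list[VariantCall]) -> str:
    """Apply calls (non-overlapping, any order) to the reference sequence."""

    def sort_key(c: VariantCall):
        return c.ref_interval[0]

    seq = ref
    for call in sorted(calls, key=sort_key, reverse=True):
        if call.kind == "insertion":
            p = call.ref_interval[0]
            seq = seq[:p] + call.alt_allele + seq[p:]
        else:
            s, e = call.ref_interval
            seq = seq[: s - 1] + call.alt_allele + seq[e:]
    return seq


def load_mutants_fasta(path: str | Path) -> dict[str, str]:
    """Mutant allele sequences keyed by record id, uppercased."""
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


_TABLE_COLS = ["gene", "pos", "ref", "alt"]


def read_variant_table(path: str | Path) -> list[tuple[str, VariantCall]]:
    """Read a VCF-like TSV (gene, pos, ref, alt; 1-based POS, VCF padding base).

    Returns (gene, call) pairs.  Indels use the VCF anchored representation:
    deletion  pos=10 ref="GAT" alt="G"; insertion pos=10 ref="G" alt="GTC".
    """
    tab = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _TABLE_COLS if c not in tab.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for row in tab.itertuples(index=False):
        pos, ref_a, alt_a = int(row.pos), str(row.ref).upper(), str(row.alt).upper()
        if len(ref_a) == len(alt_a) == 1:
            call = VariantCall("substitution", (pos, pos), ref_a, alt_a)
        elif len(ref_a) > 1 and alt_a == ref_a[0]:
            call = VariantCall(
                "deletion", (pos + 1, pos + len(ref_a) - 1), ref_a[1:], ""
            )
        elif len(alt_a) > 1 and ref_a == alt_a[0]:
            call = VariantCall("insertion", (pos, pos + 1), "", alt_a[1:])
        else:
            call = VariantCall(
                "complex", (pos, pos + len(ref_a) - 1), ref_a, alt_a
            )
        out.append((str(row.gene), call))
    return out


def write_variant_table(
    calls: list[tuple[str, VariantCall]], path: str | Path, header_lines: list[str] | None = None
) -> None:
    rows = []
    for gene, c in calls:
        rows.append(
            {
                "gene": gene,
                "kind": c.kind,
                "start": c.ref_interval[0],
                "end": c.ref_interval[1],
                "ref": c.ref_allele or ".",
                "alt": c.alt_allele or ".",
                "shift_lo": c.shift_range[0] if c.shift_range else c.ref_interval[0],
                "shift_hi": c.shift_range[1] if c.shift_range else c.ref_interval[0],
            }
        )
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
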