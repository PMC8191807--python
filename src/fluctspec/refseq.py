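"""Reference-gene model and sequence-feature scanners.

A reporter gene is a short, fully determined DNA sequence (a few kb) carrying
optional region annotations (e.g. an engineered GC-rich 5' half vs. an
unmodified 3' half) and a replication-fork direction relative to the nearest
origin.  The scanners locate the two sequence features that matter for
mutation-spectrum analysis:

* **direct repeats** — identical substrings present twice on the same strand;
  deletions/duplications between them are the signature of polymerase
  slippage, and the repeat length/separation set the slippage geometry;
* **quasi-palindromes (QPs)** — imperfect inverted repeats; insertions that
  convert them into perfect palindromes are the signature of template
  switching.

All coordinates are 1-based inclusive.  Converters for 0-based half-open
(BED) input live at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

__all__ = [
    "GeneReference",
    "RegionAnnotation",
    "DirectRepeatPair",
    "QuasiPalindrome",
    "revcomp",
    "load_reference",
    "gc_content",
    "scan_direct_repeats",
    "scan_quasipalindromes",
]

_ALPHABET = frozenset("ACGT")
_COMP = str.maketrans("ACGT", "TGCA")

FORK_DIRECTIONS = ("leftward-origin", "rightward-origin", "unknown")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMP)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMP)


@dataclass(frozen=True)
class RegionAnnotation:
    """A labelled interval on the reference, 1-based inclusive."""

    label: str
    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"region {self.label!r}: need 1 <= start <= end, got [{self.start}, {self.end}]"
            )

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class DirectRepeatPair:
    """Two identical substrings on the same strand.

    ``separation`` is the number of bases between the end of the left copy and
    the start of the right copy; 0 means the copies abut (tandem).  A slippage
    deletion between the copies removes ``separation + length`` bases.
    """

    left_start: int
    right_start: int
    length: int

    def __post_init__(self):
        if self.left_start + self.length > self.right_start:
            raise ValueError("repeat copies overlap")

    @property
    def separation(self) -> int:
        return self.right_start - (self.left_start + self.length)

    @property
    def deletion_size(self) -> int:
        """Size of the slippage deletion between the copies (one copy retained)."""
        return self.right_start - self.left_start

    def extract(self, seq: str) -> tuple[str, str]:
        l = seq[self.left_start - 1 : self.left_start - 1 + self.length]
        r = seq[self.right_start - 1 : self.right_start - 1 + self.length]
        return l, r


@dataclass(frozen=True)
class QuasiPalindrome:
    """An imperfect inverted repeat: two arms around a loop.

    ``mismatch_positions`` are the 1-based reference positions on the right
    arm whose base deviates from the reverse complement of the left arm.
    Arms may differ in length (a length-defect QP): such a QP is perfected by
    an *insertion* completing the short arm, the diagnostic event for
    template switching.
    """

    left_arm: tuple[int, int]
    right_arm: tuple[int, int]
    loop_len: int
    mismatch_positions: tuple[int, ...] = ()

    def __post_init__(self):
        if self.left_arm[1] >= self.right_arm[0]:
            raise ValueError("QP arms overlap")

    @property
    def footprint(self) -> tuple[int, int]:
        return (self.left_arm[0], self.right_arm[1])

    @property
    def is_perfect(self) -> bool:
        return (
            len(self.mismatch_positions) == 0
            and (self.left_arm[1] - self.left_arm[0])
            == (self.right_arm[1] - self.right_arm[0])
        )

    def arm_seqs(self, seq: str) -> tuple[str, str]:
        l = seq[self.left_arm[0] - 1 : self.left_arm[1]]
        r = seq[self.right_arm[0] - 1 : self.right_arm[1]]
        return l, r


@dataclass
class GeneReference:
    """A reporter gene: validated sequence plus annotations.

    fork_direction encodes which side of the gene the replication origin sits
    on ("leftward-origin" = origin left of the gene, fork moves rightward
    through it).
    """

    name: str
    sequence: str
    regions: list[RegionAnnotation] = field(default_factory=list)
    fork_direction: str = "unknown"

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"{self.name}: empty sequence")
        bad = [i for i, b in enumerate(self.sequence, start=1) if b not in _ALPHABET]
        if bad:
            raise ValueError(
                f"{self.name}: non-ACGT symbol {self.sequence[bad[0]-1]!r} at position {bad[0]}"
                " (ambiguity codes are not accepted)"
            )
        if self.fork_direction not in FORK_DIRECTIONS:
            raise ValueError(f"fork_direction must be one of {FORK_DIRECTIONS}")
        n = len(self.sequence)
        prev_end = 0
        for reg in sorted(self.regions, key=lambda r: r.start):
            if reg.end > n:
                raise ValueError(f"region {reg.label!r} exceeds sequence length {n}")
            if reg.start <= prev_end:
                raise ValueError(f"region {reg.label!r} overlaps a previous region")
            prev_end = reg.end

    def __len__(self) -> int:
        return len(self.sequence)

    def region_of(self, pos: int, default: str = "unannotated") -> str:
        for reg in self.regions:
            if reg.contains(pos):
                return reg.label
        return default


def load_reference(
    path: str | Path,
    annotations: str | Path | None = None,
    name: str | None = None,
    fork_direction: str = "unknown",
) -> GeneReference:
    """Read a reference gene from FASTA, optionally with a region TSV.

    The annotation TSV has columns ``label``, ``start``, ``end`` (1-based
    inclusive).  If the FASTA holds several records, ``name`` selects one.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    if name is not None:
        matches = [r for r in records if r.id == name]
        if not matches:
            raise ValueError(f"{path}: no record named {name!r}")
        rec = matches[0]
    else:
        if len(records) > 1:
            raise ValueError(
                f"{path}: {len(records)} records present; pass name= to select one"
            )
        rec = records[0]
    regions: list[RegionAnnotation] = []
    if annotations is not None:
        tab = pd.read_csv(annotations, sep="\t", comment="#")
        for row in tab.itertuples(index=False):
            regions.append(RegionAnnotation(str(row.label), int(row.start), int(row.end)))
    return GeneReference(
        name=rec.id, sequence=str(rec.seq), regions=regions, fork_direction=fork_direction
    )


def load_qp_registry(path: str | Path) -> list[QuasiPalindrome]:
    """Read a curated quasi-palindrome registry TSV.

    Columns: ``left_start``, ``left_end``, ``right_start``, ``right_end``,
    ``loop_len`` (1-based inclusive).  Curated registries can describe
    length-defect QPs (arms of unequal length), which the symmetric scanner
    does not emit but which are the substrates of templated insertions.
    """
    tab = pd.read_csv(path, sep="\t", comment="#")
    need = ["left_start", "left_end", "right_start", "right_end", "loop_len"]
    missing = [c for c in need if c not in tab.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        QuasiPalindrome(
            left_arm=(int(r.left_start), int(r.left_end)),
            right_arm=(int(r.right_start), int(r.right_end)),
            loop_len=int(r.loop_len),
        )
        for r in tab.itertuples(index=False)
    ]


def _seq_of(ref) -> str:
    return ref.sequence if isinstance(ref, GeneReference) else str(ref).upper()


def gc_content(ref: GeneReference | str, region: tuple[int, int] | None = None) -> float:
    """Fraction of G+C bases, optionally restricted to a 1-based inclusive interval."""
    seq = _seq_of(ref)
    if region is not None:
        start, end = region
        if not (1 <= start <= end <= len(seq)):
            raise ValueError(f"region [{start}, {end}] outside sequence of length {len(seq)}")
        seq = seq[start - 1 : end]
    if not seq:
        raise ValueError("empty region")
    return (seq.count("G") + seq.count("C")) / len(seq)


def scan_direct_repeats(
    ref: GeneReference | str,
    min_len: int = 4,
    max_separation: int | None = None,
) -> list[DirectRepeatPair]:
    """All maximal exact direct-repeat pairs with length >= min_len.

    Equivalently: for every offset d and every maximal run of positions x
    with seq[x] == seq[x+d], one pair is reported with length min(run, d)
    placed at the left end of the run.  The min(run, d) cap keeps the two
    copies non-overlapping, so a homopolymer or periodic run collapses to
    its single maximal tandem pair instead of every sub-alignment.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    seq = _seq_of(ref)
    n = len(seq)
    k = min_len
    if n < 2 * k:
        return []
    kmer_pos: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        kmer_pos.setdefault(seq[i : i + k], []).append(i)

    found: set[tuple[int, int, int]] = set()
    for positions in kmer_pos.values():
        if len(positions) < 2:
            continue
        for a in range(len(positions)):
            for b in range(a + 1, len(positions)):
                i, j = positions[a], positions[b]
                d = j - i  # offset; copies overlap iff length > d
                if d < k:
                    continue
                # extend left
                li, lj = i, j
                while li > 0 and seq[li - 1] == seq[lj - 1]:
                    li -= 1
                    lj -= 1
                # extend right from the seed end
                ri = i + k  # one past left copy end
                rj = j + k
                while rj < n and seq[ri] == seq[rj]:
                    ri += 1
                    rj += 1
                length = ri - li
                if length > d:  # cap so copies do not overlap
                    # keep the leftmost window of the matched run: tandem pair
                    lj = li + d
                    length = d
                if length < k:
                    continue
                found.add((li + 1, lj + 1, length))

    out = []
    for left_start, right_start, length in sorted(found):
        pair = DirectRepeatPair(left_start, right_start, length)
        if max_separation is not None and pair.separation > max_separation:
            continue
        out.append(pair)
    return out


def scan_quasipalindromes(
    ref: GeneReference | str,
    min_arm: int = 6,
    max_loop: int = 12,
    max_mismatch: int = 2,
) -> list[QuasiPalindrome]:
    """All maximal inverted-repeat structures (quasi-palindromes).

    For each placement of the inner boundary (end of left arm) and each loop
    length, arms grow outward symmetrically; the single largest arm whose
    mismatch count stays within ``max_mismatch`` is reported if it reaches
    ``min_arm``.  Mismatch positions are reported on the right arm.
    """
    if min_arm < 4:
        raise ValueError("min_arm must be >= 4")
    seq = _seq_of(ref)
    n = len(seq)
    out = []
    for c in range(1, n):  # c = 0-based index one past the left arm end
        for loop in range(0, max_loop + 1):
            r0 = c + loop  # 0-based start of right arm
            max_a = min(c, n - r0)
            if max_a < min_arm:
                continue
            mism: list[int] = []
            a = 0
            while a < max_a:
                lbase = seq[c - a - 1]
                rbase = seq[r0 + a]
                if rbase != complement(lbase):
                    if len(mism) == max_mismatch:
                        break
                    mism.append(r0 + a + 1)  # 1-based right-arm position
                a += 1
            if a >= min_arm:
                out.append(
                    QuasiPalindrome(
                        left_arm=(c - a + 1, c),
                        right_arm=(r0 + 1, r0 + a),
                        loop_len=loop,
                        mismatch_positions=tuple(sorted(mism)),
                    )
                )
    return out
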