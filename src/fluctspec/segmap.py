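"""Segregant interval mapping: localize a causal locus by intersection.

Each haploid meiotic segregant carries a mosaic of the two parental genomes,
recorded as parental-origin intervals per chromosome.  If a phenotype is
caused by a single locus from parent A, every phenotype-positive segregant
must carry parent A across that locus; intersecting their parent-A intervals
(and optionally excluding segments also shared by every phenotype-negative
segregant) leaves the candidate region.  The mapping is a deterministic
interval intersection, not a statistical scan.

Coordinates are 1-based inclusive internally; BED input (0-based half-open)
is converted at the boundary.  Genotype gaps are treated as unknown and do
not count as sharing (conservative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "GenotypeTrack",
    "shared_parental_segments",
    "genes_in_region",
    "load_genotype_tracks",
]


@dataclass
class GenotypeTrack:
    """Parental-origin intervals for one segregant.

    ``intervals`` holds (chromosome, start, end, parent) tuples, 1-based
    inclusive, non-overlapping and sorted per chromosome; parent labels are
    binary (conventionally "A" / "B").
    """

    segregant_id: str
    phenotype: str  # mutator | non-mutator (free-form, filtered by equality)
    intervals: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, parent in self.intervals:
            if start > end:
                raise ValueError(f"{self.segregant_id}: interval start {start} > end {end}")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(
                        f"{self.segregant_id}: overlapping intervals on {chrom}"
                    )
        self.intervals = sorted(self.intervals, key=lambda t: (t[0], t[1]))

    def parent_intervals(self, parent: str) -> dict[str, list[tuple[int, int]]]:
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, p in self.intervals:
            if p == parent:
                out.setdefault(chrom, []).append((start, end))
        return {chrom: _merge_adjacent(ivs) for chrom, ivs in out.items()}


def _merge_adjacent(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge abutting/overlapping sorted intervals so runs are maximal."""
    out: list[list[int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _intersect(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Intersection of two sorted non-overlapping 1-based inclusive interval lists."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo <= hi:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _subtract(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """a minus b, both sorted non-overlapping."""
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] < cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] <= e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs - 1))
            cur = max(cur, be + 1)
            k += 1
        if cur <= e:
            out.append((cur, e))
    return out


def shared_parental_segments(
    tracks: list[GenotypeTrack],
    required_parent: str = "A",
    phenotype_filter: str = "mutator",
    exclude_shared_by: str | None = None,
) -> list[tuple[str, int, int]]:
    """Maximal intervals carried as ``required_parent`` by every filtered track.

    ``exclude_shared_by`` optionally names a phenotype whose tracks, when
    they *all* also share a segment as ``required_parent``, remove it from
    the candidates (segments uninformative for the phenotype contrast).
    """
    selected = [t for t in tracks if t.phenotype == phenotype_filter]
    if len(selected) < 2:
        raise ValueError(
            f"need at least 2 tracks with phenotype {phenotype_filter!r}, "
            f"got {len(selected)}"
        )
    per_track = [t.parent_intervals(required_parent) for t in selected]
    chroms = set(per_track[0])
    for d in per_track[1:]:
        chroms &= set(d)

    shared: dict[str, list[tuple[int, int]]] = {}
    for chrom in sorted(chroms):
        acc = per_track[0][chrom]
        for d in per_track[1:]:
            acc = _intersect(acc, d[chrom])
            if not acc:
                break
        if acc:
            shared[chrom] = acc

    if exclude_shared_by is not None:
        others = [t for t in tracks if t.phenotype == exclude_shared_by]
        if others:
            other_per = [t.parent_intervals(required_parent) for t in others]
            for chrom in list(shared):
                acc = other_per[0].get(chrom, [])
                for d in other_per[1:]:
                    acc = _intersect(acc, d.get(chrom, []))
                    if not acc:
                        break
                if acc:
                    shared[chrom] = _subtract(shared[chrom], acc)
                if not shared[chrom]:
                    del shared[chrom]

    return [(chrom, s, e) for chrom in sorted(shared) for s, e in shared[chrom]]


def genes_in_region(
    interval: tuple[str, int, int], annotation: pd.DataFrame | str | Path
) -> list[str]:
    """Genes overlapping a (chrom, start, end) interval.

    ``annotation`` is a GFF-like TSV (or DataFrame) with columns ``chrom``,
    ``start``, ``end``, ``gene`` (1-based inclusive coordinates).
    """
    if not isinstance(annotation, pd.DataFrame):
        annotation = pd.read_csv(annotation, sep="\t", comment="#")
    missing = [c for c in ("chrom", "start", "end", "gene") if c not in annotation.columns]
    if missing:
        raise ValueError(f"annotation is missing columns {missing}")
    chrom, start, end = interval
    if start > end:
        return []
    hit = annotation[
        (annotation["chrom"] == chrom)
        & (annotation["start"].astype(int) <= end)
        & (annotation["end"].astype(int) >= start)
    ]
    return hit["gene"].astype(str).tolist()


def load_genotype_tracks(path: str | Path, coords: str = "one-based") -> list[GenotypeTrack]:
    """Read the genotype TSV (chrom, start, end, parent, segregant, phenotype).

    ``coords="bed"`` treats start/end as 0-based half-open and converts.
    """
    tab = pd.read_csv(path, sep="\t", comment="#")
    need = ["chrom", "start", "end", "parent", "segregant", "phenotype"]
    missing = [c for c in need if c not in tab.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    tracks = []
    for (seg, phen), grp in tab.groupby(["segregant", "phenotype"], sort=True):
        ivs = []
        for row in grp.itertuples(index=False):
            start, end = int(row.start), int(row.end)
            if coords == "bed":
                start, end = start + 1, end
            ivs.append((str(row.chrom), start, end, str(row.parent)))
        tracks.append(GenotypeTrack(str(seg), str(phen), ivs))
    return tracks
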