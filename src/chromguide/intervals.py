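"""Genomic interval algebra and labeled genome partitions.

All intervals are 0-based half-open ``[start, end)``. An *interval set* is a
``dict`` mapping chromosome name to a sorted list of non-overlapping
``(start, end)`` tuples; a :class:`GenomicPartition` maps a closed label
vocabulary onto such sets so that the labels are pairwise disjoint and
together tile a declared universe exactly.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

from intervaltree import IntervalTree

Interval = Tuple[int, int]
IntervalSet = Dict[str, List[Interval]]


def merge_intervals(intervals: Iterable[Interval]) -> List[Interval]:
    """Sort and merge overlapping or touching intervals into a disjoint list."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    merged: List[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def merge_interval_set(ivset: IntervalSet) -> IntervalSet:
    return {c: merge_intervals(ivs) for c, ivs in ivset.items()}


def complement_intervals(intervals: List[Interval], universe: Interval) -> List[Interval]:
    """Gaps of a merged interval list within ``universe`` (edges included)."""
    us, ue = universe
    out: List[Interval] = []
    cursor = us
    for s, e in intervals:
        s, e = max(s, us), min(e, ue)
        if e <= s:
            continue
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < ue:
        out.append((cursor, ue))
    return out


def intersect_intervals(a: List[Interval], b: List[Interval]) -> List[Interval]:
    """Intersection of two sorted disjoint interval lists (linear sweep)."""
    out: List[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def clip_intervals(intervals: Iterable[Interval], bound: Interval) -> List[Interval]:
    lo, hi = bound
    out = []
    for s, e in intervals:
        s, e = max(s, lo), min(e, hi)
        if e > s:
            out.append((s, e))
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in intervals)


def set_total_length(ivset: IntervalSet) -> int:
    return sum(total_length(ivs) for ivs in ivset.values())


def point_in_intervals(intervals: List[Interval], pos: int) -> bool:
    """Membership test on a sorted disjoint interval list via bisection."""
    i = bisect_right(intervals, (pos, float("inf"))) - 1
    return i >= 0 and intervals[i][0] <= pos < intervals[i][1]


class PartitionError(ValueError):
    """Raised when a labeled interval collection is not a valid partition."""


@dataclass
class GenomicPartition:
    """A labeled, disjoint, exhaustive set of intervals over a universe.

    Parameters
    ----------
    labels
        Mapping label -> interval set. Each label's intervals are merged on
        construction.
    universe
        Interval set the labels must tile exactly.
    """

    labels: Dict[str, IntervalSet]
    universe: IntervalSet
    _trees: Dict[str, IntervalTree] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.labels = {lab: merge_interval_set(ivset) for lab, ivset in self.labels.items()}
        self.universe = merge_interval_set(self.universe)

    def validate(self) -> None:
        """Check disjointness between labels and exact coverage of the universe."""
        for chrom, uni in self.universe.items():
            pooled: List[Interval] = []
            for lab, ivset in self.labels.items():
                pooled.extend(ivset.get(chrom, []))
            pooled.sort()
            for (s1, e1), (s2, e2) in zip(pooled, pooled[1:]):
                if s2 < e1:
                    raise PartitionError(
                        f"labels overlap on {chrom} at [{s2}, {min(e1, e2)})"
                    )
            if merge_intervals(pooled) != uni:
                raise PartitionError(f"labels do not tile the universe on {chrom}")
        # no label may stray outside the universe's chromosomes
        for lab, ivset in self.labels.items():
            for chrom, ivs in ivset.items():
                if ivs and chrom not in self.universe:
                    raise PartitionError(f"label {lab} on {chrom} outside universe")

    def _tree(self, chrom: str) -> IntervalTree:
        if chrom not in self._trees:
            tree = IntervalTree()
            for lab, ivset in self.labels.items():
                for s, e in ivset.get(chrom, []):
                    tree[s:e] = lab
            self._trees[chrom] = tree
        return self._trees[chrom]

    def label_at(self, chrom: str, pos: int) -> str:
        """Label covering ``pos``; ``"unclassified"`` outside the universe."""
        hits = self._tree(chrom)[pos] if chrom in self.universe else set()
        if not hits:
            return "unclassified"
        if len(hits) > 1:  # pragma: no cover - validate() forbids this
            raise PartitionError(f"overlapping labels at {chrom}:{pos}")
        return next(iter(hits)).data

    def label_length(self, label: str) -> int:
        return set_total_length(self.labels.get(label, {}))

    def universe_length(self) -> int:
        return set_total_length(self.universe)

    def genome_fraction(self, label: str) -> float:
        """Fraction of universe bases carrying ``label``."""
        return self.label_length(label) / self.universe_length()

    # ------------------------------------------------------------------ I/O
    def to_bed(self, path) -> None:
        """Write all labeled intervals as BED4 (name column = label)."""
        rows = []
        for lab, ivset in self.labels.items():
            for chrom, ivs in ivset.items():
                rows.extend((chrom, s, e, lab) for s, e in ivs)
        rows.sort()
        with open(path, "w") as fh:
            for chrom, s, e, lab in rows:
                fh.write(f"{chrom}\t{s}\t{e}\t{lab}\n")

    @classmethod
    def from_bed(cls, path, universe: IntervalSet) -> "GenomicPartition":
        labels: Dict[str, IntervalSet] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                chrom, s, e, lab = line.split("\t")[:4]
                labels.setdefault(lab.strip(), {}).setdefault(chrom, []).append(
                    (int(s), int(e))
                )
        return cls(labels=labels, universe=universe)


def read_bed_intervals(path) -> IntervalSet:
    """Read a BED file's first three columns into a merged interval set."""
    out: IntervalSet = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            out.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
    return merge_interval_set(out)


def write_bed_intervals(ivset: IntervalSet, path, name: str | None = None) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(ivset):
            for s, e in ivset[chrom]:
                if name is None:
                    fh.write(f"{chrom}\t{s}\t{e}\n")
                else:
                    fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")
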