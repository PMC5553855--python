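"""Open/closed chromatin (OC/CC) genome partition from ATAC-seq peak calls.

Peak calling itself is delegated to an external caller (narrowPeak files are
consumed); this module implements the read-filtering contract upstream and
everything downstream: extend each peak summit by 1000 bp on both sides,
merge across the two embryonic stages, and take the genome complement as
closed chromatin.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd

from .intervals import (
    GenomicPartition,
    IntervalSet,
    complement_intervals,
    merge_interval_set,
)
from .samio import AlignedRead

logger = logging.getLogger(__name__)

SUMMIT_EXTENSION = 1000  # bp added on each side of a peak summit
MAPQ_MIN = 30


@dataclass(frozen=True)
class AtacPeak:
    chrom: str
    start: int
    end: int
    summit: int  # absolute position
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty peak interval {self.chrom}:{self.start}-{self.end}")
        if not (self.start <= self.summit < self.end):
            raise ValueError(f"summit {self.summit} outside {self.chrom}:{self.start}-{self.end}")


def read_narrowpeak(path) -> List[AtacPeak]:
    """Parse ENCODE narrowPeak (BED6+4); column 10 is the summit offset."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            start, end = int(f[1]), int(f[2])
            offset = int(f[9])
            peaks.append(
                AtacPeak(
                    chrom=f[0], start=start, end=end,
                    summit=start + offset,
                    score=float(f[6]) if len(f) > 6 else 0.0,
                )
            )
    return peaks


def filter_atac_alignments(
    alignments: Iterable[AlignedRead],
    mapq_min: int = MAPQ_MIN,
    scaffold_pattern: str = r"scaffold",
) -> Tuple[List[AlignedRead], Dict[str, int]]:
    """Drop unmapped reads, scaffold-chromosome reads and MAPQ < ``mapq_min``."""
    pat = re.compile(scaffold_pattern, re.IGNORECASE)
    kept: List[AlignedRead] = []
    tally = {"input": 0, "dropped_unmapped": 0, "dropped_scaffold": 0,
             "dropped_mapq": 0, "kept": 0}
    for rec in alignments:
        tally["input"] += 1
        if not rec.is_mapped or rec.chrom is None:
            tally["dropped_unmapped"] += 1
        elif pat.search(rec.chrom):
            tally["dropped_scaffold"] += 1
        elif rec.mapq < mapq_min:
            tally["dropped_mapq"] += 1
        else:
            kept.append(rec)
            tally["kept"] += 1
    return kept, tally


def summits_to_oc(
    peak_sets: Sequence[Sequence[AtacPeak]],
    chrom_sizes: Dict[str, int],
    extension: int = SUMMIT_EXTENSION,
) -> IntervalSet:
    """Extend every summit by ``extension`` bp both ways and merge the union.

    Peaks from all stages are pooled before merging; extensions are clipped
    at chromosome bounds (with a warning when a summit lies beyond the end).
    """
    raw: IntervalSet = {}
    for peaks in peak_sets:
        for p in peaks:
            size = chrom_sizes.get(p.chrom)
            if size is None:
                logger.warning("peak on unknown chromosome %s skipped", p.chrom)
                continue
            if p.summit >= size:
                logger.warning("summit %s:%d beyond chromosome end, clipping", p.chrom, p.summit)
            s = max(0, p.summit - extension)
            e = min(size, p.summit + extension)
            if e > s:
                raw.setdefault(p.chrom, []).append((s, e))
    return merge_interval_set(raw)


def partition_oc_cc(oc: IntervalSet, chrom_sizes: Dict[str, int]) -> GenomicPartition:
    """OC plus its genome complement (CC) as a whole-genome partition."""
    universe: IntervalSet = {c: [(0, n)] for c, n in chrom_sizes.items()}
    cc: IntervalSet = {}
    oc_full: IntervalSet = {}
    for chrom, size in chrom_sizes.items():
        ivs = oc.get(chrom, [])
        oc_full[chrom] = ivs
        cc[chrom] = complement_intervals(ivs, (0, size))
    part = GenomicPartition(labels={"OC": oc_full, "CC": cc}, universe=universe)
    part.validate()
    return part


def genome_fraction(partition: GenomicPartition, label: str) -> float:
    """Fraction of the universe carrying ``label`` (e.g. OC over the genome)."""
    return partition.genome_fraction(label)


def read_chrom_sizes(path) -> Dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_chrom_sizes(chrom_sizes: Dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for c, n in chrom_sizes.items():
            fh.write(f"{c}\t{n}\n")
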