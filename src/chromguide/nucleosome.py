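"""Nucleosome-occupancy partition of gene bodies from MNase-seq tags.

Pipeline: shift stranded 5' tag positions by +/-73 bp to nucleosome
midpoints (dyads), pool stages, smooth the per-bp midpoint counts with a
Gaussian kernel (sigma = 20 bp), call peaks greedily with a 147 bp exclusion
zone, lay a 147 bp footprint under each peak, and classify merged footprints
and their complement gaps into nucleosome-occupied (NO), nucleosome-linker
(NL) and dynamic regions over the gene-body universe:

* merged footprint piece shorter than 180 bp -> NO
* merged footprint piece >= 180 bp -> dynamic
* complement gap g with 10 < g < 100 -> NL
* everything else in the universe -> dynamic
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import (
    GenomicPartition,
    Interval,
    IntervalSet,
    clip_intervals,
    complement_intervals,
    intersect_intervals,
    merge_intervals,
    point_in_intervals,
)

logger = logging.getLogger(__name__)

MIDPOINT_SHIFT = 73      # bp from a read 5' end to the nucleosome dyad
NUC_FOOTPRINT = 147      # bp of nucleosomal DNA; also the peak exclusion zone
NO_MAX_LEN = 180         # merged pieces shorter than this are NO
NL_GAP_BOUNDS = (10, 100)  # strict bounds on linker gap width


@dataclass(frozen=True)
class Tag:
    """A mapped-read 5' position with strand (pre-shift)."""

    chrom: str
    pos: int
    strand: str


@dataclass(frozen=True)
class NucPeak:
    chrom: str
    center: int
    score: float

    @property
    def footprint(self) -> Interval:
        # 147 centered with the left-biased even split
        return (self.center - 73, self.center + 74)


def read_tags_bed(path) -> List[Tag]:
    """Read BED6 tags; the start coordinate is the stranded 5' position.

    For minus-strand features the 5' end is the rightmost aligned base,
    i.e. ``end - 1``.
    """
    tags = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            strand = f[5] if len(f) > 5 else "+"
            pos = start if strand == "+" else end - 1
            tags.append(Tag(chrom=chrom, pos=pos, strand=strand))
    return tags


def shift_to_midpoints(
    tags: Iterable[Tag],
    chrom_sizes: Dict[str, int],
    shift: int = MIDPOINT_SHIFT,
    universe: IntervalSet | None = None,
) -> Dict[str, np.ndarray]:
    """Per-chromosome midpoint count vectors from stranded 5' tag positions.

    Plus-strand tag at p contributes a midpoint at p + shift; minus-strand
    tag with 5' coordinate q contributes q - shift. Midpoints falling outside
    chromosome bounds (or, when ``universe`` is given, outside it) are
    dropped and logged. Tags from multiple stages can simply be chained.
    """
    profiles = {c: np.zeros(n, dtype=np.int64) for c, n in chrom_sizes.items()}
    dropped = skipped = 0
    for tag in tags:
        if tag.strand == "+":
            mid = tag.pos + shift
        elif tag.strand == "-":
            mid = tag.pos - shift
        else:
            skipped += 1
            continue
        size = chrom_sizes.get(tag.chrom)
        if size is None or not (0 <= mid < size):
            dropped += 1
            continue
        if universe is not None and not point_in_intervals(
            universe.get(tag.chrom, []), mid
        ):
            dropped += 1
            continue
        profiles[tag.chrom][mid] += 1
    if skipped:
        logger.warning("skipped %d tags with unknown strand", skipped)
    if dropped:
        logger.info("dropped %d midpoints outside bounds/universe", dropped)
    return profiles


def smooth_profile(counts: np.ndarray, sigma: float = 20.0) -> np.ndarray:
    """Gaussian-smooth a count vector: s(i) = sum_j c(j) exp(-(i-j)^2/2sigma^2).

    The unnormalized kernel is truncated at +/- 5 sigma, so an isolated unit
    count yields a peak of height exactly 1.0 at its position.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    half = int(np.ceil(5 * sigma))
    x = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-(x ** 2) / (2.0 * sigma ** 2))
    return np.convolve(counts.astype(float), kernel, mode="same")


def detect_peaks(
    signal: np.ndarray,
    chrom: str,
    exclusion: int = NUC_FOOTPRINT,
    min_score: float = 5.0,
) -> List[NucPeak]:
    """Greedy highest-first peak selection with an exclusion zone.

    Candidates are the local maxima of the smoothed signal (plateaus counted
    once, at their leftmost position). Repeatedly take the highest remaining
    candidate as a peak center and exclude all positions within
    +/- floor(exclusion/2); candidates below ``min_score`` are never taken.
    Ties break leftmost. A shoulder flanking a taller peak is not a local
    maximum, so it cannot resurface just outside the exclusion zone.
    """
    if exclusion < 1:
        raise ValueError("exclusion must be >= 1")
    half = exclusion // 2
    left = np.empty(signal.size, dtype=bool)
    right = np.empty(signal.size, dtype=bool)
    left[0], right[-1] = True, True
    left[1:] = signal[1:] > signal[:-1]       # strictly rising into i
    right[:-1] = signal[:-1] >= signal[1:]    # not rising out of i (plateau-left)
    candidates = np.flatnonzero(left & right & (signal >= min_score))
    if candidates.size == 0:
        return []
    order = candidates[np.argsort(-signal[candidates], kind="stable")]
    available = np.ones(signal.size, dtype=bool)
    peaks: List[NucPeak] = []
    for pos in order:
        if available[pos]:
            peaks.append(NucPeak(chrom=chrom, center=int(pos), score=float(signal[pos])))
            available[max(0, pos - half) : pos + half + 1] = False
    peaks.sort(key=lambda p: p.center)
    return peaks


def call_nucleosome_peaks(
    profiles: Dict[str, np.ndarray],
    sigma: float = 20.0,
    exclusion: int = NUC_FOOTPRINT,
    min_score: float = 5.0,
) -> List[NucPeak]:
    peaks: List[NucPeak] = []
    for chrom in sorted(profiles):
        smoothed = smooth_profile(profiles[chrom], sigma=sigma)
        peaks.extend(detect_peaks(smoothed, chrom, exclusion=exclusion, min_score=min_score))
    return peaks


def classify_nucleosome_regions(
    peaks: Sequence[NucPeak],
    universe: IntervalSet,
    no_max_len: int = NO_MAX_LEN,
    nl_gap_bounds: Tuple[int, int] = NL_GAP_BOUNDS,
) -> GenomicPartition:
    """Partition gene bodies into NL / NO / dynamic from called peaks.

    Footprints (147 bp per peak) are merged genome-wide; each merged piece is
    classified by its *merged* length (< ``no_max_len`` -> NO, else dynamic)
    and then clipped to the universe. Complement gaps strictly between the
    ``nl_gap_bounds`` become NL; every other universe base is dynamic.
    """
    if not universe or all(not ivs for ivs in universe.values()):
        raise ValueError("universe is empty")
    lo_gap, hi_gap = nl_gap_bounds
    labels: Dict[str, IntervalSet] = {"NL": {}, "NO": {}, "dynamic": {}}

    by_chrom: Dict[str, List[Interval]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p.footprint)

    for chrom, uni in universe.items():
        merged = merge_intervals(by_chrom.get(chrom, []))
        no_pieces = [iv for iv in merged if iv[1] - iv[0] < no_max_len]
        dyn_pieces = [iv for iv in merged if iv[1] - iv[0] >= no_max_len]
        labels["NO"][chrom] = intersect_intervals(no_pieces, uni)
        dynamic = intersect_intervals(dyn_pieces, uni)

        # complement gaps within each universe interval
        nl: List[Interval] = []
        for us, ue in uni:
            clipped = clip_intervals(merged, (us, ue))
            for gs, ge in complement_intervals(clipped, (us, ue)):
                width = ge - gs
                if lo_gap < width < hi_gap:
                    nl.append((gs, ge))
                else:
                    dynamic.append((gs, ge))
        labels["NL"][chrom] = merge_intervals(nl)
        labels["dynamic"][chrom] = merge_intervals(dynamic)

    part = GenomicPartition(labels=labels, universe=universe)
    part.validate()
    return part


def peaks_to_bed(peaks: Sequence[NucPeak], path) -> None:
    rows = [(p.chrom, p.footprint[0], p.footprint[1], f"nuc_{p.chrom}_{p.center}", p.score)
            for p in peaks]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False,
                              float_format="%.3f")
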