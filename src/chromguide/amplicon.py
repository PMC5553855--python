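"""Per-target CRISPR/Cas9 efficiency from amplicon sequencing.

The measurement is the fraction of reads covering the 40 bp window around the
Cas9 cut site that carry at least one retained insertion/deletion event. The
stages are: demultiplex read pairs by primer prefixes, keep pairs whose
alignments fall around the designed site, call indel events from CIGAR
strings, aggregate events by signature and drop those below a minimum
occurrence rate (default 0.5%, strict), then form the read-count ratio.

Coordinates are 0-based half-open; the cut position is an inter-base
coordinate 3 bp 5' of the PAM (between protospacer positions 17 and 18).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd

from .samio import AlignedRead, CigarError, ReadPair, parse_cigar

logger = logging.getLogger(__name__)

WINDOW = 40  # bp around the cut site used for both event calling and coverage


class TargetTableError(ValueError):
    """Raised for an invalid or ambiguous target table."""


@dataclass(frozen=True)
class AmpliconTarget:
    """One designed gRNA site with its amplicon and primers."""

    target_id: str
    gene: str
    chrom: str
    proto_start: int
    proto_end: int  # half-open; proto_end - proto_start == 20
    strand: str  # strand carrying the protospacer
    amplicon_start: int
    amplicon_end: int
    fwd_primer: str
    rev_primer: str

    def __post_init__(self) -> None:
        if self.proto_end - self.proto_start != 20:
            raise TargetTableError(f"{self.target_id}: protospacer must be 20 bp")
        if self.strand not in "+-":
            raise TargetTableError(f"{self.target_id}: bad strand {self.strand!r}")
        if not (self.amplicon_start <= self.proto_start and self.proto_end <= self.amplicon_end):
            raise TargetTableError(f"{self.target_id}: protospacer outside amplicon")
        if not self.fwd_primer or not self.rev_primer:
            raise TargetTableError(f"{self.target_id}: empty primer")

    @property
    def pam_interval(self) -> Tuple[int, int]:
        """PAM abuts the protospacer 3' end on the protospacer strand."""
        if self.strand == "+":
            return (self.proto_end, self.proto_end + 3)
        return (self.proto_start - 3, self.proto_start)

    @property
    def cut_position(self) -> int:
        """Blunt cut, 3 bp 5' of the PAM (inter-base coordinate)."""
        return self.proto_start + 17 if self.strand == "+" else self.proto_start + 3

    def window(self, width: int = WINDOW) -> Tuple[int, int]:
        half = width // 2
        return (self.cut_position - half, self.cut_position + half)


def read_target_table(path) -> List[AmpliconTarget]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = [
        "target_id", "gene", "chrom", "proto_start", "proto_end", "strand",
        "amplicon_start", "amplicon_end", "fwd_primer", "rev_primer",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TargetTableError(f"target table missing columns: {missing}")
    targets = [
        AmpliconTarget(
            target_id=r.target_id, gene=r.gene, chrom=r.chrom,
            proto_start=int(r.proto_start), proto_end=int(r.proto_end),
            strand=r.strand,
            amplicon_start=int(r.amplicon_start), amplicon_end=int(r.amplicon_end),
            fwd_primer=r.fwd_primer, rev_primer=r.rev_primer,
        )
        for r in df.itertuples()
    ]
    validate_primer_table(targets)
    return targets


def write_target_table(targets: Sequence[AmpliconTarget], path) -> None:
    rows = [
        {
            "target_id": t.target_id, "gene": t.gene, "chrom": t.chrom,
            "proto_start": t.proto_start, "proto_end": t.proto_end,
            "strand": t.strand, "amplicon_start": t.amplicon_start,
            "amplicon_end": t.amplicon_end,
            "fwd_primer": t.fwd_primer, "rev_primer": t.rev_primer,
        }
        for t in targets
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def validate_primer_table(targets: Sequence[AmpliconTarget]) -> None:
    """Primer prefixes must be mutually distinguishable across targets."""
    fwd = [(t.fwd_primer, t.target_id) for t in targets]
    for p1, id1 in fwd:
        for p2, id2 in fwd:
            if id1 != id2 and p1.startswith(p2):
                raise TargetTableError(
                    f"ambiguous primers: forward primer of {id2} is a prefix of {id1}'s"
                )


# --------------------------------------------------------------- demultiplex
def demultiplex_reads(
    pairs: Iterable[ReadPair],
    targets: Sequence[AmpliconTarget],
    max_mismatches: int = 0,
) -> Tuple[Dict[str, List[ReadPair]], List[ReadPair]]:
    """Assign pairs to targets by exact primer-prefix match.

    Mate 1 must start with a target's forward primer and mate 2 with its
    reverse primer; a pair matching no target (or mismatched primers) lands in
    the unassigned set. Counts are conserved.
    """
    validate_primer_table(targets)

    def matches(seq: str, primer: str) -> bool:
        if len(seq) < len(primer):
            return False
        if max_mismatches == 0:
            return seq.startswith(primer)
        mm = sum(a != b for a, b in zip(seq, primer))
        return mm <= max_mismatches

    assigned: Dict[str, List[ReadPair]] = {t.target_id: [] for t in targets}
    unassigned: List[ReadPair] = []
    for pair in pairs:
        hit = None
        for t in targets:
            if matches(pair.seq1, t.fwd_primer) and matches(pair.seq2, t.rev_primer):
                hit = t.target_id
                break
        if hit is None:
            unassigned.append(pair)
        else:
            assigned[hit].append(pair)
    return assigned, unassigned


# ------------------------------------------------------------ pair filtering
def filter_on_target_pairs(
    alignments: Iterable[AlignedRead],
    target: AmpliconTarget,
    slop: int = 50,
) -> Tuple[List[AlignedRead], Dict[str, int]]:
    """Keep read pairs with both mates mapped around the designed site.

    A pair is kept iff both mates are mapped on the target chromosome and each
    mate's aligned interval overlaps the amplicon extended by ``slop`` on both
    sides. Secondary/supplementary records are dropped up front; a read whose
    mate is missing is dropped and tallied, not raised.
    """
    lo = target.amplicon_start - slop
    hi = target.amplicon_end + slop
    tally: Counter = Counter()
    by_name: Dict[str, Dict[bool, AlignedRead]] = defaultdict(dict)
    for rec in alignments:
        tally["input"] += 1
        if rec.is_secondary or rec.is_supplementary:
            tally["dropped_secondary"] += 1
            continue
        by_name[rec.name][rec.is_read1] = rec

    kept: List[AlignedRead] = []
    for name, mates in by_name.items():
        if len(mates) != 2:
            tally["dropped_missing_mate"] += len(mates)
            continue
        ok = all(m.is_mapped and m.overlaps(target.chrom, lo, hi) for m in mates.values())
        if ok:
            kept.extend([mates[True], mates[False]])
            tally["kept"] += 2
        else:
            tally["dropped_off_target"] += 2
    return kept, dict(tally)


# ------------------------------------------------------------- event calling
@dataclass(frozen=True)
class IndelEvent:
    """A distinct indel signature; identical signatures aggregate."""

    kind: str  # "ins" | "del"
    start: int  # genomic 0-based; insertion point for insertions
    length: int
    inserted_seq: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("ins", "del"):
            raise ValueError(f"bad indel kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("indel length must be >= 1")


@dataclass
class EventSummary:
    event: IndelEvent
    support: int
    rate: float


def call_read_indels(
    read: AlignedRead, target: AmpliconTarget, window: int = WINDOW
) -> List[IndelEvent]:
    """Call indel events on one read by walking its CIGAR string.

    Returns each I/D operation whose genomic footprint (for insertions, the
    insertion point) intersects the ``window`` bp region around the cut site.
    Match/mismatch operations never produce events.
    """
    win_lo, win_hi = target.window(window)
    events: List[IndelEvent] = []
    ref = read.pos
    qry = 0
    for op, n in parse_cigar(read.cigar):
        if op in "M=X":
            ref += n
            qry += n
        elif op == "D" or op == "N":
            if op == "D" and ref < win_hi and ref + n > win_lo:
                events.append(IndelEvent(kind="del", start=ref, length=n))
            ref += n
        elif op == "I":
            # an insertion sits between bases; interior of the window only
            if win_lo < ref < win_hi:
                events.append(
                    IndelEvent(kind="ins", start=ref, length=n,
                               inserted_seq=read.seq[qry : qry + n] if read.seq else "")
                )
            qry += n
        elif op == "S":
            qry += n
        # H and P consume nothing we track
    return events


def summarize_and_filter_events(
    per_read_events: Dict[str, List[IndelEvent]],
    n_total_reads: int,
    min_rate: float = 0.005,
) -> List[EventSummary]:
    """Aggregate events by signature and drop rates strictly below ``min_rate``.

    ``per_read_events`` maps a read key to the events called on it; support
    for a signature counts reads, so a signature appearing twice on one read
    (impossible for a single CIGAR walk, but guarded) still counts once.
    """
    if n_total_reads < 1:
        raise ValueError("n_total_reads must be >= 1")
    support: Counter = Counter()
    for events in per_read_events.values():
        for ev in set(events):
            support[ev] += 1
    out = [
        EventSummary(event=ev, support=c, rate=c / n_total_reads)
        for ev, c in support.items()
        if c / n_total_reads >= min_rate  # strict "less than" removal
    ]
    out.sort(key=lambda s: (s.event.start, s.event.kind, s.event.length, s.event.inserted_seq))
    return out


# ---------------------------------------------------------------- efficiency
@dataclass
class EfficiencyResult:
    target_id: str
    n_indel_reads: int
    n_total_reads: int
    events: List[EventSummary] = field(default_factory=list)
    no_coverage: bool = False
    tallies: Dict[str, int] = field(default_factory=dict)

    @property
    def efficiency(self) -> float:
        if self.no_coverage:
            raise ValueError(f"{self.target_id}: no reads cover the cut-site window")
        return self.n_indel_reads / self.n_total_reads


def compute_efficiency(
    covering_reads: Sequence[AlignedRead],
    target: AmpliconTarget,
    min_rate: float = 0.005,
    window: int = WINDOW,
) -> EfficiencyResult:
    """Efficiency = reads supporting >=1 retained indel / reads covering the window.

    ``covering_reads`` must already satisfy the coverage rule (see
    :func:`quantify_target`). A read with several retained events counts once.
    """
    n_total = len(covering_reads)
    if n_total == 0:
        return EfficiencyResult(target.target_id, 0, 0, no_coverage=True)

    per_read: Dict[str, List[IndelEvent]] = {}
    skipped = 0
    for i, read in enumerate(covering_reads):
        key = f"{read.name}/{1 if read.is_read1 else 2}#{i}"
        try:
            per_read[key] = call_read_indels(read, target, window)
        except CigarError:
            skipped += 1
            logger.warning("skipping read %s: malformed CIGAR", read.name)
            per_read[key] = []
    retained = summarize_and_filter_events(per_read, n_total, min_rate)
    retained_set = {s.event for s in retained}
    n_indel = sum(1 for events in per_read.values() if retained_set & set(events))
    return EfficiencyResult(
        target.target_id, n_indel, n_total, events=retained,
        tallies={"malformed_cigar": skipped},
    )


def quantify_target(
    alignments: Iterable[AlignedRead],
    target: AmpliconTarget,
    min_rate: float = 0.005,
    window: int = WINDOW,
    slop: int = 50,
    cover: str = "full",
) -> EfficiencyResult:
    """Full per-target quantification from raw alignments.

    ``cover="full"`` (default) requires a read to span the whole cut-site
    window to enter the denominator; ``cover="any"`` accepts any overlap.
    """
    if cover not in ("full", "any"):
        raise ValueError("cover must be 'full' or 'any'")
    kept, tally = filter_on_target_pairs(alignments, target, slop=slop)
    win_lo, win_hi = target.window(window)
    if cover == "full":
        covering = [r for r in kept if r.spans(target.chrom, win_lo, win_hi)]
    else:
        covering = [r for r in kept if r.overlaps(target.chrom, win_lo, win_hi)]
    result = compute_efficiency(covering, target, min_rate=min_rate, window=window)
    result.tallies.update(tally)
    result.tallies["covering"] = len(covering)
    return result


def efficiency_table(results: Sequence[EfficiencyResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "target_id": r.target_id,
                "n_indel_reads": r.n_indel_reads,
                "n_total_reads": r.n_total_reads,
                "efficiency": float("nan") if r.no_coverage else r.efficiency,
                "no_coverage": r.no_coverage,
                "n_events": len(r.events),
            }
        )
    return pd.DataFrame(rows)


def event_table(results: Sequence[EfficiencyResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for s in r.events:
            rows.append(
                {
                    "target_id": r.target_id,
                    "kind": s.event.kind,
                    "start": s.event.start,
                    "length": s.event.length,
                    "inserted_seq": s.event.inserted_seq,
                    "support": s.support,
                    "rate": s.rate,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["target_id", "kind", "start", "length", "inserted_seq", "support", "rate"],
    )
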