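"""Synthetic data with known ground truth for every pipeline stage.

Generators emulate the study's data types: a toy genome with exon annotation,
paired-end amplicon reads carrying indels at a programmed fraction around a
known cut site, MNase-style stranded 5'-tag pileups from planted nucleosome
dyads, two-stage ATAC peak files, and gRNA cohorts whose true mutation rates
differ by chromatin label with binomial read sampling.

Every generator takes a frozen spec carrying its own seed and draws all
randomness from one ``numpy.random.Generator`` constructed per call, so a
fixed spec reproduces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .amplicon import AmpliconTarget
from .intervals import GenomicPartition, IntervalSet, merge_interval_set
from .nucleosome import (
    MIDPOINT_SHIFT,
    NucPeak,
    Tag,
    classify_nucleosome_regions,
)
from .samio import AlignedRead, ReadPair
from .sequtils import revcomp


class SpecError(ValueError):
    """Raised when a simulation spec violates its invariants."""


# ------------------------------------------------------------------- genome
@dataclass(frozen=True)
class ToyGenomeSpec:
    """A small random genome with exon annotation.

    ``exons`` maps chromosome -> list of (start, end, gene) triples.
    """

    chrom_sizes: Dict[str, int]
    exons: Dict[str, List[Tuple[int, int, str]]] = field(default_factory=dict)
    gc_fraction: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size < 1000:
                raise SpecError(f"chromosome {chrom} shorter than 1 kb")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise SpecError("gc_fraction outside [0, 1]")
        for chrom, exons in self.exons.items():
            size = self.chrom_sizes.get(chrom)
            if size is None:
                raise SpecError(f"exons on unknown chromosome {chrom}")
            for s, e, _ in exons:
                if not (0 <= s < e <= size):
                    raise SpecError(f"exon [{s}, {e}) invalid on {chrom} (len {size})")


def gen_toy_genome(spec: ToyGenomeSpec) -> Tuple[Dict[str, str], pd.DataFrame]:
    """Random A/C/G/T sequences at the requested GC content, plus an exon table."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    half_gc = spec.gc_fraction / 2.0
    half_at = (1.0 - spec.gc_fraction) / 2.0
    probs = [half_at, half_gc, half_gc, half_at]  # A C G T
    genome = {}
    for chrom in sorted(spec.chrom_sizes):
        codes = rng.choice(4, size=spec.chrom_sizes[chrom], p=probs)
        genome[chrom] = "".join(np.array(list("ACGT"))[codes])
    rows = [
        {"chrom": chrom, "start": s, "end": e, "gene": g}
        for chrom in sorted(spec.exons)
        for s, e, g in sorted(spec.exons[chrom])
    ]
    exon_table = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])
    return genome, exon_table


def exon_interval_set(exon_table: pd.DataFrame) -> IntervalSet:
    out: IntervalSet = {}
    for row in exon_table.itertuples():
        out.setdefault(row.chrom, []).append((row.start, row.end))
    return merge_interval_set(out)


# -------------------------------------------------------------------- reads
@dataclass(frozen=True)
class IndelSpectrumEntry:
    kind: str          # "ins" | "del"
    length: int
    offset: int        # event reference position relative to the cut
    weight: float
    inserted_seq: str = ""


DEFAULT_SPECTRUM = (
    IndelSpectrumEntry("del", 5, -3, 0.35),
    IndelSpectrumEntry("del", 2, -1, 0.25),
    IndelSpectrumEntry("ins", 1, 0, 0.25, "A"),
    IndelSpectrumEntry("ins", 3, -1, 0.15, "TAG"),
)


@dataclass(frozen=True)
class ReadSimSpec:
    """Paired-end amplicon read simulation around one target.

    The amplicon sequence must begin with the forward primer and end with the
    reverse complement of the reverse primer (as a real amplicon does), so
    demultiplexing by primer prefix is exercised.
    """

    target: AmpliconTarget
    amplicon_seq: str
    indel_fraction: float = 0.1
    spectrum: Tuple[IndelSpectrumEntry, ...] = DEFAULT_SPECTRUM
    sub_error_rate: float = 0.001
    indel_error_rate: float = 0.0  # opt-in spurious 1 bp indels
    read_length: int = 150
    n_pairs: int = 5000
    seed: int = 0

    def validate(self) -> None:
        t = self.target
        if len(self.amplicon_seq) != t.amplicon_end - t.amplicon_start:
            raise SpecError("amplicon sequence length disagrees with target interval")
        if len(self.amplicon_seq) <= self.read_length:
            raise SpecError("amplicon must be longer than the read length")
        if not 0.0 <= self.indel_fraction <= 1.0:
            raise SpecError("indel_fraction outside [0, 1]")
        if not 0.0 <= self.sub_error_rate <= 1.0:
            raise SpecError("sub_error_rate outside [0, 1]")
        if abs(sum(e.weight for e in self.spectrum) - 1.0) > 1e-9:
            raise SpecError("spectrum weights must sum to 1")
        if not self.amplicon_seq.startswith(t.fwd_primer):
            raise SpecError("amplicon must start with the forward primer")
        if not self.amplicon_seq.endswith(revcomp(t.rev_primer)):
            raise SpecError("amplicon must end with revcomp(reverse primer)")
        cut_off = t.cut_position - t.amplicon_start
        amp_len = len(self.amplicon_seq)
        for e in self.spectrum:
            if e.kind not in ("ins", "del"):
                raise SpecError(f"bad spectrum kind {e.kind!r}")
            pos = cut_off + e.offset
            end = pos + (e.length if e.kind == "del" else 0)
            if not (len(t.fwd_primer) <= pos and end <= amp_len - len(t.rev_primer)):
                raise SpecError(f"spectrum event at offset {e.offset} leaves the amplicon")
            if e.kind == "del" and e.length >= amp_len:
                raise SpecError("deletion longer than the amplicon")
            if e.kind == "ins" and len(e.inserted_seq) != e.length:
                raise SpecError("inserted_seq length must equal event length")


@dataclass
class SimulatedReads:
    """Reads plus per-pair truth labels and truth alignments."""

    pairs: List[ReadPair]
    truth: pd.DataFrame  # pair name, carries_indel, event kind/pos/len
    alignments: List[AlignedRead]

    @property
    def true_indel_fraction(self) -> float:
        return float(self.truth["carries_indel"].mean())


def _apply_event(ref: str, kind: str, pos: int, length: int, ins: str) -> str:
    if kind == "del":
        return ref[:pos] + ref[pos + length:]
    return ref[:pos] + ins + ref[pos:]


def _mate1_cigar(kind: Optional[str], e: int, L: int, read_len: int) -> str:
    """CIGAR for the forward mate (covers mutated amplicon [0, read_len))."""
    if kind is None or read_len <= e:
        return f"{read_len}M"
    if kind == "del":
        return f"{e}M{L}D{read_len - e}M"
    covered_ins = min(L, read_len - e)
    tail = read_len - e - covered_ins
    return f"{e}M{covered_ins}I{tail}M" if tail else f"{e}M{covered_ins}I"


def _mate2_alignment(
    kind: Optional[str], e: int, L: int, read_len: int, mut_len: int
) -> Tuple[int, str]:
    """(reference start offset, CIGAR) for the reverse mate.

    The reverse mate covers the last ``read_len`` bases of the mutated
    amplicon; t is its start in mutated coordinates.
    """
    t = mut_len - read_len
    if kind is None or (kind == "del" and t >= e) or (kind == "ins" and t >= e + L):
        shift = 0 if kind is None else (L if kind == "del" else -L)
        return t + shift, f"{read_len}M"
    if kind == "del":
        return t, f"{e - t}M{L}D{mut_len - e}M"
    if t >= e:  # leading partial insertion
        head = e + L - t
        return e, f"{head}I{mut_len - e - L}M"
    return t, f"{e - t}M{L}I{mut_len - e - L}M"


def _add_sub_errors(seq: str, rng: np.random.Generator, rate: float, protect: int) -> str:
    """Substitution errors outside the first ``protect`` (primer) bases."""
    if rate <= 0:
        return seq
    arr = list(seq)
    n_err = rng.binomial(len(seq) - protect, rate)
    if n_err == 0:
        return seq
    positions = rng.choice(np.arange(protect, len(seq)), size=n_err, replace=False)
    for p in positions:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(3)]
    return "".join(arr)


def gen_amplicon_reads(spec: ReadSimSpec) -> SimulatedReads:
    """Simulate paired amplicon reads with planted indels and truth records.

    Each pair independently carries a planted indel with probability
    ``indel_fraction`` (event drawn from the spectrum by weight), so the
    carrier fraction is Binomial(n, f)/n. Substitution errors never touch the
    primer prefixes; optional spurious 1 bp indel errors
    (``indel_error_rate``, per read) are only injected on non-carrier reads.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    t = spec.target
    cut_off = t.cut_position - t.amplicon_start
    weights = np.array([e.weight for e in spec.spectrum])
    carriers = rng.random(spec.n_pairs) < spec.indel_fraction
    event_idx = rng.choice(len(spec.spectrum), size=spec.n_pairs, p=weights)

    pairs: List[ReadPair] = []
    truth_rows = []
    alignments: List[AlignedRead] = []
    for i in range(spec.n_pairs):
        name = f"{t.target_id}_read{i:06d}"
        if carriers[i]:
            ev = spec.spectrum[event_idx[i]]
            e = cut_off + ev.offset
            mutated = _apply_event(spec.amplicon_seq, ev.kind, e, ev.length, ev.inserted_seq)
            kind: Optional[str] = ev.kind
            length = ev.length
        else:
            mutated = spec.amplicon_seq
            kind, length, e = None, 0, 0

        mut_len = len(mutated)
        read_len = min(spec.read_length, mut_len)
        seq1 = mutated[:read_len]
        seq2_ref = mutated[mut_len - read_len:]

        cigar1 = _mate1_cigar(kind, e, length, read_len)
        ref2_off, cigar2 = _mate2_alignment(kind, e, length, read_len, mut_len)

        if kind is None and spec.indel_error_rate > 0:
            seq1, cigar1 = _maybe_spurious_indel(seq1, cigar1, rng, spec.indel_error_rate)
            seq2_ref, cigar2 = _maybe_spurious_indel(seq2_ref, cigar2, rng, spec.indel_error_rate)

        seq1 = _add_sub_errors(seq1, rng, spec.sub_error_rate, len(t.fwd_primer))
        seq2_fastq = _add_sub_errors(revcomp(seq2_ref), rng, spec.sub_error_rate, len(t.rev_primer))
        seq2_ref = revcomp(seq2_fastq)

        pairs.append(ReadPair(name=name, seq1=seq1, seq2=seq2_fastq))
        alignments.append(
            AlignedRead(name=name, chrom=t.chrom, pos=t.amplicon_start, mapq=60,
                        cigar=cigar1, seq=seq1, is_reverse=False, is_read1=True)
        )
        alignments.append(
            AlignedRead(name=name, chrom=t.chrom, pos=t.amplicon_start + ref2_off,
                        mapq=60, cigar=cigar2, seq=seq2_ref, is_reverse=True,
                        is_read1=False)
        )
        truth_rows.append(
            {
                "name": name,
                "target_id": t.target_id,
                "carries_indel": bool(carriers[i]),
                "kind": kind or "",
                "ref_pos": t.amplicon_start + e if kind else -1,
                "length": length,
            }
        )
    truth = pd.DataFrame(truth_rows)
    return SimulatedReads(pairs=pairs, truth=truth, alignments=alignments)


def _maybe_spurious_indel(
    seq: str, cigar: str, rng: np.random.Generator, rate: float
) -> Tuple[str, str]:
    """With probability ``rate`` put one random 1 bp indel error on a clean read."""
    if rng.random() >= rate or cigar != f"{len(seq)}M":
        return seq, cigar
    p = int(rng.integers(10, len(seq) - 10))
    if rng.random() < 0.5:
        seq2 = seq[:p] + seq[p + 1:]
        return seq2, f"{p}M1D{len(seq2) - p}M"
    base = "ACGT"[rng.integers(4)]
    seq2 = seq[:p] + base + seq[p:]
    return seq2, f"{p}M1I{len(seq) - p}M"


# ---------------------------------------------------------------- MNase tags
@dataclass(frozen=True)
class NucArraySpec:
    """Planted nucleosome dyads emitting stranded 5' tags, plus background."""

    chrom: str
    chrom_size: int
    dyads: Tuple[Tuple[int, int], ...]  # (position, tag count)
    jitter_sd: float = 0.0
    background_rate: float = 0.0  # uniform tags per bp
    universe: Optional[Tuple[Tuple[int, int], ...]] = None  # gene bodies
    seed: int = 0

    def validate(self) -> None:
        for pos, count in self.dyads:
            if not 0 <= pos < self.chrom_size:
                raise SpecError(f"dyad {pos} outside chromosome")
            if count < 0:
                raise SpecError("dyad tag count must be >= 0")
        if self.background_rate < 0 or self.jitter_sd < 0:
            raise SpecError("rates must be >= 0")


def gen_midpoint_tags(spec: NucArraySpec) -> Tuple[List[Tag], GenomicPartition]:
    """Stranded 5' tag positions (pre-shift) and the noise-free truth partition.

    A plus-strand tag for a dyad at d starts at d - 73 and a minus-strand tag
    has its 5' coordinate at d + 73, so the +/-73 midpoint shift reconstructs
    the (jittered) dyad. The truth partition applies the NL/NO/dynamic rules
    to the noise-free dyads.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    tags: List[Tag] = []
    for dyad, count in spec.dyads:
        if count == 0:
            continue
        jitter = (
            np.round(rng.normal(0.0, spec.jitter_sd, size=count)).astype(int)
            if spec.jitter_sd > 0
            else np.zeros(count, dtype=int)
        )
        strands = rng.random(count) < 0.5
        for j, plus in zip(jitter, strands):
            d = dyad + int(j)
            if plus:
                tags.append(Tag(spec.chrom, d - MIDPOINT_SHIFT, "+"))
            else:
                tags.append(Tag(spec.chrom, d + MIDPOINT_SHIFT, "-"))
    universe: IntervalSet = {
        spec.chrom: [tuple(iv) for iv in (spec.universe or [(0, spec.chrom_size)])]
    }
    if spec.background_rate > 0:
        span = sum(e - s for s, e in universe[spec.chrom])
        n_bg = rng.poisson(spec.background_rate * span)
        offsets = rng.integers(0, span, size=n_bg)
        starts = np.concatenate([[0], np.cumsum([e - s for s, e in universe[spec.chrom]])])
        for off in offsets:
            k = int(np.searchsorted(starts, off, side="right") - 1)
            pos = universe[spec.chrom][k][0] + int(off - starts[k])
            plus = rng.random() < 0.5
            tags.append(
                Tag(spec.chrom, pos - MIDPOINT_SHIFT, "+")
                if plus
                else Tag(spec.chrom, pos + MIDPOINT_SHIFT, "-")
            )

    truth_peaks = [
        NucPeak(chrom=spec.chrom, center=pos, score=float(count))
        for pos, count in spec.dyads
        if count > 0
    ]
    truth = classify_nucleosome_regions(truth_peaks, universe)
    return tags, truth


def write_tags_bed(tags: Sequence[Tag], path) -> None:
    """Write tags as BED6 single-base features at the stranded 5' position."""
    with open(path, "w") as fh:
        for i, t in enumerate(tags):
            fh.write(f"{t.chrom}\t{t.pos}\t{t.pos + 1}\ttag{i}\t0\t{t.strand}\n")


# ------------------------------------------------------------------- cohort
@dataclass(frozen=True)
class CohortSimSpec:
    """gRNA cohorts with label-dependent true mutation rates.

    Defaults follow the study designs: the unpaired cohort emulates the
    110-guide multiplex co-injection (37 open-chromatin targets) with low
    overall rates; the paired design (20 OC/CC pairs) is requested with
    ``paired=True`` and the planted 15% vs 4% rates.
    """

    n_guides: int = 110
    frac_oc: float = 37 / 110
    rate_oc: float = 0.05
    rate_cc: float = 0.03
    n_reads: int = 5000
    paired: bool = False
    labels: Tuple[str, str] = ("OC", "CC")
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.rate_oc <= 1 and 0 <= self.rate_cc <= 1):
            raise SpecError("rates outside [0, 1]")
        if self.n_reads < 1:
            raise SpecError("n_reads must be >= 1")
        if not 0 <= self.frac_oc <= 1:
            raise SpecError("frac_oc outside [0, 1]")
        if self.paired and self.n_guides % 2:
            raise SpecError("paired design needs an even number of guides")


def gen_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Cohort table with true rates and binomially sampled indel read counts.

    Observed efficiency per guide is Binomial(n_reads, true rate)/n_reads. In
    the paired design every pair has one guide of each label and a shared
    pair identifier.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lab_hi, lab_lo = spec.labels
    if spec.paired:
        n_pairs = spec.n_guides // 2
        labels = [lab_hi, lab_lo] * n_pairs
        pair_ids = [f"pair{p:03d}" for p in range(n_pairs) for _ in range(2)]
    else:
        n_hi = int(round(spec.frac_oc * spec.n_guides))
        labels = [lab_hi] * n_hi + [lab_lo] * (spec.n_guides - n_hi)
        pair_ids = [""] * spec.n_guides
    true_rates = np.where(np.array(labels) == lab_hi, spec.rate_oc, spec.rate_cc)
    n_indel = rng.binomial(spec.n_reads, true_rates)
    return pd.DataFrame(
        {
            "guide_id": [f"g{i:04d}" for i in range(spec.n_guides)],
            "label": labels,
            "pair_id": pair_ids,
            "true_rate": true_rates,
            "n_reads": spec.n_reads,
            "n_indel_reads": n_indel,
            "efficiency": n_indel / spec.n_reads,
        }
    )


def with_seed(spec, seed: int):
    """Return a copy of any frozen spec with a different seed."""
    return replace(spec, seed=seed)
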