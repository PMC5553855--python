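"""Alignment and read I/O.

SAM/BAM parsing and writing go through :mod:`pysam`; inside the package
alignments travel as lightweight :class:`AlignedRead` records so the calling
code is independent of file handles. FASTQ is written gzipped through
:mod:`Bio.SeqIO`-free plain text (4-line records) for speed.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Tuple

import pysam

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_CONSUMES_REF = set("MDN=X")
_CONSUMES_READ = set("MIS=X")


class CigarError(ValueError):
    """Raised for a malformed CIGAR string."""


def parse_cigar(cigar: str) -> List[Tuple[str, int]]:
    """Parse a CIGAR string into ``(op, length)`` tuples, validating syntax."""
    if not cigar or cigar == "*":
        return []
    ops = _CIGAR_RE.findall(cigar)
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise CigarError(f"malformed CIGAR: {cigar!r}")
    return [(op, int(n)) for n, op in ops]


def cigar_reference_length(cigar: str) -> int:
    return sum(n for op, n in parse_cigar(cigar) if op in _CONSUMES_REF)


@dataclass
class AlignedRead:
    """One SAM record, reduced to the fields the pipeline consumes."""

    name: str
    chrom: str | None
    pos: int  # 0-based leftmost reference coordinate
    mapq: int
    cigar: str
    seq: str
    is_reverse: bool = False
    is_read1: bool = True
    is_mapped: bool = True
    is_secondary: bool = False
    is_supplementary: bool = False

    @property
    def reference_end(self) -> int:
        """One past the last reference base consumed by the alignment."""
        return self.pos + cigar_reference_length(self.cigar)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return (
            self.is_mapped
            and self.chrom == chrom
            and self.pos < end
            and self.reference_end > start
        )

    def spans(self, chrom: str, start: int, end: int) -> bool:
        return (
            self.is_mapped
            and self.chrom == chrom
            and self.pos <= start
            and self.reference_end >= end
        )


def read_sam(path) -> Iterator[AlignedRead]:
    """Stream a SAM/BAM file as :class:`AlignedRead` records."""
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            yield AlignedRead(
                name=rec.query_name or "",
                chrom=rec.reference_name if rec.reference_id >= 0 else None,
                pos=rec.reference_start if rec.reference_start is not None else -1,
                mapq=rec.mapping_quality,
                cigar=rec.cigarstring or "*",
                seq=rec.query_sequence or "",
                is_reverse=rec.is_reverse,
                is_read1=not rec.is_read2,
                is_mapped=not rec.is_unmapped,
                is_secondary=rec.is_secondary,
                is_supplementary=rec.is_supplementary,
            )


def write_sam(reads: Iterable[AlignedRead], path, chrom_sizes: Dict[str, int]) -> None:
    """Write records as plain SAM with a proper @SQ header."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": int(n)} for c, n in chrom_sizes.items()],
        }
    )
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in reads:
            seg = pysam.AlignedSegment(header)
            seg.query_name = r.name
            flag = 0x1  # paired
            flag |= 0x40 if r.is_read1 else 0x80
            if r.is_reverse:
                flag |= 0x10
            if not r.is_mapped:
                flag |= 0x4
            if r.is_secondary:
                flag |= 0x100
            if r.is_supplementary:
                flag |= 0x800
            seg.flag = flag
            if r.is_mapped and r.chrom is not None:
                seg.reference_id = header.get_tid(r.chrom)
                seg.reference_start = r.pos
                seg.cigarstring = r.cigar
                seg.mapping_quality = r.mapq
            seg.query_sequence = r.seq
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(r.seq))
            out.write(seg)


@dataclass
class ReadPair:
    """A sequenced read pair as it would come off the machine (R1/R2)."""

    name: str
    seq1: str
    seq2: str


def write_fastq_pair(pairs: Iterable[ReadPair], prefix) -> Tuple[Path, Path]:
    """Write pairs to ``<prefix>_R1.fastq.gz`` / ``<prefix>_R2.fastq.gz``."""
    p1 = Path(f"{prefix}_R1.fastq.gz")
    p2 = Path(f"{prefix}_R2.fastq.gz")

    def _open(path):
        # mtime pinned so identical runs are byte-identical
        import io

        return io.TextIOWrapper(gzip.GzipFile(path, "wb", mtime=0))

    with _open(p1) as f1, _open(p2) as f2:
        for p in pairs:
            f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{'I' * len(p.seq1)}\n")
            f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{'I' * len(p.seq2)}\n")
    return p1, p2


def read_fastq_pair(path1, path2) -> Iterator[ReadPair]:
    def records(path):
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            while True:
                header = fh.readline()
                if not header:
                    return
                seq = fh.readline().strip()
                fh.readline()
                fh.readline()
                yield header[1:].strip().split("/")[0].split()[0], seq

    for (n1, s1), (n2, s2) in zip(records(path1), records(path2)):
        if n1 != n2:
            raise ValueError(f"FASTQ pair out of sync: {n1!r} vs {n2!r}")
        yield ReadPair(name=n1, seq1=s1, seq2=s2)
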