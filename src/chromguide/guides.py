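"""Exome-wide gRNA target scanning, chromatin annotation and off-target counts.

A candidate is any genomic 20-mer followed immediately by an NGG PAM on
either strand whose protospacer overlaps an annotated exon. Each candidate is
annotated with the chromatin label at its cut position (OC/CC and
NL/NO/dynamic/unclassified), an optional externally computed sequence score,
and exact genome-wide counts of sites matching the protospacer with 0, 1 and
2 substitutions (no PAM requirement by default, mirroring an end-to-end
ungapped-alignment search; ``require_pam=True`` adds the constraint).

The mismatch counter uses a pigeonhole seed partition: the 20-mer is split
into three seeds (7 + 7 + 6 bp); any site with at most two mismatches must
match at least one seed exactly, so exact seed hits (found via vectorized
k-mer integer codes) are verified by full Hamming comparison. Counts are
exact.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomicPartition, IntervalSet, point_in_intervals
from .sequtils import encode_seq, revcomp

SEED_SPANS = ((0, 7), (7, 14), (14, 20))  # pigeonhole split for <=2 mismatches


# ------------------------------------------------------------------ scanning
def scan_pam_targets(
    genome: Dict[str, str],
    exons: IntervalSet,
    require_exon_overlap: bool = True,
) -> pd.DataFrame:
    """Enumerate 20-mer + NGG candidates on both strands over exons.

    Candidates containing ambiguous bases in protospacer or PAM are skipped;
    output is deduplicated by (chrom, strand, protospacer interval) and sorted.
    """
    for chrom, ivs in exons.items():
        if chrom not in genome:
            raise ValueError(f"exon chromosome {chrom} not in genome")
        size = len(genome[chrom])
        for s, e in ivs:
            if s < 0 or e > size:
                raise ValueError(f"exon {chrom}:{s}-{e} outside chromosome (len {size})")

    rows = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        ex = exons.get(chrom, [])
        if require_exon_overlap and not ex:
            continue
        n = len(seq)
        # plus strand: GG at [p, p+2) => PAM [p-1, p+2), protospacer [p-21, p-1)
        p = seq.find("GG", 21)
        while p != -1:
            ps, pe = p - 21, p - 1
            proto = seq[ps:pe]
            pam = seq[pe : pe + 3]
            if "N" not in proto and "N" not in pam:
                if not require_exon_overlap or _overlaps_any(ex, ps, pe):
                    rows.append((chrom, "+", ps, pe, proto, pe, pe + 3, pam, ps + 17))
            p = seq.find("GG", p + 1)
        # minus strand: CC at [q, q+2) => PAM [q, q+3), protospacer [q+3, q+23)
        q = seq.find("CC", 0)
        while q != -1:
            if q + 23 <= n:
                ps, pe = q + 3, q + 23
                proto = revcomp(seq[ps:pe])
                pam = revcomp(seq[q : q + 3])
                if "N" not in proto and "N" not in pam:
                    if not require_exon_overlap or _overlaps_any(ex, ps, pe):
                        rows.append((chrom, "-", ps, pe, proto, q, q + 3, pam, q + 6))
            q = seq.find("CC", q + 1)

    df = pd.DataFrame(
        rows,
        columns=["chrom", "strand", "proto_start", "proto_end", "protospacer",
                 "pam_start", "pam_end", "pam", "cut"],
    )
    df = df.drop_duplicates(subset=["chrom", "strand", "proto_start"])
    df = df.sort_values(["chrom", "proto_start", "strand"], kind="stable")
    return df.reset_index(drop=True)


def _overlaps_any(intervals, start: int, end: int) -> bool:
    from bisect import bisect_right

    i = bisect_right(intervals, (start, float("inf"))) - 1
    if i >= 0 and intervals[i][1] > start:
        return True
    return i + 1 < len(intervals) and intervals[i + 1][0] < end


def assign_genes(candidates: pd.DataFrame, exon_table: pd.DataFrame) -> pd.DataFrame:
    """Attach gene names by protospacer/exon overlap (';'-joined when several).

    ``exon_table`` needs columns chrom, start, end, gene.
    """
    out = candidates.copy()
    genes: List[str] = []
    grouped = {c: g.sort_values("start") for c, g in exon_table.groupby("chrom")}
    for row in out.itertuples():
        g = grouped.get(row.chrom)
        if g is None:
            genes.append("")
            continue
        hit = g[(g["start"] < row.proto_end) & (g["end"] > row.proto_start)]
        genes.append(";".join(sorted(set(hit["gene"]))))
    out["gene"] = genes
    return out


# ---------------------------------------------------------------- annotation
def annotate_chromatin(
    candidates: pd.DataFrame,
    oc_partition: GenomicPartition | None = None,
    nuc_partition: GenomicPartition | None = None,
    mode: str = "cut",
) -> pd.DataFrame:
    """Label each candidate by the chromatin partitions.

    ``mode="cut"`` (default) uses the single base immediately 5' of the cut on
    the protospacer strand; ``mode="majority"`` uses the label covering the
    most protospacer bases.
    """
    if mode not in ("cut", "majority"):
        raise ValueError("mode must be 'cut' or 'majority'")
    out = candidates.copy()

    def probe_positions(row) -> List[int]:
        if mode == "cut":
            # base 5' of the inter-base cut coordinate on the protospacer strand
            return [row.cut - 1 if row.strand == "+" else row.cut]
        return list(range(row.proto_start, row.proto_end))

    for col, part in (("oc_label", oc_partition), ("nuc_label", nuc_partition)):
        if part is None:
            continue
        labels = []
        for row in out.itertuples():
            votes = [part.label_at(row.chrom, p) for p in probe_positions(row)]
            labels.append(max(set(votes), key=votes.count) if len(votes) > 1 else votes[0])
        out[col] = labels
    return out


# ------------------------------------------------------- mismatch enumeration
class GenomeIndex:
    """Vectorized k-mer integer codes over a genome, for seed lookups.

    For every chromosome and both seed lengths (7 and 6) the index stores an
    array where entry i is the exact base-4 code of the k-mer starting at i
    (or a sentinel when the k-mer contains a non-ACGT base).
    """

    SENTINEL = np.uint32(0xFFFFFFFF)

    def __init__(self, genome: Dict[str, str]):
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.codes: Dict[str, np.ndarray] = {c: encode_seq(s) for c, s in self.genome.items()}
        self.kmer_codes: Dict[int, Dict[str, np.ndarray]] = {}
        for k in {e - s for s, e in SEED_SPANS}:
            self.kmer_codes[k] = {c: self._kmer_array(arr, k) for c, arr in self.codes.items()}

    @classmethod
    def _kmer_array(cls, codes: np.ndarray, k: int) -> np.ndarray:
        n = codes.size - k + 1
        if n <= 0:
            return np.empty(0, dtype=np.uint32)
        out = np.zeros(n, dtype=np.uint32)
        bad = np.zeros(n, dtype=bool)
        for j in range(k):
            window = codes[j : j + n]
            out = out * 4 + np.minimum(window, 3).astype(np.uint32)
            bad |= window > 3
        out[bad] = cls.SENTINEL
        return out

    @staticmethod
    def kmer_code(seq: str) -> int:
        code = 0
        for b in seq:
            code = code * 4 + "ACGT".index(b)
        return code


def _seed_hits(index: GenomeIndex, chrom: str, query: str) -> np.ndarray:
    """Start positions of all pigeonhole-seed exact matches of ``query``."""
    hits = []
    for s, e in SEED_SPANS:
        k = e - s
        arr = index.kmer_codes[k][chrom]
        code = np.uint32(GenomeIndex.kmer_code(query[s:e]))
        pos = np.flatnonzero(arr == code) - s
        hits.append(pos)
    pos = np.unique(np.concatenate(hits))
    return pos[(pos >= 0) & (pos + len(query) <= index.codes[chrom].size)]


def count_mismatch_sites(
    protospacer: str,
    index: GenomeIndex,
    max_mm: int = 2,
    require_pam: bool = False,
) -> Tuple[int, ...]:
    """Exact genome-wide counts of sites at Hamming distance 0..max_mm.

    Both strands are searched; ``m0`` includes the candidate's own locus. With
    ``require_pam`` a site only counts when followed by NGG on its strand.
    """
    if max_mm > 2:
        raise ValueError("seed partition guarantees completeness only for max_mm <= 2")
    L = len(protospacer)
    counts = [0] * (max_mm + 1)
    for query, sense in ((protospacer, "+"), (revcomp(protospacer), "-")):
        q = encode_seq(query)
        for chrom, codes in index.codes.items():
            pos = _seed_hits(index, chrom, query)
            if pos.size == 0:
                continue
            # full Hamming verification at candidate positions only
            window = codes[pos[:, None] + np.arange(L)]
            mm = (window != q).sum(axis=1)
            for k in range(max_mm + 1):
                sites = pos[mm == k]
                if require_pam and sites.size:
                    seq = index.genome[chrom]
                    sites = np.array(
                        [p for p in sites if _has_pam(seq, int(p), L, sense)], dtype=int
                    )
                counts[k] += int(sites.size)
    return tuple(counts)


def _has_pam(seq: str, pos: int, length: int, sense: str) -> bool:
    if sense == "+":
        pam = seq[pos + length : pos + length + 3]
        return len(pam) == 3 and pam[1:] == "GG"
    pam = seq[pos - 3 : pos]
    return len(pam) == 3 and pam[:2] == "CC"


def add_mismatch_counts(
    candidates: pd.DataFrame,
    genome: Dict[str, str],
    max_mm: int = 2,
    require_pam: bool = False,
) -> pd.DataFrame:
    """Annotate a candidate table with m0..m2 site counts (exact)."""
    index = GenomeIndex(genome)
    out = candidates.copy()
    cols = {f"m{k}": [] for k in range(max_mm + 1)}
    cache: Dict[str, Tuple[int, ...]] = {}
    for proto in out["protospacer"]:
        if proto not in cache:
            cache[proto] = count_mismatch_sites(proto, index, max_mm, require_pam)
        for k, v in enumerate(cache[proto]):
            cols[f"m{k}"].append(v)
    for name, vals in cols.items():
        out[name] = vals
    return out


# ------------------------------------------------------------------- scoring
def attach_sequence_score(
    candidates: pd.DataFrame, score_table: pd.DataFrame | None
) -> pd.DataFrame:
    """Left-join externally computed per-guide sequence scores.

    ``score_table`` must have columns ``protospacer`` and ``score``; missing
    guides get a null score, never a silent zero.
    """
    out = candidates.copy()
    if score_table is None or score_table.empty:
        out["score"] = np.nan
        return out
    if score_table["protospacer"].duplicated().any():
        dup = score_table.loc[score_table["protospacer"].duplicated(), "protospacer"].iloc[0]
        raise ValueError(f"duplicate key in score table: {dup}")
    merged = out.merge(
        score_table[["protospacer", "score"]], on="protospacer", how="left", sort=False
    )
    return merged


# -------------------------------------------------------------------- export
GUIDE_DB_COLUMNS = [
    "chrom", "proto_start", "proto_end", "strand", "protospacer", "pam",
    "cut", "gene", "oc_label", "nuc_label", "score", "m0", "m1", "m2",
]


def export_guide_db(candidates: pd.DataFrame, path) -> pd.DataFrame:
    """Write the guide database TSV, deterministically sorted."""
    out = candidates.copy()
    for col in GUIDE_DB_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out = out[GUIDE_DB_COLUMNS].sort_values(
        ["chrom", "proto_start", "strand"], kind="stable"
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.4f")
    return out.reset_index(drop=True)


def per_gene_oc_counts(candidates: pd.DataFrame) -> pd.DataFrame:
    """Per-gene counts of OC-labeled candidates (genes split on ';')."""
    rows: Dict[str, int] = {}
    for row in candidates.itertuples():
        gene_field = getattr(row, "gene", "") or ""
        is_oc = getattr(row, "oc_label", "") == "OC"
        for gene in filter(None, str(gene_field).split(";")):
            rows.setdefault(gene, 0)
            if is_oc:
                rows[gene] += 1
    df = pd.DataFrame({"gene": list(rows), "n_oc_targets": list(rows.values())})
    return df.sort_values("gene").reset_index(drop=True)


def fraction_genes_with_min_oc(per_gene: pd.DataFrame, min_targets: int = 5) -> float:
    """Fraction of genes with at least ``min_targets`` OC-labeled candidates."""
    if per_gene.empty:
        return 0.0
    return float((per_gene["n_oc_targets"] >= min_targets).mean())
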