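"""PAM scanning, chromatin annotation and exact mismatch-site counting.

The brute-force oracles here re-derive candidate sets and Hamming-distance
counts position by position, independently of the scanning/seed code paths.
"""

import numpy as np
import pandas as pd
import pytest

from chromguide.guides import (
    GenomeIndex,
    add_mismatch_counts,
    annotate_chromatin,
    attach_sequence_score,
    count_mismatch_sites,
    export_guide_db,
    fraction_genes_with_min_oc,
    per_gene_oc_counts,
    scan_pam_targets,
)
from chromguide.intervals import GenomicPartition
from chromguide.sequtils import encode_seq, revcomp
from chromguide.synthetic import ToyGenomeSpec, gen_toy_genome


# ------------------------------------------------------------------ oracles
def brute_force_scan(seq: str):
    """All (strand, proto_start) with 20-mer followed by NGG, by literal check."""
    out = set()
    n = len(seq)
    for i in range(n - 22):
        if seq[i + 21 : i + 23] == "GG" and "N" not in seq[i : i + 23]:
            out.add(("+", i))
        rc = revcomp(seq[i : i + 23])
        if rc[21:23] == "GG" and "N" not in rc:
            out.add(("-", i + 3))
    return out


def brute_force_mismatch_counts(proto: str, genome: dict, max_mm: int = 2):
    """Sliding-window Hamming distance over every position, both strands."""
    counts = [0] * (max_mm + 1)
    for query in (proto, revcomp(proto)):
        q = encode_seq(query)
        for seq in genome.values():
            g = encode_seq(seq)
            n = g.size - q.size + 1
            mm = np.zeros(n, dtype=int)
            for k in range(q.size):
                mm += g[k : k + n] != q[k]
            for k in range(max_mm + 1):
                counts[k] += int((mm == k).sum())
    return tuple(counts)


def _random_genome(size=50_000, seed=0, gc=0.45):
    genome, _ = gen_toy_genome(
        ToyGenomeSpec(chrom_sizes={"chr1": size}, gc_fraction=gc, seed=seed)
    )
    return genome


# ----------------------------------------------------------------- scanning
class TestScan:
    def test_literal_example(self):
        seq = "ACGTACGTACGTACGTACGTAAAGGGTTTT"
        df = scan_pam_targets({"c": seq}, {"c": [(0, len(seq))]})
        plus = df[df.strand == "+"]
        assert [(r.proto_start, r.proto_end, r.pam) for r in plus.itertuples()] == [
            (2, 22, "AGG"), (3, 23, "GGG"),
        ]

    def test_no_gg_or_cc_no_candidates(self):
        seq = "ATATATATATATATATATATATATATATATAT"
        df = scan_pam_targets({"c": seq}, {"c": [(0, len(seq))]})
        assert df.empty

    def test_matches_brute_force_oracle(self):
        genome = _random_genome(5_000, seed=9)
        df = scan_pam_targets(genome, {"chr1": [(0, 5_000)]})
        got = set(zip(df["strand"], df["proto_start"]))
        assert got == brute_force_scan(genome["chr1"])

    def test_strand_symmetry_under_revcomp(self):
        genome = _random_genome(3_000, seed=4)
        n = 3_000
        df = scan_pam_targets(genome, {"chr1": [(0, n)]})
        rc = {"chr1": revcomp(genome["chr1"])}
        df_rc = scan_pam_targets(rc, {"chr1": [(0, n)]})
        # mirror: (strand, start) -> (other strand, n - end)
        mirrored = {
            ("-" if s == "+" else "+", n - e)
            for s, e in zip(df["strand"], df["proto_end"])
        }
        got = set(zip(df_rc["strand"], df_rc["proto_start"]))
        assert got == mirrored
        assert sorted(df["protospacer"]) == sorted(df_rc["protospacer"])

    def test_exon_overlap_required(self):
        genome = _random_genome(5_000, seed=2)
        full = scan_pam_targets(genome, {"chr1": [(0, 5_000)]})
        windowed = scan_pam_targets(genome, {"chr1": [(1_000, 1_500)]})
        assert len(windowed) < len(full)
        assert ((windowed["proto_start"] < 1_500) & (windowed["proto_end"] > 1_000)).all()

    def test_exon_outside_chromosome_rejected(self):
        genome = _random_genome(2_000, seed=1)
        with pytest.raises(ValueError):
            scan_pam_targets(genome, {"chr1": [(1_900, 2_500)]})


# --------------------------------------------------------- mismatch counting
class TestMismatchCounts:
    def test_own_locus_counts_in_m0(self):
        genome = _random_genome(10_000, seed=6)
        df = scan_pam_targets(genome, {"chr1": [(0, 10_000)]}).head(5)
        index = GenomeIndex(genome)
        for proto in df["protospacer"]:
            m = count_mismatch_sites(proto, index)
            assert m[0] >= 1

    def test_planted_one_mismatch_duplicate(self):
        genome = _random_genome(10_000, seed=3)
        df = scan_pam_targets(genome, {"chr1": [(0, 10_000)]})
        proto = df["protospacer"].iloc[0]
        base = count_mismatch_sites(proto, GenomeIndex(genome))
        variant = list(proto)
        variant[10] = "A" if variant[10] != "A" else "C"
        planted = genome["chr1"] + "TTTTT" + "".join(variant) + "TTTTT"
        m = count_mismatch_sites(proto, GenomeIndex({"chr1": planted}))
        assert m[1] == base[1] + 1

    def test_equals_hamming_oracle(self):
        genome = _random_genome(30_000, seed=11)
        df = scan_pam_targets(genome, {"chr1": [(2_000, 3_000)]})
        index = GenomeIndex(genome)
        assert len(df) > 10
        for proto in df["protospacer"].head(15):
            assert count_mismatch_sites(proto, index) == \
                brute_force_mismatch_counts(proto, genome)

    def test_invariant_under_genome_revcomp(self):
        genome = _random_genome(20_000, seed=12)
        rc = {"chr1": revcomp(genome["chr1"])}
        df = scan_pam_targets(genome, {"chr1": [(5_000, 5_500)]})
        for proto in df["protospacer"].head(8):
            assert count_mismatch_sites(proto, GenomeIndex(genome)) == \
                count_mismatch_sites(proto, GenomeIndex(rc))

    def test_require_pam_never_increases_counts(self):
        genome = _random_genome(20_000, seed=13)
        df = scan_pam_targets(genome, {"chr1": [(1_000, 1_300)]})
        index = GenomeIndex(genome)
        for proto in df["protospacer"].head(5):
            free = count_mismatch_sites(proto, index)
            pam = count_mismatch_sites(proto, index, require_pam=True)
            assert all(p <= f for p, f in zip(pam, free))
            assert pam[0] >= 1  # own locus always has its PAM


# ---------------------------------------------------------------- annotation
class TestAnnotation:
    def _parts(self):
        oc = GenomicPartition(
            labels={"OC": {"c": [(0, 500)]}, "CC": {"c": [(500, 2_000)]}},
            universe={"c": [(0, 2_000)]},
        )
        nuc = GenomicPartition(
            labels={"NO": {"c": [(100, 247)]}, "NL": {"c": [(247, 300)]},
                    "dynamic": {"c": [(300, 1_000)]}},
            universe={"c": [(100, 1_000)]},
        )
        return oc, nuc

    def _cands(self, cuts):
        return pd.DataFrame(
            {
                "chrom": "c", "strand": "+",
                "proto_start": [c - 17 for c in cuts],
                "proto_end": [c + 3 for c in cuts],
                "protospacer": "A" * 20, "pam": "AGG",
                "pam_start": [c + 3 for c in cuts], "pam_end": [c + 6 for c in cuts],
                "cut": cuts,
            }
        )

    def test_cut_position_labels(self):
        oc, nuc = self._parts()
        out = annotate_chromatin(self._cands([200, 600]), oc, nuc)
        assert list(out["oc_label"]) == ["OC", "CC"]
        assert list(out["nuc_label"]) == ["NO", "dynamic"]

    def test_intergenic_cut_unclassified_for_nuc_only(self):
        oc, nuc = self._parts()
        out = annotate_chromatin(self._cands([1_500]), oc, nuc)
        assert out["oc_label"].iloc[0] == "CC"
        assert out["nuc_label"].iloc[0] == "unclassified"

    def test_order_invariance(self):
        oc, nuc = self._parts()
        cands = self._cands([200, 260, 600, 1_500])
        a = annotate_chromatin(cands, oc, nuc)
        b = annotate_chromatin(cands.iloc[::-1].reset_index(drop=True), oc, nuc)
        merged = a.merge(b, on="cut", suffixes=("_a", "_b"))
        assert (merged["oc_label_a"] == merged["oc_label_b"]).all()


# ------------------------------------------------------------ scores, export
class TestScoresAndExport:
    def _cands(self):
        genome = _random_genome(5_000, seed=21)
        df = scan_pam_targets(genome, {"chr1": [(1_000, 1_400)]})
        df["gene"] = "geneA"
        return df

    def test_full_and_empty_score_tables(self):
        cands = self._cands()
        table = pd.DataFrame({"protospacer": cands["protospacer"].unique()})
        table["score"] = np.arange(len(table), dtype=float)
        out = attach_sequence_score(cands, table)
        assert out["score"].notna().all()
        out_empty = attach_sequence_score(cands, None)
        assert out_empty["score"].isna().all()

    def test_shuffled_score_table_same_result(self):
        cands = self._cands()
        table = pd.DataFrame({"protospacer": cands["protospacer"].unique()})
        table["score"] = np.arange(len(table), dtype=float)
        a = attach_sequence_score(cands, table)
        b = attach_sequence_score(cands, table.sample(frac=1, random_state=0))
        assert a["score"].tolist() == b["score"].tolist()

    def test_duplicate_score_keys_rejected(self):
        cands = self._cands()
        proto = cands["protospacer"].iloc[0]
        table = pd.DataFrame({"protospacer": [proto, proto], "score": [1.0, 2.0]})
        with pytest.raises(ValueError):
            attach_sequence_score(cands, table)

    def test_export_deterministic(self, tmp_path):
        cands = self._cands()
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        export_guide_db(cands, p1)
        export_guide_db(cands.sample(frac=1, random_state=3), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_per_gene_oc_threshold_bin(self):
        cands = pd.DataFrame(
            {
                "gene": ["g1"] * 5 + ["g2"] * 3,
                "oc_label": ["OC"] * 5 + ["OC", "CC", "CC"],
            }
        )
        per_gene = per_gene_oc_counts(cands)
        assert dict(zip(per_gene["gene"], per_gene["n_oc_targets"])) == {"g1": 5, "g2": 1}
        assert fraction_genes_with_min_oc(per_gene, 5) == pytest.approx(0.5)


def test_add_mismatch_counts_table(tmp_path):
    genome = _random_genome(8_000, seed=30)
    cands = scan_pam_targets(genome, {"chr1": [(3_000, 3_200)]})
    out = add_mismatch_counts(cands, genome)
    assert (out["m0"] >= 1).all()
    assert {"m0", "m1", "m2"} <= set(out.columns)
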