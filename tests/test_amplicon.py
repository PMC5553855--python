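"""Amplicon indel quantification: demultiplexing, filtering, CIGAR calling."""

import numpy as np
import pytest

from chromguide.amplicon import (
    AmpliconTarget,
    IndelEvent,
    TargetTableError,
    call_read_indels,
    compute_efficiency,
    demultiplex_reads,
    filter_on_target_pairs,
    quantify_target,
    summarize_and_filter_events,
    validate_primer_table,
)
from chromguide.samio import AlignedRead, ReadPair
from chromguide.synthetic import ReadSimSpec, gen_amplicon_reads
from conftest import SINGLE_DEL5, build_target


def _pair(name, chrom, pos1, cigar1, pos2, cigar2, mapped=(True, True)):
    r1 = AlignedRead(name=name, chrom=chrom, pos=pos1, mapq=60, cigar=cigar1,
                     seq="A" * 100, is_read1=True, is_mapped=mapped[0])
    r2 = AlignedRead(name=name, chrom=chrom, pos=pos2, mapq=60, cigar=cigar2,
                     seq="A" * 100, is_read1=False, is_mapped=mapped[1])
    return [r1, r2]


class TestDemultiplex:
    def test_assignment_and_unassigned(self, target_and_amplicon):
        target, amplicon = target_and_amplicon
        good = ReadPair("p1", amplicon[:100], "NNN" + "A" * 97)
        good = ReadPair("p1", target.fwd_primer + "A" * 80,
                        target.rev_primer + "C" * 80)
        bad = ReadPair("p2", "T" * 100, "G" * 100)
        assigned, unassigned = demultiplex_reads([good, bad], [target])
        assert [p.name for p in assigned[target.target_id]] == ["p1"]
        assert [p.name for p in unassigned] == ["p2"]

    def test_counts_conserved_on_simulated_pool(self):
        rng = np.random.default_rng(0)
        sims, targets = [], []
        for i in range(4):
            target, amplicon = build_target(target_id=f"t{i}", cut=1110, seed=100 + i)
            spec = ReadSimSpec(target=target, amplicon_seq=amplicon,
                               indel_fraction=0.2, n_pairs=50, seed=200 + i)
            sims.append(gen_amplicon_reads(spec))
            targets.append(target)
        pool = [p for s in sims for p in s.pairs]
        rng.shuffle(pool)
        assigned, unassigned = demultiplex_reads(pool, targets)
        assert not unassigned
        for t, s in zip(targets, sims):
            assert len(assigned[t.target_id]) == len(s.pairs)
        assert sum(map(len, assigned.values())) + len(unassigned) == len(pool)

    def test_ambiguous_primer_table_rejected(self):
        t1, _ = build_target(target_id="a", seed=1)
        t2 = AmpliconTarget(
            target_id="b", gene="g", chrom=t1.chrom,
            proto_start=t1.proto_start, proto_end=t1.proto_end, strand="+",
            amplicon_start=t1.amplicon_start, amplicon_end=t1.amplicon_end,
            fwd_primer=t1.fwd_primer + "ACGT", rev_primer="TTTTTTTTTT",
        )
        with pytest.raises(TargetTableError):
            validate_primer_table([t1, t2])


class TestPairFilter:
    def test_both_mates_inside_kept(self, target_and_amplicon):
        target, _ = target_and_amplicon
        reads = _pair("p", target.chrom, target.amplicon_start, "100M",
                      target.amplicon_end - 100, "100M")
        kept, tally = filter_on_target_pairs(reads, target)
        assert len(kept) == 2 and tally["kept"] == 2

    def test_wrong_chromosome_dropped(self, target_and_amplicon):
        target, _ = target_and_amplicon
        reads = _pair("p", target.chrom, target.amplicon_start, "100M",
                      target.amplicon_end - 100, "100M")
        reads[1] = AlignedRead(name="p", chrom="other", pos=reads[1].pos, mapq=60,
                               cigar="100M", seq="A" * 100, is_read1=False)
        kept, tally = filter_on_target_pairs(reads, target)
        assert not kept and tally["dropped_off_target"] == 2

    def test_slop_boundary(self, target_and_amplicon):
        # mate ending exactly at amplicon_start - 50 is out; one base later is in
        target, _ = target_and_amplicon
        for end_at, expect_kept in ((target.amplicon_start - 50, 0),
                                    (target.amplicon_start - 49, 2)):
            reads = _pair("p", target.chrom, end_at - 100, "100M",
                          target.amplicon_start, "100M")
            kept, _ = filter_on_target_pairs(reads, target, slop=50)
            assert len(kept) == expect_kept

    def test_missing_mate_tallied_not_raised(self, target_and_amplicon):
        target, _ = target_and_amplicon
        lone = AlignedRead(name="p", chrom=target.chrom, pos=target.amplicon_start,
                           mapq=60, cigar="100M", seq="A" * 100, is_read1=True)
        kept, tally = filter_on_target_pairs([lone], target)
        assert not kept and tally["dropped_missing_mate"] == 1


class TestCallReadIndels:
    def test_perfect_match_no_events(self, target_and_amplicon):
        target, _ = target_and_amplicon
        read = AlignedRead(name="r", chrom=target.chrom, pos=target.cut_position - 50,
                           mapq=60, cigar="100M", seq="A" * 100)
        assert call_read_indels(read, target) == []

    def test_deletion_coordinates_from_cigar_walk(self, target_and_amplicon):
        target, _ = target_and_amplicon
        cut = target.cut_position
        read = AlignedRead(name="r", chrom=target.chrom, pos=cut - 50, mapq=60,
                           cigar="45M5D55M", seq="A" * 100)
        events = call_read_indels(read, target)
        assert events == [IndelEvent(kind="del", start=cut - 5, length=5)]

    def test_insertion_outside_window_ignored(self, target_and_amplicon):
        target, _ = target_and_amplicon
        cut = target.cut_position
        # insertion point at cut + 30: outside the +/-20 window
        read = AlignedRead(name="r", chrom=target.chrom, pos=cut - 50, mapq=60,
                           cigar="80M2I18M", seq="A" * 100)
        assert call_read_indels(read, target) == []

    def test_insertion_inside_window_called(self, target_and_amplicon):
        target, _ = target_and_amplicon
        cut = target.cut_position
        read = AlignedRead(name="r", chrom=target.chrom, pos=cut - 50, mapq=60,
                           cigar="50M2I48M", seq="A" * 50 + "GG" + "A" * 48)
        events = call_read_indels(read, target)
        assert events == [IndelEvent(kind="ins", start=cut, length=2, inserted_seq="GG")]


class TestEventFilter:
    def test_rate_boundary_strict_less_than(self):
        ev4 = IndelEvent("del", 100, 5)
        ev5 = IndelEvent("del", 200, 3)
        per_read = {f"r{i}": [ev4] for i in range(4)}
        per_read.update({f"s{i}": [ev5] for i in range(5)})
        per_read.update({f"clean{i}": [] for i in range(991)})
        retained = summarize_and_filter_events(per_read, 1000, min_rate=0.005)
        kept = {s.event: s for s in retained}
        assert ev4 not in kept          # 4/1000 = 0.4% removed
        assert kept[ev5].rate == 0.005  # 5/1000 retained exactly at the bound

    def test_empty_events(self):
        assert summarize_and_filter_events({"r": []}, 10) == []


class TestEfficiency:
    def _covering_reads(self, target, n_indel, n_total):
        cut = target.cut_position
        reads = []
        for i in range(n_total):
            cigar = "45M5D55M" if i < n_indel else "100M"
            reads.append(AlignedRead(name=f"r{i}", chrom=target.chrom,
                                     pos=cut - 50, mapq=60, cigar=cigar,
                                     seq="A" * 100))
        return reads

    def test_direct_count(self, target_and_amplicon):
        target, _ = target_and_amplicon
        res = compute_efficiency(self._covering_reads(target, 300, 1000), target)
        assert res.efficiency == pytest.approx(0.30)
        assert res.n_indel_reads == 300 and res.n_total_reads == 1000

    def test_all_perfect_reads_zero(self, target_and_amplicon):
        target, _ = target_and_amplicon
        res = compute_efficiency(self._covering_reads(target, 0, 100), target)
        assert res.efficiency == 0.0

    def test_no_coverage_flagged(self, target_and_amplicon):
        target, _ = target_and_amplicon
        res = compute_efficiency([], target)
        assert res.no_coverage
        with pytest.raises(ValueError):
            _ = res.efficiency

    def test_monotone_in_min_rate(self, target_and_amplicon):
        target, amplicon = target_and_amplicon
        spec = ReadSimSpec(target=target, amplicon_seq=amplicon,
                           indel_fraction=0.25, n_pairs=400, seed=77)
        sim = gen_amplicon_reads(spec)
        effs = [
            quantify_target(sim.alignments, target, min_rate=r).efficiency
            for r in (0.0, 0.005, 0.05, 0.2, 0.5)
        ]
        assert all(a >= b for a, b in zip(effs, effs[1:]))


class TestOracleEquivalence:
    def test_efficiency_equals_generator_truth_exactly(self, target_and_amplicon):
        target, amplicon = target_and_amplicon
        spec = ReadSimSpec(target=target, amplicon_seq=amplicon,
                           spectrum=SINGLE_DEL5, indel_fraction=0.3,
                           n_pairs=2000, seed=21)
        sim = gen_amplicon_reads(spec)
        res = quantify_target(sim.alignments, target)
        assert res.efficiency == sim.true_indel_fraction
        assert res.n_total_reads == 2 * spec.n_pairs  # both mates span the window

    def test_spurious_indel_errors_filtered_out(self, target_and_amplicon):
        target, amplicon = target_and_amplicon
        spec = ReadSimSpec(target=target, amplicon_seq=amplicon,
                           spectrum=SINGLE_DEL5, indel_fraction=0.2,
                           indel_error_rate=0.02, n_pairs=2000, seed=5)
        sim = gen_amplicon_reads(spec)
        res = quantify_target(sim.alignments, target)
        # each spurious 1 bp indel signature is far below the 0.5% rate filter
        assert abs(res.efficiency - sim.true_indel_fraction) < 0.01

    def test_read_count_conservation(self, target_and_amplicon):
        target, amplicon = target_and_amplicon
        spec = ReadSimSpec(target=target, amplicon_seq=amplicon,
                           indel_fraction=0.1, n_pairs=300, seed=4)
        sim = gen_amplicon_reads(spec)
        kept, tally = filter_on_target_pairs(sim.alignments, target)
        assert tally["kept"] + tally.get("dropped_off_target", 0) + \
            tally.get("dropped_missing_mate", 0) + \
            tally.get("dropped_secondary", 0) == tally["input"]
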