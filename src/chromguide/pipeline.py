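"""End-to-end orchestration: one config, six stages, one manifest.

``run_pipeline`` executes the stages in dependency order on declared input
files and writes every stage output plus a manifest (parameters, input and
output checksums) under the configured run directory; identical config and
inputs reproduce byte-identical outputs. ``make_demo`` emits a fully
synthetic dataset (toy genome, per-target reads/alignments, MNase tags,
two-stage peak files, target table) with known truth, sized so the whole
pipeline runs in well under a minute.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import accessibility, amplicon, guides, nucleosome, stats, synthetic
from .intervals import IntervalSet, merge_interval_set
from .samio import read_sam, write_fastq_pair, write_sam
from .sequtils import read_fasta, write_fasta

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised before any work starts when the config is invalid."""


@dataclass
class RunConfig:
    """All paths and numeric parameters of a pipeline run.

    The numeric defaults are the analysis constants: 40 bp cut-site window,
    0.5% minimum event rate, 73 bp midpoint shift, sigma 20 smoothing, 147 bp
    exclusion/footprint, 180 bp NO length bound, (10, 100) NL gap bounds,
    1000 bp summit extension, MAPQ 30, 1% effectiveness threshold and up to 2
    off-target mismatches.
    """

    genome: str = ""
    exons: str = ""
    targets: str = ""
    sam_dir: str = ""
    mnase_tags: str = ""
    atac_peaks: List[str] = field(default_factory=list)
    chrom_sizes: str = ""
    outdir: str = "run"

    window: int = 40
    min_event_rate: float = 0.005
    slop: int = 50
    cover: str = "full"
    shift: int = 73
    sigma: float = 20.0
    exclusion: int = 147
    min_score: float = 5.0
    no_max_len: int = 180
    nl_gap_min: int = 10
    nl_gap_max: int = 100
    oc_extension: int = 1000
    mapq_min: int = 30
    effective_threshold: float = 0.01
    max_mm: int = 2
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        checks = [
            (self.window > 0, "window must be > 0"),
            (0 <= self.min_event_rate <= 1, "min_event_rate outside [0, 1]"),
            (self.slop >= 0, "slop must be >= 0"),
            (self.cover in ("full", "any"), "cover must be 'full' or 'any'"),
            (self.shift >= 0, "shift must be >= 0"),
            (self.sigma > 0, "sigma must be > 0"),
            (self.exclusion >= 1, "exclusion must be >= 1"),
            (self.min_score >= 0, "min_score must be >= 0"),
            (self.no_max_len > 0, "no_max_len must be > 0"),
            (0 <= self.nl_gap_min < self.nl_gap_max, "NL gap bounds must satisfy 0 <= min < max"),
            (self.oc_extension > 0, "oc_extension must be > 0"),
            (self.mapq_min >= 0, "mapq_min must be >= 0"),
            (0 <= self.effective_threshold <= 1, "effective_threshold outside [0, 1]"),
            (0 <= self.max_mm <= 2, "max_mm must be 0..2"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Dict) -> "RunConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _md5(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _gene_bodies(exon_table: pd.DataFrame) -> IntervalSet:
    """Per-gene span of its exons, merged per chromosome."""
    bodies: IntervalSet = {}
    for (chrom, _), grp in exon_table.groupby(["chrom", "gene"]):
        bodies.setdefault(chrom, []).append((int(grp["start"].min()), int(grp["end"].max())))
    return merge_interval_set(bodies)


def run_pipeline(config: RunConfig) -> Dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    config.validate()
    logging.basicConfig(level=config.log_level)

    required = {
        "quantify": [config.targets, config.sam_dir],
        "nuc-classify": [config.mnase_tags, config.exons],
        "atac-regions": [config.chrom_sizes, *config.atac_peaks],
        "scan": [config.genome, config.exons],
    }
    for stage, paths in required.items():
        for p in paths:
            if not p or not Path(p).exists():
                raise ConfigError(f"stage {stage}: missing input {p!r}")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: Dict[str, str] = {}

    # stage 1: per-target efficiency quantification
    targets = amplicon.read_target_table(config.targets)
    target_extra = pd.read_csv(config.targets, sep="\t", dtype=str)
    results = []
    for t in targets:
        sam_path = Path(config.sam_dir) / f"{t.target_id}.sam"
        if not sam_path.exists():
            raise ConfigError(f"stage quantify: missing input {sam_path}")
        res = amplicon.quantify_target(
            read_sam(sam_path), t, min_rate=config.min_event_rate,
            window=config.window, slop=config.slop, cover=config.cover,
        )
        results.append(res)
        logger.info("quantified %s: %d/%d reads", t.target_id, res.n_indel_reads,
                    res.n_total_reads)
    eff_df = amplicon.efficiency_table(results)
    eff_path = outdir / "efficiency.tsv"
    eff_df.to_csv(eff_path, sep="\t", index=False, float_format="%.6f")
    amplicon.event_table(results).to_csv(
        outdir / "events.tsv", sep="\t", index=False, float_format="%.6f"
    )
    outputs["efficiency"] = str(eff_path)

    # stage 2: NL/NO/dynamic partition of gene bodies
    chrom_sizes = accessibility.read_chrom_sizes(config.chrom_sizes)
    exon_table = pd.read_csv(config.exons, sep="\t", header=None,
                             names=["chrom", "start", "end", "gene"])
    bodies = _gene_bodies(exon_table)
    tags = nucleosome.read_tags_bed(config.mnase_tags)
    profiles = nucleosome.shift_to_midpoints(
        tags, chrom_sizes, shift=config.shift, universe=bodies
    )
    peaks = nucleosome.call_nucleosome_peaks(
        profiles, sigma=config.sigma, exclusion=config.exclusion,
        min_score=config.min_score,
    )
    nuc_part = nucleosome.classify_nucleosome_regions(
        peaks, bodies, no_max_len=config.no_max_len,
        nl_gap_bounds=(config.nl_gap_min, config.nl_gap_max),
    )
    nuc_path = outdir / "nucleosome_partition.bed"
    nuc_part.to_bed(nuc_path)
    nucleosome.peaks_to_bed(peaks, outdir / "nucleosome_peaks.bed")
    outputs["nuc-classify"] = str(nuc_path)
    logger.info("called %d nucleosome peaks", len(peaks))

    # stage 3: OC/CC partition of the genome
    peak_sets = [accessibility.read_narrowpeak(p) for p in config.atac_peaks]
    oc = accessibility.summits_to_oc(peak_sets, chrom_sizes, extension=config.oc_extension)
    oc_part = accessibility.partition_oc_cc(oc, chrom_sizes)
    oc_path = outdir / "chromatin_oc_cc.bed"
    oc_part.to_bed(oc_path)
    outputs["atac-regions"] = str(oc_path)
    logger.info("OC fraction: %.4f", oc_part.genome_fraction("OC"))

    # stage 4: exome-wide guide scan + annotation + off-target counts
    genome = read_fasta(config.genome)
    exon_set = synthetic.exon_interval_set(exon_table)
    cands = guides.scan_pam_targets(genome, exon_set)
    cands = guides.assign_genes(cands, exon_table)
    cands = guides.annotate_chromatin(cands, oc_partition=oc_part, nuc_partition=nuc_part)
    cands = guides.add_mismatch_counts(cands, genome, max_mm=config.max_mm)
    cands = guides.attach_sequence_score(cands, None)
    guide_path = outdir / "guides.tsv"
    guides.export_guide_db(cands, guide_path)
    per_gene = guides.per_gene_oc_counts(cands)
    per_gene.to_csv(outdir / "per_gene_oc.tsv", sep="\t", index=False)
    outputs["scan"] = str(guide_path)
    logger.info("scanned %d guide candidates", len(cands))

    # stage 5: cohort assembly (efficiencies + chromatin labels + pairing)
    cohort_rows = []
    for t, res in zip(targets, results):
        extra = target_extra[target_extra["target_id"] == t.target_id]
        pair_id = ""
        if "pair_id" in extra.columns and not extra.empty:
            pair_id = str(extra["pair_id"].iloc[0] or "")
            if pair_id == "nan":
                pair_id = ""
        cohort_rows.append(
            {
                "guide_id": t.target_id,
                "label": oc_part.label_at(t.chrom, t.cut_position),
                "nuc_label": nuc_part.label_at(t.chrom, t.cut_position),
                "pair_id": pair_id,
                "n_reads": res.n_total_reads,
                "n_indel_reads": res.n_indel_reads,
                "efficiency": np.nan if res.no_coverage else res.efficiency,
            }
        )
    cohort = pd.DataFrame(cohort_rows)
    cohort_path = outdir / "cohort.tsv"
    cohort.to_csv(cohort_path, sep="\t", index=False, float_format="%.6f")
    outputs["cohort"] = str(cohort_path)

    # stage 6: effectiveness statistics
    paired = bool((cohort["pair_id"] != "").any())
    report = stats.cohort_report(
        cohort.dropna(subset=["efficiency"]), "OC", "CC",
        paired=paired, threshold=config.effective_threshold,
    )
    stats_path = outdir / "stats.json"
    with open(stats_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    outputs["stats"] = str(stats_path)

    input_paths = [config.genome, config.exons, config.targets, config.mnase_tags,
                   config.chrom_sizes, *config.atac_peaks]
    manifest = {
        "parameters": config.to_dict(),
        "inputs": {p: _md5(p) for p in input_paths},
        "stages": list(outputs),
        "outputs": {name: _md5(path) for name, path in outputs.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ----------------------------------------------------------------- demo data
DEMO_OC_RATES = (0.32, 0.18, 0.16, 0.12, 0.10, 0.06)   # emulate the paired design:
DEMO_CC_RATES = (0.08, 0.05, 0.04, 0.03, 0.02, 0.01)   # open ~15%, closed ~4%


def make_demo(outdir, seed: int = 0, n_pairs_per_target: int = 1200) -> Tuple[RunConfig, Dict]:
    """Build a self-contained synthetic dataset plus a ready-to-run config.

    Returns ``(config, truth)`` where truth records the planted per-target
    rates and labels. The demo genome is 250 kb over two chromosomes with 16
    genes; six OC/CC target pairs emulate the paired co-injection design, and
    the two-stage peak files are laid out so that open chromatin covers 5.4%
    of the genome.
    """
    outdir = Path(outdir).resolve()  # config paths survive a cwd change
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    chrom_sizes = {"chr1": 150_000, "chr2": 100_000}
    exons: Dict[str, List[Tuple[int, int, str]]] = {"chr1": [], "chr2": []}
    gene_slots = [("chr1", i) for i in range(10)] + [("chr2", i) for i in range(6)]
    gene_names = []
    for gi, (chrom, slot) in enumerate(gene_slots):
        body = 15_000 * slot + 2_000
        gene = f"gene{gi:02d}"
        gene_names.append((gene, chrom, body, body + 6_000))
        exons[chrom].append((body, body + 2_000, gene))
        exons[chrom].append((body + 4_000, body + 6_000, gene))

    gspec = synthetic.ToyGenomeSpec(
        chrom_sizes=chrom_sizes, exons=exons, gc_fraction=0.4,
        seed=int(rng.integers(2 ** 31)),
    )
    genome, exon_table = synthetic.gen_toy_genome(gspec)
    write_fasta(genome, outdir / "genome.fa")
    exon_table.to_csv(outdir / "exons.bed", sep="\t", header=False, index=False)
    accessibility.write_chrom_sizes(chrom_sizes, outdir / "chrom.sizes")

    # six OC/CC target pairs in the first exons of genes 0..11
    sam_dir = outdir / "sam"
    sam_dir.mkdir(exist_ok=True)
    targets, truth_targets = [], []
    pair_col = []
    for j in range(6):
        for label, gi, rate in (
            ("OC", 2 * j, DEMO_OC_RATES[j]),
            ("CC", 2 * j + 1, DEMO_CC_RATES[j]),
        ):
            gene, chrom, body, _ = gene_names[gi]
            target = _pick_target(genome, chrom, (body, body + 2_000),
                                  f"t_{label}{j}", gene)
            rspec = synthetic.ReadSimSpec(
                target=target,
                amplicon_seq=genome[chrom][target.amplicon_start:target.amplicon_end],
                indel_fraction=rate,
                n_pairs=n_pairs_per_target,
                seed=int(rng.integers(2 ** 31)),
            )
            sim = synthetic.gen_amplicon_reads(rspec)
            write_sam(sim.alignments, sam_dir / f"{target.target_id}.sam", chrom_sizes)
            write_fastq_pair(sim.pairs, outdir / f"reads_{target.target_id}")
            targets.append(target)
            pair_col.append(f"pair{j}")
            truth_targets.append(
                {"target_id": target.target_id, "gene": gene, "label": label,
                 "pair_id": f"pair{j}", "true_rate": rate,
                 "cut": target.cut_position, "chrom": chrom}
            )
    amplicon.write_target_table(targets, outdir / "targets.tsv")
    ttab = pd.read_csv(outdir / "targets.tsv", sep="\t", dtype=str)
    ttab["pair_id"] = pair_col
    ttab.to_csv(outdir / "targets.tsv", sep="\t", index=False)

    # ATAC peaks: a summit at each OC target cut + one edge summit on chr2;
    # 6 x 2000 + 1500 clipped bases = 13,500 of 250,000 bp -> 5.4% open
    oc_summits = [(t["chrom"], t["cut"]) for t in truth_targets if t["label"] == "OC"]
    edge = ("chr2", 500)
    stage1 = oc_summits[:4] + [edge]
    stage2 = oc_summits[2:] + [edge]
    for name, summits in (("stage1.narrowPeak", stage1), ("stage2.narrowPeak", stage2)):
        with open(outdir / name, "w") as fh:
            for i, (chrom, s) in enumerate(summits):
                lo = max(0, s - 200)
                fh.write(
                    f"{chrom}\t{lo}\t{s + 200}\tpeak{i}\t100\t.\t5.0\t10.0\t8.0\t{s - lo}\n"
                )

    # MNase tags: regular nucleosome arrays along every gene body
    all_tags = []
    for chrom, size in chrom_sizes.items():
        bodies = [(s, e) for g, c, s, e in gene_names if c == chrom]
        dyads = []
        for bs, be in bodies:
            dyads.extend((pos, 40) for pos in range(bs + 100, be - 100, 200))
        nspec = synthetic.NucArraySpec(
            chrom=chrom, chrom_size=size, dyads=tuple(dyads), jitter_sd=5.0,
            background_rate=0.005, universe=tuple(bodies),
            seed=int(rng.integers(2 ** 31)),
        )
        tags, _ = synthetic.gen_midpoint_tags(nspec)
        all_tags.extend(tags)
    synthetic.write_tags_bed(all_tags, outdir / "mnase_tags.bed")

    config = RunConfig(
        genome=str(outdir / "genome.fa"),
        exons=str(outdir / "exons.bed"),
        targets=str(outdir / "targets.tsv"),
        sam_dir=str(sam_dir),
        mnase_tags=str(outdir / "mnase_tags.bed"),
        atac_peaks=[str(outdir / "stage1.narrowPeak"), str(outdir / "stage2.narrowPeak")],
        chrom_sizes=str(outdir / "chrom.sizes"),
        outdir=str(outdir / "run"),
        seed=seed,
    )
    config.dump(outdir / "config.yaml")
    truth = {
        "targets": truth_targets,
        "expected_oc_fraction": 13_500 / 250_000,
        "mean_true_rate_oc": float(np.mean(DEMO_OC_RATES)),
        "mean_true_rate_cc": float(np.mean(DEMO_CC_RATES)),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return config, truth


def _pick_target(
    genome: Dict[str, str], chrom: str, region: Tuple[int, int],
    target_id: str, gene: str,
) -> amplicon.AmpliconTarget:
    """Deterministically pick the PAM candidate nearest the region center."""
    cands = guides.scan_pam_targets(
        genome={chrom: genome[chrom]}, exons={chrom: [region]},
    )
    if cands.empty:
        raise RuntimeError(f"no PAM candidate in {chrom}:{region}")
    center = (region[0] + region[1]) // 2
    cands = cands.assign(dist=(cands["cut"] - center).abs())
    row = cands.sort_values(["dist", "proto_start", "strand"]).iloc[0]
    amp_start, amp_end = int(row.cut) - 110, int(row.cut) + 110
    seq = genome[chrom]
    from .sequtils import revcomp

    return amplicon.AmpliconTarget(
        target_id=target_id, gene=gene, chrom=chrom,
        proto_start=int(row.proto_start), proto_end=int(row.proto_end),
        strand=row.strand, amplicon_start=amp_start, amplicon_end=amp_end,
        fwd_primer=seq[amp_start : amp_start + 22],
        rev_primer=revcomp(seq[amp_end - 22 : amp_end]),
    )
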