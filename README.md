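# chromguide

Local chromatin structure and CRISPR/Cas9 efficiency in zebrafish, as a
tested, reusable pipeline. For zebrafish mutant construction the screening
workload is set by the founder mutation rate, so choosing gRNAs that cut
well matters; beyond sequence features, the local chromatin context of the
target — nucleosome occupancy and accessibility during the early embryonic
stages when Cas9 actually edits — carries usable signal. `chromguide`
implements the full computation:

* **Amplicon indel quantification** — demultiplex read pairs by primer
  prefixes, keep on-target alignments, call insertion/deletion events from
  CIGAR strings in the 40 bp window around the cut site, drop event
  signatures with occurrence rate < 0.5%, and report

  `efficiency = n_indel_reads / n_total_reads`

  over reads spanning the window (a guide is *effective* when
  efficiency > 1%).
* **Nucleosome partition** — MNase-seq 5' tags shifted ±73 bp to dyad
  midpoints, Gaussian-smoothed (σ = 20), peaks called with a 147 bp
  exclusion zone; merged 147 bp footprints < 180 bp are nucleosome-occupied
  (NO), larger pieces dynamic, and complement gaps of 10–100 bp are linkers
  (NL), over gene bodies.
* **Accessibility partition** — ATAC-seq peak summits from two embryonic
  stages extended ±1000 bp and merged are open chromatin (OC); the genome
  complement is closed (CC).
* **Guide scanning** — every exon-overlapping 20-mer + NGG on both strands,
  annotated with the chromatin label at its cut position and exact
  genome-wide counts of 0/1/2-mismatch sites (pigeonhole seed search,
  verified against a brute-force oracle).
* **Cohort statistics** — effective/ineffective 2×2 tables with odds ratio
  ad/(bc), Welch and paired t-tests on mutation rates, discretized rate
  bins, and per-pair rate differences for the co-injection design.

A synthetic-data module generates every input type with known ground truth
(planted indel fractions, nucleosome arrays, two-stage peak layouts, cohort
rates), so the whole pipeline is testable offline.

## Worked example

Build the bundled synthetic demo (250 kb genome, six OC/CC gRNA pairs with
planted rates ≈15% vs ≈4%, open chromatin laid out to cover 5.4% of the
genome) and run all six stages:

```bash
chromguide demo --outdir scratch/demo --seed 1
```

or run the numbered drivers, which narrate each stage and write tables
under `results/`:

```bash
cd analysis
python 01_simulate.py && python 02_quantify.py && python 03_partition.py
python 04_scan.py && python 05_stats.py
```

Output from the demo run (seed 1):

```
max |estimate - planted| = 0.0192 over 12 targets          # 02_quantify
open chromatin covers 5.4% of the demo genome              # 03_partition
5301 candidates scanned; 1010 (19.1%) in open chromatin    # 04_scan
published-group odds ratios: OC/CC 1.52, NL/NO 1.25        # 05_stats
demo cohort: mean rate OC 0.152 vs CC 0.037, paired p = 0.0050
demo mean pair difference: 0.115
```

Reading the numbers: the quantifier recovers every planted editing rate to
within binomial noise; the accessibility stage reproduces the designed open
fraction exactly; and on the paired cohort the open-chromatin guide of each
pair out-edits its closed partner (mean difference 0.115, paired t-test
p ≈ 0.005) — the synthetic analogue of the finding that accessibility
predicts efficiency. The OC/CC odds ratio 1.52 is recomputed from the
published group sizes (37 open guides, 48.6% effective, vs 73 closed at
38.9%).

Each stage is also a standalone subcommand (`quantify`, `nuc-classify`,
`atac-regions`, `scan`, `stats`, `run`) operating on standard formats
(FASTQ/SAM/BAM, BED, narrowPeak, FASTA, TSV); `chromguide run --config
config.yaml` executes everything from one config and writes a manifest with
parameters and input/output checksums, so identical configs reproduce
byte-identical runs.

## Layout

```
src/chromguide/     library (synthetic, amplicon, nucleosome, accessibility,
                    guides, stats, intervals, samio, pipeline, cli)
analysis/           numbered narrative drivers over the library
tests/              pytest suite, including end-to-end acceptance checks
scripts/            acceptance.py
docs/methods.md     models, parameters, design choices, limitations
```
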