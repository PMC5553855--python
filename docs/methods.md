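# Methods

`chromguide` reimplements, as a tested library plus analysis pipeline, the
computation linking local chromatin structure to CRISPR/Cas9 editing
efficiency in early zebrafish embryos: amplicon-sequencing indel
quantification, an MNase-seq nucleosome partition and an ATAC-seq
accessibility partition of the genome, exome-wide gRNA candidate scanning
with off-target counting, and the contingency/comparison statistics that
relate chromatin state to gRNA effectiveness. This note describes the model
behind each stage, the parameters that matter, the synthetic data used to
validate it, and the numerical choices made where the procedure was
genuinely open.

All coordinates are 0-based half-open. The Cas9 cut position is an
inter-base coordinate 3 bp 5' of the PAM, between protospacer positions 17
and 18.

## Efficiency from amplicon sequencing

For each designed target, read pairs are demultiplexed by exact prefix match
of the forward primer on mate 1 and the reverse primer on mate 2 (a mismatch
allowance is available but defaults to 0, since primer synthesis errors are
rare relative to the sequencing depth involved). A pair is kept when both
mates are mapped on the target chromosome and overlap the amplicon extended
by a 50 bp slop; "around the designed site" is not otherwise quantified, so
the slop is exposed as a parameter.

Indel events are read directly off CIGAR strings: every I/D operation whose
genomic footprint (for insertions, the insertion point) intersects the 40 bp
window centered on the cut, `[cut - 20, cut + 20)`, is an event keyed by
(type, genomic start, length, inserted sequence). Substitutions never count.
Events are aggregated by signature across reads and any signature whose
occurrence rate among window-covering reads is strictly below 0.5% is
discarded as likely PCR/sequencing error; a rate of exactly 0.5% is
retained. Efficiency is then

    efficiency = (# covering reads supporting >= 1 retained event)
               / (# reads fully spanning the 40 bp window),

with a read carrying several events counted once. Reads, not pairs, are
counted: overlapping mates both enter numerator and denominator (a
pair-collapsing flag exists). A target with zero covering reads yields an
explicit no-coverage result, never a silent 0. The full-spanning denominator
is the default; `cover="any"` accepts any window overlap.

## Nucleosome partition (NL / NO / dynamic)

MNase-seq 5' tag positions from the 256-cell and dome stages are pooled,
restricted to gene bodies (the biological question concerns exonic targets),
and shifted to nucleosome midpoints: +73 bp on the plus strand, -73 bp from
the minus-strand 5' coordinate (the rightmost aligned base), half the 147 bp
nucleosomal DNA length. Midpoint counts are smoothed with an unnormalized
Gaussian kernel, sigma = 20 bp, truncated at 5 sigma, so an isolated tag
contributes a peak of height exactly 1.

Peaks are called greedily over local maxima of the smoothed signal: take the
highest remaining local maximum, exclude all positions within +/-73 bp
(floor(147/2)), repeat until the best candidate falls below `min_score`.
Restricting candidates to local maxima is what standard exclusion-zone
callers do; selecting over raw positions would re-seed a spurious peak on
the shoulder of a tall peak exactly one base outside its exclusion zone.
`min_score` defaults to 5 smoothed tag-equivalents; the upstream enrichment
cutoff this mirrors is not published, so the value is prominently
configurable and recorded in the run manifest.

Each peak lays a 147 bp footprint `[center - 73, center + 74)` (left-biased
even split). Footprints are merged; merged pieces shorter than 180 bp are
nucleosome-occupied (NO), longer pieces are dynamic (several overlapping
alternative positions cannot be one stable nucleosome). Complement gaps
strictly between 10 and 100 bp are linkers (NL); all remaining gene-body
bases, including gaps outside those bounds, are dynamic. Bound handling is
strict on both sides; piece length is measured before clipping to the
gene-body universe. The result is validated as a partition: labels pairwise
disjoint and tiling the universe exactly. Positions outside the universe
query as "unclassified".

## Accessibility partition (OC / CC)

Peak calling itself is delegated to an external caller; the module consumes
narrowPeak files (summit = interval start + column 10). Upstream of that it
implements the read-filtering contract: drop unmapped reads, reads on
scaffold chromosomes (name pattern, default `scaffold`), and MAPQ < 30.

Every summit from both stages is extended to `[s - 1000, s + 1000)`,
extensions are clipped at chromosome bounds, and the merged union is open
chromatin (OC); the genome complement is closed chromatin (CC). Merging is
a union, not an intersection, across stages: accessibility established by
the 256-cell stage largely persists to dome, so the union approximates
"open at any point during the editing window".

## Guide scanning and off-target counting

Candidates are all genomic 20-mers followed immediately by NGG on either
strand whose protospacer overlaps an annotated exon by >= 1 bp, deduplicated
by locus and strand; candidates containing ambiguous bases are skipped.
Chromatin labels are assigned at the single base 5' of the cut on the
protospacer strand — the mechanistically relevant point, and a single-base
rule avoids partitions straddling the protospacer (a protospacer-majority
mode is available).

Off-target potential is the exact count of genomic sites (both strands)
whose 20-mer aligns end-to-end with exactly 0, 1 or 2 substitutions — no
PAM requirement by default, mirroring an ungapped alignment-based search;
`require_pam` adds the NGG constraint. m0 includes the candidate's own
locus. The counter is exact by a pigeonhole argument: the 20-mer is split
into seeds of 7 + 7 + 6 bp, and any site with <= 2 mismatches must match at
least one seed exactly. Seed hits are found by comparing vectorized integer
k-mer codes (exact base-4 encoding, not hashing) and verified by full
Hamming comparison at the hit positions only. The test suite checks this
route against an independent position-by-position sliding Hamming oracle.

External sequence scores (e.g. from a published scoring model) are joined
from a user-supplied table keyed by protospacer; missing scores stay null.
The exported database table is deterministically sorted and accompanied by
per-gene counts of open-chromatin candidates, from which the fraction of
genes with >= k such candidates is computed.

## Cohort statistics

A guide is *effective* when efficiency > 1% (strict). Between two chromatin
groups the effective/ineffective 2x2 table gives the odds ratio ad/(bc),
reported with both group proportions; a zero cell falls back to the
Haldane-Anscombe +0.5 correction with an explicit flag. When reconstructing
a table from published group sizes and percentages, effective counts are
`round(pct x n)`. Two such reconstructions are worth noting: 37 open
guides at 48.6% vs 73 closed at 38.9% gives OR 1.52 as published, while
21 linker at 47.6% vs 38 occupied at 42.1% gives ad/(bc) = 1.25 where the
source figure prints 1.22, and 28/73 = 38.4% where 38.9% is printed — the
exact counts behind those printed values are not recoverable, so the
package reports the arithmetic value and documents the gap rather than
forcing agreement.

Mean-rate comparisons use a Welch two-sample t-test (unpaired; safer than
the pooled-variance variant when group sizes and variances differ, with a
flag for the pooled version) or a paired t-test on within-pair differences
for the co-injection design. An `effective_only` restriction reproduces the
convention of comparing rate distributions among working guides only.
Rates are also discretized into (<=1%], (1-15%], (15-30%], (>30%) bins with
strict upper comparisons, and per-pair OC - CC differences are reported
with their mean.

## Synthetic data: what it emulates and what it does not

Every stage is validated against generators with known truth:

* **Toy genome** — i.i.d. bases at a target GC fraction (default 0.4,
  roughly the AT-rich vertebrate regime) with exon annotation. No repeats,
  isochores or assembly gaps: off-target counts on it are calibration
  checks, not genome-realistic distributions.
* **Amplicon reads** — each pair independently carries a planted indel with
  probability f, drawn from a weighted spectrum of insertions/deletions near
  the cut (default: 5 bp and 2 bp deletions, 1 bp and 3 bp insertions, all
  within a few bp of the cut). Substitution errors at 0.001/bp never touch
  the primer prefixes, so demultiplexing truth counts are exact. An opt-in
  spurious-indel error mode plants random 1 bp indels on non-carrier reads
  to exercise the 0.5% event filter (carrier reads are left clean to keep
  truth CIGARs exact). Amplicons are 220 bp with 150 bp reads, so both mates
  span the cut window and the estimator's effective sample size is the pair
  count. No quality-score model, PCR duplicates or chimeras.
* **MNase tags** — planted dyads with per-dyad tag counts, Gaussian
  positional jitter and uniform background; tags are emitted as pre-shift
  5' positions so the +/-73 reconstruction is exercised. The truth partition
  applies the classification rules to the noise-free dyads. Parameter
  recovery fixtures use arrays at 200 bp spacing (147 bp footprints with
  53 bp linker gaps), jitter SD <= 10 bp and >= 20 tags/dyad.
* **Cohorts** — per-guide efficiencies are Binomial(n_reads, true rate)
  draws. The unpaired default emulates the 110-guide multiplex design
  (37 open-chromatin targets, low overall rates); the paired design plants
  15% vs 4% as in the 20-pair co-injection experiment.

Recovery fixtures for the efficiency estimator use a single-signature
spectrum (one 5 bp deletion at the cut). With a dispersed spectrum and
f = 1%, every individual signature sits below the 0.5% occurrence filter
and is removed by construction — the concentrated spectrum, typical of a
dominant microhomology-mediated repair outcome, is the regime in which
estimator accuracy is a meaningful question at the effectiveness boundary.

The bundled demo (250 kb genome, 16 genes, six OC/CC target pairs at
1200 read pairs each) reproduces the study's macroscopic numbers by design:
open chromatin covers exactly 5.4% of the demo genome, and planted paired
rates average ~15% (OC) vs ~4% (CC). It runs end to end in well under a
minute on one CPU.

## Numerical choices and degenerate inputs

* Problem sizes in the test suite (1 Mb partition universes, 300 kb scan
  genomes, 100-1000 statistical replicates, 5000 read pairs per recovery
  replicate) were chosen as the smallest scales at which the binomial error
  bars and base-level scans are meaningful.
* Peak-calling ties break leftmost (stable sort); plateau local maxima
  count once, at their left edge.
* Interval merging treats touching intervals as one; a zero-width gap is
  not a linker candidate.
* Degenerate statistics are flagged, not raised: identical groups return
  statistic 0 and p = 1; a zero contingency cell triggers the Haldane
  correction with `haldane_corrected=True`.
* All generator randomness flows from one `numpy.random.Generator` per
  call, seeded from the spec; identical specs give byte-identical outputs,
  and gzip streams are written with a pinned mtime so reruns are
  byte-identical too.

## Known limitations

* The enrichment-score cutoff for nucleosome peaks and the exact
  filter-then-merge order of the original caller are not published;
  remove-then-merge with a configurable `min_score` is implemented.
* Off-target counting is substitution-only (ungapped), `max_mm <= 2`; bulge
  off-targets are out of scope.
* The scanner deduplicates candidates per genomic locus; a count per
  transcript annotation would differ where isoforms share exons.
* Reprocessing the original deposited sequencing runs (and hence the
  published genome-scale numbers such as the 5.4% open-chromatin fraction
  on the real assembly) requires external downloads and an aligner; the
  package consumes alignments and peak calls but does not fetch them.
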