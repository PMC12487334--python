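# Methods

This note documents the models, rules and numerical choices behind
`svatlas`, and what the synthetic-data validation does and does not
demonstrate about real data.

## Coordinates and data model

All internal coordinates are 0-based half-open. VCF and GFF3 (both
1-based inclusive) are converted at the I/O boundary; BED and bedGraph
pass through unchanged. SV length is breakpoint span `end − start`
(symbolic alleles; no sequence resolution), undefined for translocation
breakends (BND), which are carried only until the filter step that
removes them. Genotypes are a four-state code (hom-ref / het / hom-alt /
missing); an END smaller than POS in an input VCF is a hard error
(checked on the raw text, since htslib silently drops such an END).

## Filter cascade

Order is fixed and meaningful: site-level filters → DHFFC genotype
masking → allele-count/call-rate filters, because the final step must
see masked genotypes.

* **Chromosome whitelist / translocations** — records off the
  whitelisted chromosomes, and all BND records, are removed.
* **Gaps and high-depth regions** — removal on ≥ 1 bp intersection.
  "High depth" is the maximal merge of depth-track segments with mean
  depth strictly above the threshold (default 100×). The ≥ 1 bp rule is
  the most permissive removal; for a QC filter that is the conservative
  direction.
* **DHFFC masking** — DHFFC is the fold-change of mean depth inside the
  SV relative to both flanks jointly (default 1 kb each side, clipped at
  chromosome ends, length-weighted; a zero/absent flank mean yields "no
  evidence"). Masking applies to **carrier genotypes only** (het,
  hom-alt): deletions with DHFFC > 0.7, duplications with DHFFC < 1.3,
  inversions with DHFFC strictly inside (0.7, 1.3) are set to missing.
  All thresholds are strict inequalities. Non-carriers are exempt
  because their expected fold-change is ≈ 1 regardless of the call;
  masking them would erase every reference genotype at real deletions.
  A carrier without a DHFFC value is retained: the filter acts only on
  positive evidence of depth inconsistency.
* **Allele count / call rate** — after masking, sites with ALT allele
  count ≤ 2 (het = 1, hom-alt = 2, over non-missing calls) or call rate
  < 0.80 are removed; a rate of exactly 0.80 survives. Allele counts are
  recomputed post-masking rather than taken from a VCF `AC` field.
* Visual curation of candidate sites is out of scope; the curation
  *sample-selection* rule is implemented (per SV: 2 hom-ref + 2 het +
  3 hom-alt drawn without replacement, shortfalls back-filled from the
  remaining called samples, everything returned when fewer than 7 calls
  exist).

## Interval semantics

`overlap_join` reports every query/subject pair with shared span
≥ `min_bp` and both overlap fractions ≥ `min_recip` — the inclusive
(≥) semantics of `bedtools intersect -wo -f F -r`. Redundancy
clustering of same-type records uses *strictly greater than* the 95%
reciprocal threshold (single linkage). "100% reciprocal overlap" for
merging SV sets is implemented as exact coordinate identity (chrom,
start, end) plus matching SV type; any floating tolerance would
contradict 100% of both lengths. Constrained-element (GERP-style)
overlap uses ≥ 1 bp and reports the mean/SD of overlapped element
lengths and of overlap lengths (population SD, ddof = 0, configurable);
with no overlapping pair the summaries are absent, not zero.

## Consequence annotation

The vocabulary is a deliberate simplification of SnpEff's SV logic;
downstream analyses depend only on the HIGH/non-HIGH partition and on
the broad category groups. HIGH = {transcript_ablation,
exon_loss_variant, frameshift_variant, gene_fusion,
bidirectional_gene_fusion}. Specific choices:

* Frameshift requires a breakpoint base strictly inside a CDS interval
  of a transcript *and* total CDS overlap not divisible by 3, evaluated
  per transcript, reported per gene; only deletions and duplications
  qualify.
* Fusions fire when the SV leaves one breakpoint base inside each of
  two distinct genes; same strand → `gene_fusion`, opposite →
  `bidirectional_gene_fusion`. Breakpoint bases are the first and last
  base the SV touches.
* Up/downstream labels are strand-aware and use the gap between the SV
  and the gene boundary (≤ 5 kb by default); one SV can be upstream of
  one gene and downstream of another. `intergenic_region` is emitted
  iff no gene overlaps and none lies within the window.
* An SV overlapping a gene without matching any specific rule (e.g. a
  breakpoint inside a non-coding exon) receives the catch-all
  `gene_variant` (MODIFIER) so every SV carries at least one
  annotation.
* The enrichment background distinguishes *affected* genes (≥ 1 HIGH
  annotation) from *associated* genes (any annotation, including
  proximity-only), mirroring how annotation tools report associations.
  Category proportions are per annotation, not per SV.

## Population genetics

Per-site Weir & Cockerham (1984) θ̂ for two diploid populations is
computed from the variance components (a: among populations, b: among
individuals within populations, c: within individuals) using observed
sample sizes, ALT frequencies and heterozygote frequencies over called
genotypes; sites need ≥ 2 called genotypes per group and are undefined
when a+b+c = 0 (monomorphic). Negative values are retained — they carry
ranking information and standard tools report them. The per-site value
is the unit statistic of the candidate scan; the multi-locus
ratio-of-averages Σa/Σ(a+b+c) is reported as a diagnostic.

A caveat the validation quantifies: the *mean* of per-site θ̂ is a
mean of ratios and sits below the simulated divergence, increasingly so
for larger F (≈ 0.15 at a true F of 0.2 under the validation
conditions) — a Jensen-type bias that persists at any sample size
because the numerator also appears in the denominator. The
ratio-of-averages recovers F to well within 0.01 and is the quantity to
use when a single differentiation estimate is wanted.

Density windows count SVs by start position on a fixed 1-Mb grid with
strict class thresholds (> 80 high, < 10 low); trailing partial windows
are flagged and keep raw counts. PCA codes genotypes 0/1/2, imputes
missing values with the per-SV mean, centers (scaling optional), and
uses an SVD with a deterministic sign convention (largest-magnitude
loading positive).

## Domestication scan

The top set of each comparison is `theta ≥ empirical quantile` of the
*defined* per-site values (linear-interpolation quantile, default
q = 0.95); threshold ties are all included rather than truncating to an
exact 5% count, and the threshold is reported so the selection is
auditable. Candidates are the intersection of all top sets, restricted
to SVs whose farmed-minus-wild allele-frequency difference has the same
non-zero sign in every comparison (a zero difference fails the rule —
"same direction" is undefined at zero, and strict is conservative).
Output is sorted by mean θ̂.

## Enrichment statistics

The per-term p-value is the one-sided upper hypergeometric tail
P(X ≥ k) — the enrichment-directional Fisher exact probability. Fold
enrichment is (k/n_affected)/((K−k)/n_background), which is +∞ exactly
when every carrier of the term is affected (K = k > 0) and 0 when
k = 0. Benjamini–Hochberg adjustment is the standard step-up with
monotonicity enforcement. The subset-proportion comparison is a Pearson
chi-square (df = 1, no continuity correction) on subset vs complement;
its construction is stated because published analyses rarely specify
theirs, and different defensible constructions move the p-value within
a factor of ~2. A warning flag is attached when an expected cell count
falls below 1.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis
assumes: a farmed group (n = 90) and three wild groups (n = 13/22/37,
with 8 excluded hybrid samples) diverged under the Balding–Nichols
model at a configurable F (default 0.1; ancestral frequencies uniform
on [0.05, 0.95]); HWE genotypes within populations; deletion-dominated
type proportions with log-normal lengths whose defaults give medians of
about 120 bp (DEL), 619 bp (DUP) and 2,456 bp (INV); and
genotype-conditional DHFFC draws (deletion het ≈ N(0.5, 0.1), deletion
hom-alt ≈ N(0.05, 0.05), duplication carriers ≈ N(1.6, 0.15), inversion
carriers ≈ N(1.0, 0.1), non-carriers ≈ N(1.0, 0.05)). Note the
inversion default places most true inversion carriers inside the
masking band — copy-neutral events show no depth change — so simulated
inversions suffer heavy attrition at the masking + allele-count steps,
as real short-read inversion calls do under this filter.

Planted structure drives the validation: records violating each filter
predicate (gap overlap, high-depth overlap, depth-artifact carriers
drawn strictly inside the masking region, low call rate, low allele
count, translocations, unplaced-scaffold placement), records
constructed to realize exact consequence terms (fully intronic,
internal-exon-deleting, two-gene-spanning), and domestication loci. For
planted domestication SVs the wild groups share a single allele
frequency (the ancestral draw) and the farmed frequency is displaced by
exactly ΔAF (default 0.5) in a direction chosen so the full
displacement stays inside [0.02, 0.98] — the planted contrast is
defined against a common wild baseline. The truth table's expected
filter outcomes are evaluated from the emitted genotypes, DHFFC values
and depth track (planting determines where violations are likely; the
labels record what the data actually contain), so cascade-vs-truth
comparisons are exact for the deterministic thresholds.

Not emulated: linkage disequilibrium (sites are independent),
breakpoint uncertainty and sequence context, read-level artifacts,
genotyping error beyond the planted modes, overlapping gene models, and
demographic history beyond one divergence parameter per population.
Passing tests therefore demonstrate the correctness of the *rules and
statistics*, not calling performance on real sequencing data.

## Validation problem sizes

The suite exercises: cohorts of ~2,000 SVs × 100–170 samples for
filter-truth recovery; 5,000-SV two-population cohorts (50 diploids per
group) per divergence level for F_ST recovery; 40,050-SV four-population
cohorts across five replicates for the candidate scan; 500 × 500 random
intervals against an all-pairs oracle for the overlap engine; exhaustive
hypergeometric enumeration for all tables with N ≤ 25 plus 2,000 random
tables up to N = 200; and 200-permutation null calibration of the
gene-set test. These sizes give stable checks at interactive runtimes;
every threshold asserted is the one stated by the corresponding rule,
not fitted to a run.

## Known limitations

* One transcript per gene is assumed by the generator (the annotator
  itself handles multiple transcripts).
* `merge_sv_sets` requires exact coordinate identity; callers wanting
  fuzzy breakpoint matching (e.g. 50-bp slop) need a different join.
* The chi-square subset test is asymptotic; for small subsets the
  attached reliability flag should be heeded.
* Per-site θ̂ means are biased low (see above); comparisons across
  studies should use the ratio-of-averages.
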