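# Methods

This note records the models, rules and numerical choices behind each
stage, what the synthetic-data generator does and does not emulate, and
the design decisions taken where the conventions of the field leave room.

## Coordinates and formats

All internal coordinates are 0-based half-open. GFF3/GTF are read and
written 1-based inclusive, BED/BEDPE 0-based half-open, cytosine reports
1-based; each conversion happens exactly once at the I/O boundary
(`oryzanc.io`). Interval joins use an interval tree per chromosome with
≥ 1 bp overlap semantics (`IntervalIndex`); abutting half-open intervals
do not overlap.

## lncRNA identification and classification

Filters (applied in a fixed order so every rejection is attributable to
one rule): length ≥ 200 bp → mean FPKM ≥ 0.1 → not a known protein-coding
id → no confident protein-domain hit (a best Pfam e-value ≤ 1e−5 rejects;
absent or weaker evidence passes) → coding probability < 0.5. Coding
probabilities and Pfam e-values are consumed from upstream tools, never
recomputed.

The five positional classes are assigned by precedence, which resolves
multi-overlap cases deterministically:

1. **sense** — ≥ 1 bp same-strand overlap with an exon of a coding gene;
2. **intronic** — fully contained in a single intron, same strand;
3. **antisense** — any opposite-strand overlap (exonic or intronic);
4. **bidirectional** — no overlap, TSS within 1 kb of a coding TSS in
   divergent (head-to-head) orientation; the window is a parameter
   (`bidirectional_window`) because published classifiers differ;
5. **intergenic** otherwise.

Classification never looks at expression, so filtering and classification
commute; a property test asserts this.

**Hot clusters.** lncRNAs are binned by their strand-aware 5′ start into
100-kb bins. The reference level is the genome-wide mean count per bin
(not per-chromosome — the conservative single reference when the scope is
ambiguous); bins strictly above 2× that mean are merged when consecutive
and reported when the merged span strictly exceeds 500 kb. With all-equal
non-zero counts no bin can strictly exceed twice the mean, so uniform
landscapes yield no clusters.

**Expression summaries.** Tiers: low < 0.5 ≤ middle ≤ 2 < high (both
printed boundaries closed into the middle tier, since the source
inequalities leave them open on both sides). Tissue sharing counts a
feature as expressed in a tissue when the mean FPKM over that tissue's
replicates reaches 0.1, the same threshold as the identification filter.

## circRNA processing

A circRNA is the half-open genomic span between its two back-splice
junction positions. QC keeps calls with ≥ 2 junction reads and span
≤ 100 kb, applied uniformly to every caller (the published protocols state
these separately per tool; uniform semantics satisfies both). Tool merging
uses exact (chrom, start, end, strand) identity — back-splice coordinates
are base-exact — and takes the *maximum* read count across tools rather
than the sum, because the callers see the same fragments. Classification:
exonic when both junction bases fall in exons of one same-strand gene;
intronic when the whole span sits inside a single intron of a same-strand
gene; everything else — including partial gene overlap and antisense
overlap — is intergenic, the conservative reading. Intergenic spans
> 10 kb (strictly) are removed. RPM = junction reads / library size × 10⁶.
Parental-gene correlation uses Pearson r with the two-sided t-based
p-value (n − 2 df) and flags p < 0.05 with r > 0.

The position profile maps each parental gene body to [0, 1) from the TSS
(minus-strand genes flipped), increments every bin overlapped by the
circRNA's relative span, and divides by the number of circRNAs; with
short uniformly-placed spans the interior bins have identical expected
occupancy, which the tests exploit.

## Methylome

All levels are read-count weighted: Σ count_meth / Σ (count_meth +
count_unmeth) over the covered cytosines of one context. Bins or features
without coverage are NaN, never silently zero. Metagene profiles rescale
the feature body to `body_bins` (default 60) and cut fixed `flank_bp`
windows (1 kb by default, 2 kb for TSS/TES views) into `flank_bins` = 20
bins each; minus-strand features are reversed so bin 0 is always the
distal 5′ flank. Weighting by reads rather than averaging per-feature
ratios keeps low-coverage features from dominating.

The bisulfite non-conversion (error) rate is the weighted level over the
chloroplast contig, which carries no true methylation in plants.

**DMR test.** For each cytosine covered by ≥ `min_coverage` (default 4)
reads in both samples, sample A's methylated count k_A out of n_A is
tested with an exact two-sided binomial test — the p-value sums P(X = i)
over all i with P(X = i) ≤ P(X = k_A), comparisons within one part in
10⁹ resolved in exact rational arithmetic so enumeration-level ties come
out exactly. The null proportion is the **pooled** estimate
(k_A + k_B)/(n_A + n_B), clamped to [ε, 1 − ε] with ε the chloroplast
error rate. A site is differential iff p ≤ 0.05 and |m_A − m_B| ≥ 0.6;
significant sites within 200 bp, same direction and context, merge into
regions with pooled levels (the region-level difference is reported; the
0.6 rule is applied per site). Direction is hyper when sample A is higher.

Why the pooled null: testing A against B's *observed* proportion treats an
estimate as a known constant and rejects ~16% of truly-null sites at
P ≤ 0.05 under 20× coverage (~10–13% even when both directions are
required); the pooled proportion is the natural estimate of the common
level under H₀ and brings the empirical false-positive rate under 0.5%
at every common level while keeping sensitivity ≈ 0.97 on 0.9-vs-0.1
sites at 20×. Both alternatives remain available (`null="other"`,
`symmetric=True`), as does optional Benjamini–Hochberg correction
(`bh=True`, off by default — the published rule is a raw P ≤ 0.05).

Even with the 0.6 difference filter, a null landscape at common level 0.5
retains ≈ 2 × 10⁻⁴ false sites per site tested (e.g. 16/20 vs 4/20 reads
gives a difference of exactly 0.6 at p ≈ 0.01), so a 10⁴-site null panel
typically shows a handful of single-site calls; this is a property of the
site-level rule itself, not of the implementation, and the corresponding
acceptance check records it.

## TEs and epigenome marks

TE association for transcripts: ≥ 1 bp TE overlap AND not fully contained
in any *single* TE interval (containment in the union but not in one TE
still counts as associated); strand-agnostic. circRNAs are TE-associated
through TE-annotated parental genes; intergenic circRNAs never are.
Superfamily composition reports, per superfamily, the number of features
whose overlap set includes it (a feature counts once per superfamily) and
the total overlapped bp; length shares sum to 1.

Histone/RNAPII marking is a boolean per feature under the 1-bp rule.
RNAPII stratification: a feature is *peak_with_interaction* when one of
its overlapping RNAPII peaks itself overlaps (≥ 1 bp, the same rule) an
anchor of an interaction pair; *peak_only* when bound but never through an
anchored peak; *no_peak* otherwise. The peak-mediated reading is the
default; `direct_anchor_overlap=True` additionally accepts a feature that
touches an anchor without a peak in between. Intensity partitions at the
median signal (configurable quantile): strictly above → strong, ties at
the split → weak, which makes the all-equal and singleton cases
deterministic. Group comparisons use the two-sided Wilcoxon rank-sum test,
exact for group sizes ≤ 8.

## ceRNA networks and conservation

lncRNAs and mRNAs under mean FPKM 0.5 are removed before correlation;
circRNAs (RPM scale) are exempt. For every miRNA, each surviving
non-coding target × mRNA target pair is scored with Pearson r across all
samples of the design (18 by default: 3 tissues × 3 varieties × 2
replicates); pairs with r > 0.8 (strict) and p < 0.05 become triplets.
Zero-variance vectors yield no pair rather than r = 0. Target edges from
multiple predictors are unioned by default (`intersect_sources` switches
to the intersection); an allow-list restricts to experimentally verified
miRNAs when supplied. DE calls: Up iff FC > 2 and FDR < 0.05, Down iff
FC < 0.5 and FDR < 0.05, all strict as printed; Benjamini–Hochberg is
applied (and flagged) when only raw p-values are supplied. Tissue networks
keep triplets whose mRNA is DE and whose ncRNA is a DE lncRNA or a
circRNA expressed in that tissue. Conservation tiers on BLAST tabular
hits: oryza (identity ≥ 80, e < 1e−5), monocot_dicot (≥ 50, e < 1e−5),
junction (≥ 95, e < 1e−5, ≤ 1 gap — counted as gap *openings*, the
tabular `gapopen` column; a flag can point the rule at a total-gaps
column instead).

## Synthetic-data generator

The generator emulates the *shape* of the study's inputs, not its
sequences: no reads, alignments or base-level bisulfite conversion are
simulated, and no distributional claim is made about the real data —
where the study reports no distributional form, standing choices are made
once and documented here.

- **Genome**: 2 × 2-Mb chromosomes (scaled down from rice for desk-scale
  runs), genes packed one per equal slot (1–5 kb, 2–5 exons), a 120-kb
  chloroplast control contig, TEs drawn from superfamily weights echoing
  the reported genome composition (Gypsy-dominated, ~7% Helitron).
- **lncRNA candidates**: a 100-kb bin is sampled with probability
  proportional to the hot-cluster density multipliers, then the sampled
  positional class is realized near that bin, so per-bin placement rate =
  background × multiplier and every candidate's class is true by
  construction. Class frequencies echo the reported rice class mix
  (half intergenic, lncNATs next). Disjoint 5% subsets violate each
  identification filter. Expression is log-normal around tissue means,
  with an expressed-tissue set per candidate (45% all tissues / 30% one /
  25% two) matching the reported sharing pattern; 18 samples.
- **circRNAs**: true junctions appear in ≥ 2 tools with ≥ 2 reads at
  exact coordinates (class mix ~78% exonic / 6% intronic / 16%
  intergenic); decoys are planted one per failure mode — single-tool,
  single-read, span > 100 kb, intergenic span > 10 kb — and labelled in
  the truth table. Per-sample junction reads are Poisson around a
  per-circRNA abundance, independent of the parental gene's FPKM, so the
  significant-positive-correlation fraction has its null value.
- **Methylome**: per-context site grids (CG/CHG/CHH spacing 30/45/15 bp),
  base levels 0.35/0.12/0.02, Poisson(20) coverage, binomial counts. The
  TSS dip multiplies levels by (1 − depth) within a half-width (default
  0.6 depth, 400 bp) of any gene TSS; planted DMR regions impose
  (level_A, level_B); the chloroplast methylates only at the error rate
  (0.003).
- **Peaks/interactions**: per-gene truth classes drawn at configured
  fractions; promoter RNAPII peaks, anchors equal to the peaks of
  interacting genes, log-normal signals spanning the weak/strong split.
  Gene slots and peak widths are sized so peaks never touch neighbouring
  genes, keeping the planted classes exact.
- **ceRNA**: planted triplets share a latent factor z with
  x = √ρ·z + √(1−ρ)·ε, giving corr(x, y) = ρ; expression is an affine
  map of x so the sample Pearson correlation concentrates at the latent
  ρ. Decoys share a miRNA with independent expression, or correlate at
  ρ without any shared miRNA.

One RNG stream per output family is derived from the master seed via a
stable label (CRC32), so regenerating one file never perturbs another;
identical configs give byte-identical files.

What passing tests on this generator do **not** show: robustness to
assembly artifacts, fragmented annotations, coverage biases, non-binomial
overdispersion of methylation counts, correlated replicates, or
predictor-specific miRNA-target error structure — none of which are
modelled.

## Validation experiments and their sizes

The experiments in `oryzanc.experiments` (run by `scripts/acceptance.py`
and asserted by the test suite) use these problem sizes, chosen so the
planted signal sits several standard deviations inside the stated margins:
hot-cluster recovery at 3000 lncRNAs over 40 bins × 20 seeds (a ×4 bin
then sits ≈ 4σ above the detection threshold); DMR null calibration at
10⁴ CG sites and recovery at 200 planted sites, both 20×; TSS-dip
recovery at 5000 genes, 20×; error-rate recovery at 10⁴ control sites;
triplet recovery at 20 planted triplets × 20 seeds. The flat-profile
check bounds every bin's |z| by the Bonferroni-adjusted 3-SE threshold
(Φ⁻¹(1 − 0.00135/B) ≈ 4.06 at B = 100 bins): the uncorrected per-bin
3-SE bound is exceeded somewhere in ~24% of exactly-null landscapes, so
the simultaneous form carries the intended family-wise ~0.27% false-alarm
rate.

## Known limitations

- The five-class precedence and the 1-kb bidirectional window are
  conventions; real classifiers disagree on multi-overlap transcripts.
- The DMR caller tests sites independently; no spatial smoothing, no
  within-region recounting of the 0.6 rule after merging.
- `merge_high_confidence` matches junctions base-exactly by default; the
  `tolerance` option accepts small per-end coordinate shifts but uses a
  quadratic scan, sized for call tables, not read-level data.
- The pipeline driver holds each stage's tables in memory; it is sized
  for annotation-level data, not for per-read matrices.
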