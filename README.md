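# oryzanc

Downstream characterization of plant long non-coding RNAs (lncRNAs) and
circular RNAs (circRNAs), written for the annotation-level outputs that a
rice (*Oryza sativa*) whole-transcriptome study produces: assembled
transcript candidates with coding-potential scores, per-tool back-splice
junction calls, per-cytosine bisulfite reports, ChIP-seq peaks and
ChIA-PET anchor pairs, miRNA target tables and BLAST hits. Everything the
pipeline consumes can also be *simulated* with planted, parameter-controlled
signal, so each stage is testable end to end without any sequencing data.

It is a library: import it, or start from the narrative scripts in
`examples/`.

## What it computes

- **lncRNA identification and positional classes** — candidates are kept
  when length ≥ 200 bp, mean FPKM ≥ 0.1, coding probability < 0.5 and no
  confident Pfam domain (best e-value ≤ 1e−5 removes a candidate), then
  classified against protein-coding genes into *sense*, *intronic*,
  *antisense*, *bidirectional* (divergent TSS within 1 kb) or *intergenic*
  by fixed precedence. Genome-wide 100-kb binning flags **hot clusters**:
  runs of bins with count > 2× the genome-wide bin mean, spanning > 500 kb.
- **circRNA QC and classification** — per-tool junction calls are filtered
  (≥ 2 junction reads, span ≤ 100 kb), intersected across callers at exact
  coordinates into a high-confidence set, classified exonic / intronic /
  intergenic against the gene models (intergenic spans > 10 kb dropped),
  normalized to RPM, and related to their parental genes (Pearson
  correlation, alternative back-splicing, length-normalized position
  profiles along the gene body).
- **DNA methylation** — CG/CHG/CHH weighted levels
  (Σmeth ⁄ Σ(meth+unmeth)) over features, metagene/TSS/TES profiles with
  fixed-width flanks, expression-stratified profiles, the bisulfite
  non-conversion error rate from the unmethylated chloroplast, and **DMR
  calling**: an exact two-sided binomial test per cytosine (P ≤ 0.05) with
  a between-sample level difference ≥ 0.6, merged into regions.
- **TEs and the epigenome** — TE association (a TE inside the transcript's
  boundaries, but the transcript not fully inside a TE; circRNAs via
  TE-annotated parents), superfamily composition by count and overlapped
  length, histone/RNAPII marking by the 1-bp overlap rule, RNAPII
  peak + interaction stratification via ChIA-PET anchors, and a
  median-split weak/strong intensity partition with Wilcoxon rank-sum
  group comparisons.
- **ceRNA networks** — competing triplets (miRNA, ncRNA, mRNA) where both
  transcripts are targets of a common miRNA and co-expressed with Pearson
  r > 0.8 and P < 0.05 across the 18-sample design; DE-restricted tissue
  networks (FC > 2 or < 0.5, FDR < 0.05); tiered BLAST conservation
  (identity ≥ 80% within the genus, ≥ 50% across monocots/dicots, ≥ 95%
  with ≤ 1 gap for back-splice junction sequences; e-value < 1e−5
  throughout); GraphML/TSV export.

## Worked example

`python examples/02_lncrna_classification.py` simulates a two-chromosome
genome with a planted high-density lncRNA region on Chr1 (600–1200 kb,
5× background placement rate) and runs identification, classification and
cluster detection:

```
candidates: 1500, retained as lncRNA: 1172
rejections by first failing rule: Counter({'fpkm': 107, 'length': 75, 'coding_probability': 73, 'pfam': 73})
positional classes: {'intergenic': 638, 'antisense': 193, 'bidirectional': 108, 'intronic': 69, 'sense': 164}
hot cluster: Chr1:600000-1200000 with 556 lncRNAs
tissue sharing: {'shared': 503, 'specific': 359, 'intermediate': 310}
expression tiers (FPKM <0.5 / 0.5-2 / >2): {'middle': 610, 'high': 332, 'low': 230}
```

Reading the output: 328 candidates fail exactly one identification filter
(each rejection is logged with the first failing rule); the five-class
split is dominated by intergenic lncRNAs (lincRNAs) followed by antisense
(lncNATs), as in rice; the single detected hot cluster coincides exactly
with the planted region; and roughly 43% of retained lncRNAs are expressed
in all three tissues.

The other examples cover the synthetic genome itself (01), circRNA QC and
classification (03), methylation profiles and DMRs (04), TE/epigenome
stratification (05), ceRNA networks and conservation (06), and the
end-to-end pipeline driver (07), which writes every stage's tables plus a
manifest and is byte-reproducible under a fixed config.

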