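# g4splice

G-quadruplex (G4) motif topography around splice sites, and its
association with alternative splicing.

G-quadruplexes are four-stranded nucleic-acid structures formed by
stacked guanine tetrads; the consensus sequence motif is four runs of at
least three guanines separated by loops of 1–7 nucleotides
(G≥3 N1–7 G≥3 N1–7 G≥3 N1–7 G≥3). This package implements, as a tested
and reusable pipeline, a genome-wide analysis of where such motifs sit
relative to exon/intron junctions and what that position is associated
with:

- **Scanning** — consensus G4 motifs and blocks of 1–6 consecutive
  G-runs, on both strands of a genome, with maximal, non-overlapping,
  leftmost-first matches (`motif_scan`).
- **Splice-site anchors** — internal exons flanked by canonical GT–AG
  introns, donor (5′ss) and acceptor (3′ss) junctions, template /
  non-template strand context, exon position groups, microexons
  (`splice_annot`).
- **Positional enrichment** — per-offset metaprofiles around junctions,
  normalised by the median count over a 1 kb window so flat background
  sits at 1; Wilson 95% CIs; bootstrap densities; nearest-feature
  distances; three-way overlap counts (`enrichment`).
- **Permutation null** — exact dinucleotide-preserving shuffles
  (Altschul–Erickson Eulerian-path construction) of splice-site
  windows; corrected fold = observed / median of N permutations;
  add-one empirical p (`permutation`).
- **Splice-site strength** — log₂-odds scoring against positional
  frequency matrices, `score = Σᵢ log2((f(bᵢ,i)+ε)/0.25)`, and
  quartile/decile stratification (`splice_strength`).
- **Association statistics** — splicing nodes called differential when
  |ΔPSI| ≥ 0.1 and probability ≥ 0.9; G4-associated when a node
  boundary is within 100 bp of a motif midpoint or 45 bp of a G4-seq
  peak midpoint; 2×2 odds ratios with Yates-corrected chi-squared and
  Bonferroni adjustment; GC-matched intron controls; SNP-adjusted sQTL
  enrichment in 25 bp bins over ±500 bp (`association_stats`).
- **RBP integration** — eCLIP binding fractions in 10 bp bins for
  G4-flanked vs non-flanked splice sites, per-bin significance masking,
  Ward clustering into k groups, and high-confidence factor calling
  against loss-of-function RNA-seq results (`rbp_integration`).
- **Synthetic data** — seeded generators for every input class with
  planted, machine-readable truth: Markov genomes, GT–AG gene models,
  planted G4s with controlled rate/offset/strand bias, PSI tables with
  a planted odds ratio, variant and peak tracks, per-bin binding
  (`synthetic_data`).

All coordinates are 0-based half-open (BED convention); offsets around
junctions are signed in transcription orientation (negative =
upstream).

## Worked example

The `demo` subcommand runs the whole pipeline on a small synthetic
bundle — generate a genome with planted G4s, scan it, profile the
hits around donor sites, run the permutation test, and test the
G4 × differential-inclusion association:

```sh
$ g4splice demo --seed 7 --out demo_out --n-perm 200
{
  "seed": 7,
  "n_sites": 480,
  "n_g4_planted": 141,
  "n_g4_scanned": 153,
  "profile_peak_enrichment": 24.0,
  "perm_fold": null,
  "perm_p": 0.004975124378109453,
  "assoc_odds_ratio": 2.3076923076923075,
  "assoc_p_adj": 0.001316899596361919
}
```

Reading the numbers: the scanner finds all 141 planted consensus G4s
plus 12 background motifs that arose by chance in the 0.8 Mb genome.
The donor-site metaprofile peaks at 24× its median-normalised
background, reflecting the planted offset distribution (mean +50 nt
into the intron). The permutation p of 1/201 says no dinucleotide-
preserving shuffle of the splice windows produced as many G4s as the
real windows (at this small scale the shuffled median is 0, so the
corrected fold itself is undefined and reported as null). The planted
odds ratio linking G4 presence to differential exon inclusion (2.0) is
recovered as 2.31 with a Bonferroni-adjusted chi-squared p ≈ 0.001.

Every stage is also available as its own subcommand (`scan`, `sites`,
`strength`, `profile`, `permtest`, `assoc`, `sqtl`, `rbp`, `synth`) on
standard formats: FASTA, BED3/6/12, bedGraph, GTF, and plain TSV
tables. For example:

```sh
g4splice synth --seed 3 --out bundle/
g4splice scan  --fasta bundle/genome.fa --kind g4 --out hits.bed
g4splice sites --annotation bundle/annotation.bed12 --fasta bundle/genome.fa --out sites.bed
g4splice assoc --psi bundle/psi.tsv --g4 hits.bed --peaks bundle/peaks.bed --out assoc.tsv
```

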