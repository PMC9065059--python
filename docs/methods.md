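# Methods

This note documents the models and procedures implemented in
`g4splice`, the parameters that matter with their defaults, the
synthetic-data generating process the test suite relies on, and the
numerical choices made where the design was genuinely open.

## Motif model and scanning

A consensus G4 motif is four or more runs of ≥3 guanines separated by
loops of 1–7 nt; a G-run block is any chain of 1–6 such runs with the
same loop constraint. Scanning is implemented by *run chaining*: maximal
G-runs are found first, two adjacent runs join a chain when the gap
between them is 1–7 nt, and a chain of k runs is one motif (k ≥ 4 for
G4s) spanning from its first to its last run. This is equivalent to
leftmost-longest regular-expression matching of the consensus pattern
under the convention that runs absorb adjacent Gs greedily — a loop may
contain G in its interior but can never start or end with one, since
such a G would extend the neighbouring run. Consequences of this
convention worth spelling out:

- Matches on one strand are maximal, non-overlapping and found left to
  right; a chain of 5+ runs is a single hit, with the reported run
  count capped at 6 (`n_g_runs`). An `overlap_mode="all"` flag instead
  reports every minimal 4-run window for sensitivity analysis.
- An 8-G run is one run, never "run + G-loop + run"; a sequence of
  three runs, one of them long, is *not* a consensus G4.
- Minus-strand motifs are found by matching the complementary C-pattern
  on the plus sequence, so coordinates never need mirroring; the two
  strands' motifs are independent records and may overlap.
- `N` never counts as G (conservative calling on masked assemblies) but
  is legal loop content. Soft-masked (lowercase) sequence is scanned
  like any other; it is upper-cased on input.

The test suite checks the scanner against an independent brute-force
oracle (leftmost-longest full-regex matching over substrings) on 10⁴
random 60-mers plus 300 200-mers across three base compositions, and
asserts strand symmetry under reverse complement.

## Splice-site anchors

Internal exons of transcripts with ≥3 exons contribute one acceptor
(3′ss) and one donor (5′ss) each. With a genome attached, sites whose
intronic-side intron is not GT..AG on the gene strand are excluded by
default. Junctions shared by several transcripts are collapsed to one
site keyed by (chrom, junction, kind, strand); per-transcript
duplicates can be kept with a flag. "Longest transcript" for the
exon-position-group analysis means largest summed exon length, ties
broken by transcript id; only genes whose longest transcript has ≥9
exons are labelled (first1..first4, middle, last4..last1), and terminal
junctions are included only there. A motif is on the **non-template**
(coding, mRNA-like) strand when its strand equals the gene's
transcription strand — those motifs appear in the pre-mRNA as RNA G4s.
Microexons are exons < 30 nt. Splice-site windows are clipped at
chromosome ends only; they may run into neighbouring features (no
trimming at half-intron boundaries).

## Positional metaprofiles

For a set of oriented anchors, the count at signed offset t (negative =
transcription-upstream) is the number of anchors at which a feature
registers at that offset. Registration is **coverage** by default (any
feature base pair overlaps the position); `start` and `midpoint` modes
exist because published motif profiles do not always state their
convention. Enrichment is count over the **median count across a fixed
1 kb window** regardless of the displayed width, so flat background is
1 by construction; a zero median leaves enrichment undefined (NaN, with
a warning). Per-offset 95% CIs are Wilson score intervals on count/n
scaled by the same normalisation constant. Densities are occurrences
per bp over flank windows, with a seeded bootstrap (resampling sites
with replacement, 1000 draws by default) for the SD.

Nearest distances are junction-to-feature-midpoint, signed in
transcription orientation, ties broken toward the intronic side.
Three-way overlaps are reported per set (an element of A is counted in
the region named by which of B, C it intersects), because interval
overlap is not an equivalence relation.

## Permutation null

Splice-window motif counts are compared against windows shuffled while
preserving the exact dinucleotide multiset, using the
Altschul–Erickson Eulerian-path construction: the transition multigraph
of the window gets a uniformly random last-edge arborescence (rejection
sampling) and uniformly permuted remaining edges; the first character
is fixed and the last follows from the edge balance. Windows are
shuffled independently so no motif can span a boundary. The corrected
fold is observed / median of N whole-set permutations (N = 1000 at full
scale); the one-sided empirical p uses the add-one estimator
(1 + #{perm ≥ obs}) / (N + 1), with the plain exceedance fraction also
reported. Child seeds derive from the master seed by counter, so
results are reproducible regardless of execution order.

Calibration note: the permutation p is exactly valid for windows drawn
from any i.i.d. or first-order Markov background (conditional on the
dinucleotide counts and first character, such windows are uniform over
the class the shuffle samples). Windows cut at real (or synthetic)
splice sites are *not* null draws — their fixed consensus signals
(polypyrimidine tract, junction dinucleotides) are genuine non-random
structure that the null correctly detects at a rate above α. The
calibration tests therefore use background-drawn windows; detection of
planted structure is tested separately.

## Splice-site strength

Strength is a log₂-odds score against a positional frequency matrix:
`Σᵢ log2((f(bᵢ,i)+ε)/0.25)` with uniform background and pseudocount
ε = 10⁻³. Window geometry follows the classic convention — donor 9-mer
(3 exonic + 6 intronic), acceptor 23-mer (20 intronic + 3 exonic) — but
width and junction offset are read from the matrix file itself
(`#junction_offset=K` metadata line). Windows containing N score NaN
and the site is dropped with a logged warning. Quantile stratification
(quartiles by default, deciles for heatmaps) is rank-based: ties share
the lower bin, distinct scores give bin sizes differing by at most one,
and any affine transformation of the scores leaves the bins unchanged.
The matrices shipped for testing are synthetic, generated from a
documented consensus (donor CAG|GTAAGT, acceptor T₁₇CAG|GTC) — they are
fixtures, not measured matrices.

## Association statistics

A splicing node is differential when |ΔPSI| ≥ 0.1 **and**
probability ≥ 0.9 — both inclusive; the thresholds are recorded on the
node. A node is G4-associated when the nearer of its two boundaries is
within 100 bp of a motif midpoint or 45 bp of a G4-seq peak midpoint;
orientation-restricted variants (non-template-only, template-only) are
selectable. Association is a 2×2 per (node type × direction) stratum,
controls being the non-differential nodes of the same type: odds ratio
(a·d)/(b·c) with the Haldane 0.5 correction applied to all cells iff
any cell is zero (flagged), Yates-corrected chi-squared, and Bonferroni
adjustment over the m strata tested in one run (m reported). The
log-OR confidence interval uses Gart's adjusted logit — 0.5 added to
every cell for both centre and SE — because the plain Woolf interval
is slightly anticonservative at moderate cell counts; the point
estimate stays unadjusted.

GC-matched intron controls: introns are split at 500 nt, each short
intron greedily takes the available long intron with nearest GC
(whole-intron GC; seeded random processing order; no replacement), and
pairs with |ΔGC| > 0.01 are discarded; fewer than 10 pairs is an error.

sQTL adjusted enrichment: 25 bp bins over ±500 bp around junctions in
transcription orientation. Per bin and variant class, the in-G4
density is the class's variants falling on G4 base pairs in that bin
over the G4 base pairs there; the enrichment e is that density
relative to the class's mean per-bp density over the whole track (all
of the class's variants in the ±500 windows, inside G4s or not); the
adjusted enrichment is e_sQTL / e_SNP. This normalisation reproduces a
planted in-G4 uplift at face value (uplift u reads out as ≈u in the
uplifted bins, ≈1 elsewhere), is scale-invariant under multiplying
both variant sets, and reports NaN where a bin has no G4 bp or zero
SNP enrichment. Normalising instead by the mean *in-G4* density would
absorb the uplift into the normaliser whenever most G4 bp lie in the
uplifted region, which is why it was rejected.

## eCLIP integration

Per factor replicate and orientation, the splice-site region (default
−100..+100, 10 bp bins) is summarised as the *bound-site fraction*: the
share of sites in the group whose bin overlaps ≥1 peak bp. (Peaks are
presence/absence calls; a read-density-weighted statistic is not
printed anywhere upstream, so the fraction keeps estimate and test
coherent.) The differential profile is fraction(G4-flanked) −
fraction(non-flanked), with a per-bin 2×2 chi-squared
(bound/unbound × group, Yates) Bonferroni-corrected over the profile's
bins; groups under 20 sites flag the profile low-power. Before Ward
clustering (Euclidean, concatenated non-template ‖ template tracks,
cut at k = 10), non-significant differentials are set to exactly 0;
missing orientations are imputed as zeros; rows are sorted by profile
id so the clustering is order-invariant. A factor is high-confidence
when it has a significant eCLIP profile and a significant LoF
association (adjusted p < 0.05) in the same cell line, and at least two
of its eCLIP replicates share a cluster; the direction of the LoF
log-OR is reported.

## Synthetic data: what it emulates, and what it does not

The generators produce every input class with planted truth from one
master seed (per-stage child seeds via `SeedSequence.spawn`). Defaults
are the desk-scale bundle: 5 chromosomes × 1 Mb, 300 genes of 4–8
exons (exon lengths log-normal, median ≈140 nt; intron lengths
log-normal, median ≈1 kb — the heavy tail the length analyses rely
on), ≈1500–2500 internal junctions. Donor/acceptor windows are drawn
from the synthetic consensus PFMs (a configurable fraction of sites
gets uniform background instead, giving a controllable strength
distribution), then GT/AG is forced. G4s are planted by *overwriting*
background (never inserting, so coordinates stay stable) on the
intronic side at a drawn offset (normal, default mean 50 nt, SD 15,
minimum 12), non-template with probability r/(1+r) for the configured
2:1 ratio, runs of 3–5 G with loops of 1–7 non-G bases. An 8 nt A/T
buffer is written around each planted motif and placement keeps 3 nt
clear of both intron ends — this guarantees the scanner recovers
exactly the planted span (no chaining with background runs) and never
touches junction dinucleotides. Planting probability can be coupled to
intron length (separate rate above a 500 nt threshold) for the
short-intron analyses. PSI tables assign differential exclusion by a
Bernoulli model whose odds multiply by the planted OR (default 2) when
the node is G4-flanked, with 89% of differential nodes excluded;
magnitudes and probabilities are drawn on the correct side of the
0.1/0.9 thresholds. Variant tracks share one background rate
(2×10⁻³/bp in the ±500 windows) with an sQTL-only uplift (default 2×)
restricted to G4 base pairs within ±100 bp. Peaks cover planted motifs
with probability 0.8 and jittered edges; eCLIP binding is per-site,
per-bin Bernoulli by group.

What passing tests on this material do **not** show about real data:
the background is (by default) a uniform or low-order Markov sequence
without repeats, isochores or CpG islands; gene models have no
alternative isoforms, overlapping genes or U12 introns; planted
couplings are the *only* dependence between tracks; and effect sizes
are set, not estimated. Recovery of a planted parameter demonstrates
correctness of the estimator under its assumptions, not robustness to
real-genome confounding (the dinucleotide shuffle and the GC-matched
controls are the in-pipeline tools for that).

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen as the package's
own defaults: scanner-oracle equivalence on 10⁴ 60-mers + 300
200-mers; shuffle exactness on 500 sequences up to 400 nt; null
calibration on 100 repetitions of 300 background 100-nt windows with
N = 178 permutations (N chosen so the add-one threshold sits just
below an integer, keeping the discrete estimator on the conservative
side of its nominal 5%); planted-effect bundles of 0.8–6 Mb; OR
recovery at 100 repetitions × 2000 nodes for each planted OR in
{1, 2, 4}; sQTL tracks over 300 sites; eCLIP calibration over 200
profiles of 60+60 sites and recovery at 500+500. Degenerate inputs are
defined rather than accidental: empty sequences scan to empty lists,
sequences shorter than 2 return unchanged from the shuffle, all-equal
strength scores collapse to bin 1 with a warning, zero-median profiles
and zero-SNP bins report NaN with a log line, and empty contingency
margins are flagged untestable instead of raising.

## Known limitations

Only canonical consensus G4s are modelled — no bulged, long-loop or
intermolecular variants, and no thermodynamic scoring; the other non-B
DNA classes are consumed as external BED maps, not detected. The PFM
scorer is position-independent (no dependency-aware maximum-entropy
model). BAM/CRAM input, indexed FASTA and remote fetching are out of
scope; genomes are held in memory, which is comfortable to ~100 Mb but
not for mammalian assemblies without chunking. Chromosome-name
mismatches between FASTA and annotation are an error by design, with
an explicit "chr"-prefix normaliser rather than silent reconciliation.
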