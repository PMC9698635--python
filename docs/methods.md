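# Methods

## The problem

Plant microRNAs (miRNAs) are 20–24-nt regulators processed from stem-loop
(hairpin) precursors. A miRNA *family* — the unit of conservation analysis —
is a set of loci whose mature sequences differ by at most a small number of
mismatches (2 here). A family detected in exactly one species is
*species-specific* (SS); everything else is non-species-specific (NSS).
`specmir` implements a sequence-evidence–based caller of SS-miRNAs, the
classical genomic-homology baseline it improves on, and the downstream
characterization of SS vs NSS loci: intrinsic sequence features, genomic
context relative to protein-coding genes, and predicted target spectra with
GO enrichment.

## The seq-based caller

A family is labeled SS if and only if

1. its members occur in a single species (conservation-matrix column count
   = 1), **and** no mature miRNA of any other species lies within 2 edits
   of any member mature — this is checked by an explicit all-pairs scan
   rather than trusted to the clustering, because greedy founder linkage
   can place two ≤2-edit matures in different families;
2. every member hairpin folds into a stable structure: normalized minimum
   free energy NMFE = MFE/length ≤ −0.20 kcal/mol per nt and ≥60% of
   mature positions paired in the MFE structure (ViennaRNA, 37 °C);
3. every member shows the canonical sRNA-seq read distribution: strictly
   more than 75% of reads in the mature + star regions and at most 20%
   boundary-straddling reads.

Checks 2 and 3 are on by default and can be disabled for inputs that were
already quality-controlled upstream. "Mismatch" is unit-cost edit distance
(not Hamming): matures vary in length and 1-nt isomiR-style shifts should
count as small differences. The 75% bound is strict and the 20% bound
non-strict, matching the rule's wording; the boundary behaviour is pinned
by an exhaustive enumeration test over all profiles with ≤40 reads.

### Family clustering

Loci are ranked by total read abundance (ties: mature sequence, then locus
id) and processed greedily: a locus joins the first family whose *founder*
mature is within 2 edits, else founds a new family. Founder linkage keeps
the stated family property (all members near the founder) testable; single
linkage would allow chaining beyond 2 mismatches. Family ids are assigned
`F000001…` in founding order so outputs diff cleanly.

### Homology baseline

Each hairpin is aligned (as DNA, both strands) against every other
species' genome with a Smith-Waterman aligner at blastn-like scoring
(match +2, mismatch −3, gap open −5, extend −2; biotite's C
implementation). Significance uses Karlin–Altschul e-values
(λ = 0.625, K = 0.41 for these scores) sized by total genome length. Hits
with e ≥ 1e-10 are discarded, regions covering <70% of the hairpin are
filtered, and overlapping hits (hairpins are near-palindromes, so both
strands usually align to one region) are merged keeping the best strand.
A locus is SS under this baseline iff no region survives in any other
genome. One best local hit per genome record per strand stands in for
per-region hit unions; at the one-homolog-per-genome scale of the bundled
fixtures the two coincide.

## Intrinsic features and importance

Per locus: NMFE, AU content of mature and hairpin, 5′ first base, mature
and hairpin lengths. Group contrasts use Welch's unequal-variance t-test
(two-tailed); SS and NSS groups differ greatly in size, so a
pooled-variance test is inappropriate. Feature importance comes from an
XGBoost classifier with learning rate 1, depth 2, 50 rounds and a binary
logistic objective, gain-based importances, first base one-hot encoded
(9 design columns total; the feature list is configurable). A 25%
stratified holdout reports accuracy; everything is deterministic under the
run seed.

## Genomic context

Overlap between hairpin and gene intervals is strand-agnostic (≥1 shared
bp on 1-based inclusive coordinates); ties go to the largest overlap,
then smallest gene id. Distances are measured from the hairpin *midpoint*
to the nearest gene's TSS and TTS in the gene's orientation (negative =
upstream of the TSS; 0,0 inside the gene); the midpoint anchor is
symmetric and robust to hairpin-length differences, and is configurable.
The SS-vs-NSS intragenic contrast is tested across per-species
proportions (box-plot semantics), not pooled loci. Host concordance:
per-pair argmax-tissue match plus a Pearson correlation over all
(miRNA, host) values after per-row max normalization.

## Target prediction and enrichment

A duplex expectation penalty is summed over aligned positions: 0 for a
Watson–Crick pair, 0.5 for G:U, 1.0 per mismatch, 2.0 per gap, all
doubled at miRNA positions 2–13 (core). A gap column takes the core
weight of the miRNA position it interrupts. Transcripts are scanned
antiparallel with at most one gap per duplex; the scanner evaluates all
ungapped windows plus every interior single-gap placement via vectorized
prefix/suffix penalty sums, and is verified exactly against a brute-force
window/gap enumeration. Only the best site per (miRNA, transcript) is
kept; sites with expectation ≤ 3 count as targets, so target counts are
gene counts, not site counts. These scoring constants follow the common
plant target-prediction scheme and are configuration-exposed; exact
numerical agreement with any web service is not promised.

GO enrichment: one-sided Fisher exact test per term with at least one
foreground gene, Benjamini–Hochberg correction, enriched at adjusted
p < 0.05. The background is all GO-annotated genes under study.

## The synthetic-data generator

The generator plants every truth the pipeline should recover, under the
default study conditions: 5 species, 30 conserved families, 10 SS loci
per species, noise-free read profiles (`frac_valid_profiles = 1`), AU
shift +0.10 for SS loci, intragenic rates 0.5 (SS) vs 0.2 (NSS), mean
planted targets 1.6 (SS) vs 2.3 (NSS) — chosen so the zero-target
fractions fall near 20% vs 10% under the Poisson draw.

Design choices that make recovery tests sharp rather than probabilistic:

* Conserved-family founders are rejection-sampled ≥5 edits apart
  (`cross_family_min_mismatch`, above 2·2 so greedy clustering is
  order-independent); members carry ≤2 substitutions of the founder, and
  the founder always receives the highest read count of its family, so
  abundance-ranked founder linkage recovers the planted partition
  exactly.
* SS matures are rejection-sampled ≥5 edits from *every* other mature, so
  the caller's cross-species post-check cannot flip a planted label.
* Hairpins are built as long continuous stems — 5′ extension + mature +
  loop + star + complementary 3′ extension, star = reverse complement of
  the mature with 1–3 interior bulge substitutions (the biological 2-nt
  duplex overhangs are absorbed into loop/extension boundaries). Stems of
  this length fold far below the −0.20 NMFE cutoff even at elevated AU.
* The SS AU shift is applied at the nucleotide-sampling level, not by
  post-hoc editing; since A:U stacks are thermodynamically weaker, the
  NMFE contrast (SS less stable) emerges from the same mechanism.
* Chromosome names are species-qualified (`sp01_chr1`) so pooled interval
  operations cannot collide across species.
* Planted target sites are perfect reverse complements or carry one
  non-core G:U (expectation ≤ 0.5), inserted without overlapping
  previously planted sites. Random-background hits at threshold 3 are
  astronomically unlikely for 20–24-nt queries, so planted = recovered.
* Determinism: every stage derives its generator from `(seed, stage)`;
  identical configs give byte-identical on-disk datasets.

What the generator does **not** emulate: read-level sRNA-seq data (only
per-region counts), transposon-derived origination, sequence composition
biases of real genomes, isomiR length heterogeneity within a locus, and
multi-chromosome genome architecture. Passing tests therefore demonstrate
correctness of the pipeline's logic and statistics under controlled
conditions, not that the thresholds are optimal for any particular real
dataset.

## Numerical choices and degenerate inputs

* Zero-variance equal-mean Welch input returns t = 0, p = 1 by
  convention.
* A locus with reads but no star sequence treats the star region as
  unknown: the profile validator still applies to the counts given, and a
  missing profile is not counted as evidence against SS.
* Scanner tie-breaks: equal-expectation candidates prefer ungapped over
  gapped alignments, then the leftmost site; clustering ties prefer
  higher abundance, then lexicographic mature, then locus id.
* `filter_species` applies "more than 100 miRNAs" strictly and exempts an
  explicit allowlist (e.g. chlorophyte outgroups); the list of required
  conserved families is a mandatory input with no default.
* Problem sizes in tests and the acceptance script (default simulation of
  ~150 loci across 5 species; 500 loci per class for feature studies;
  10–20 seeds for stochastic claims) were chosen as the smallest scales
  at which the planted effects are unambiguous.

## Known limitations

* The homology engine reports one merged best region per genome record
  rather than full BLAST-style HSP unions; sensitivity on genomes with
  many dispersed partial copies would differ from BLAST.
* Taxon summaries require a user-supplied species→clade mapping; no
  phylogeny is inferred.
* The expectation scorer is a faithful implementation of the published
  constants, not a re-implementation of any specific web service's
  engine.
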