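# Methods

`phageminer` identifies phage contigs in mixed metagenomic assemblies and
carries the predictions through host assignment, taxonomy, and community
statistics. This note records the models and procedures the package
implements, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions used
throughout.

## Ground-truth labeling from paired phageomes

When a sample has both a bulk metagenome and a phageome (a library
sequenced from purified phage particles), metagenomic contigs that align
well to the phageome assembly are phage-derived by construction. Alignments
are filtered at e-value < 1e-5 and identity > 98% (both strict), all HSPs
of one contig pair are merged by taking the union of query-side intervals
(so overlapping HSPs are not double-counted), and coverage is the merged
length divided by the shorter of the two contigs. A contig is labeled

- **phage** when any single pair reaches coverage > 0.80 or merged aligned
  length > 10 kb;
- **ambiguous** when any pair falls in the inclusive bands [0.40, 0.80]
  coverage or [4 kb, 10 kb] aligned length;
- **non-phage** otherwise.

Boundary semantics follow the band wording: coverage of exactly 0.80 is
ambiguous, not phage. Evidence is never summed across different phageome
contigs — each pair must qualify on its own. Labeling is checked against a
brute-force re-coding of the rules on random evidence sets, and label
assignment is monotone: raising coverage or aligned length never demotes a
contig.

## Predictors and the random-forest classifier

Ten predictors per contig: average read depth (mapped reads / contig
length, reads per bp), the number of predicted genes, the counts of genes
with hits to phage orthologous groups (uPOG), viral protein families, KO
terms, Pfam domains, and viral hallmark genes, and the gene fractions
annotated to viral protein families, KO, and Pfam. Annotation hits qualify
at e-value <= 1e-5 (inclusive — a conventional cutoff reading, deliberately
different from the strict ground-truth filters above, and applied
identically everywhere features are built). Each gene counts once per
database regardless of hit multiplicity. Fractions are stored in [0, 1]
rather than percent; tree models are scale-invariant, so the unit choice is
cosmetic, and fractions avoid a 0–100/0–1 mix in one matrix. Only contigs
strictly longer than 5 kb enter the model (1 kb/3 kb variants are supported
for sensitivity analyses and change only which contigs appear, never a
feature value). Contigs without predicted genes are retained with all
count/fraction features at zero, since depth is still informative.

The classifier is a random forest of 1500 trees with 7 candidate features
per split (the conventions of the R `randomForest` implementation the field
uses: trees fully grown, bootstrap sample equal to the training-set size),
fitted with scikit-learn and seeded end to end. Because confident non-phage
contigs dominate real assemblies, each training set is rebalanced: all
phage contigs (positives), all ambiguous contigs (negatives), and a uniform
seeded sample of up to 3000 confident non-phage contigs drawn from those at
or above the median non-phage relative abundance. When fewer are eligible,
all are taken and a warning is issued. Ambiguous contigs are trained as
negatives because they are also scored as negatives at evaluation time;
`ambiguous_as_negative=False` excludes them instead. The decision threshold
is 0.5 on the forest's phage probability and is exposed in the
configuration. Cross-validation is leave-one-subject-out — all samples of
one individual form the test fold, which prevents within-subject leakage —
with the negative subsample redrawn per fold.

A rule-based baseline implements the published homology-profile conditions
(>= 5 viral-protein-family hits with < 20% KO, <= 40% Pfam and > 10%
viral-family gene fractions; or viral-family hits >= Pfam hits; or >= 60%
viral-family genes) and is verified against an independent truth-table
evaluation.

## Evaluation

Two measurement schemes share one confusion-matrix machinery: under *count*
weighting each contig contributes a unit; under *abundance* weighting it
contributes its relative abundance (mapped reads / sample total), so the
metrics describe the fraction of the community's reads on correctly
classified contigs and emphasize abundant phages. Sensitivity, specificity,
precision, F1, accuracy, and the Matthews correlation coefficient are
reported; MCC under count weighting equals the Pearson correlation of the
binary label/prediction vectors, which is used as an oracle test.
Zero-denominator ratios are NaN with an explicit flag — never silently
zero — and aggregation across subjects reports mean, sample SD, and the
count of defined values per metric. A reporting filter restricted to
contigs with relative abundance strictly above 0.001 is available for
high-abundance views.

## Virus quotients and taxon-signature groups

For a phage orthologous group, matches are thresholded at e-value <= 0.001,
bit score > 40, and >= 40 aligned amino acids; the virus quotient is
VQ = |viral genomes matched| / (|viral| + |prokaryotic genomes matched|),
counting each genome once (hit multiplicity would double-count paralogs)
and excluding prokaryotic genomes with annotated prophage regions, whose
"prokaryotic" matches are themselves viral sequence. VQ > 0.85 (strict)
marks a virus-specific group; at exactly 17 viral and 3 prokaryotic genome
matches VQ is 0.85 and the group is *not* virus-specific. A taxon-signature
group additionally requires precision exactly 1.0 (set membership, no
float tolerance), recall > 0.85 (strict, per the wording adopted here),
and a single copy in every containing genome.

## CRISPR arrays and host prediction

The array detector is a self-contained seed-and-extend recognizer in the
style of the classic CRISPR recognition tools: exact 19-mer seeds recurring
with gaps of 38–86 bp are chained, each chain is extended outward into the
full repeat while all copies agree with the per-column majority (each copy
allowed at most one mismatch), and edge columns that are not unanimous
across copies are trimmed back, since tolerant extension can otherwise
creep a base or two into the spacers. Arrays need >= 3 repeats of 19–38 bp
and spacers of 19–48 bp; candidates whose spacers are mutually > 90%
identical are rejected as plain tandem repeats. Detection is
case-insensitive, and a reverse-complemented contig yields the
reverse-complemented spacers.

Spacer matching is ungapped, full-length, on both strands, with a mismatch
budget of floor(0.05 × length) — i.e. >= 95% identity; a 32-bp spacer
tolerates one mismatch and is rejected at two. The budget replaces an
e-value threshold because e-values depend on database size; the mismatch
fraction is recorded as `evalue_proxy`. Only the best match per spacer is
kept (highest identity, then longest, then lexicographically smallest
contig id — a deterministic stand-in for a best-hit search), and an
`exact` flag restricts to perfect matches. Matches aggregate into
phage–host edges at contig, species, or genus level, with missing taxonomy
labeled `unclassified` and support equal to the number of spacer matches.

## 8-mer naive-Bayes taxonomy

The taxonomy classifier follows the word-presence naive-Bayes formulation
of the rRNA-classification literature, applied to phage contigs with 8-base
words: prior P(w) = (n(w) + 0.5) / (N + 1) over training genomes,
per-taxon conditional P(w|t) = (m(w) + P(w)) / (M + 1), assignment by
maximum summed log conditional over the contig's *distinct* words
(duplicated words change nothing). Confidence is the fraction of 100
bootstrap trials — each rescoring ceil(W/8) words sampled without
replacement — that agree with the full-word assignment at the rank in
question; genus confidence is therefore at least species confidence.
Assignments at confidence <= 0.5 are discarded. Because phage genome
strand is arbitrary, words are merged with their reverse complements
(canonical form) by default; `canonical=False` disables the merge.

## Community statistics

Abundance is expressed as TPM: counts are converted to per-kilobase rates
and scaled so each sample sums to 10^6. Functional-category (KO/Pfam)
abundance sums gene-level TPM per category. Two-group comparisons use the
two-sided Wilcoxon rank-sum test per feature — the exact null distribution
when both groups are small and tie-free, otherwise the tie-corrected normal
approximation with midranks — with the conventional raw p < 0.05 flag and
Benjamini–Hochberg FDR reported side by side (raw p mirrors common
practice in this literature; the FDR column is what a modern reader
expects). Diversity over phage taxa reports richness, Shannon
H = −Σ p log p, Simpson in Gini form 1 − Σ p² (inverse Simpson via flag),
and Pielou J = H / ln S, NaN-flagged at S <= 1. Diversity uses
abundance-weighted inputs (taxon-summed contig abundances); richness counts
taxa with positive abundance.

## The synthetic study generator

The generator emulates the structure of a paired-cohort study so that every
module is testable without external downloads: by default 10 subjects × 6
timepoints × 100 contigs per sample, ~2% phage plus ~1% prophage-carrying
bacterial contigs, lognormal contig lengths (median ≈ 12 kb, clipped to
5.2–120 kb so every contig clears the 5-kb model cutoff), lognormal
read-count abundances (σ = 1.5, 10^6 reads per sample; an `equal_reads`
mode makes the two evaluation schemes coincide), and class-conditional
per-gene annotation rates (e.g. on the `easy` preset, viral-family hits at
0.50 per gene on phage contigs vs 0.01 on bacterial). Each phage contig is
echoed into the phageome with configurable recovery and alignment coverage
drawn above the phage threshold; prophage contigs get partial (40–80%)
coverage and hence ambiguous labels. Difficulty presets (`easy`, `medium`,
`hard`) shrink the annotation-rate gap and the phageome recovery.

Sequence-level generators support the CRISPR and taxonomy modules:
`plant_crispr` inserts a repeat-spacer array whose spacers are substrings
of a phage contig (redrawing protospacers whose boundary bases are
unanimous, so the planted repeat/spacer boundary is recoverable exactly),
and `generate_genus_genomes` samples genomes from per-genus random Markov
transition matrices (order 3 by default), with held-out genomes from the
same matrices for recovery tests and a shared-composition mode as a
no-signal negative control.

The generator does **not** simulate reads, sequencing error, assembly
artifacts, shared phage content between subjects, or realistic phage gene
architecture; passing tests demonstrate the correctness and internal
consistency of the pipeline under its stated assumptions, not its accuracy
on real gut metagenomes.

## Problem sizes and numerical conventions

Test and acceptance runs use the default generator sizes above (6,000
contigs, ~88,000 genes) for the classification closure, 50 planted arrays
for the CRISPR closure, 8 training genomes of 40 kb plus 30 held-out 10-kb
fragments for taxonomy, and 1,000-feature null simulations for the rank-sum
calibration — sizes chosen so the full pipeline exercises every code path
at desk scale. With ~2,600 eligible non-phage contigs per fold, the
3000-contig negative sample clamps to all eligible contigs, which is the
intended behavior of the sampler at this study size. Coordinates are
1-based inclusive everywhere; tabular alignment inputs are the 12-column
BLAST `outfmt 6` dialect; `#`-comment lines are skipped in all readers.
All randomness flows through `numpy.random.default_rng` seeds; refitting
with the same seed and data reproduces predictions bit-for-bit.

## Known limitations

- Read mapping, assembly, gene calling, and homology searching are out of
  scope; the package consumes their tabular outputs and trusts the stated
  upstream filters (e.g. the 99%-identity read filter behind mapping
  counts).
- The array detector requires an exact 19-mer seed shared by all repeat
  copies; heavily degenerate repeats (more than ~1 mismatch per copy) can
  be missed. Spacer matching is ungapped, so protospacers with indels are
  not recovered.
- The taxonomy model is presence/absence over 8-mers; very short contigs
  (a few hundred bp) carry few distinct words and yield low confidence.
- Whether the cohort methodology summed HSPs or used the single best HSP
  for coverage, and the training-time class of ambiguous contigs, are not
  determinable from the available description; the choices here (interval
  union; ambiguous as negative) are documented above and configurable
  where meaningful.
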