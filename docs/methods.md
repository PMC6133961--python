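# Methods

`amplihap` implements a reference-free hybrid workflow for multi-kilobase
amplicons of highly polymorphic loci: noisy single-molecule long reads
provide a scaffold spanning regions short reads cannot assemble, accurate
short reads correct the scaffold's base calls and genotype individuals
against it, and statistical post-processing phases haplotypes and scans
them for recombination. This note records the models, conventions and
numerical choices behind each stage, and what the synthetic-data tests do
and do not demonstrate.

## Synthetic data model

**Template.** `simulate.make_amplicon_template` builds a ~9 kb diploid
locus: a random backbone at a target GC fraction (default 0.41), a set of
planted homopolymer tracts (default six tracts of 8–13 identical bases,
including one 13-mer, mirroring the poly-T/poly-A tracts that break
short-read assembly of such loci), one compound dinucleotide STR whose two
alleles are (GT)3T(GT)4 and (GT)9 (1-based position 369 by default), and a
truth set of 102 SNPs and 7 indels (1–3 bp) placed at least 100 bp from
the amplicon ends and away from the low-complexity tracts, with ≥12 bp
spacing so that left-normalized representations are unambiguous.
Haplotype B is haplotype A with every alternative allele applied; the
invariant `apply_variants(hap_a, truth) == hap_b` is asserted in tests.
`make_haplotype_pool` derives additional population haplotypes as random
0/1 allele vectors over the same sites, and `sample_individuals` draws
diploid individuals under Hardy–Weinberg proportions.

**Long reads.** Per-base i.i.d. errors: substitution (default 4.8%,
uniform over the three alternatives), deletion (3.0%), and insertion of a
uniform random base after a position (4.1%); the three defaults are the
component error rates of early-chemistry 2D nanopore reads. An optional
multiplier (used at 2× in the noisy-consensus scenario) inflates the
insertion/deletion rates inside annotated homopolymer/STR tracts, the
dominant real nanopore error context that the i.i.d. model misses. Read
lengths are log-normal parameterized by mean 4,186 bp and SD 2,550 bp
(equivalently median ≈ 3,575 bp), rejected below 200 bp and clamped above
at min(12,000, molecule length): a read cannot outrun its molecule, so the
over-length mass piles up at full amplicon length, which is exactly the
spike of whole-amplicon reads that seed selection relies on. Amplicon
reads start at a molecule end (either end, either strand, adapter-ligation
geometry) and truncate at the drawn length, giving near-uniform coverage;
the spike-in control instead uses uniformly placed fragments, appropriate
for sheared genomic DNA. Every read id records its source haplotype,
coordinates and realized error counts after a reserved `|truth|` token;
only tests read it.

**Short reads.** 2×250 bp pairs from ~300±60 bp fragments drawn equally
from the two haplotypes, substitution-only errors at 0.1%, constant Phred
qualities consistent with the error rate. **Chimeras.** Positional
artefacts concatenate a prefix and suffix drawn independently (possibly
from different templates) at a fractional breakpoint recorded in the id.

Not emulated: basecaller quality strings, k-mer-context error models,
PCR duplicates, the multi-peak off-target amplification of real long-range
PCR, and barcode demultiplexing. Tests passing on this generator therefore
demonstrate algorithmic correctness under a faithful error-rate and
length-structure model, not robustness to every artefact of real runs.

## Alignment engine

`align.semiglobal_align` is a banded affine-gap semi-global DP (free end
gaps on the reference; the query is consumed in full), JIT-compiled with
numba. The band covers `|j − i − offset| ≤ band_width`; a geometric
failure to connect raises a band-overflow error. Traceback ties prefer
diagonal, then insertion, then deletion. `map_read` locates a read on a
long reference by a 13-mer diagonal vote (bins of 64 bp; k-mers with more
than 8 reference hits are skipped), aligns the better-supported strand
first, and skips the opposite strand when its vote is 4-fold weaker.
Accepted alignments require mismatch fraction ≤ 0.40, total gap fraction
≤ 0.20 and no single indel > 50 bp, all computed over aligned read bases.

Default scores are match +2, mismatch −4, gap open −4, gap extend −2, so
one mismatch (−4) is cheaper than a 1 bp gap (−6), which is cheaper than
two mismatches (−8): substitutions stay mismatches and the indel-dominated
long-read errors stay gaps instead of being smeared into mismatch pairs.
After traceback every gap is shifted to its leftmost score-equivalent
placement against the reference, so reads sequenced from either strand
stack their indel evidence on the same pileup column — without this,
repeat-internal indel support splits across columns and plurality calling
degrades.

## Consensus from long reads

Reads outside [1,000, 10,000] bp are excluded; positional chimeras are
screened by chunk-mapping each read in 250 bp pieces and merging chunks of
consistent strand/diagonal (±150 bp) into segments — a read is flagged
when no single segment covers 80% of it while two disjoint segments of
≥500 bp each align at ≥0.75 identity, and the breakpoint estimate is the
boundary between the two largest segments. Unmapped chunks never split a
segment (they are usually local noise, not junctions).

Seed reads are sampled uniformly among reads within ±10% of the expected
amplicon length; the first template is the seed minimizing the summed
pairwise edit distance to the other seeds (medoid, strand-aware via
edlib), with ties going to the longer read because a truncated template
cannot be extended by pileup iterations. Five iterations of star-pileup
consensus follow: map the seeds (round 1) or all kept reads (later
rounds), build a pileup including insertion evidence keyed to the
preceding column, and call per column — a deletion only when deletions
exceed 50% of spanning reads, an insertion only when inserting reads
exceed 50% (emitting the plurality inserted sequence), otherwise the
plurality base with alphabetical tie-break; uncovered columns keep the
template base. Iteration stops early at a fixed point. The strict >50%
indel thresholds deliberately leave marginal-support indel errors (the
draft is biased toward small deletions) because the short-read polish
stage corrects them with far stronger evidence; the 60-read scenario
yields a ≥99.5%-identity draft whose residual errors vanish after
polishing, so discrepancies between polished assemblies are confined to
low-complexity tracts, matching how such assemblies differ in practice.

## Diploid-aware polishing

Short reads are re-mapped to the current sequence each round (up to 3
rounds, full re-mapping avoids coordinate bookkeeping). At columns with
depth ≥ 20: a plurality allele (base or deletion) at ≥80% that disagrees
with the draft is corrected; insertions are restored only when
insertion-bearing reads reach 80% of depth *and* a single inserted
sequence dominates them (avoiding chimeric insertion alleles); columns
whose top two allele fractions both fall in [0.25, 0.75] are left
untouched and reported as heterozygous candidates — the "diploid mode"
that keeps true variation out of the correction list. The report
accounts for every change (1-based positions) and the per-category totals.

## Error profiling

Control-read alignments are walked in read coordinates; minus-strand
reads are walked 3′→5′ so position 1 is always the sequencing start. A
mismatch column counts one substitution at its read position; an
insertion counts its length at the positions of the inserted bases; a
deletion is attributed, with its length, to the read position preceding
the gap (a deletion has no coordinate of its own — one convention must be
fixed). Rates divide events by reference-consuming aligned columns
attributed to each 100 bp read-position bin; the overall averages are
therefore total events over total aligned columns, which recovers the
generating per-template-base rates up to the alignment effect.

That alignment effect is irreducible and worth stating: an insertion of a
random base immediately adjacent to a deletion is *indistinguishable*
from a substitution, and substitutions inside repeats can be absorbed
into gap reconfigurations. At the default rates this biases the
substitution average about −9% relative (4.37% observed vs 4.8%
generated) with insertions and deletions within ~1.5% relative. The three
built-in mapper presets (`MAPPER_PRESETS`) expose how the split between
components moves with gap penalties; `compare_mappers` tabulates them and
combines by median. The default profiling preset (match 2, mismatch −4,
gap open −2, gap extend −1) was chosen so a lone substitution stays a
mismatch while a true ins+del pair stays gaps, the configuration with the
least component leakage.

## Genotyping

Low-complexity masking covers every homopolymer run ≥6 bp and every
tandem repeat of a ≤6 bp motif with ≥4 units, extended over partial
leading/trailing units. Variant calling is a plain high-coverage pileup
genotyper: per sample and column, alleles (bases, deletion, insertion
sequences) observed at ≥10% of depth; genotype homozygous at ≥80%,
heterozygous when the top two fractions both lie in [0.25, 0.75],
otherwise undefined with a balance-skew flag; undefined with a low-depth
flag below 20×; more than two observed alleles flags the site
tri-allelic. Insertion alleles coexist with their anchor base call, so an
insertion is homozygous/heterozygous by the insertion-bearing fraction of
depth. Sites are emitted only where some sample shows non-reference
evidence; masked columns are reported with all genotypes undefined.
Consecutive deletion columns with concordant genotypes merge into one
multi-base deletion record; indel records are anchored and
left-normalized, so calls compare to truth by (position, ref, alt).

The STR is typed directly from reads: a read spanning both 20 bp flanks
(exact or one mismatch, either orientation) contributes its verbatim
enclosed tract; tracts cluster by sequence and the top one or two
(each ≥20% of spanning reads) are reported, with a no-call below 5
spanning reads. When a flank overlaps the repeat itself the extracted
tract is a deterministic truncation of the full allele — allele identity
and balance are preserved even though the printed tract may be shorter
than the biological repeat.

The duplication screen reports tri-allelic site counts, per-sample
heterozygous-site fractions, and het sites whose allele balance both
rejects 50:50 (two-sided binomial, Bonferroni over het tests at α=0.05)
and shows a major-allele fraction in [0.70, 0.80] — i.e. consistent with
the 25:75 signature of two co-amplified copies; requiring the effect size
keeps the family-wise false-verdict rate well below the ~5% a pure
rejection rule would give by construction.

## Haplotype phasing

Classical haplotype-frequency EM over biallelic sites (indels coded like
SNPs): the E-step distributes each individual over compatible ordered
pairs proportional to frequency products, the M-step re-estimates
frequencies; the log-likelihood is asserted non-decreasing every
iteration; three restarts (one uniform, two Dirichlet-perturbed) guard
against local optima; missing genotypes are marginalized by enumerating
both alleles. Sites are partitioned into consecutive blocks with at most
12 ambiguous (het or missing) genotypes per individual; blocks are phased
independently and ligated left-to-right, carrying the top-4 candidate
pairs per individual and resolving the two possible joins per candidate
with a restricted EM over concatenated haplotypes. A final refinement
re-explains every individual with all compatible pairs drawn from the
pooled haplotype set — this pulls solutions toward few shared haplotypes,
the role a coalescent prior plays in MCMC phasers, and removes the
chimeric haplotypes plain ligation produces at small sample sizes.
Reported pairs are unordered; a single heterozygous site therefore has
pair posterior 1.0 (the two orderings are the same unordered pair, each
ordered phase having probability 0.5). `count_haplotypes` counts distinct
haplotypes among pairs at posterior ≥0.9. There is no analogue of MCMC
iteration/burn-in counts; `max_iter` and `tol` (1e-8) govern convergence.

## Recombination scans

MaxChi scans every boundary between consecutive informative sites with
≥`window_w` (default 35) sites per side: the 2×2 table of
match/mismatch counts in the two windows gives a chi-square without
continuity correction (zero-margin tables score 0). Chimaera first
restricts to sites where the two parents differ, encodes the child by
which parent it matches (sites matching neither are dropped), and applies
the same scan. Significance comes from permuting informative-site order
(default 1,000 permutations; p = fraction of permuted maxima ≥ observed);
the breakpoint is reported 1-based as the midpoint between the flanking
informative sites at the argmax. `breakpoint_ci` bootstraps sites with
replacement (order preserved) and returns the central-quantile interval,
widened if necessary to contain the point estimate; no CI is reported for
scans with p > 0.05. `scan_all` runs all pairs (MaxChi, using the
polymorphic columns of the whole haplotype set) and all triplets
(Chimaera), Bonferroni-adjusts across scans, and summarizes breakpoint
concordance. Only a single breakpoint per scan is estimated; the end of a
recombinant region is not separately localized.

## Pipeline and problem sizes

`amplihap run-all` executes trim → length filter → chimera screen → seed
selection → consensus → polish (using the homozygous reference
individual's reads) → optional control profiling → per-sample mapping and
variant calling → STR typing → duplication screen → phasing →
recombination scans, logging per-stage counts and writing FASTA/VCF/TSV
artifacts plus the resolved configuration. Because the simulation driver
knows its own ground truth, the run summary also reports genotype
concordance and the undefined-genotype/mask correspondence.

Test problem sizes were chosen as the smallest that exercise each claim
meaningfully: the full 9 kb template with 60 long reads and ~×100 short
reads for the consensus/polish/genotyping scenarios, 2,000 control reads
for error-profile recovery, 20 individuals × 30 sites (and exhaustive
oracles up to 6 individuals × 5 sites) for phasing, and 200 replicates ×
100 permutations for recombination calibration; the end-to-end pipeline
test runs a 3 kb template at ×60.

## Known limitations

The consensus cannot extend beyond its seed template, so it depends on
full-length seed reads (real amplicon runs provide them; highly
fragmented inputs would not). The genotyper has no local reassembly, so
dense variant clusters (<4 bp apart) could merge into complex records.
The error profiler's component estimates carry the alignment-effect bias
quantified above. Phasing posteriors are relative to the enumerated
candidate sets and can be overconfident for individuals with many
ambiguous blocks. Recombination scans assume aligned, gap-free haplotype
strings over shared coordinates.
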