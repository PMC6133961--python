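# amplihap

Reference-free assembly and genotyping of multi-kilobase amplicons from
hybrid long-read + short-read sequencing.

Highly polymorphic loci such as the MHC class II *DRB* region resist
short-read assembly: heterozygous indels, homopolymer tracts and short
tandem repeats fragment the contigs, and without a reference genome there
is nothing to scaffold against. `amplihap` implements the complementary
strategy: noisy single-molecule long reads (nanopore-like, ~10% error)
span the whole ~9 kb amplicon and yield a draft consensus; accurate
2×250 bp short reads then polish that draft in diploid-aware mode and
genotype every barcoded individual against it; statistical phasing and
recombination scans characterize the resulting haplotypes.

The toolkit covers, as importable modules and as a CLI:

- `simulate` — a diploid amplicon simulator (SNPs, indels, a heterozygous
  (GT)-repeat STR, homopolymer tracts, GC control) with noisy long reads,
  paired short reads, a lambda-sized spike-in control and chimeric
  artefacts; every read records its ground truth for testing.
- `align` — banded affine-gap semi-global alignment (numba-accelerated)
  with k-mer seeding, strand resolution, acceptance filters
  (≤40% mismatches, ≤20% gaps, no indel >50 bp) and reference left-aligned
  indels.
- `consensus` — length filtering, split-alignment chimera screening,
  seed selection (~20 reads near amplicon length), and iterative
  star-pileup consensus from a medoid seed (5 iterations).
- `polish` — short-read pileup polishing with a heterozygous band
  [0.25, 0.75] left uncorrected, and full accounting of every change.
- `errorprofile` — per-read-position substitution/insertion/deletion
  rates from control alignments, with three mapper parameterizations and
  a comparison table.
- `genotype` — high-coverage pileup genotyping with homopolymer/STR
  masking, direct STR typing from flank-anchored reads, duplication
  signatures (tri-allelic sites, 25:75 balance, heterozygosity), VCF 4.2
  output.
- `phase` — haplotype-frequency EM with block ligation and pool
  refinement; `recomb` — MaxChi and Chimaera scans with permutation
  p-values and bootstrap breakpoint confidence intervals.

## Worked example

The whole workflow runs on simulated data with one command:

```bash
amplihap run-all --seed 7 --out results/demo
```

which logs each stage (abridged):

```
[simulate] template 9001 bp, 110 truth variants, 6 individuals
[filter] kept 119, too_short 1, too_long 0
[chimera] 0 flagged of 119
[consensus] 8996 bp after 4 iterations
[polish] 16 corrections (8 deletions restored, 5 substitutions,
         3 insertions removed); 9001 bp
[genotype] 110 sites emitted
[str] typed STR at 375-383 (1-based)
[phase] 4 distinct haplotypes at posterior >= 0.9 (109 sites)
[recomb] 8 scans: no significant recombination signal
```

Reading: the long-read draft comes out 8996 bp at ~99.7% identity; the
short reads repair the last 16 positions, landing on the true 9001 bp
sequence exactly. All 109 SNP/indel sites are genotyped in the six
individuals (the STR is typed separately and its tract masked), phasing
recovers the four haplotypes actually segregating in the sample, and no
recombination breakpoint is reported because none was simulated. The
output directory holds the consensus FASTA, VCF, mask BED, STR and
haplotype tables, the duplication report and `summary.json` with
truth-aware metrics (genotype concordance 1.0 in this run).

Library use mirrors the CLI; for instance the error profiler:

```python
from amplihap.simulate import simulate_control
from amplihap.errorprofile import profile_reads

ref, reads = simulate_control(n_reads=2000, seed=1)
print(profile_reads(reads, ref).summary())
# 2000 reads, 8234725 aligned bases: sub 4.37%, ins 4.06%, del 2.96%,
# total 11.40%
```

against generating rates of 4.8% / 4.1% / 3.0% — the small substitution
deficit is the alignment effect discussed in `docs/methods.md`.

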