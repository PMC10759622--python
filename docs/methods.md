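# Methods

## Coordinate model

All intervals are 1-based closed; the length of (start, end) is
end − start + 1. Chromosomes are tiled by fixed 400 bp bins starting at
position 1 (bin *i* covers [400·i + 1, 400·(i+1)]); chromosome lengths
are truncated to whole bins at construction. The 400 bp default matches
the granularity that read-depth CNV callers typically emit and makes
every call and CNVR bin-aligned. BED and VCF exports convert to their
native conventions (0-based half-open and 1-based POS respectively);
converting out and back is the identity.

## Synthetic cohort generator

The generator emulates a three-population resequencing design:
populations JD, SX and SM with 10 diploid samples each and a mean
mapped depth of 22.65×, over 10 autosomes from 2.0 Mb down to 0.2 Mb
(11 Mb, 27,500 bins). The genome is deliberately small — large enough
to hold > 500 planted loci in disjoint 50-bin slots and to give the
per-chromosome count regression a real length gradient, small enough
that the full cohort simulates in seconds on one CPU.

**Population CNV architecture.** Each planted locus is a deletion
(probability 0.64, mirroring the usual excess of deletion calls in
read-depth data) or duplication, 5–15 bins long, with a carrier-allele
frequency per population. Background loci draw a base frequency
U(0.08, 0.5) and per-population jitter U(−0.1, 0.1), so
between-population differences never exceed 0.2. One locus per
population is strongly differentiated: frequency 0.9 in the focal
population, 0.1 in the others, length 8 bins. These frequencies are
package defaults for a plausible closed-breed architecture, not
estimates from any dataset.

**Genotypes and depth.** Per sample, the variant-allele count at a
locus is binomial(2, f) with f the population frequency. Per-bin read
counts are Poisson with mean

    lambda = mean_depth × (bin_size / read_unit) × copy_ratio,

where read_unit = 100 bp converts base coverage into an expected read
count per bin (≈ 90 reads per 400 bp bin at 22.65×) and copy_ratio is
(total copies)/2: 0.5/0.0 for het/hom deletions, 1.5/2.0 for het/hom
duplications, 1.0 outside planted loci. An optional negative-binomial
switch adds overdispersion for robustness experiments, and an optional
smooth GC-bias multiplier in [0.8, 1.2] is tracked per bin so that
GC-stratified correction can be tested; both are off by default.

**What the generator does not emulate:** read-level artifacts
(mappability, duplicate reads, alignment error), breakpoint
microhomology or sub-bin breakpoints, sex chromosomes, overlapping or
nested CNVs at one locus, and linkage between loci. Passing recovery
tests therefore demonstrates that the calling, merging and scanning
logic is correct under the stated noise model — not that the pipeline
is robust to every artifact of real sequencing data.

## CNV calling

Raw counts are normalized by the genome-wide median (robust to the
small CNV fraction of the genome); a GC track, when present, divides
counts before normalization. Bins are labeled deletion candidates
(RD < 0.7), duplication candidates (RD > 1.3) — both strict, boundary
values are normal — and maximal single-state runs tolerating at most
`gap_bins` (default 1) interior normal bins become segments. An
opposite-state bin always breaks a run. Segment mean RD is taken over
the whole span, gap bins included, and the same span feeds a two-sided
one-sample *t*-test against RD = 1.0. A segment becomes a call iff
*p* < 0.01, span > 1,000 bp (strict: a 1,000 bp segment fails), and the
span mean clears the candidate threshold of its state.

Numerical edge cases: a zero-variance segment with mean ≠ 1 is maximally
inconsistent with diploid depth and receives the smallest positive
double (p ≈ 4.9e−324) rather than the NaN a naive *t*-test returns; a
zero-variance segment at exactly 1.0 gets p = 1. Single-bin segments
have no defined significance and are rejected with a logged reason.

At the default depth the run-length requirement implied by the 1 kb rule
(≥ 3 bins) plus the *t*-test makes false calls on null genomes rare
(≈ 0.0 per 10,000-bin genome in the test suite's 20-seed average). For
recovery scoring, breakpoint accuracy is summarized as the mean per-side
error over matched calls; isolated events (≈ 0.7 %, almost all
heterozygous duplications whose two outermost bins both fall below the
1.3 threshold) can lose more than two edge bins, which a mean of
≈ 0.08 bins absorbs while still exposing any systematic boundary bias.

## CNVR construction

Calls overlapping by ≥ 1 bp are merged transitively (single forward
sweep over sorted calls); book-ended calls are not merged. Regions with
fewer than `min_support` (default 2) supporting calls are discarded —
at every scope, i.e. within each population set and in the
metapopulation set; `min_support=1` disables the discard where a
different convention is wanted. Type classification: DELETION iff all
supporting calls are deletions, DUPLICATION iff all duplications,
COMPLEX otherwise. Genome coverage is the union length over the genome
length (CNVR sets are non-overlapping by construction, enforced at
construction time). The per-chromosome count regression is ordinary
least squares of CNVR count on chromosome length; constant counts make
R² undefined and are reported as 0 with a warning.

## Genotype encoding and F_ST

Each CNVR is a biallelic pseudo-locus; allele 1 is the carrier allele.
A sample with no overlapping call is 0/0. A carrier's zygosity comes
from its locus mean RD: deletions are 1/1 below 0.25, duplications 1/1
above 1.75, otherwise 0/1. The 0.25/1.75 cutoffs are the midpoints
between the heterozygous (0.5/1.5) and homozygous (0.0/2.0) expected
copy ratios, shifted conservatively toward the homozygous state; both
are configurable. When a sample has calls of both types over one
region, the type with the larger overlapping span wins. Samples without
depth data at a locus are missing and are excluded locus-wise.

θ̂ is the two-group Weir & Cockerham (1984) estimator computed from
per-group sample sizes, allele frequencies and heterozygote proportions
(components a, b, c; θ̂ = a/(a+b+c)). The rest populations are pooled
into a single second group, matching the one-vs-rest contrast design.
Negative estimates are kept as computed and participate in ranking;
loci where every component vanishes (both groups fixed for the same
allele) are undefined and excluded. Outlier selection flags exactly
⌈0.05·m⌉ of the m defined loci per contrast, breaking ties at the
threshold by genome order (earlier locus first) so the flag count is
reproducible.

## Annotation

Genes are read from GFF3 (`gene` features only, native 1-based closed
coordinates). A gene is retained for a CNVR when the overlap is at
least `min_gene_fraction` (default 0.5) of the **gene** length —
the gene is the measured unit; a flag switches the denominator to the
CNVR for the alternative convention. Strand is ignored. Population
gene-set partitioning is plain set algebra over gene ids: shared by
all, specific to one, or labeled intermediate subsets.

## Reproducibility and problem sizes

Every stochastic stage takes an explicit seed; one pipeline run derives
stage seeds by fixed offsets from the config seed, and two runs with
identical config and seed produce byte-identical outputs (verified down
to the VCF and F_ST tables in the test suite). The default scenario —
30 samples, 27,500 bins, ≈ 513 loci — was sized so that a full
simulate–call–merge–scan–annotate cycle takes a few seconds and the
complete test suite, including five independent end-to-end scan
recoveries and a 20-seed null false-positive average, stays around a
minute on one CPU.

## Known limitations

- The threshold-run segmentation is intentionally simple; it has no
  power below 3 bins (1.2 kb at the default bin size) and estimates
  breakpoints only to bin resolution.
- The plain *t*-test p-value is not corrected for the genome-wide
  number of candidate segments; the size and RD filters carry most of
  the specificity burden, which is adequate at read-count noise levels
  (λ ≈ 90) but would not be at per-bin λ below ~30.
- One CNVR = one biallelic locus: multi-allelic copy states and
  partially overlapping events collapse onto a single carrier allele.
- θ̂ on pooled "rest" samples ignores substructure among the rest
  populations; that is the intended contrast semantics, not an
  approximation of a multi-group estimator.
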