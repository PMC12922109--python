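# Methods

This note records the models, defaults, and design choices behind
`cherrygt`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic data do and do not emulate.

## Amplicon construct and panel model

The simulated construct reproduces the two-round PCR library: read 1 is
`i5 barcode (6 bp) · OH1 adapter (32 bp) · forward primer · insert`, and
read 2 is `i7 (6 bp) · OH2 (22 bp) · reverse primer · insert′` on the
opposite strand, both truncated to 150 bp (PE150). Because the second-round
primers bind the OH adapters, barcodes sit at a fixed offset — the first
six bases of each mate — and demultiplexing is deterministic substring
extraction, not motif search. The OH adapter at its expected offset is
verified per read as a diagnostic counter but never used to reject reads.

Panel design rules enforced by `panel.validate_panel`: amplicons at most
300 bp (hard error, for PE150 compatibility), SNP preferably 50–100 bp from
one of the primers (warning only, since it is a design preference), unique
6-bp barcodes per set, unique `(pool, i5, i7)` triples in the sample sheet.
Generated barcode sets use pairwise Hamming distance ≥ 3 so that optional
single-mismatch rescue is always unambiguous.

The default panel targets the two coding SNPs of the carotenoid-oxygenase
gene (cDNA 927 C>A and 935 A>C), each modelled as its own amplicon with its
own primer pair. Treating the two SNPs as separate amplicons (rather than
two positions on one amplicon) keeps per-locus read sets disjoint; linked
phasing of nearby SNPs is out of scope.

**Barcode capacity and pooling.** The study design's 8 × 24 = 192 barcode
combinations uniquely tag one 192-individual plate. A pooled submission
carrying two strain plates (e.g. red + yellow) would collide on those 192
pairs, so the default simulation scenario extends the i5 set to 16 tags and
gives each plate within a pool its own block of 8 — every one of the 768
individuals then has a unique `(pool, i5, i7)` identity, and individuals are
resolved by that triple. `panel.default_barcode_panel()` remains the 8 × 24
design panel.

## Synthetic data generator

The generator defines the study conditions; its defaults are fixed, not
tuned per experiment:

| parameter | default | meaning |
|---|---|---|
| strains | red, yellow, blue, wild | colour strains, two pools ({red, yellow}, {blue, wild}) |
| n per strain | 192 | individuals per strain plate |
| yellow p(het) | 0.3 | heterozygote probability at both loci; other strains fixed hom-ref |
| depth | 200 | read pairs per individual × locus |
| error rate | 0.005 | uniform per-base substitution probability |
| read length | 150 bp | PE150 truncation |

Only the yellow strain segregates — that is the association pattern the
analysis is meant to recover. Per-locus depth is not reported for the real
study; 200 with 0.5 % error is a realistic targeted-amplicon working point
and makes the AFI zones essentially deterministic (a heterozygote's
ref-fraction would need to leave (1/6, 5/6) — a > 4σ binomial excursion at
depth 200 — to be miscalled). Heterozygotes emit either allele per read as
an independent Bernoulli(1/2); errors are substitutions only (no indels,
so fixed-offset extraction stays valid); depth is exactly constant (no
overdispersion); quality strings are a constant Phred-30 symbol because
the pipeline never consumes qualities. PCR chimeras, index hopping, and
contamination are deliberately not modelled, so passing tests demonstrate
correctness of the decoding/calling logic, not robustness to those
real-data artifacts.

Amplicon filler sequence is keyed on the locus id alone (CRC-seeded RNG),
so the synthetic reference is stable across runs; all sampling uses a
single user seed, and fixed seeds give byte-identical FASTQ.

Image fixtures render rotated red-dominant ellipses of known axes and
painted RPB on a neutral grey background, placed on a jittered grid so
clusters never merge; truth records the post-quantisation colour ratio.
Ct tables put all noise on the target gene with a constant reference Ct,
so group ΔCt has exactly the requested mean and SD.

## Demultiplexing

Tags are the concatenated first 6 bases of both mates, resolved against
the sample sheet by the `(pool, i5, i7)` triple; pool identity comes from
the input file pair. Default matching is exact; `max_mismatch=1` enables
rescue, which on a distance-≥ 3 panel can only increase the assigned count
(verified as a property test). Unassigned reads are categorised
(too-short, no-match or ambiguous per barcode side, not-in-sheet) and
conservation (assigned + unassigned = total) always holds.

## Genotype calling

The allele frequency index is the ref/alt read-count ratio: `AFI =
n_ref/n_alt`, +∞ when alt is absent, undefined (NaN) when both counts are
zero. The verbal "count over total" phrasing of the index is treated as
shorthand: thresholds of 0.1/0.2/5/10 are only meaningful on a count
*ratio*, the usual GT-seq convention. Classification:

- AFI > 10 (or +∞) → homozygous reference
- AFI < 0.1 → homozygous alternate
- 0.2 < AFI < 5 → heterozygous
- [0.1, 0.2] and [5, 10] (boundaries inclusive) → unclassifiable buffers
- total depth (including non-ref/alt bases) < 10 → unclassifiable

The buffer-zone reading resolves the otherwise self-contradictory printed
heterozygote condition; boundary values are assigned to unclassifiable
because the printed inequalities are strict on both sides. The depth floor
of 10 is this package's choice — ratio thresholds are meaningless on a
handful of reads. Non-ref/alt ("other") bases count toward reported depth
but never toward AFI. Primer location tolerates up to 2 substitutions
(default) in the primer window; at a 0.5 % error rate this loses ~0.002 %
of reads rather than the ~12 % that exact matching would.

## Association

Unclassifiable calls are excluded from contingency tables by default —
they are non-calls, not a genotype class. Zero rows/columns are dropped
(with a log note) before testing; the statistic is plain Pearson χ² (no
Yates correction, available by flag), with a flag raised when any
expected count is below 5. Pairwise testing takes a focal strain against
each other strain (Bonferroni-adjusted over those comparisons, raw p also
reported) and against all others pooled. Mutant allele frequency is
computed from pooled read counts, `n_alt/(n_ref+n_alt)`; under the default
scenario the yellow-strain value concentrates at p(het)/2.

## Coding-effect annotation

Coordinates are 1-based on the CDS with the frame anchored at position 1,
so position `p` is codon `⌈p/3⌉`, within-codon position `((p−1) mod 3)+1`;
the mapping is exactly invertible. Translation uses the standard nuclear
code (these are nuclear transcripts); stops render as `*`. The real
transcript is not shipped: `coding.synthetic_cds()` generates a synthetic
400-codon stand-in carrying the codon contexts the panel's variants
require — AGC at codon 309 (the unique serine codon whose third-position
C>A gives arginine) and AAA at codon 312 (AAA→ACA, lysine→threonine) —
plus an A at nucleotide 920 for the third, monomorphic variant, whose
codon context is otherwise unconstrained.

## Phenotype metrics

RPB uses raw channel intensities (no luma weighting): the red sum over
the three-channel sum in the region, which makes it invariant under
uniform rescaling and additive over partitions (both property-tested).
Cluster length and width are the extents (max − min + 1 of projected
pixel centres) along the eigenvectors of the pixel-coordinate covariance
matrix. Extents were chosen over the ellipse-equivalent axis lengths
(4√λ) because the latter over-reports a filled rectangle's size by ~15 %;
extents reproduce a 10 × 4 rectangle exactly and are rotation-stable to
within rasterisation error. A single pixel measures 1 × 1. Segmentation
for the synthetic images is global thresholding plus 8-connected
components — real-micrograph segmentation is out of scope. Group
comparison is a two-sided Student's t (pooled variance) by default, Welch
by flag; both-constant-and-equal groups are reported as t = 0, p = 1.

## Expression

ΔCt = target Ct − reference Ct per sample; the calibrator is the
calibrator group's arithmetic mean ΔCt; relative expression is 2^−ΔΔCt.
Testing runs on the expression scale by default (as plotted); the
returned frame retains ΔCt columns for Ct-scale analysis. ANOVA is the
standard one-way decomposition, followed by Tukey HSD and an
insert-and-absorb compact-letter display (groups sharing no letter differ
at α). Replicate Ct values are treated as independent observations; if
they are technical replicates this is statistically generous, and users
should aggregate to biological replicates first where that matters.

## Numerical and testing notes

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; derived seeds stay below 2³¹.
- Threshold comparisons on AFI are float, but for counts up to ~10¹⁴ the
  float ratio cannot cross a threshold spuriously (the nearest count
  ratio differs from each threshold by far more than double-precision
  rounding); the test suite checks the classifier against an
  exact-rational oracle over all counts in [0, 300]².
- Scaled problem sizes in the test suite: the full 768-individual
  demultiplexing check runs error-free at depth 50; the noisy concordance
  check runs at the default depth 200 and error 0.005 with 24 individuals
  per strain (192 calls), sizes at which every binomial failure mode is
  still far inside its tolerance.
- Known limitations: no indel or quality modelling, no contamination or
  index-hopping, no likelihood-based calling, no Hardy–Weinberg or F_st
  analysis, no pigment-dispersion scale (user-supplied ordinal scores can
  be compared through `phenotype.compare_groups`).
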