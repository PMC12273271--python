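# Methods

## Scope and model

`cgibench` quantifies two complementary departures of tumor methylomes from
their healthy counterparts: focal gain of methylation at CpG islands
(CGIs), concentrated at PRC2-repressed promoters, and diffuse loss of
methylation across partially methylated domains (PMDs). The package does
not align reads or call methylation; it starts from per-CpG methylation
fractions (sequencing calls with read counts, or array beta values
positioned through a probe manifest) and ends at cohort-level statistics.

All coordinates are 0-based half-open internally. BED input is native;
Bismark coverage files (1-based) are shifted at the reader boundary, and
whenever methylated/unmethylated read counts are present the methylation
fraction is recomputed from the counts rather than trusted from a percent
column.

## Decision rules and their boundaries

Every rule is applied exactly as stated, with no floating-point epsilon;
the test suite pins each boundary.

| rule | comparison |
| --- | --- |
| unmethylated in the healthy reference | signature ≤ 0.2 (inclusive) |
| methylated CGI / methylated in tumor | mean > 0.2 (strict) |
| hyper-call gain | tumor − signature > 0.1 (strict) |
| common set membership | called in ≥ 50% of samples (inclusive) |
| pan-cancer membership | common in ≥ 30% of types, i.e. ≥ ceil(0.3·n) |
| WGBS / RRBS coverage | 10–150 / 5–150 reads, both ends inclusive |
| feature evaluable | ≥ 3 covered CpGs (arrays: ≥ 1 probe) |
| promoter CGI / H3K27me3 PRC2 flag | overlap ≥ 20% of CGI or promoter |
| DMR significance | q < 0.05 (strict) |
| PMD merge / size | gap ≤ 200 kb merged; length > 200 kb kept |

The inclusive-fraction thresholds are computed as `ceil(f·n − 1e−9)`; the
tiny guard only protects against binary float products (e.g. `0.3 * 10`)
crossing the integer boundary and never changes an exact rational case.

Missingness: a CGI with fewer than the required CpGs in either the tumor
sample or the healthy signature is ineligible for hyper calling — a CGI
unmeasurable in the control cannot be classified as unmethylated there.
Medians and methylated fractions are computed over non-missing
(“evaluable”) features only; even-length medians take the midpoint of the
central pair.

## Feature annotation

CGI shores are the 2 kb flanking each side of a CGI, shelves the outer 2 kb
beyond each shore, the remainder open water. Each base is labeled by its
distance to the nearest CGI base, which realizes the precedence
CGI > shore > shelf and splits colliding flanks of neighboring CGIs at the
gap midpoint (the left CGI takes the extra base of an odd gap; since the
label depends only on distance, the tie side never changes a label).
Overlapping input CGIs are merged first. Promoters span TSS−1500 to
TSS+500 on the plus strand (mirrored on minus), clipped at zero. Chromatin
states are assigned per CGI by largest total overlap, ties broken by the
lexicographically smallest label — deterministic and assay-independent.
The PRC2-target set is the bivalent/Polycomb states (10_TssBiv, 11_BivFlnk,
12_EnhBiv, 13_ReprPC, 14_ReprPCWk) for state-based (human) input, or an
H3K27me3-domain overlap of ≥ 20% for domain-based (mouse) input, in both
cases intersected with promoter CGIs. Cross-species projection consumes
pre-lifted intervals (the lift itself is external) and keeps every
many-to-many overlap pair.

## Cohort statistics

**Saturation.** Within each of 100 iterations, 100 samples are drawn
without replacement and the cumulative union of their hyper sets recorded;
curves are averaged over iterations. The denominator is the union over the
type's full cohort, so the curve measures coverage of the observed
repertoire; only types with at least 100 samples are analyzed by default.
For i.i.d. per-CGI call probability p the expectation is 1 − (1−p)^m,
which the implementation reproduces to ±0.002 at the default problem size
(2000 CGIs, 120 samples).

**Cross-control recovery.** Each tumor type's common set is rebuilt using
every other tissue's healthy signature; recovery is the fraction of the
original (matched-control) set retained, additions the set difference. The
matched diagonal is identically 1 whenever the original set is non-empty.

**Random-sampling enrichment.** The null draws subsets of matching size
uniformly from the eligible CGI universe (1000 draws, seeded, per-type
fixed universe); the statistic is log2(observed / mean null overlap
fraction). A zero null mean is reported as log2(observed / f_min) with
f_min = 1/(draws·set size), flagged as capped.

**CpG-level shift.** CpG methylation values are binned into ten 0.1-wide
levels ([0.9, 1.0] closed at the top, binned with `digitize` so exact
decimal boundaries land on the correct side); per-level fractions are
averaged across healthy samples and subtracted from each tumor sample, so
each shift column sums to zero by construction.

**Variable CpGs.** The top-n CpGs by unbiased (n−1) sample variance over
complete cases (CpGs covered in every sample), ties broken by genomic
order; scope `cgi` restricts to CpGs inside CGIs.

## PMDs and DMRs

Raw PMD calls (from an external HMM, or the package's deliberately simple
sliding-window seed caller over non-CGI CpGs at threshold 0.7) are merged
across gaps of ≤ 200 kb and filtered to > 200 kb. HMDs are the complement,
minus uncovered runs longer than 100 kb (e.g. centromeres). 100-kb tiles
take the class with the larger overlap, ties to HMD (conservative: avoids
inflating apparent PMD hypomethylation).

DMRs arrive in the metilene output dialect (a column-map override handles
dialect drift); direction follows the sign of the mean difference. Feature
assignment is by maximum overlap with a context partition or a chromatin
state segmentation grouped into eight classes (Active TSS, Bivalent TSS,
Transcript, Enhancer, Bivalent enhancer, Heterochromatin,
Polycomb-repressed, Quiescent). Background regions are length-matched,
same-chromosome uniform placements (10 per DMR, seeded, optional exclusion
masking with rejection sampling); this scheme is a reconstruction chosen
for simplicity — the precise historical construction is not fully
specified anywhere we could verify, so the class fractions of the
background are themselves validated against genomic composition in the
tests. Enrichment is the log2 ratio of class fractions, with ±inf
sentinels for empty fractions.

## The synthetic cohort generator

The generator emulates the statistical structure of healthy/tumor
methylome cohorts; its defaults are the package's study conditions:

| parameter | default | meaning |
| --- | --- | --- |
| genome | 2 autosomes × 6 Mb | CpGs ~150 bp apart, ~15 bp inside CGIs |
| n_cgis / cgi_length | 500 / 1 kb | ≥ 10 kb apart, placed outside PMDs |
| frac_prc2 | 0.5 | PRC2-target promoter CGIs (each gets a TSS) |
| frac_constitutive_meth | 0.30 | CGIs methylated in every healthy tissue |
| tissue_specific_meth_per_tissue | 8 | per-tissue methylated complement; with 150 constitutive CGIs two tissues overlap 150/166 ≈ 90% |
| n_healthy / n_tumor | 30 / 30 | per type |
| planted_set_size (K) | 200 | planted hyper CGIs ⊆ PRC2 promoter CGIs |
| p_include / gain_level | 0.8 / 0.6 | per-tumor inclusion and mean gain |
| pmd_fraction | 0.30 | blocks of 300 kb–1 Mb, ≥ 400 kb apart |
| hmd_baseline | 0.85 | background methylation mean |
| pmd_loss_per_unit_history | 0.1 | PMD mean = 0.85 − 0.1·history, floor 0.3 |
| healthy / tumor history | 0 / 2 | proliferative history units |
| beta_concentration | 50 | within-class Beta spread (classes sit near, not across, the 0.2/0.1 boundaries) |
| coverage_mean | 30 | Poisson, truncated into the assay bounds |

Per CpG, a latent mean is drawn from a Beta around its class mean
(unmethylated CGI 0.05; methylated CGI 0.85; included planted CGI 0.6; HMD
0.85; PMD eroded by history) and observed as a binomial draw at the
truncated-Poisson coverage (truncation by clipping — at mean 30 and bounds
[10, 150] the boundary mass is negligible, and every call passes the filter
by construction; a `raw_coverage` mode skips truncation to exercise the
filter). Array mode emits Gaussian-noised (sd 0.05), clipped beta values at
CGI CpGs plus a thinned background subset, without coverage. Constitutive
methylated CGIs are drawn from non-PRC2 CGIs (methylated CGIs sit in gene
bodies and intergenic space, not at PRC2 promoters); tissue-specific ones
are drawn uniformly from the rest and may therefore graze a planted set —
the corresponding planted CGIs are genuinely ineligible, which is why
default recall is ~0.97 rather than 1.0. Solo-WCGW stand-in sites are
background CpGs inside PMDs with no neighboring CpG within 35 bp. All
randomness flows through one `SeedSequence` hierarchy; cohort files are
byte-identical across runs with the same seed.

What the generator does **not** emulate: sequence context (no FASTA, no
true WCGW flanks — isolation is the proxy), SNPs and cross-reactive
probes, copy-number effects, tumor purity mixtures, batch effects between
studies, and the gradual, region-autocorrelated character of real PMD
erosion. Passing recovery tests therefore demonstrates the correctness of
the calling logic under the stated noise model, not robustness to every
artifact of real cohorts.

## Problem sizes

The default simulated genome (12 Mb, ~110k CpGs per sample) keeps a full
30/30 cohort run in the tens of seconds while leaving every rate parameter
(coverage, spacing, class means) at realistic values; the pan-cancer
construction uses ten types of 8/8 samples with K = 60 and a 50% shared
core (small enough to run routinely, large enough that the ≥ 50%-of-samples
rule is stable at p_include = 0.8), and the cross-control scenario two
types of 12/12. These sizes are the package's chosen study conditions and
are asserted as such by the acceptance tests.

## Known limitations

- The naive PMD seed caller is a plumbing stand-in for a dedicated HMM; it
  is only expected to recover clean, deeply eroded domains (as planted by
  the generator), not the subtle boundaries of real PMDs.
- The background-DMR scheme and the random-sampling enrichment null are
  the simplest constructions consistent with their descriptions; both are
  seeded and configurable.
- Stage-stratified summaries are expressed through group labels in the
  sample sheet (per-sample metrics grouped afterwards) rather than bespoke
  stratification code.
- Array mode attaches no detection p-values; probe QC is expected to have
  happened upstream (the manifest may be a pre-masked probe list).
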