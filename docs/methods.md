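# Methods

This note documents the statistical procedures `herdscan` implements, the
choices made where conventions differ between tools, and what the synthetic
cohort does and does not emulate.

## Quality control

Site retention follows the standard resequencing criteria: biallelic SNPs
only, per-site missing rate ≤ 0.20 at the detection stage, minor allele
frequency (MAF) ≥ 0.05 computed on non-missing alleles, and a Hardy–Weinberg
equilibrium (HWE) exact-test p-value > 1×10⁻⁶; sample missing rate ≤ 0.10;
then a second, stricter site-missingness pass at ≤ 0.05 mirroring a
conversion-stage filter. Removed sites are attributed to the first failing
criterion in the order biallelic → missingness → MAF → HWE, so report counts
sum exactly. Ties at a threshold are retained (inclusive comparisons).

The HWE test is the plain two-sided exact test (no mid-p): conditioning on
the observed allele counts, heterozygote configurations are enumerated with
probability ∝ 2^h·n!/(h!·n_AA!·n_aa!), and configurations no more likely than
the observed one are summed. An exact test was chosen over the chi-square
approximation because the screen targets low-frequency alleles where the
asymptotic test is unreliable. The test is applied pooled across samples by
default, with the per-population option left to the caller; a pooled test
with the lenient 10⁻⁶ threshold is insensitive to the modest Wahlund effect
of the structured cohorts analyzed here.

**Two QC regimes in the pipeline.** The structure track (IBS/GRM/PCA/NJ,
ROH, LD) uses the full criteria including the MAF floor. The screen track
(windowed scan and rare-allele screen) omits the MAF floor: a pooled MAF ≥
0.05 filter would remove the screen's own targets by construction, since a
variant at frequency ~0.09 in 57 twins and < 0.05 everywhere else is below
5% in the pooled cohort.

## Relatedness and structure

* **IBS distance**: 1 − shared alleles / (2 × jointly genotyped loci), with
  per-locus sharing 2 − |dosage_i − dosage_j|. The distance orientation means
  unrelated pairs score high (~0.1 in outbred cattle) and close relatives
  low.
* **GRM**: frequency-standardized (VanRaden/GCTA-style),
  G_ik = mean_j (x_ij − 2p_j)(x_kj − 2p_j)/(2p_j(1−p_j)), with p estimated
  from the analyzed table and missing entries excluded pairwise. With
  sample-estimated frequencies the off-diagonal mean of an unrelated cohort
  is −1/(n−1), not 0; tests assert that finite-sample expectation. No
  attempt is made to byte-match GCTA's missing-data handling.
* **PCA**: SVD of the standardized, mean-imputed genotype matrix
  (centered by 2p, scaled by 1/√(2p(1−p)), missing → 0 after
  standardization, re-centered). Scores equal eigendecomposition of the
  corresponding relationship matrix; both routes are cross-checked in tests.
* **NJ tree**: Saitou–Nei neighbor joining on the IBS matrix via scikit-bio;
  negative branch lengths are clamped to zero. On additive matrices the tree
  reproduces the input distances exactly. Pairs with no jointly genotyped
  loci make the matrix incomplete and NJ refuses to run.

## Runs of homozygosity

PLINK-style sliding-window semantics with the standard parameterization
(window 50 SNPs, ≤ 3 heterozygous and ≤ 5 missing calls per compatible
window, SNP in-run when ≥ 5% of covering windows are compatible, runs ≥ 50
SNPs, ≥ 500 kb, gap split at 100 kb, density ≤ 50 kb/SNP). Runs are trimmed
to start and end on homozygous calls and reported SNP-delimited. Gap and
density checks run after run assembly, in that order, keeping each filter
independently testable. Chromosomes shorter than one window are evaluated
with a single truncated window. Exact PLINK byte-matching is not a goal;
acceptance is truth recovery on planted tracts. Note that under the hit-rate
rule a run can legitimately extend onto background homozygotes flanking a
planted tract; boundary tightness (≤ 2 inter-SNP intervals) is therefore a
property guaranteed only against het-dominated flanks, and is tested as
such. F_ROH divides the per-sample summed run length by the autosomal
genome length, default 2,489.39 Mb (the bovine autosome total), overridable.

## Linkage disequilibrium

Genotype (dosage) r² — squared Pearson correlation over jointly called
samples — for intra-chromosome pairs within 500 kb; phase is never assumed.
Decay curves average r² in fixed 1-kb bins by default (wider bins for
plotting/comparison are a parameter). Computation is per population from
the sample sheet; no cross-population pooling. A greedy window r² pruner is
provided as a utility for thinning markers before structure analyses.

## Selection scan

Windows are anchored at 1, 1+step, … per chromosome (50 kb / 20 kb
defaults); trailing windows keep their true span. Window F<sub>ST</sub> is
the Weir–Cockerham (1984) two-population ratio of summed variance
components; negative window values are retained so the empirical threshold
is undistorted. Window θπ is the summed per-site unbiased heterozygosity
divided by the window span in bp (sites with fewer than two called alleles
are skipped). The θπ-ratio is oriented control/twin so that selection
(diversity loss) in the twin cohort gives positive log₂ values; the
orientation is configurable. Thresholds are type-7 empirical quantiles over
windows with defined values, and selection is strict (> threshold). Regions
from the two statistics can be intersected (strong-signal overlap) or
unioned (maximum search scope); the screen defaults to the union, matching
the rare-variant rationale: a low-frequency causal allele may move one
statistic more than the other.

## Twin screen

A pure conjunction of four gates: (i) inside the selected regions, (ii) ALT
frequency strictly below 0.05 in every control population with called
alleles (populations with no calls at a variant abstain), (iii) twin-cohort
minor allele count ≥ 10 — the flag convention (≥), under which the minimum
attainable twin frequency with 57 fully genotyped diploids is 10/114 =
0.0877193 — and (iv) twin-cohort genotype missing rate ≤ 0.1 (the
"retain ≥ 90% called" convention expressed as a missing-rate bound).
Annotation against a gene model classifies each candidate as
exonic/intronic when exon structure is available (GFF3), otherwise "genic";
within a strand-aware 1-kb flank as upstream/downstream; otherwise the
nearest gene within 100 kb (a window motivated by regulatory associations
reported tens of kb from their gene) with its distance.

## Synthetic cohort

The generator emulates the features the analysis consumes, not cattle
demography:

* **Allele-frequency architecture**: ancestral frequencies ~ U(0.15, 0.85)
  per site; K = 5 ancestry components via Balding–Nichols drift (F = 0.15);
  each population is a fixed admixture (dominant weight 0.7) with additional
  population drift (F = 0.03); final per-population frequencies are clipped
  to [0.10, 0.90]. Background variants are therefore common — emulating a
  post-QC SNP panel — so the screen's "rare in all controls" signal exists
  only where planted, giving recovery tests a deterministic denominator.
* **LD**: individuals are mosaics of per-population founder haplotype pools
  (geometric segment lengths, mean 1.5 Mb). Fewer founders → smaller
  effective population → uniformly higher r²; the founder counts of the six
  default populations encode the expected LD-decay ordering (largest pool
  for the fastest-decaying population, smallest for the slowest).
* **Cohorts**: six control populations (sizes 40/26/18/17/31/30; the
  documented sizes where available, with the largest population down-sampled
  and the twin-source control population set at desk scale), plus a
  57-sample twin cohort and a 21-sample ≥4-parity single-calving control
  cohort drawn from the same founder pool as the twin-source population, so
  background twin-vs-control F<sub>ST</sub> is pure sampling noise.
* **Sweeps**: inside each planted interval a fraction (default 0.8) of twin
  haplotypes is replaced by one sweep haplotype and the rest are pulled
  toward it per site with probability 0.3, jointly depressing twin θπ and
  raising F<sub>ST</sub> in the planted windows.
* **Rare plants**: explicit genotype edits with exact counts (twin ALT count
  ≥ 10; per-population control counts capped strictly below 4% frequency);
  planted sites are exempt from missingness so the counts are exact, and
  realized control frequencies are re-verified against the 5% threshold
  after generation.
* **ROH plants**: one haplotype copied over the other inside ≥ 0.7–1.5 Mb
  intervals of selected samples.
* **Missingness**: uniform 2% dropout.

Default scale is 2 chromosomes × 5 Mb at 1 SNP/kb with 240 samples — large
enough for 500 sliding windows and stable quantiles, small enough that the
full pipeline runs in under a minute. What passing tests show is that the
estimators and the screen recover planted structure of realistic effect
size under missingness and population structure; they do not show
robustness to features the generator omits (genotyping error, linked
background selection, pedigree relatives, uneven SNP density,
reference-allele bias).

## Numerical choices and degenerate inputs

Sites monomorphic across both groups contribute zero Weir–Cockerham
components (they cannot carry differentiation signal); windows with no
informative sites have undefined F<sub>ST</sub>/θπ-ratio and are excluded
from quantile computation; log₂ ratios are undefined when either diversity
is zero and such windows are excluded and counted. Pairs with zero dosage
variance are skipped (and counted) in r². All-missing sites fail the
missingness filter before any frequency is computed, so no division by zero
occurs. Interval sets are merged book-ended (adjacent intervals coalesce);
membership semantics are 1-based inclusive everywhere, with BED converted
at the I/O boundary. Determinism: a single integer-seeded generator drives
all simulation randomness; identical configs yield byte-identical outputs.

## Known limitations

The two-population Weir–Cockerham form is implemented (the scan's use
case); multi-population F<sub>ST</sub> is out of scope. ADMIXTURE-style
ancestry estimation, GO/KEGG enrichment, and haplotype-based scans (XP-EHH,
iHS) are deliberately not provided. The GRM is not a byte-level GCTA
reproduction, and the ROH caller is not a byte-level PLINK reproduction;
both are validated against formula oracles and truth recovery instead.
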