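# Methods

This note documents the models and conventions `hrdkit` implements, the
parameters that matter, the synthetic-data design, and the numerical
choices made where the underlying literature leaves room.

## Coordinates and inputs

All genomic coordinates are 1-based inclusive, matching the
allele-specific copy-number callers whose segment tables the package
consumes. Segments carry integer major/minor allele copy numbers
(A ≥ B ≥ 0; readers swap misordered pairs before validating). The
packaged genome build covers the 22 autosomes with GRCh38 lengths and
centromere intervals; sex chromosomes are excluded by default because
their copy-number interpretation differs by karyotype, and any custom
build file is accepted. Arms are defined as everything strictly before
(p) / after (q) the centromere interval; for arm-wise processing,
segments overlapping the centromere are split at its boundaries.

## Scar scores

Scores count maximal *runs* of equal-property segments, never raw
segments, so results are invariant to how a segmentation algorithm
fragments an event (enforced by property tests that split segments at
random points). Abutting segments are merged during preprocessing;
a coverage gap breaks a run.

- **LOH**: runs with minor copy number B = 0 whose span exceeds
  `loh_min_length` (default 15 Mb) and that do not cover the entire
  chromosome. Homozygous-deletion segments (A = B = 0) satisfy B = 0
  and are counted by default; `loh_count_homdel=False` switches to the
  dialect that requires a retained major allele.
- **TAI**: runs of allelic imbalance (A ≠ B) touching position 1 or the
  chromosome end, not intersecting the centromere interval, not
  spanning the whole chromosome, and at least `tai_min_length` long
  (default 0; some published implementations use ~11 Mb, hence the
  knob).
- **LST**: per arm, fragments shorter than `lst_smoothing` (3 Mb) are
  deleted smallest-first with equal-state neighbours re-merged across
  gaps ≤ 3 Mb, iterated to a fixed point; then every junction between
  different states with both flanks ≥ `lst_min_segment` (10 Mb) and gap
  ≤ 3 Mb counts. No ploidy-dependent adjustment is applied: the
  downstream decision uses a single HRDsum cutpoint on raw counts.

HRDsum = LOH + TAI + LST; `hrd_cutpoint` defaults to 42. All three
thresholds are configuration so alternative tool dialects can be
matched exactly.

## Variant tiers and tumor classes

Database assessments arrive pre-joined in the variant table
(`source:assessment;...`), keeping classification offline and
reproducible. Germline variants take the first listed source's verdict;
somatic variants take a unanimous verdict and fall to VUS on any
conflict. Variants listed nowhere fall back to mutation type:
frameshift, nonsense and splice-site → likely deleterious; intronic and
synonymous → polymorphism; everything else → VUS. The
likely-polymorphism tier is representable but only databases can assign
it. Homozygous deletions (any overlap between a gene interval and an
A = B = 0 segment) are deleterious by definition. TMB and TIB are raw
counts of somatic missense and small-indel records respectively — no
per-megabase normalization, since only rank information is consumed
downstream.

H-classes apply in strict priority: (likely) deleterious *BRCA1/2* →
H1a; else (likely) deleterious other-HRR gene → H1b; else *BRCA1/2*
VUS → H2a; else other-HRR VUS → H2b; else H3. The "other HRR" set is a
packaged editable list — concise (20 genes) or extended (140 symbols;
the 20 plus a placeholder seeding of DNA-damage-response genes that
users should replace with their preferred curated list). *BRCA1/2* are
never members of these lists.

## Hit typing

For a gene's deleterious alteration set, the locus state (A, B) at each
variant position defines α = A/(2·CN) and β = B/(2·CN) — the expected
VAF if the mutation rides on at least half of the major or minor
allele's copies. VAFs are divided by tumor purity and capped at 1
(division can exceed 1; a fraction cannot). The five biallelic criteria
are evaluated in fixed order, the first hit is reported; the BA/MA
outcome is order-independent. When multiple variants sit on different
segments each uses its own locus thresholds. Missing purity defaults to
1.0 with a warning. Germline events must themselves be (likely)
deleterious to enter criteria 2 and 4 (VUS-tier germline variants are
excluded by default). An exhaustive grid test checks the classifier
against an independently written literal evaluator of the criteria.

## BRCA1 promoter methylation

Status is called from the four indicative promoter CpGs (cg04658354,
cg08993267, cg10893007, cg19531713): strong if any beta ≥ 0.6, moderate
if any ≥ 0.2 but none ≥ 0.6, else unmethylated. Missing betas are
ignored; no measurable probe → unevaluable. The indicative set can be
re-derived by `select_indicative_cpgs`: probes with Spearman rho ≤ −0.3
against *BRCA1* expression at BH FDR < 10%. Hypermethylation never
changes the mutation-based H-class; it acts only at the combined
reporting stage, where strong (and, by default, also moderate —
configurable via `include_moderate_hm_in_combined`) hypermethylated
tumors join "H1a, BA/HM". Moderate inclusion is the default because the
combined class is meant to capture epigenetic *BRCA1* inactivation of
either strength; cohorts where moderate methylation is a weaker marker
can switch it off.

## Synthetic cohorts

The generator exists so every downstream step can be verified against
planted truth without external data.

*Profiles* start from a diploid (1,1) genome and plant events built
from templates whose 5 Mb buffer segments isolate the three scores: an
interior 20 Mb B = 0 core flanked by (2,1) buffers adds exactly one LOH
run and no LST junction (buffers are kept by smoothing but are too
short to qualify as junction partners); a 20 Mb telomeric (2,1) run
plus buffer adds exactly one TAI; a 15 Mb balanced step behind a buffer
adds exactly one LST junction. Events are separated by ≥ 12 Mb of
baseline with seeded jitter, placed greedily over shuffled arms, and a
clear capacity error replaces any silent overlap.

*Variant tables* realize a target (class, hit type): biallelic targets
draw one of the five criteria and place corrected-VAF targets at least
0.15 above the relevant α/β threshold so binomial read-count noise
(default depth 600) cannot flip the call; monoallelic targets use
configurations that are MA for every VAF (single somatic hit at a
heterozygous diploid locus, or a germline hit without LOH). The gene's
locus state is imposed by splicing a ± 2 Mb window around the gene into
the profile — too short to register in any scar score. Purity is drawn
uniform on [0.6, 1.0], echoing the high-purity selection of typical
reference cohorts.

*Scores* for association analyses are per-class normal draws (defaults:
biallelic *BRCA1/2* and hypermethylated tumors mean 55, other-HRR
biallelic 45, monoallelic/VUS classes ≈ 30, unaltered 25, sd 10–12) —
ordered as observed in tumor cohorts but plain configuration, not a
claim. Planted per-profile events stay small (≤ 2 per score), so
segment-derived HRDsum and the emulated score distributions are
deliberately decoupled.

What the generator does **not** emulate: subclonal copy number, caller
segmentation noise, gaps and missing data, correlated purity/ploidy
estimation errors, mutational-signature structure, or realistic
gene-level alteration frequencies. Passing round-trips therefore
demonstrate the internal consistency of the pipeline's logic, not
performance on real tumors.

## Purity dilution and copy-number re-fit

Read-level mixing is emulated at allele-count level: per heterozygous
locus, tumor reads are kept with probability f and normal reads
admitted with probability 1 − f (binomial thinning; depth preserved in
expectation), with the closed-form expected BAF
((1−p) + pB)/(2(1−p) + p·CN) and relative coverage normalized to the
within-sample length-weighted mean. Integer allele-specific copy
numbers are re-fit by grid search over purity (0.05–1.00, step 0.01)
and ploidy (1.5–5.0, step 0.05), minimizing the length-weighted squared
distance of the inverted continuous (A, B) to non-negative integers.

The family (A, B) → (A+k, B+k) with purity p/(1−p) reparametrizes the
same data exactly, so near-minimal candidates are statistically
indistinguishable; the fit resolves this by parsimony among candidates
within twice the minimal distance: ploidy closest to 2, then higher
purity, then lower ploidy. Consequently the reported purity/ploidy are
only weakly identified while integer (A, B) recovery is exact whenever
the data support it — the property the tests pin down. Defaults of
depth 100 with 150 loci per segment are conservative for array or
exome data (multi-megabase segments carry hundreds to thousands of
informative SNPs). Noiseless mode (seed `None`) rounds expected counts
and is used for exactness checks. Coverage has no GC or
replication-timing structure; the noise model is Poisson/binomial only.

The dilution analyses use 40 tumors × 10 fractions at depth 100
(~1.5 min on one CPU); the narrative driver uses 12 tumors. Both show
the same picture: exact HRDsum recovery down to tumor fraction ≈ 0.4
and a systematic downshift below, because low-purity LOH segments
(BAF → 0.5) become indistinguishable from balanced states.

## Statistics

AUC is the normalized Mann–Whitney U (pair-counting identity is
property-tested), with one-sided rank-test significance in the
direction "altered class scores higher" (the package-wide convention;
configurable by swapping groups). DeLong comparison uses the structural
components estimator. Youden cutpoints scan observed score values with
the rule "positive at score ≥ c"; ties break toward higher specificity,
then the lower cutpoint. Under leave-one-out cross-validation the refit
rule classifies each held-out sample with the cutpoint re-optimized on
the remainder; note that a held-out boundary positive is then always
misclassified, so the refit rule's cross-validated J is below 1 even on
perfectly separated cohorts — an honest property of the convention, not
a defect. Fisher exact tests default to the one-sided enrichment
alternative; Fisher's method combines strata as −2Σln p against χ²(2k);
BH adjustment spans the gene family. The gene–HRD association filter
(prevalence ≥ 5%) is computed on the analyzed (sub)cohort. The
group-shift fold change adds a pseudo-count of 1 to both means only
when the reference mean is zero.

## Known limitations

- Scar-score dialects differ between published tools (TAI minimum
  length, homozygous-deletion handling in LOH, LST ploidy adjustment);
  defaults follow the most common operational readings and every knob
  is exposed, but exact numerical agreement with a specific external
  tool requires matching its dialect.
- The purity/ploidy grid fit assumes the segmentation is known and the
  contaminating normal is diploid; it is a desk-scale stand-in for full
  segmentation-and-fit pipelines, adequate for studying purity bias but
  not a replacement for them on real data.
- The 140-gene extended list ships as an editable placeholder seeding;
  analyses that depend on the precise membership of the extended HRR
  set must substitute a curated list.
- Type-I error of the rank test is verified at the 5% level under
  continuous null scores; heavily tied score distributions shift the
  attained level as usual for rank tests.
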