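# Methods

`hgtscan` implements a screen for host-to-tumor horizontal transfer of
nuclear DNA in clonally transmissible cancers, together with the validation,
dating, haplotype-inference and expression analyses that characterise a
detected element, and a synthetic-cohort generator that makes every stage
verifiable at desk scale. This note records the models, the parameters that
matter, and the design choices made where the design was genuinely open.

## The detection problem

A transmissible cancer propagates the germline genome of one long-dead
founder animal through every tumor of the lineage. Against this clonally
frozen background, DNA captured from a transient host is visible as a
haplotype that no tumor should carry: at germline SNPs where the founder is
homozygous but the donor carries the other allele, tumors bearing the
transferred copy appear heterozygous. A *flipping SNP* is a site whose
per-tumor genotype state conflicts with the lineage consensus; an extended
run of hom→het flips confined to a subset of tumors is the screen's
elementary signal. The screen is restricted to regions of copy number ≥ 2
that retain both founder homologues (evidenced by consensus
heterozygosity): a transfer replacing a haplotype in a region that has lost
heterozygosity is indistinguishable from simple LOH and is out of reach by
construction.

## Genotype states under purity and copy number

A biopsy mixes cancer cells (purity `p`) with diploid host cells. At a
biallelic site with cancer copy number `c`, cancer alternate dosage `k` and
host alternate copies `h`, the expected alternate-read fraction is

    q(k) = (p·k + (1−p)·h) / (p·c + 2·(1−p))

Genotypes are called by maximising the binomial likelihood of the observed
read counts over `k = 0..c` (confidence = log-likelihood gap between the two
best dosages), rather than by fixed VAF cutoffs; the likelihood rule
generalises across copy number and purity. Host dosage comes from the
matched host's reads (2·VAF rounded to {0, ½, 1}); sites below 15× depth,
with copy number < 2, or with unresolvable host dosage are missing.
Consensus per site is a strict majority of non-missing hom vs het calls,
undetermined on ties or when fewer than 80% of tumors have calls. The
purity correction `correct_vaf` inverts the mixture exactly:
`(VAF·D − 2(1−p)·g_h)/(p·c)` with `D = p·c + 2(1−p)`, clamped to [0, 1].

## Window screen

Hom→het flips are counted in non-overlapping 100-kb windows tiling the
screened segments (≥ 100 windows required genome-wide). A window is flagged
for a tumor when two statistics agree:

* a robust z-score `0.6745·(x − median)/MAD` of the tumor's genome-wide
  window counts exceeds 3.5. When the MAD is zero (the typical case — most
  windows carry no flips) the z-score is replaced by a Poisson upper-tail
  test at α = 10⁻³ against a background rate estimated from the fraction of
  zero-count windows (`λ = −ln P₀`). The zero-fraction estimator is robust
  to the minority of true-signal windows, which would inflate a plain mean
  and mask the very signal being sought.
* the window's Cook's distance exceeds 4/n in an OLS regression of the
  tumor's window counts on the cohort-median window profile. The regression
  model is not specified by the original description; regressing each tumor
  on the cohort median isolates tumor-specific excess from positional
  artefacts shared across the cohort. Cook's distance uses the closed form
  for the two-parameter model (validated against statsmodels in the test
  suite) and degrades to the intercept-only model when the median profile
  has no variance.

Runs of ≥ 3 flagged windows (bridging gaps ≤ 500 kb) become candidate
regions. Only hom→het flips seed regions; het→hom flips are reported but
carry no transfer signature. All thresholds are configuration-exposed.

The Cook's filter assumes outliers are a minority of windows, so validation
cohorts keep the planted element a small fraction of the simulated genome
(a 5.5-Mb block in a 100-Mb genome, ~1,000 windows).

## Hallmarks of horizontal transfer

Three lines of evidence validate a candidate region against the
alternative — duplication of a parental chromosome:

1. **Integer copy-number step.** Modal copy number per segment must be
   exactly one state higher in flagged tumors than in the rest; ties are
   indeterminate and fail the hallmark.
2. **Somatic-VAF pattern.** In carrier regions of copy number 3, each
   somatic mutation's reads are scored under dosage 1/3 vs 2/3 (binomial
   likelihoods at the purity-adjusted mixture). Mutations predating a
   duplication ride 2 of 3 copies; a transferred haplotype arrives free of
   the cancer's mutations, so the hallmark passes when < 5% of ≥ 10
   mutations favour 2/3.
3. **Per-copy mutation-density deficit.** Mutations per 10-kb window per
   chromosome copy inside the region are compared with an equal number of
   immediately flanking windows (split half per side, truncated at
   chromosome ends and at other candidate regions, topping up from the
   other side and flagging imbalance) by Welch's two-sided t-test. Window
   counts are matched rather than lengths; Welch rather than pooled
   variance — both choices where the original description is silent.

A recent duplication mimics both the copy-number step and the density
deficit (the new copy is young either way); the VAF pattern is the
discriminating hallmark, which is what the duplication-decoy simulations
exercise.

## Chain assembly

Step segments are the blocks of the transferred element; structural-variant
junctions pair their ends (breakend side 'left'/'right', encoded in BEDPE
strands as −/+; matching tolerance ±5 kb, since copy-number breakpoints are
window-resolution; minimum junction support 3 reads). From a seed terminus
the walk alternates segment traversal and junction hops; a block is '+'
when entered through its left end. Branching breakends raise an error
listing the ambiguous ends; returning to the start marks the element
circular. Termini are labelled centromeric when within 500 kb of position 0
(the study species' chromosomes are acrocentric) and telomeric near the
chromosome end when lengths are known. The published element's topology
(11 blocks, 6 chromosomes, ~15 Mb, centromere-to-centromere) is packaged as
a synthetic fixture for regression testing; the real junction table is an
external supplementary dataset.

## CpG clock dating

C>T mutations at CpG dinucleotides accumulate at a near-constant rate per
site per year per chromosome copy (default diploid rate 6.87×10⁻⁷, i.e.
3.435×10⁻⁷ per copy). In *step segments* — non-carrier modal copy number in
{0, 1, 2}, carrier modal exactly one higher — the parental per-copy (C>T)G
density is measured per 1-kb bin in non-carrier tumors; the expected
parental mass is subtracted from each carrier's bin counts, and the mean
residual per CpG site is the transferred copy's density `d_h`. Age =
`d_h / r` with a 95% CI propagating the SE of `d_h` taken across carrier
tumors (not bins): the transferred copy's mutations are private to each
carrier, so the across-carrier spread is the calibrated uncertainty,
whereas truncal mutations are shared by carriers and non-carriers alike and
cancel exactly in the subtraction. Negative residuals are retained as
counting noise; only the final reported mean is clamped at zero. The
published "range" is computed across per-carrier means (whether the
original range is across tumors or bins is unstated; per-carrier is noted
in the output).

## Haplotype inference

Within step segments, the parental alternate dosage `a_p` at a biallelic
site is the modal ML dosage among non-carriers. Each carrier's reads are
scored under alternate dosage `a_p` vs `a_p + 1` (the transferred copy
carrying reference vs alternate) at the purity-adjusted mixture for copy
number `c_p + 1`; log-likelihoods sum across carriers, and calls with
|Δlog L| < 3 (a strong-evidence convention) are undetermined, as are sites
with inconsistent carrier copy number. A likelihood comparison was chosen
over hard count subtraction for robustness to read noise; the default
transversion-only filter mirrors the downstream population-genetic use of
the inferred haplotype (transitions overlap the dominant somatic mutation
classes).

## Allelic expression deconvolution

An allele is informative for one of {transferred element, cancer parental
chromosomes, infiltrating host} when exactly one source carries it in that
tumor's genotype configuration. Informative read counts are normalised by
median-of-ratios size factors computed in-module from the per-gene count
matrix, divided by the allele's copy number in its source, and pooled per
(gene, source) across tumors with SEM-based 95% CIs; genes need ≥ 5
informative reads. Source programs are compared per gene by least-squares
regression and Pearson correlation. Per-copy values are defined up to one
common normalisation constant — all cross-source comparisons are ratio- and
correlation-based, which that constant cannot affect.

## The synthetic cohort generator

`simcohort.simulate_cohort` draws, deterministically per seed:

* **Samples.** 47 tumors by default, split 7 (carrier clade) / 40, each
  with a matched host; purity uniform on (0.7, 0.95); mean depth 77×
  (cohort-scale medians).
* **Germline panel.** Biallelic SNPs at mean 2-kb spacing (1 kb in screen
  validation runs, the density of heterozygous sites in dog genomes);
  founder heterozygous with probability 0.3, otherwise hom-ref/hom-alt
  equally; transition:transversion 2:1. Matched hosts are independent
  draws from the same panel distribution — an exchangeable-population
  simplification.
* **Donor haplotype.** Per site the donor's haploid allele copies a random
  founder allele and is redrawn uniformly from the two panel alleles with
  probability 0.3 (`donor_divergence`); no explicit donor population model
  is attempted, because the screen responds only to allelic difference.
* **Copy number and junctions.** Baseline CN 2; carriers gain +1 inside
  the planted blocks (11 blocks on 6 chromosomes by default, mirroring the
  real element's structure at reduced scale); BEDPE junctions encode the
  planted chain with Poisson-distributed read support.
* **Somatic mutations.** The clonal genealogy is a trunk (lineage age
  6,433.6 y by default, so that the parental per-copy CpG density equals
  the published non-carrier value at the published rate), a clade split at
  2,000 y, a star within each clade (an optional clade-stem branch is off
  by default), and a transferred copy acquired 2,000 y ago that starts
  mutation-free. CpG C>T events are explicit, positioned by CpG weight in
  1-kb bins (CpG sites per bin ~ Binomial(1000, cpg_fraction); default
  cpg_fraction 0.01 ≈ 10 CpG/kb, mammalian scale; 0.05 in dating runs for
  estimator precision), shared correctly along the tree, and read-sampled
  per tumor. Non-CpG mutations enter as per-bin Poisson aggregates without
  shared structure — only window densities consume them, and event-level
  simulation at realistic densities (2.2×10⁻³/site) would be millions of
  rows for no analytical gain. Mutations are tracked only inside the
  planted blocks plus flanking margins (0.6 block lengths per side), which
  is where every downstream analysis reads them.
* **Duplication decoy.** `decoy_duplication_years` replaces the donor
  haplotype with a duplicated parental homologue of the stated age:
  the same copy-number step, pre-duplication mutations at dosage 2/3, and
  an extra-copy mutation load matching the duplication age.
* **RNA.** 73 element genes (3 exonic variant sites each) and 1,500
  background genes outside the element; per-copy expression is lognormal
  across genes, with the transferred copy following the cancer program and
  host infiltrate an independent program; counts are Poisson around
  size-factor-scaled expectations with per-(gene, site, tumor) lognormal
  biological noise (σ = 0.3), giving bulk-RNA-seq-like overdispersion. The
  background transcriptome exists so that median-of-ratios size factors
  are not biased by the element's extra copy, as in real data where the
  element is < 1% of genes.

### What the generator does not emulate

Sequence-level reads, realistic karyotypes, mutational-signature
composition (only a CpG flag is modelled), sub-clonal copy number,
multi-allelic sites, linkage structure in the donor population, and
within-clade phylogenetic resolution (the star approximation). Tests
passing on these cohorts therefore demonstrate the estimators' correctness
under the stated generative assumptions, not performance on real alignments
or callers — variant calling, copy-number estimation and SV calling are
upstream of this package by design.

## Validation problem sizes

The packaged presets (`hgtscan.presets`) pin the cohort structure and scale
the free quantities per check: screen recovery uses 50 replicate 47-tumor
cohorts on a 100-Mb genome; dating recovery uses 20 replicates with
~5.6×10⁵ CpG sites in step segments (recovery-vs-nominal precision is
limited by shared ancestral Poisson noise, which shrinks with CpG count —
the across-tumor SE cannot see trunk-realisation noise, so the parental
check uses an analytic Poisson-propagation SE); expression checks pool
genes over 4 replicate cohorts and test per-gene HT-vs-cancer consistency
by Welch tests at the 1% level among genes with ≥ 3 informative
observations per source (SEM CIs from 1–2 points are degenerate and would
make any overlap check meaningless).

## Numerical choices and degenerate inputs

Binomial log-likelihoods drop the dosage-independent `log C(n, k)` term and
clip success probabilities to [10⁻⁹, 1−10⁻⁹]; modal-state ties are
indeterminate everywhere rather than broken arbitrarily; zero-CpG bins and
parental-CN-0 segments are excluded from the clock; MAD-degenerate tumors
use the Poisson fallback above; zero-size-factor samples are excluded with
a warning; empty chains and non-positive rates raise configuration errors.
Age is reported rounded to the nearest year with the raw float retained.

## Known limitations

The screen cannot detect transfers into LOH regions or transfers that do
not alter copy number in regions lacking retained heterozygosity; the
dating estimator assumes the carrier and non-carrier parental chromosomes
share a mutation density; the haplotype caller assumes one consistent extra
copy across carriers; and the pipeline treats segmentation as shared across
samples (the upstream copy-number caller's convention).
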