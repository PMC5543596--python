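# Methods

## Polarization model

A 1–5 bp indel on the human lineage is inferred from an 8-species
alignment block (human reference plus seven primate outgroups) by
requiring one identical ancestral allele in all seven outgroups over the
event columns. The rationale is homoplasy control: small indels recur at
appreciable rates in repeat-rich contexts, and a single outgroup sharing
the human state is enough to flip the inferred ancestral state and hence
the event type. Requiring seven concordant outgroups trades sensitivity
(sites must be alignable and stable across ~40 My of primate evolution)
for polarity reliability; calls are therefore biased toward conserved,
non-repetitive sequence, and all downstream contrasts inherit that bias.

Blocks missing any species are dropped; blocks whose human row is on the
'-' strand are reverse-complemented on ingestion so every emitted
coordinate is on the '+' reference strand. Positions follow the VCF
anchor convention: the 1-based coordinate of the base immediately left
of the event, with unanchored event alleles (a deletion stores the
deleted bases as its ancestral allele and an empty derived allele).

### Gap normalization

Within a repeat tract a gap run has several equivalent placements; calls
are canonicalized to the leftmost placement, matching VCF left-alignment
so reference-scan calls merge with cohort records by coordinate. The
shift rule moves a gap run one column left when the base that would slide
across the run equals the counterpart row's base at the run's right edge
(the human row acts as counterpart for outgroup gaps and the first
outgroup for human gaps); this is iterated to a fixpoint together with
all-gap-column removal, making the operation idempotent and leaving
every row's ungapped sequence unchanged. The rule canonicalizes
period-1 (and by iteration most short-period) repeat placements; exotic
longer-period equivalences are left where the aligner put them.

### Rejection taxonomy

Rejections are data, not errors: `outgroup_disagreement` (ungapped
outgroups carry different alleles), `mixed_gap_base` (gap and base
states mixed across species — the signature of a homoplasic indel in one
outgroup), `ambiguous_base` (N or soft-masked base in the event
columns; masked bases signal repeat or low-quality sequence, so calls
there are not trusted), `too_long` (> 5 bp), `complex_region` (another
gap run within one column; adjacent events cannot be decomposed into
single clean indels), `block_edge` (no anchoring base to the left),
and `contradictory_overlap` (overlapping blocks yield conflicting
calls at one position; both are dropped).

## Stratification

Cohort indels are restricted to biallelic, non-symbolic records with an
allele-length difference of 1–5 bp; multiallelic sites are dropped
because more than one derived state makes polarity ambiguous. The VCF
allele matching the 7-outgroup consensus becomes ancestral; the rule is
invariant under REF/ALT swap. Reference-scan calls absent from the
cohort are fixed; cohort records win as polymorphic when present, and
cohort variants at derived frequency 1.0 in every population are
promoted to fixed. Missing genotypes are excluded from frequency
denominators.

Archaic sharing needs at least one archaic copy of the derived allele
(heterozygous counts as shared: a het Neandertal demonstrably carries
the derived allele). Sites absent from the archaic VCF or with a
missing genotype are `uncovered` and excluded from shared-vs-specific
contrasts rather than guessed. The introgression rule is deliberately
rule-based, not probabilistic: derived allele count exactly 0 across the
configured sub-Saharan African populations, derived frequency > 0 in the
EUR or EAS superpopulation, archaic carrier. Admixed superpopulations
(AMR/SAS) do not enter the rule but keep their frequency columns. This
intentionally trades recall (true introgressed alleles that drifted into
Africa, or back-migrated, are missed) for precision.

## Selection statistics

* **MK-style contrast.** Rows are an older and a younger variant class,
  columns deletion/insertion counts. Both row ratios (rDI) estimate the
  deletion:insertion mutation-rate ratio under neutrality, so the Fisher
  exact test on the table is a test of differential selection, not of
  mutation bias. The two-sided p sums hypergeometric probabilities of
  tables at most as probable as the observed one (with the customary
  1+1e-7 slack), accumulated with log-sum-exp so p-values of genome-scale
  tables are reported as finite log₁₀ p rather than 0.0. Both the sample
  odds ratio ad/bc and the conditional-MLE odds ratio are reported; at
  the table sizes of interest they agree to four decimals.
* **AFS comparison.** Two-sided Wilcoxon rank-sum with mid-ranks,
  tie-corrected normal approximation and continuity correction for
  realistic sample sizes; an exact permutation null (full enumeration)
  is used automatically when the pooled sample is ≤ 24, where the normal
  approximation is unreliable. Spectra are binned into 20 equal-width
  frequency bins for plotting only; tests use unbinned frequencies.
* **Region enrichment.** Per region class and class pair, a 2×2 of
  in/out-of-region counts; all raw p-values across regions and contrasts
  are Benjamini–Hochberg adjusted as one family. The 95% CI is the Wald
  interval on the log sample odds ratio. Tables with an empty cell are
  flagged degenerate and excluded from the adjustment.
* **Category contrast.** Each gene category is a two-sided binomial test
  of its class-A count against the global class-A proportion, Bonferroni
  controlled. This replaces a full graph-aware GO refinement with a flat
  contrast; it ignores the GO DAG structure and is documented as a
  simplification.
* **F_ST.** Hudson's estimator in the Bhatia et al. ratio-of-averages
  per-site form, clipped to [0,1]; used only for ranking introgressed
  variants by EUR/EAS differentiation. The estimator choice is a
  convention, labeled as such.
* **C-score filter.** Candidates require a phred-scaled deleteriousness
  score ≥ 20 (top 1% of variants); the threshold is inclusive and
  duplicate score rows keep the maximum.

## Introgression analyses

* **ILS length test.** P(length ≥ m) = (1 + m/L)·exp(−m/L) with
  L = 1/(r·t): the tract extends independently left and right of a focal
  point with exponential(L) lengths, so total length is Gamma(shape 2,
  scale L). Defaults: r from the local recombination map (cM/Mb × 1e-8
  per bp per generation), t = 19,000 generations (≈550 ky at 29
  years/generation, consistent with the archaic–modern split); t is an
  assumption, exposed as a parameter, not an estimate produced here.
* **Shared extent.** Carriers of a focal introgressed variant each
  define a maximal contiguous run of introgressed variants they carry;
  the shared region is the intersection of carrier runs and its length
  spans the outermost variants inside it. Unphased dosages stand in for
  haplotypes (a carrier of ≥1 copy counts), which can only widen runs
  relative to true phased haplotypes; this is a documented limitation.
* **Perfect LD.** Two dosage vectors over the same individuals are
  perfectly linked iff identical after orienting the SNP to the indel's
  derived allele (x or 2−x). Any missing genotype excludes the SNP —
  imputing would manufacture linkage. GWAS pairing scans a 1 Mb window
  and keeps associations with p ≤ 1e-5.

## Synthetic data

The generators emulate the statistical structure the pipeline relies on,
at desk scale:

* Alignment: per-block ancestral sequence, planted events at ≥ 12 bp
  separation (so no event is rejected as `complex_region` by
  construction), event lengths uniform on 1–5, deletion:insertion 2:1,
  outgroup substitution noise (0.5%/bp) away from event columns.
  Events are left-normalized at generation time — the base left of each
  event is forced to differ from the event's final base — so truth
  coordinates equal post-normalization call coordinates exactly.
  Homoplasic events copy the human state into one random outgroup.
* Cohort: 100 individuals per superpopulation (AFR/EUR/EAS, two
  populations each) by default; background site frequencies follow a
  discretized 1/x spectrum (the constant-size neutral expectation —
  the analysis only measures the spectrum, so a simple neutral shape
  suffices); sites are independent apart from planted haplotypes.
  Introgressed haplotypes are 200 kb runs of derived variants on a
  jittered ~2 kb grid, carried by the archaic sample and by EUR/EAS
  chromosomes at targets 0.027/0.048, absent from Africans. The grid
  keeps the first and last variant within about half a spacing of the
  haplotype ends, giving shared-extent recovery a known error scale of
  roughly one spacing. Archaic-shared background sites are forced to
  carry ≥ 1 African derived allele so the planted introgression truth is
  exact by construction, which is what makes sensitivity/specificity
  = 1.0 a meaningful pipeline check rather than a statistical accident.
* MK tables: binomial draws with polymorphic deletion proportion
  ρ/(ρ+1) and fixed proportion ρ·s/(ρ·s+1) for rate ratio ρ and
  fixation-probability ratio s.

What passing these tests shows — and does not. Exact planted-truth
recovery demonstrates the calling, merging and rule logic, not
performance on real data: the simulator has no alignment error, no
genotyping error, no background linkage, no recurrent mutation outside
the planted homoplasies, and clean left-alignable repeat contexts. Real
data adds all of these, so genome-scale counts and rates cannot be
reproduced from synthetic fixtures and are not asserted anywhere.

## Problem sizes and numerics

Test and acceptance runs use 500 planted alignment events across five
5 kb blocks, cohorts of 300 individuals with ~900 sites, 2,000 replicate
MK tables at n = 2,000 per class for type-I calibration and n = 1e5 for
rDI convergence — sizes chosen so every distributional check has
negligible Monte-Carlo noise at desk scale. Degenerate inputs: a 2×2
with a zero margin returns p = 1 with a warning; rDI requires a positive
insertion count; divergence requires a positive total; FST is undefined
when both populations are monomorphic. All randomness flows through
`numpy.random.default_rng(seed)`; identical configurations produce
byte-identical output files.
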