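# Methods

This note documents the statistical procedures, the synthetic-data model, and
the numerical/design choices in `scerpop`, at the level of detail a user needs
to judge what the package's passing tests do and do not demonstrate.

## Cohort model

The unit of analysis is a diploid isolate carrying biallelic SNP genotypes
(alt-allele dosage 0/1/2, missing allowed) at positions on a reference
genome.  Isolates are organised hierarchically: population (wild vs
domesticated) → group (Wild, LSF, SSF) → lineage (e.g. Wine, Mantou).  All
group-level statistics are driven by this sample sheet; the genotype matrix
itself carries no labels.

## Variant QC cascade

Order: caller consensus → depth bounds → allele read support → matrix
assembly → missingness.  MAF and LD filters are applied separately, only
ahead of structure analyses (PCA), mirroring the usual practice of building
trees from the full post-missingness SNP set but pruning for
PCA/ADMIXTURE-style methods.

Boundary semantics, fixed and tested exactly:

- depth ≥ `min_coverage` (15 reads) kept; depth strictly greater than
  `max_depth_fold` (4) × the isolate's mean depth removed — 4× exactly kept.
- homozygous calls kept when called-allele reads / (ref+alt reads) ≥ 0.80;
  heterozygous calls kept when the *minor* of the two allele read counts is
  ≥ 0.20 of ref+alt (symmetric reading: both alleles need support).  The
  denominator is ref+alt, not total depth, so reads on third bases do not
  dilute the rule.  Entries with zero informative reads become missing
  rather than being silently dropped.
- missing fraction ≤ 1% kept; MAF ≥ 0.01 kept (inclusive-keep on both,
  because the removal side is what the thresholds state).
- caller consensus requires the identical non-missing genotype at the same
  (isolate, site), not mere co-location.

LD pruning slides a 50-SNP window by 5 SNPs over the *retained* sites; within
a window, while any retained pair has r² > 0.5 (squared Pearson correlation
of dosage vectors over pairwise-complete isolates), the pair member with the
lower MAF is removed (tie: later position).  Sweeps repeat until no window
removes anything, so the retained set is a fixpoint and the filter is
idempotent — re-running it never removes more sites.

## Heterozygosity and diversity

The per-isolate heterozygosity statistic is the count of heterozygous SNP
genotypes divided by the isolate's consensus (callable) genome size in bases.

π and θ_W are normalised by a user-supplied surveyed genome length L
(default 12,071,326 bp, the S288c reference scale), not by the SNP count:
the reported quantities are per-genomic-site, which is what makes values on
the 10⁻³ scale comparable across cohorts.  For each population/group/lineage
only sites genotyped in ≥ 80% of its isolates enter (`NumNuc`, the fixed
minimum sample size); θ's harmonic number uses the fixed allele count
n₀ = 2·NumNuc rather than the per-site called-allele count.  This mirrors
fixed-sample-size estimator semantics; with low missingness the difference
from a per-site harmonic number is well below other sources of error, and
the choice is deliberately documented rather than configurable.  Diploids
contribute two alleles per site; heterozygotes one of each.

## RRHS consensus phylogenomics

Assumption: no phase information exists in a SNP matrix, so heterozygous
sites are resolved independently per site (ref or alt with probability ½).
Per replicate, p-distances (mismatches over pairwise non-missing sites) feed
neighbor joining.  Negative NJ branch lengths are clamped to zero with the
deficit shifted to the adjacent branch of the join, preserving path lengths.
Splits present in > 50% of replicates form the consensus; support is the
occurrence percentage, internal branch lengths are means over the replicates
containing the split, and terminal branch lengths are means over all
replicates.  The per-replicate engine is pluggable (`tree_builder=`): the
consensus machinery does not care how replicate trees are inferred, and a
likelihood-based engine could be substituted without touching the summary.

Haplotype resolution draws from a stream keyed by (seed, replicate, isolate
name), so consensus supports are exactly invariant to the column order of
the input matrix.

Sampling-fairness, split-tabulation correctness, and the reps = 1 identity
are tested against independent oracles (binomial bounds, dendropy-parsed
replicate newicks).

## Pan-genome

Presence of a catalog ORF in an isolate requires an alignment record with
identity ≥ 95% and aligned length ≥ 75% of the catalog ORF length (coverage
capped at 1; gapped alignments can exceed the query length).  Both
boundaries are inclusive and configurable; the prose around such thresholds
is usually ambiguous ("over 95%") and the inclusive reading was chosen
because the same sources restate them as thresholds.  The coverage
denominator is the catalog (query) ORF length.  Group-majority detection is
strict on both sides (> 0.90 and < 0.10) as the printed inequalities state.
Gene-content dimension reduction ships as PCA (deterministic up to sign);
t-SNE-style embeddings are presentation-only and out of scope.

## Allele scan

Pipeline order is fixed: sharing filter (alt allele carried by ≥ 1% of all
isolates) → seeded uniform subsample without replacement (an explicit error,
never a silent take-all, when fewer sites are available) → per-lineage
presence filter (≥ 80% of every lineage genotyped) → detection.  "Carrying"
an allele means possessing ≥ 1 copy, so a heterozygote carries both alleles —
important because domesticated isolates are frequently heterozygous at
exactly the discriminating sites.  An allele is specific to group A when its
carrier fraction among A's genotyped isolates is > 0.90 while B's is ≤ 0.90
(the complement of the strict rule).  SNP positions are 1-based; gene
intervals are half-open 0-based [start, end), so position p maps to a gene
iff p − 1 ∈ [start, end).

## Enrichment

Raw p-values are upper-tail hypergeometric probabilities P(X ≥ k) with
universe N, term size K, query size n, overlap k.  "Corrected P" is
Benjamini–Hochberg by default (Bonferroni available); significance at
corrected P < 0.01.  The gene universe defaults to the supplied annotation's
genes and is overridable (e.g. to the full pan-genome).  Kappa is Cohen's
chance-corrected agreement of the two membership indicators over the
universe; degenerate marginals (expected agreement 1) define kappa = 0, and
negative kappas are floored at 0 only for network edge weights.  Edges
require kappa strictly above 0.3.

## Synthetic cohort generator

What it emulates: a wild population of near-homozygous isolates and two
domesticated groups with elevated heterozygosity; lineage substructure within
groups; planted group-specific and lineage-specific SNP alleles and ORF
content; per-site read support from two callers; uniform missingness.

Default study conditions: 3 groups × 4 lineages × 10 isolates, 5,000 SNP
sites on a 45,000 bp surveyed genome, heterozygous-site rates 0.005% (wild)
and 0.143% (domesticated) of the genome, 2% missingness, 50 planted
group-specific sites per domesticated group, mean sequencing depth 184×
(negative binomial, dispersion 30), base error rate 0.2%.

Model choices, and why:

- **Scaled genome.** 5,000 sites on 45 kb keeps the ratio of heterozygous
  sites to SNP sites near the real-data scale (~1.2% of SNP sites
  heterozygous per domesticated isolate).  A much larger genome-to-SNP ratio
  would make heterozygote flips dominate carrier fractions and distort every
  frequency-threshold operation.
- **Exact background carrier counts.** Non-planted sites realise per-group
  carrier counts exactly from frequencies clipped to [0.2, 0.8] (group
  effects: normal with SD 0.25 around a shared uniform base frequency;
  lineage skew: Dirichlet-weighted carrier assignment within groups).  This
  guarantees that only planted sites can satisfy the > 90% group-specific
  rule, which is what makes precision against the truth tables a meaningful
  quantity.  The clipping sacrifices the extremes of a realistic site
  frequency spectrum for an unambiguous ground truth.
- **Heterozygosity by flipping.** Per isolate, a binomial number of genome
  sites (rate × genome length) is flipped from homozygous to heterozygous.
  This plants exactly the statistic the pipeline measures; it is not a
  mating or coalescent model.
- **Consensus genome sizes.** Emitted as genome_length × (1 − missing rate):
  an isolate's consensus genome excludes uncallable positions, which keeps
  the heterozygosity-ratio estimator unbiased for the configured rate.
- **Lineage-specific alleles at low frequency** (30% of the host lineage):
  near-fixed exclusive alleles would make the *reference* allele
  group-specific between the domesticated groups and conflate the two
  planted signals.
- **Depth 184×** is the real sequencing scale for such cohorts; with
  dispersion 30 the probability of a site falling below the 15-read floor is
  negligible, so the noiseless cascade-conservation property does not hinge
  on a lucky seed.
- **Independent sites** by default; `ld_block_size > 1` copies allele
  patterns across blocks of consecutive background sites to give LD pruning
  real structure to remove.
- **ORF evidence.** Present ORFs get alignment records with identity ≥ 97%
  and coverage ≥ 90%; absent ORFs get no record (70%) or a decoy below both
  thresholds (30%).  Variable (non-planted) ORF content realises clipped
  per-group frequencies in [0.25, 0.75] exactly, again so only planted ORFs
  can reach the group-majority rule.

What the generator does **not** emulate — and hence what passing tests do not
show about real data: recombination and linkage disequilibrium from shared
ancestry, a realistic site-frequency spectrum, sequence-level reads (FASTQ),
batch- or lineage-structured missingness, reference bias, introgression from
sister species, and caller-specific error modes.  Recovery rates of 1.0 on
planted structure certify the *operations*, not expected performance on real
cohorts, where the discriminating signals are weaker and the thresholds
interact with demography.

## Numerical details

- Genotypes are int8 dosages with −1 as missing; all filters are vectorised
  and remove rows only — genotype values are never edited, except the
  zero-informative-reads rule which sets entries missing.
- Pairwise-complete r² is computed by masked matrix products; pairs with
  fewer than 2 shared isolates or zero variance get r² = 0.
- PCA uses the full SVD (deterministic up to component sign); missing
  dosages are imputed to the site mean before centring.
- NJ pair selection takes the first minimum of the Q-matrix in row-major
  order; together with the lower-MAF/later-position LD tie-breaks, every
  pipeline stage is deterministic given its seed.
- Subsampling and haplotype resolution derive generators from
  `numpy.random.SeedSequence`; seeds are masked to 31 bits.

## Known limitations

- θ with fixed NumNuc slightly differs from a per-site-n estimator when
  missingness varies strongly across sites.
- The LD pruner is a faithful windowed r² pruner but is not guaranteed to
  reproduce any external tool's removal order; only the retained-set
  invariant (no within-window pair above r²) is contractual.
- `consensus_sites` compares genotypes only; callers disagreeing on the alt
  allele at a biallelic site are not distinguished from genotype mismatches.
- Multiallelic sites and indels are out of scope throughout.
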