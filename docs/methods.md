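# Methods

This note documents the models, estimators and numerical choices in
`panelforge`, and what the synthetic-data generator does and does not
emulate.

## Genotype representation

Genotypes are additive dosages of the alternate allele: 0/1/2 for
diploids, {0, 2} for haploids, with a single MISSING sentinel (−1).
Haploids share the diploid dosage scale so one matrix holds both; a
dosage of 1 at a haploid sample is *representable on purpose* — it is
the artifact signal (collapsed paralogs, call errors) that the
curation filters consume, never a real genotype. Coordinates are
1-based as in VCF; exclusion windows are inclusive at both endpoints.

On VCF read, diploid `0/0, 0/1, 1/1, ./.` map to 0/1/2/MISSING and
haploid `0, 1, .` to 0/2/MISSING. Because both single-allele and
homozygous-diploid encodings of haploids occur in the wild, the reader
accepts either when the haploid samples are declared (argument or the
writer's own header annotation); undeclared arity mixing within one
sample is an error. Artifact haploid hets are written as `0/1` so a
write/read cycle is the identity on calls and ploidy.

## Synthetic-data generator

The generator produces every structure the pipeline consumes. All
generators are pure functions of (config, seed); artifact injection
composes in the fixed order paralogs → errors → missingness, and truth
labels are keyed by ids so they survive composition.

**Population model.** Frequency-based models (`uniform`, `fixed`)
draw an allele frequency per locus and genotypes as Binomial(2, p) —
exact HWE. The `neutral` model instead draws each locus's *minor
allele count* from the folded neutral class weights
(1/i + 1/(n−i), halved at i = n/2) at the sample's chromosome count n,
and places the alleles uniformly at random among chromosomes before
random pairing into diploids. Random placement conditional on an
allele count is exactly the HWE distribution conditional on that
count, so the HW exact test retains its null behaviour, while the
realized folded spectrum equals the neutral expectation up to
multinomial noise. Drawing a continuous frequency and re-sampling
binomially would smear the count classes and no longer reproduce the
finite-sample neutral spectrum, which is the property the
ascertainment diagnostics are tested against.

**Structure.** Two-population draws follow the Balding–Nichols model:
population frequencies are Beta-distributed around the ancestral
frequency with variance p(1−p)F_ST. As F_ST → 0 this converges to the
panmictic model (verified by a Kolmogorov–Smirnov check in the tests).

**Crossing design.** The default family layout is 10 full-sib
families with 18 distinct parents and 135 offspring (family sizes
14×5 + 13×5), where families f01/f09 and f06/f10 each share one
parent — the structure that produces parent–offspring, full-sib,
half-sib and unrelated pairs simultaneously. Offspring receive one
allele per locus from each parent, independently across loci (loci
are unlinked; no recombination map is modeled). Haploid
megagametophytes are single maternal meiotic products: one allele of
the mother per locus.

**Paralog collapse.** Two modes. `fixed` models the classic spurious
SNP: a fixed difference between two collapsed genomic copies, so every
sample — any ploidy — carries both alleles and is called heterozygous.
This single mode produces both diagnostic signatures at full strength
(haploid het calls with probability 1; diploid genotype counts
(0, n, 0), for which the HW exact p-value is astronomically small for
n ≥ 50). `segregating` gives the hidden copy its own HWE genotype at a
configurable frequency and calls the superposition of the two copies'
allele sets, producing partial signals. Real per-source paralog rates
are not well characterized; the default `paralog_fraction` of 0 means
tests opt in explicitly, and any nonzero choice in examples is
illustrative, not calibrated.

**Error model.** Each non-missing call is independently replaced with
probability `error_rate` by a uniform draw from the sample's valid
call space ({0,1,2} diploid, {0,2} haploid). The draw may coincide
with the original call, so the realized flip rate is 2/3 (diploid) or
1/2 (haploid) of the nominal rate, and the expected discordance
between two replicates is 1 − (1 − 2e/3)² − 2(e/3)² for diploids.
This is the simplest model consistent with symmetric replicate
discordance; it has no allele-frequency or cluster-geometry
dependence, so error structure specific to intensity-based calling
(e.g. hom→het asymmetries) is not represented.

**Ascertainment.** A discovery panel of configurable size is drawn at
random; loci polymorphic in the panel with panel-MAF ≥ threshold are
retained. This reproduces both observed consequences: depletion of
rare frequency classes in non-panel samples, and panel members
becoming atypical in PCA of the ascertained loci.

**What the generator does not emulate.** Linkage between loci,
realistic gene-dropping along chromosomes, intensity-space cluster
calling (OTV classes, dQC), batch/plate effects, and null alleles.
Passing tests therefore demonstrate correctness of the estimators and
filters under the stated models, not robustness to every failure mode
of real array data.

## Statistics

**HW exact test.** The standard two-sided conditional exact test (no
mid-p): enumerate all heterozygote counts h with the observed allele
counts and parity, weight each by the conditional probability
∝ n!/(n_AA! h! n_aa!)·2^h, and sum the probabilities ≤ that of the
observed h. Probabilities are computed in log space via `gammaln` and
normalized over the support; a relative tolerance of 1e−9 guards
floating-point ties between configurations of equal weight.
Monomorphic counts give p = 1, so the p-value is always in (0, 1].
A vectorized form groups loci by (total, rare-allele count) so
genome-scale scans reuse each enumeration. The implementation is
verified exhaustively against an exact-rational enumeration for all
configurations with ≤ 12 individuals.

**LD.** r² is the squared Pearson correlation of genotype dosages
over pairwise-complete samples (composite LD) — phase is unavailable
on array calls, so this is deliberately not haplotype r²; users
comparing against EM-based tools should expect the dosage dialect.
Undefined r² (a monomorphic partner, fewer than two complete pairs)
never prunes. Pruning visits pairs in a fixed order (position, then
locus id) within each contig group, dropping the lower-MAF member of
each violating pair (ties drop the lexicographically later id); the
order is fixed for determinism since the original pair order of such
pruning runs is generally unrecorded.

**Mendelian consistency.** A trio×locus is an error iff the child
dosage lies outside [min, max] transmissible dosage, where each parent
contributes 0 or 1 alternate alleles according to its genotype — this
interval form is equivalent to the full 3×3→3 consistency table and is
verified against gamete enumeration over all 27 configurations.
Trios with any missing member at a locus are not evaluated there.
Duo (single-parent) checking is not performed; error counts aggregate
across families by default, with per-family tables available.

**KING-robust kinship.** The between-family estimator
K = (N_both_het − 2·N_opposite_hom)/(N_het_i + N_het_j) over
pairwise-complete loci, with IBS0 = N_opposite_hom/n. It is restated
in-package (a few indicator-matrix products) rather than shelling out
to an external tool; the all-pairs form computes every statistic with
five matrix multiplications, keeping 150 samples × 40k loci around a
second. Relationship classes use the standard powers-of-two bands
(duplicate > 2^−1.5 ≥ first degree > 2^−2.5 ≥ second degree > 2^−3.5 ≥
unrelated); within first degree, IBS0 < 0.005 calls parent–offspring.
The 0.005 cutoff sits between the empirical cluster locations
(parent–offspring ≈ 0.001, full sibs ≈ 0.015 at ~1% error) and is
configurable, since no principled closed form exists once genotyping
error is nonzero. Haploid samples are excluded from kinship.

**Folded SFS.** Complete-case by default (only loci with no missing
call contribute, all at the full chromosome count); a per-locus-n mode
tallies each locus at its own non-missing count and projects down to a
common target. Projection is hypergeometric: a class-i locus of n
chromosomes spreads its mass over minor-allele counts of n_target
draws without replacement, with mass landing on 0 or n_target moving
to the monomorphic tally, so total mass is conserved exactly and the
operation is deterministic. Projection was chosen over literal
re-sampling of individuals for determinism; the neutral spectrum is
sampling-consistent, so the two agree in expectation.

**PCA.** Missing dosages are imputed with the locus mean dosage 2p —
the interpretation of frequency-based imputation on the dosage scale
that leaves the column mean unchanged. Columns are then centered and
unit-scaled; zero-variance columns (monomorphic after imputation)
cannot be scaled and are dropped with a warning. Scores come from an
SVD with a fixed sign convention (largest-magnitude loading of each
component positive) so runs are byte-reproducible.

**Panel-separation diagnostic.** Members of a very small discovery
panel each ascertain *their own* rare alleles, so in a PCA of
ascertained loci they become extreme along different axes rather than
clustering together; a centroid-distance test misses the effect
entirely (permutation p ≈ 0.1–0.3 in our simulations). The shipped
test therefore uses the mean score *norm* (distance from the origin in
the leading components) of panel members minus non-members, with a
label-permutation p-value; this detects the effect robustly (p ≈ 0.001
across seeds at panel size 4).

**HW Q–Q data.** The null is generated by redrawing genotype counts
under HWE at each locus's estimated allele frequency and sample size,
re-testing, and pooling the sorted p-values over replicates; the
envelope is the per-rank range. The function takes genotype counts
(not bare p-values) because the matched null cannot be parameterized
without them.

## Panel selection

Tiers are admitted in priority order, each under its own thresholds;
the shipped default mirrors a realistic array design: proven markers
from a previous array first (MAF ≥ 0.05), candidate-gene tiers under a
lenient rule (MAF ≥ 0.01, call rate ≥ 0.90, CRBT admitted — candidate
markers are kept for their biology, not their statistics), then the
general pool with a raised MAF floor (≥ 0.08) for the residual fill.
Only the lowest admitted tier is trimmed when the pool overshoots the
target, dropping lowest-MAF markers first with id tie-breaks; this
makes selection deterministic and nested in the target size
(raising the target never removes a previously selected marker).
Overflowing a higher tier raises an error rather than silently
cutting, and a shortfall is reported, never padded. LD pruning runs
before the residual MAF cut.

## Problem sizes and tolerances in the shipped tests

The test suite validates kinship recovery on the full 10-family design
at 40,000 loci (the scale at which class means concentrate: the
Monte-Carlo standard error of a class mean is well below 0.005),
HW-test calibration and neutral-spectrum goodness of fit at 10⁵ loci,
and ascertainment diagnostics on 120 samples × 30,000 loci. Exhaustive
oracle sweeps (HW test ≤ 12 individuals, Mendelian 27 configurations,
LD pruning groups ≤ 8) cover the combinatorial cores completely.
Statistical assertions use fixed seeds with tolerance bands derived
from the estimator's sampling variance (binomial/multinomial 99%
intervals, chi-square at α = 0.01), not tuned constants.

## Known limitations

* Conversion classes are assigned from calls alone; intensity-only
  classes (OTV, "other") cannot be assigned and are documented as
  out of reach.
* The kinship estimator assumes diploidy and unlinked loci; linked
  loci would not bias the means but would shrink the effective number
  of independent loci, widening class spreads relative to this
  package's simulations.
* The error model is uniform within the call space; real array error
  is genotype-dependent.
* `merge_duplicates` requires a shared coordinate (or flank-key)
  namespace across sources; it cannot detect duplicates across
  un-aligned references.
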