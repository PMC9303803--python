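# panelforge

Marker curation, panel selection and post-genotyping validation for
SNP genotyping arrays — built for species where the biology itself
supplies the error signals: conifers with haploid megagametophyte
tissue, outcrossing natural populations expected to sit in
Hardy–Weinberg equilibrium, and structured crossing designs with known
pedigrees.

Designing an array for a large, repetitive conifer genome (20+ Gbp,
mostly repeats, no finished reference) means fighting spurious SNPs
from collapsed paralogs, genotyping error, and ascertainment bias from
small discovery panels. `panelforge` implements the full desk-side
computational pipeline:

* **Curation filters** — Hardy–Weinberg exact-test filtering,
  paralog detection via heterozygous calls in haploid samples,
  Mendelian-error screening in trios, LD pruning (r² > 0.9, keeping
  the higher-MAF marker), exclusion windows around suspect sites,
  call-rate QC, conversion classification (PHR/NMH/MHR/CRBT) and
  merging of markers discovered independently by several sources.
* **Panel selection** — priority-tiered admission with per-tier MAF /
  call-rate / conversion-class rules, a lenient rule for candidate-gene
  tiers, deterministic lowest-tier trimming, and probe-replication
  plans for markers of special interest.
* **Validation** — replicate error rates, megagametophyte
  heterozygosity, KING-robust kinship with IBS0-based relationship
  classification, and family-wise Mendelian error summaries.
* **Diagnostics** — genotype PCA with allele-frequency imputation,
  folded site-frequency spectra with the neutral expectation and
  hypergeometric down-projection, ascertainment-bias comparisons and
  Hardy–Weinberg Q–Q data.
* **Synthetic data** — a generator that emulates every structure the
  pipeline consumes: HWE populations with neutral-like folded MAF
  spectra, two populations diverged by F<sub>ST</sub> (Balding–Nichols),
  full-sib families with shared parents, maternal-meiosis haploids,
  paralog-collapsed loci, per-call error/missingness, MAF-threshold
  discovery panels, and replicated controls.

## The statistics at the core

**Hardy–Weinberg exact test.** For diploid genotype counts
(n_AA, n_Aa, n_aa) the conditional probability of the heterozygote
count h given the allele counts is

    P(h | n, n_a) ∝ n! / (n_AA! · h! · n_aa!) · 2^h

and the two-sided p-value sums P over every h (same parity, same
allele counts) with P(h) ≤ P(h_obs). Departures flag paralogs and
clustering artifacts; the filter uses P < 0.001 (panel selection) or
P < 0.05 (discovery pre-filter).

**KING-robust kinship.** For a sample pair over pairwise-complete loci,

    K = (N_both_het − 2·N_opposite_hom) / (N_het_i + N_het_j)

with IBS0 the fraction of loci at opposite homozygotes. Expectations:
K ≈ 0.25 for parent–offspring and full sibs (separated by IBS0, which
is ≈ 0 only for parent–offspring), 0.125 for half sibs, 0 for
unrelated pairs.

**Folded SFS.** The minor-allele-count spectrum across loci; under the
standard neutral model class i of n chromosomes has expectation
∝ 1/i + 1/(n−i) (halved at i = n/2). Spectra are compared after
hypergeometric projection to a common sample size; a deficit in the
rare classes is the signature of MAF-threshold ascertainment.

## Worked example: pedigree recovery from array genotypes

Simulate a crossing design of 10 full-sib families (18 distinct
parents, 135 offspring, two family pairs sharing a parent) at 10,000
SNPs with 0.9% genotyping error, then recover the pedigree from the
genotypes alone:

```python
import panelforge as pf

cfg = pf.SimConfig(seed=42, n_loci=10_000,
                   maf_model=("uniform", 0.08, 0.5), error_rate=0.009)
matrix, pedigree = pf.sim_study_pedigree(cfg)
matrix = pf.inject_errors(matrix, cfg.error_rate, seed=43)

pairs = pf.kinship_pairs(matrix)
pairs["inferred_class"] = [
    pf.classify_relationship(k, i) for k, i in zip(pairs["K"], pairs["ibs0"])
]
truth = pf.expected_relationships(pedigree)
key = lambda f: [tuple(sorted(t)) for t in zip(f["sample_i"], f["sample_j"])]
pairs["pair"], truth["pair"] = key(pairs), key(truth)
merged = pairs.merge(truth[["pair", "relationship"]], on="pair")
print(merged.groupby("relationship")[["K", "ibs0"]].mean().round(3))
acc = (merged.inferred_class == merged.relationship).mean()
print(f"\nagreement with the crossing design: {acc:.1%}")
```

```
                         K   ibs0
relationship
full_sib             0.239  0.023
half_sib_2nd_degree  0.116  0.043
parent_offspring     0.239  0.004
unrelated           -0.008  0.081

agreement with the crossing design: 100.0%
```

The four relationship classes sit at their expected kinship levels —
first-degree pairs near 0.25 (parent–offspring and full sibs told
apart by IBS0), half sibs near 0.125, unrelated pairs near 0 — and
every pair is classified correctly from genotypes alone.

## Command line

```
panelforge simulate --seed 1 --out pop.vcf          # synthetic cohort
panelforge stats    pop.vcf --out stats.tsv          # MAF, CR, HW p per marker
panelforge filter   pop.vcf --out report.tsv         # curation filter report
panelforge select   markers.tsv --target-size 47712 --out panel.tsv
panelforge qc       trio.vcf --pedigree ped.tsv --out kinship.tsv
panelforge pca      pop.vcf --out scores.tsv
panelforge sfs      pop.vcf --project-to 30 --out sfs.tsv
```

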