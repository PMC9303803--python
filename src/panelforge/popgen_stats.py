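"""Population-genetic statistics underlying marker curation.

Allele frequencies and the Hardy-Weinberg exact test feed the marker
filters; the folded site-frequency spectrum (SFS), its neutral
expectation and hypergeometric down-projection drive the
ascertainment-bias diagnostics.

Conventions
-----------
* Haploid samples contribute one chromosome per locus, diploids two.
* LD is measured as the squared Pearson correlation of genotype
  dosages (composite LD) because phase is unavailable on array calls;
  users comparing against haplotype-based r^2 should expect the
  genotype-dosage dialect.
* The HW exact test is the standard two-sided conditional test (no
  mid-p): the p-value sums the conditional probabilities of every
  heterozygote count, with the observed allele counts and parity,
  whose probability does not exceed that of the observed count.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln
from scipy.stats import hypergeom

from .datatypes import MISSING, SFS, GenotypeMatrix, ValidationError

__all__ = [
    "allele_counts",
    "minor_allele_freq",
    "maf_per_locus",
    "hw_exact_test",
    "hw_exact_test_many",
    "hw_counts_per_locus",
    "hw_p_per_locus",
    "ld_r2",
    "folded_sfs",
    "expected_neutral_folded_sfs",
    "project_sfs",
]


# ---------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------

def allele_counts(calls: np.ndarray, ploidy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (alt allele count, total allele count) over non-missing calls.

    ``calls`` is (n_samples, n_loci) dosage codes; haploid dosages {0, 2}
    carry a single allele.  Artifact het calls in haploids (dosage 1)
    contribute half an alternate allele; they only exist upstream of the
    filters that remove them, and rounding them away would hide the signal.
    """
    calls = np.atleast_2d(np.asarray(calls))
    ploidy = np.asarray(ploidy)
    present = calls != MISSING
    dose = np.where(present, calls, 0).astype(float)
    hap = ploidy == 1
    # haploid dosage scale is {0,2} for {ref,alt}: one allele per call
    alt = dose[~hap].sum(axis=0) + (dose[hap] / 2.0).sum(axis=0)
    n_alleles = (present * ploidy[:, None]).sum(axis=0)
    return alt, n_alleles.astype(float)


def minor_allele_freq(calls: np.ndarray, ploidy: np.ndarray | int = 2) -> float:
    """Minor-allele frequency of a single locus.

    ``ploidy`` may be a scalar (applied to every call) or a per-sample
    vector.  Raises on an all-missing locus rather than returning a
    silent NaN.
    """
    calls = np.asarray(calls)
    if np.isscalar(ploidy):
        ploidy = np.full(calls.shape[0], ploidy)
    alt, n = allele_counts(calls[:, None], np.asarray(ploidy))
    if n[0] == 0:
        raise ValidationError("minor_allele_freq undefined for an all-missing locus")
    f = alt[0] / n[0]
    return float(min(f, 1.0 - f))


def maf_per_locus(matrix: GenotypeMatrix) -> np.ndarray:
    """Vector of per-locus MAFs; NaN where every call is missing."""
    alt, n = allele_counts(matrix.calls, matrix.ploidy)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return np.where(n > 0, np.minimum(f, 1.0 - f), np.nan)


# ---------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------

def _het_support(n_a: int, n_total: int) -> np.ndarray:
    """All heterozygote counts compatible with n_a copies of the rarer allele."""
    h_max = min(n_a, 2 * n_total - n_a)
    return np.arange(n_a % 2, h_max + 1, 2)

def _log_het_probs(hets: np.ndarray, n_a: int, n_total: int) -> np.ndarray:
    """Log conditional probabilities of each heterozygote count.

    P(h | n, nA) ∝ n! / (nAA! h! naa!) * 2^h with nAA = (nA - h)/2.
    Normalized over the support so the probabilities sum to one.
    """
    n_rare_hom = (n_a - hets) // 2
    n_comm_hom = n_total - hets - n_rare_hom
    logp = (
        gammaln(n_total + 1)
        - gammaln(n_rare_hom + 1)
        - gammaln(hets + 1)
        - gammaln(n_comm_hom + 1)
        + hets * np.log(2.0)
    )
    logp -= logp.max()
    return logp - np.log(np.exp(logp).sum())


def hw_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided conditional exact test of Hardy-Weinberg proportions.

    Returns the sum of conditional probabilities of all heterozygote
    counts at least as unusual as the observed one; monomorphic counts
    give p = 1.  The result is always in (0, 1].
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValidationError("genotype counts must be non-negative")
    n_total = n_AA + n_Aa + n_aa
    if n_total == 0:
        raise ValidationError("no genotyped individuals")
    n_a = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)  # rarer-allele copies
    if n_a == 0:
        return 1.0
    hets = _het_support(n_a, n_total)
    probs = np.exp(_log_het_probs(hets, n_a, n_total))
    p_obs = probs[np.searchsorted(hets, n_Aa)]
    # tolerance guards float ties between configurations of equal weight
    p = probs[probs <= p_obs * (1.0 + 1e-9)].sum()
    return float(min(p, 1.0))


def hw_exact_test_many(
    n_AA: np.ndarray, n_Aa: np.ndarray, n_aa: np.ndarray
) -> np.ndarray:
    """Vectorized :func:`hw_exact_test` over many loci.

    Loci sharing (total, rare-allele count) reuse one enumeration, which
    makes genome-scale scans cheap.
    """
    n_AA = np.asarray(n_AA, dtype=np.int64)
    n_Aa = np.asarray(n_Aa, dtype=np.int64)
    n_aa = np.asarray(n_aa, dtype=np.int64)
    n_total = n_AA + n_Aa + n_aa
    n_a = np.minimum(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    out = np.ones(len(n_total), dtype=float)
    keys = n_total * (2 * n_total.max() + 2) + n_a
    for key in np.unique(keys[n_a > 0]):
        idx = np.flatnonzero(keys == key)
        idx = idx[n_a[idx] > 0]
        if len(idx) == 0:
            continue
        nt, na = int(n_total[idx[0]]), int(n_a[idx[0]])
        hets = _het_support(na, nt)
        probs = np.exp(_log_het_probs(hets, na, nt))
        pos = np.searchsorted(hets, n_Aa[idx])
        p_obs = probs[pos]
        cum = (probs[None, :] <= p_obs[:, None] * (1.0 + 1e-9)) @ probs
        out[idx] = np.minimum(cum, 1.0)
    return out


def hw_counts_per_locus(matrix: GenotypeMatrix) -> np.ndarray:
    """(n_loci, 3) genotype counts (hom-ref, het, hom-alt) over diploids."""
    dip = matrix.calls[matrix.is_diploid]
    return np.stack(
        [(dip == 0).sum(axis=0), (dip == 1).sum(axis=0), (dip == 2).sum(axis=0)],
        axis=1,
    )


def hw_p_per_locus(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-locus HW exact p-values over the diploid samples."""
    c = hw_counts_per_locus(matrix)
    return hw_exact_test_many(c[:, 0], c[:, 1], c[:, 2])


# ---------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------

def ld_r2(calls_i: np.ndarray, calls_j: np.ndarray) -> float:
    """Squared dosage correlation over pairwise-complete samples.

    Returns NaN (undefined, non-prunable) when fewer than two samples
    are complete at both loci or either locus is constant on the shared
    samples.
    """
    x = np.asarray(calls_i, dtype=float)
    y = np.asarray(calls_j, dtype=float)
    ok = (x != MISSING) & (y != MISSING)
    x, y = x[ok], y[ok]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------
# site-frequency spectra
# ---------------------------------------------------------------------

def folded_sfs(
    matrix: GenotypeMatrix,
    loci: np.ndarray | list[str] | None = None,
    complete_case: bool = True,
    n_target: int | None = None,
) -> SFS:
    """Folded SFS of the given loci (defaults to all).

    With ``complete_case`` (default) only loci with no missing call
    contribute, all at the full chromosome count.  Otherwise each locus
    is tallied at its own non-missing chromosome count and projected
    down to ``n_target`` chromosomes (required in that mode) with the
    hypergeometric kernel of :func:`project_sfs`.
    """
    if loci is not None:
        if len(loci) and isinstance(loci[0], str):
            matrix = matrix.subset_loci(list(loci))
        else:
            matrix = matrix.take_loci(np.asarray(loci))
    n_chrom = int(matrix.ploidy.sum())
    if n_chrom < 2:
        raise ValidationError("need at least 2 chromosomes for an SFS")
    alt, n = allele_counts(matrix.calls, matrix.ploidy)
    if complete_case:
        full = n == n_chrom
        alt, n = alt[full], n[full]
        minor = np.minimum(alt, n_chrom - alt)
        # artifact half-counts from haploid hets round down (pre-filter data)
        minor = np.floor(minor).astype(np.int64)
        counts = np.bincount(minor, minlength=n_chrom // 2 + 1)
        return SFS(
            n_chromosomes=n_chrom,
            folded_counts=counts[1 : n_chrom // 2 + 1].astype(float),
            monomorphic_count=float(counts[0]),
        )
    if n_target is None:
        raise ValidationError("per-locus-n mode requires n_target")
    n = n.astype(np.int64)
    usable = n >= n_target
    alt, n = alt[usable], n[usable]
    minor = np.floor(np.minimum(alt, n - alt)).astype(np.int64)
    folded = np.zeros(n_target // 2, dtype=float)
    mono = 0.0
    for n_loc in np.unique(n):
        sel = n == n_loc
        counts = np.bincount(minor[sel], minlength=n_loc // 2 + 1)
        sub = SFS(int(n_loc), counts[1 : n_loc // 2 + 1].astype(float), float(counts[0]))
        proj = project_sfs(sub, n_target) if n_loc > n_target else sub
        folded += proj.folded_counts
        mono += proj.monomorphic_count
    return SFS(n_target, folded, mono)


def expected_neutral_folded_sfs(n_chromosomes: int) -> np.ndarray:
    """Expected folded-SFS proportions under the standard neutral model.

    Class i (minor-allele count) has weight (1/i + 1/(n-i)), halved when
    i = n - i; the vector is normalized to sum to one.
    """
    n = int(n_chromosomes)
    if n < 2:
        raise ValidationError("n_chromosomes must be >= 2")
    i = np.arange(1, n // 2 + 1, dtype=float)
    w = (1.0 / i + 1.0 / (n - i)) / np.where(i == n - i, 2.0, 1.0)
    return w / w.sum()


def project_sfs(sfs: SFS, n_target: int) -> SFS:
    """Hypergeometric down-projection of a folded SFS.

    Each class-i locus spreads its mass over the minor-allele counts of
    ``n_target`` chromosomes drawn without replacement; mass landing on
    0 or ``n_target`` copies becomes monomorphic.  Total mass (folded +
    monomorphic) is conserved exactly.
    """
    n = sfs.n_chromosomes
    if n_target > n:
        raise ValidationError("cannot project to a larger sample")
    if n_target % 2 or n % 2:
        raise ValidationError("projection requires even chromosome counts")
    if n_target == n:
        return SFS(n, sfs.folded_counts.copy(), sfs.monomorphic_count)
    folded = np.zeros(n_target // 2, dtype=float)
    mono = float(sfs.monomorphic_count)
    j = np.arange(n_target + 1)
    for cls in range(1, n // 2 + 1):
        weight = sfs.folded_counts[cls - 1]
        if weight == 0:
            continue
        pmf = hypergeom.pmf(j, n, cls, n_target)
        mono += weight * (pmf[0] + pmf[-1])
        fold_j = np.minimum(j, n_target - j)
        for jc in range(1, n_target // 2 + 1):
            folded[jc - 1] += weight * pmf[fold_j == jc].sum()
    return SFS(n_target, folded, mono)
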