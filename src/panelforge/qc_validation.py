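"""Post-genotyping validation of an array run.

Covers the four checks run on a finished genotyping batch: replicate
concordance (technical error rate), heterozygosity of haploid
megagametophyte samples (residual paralogy), pairwise kinship / IBS0
relationship inference against the known crossing design, and
family-wise Mendelian error rates.

Kinship uses the KING-robust between-family estimator

    K = (N_both_het - 2 * N_opposite_hom) / (N_het_i + N_het_j)

computed over pairwise-complete loci, with IBS0 the fraction of those
loci where the pair carries opposite homozygotes.  Expected values are
0.25 for first-degree pairs (parent-offspring and full sibs, separated
by IBS0, which is near zero only for parent-offspring), 0.125 for
second-degree pairs and 0 for unrelated pairs.  Haploid samples are
excluded: the estimator assumes diploid genotypes.
"""

from __future__ import annotations

import warnings
from math import sqrt

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix, ValidationError
from .marker_filters import MendelResult, mendelian_errors

__all__ = [
    "replicate_error_rate",
    "haploid_heterozygosity",
    "king_kinship",
    "kinship_pairs",
    "classify_relationship",
    "expected_relationships",
    "RelationshipThresholds",
    "family_mendel_rates",
]


def replicate_error_rate(calls_a: np.ndarray, calls_b: np.ndarray) -> float:
    """Discordance between two replicate genotypings of one sample.

    Mismatching calls over pairwise-complete loci; NaN (undefined) when
    no locus is called in both replicates.
    """
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    if a.shape != b.shape:
        raise ValidationError("replicates must cover the same locus set")
    ok = (a != MISSING) & (b != MISSING)
    n = int(ok.sum())
    if n == 0:
        return float("nan")
    return float((a[ok] != b[ok]).sum() / n)


def haploid_heterozygosity(calls: np.ndarray, ploidy: int = 1) -> float:
    """Fraction of het calls in a haploid sample.

    Any heterozygous call in a megagametophyte is an artifact, so this
    fraction is a direct probe of residual paralogy / call error.
    NaN when every call is missing.
    """
    if ploidy != 1:
        raise ValidationError("haploid_heterozygosity is defined for ploidy-1 samples")
    calls = np.asarray(calls)
    present = calls != MISSING
    n = int(present.sum())
    if n == 0:
        return float("nan")
    return float((calls[present] == 1).sum() / n)


# ---------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------

def king_kinship(
    calls_i: np.ndarray, calls_j: np.ndarray
) -> tuple[float, float, int]:
    """KING-robust kinship and IBS0 for one diploid pair.

    Returns ``(K, ibs0, n_compared)``; K is NaN when neither sample has
    a heterozygous call on the shared loci (zero denominator).
    """
    a = np.asarray(calls_i)
    b = np.asarray(calls_j)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    n = len(a)
    if n == 0:
        raise ValidationError("no pairwise-complete loci")
    both_het = int(((a == 1) & (b == 1)).sum())
    opp = int((((a == 0) & (b == 2)) | ((a == 2) & (b == 0))).sum())
    het_sum = int((a == 1).sum() + (b == 1).sum())
    ibs0 = opp / n
    if het_sum == 0:
        return float("nan"), ibs0, n
    return (both_het - 2.0 * opp) / het_sum, ibs0, n


def kinship_pairs(
    matrix: GenotypeMatrix, sample_ids: list[str] | None = None
) -> pd.DataFrame:
    """All-pairs KING-robust estimates over the diploid samples.

    Vectorized with indicator-matrix products so genome-scale panels
    (10^2 samples x 10^4 loci) stay fast.  Returns one row per
    unordered pair: sample_i, sample_j, K, ibs0, n_compared.
    """
    if sample_ids is None:
        keep = np.flatnonzero(matrix.is_diploid)
    else:
        keep = np.array([matrix.sample_index(s) for s in sample_ids])
        if (matrix.ploidy[keep] == 1).any():
            raise ValidationError("kinship requires diploid samples")
    ids = [matrix.sample_ids[i] for i in keep]
    calls = matrix.calls[keep]
    het = (calls == 1).astype(np.float64)
    hom0 = (calls == 0).astype(np.float64)
    hom2 = (calls == 2).astype(np.float64)
    present = (calls != MISSING).astype(np.float64)
    both_het = het @ het.T
    opp = hom0 @ hom2.T + hom2 @ hom0.T
    het_vs_present = het @ present.T  # loci het in row-sample, called in both
    denom = het_vs_present + het_vs_present.T
    n_cmp = present @ present.T
    with np.errstate(invalid="ignore", divide="ignore"):
        K = np.where(denom > 0, (both_het - 2.0 * opp) / np.maximum(denom, 1), np.nan)
        ibs0 = np.where(n_cmp > 0, opp / np.maximum(n_cmp, 1), np.nan)
    iu, ju = np.triu_indices(len(ids), k=1)
    return pd.DataFrame(
        {
            "sample_i": [ids[i] for i in iu],
            "sample_j": [ids[j] for j in ju],
            "K": K[iu, ju],
            "ibs0": ibs0[iu, ju],
            "n_compared": n_cmp[iu, ju].astype(int),
        }
    )


class RelationshipThresholds:
    """Kinship bands at the standard powers-of-two midpoints.

    Degrees split at 2^-1.5, 2^-2.5, 2^-3.5 (duplicate / first /
    second degree / unrelated).  Within first degree, IBS0 below
    ``po_ibs0`` calls parent-offspring, else full sib; the default
    0.005 sits between the observed cluster locations (~0.001 for
    parent-offspring, ~0.015 for full sibs at realistic error rates).
    """

    def __init__(
        self,
        duplicate: float = 2 ** -1.5,
        first_degree: float = 2 ** -2.5,
        second_degree: float = 2 ** -3.5,
        po_ibs0: float = 0.005,
    ) -> None:
        self.duplicate = duplicate
        self.first_degree = first_degree
        self.second_degree = second_degree
        self.po_ibs0 = po_ibs0


def classify_relationship(
    K: float, ibs0: float, thresholds: RelationshipThresholds | None = None
) -> str:
    """Map a (K, IBS0) estimate to a relationship class."""
    t = thresholds or RelationshipThresholds()
    if K is None or (isinstance(K, float) and np.isnan(K)):
        return "undefined"
    if K > t.duplicate:
        return "duplicate"
    if K > t.first_degree:
        return "parent_offspring" if ibs0 < t.po_ibs0 else "full_sib"
    if K > t.second_degree:
        return "half_sib_2nd_degree"
    return "unrelated"


def expected_relationships(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Truth relationship class for every sample pair in a pedigree.

    Classes follow the two-generation crossing designs this package
    simulates (unrelated founders, full-sib families, families sharing
    one parent): parent_offspring, full_sib, half_sib_2nd_degree or
    unrelated.  Used to score kinship estimates against the design.
    """
    parents = {
        row.sample_id: frozenset(
            p for p in (row.sire_id, row.dam_id) if p is not None and p == p and p != ""
        )
        for row in pedigree.itertuples(index=False)
    }
    ids = list(parents)
    rows = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            i, j = ids[a], ids[b]
            pi, pj = parents[i], parents[j]
            if j in pi or i in pj:
                cls = "parent_offspring"
            elif pi and pj and pi == pj:
                cls = "full_sib"
            elif pi and pj and pi & pj:
                cls = "half_sib_2nd_degree"
            else:
                cls = "unrelated"
            rows.append((i, j, cls))
    return pd.DataFrame(rows, columns=["sample_i", "sample_j", "relationship"])


# ---------------------------------------------------------------------
# family-wise Mendelian error rates
# ---------------------------------------------------------------------

def family_mendel_rates(
    matrix: GenotypeMatrix, pedigree: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Family-level Mendelian error summaries.

    Returns ``per_family`` (total errors and evaluated trio x locus
    cells per family), ``per_locus`` (error counts and rates over all
    trios) and ``sharing`` (loci with errors in exactly one family vs
    two or more — shared errors point at the marker, private ones at a
    single bad call).
    """
    result: MendelResult = mendelian_errors(matrix, pedigree)
    if result.trios.empty:
        warnings.warn("no complete trios; Mendelian rates are empty")
        empty = pd.DataFrame()
        return {"per_family": empty, "per_locus": empty, "sharing": empty, "result": result}
    fams_with_trios = set(result.trios["family_id"])
    all_fams = set(pedigree.loc[pedigree["sire_id"].notna(), "family_id"])
    skipped = all_fams - fams_with_trios
    if skipped:
        warnings.warn(f"families without complete trios excluded: {sorted(skipped)}")
    per_family = result.per_family_counts()
    per_locus = result.per_locus_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus["error_rate"] = np.where(
            per_locus["n_evaluated"] > 0,
            per_locus["n_errors"] / per_locus["n_evaluated"].clip(lower=1),
            np.nan,
        )
    fam_locus = result.per_locus_family_errors()
    n_fams_with_error = (fam_locus > 0).sum(axis=1)
    sharing = pd.DataFrame(
        {
            "n_loci": [
                int((n_fams_with_error == 1).sum()),
                int((n_fams_with_error >= 2).sum()),
            ]
        },
        index=pd.Index(["single_family", "multi_family"], name="sharing"),
    )
    return {
        "per_family": per_family,
        "per_locus": per_locus,
        "sharing": sharing,
        "result": result,
    }
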