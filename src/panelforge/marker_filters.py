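"""Marker curation cascade: the per-marker filters applied between SNP
discovery and final panel selection.

Each filter returns a *filter report*: one row per marker with the
filter name, the statistic evaluated, the threshold and a pass/fail
outcome.  Reports from successive stages concatenate into an audit
trail whose pass/fail counts reconcile exactly with the marker counts
entering and leaving every stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix, ValidationError
from .popgen_stats import ld_r2, maf_per_locus

__all__ = [
    "make_filter_report",
    "haploid_het_filter",
    "exclusion_window",
    "mendelian_errors",
    "MendelResult",
    "hw_filter",
    "ld_prune",
    "call_rate",
    "sample_qc",
    "conversion_classify",
    "conversion_classify_matrix",
    "merge_duplicates",
]

REPORT_COLUMNS = ("marker_id", "filter_name", "outcome", "statistic", "threshold")


def make_filter_report(
    marker_ids,
    filter_name: str,
    passed: np.ndarray,
    statistic: np.ndarray,
    threshold,
) -> pd.DataFrame:
    """Assemble a tidy pass/fail report for one filter stage."""
    passed = np.asarray(passed, dtype=bool)
    return pd.DataFrame(
        {
            "marker_id": list(marker_ids),
            "filter_name": filter_name,
            "outcome": np.where(passed, "pass", "fail"),
            "statistic": np.asarray(statistic, dtype=float),
            "threshold": threshold,
        }
    )


# ---------------------------------------------------------------------
# paralog screening via haploid heterozygosity
# ---------------------------------------------------------------------

def haploid_het_filter(
    matrix: GenotypeMatrix,
    haploid_ids: list[str],
    marker_table: pd.DataFrame | None = None,
    high_priority_sources: set[str] | frozenset[str] = frozenset(),
    allowed_default: int = 0,
    allowed_high_priority: int = 1,
) -> pd.DataFrame:
    """Fail markers with heterozygous calls in haploid samples.

    A het call in a haploid megagametophyte cannot be a real genotype,
    so it flags a collapsed paralog (or a call error).  Markers from
    high-priority sources are granted ``allowed_high_priority`` het
    calls (default one) before failing; all others fail on the first.
    """
    idx = [matrix.sample_index(s) for s in haploid_ids]
    for i in idx:
        if matrix.ploidy[i] != 1:
            raise ValidationError(f"sample {matrix.sample_ids[i]!r} is not haploid")
    if not idx:
        warnings.warn("no haploid samples: haploid_het_filter passes every marker")
        het_counts = np.zeros(matrix.n_loci, dtype=int)
    else:
        het_counts = (matrix.calls[idx, :] == 1).sum(axis=0)
    allowed = np.full(matrix.n_loci, allowed_default)
    if marker_table is not None and high_priority_sources:
        src = (
            marker_table.set_index("marker_id")["source"]
            .reindex(matrix.locus_ids)
            .to_numpy()
        )
        allowed = np.where(
            np.isin(src, list(high_priority_sources)), allowed_high_priority, allowed
        )
    passed = het_counts <= allowed
    report = make_filter_report(
        matrix.locus_ids, "haploid_het", passed, het_counts, allowed_default
    )
    report["threshold"] = allowed
    return report


def exclusion_window(
    marker_positions: pd.DataFrame,
    flagged_positions: pd.DataFrame,
    window_bp: int,
) -> set[str]:
    """Markers within ``window_bp`` (inclusive) of a flagged position.

    Both frames use 1-based coordinates and share a contig namespace.
    A marker sitting exactly at a flagged position (distance 0) is
    removed, so flagged markers remove themselves.
    """
    if window_bp < 0:
        raise ValidationError("window_bp must be non-negative")
    removed: set[str] = set()
    flags_by_contig = {
        c: np.sort(g["position"].to_numpy())
        for c, g in flagged_positions.groupby("contig")
    }
    for contig, group in marker_positions.groupby("contig"):
        flags = flags_by_contig.get(contig)
        if flags is None:
            continue
        pos = group["position"].to_numpy()
        lo = np.searchsorted(flags, pos - window_bp, side="left")
        hi = np.searchsorted(flags, pos + window_bp, side="right")
        hit = hi > lo
        removed.update(group.loc[hit, "marker_id"] if "marker_id" in group else group.index[hit])
    return removed


# ---------------------------------------------------------------------
# Mendelian consistency
# ---------------------------------------------------------------------

@dataclass
class MendelResult:
    """Trio-level Mendelian check over all loci.

    ``errors`` and ``evaluated`` are (n_trios, n_loci) booleans; a
    trio x locus is evaluated only when child, sire and dam are all
    called there.
    """

    trios: pd.DataFrame  # child_id, sire_id, dam_id, family_id
    errors: np.ndarray
    evaluated: np.ndarray
    locus_ids: list[str]

    def per_locus_counts(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.locus_ids,
                "n_errors": self.errors.sum(axis=0),
                "n_evaluated": self.evaluated.sum(axis=0),
            }
        )

    def per_family_counts(self) -> pd.DataFrame:
        fam = self.trios["family_id"].to_numpy()
        rows = []
        for f in pd.unique(fam):
            sel = fam == f
            rows.append((f, int(self.errors[sel].sum()), int(self.evaluated[sel].sum())))
        return pd.DataFrame(rows, columns=["family_id", "n_errors", "n_evaluated"])

    def per_locus_family_errors(self) -> pd.DataFrame:
        """Per (family, locus) error counts, families as rows."""
        fam = self.trios["family_id"].to_numpy()
        data = {
            f: self.errors[fam == f].sum(axis=0) for f in pd.unique(fam)
        }
        return pd.DataFrame(data, index=self.locus_ids)


def mendelian_errors(
    matrix: GenotypeMatrix,
    pedigree: pd.DataFrame,
    loci: list[str] | None = None,
) -> MendelResult:
    """Detect genotype configurations impossible under Mendelian
    transmission in every complete trio.

    A child dosage is consistent iff it lies between the minimum and
    maximum dosage transmissible by the parent pair (each parent
    contributes 0 or 1 alternate alleles depending on its genotype).
    Trios with a missing member at a locus are not evaluated there;
    children lacking either parent are skipped entirely.
    """
    if loci is not None:
        matrix = matrix.subset_loci(loci)
    ids = set(matrix.sample_ids)
    trios = pedigree.dropna(subset=["sire_id", "dam_id"])
    trios = trios[
        trios["sample_id"].isin(ids)
        & trios["sire_id"].isin(ids)
        & trios["dam_id"].isin(ids)
    ][["sample_id", "sire_id", "dam_id", "family_id"]].rename(
        columns={"sample_id": "child_id"}
    )
    n_trios = len(trios)
    errors = np.zeros((n_trios, matrix.n_loci), dtype=bool)
    evaluated = np.zeros((n_trios, matrix.n_loci), dtype=bool)
    for t, row in enumerate(trios.itertuples(index=False)):
        c = matrix.calls[matrix.sample_index(row.child_id)]
        s = matrix.calls[matrix.sample_index(row.sire_id)]
        d = matrix.calls[matrix.sample_index(row.dam_id)]
        ok = (c != MISSING) & (s != MISSING) & (d != MISSING)
        lo = (s == 2).astype(np.int8) + (d == 2).astype(np.int8)
        hi = (s >= 1).astype(np.int8) + (d >= 1).astype(np.int8)
        evaluated[t] = ok
        errors[t] = ok & ((c < lo) | (c > hi))
    return MendelResult(
        trios=trios.reset_index(drop=True),
        errors=errors,
        evaluated=evaluated,
        locus_ids=list(matrix.locus_ids),
    )


# ---------------------------------------------------------------------
# marginal marker filters
# ---------------------------------------------------------------------

def hw_filter(marker_table: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Fail markers whose HW exact p-value is strictly below ``alpha``.

    The same operation serves the lenient discovery pre-filter
    (alpha = 0.05) and the panel-selection filter (alpha = 0.001);
    monomorphic markers carry p = 1 and always pass.
    """
    p = marker_table["hw_p"].to_numpy(dtype=float)
    return make_filter_report(
        marker_table["marker_id"], f"hw_p<{alpha:g}", p >= alpha, p, alpha
    )


def ld_prune(
    matrix: GenotypeMatrix,
    marker_table: pd.DataFrame | None = None,
    r2_threshold: float = 0.9,
    grouping: str = "contig",
) -> list[str]:
    """Greedy LD pruning keeping the higher-MAF member of each pair.

    Pairs are visited in a fixed order (position, then locus id) within
    each group; whenever two still-kept loci exceed the r^2 threshold
    (strict >) the lower-MAF one is dropped, ties dropping the
    lexicographically later id.  Undefined r^2 (monomorphic partner,
    too few complete pairs) never prunes.
    """
    if grouping not in ("contig", "all"):
        raise ValidationError(f"unknown grouping {grouping!r}")
    if marker_table is not None and "maf" in marker_table.columns:
        maf = (
            marker_table.set_index("marker_id")["maf"]
            .reindex(matrix.locus_ids)
            .to_numpy(dtype=float)
        )
    else:
        maf = maf_per_locus(matrix)
    order = sorted(
        range(matrix.n_loci),
        key=lambda j: (matrix.position[j], matrix.locus_ids[j]),
    )
    groups: dict[str, list[int]] = {}
    for j in order:
        key = matrix.contig[j] if grouping == "contig" else "all"
        groups.setdefault(key, []).append(j)
    kept = np.ones(matrix.n_loci, dtype=bool)
    for members in groups.values():
        for a_pos, j in enumerate(members):
            if not kept[j]:
                continue
            for k in members[a_pos + 1 :]:
                if not kept[k] or not kept[j]:
                    continue
                r2 = ld_r2(matrix.calls[:, j], matrix.calls[:, k])
                if np.isnan(r2) or r2 <= r2_threshold:
                    continue
                if maf[j] > maf[k]:
                    kept[k] = False
                elif maf[j] < maf[k]:
                    kept[j] = False
                else:  # tie: drop the lexicographically later id
                    if matrix.locus_ids[j] < matrix.locus_ids[k]:
                        kept[k] = False
                    else:
                        kept[j] = False
    return [matrix.locus_ids[j] for j in range(matrix.n_loci) if kept[j]]


def call_rate(matrix: GenotypeMatrix, by: str = "marker") -> pd.Series:
    """Fraction of non-missing calls per marker or per sample."""
    present = matrix.calls != MISSING
    if by == "marker":
        return pd.Series(present.mean(axis=0), index=matrix.locus_ids, name="call_rate")
    if by == "sample":
        return pd.Series(present.mean(axis=1), index=matrix.sample_ids, name="call_rate")
    raise ValidationError("by must be 'marker' or 'sample'")


def sample_qc(rates: pd.Series, threshold: float = 0.97) -> list[str]:
    """Samples whose call rate meets the threshold (>= semantics)."""
    return list(rates.index[rates >= threshold])


# ---------------------------------------------------------------------
# conversion classification
# ---------------------------------------------------------------------

def conversion_classify(calls: np.ndarray, cr_threshold: float = 0.97) -> str:
    """Assign an array-conversion performance class from calls alone.

    CRBT when call rate is below threshold; otherwise PHR (all three
    genotype classes), NMH (one homozygote class plus hets), MHR
    (monomorphic homozygous).  Patterns the cluster taxonomy does not
    cover (het-only, both homozygotes without hets) are UNCLASSIFIED;
    intensity-only classes (OTV) are not assignable from calls.
    """
    calls = np.asarray(calls)
    present = calls != MISSING
    if present.size == 0 or present.mean() < cr_threshold:
        return "CRBT"
    seen = set(np.unique(calls[present]).tolist())
    if seen == {0, 1, 2}:
        return "PHR"
    if seen in ({0, 1}, {1, 2}):
        return "NMH"
    if seen in ({0}, {2}):
        return "MHR"
    return "UNCLASSIFIED"


def conversion_classify_matrix(
    matrix: GenotypeMatrix, cr_threshold: float = 0.97, diploid_only: bool = True
) -> pd.Series:
    """Per-locus conversion classes (clusters read from diploid calls)."""
    sub = matrix.take_samples(matrix.is_diploid) if diploid_only else matrix
    classes = [
        conversion_classify(sub.calls[:, j], cr_threshold) for j in range(sub.n_loci)
    ]
    return pd.Series(classes, index=matrix.locus_ids, name="conversion_class")


# ---------------------------------------------------------------------
# duplicate-discovery merging
# ---------------------------------------------------------------------

def merge_duplicates(
    marker_table: pd.DataFrame,
    context_key: tuple[str, ...] = ("contig", "position"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse markers discovered independently by several sources.

    Groups sharing the context key merge into one record whose
    authoritative source is the highest-priority member (lowest
    ``priority_tier``); every member source is kept in a provenance
    column.  Groups whose members disagree on alleles are dropped and
    reported.
    """
    for col in context_key:
        if col not in marker_table.columns:
            raise ValidationError(f"context key column {col!r} missing")
    conflicts = []
    merged_rows = []
    for _, group in marker_table.groupby(list(context_key), sort=True):
        if len(group) == 1:
            row = group.iloc[0].copy()
            row["merged_sources"] = row["source"]
            merged_rows.append(row)
            continue
        if {"ref", "alt"} <= set(group.columns):
            alleles = set(map(tuple, group[["ref", "alt"]].itertuples(index=False)))
            if len(alleles) > 1:
                conflicts.append(
                    pd.DataFrame(
                        {
                            "marker_id": group["marker_id"],
                            "reason": "allele_conflict",
                        }
                    )
                )
                continue
        best = group.sort_values(["priority_tier", "marker_id"]).iloc[0].copy()
        best["merged_sources"] = ",".join(sorted(group["source"].unique()))
        merged_rows.append(best)
    merged = pd.DataFrame(merged_rows).reset_index(drop=True)
    conflict_report = (
        pd.concat(conflicts, ignore_index=True)
        if conflicts
        else pd.DataFrame(columns=["marker_id", "reason"])
    )
    return merged, conflict_report
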