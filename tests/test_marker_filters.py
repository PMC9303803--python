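"""The curation cascade: filters, classification and bookkeeping."""

import itertools

import numpy as np
import pandas as pd
import pytest

from panelforge import (
    ValidationError,
    call_rate,
    conversion_classify,
    conversion_classify_matrix,
    exclusion_window,
    haploid_het_filter,
    hw_filter,
    ld_prune,
    mendelian_errors,
    merge_duplicates,
    sample_qc,
)
from panelforge.popgen_stats import ld_r2

from conftest import make_matrix


# ---------------------------------------------------------------------
# haploid het filter
# ---------------------------------------------------------------------

class TestHaploidHetFilter:
    def _run(self, het_counts, source, allowed_sources=frozenset({"hp"})):
        calls = np.zeros((2, len(het_counts)), dtype=int)
        for j, c in enumerate(het_counts):
            calls[:c, j] = 1
        m = make_matrix(calls, ploidy=[1, 1])
        table = pd.DataFrame(
            {"marker_id": m.locus_ids, "source": source, "priority_tier": 1}
        )
        return haploid_het_filter(
            m, m.sample_ids, table, high_priority_sources=allowed_sources
        )

    def test_one_error_allowed_for_high_priority(self):
        report = self._run([1], source="hp")
        assert report["outcome"].iloc[0] == "pass"

    def test_one_het_fails_ordinary_source(self):
        report = self._run([1], source="ordinary")
        assert report["outcome"].iloc[0] == "fail"

    def test_two_hets_fail_even_high_priority(self):
        report = self._run([2], source="hp")
        assert report["outcome"].iloc[0] == "fail"

    def test_no_haploids_passes_with_warning(self):
        m = make_matrix([[1, 1]], ploidy=[2])
        with pytest.warns(UserWarning):
            report = haploid_het_filter(m, [])
        assert (report["outcome"] == "pass").all()

    def test_diploid_passed_as_haploid_rejected(self):
        m = make_matrix([[1]], ploidy=[2])
        with pytest.raises(ValidationError):
            haploid_het_filter(m, ["s0"])


# ---------------------------------------------------------------------
# exclusion windows
# ---------------------------------------------------------------------

def test_exclusion_window_boundary_inclusive():
    markers = pd.DataFrame(
        {
            "marker_id": ["at100", "at100_other_ctg"],
            "contig": ["c1", "c2"],
            "position": [100, 100],
        }
    )
    flagged = pd.DataFrame({"contig": ["c1"], "position": [150]})
    removed = exclusion_window(markers, flagged, 50)
    assert removed == {"at100"}  # distance 50 inclusive; other contig kept
    removed51 = exclusion_window(
        markers, pd.DataFrame({"contig": ["c1"], "position": [151]}), 50
    )
    assert removed51 == set()  # distance 51 exceeds the window


def test_exclusion_window_flagged_marker_removes_itself():
    markers = pd.DataFrame({"marker_id": ["x"], "contig": ["c1"], "position": [500]})
    flagged = pd.DataFrame({"contig": ["c1"], "position": [500]})
    assert exclusion_window(markers, flagged, 25) == {"x"}


def test_exclusion_window_rejects_negative_window():
    with pytest.raises(ValidationError):
        exclusion_window(pd.DataFrame(columns=["marker_id", "contig", "position"]),
                         pd.DataFrame(columns=["contig", "position"]), -1)


# ---------------------------------------------------------------------
# Mendelian errors
# ---------------------------------------------------------------------

def mendel_consistent_oracle(sire, dam, child):
    """Brute force: child consistent iff some gamete pair reproduces it."""
    alleles = {0: [0], 1: [0, 1], 2: [1]}
    return any(
        a + b == child for a in alleles[sire] for b in alleles[dam]
    )


def test_mendelian_errors_all_27_trio_configurations():
    """The consistency table agrees with gamete enumeration everywhere."""
    configs = list(itertools.product([0, 1, 2], repeat=3))
    calls = np.array(
        [[s for s, d, c in configs], [d for s, d, c in configs], [c for s, d, c in configs]]
    )
    m = make_matrix(calls, sample_ids=["sire", "dam", "child"])
    ped = pd.DataFrame(
        {
            "sample_id": ["sire", "dam", "child"],
            "family_id": ["f", "f", "f"],
            "sire_id": [None, None, "sire"],
            "dam_id": [None, None, "dam"],
            "tissue": "needle",
        }
    )
    result = mendelian_errors(m, ped)
    for j, (s, d, c) in enumerate(configs):
        assert result.errors[0, j] == (not mendel_consistent_oracle(s, d, c)), (s, d, c)


def test_mendelian_missing_member_not_evaluated():
    m = make_matrix([[0], [-1], [1]], sample_ids=["sire", "dam", "child"])
    ped = pd.DataFrame(
        {
            "sample_id": ["sire", "dam", "child"],
            "family_id": "f",
            "sire_id": [None, None, "sire"],
            "dam_id": [None, None, "dam"],
            "tissue": "needle",
        }
    )
    result = mendelian_errors(m, ped)
    assert result.evaluated.sum() == 0
    assert result.errors.sum() == 0


# ---------------------------------------------------------------------
# HW filter
# ---------------------------------------------------------------------

def test_hw_filter_strict_inequality():
    table = pd.DataFrame(
        {"marker_id": ["a", "b", "c"], "hw_p": [0.0009, 0.001, 1.0]}
    )
    report = hw_filter(table, 0.001)
    assert report["outcome"].tolist() == ["fail", "pass", "pass"]


# ---------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------

def greedy_prune_reference(calls, maf, ids, positions, threshold):
    """Independent straightforward reimplementation of the stated rule."""
    order = sorted(range(len(ids)), key=lambda j: (positions[j], ids[j]))
    kept = set(order)
    for a, j in enumerate(order):
        for k in order[a + 1 :]:
            if j not in kept or k not in kept:
                continue
            r2 = ld_r2(calls[:, j], calls[:, k])
            if np.isnan(r2) or r2 <= threshold:
                continue
            if maf[j] > maf[k]:
                kept.discard(k)
            elif maf[k] > maf[j]:
                kept.discard(j)
            else:
                kept.discard(k if ids[j] < ids[k] else j)
    return {ids[j] for j in kept}


def test_ld_prune_keeps_higher_maf_of_pair():
    # m0 and m1 perfectly correlated; m0 has higher MAF
    calls = np.array([[0, 0], [1, 1], [2, 2], [1, 1], [0, 0], [1, 1]])
    m = make_matrix(calls)
    table = pd.DataFrame({"marker_id": ["m0", "m1"], "maf": [0.3, 0.2]})
    assert ld_prune(m, table, 0.9) == ["m0"]


def test_ld_prune_strict_threshold_keeps_exact_boundary():
    rng = np.random.default_rng(1)
    x = rng.integers(0, 3, 50)
    m = make_matrix(np.stack([x, x], axis=1))
    table = pd.DataFrame({"marker_id": ["m0", "m1"], "maf": [0.3, 0.2]})
    # r2 == 1 > 0.9 prunes; with threshold 1.0 the pair survives (strict >)
    assert ld_prune(m, table, 1.0) == ["m0", "m1"]


def test_ld_prune_mutually_correlated_triple():
    x = np.array([0, 0, 1, 1, 2, 2])
    m = make_matrix(np.stack([x, x, x], axis=1))
    table = pd.DataFrame({"marker_id": ["m0", "m1", "m2"], "maf": [0.3, 0.2, 0.1]})
    assert ld_prune(m, table, 0.9) == ["m0"]


def test_ld_prune_matches_reference_and_is_violation_free():
    """Exhaustive check on random groups of <= 8 loci."""
    rng = np.random.default_rng(42)
    for trial in range(20):
        n_loci = rng.integers(2, 9)
        base = rng.integers(0, 3, size=(30, n_loci))
        # induce correlation by copying columns with noise
        for j in range(1, n_loci):
            if rng.random() < 0.5:
                base[:, j] = base[:, j - 1]
        m = make_matrix(base)
        maf = np.clip(rng.random(n_loci) * 0.5, 0.01, 0.5)
        table = pd.DataFrame({"marker_id": m.locus_ids, "maf": maf})
        kept = ld_prune(m, table, 0.9)
        want = greedy_prune_reference(
            base, maf, m.locus_ids, m.position, 0.9
        )
        assert set(kept) == want, trial
        # no kept pair violates the threshold
        for a in range(len(kept)):
            for b in range(a + 1, len(kept)):
                r2 = ld_r2(
                    base[:, m.locus_ids.index(kept[a])],
                    base[:, m.locus_ids.index(kept[b])],
                )
                assert np.isnan(r2) or r2 <= 0.9


# ---------------------------------------------------------------------
# call rates and conversion classes
# ---------------------------------------------------------------------

def test_call_rate_and_sample_qc():
    calls = np.array([[0, 1, -1, 2], [-1, -1, -1, -1]])
    m = make_matrix(calls)
    per_sample = call_rate(m, by="sample")
    assert per_sample.tolist() == [0.75, 0.0]
    per_marker = call_rate(m, by="marker")
    assert per_marker.tolist() == [0.5, 0.5, 0.0, 0.5]
    assert sample_qc(per_sample, 0.75) == ["s0"]  # >= semantics


@pytest.mark.parametrize(
    "calls, expected",
    [
        ([0, 1, 2, 1], "PHR"),
        ([0, 1, 1, 0], "NMH"),
        ([1, 2, 2, 1], "NMH"),
        ([0, 0, 0, 0], "MHR"),
        ([2, 2, 2, 2], "MHR"),
        ([1, 1, 1, 1], "UNCLASSIFIED"),  # het-only: paralog signature
        ([0, 2, 0, 2], "UNCLASSIFIED"),
    ],
)
def test_conversion_classify(calls, expected):
    assert conversion_classify(np.array(calls)) == expected


def test_conversion_classify_call_rate_dominates():
    calls = np.array([0, 1, 2] + [-1] * 7)
    assert conversion_classify(calls, cr_threshold=0.97) == "CRBT"
    assert conversion_classify(calls, cr_threshold=0.2) == "PHR"


def test_conversion_classify_matrix_uses_diploids_only():
    m = make_matrix([[0, 0], [1, 0], [2, 1]], ploidy=[2, 2, 1])
    classes = conversion_classify_matrix(m)
    assert classes.tolist() == ["NMH", "MHR"]


# ---------------------------------------------------------------------
# duplicate merging
# ---------------------------------------------------------------------

def _marker_frame():
    return pd.DataFrame(
        {
            "marker_id": ["a1", "a2", "b1"],
            "source": ["ukceh1", "uoulu_rnaseq", "luke_candidate"],
            "priority_tier": [1, 3, 4],
            "contig": ["c1", "c1", "c2"],
            "position": [100, 100, 500],
            "ref": ["A", "A", "G"],
            "alt": ["T", "T", "C"],
        }
    )


def test_merge_duplicates_keeps_highest_priority_source():
    merged, conflicts = merge_duplicates(_marker_frame())
    assert len(merged) == 2
    row = merged[merged["contig"] == "c1"].iloc[0]
    assert row["source"] == "ukceh1"
    assert row["merged_sources"] == "ukceh1,uoulu_rnaseq"
    assert conflicts.empty


def test_merge_duplicates_identity_without_duplicates():
    frame = _marker_frame().iloc[[0, 2]]
    merged, _ = merge_duplicates(frame)
    assert sorted(merged["marker_id"]) == ["a1", "b1"]


def test_merge_duplicates_drops_allele_conflicts():
    frame = _marker_frame()
    frame.loc[1, "alt"] = "G"
    merged, conflicts = merge_duplicates(frame)
    assert "a1" not in merged["marker_id"].tolist()
    assert set(conflicts["marker_id"]) == {"a1", "a2"}
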