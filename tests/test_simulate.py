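"""The synthetic-data generators: determinism, distributional fidelity
and artifact injection."""

import numpy as np
import pytest
from scipy import stats

from panelforge import (
    SimConfig,
    ValidationError,
    default_family_design,
    inject_errors,
    inject_missing,
    inject_paralogs,
    maf_per_locus,
    replicate_error_rate,
    sim_ascertainment,
    sim_controls,
    sim_haploids,
    sim_pedigree,
    sim_population,
    sim_structured,
)
from panelforge.marker_filters import mendelian_errors

from conftest import make_matrix


def test_default_family_design_matches_study_layout():
    design = default_family_design()
    parents = {p for _, s, d, _ in design for p in (s, d)}
    assert len(design) == 10
    assert len(parents) == 18
    assert sum(n for *_, n in design) == 135
    # two family pairs share exactly one parent
    shared = 0
    for i, (_, s1, d1, _) in enumerate(design):
        for _, s2, d2, _ in design[i + 1 :]:
            shared += len({s1, d1} & {s2, d2})
    assert shared == 2


def test_sim_population_deterministic_under_seed():
    cfg = SimConfig(seed=7, n_loci=200, n_pop_samples=25)
    a, b = sim_population(cfg), sim_population(cfg)
    np.testing.assert_array_equal(a.calls, b.calls)


def test_sim_population_fixed_maf_half():
    cfg = SimConfig(seed=8, n_loci=1, n_pop_samples=10_000, maf_model=("fixed", [0.5]))
    m = sim_population(cfg)
    freq = m.calls.sum() / (2 * m.n_samples)
    # binomial 99% CI for p=0.5 over 20,000 chromosomes
    half_width = 2.576 * np.sqrt(0.25 / 20_000)
    assert abs(freq - 0.5) < half_width


def test_sim_population_rejects_bad_config():
    with pytest.raises(ValidationError):
        SimConfig(n_loci=0)
    with pytest.raises(ValidationError):
        SimConfig(error_rate=1.5)


def test_sim_structured_requires_positive_fst(small_population):
    with pytest.raises(ValidationError):
        sim_structured(SimConfig(seed=1, fst=0.0))


def test_sim_structured_fst_limit_matches_panmixia():
    """As F_ST -> 0 the two-population draw converges to one population."""
    cfg_s = SimConfig(seed=9, n_loci=3000, n_pop_samples=200, fst=1e-6)
    cfg_p = SimConfig(seed=9, n_loci=3000, n_pop_samples=200)
    f_s = maf_per_locus(sim_structured(cfg_s))
    f_p = maf_per_locus(sim_population(cfg_p))
    assert stats.ks_2samp(f_s, f_p).pvalue > 0.01


def test_sim_pedigree_clean_has_zero_mendel_errors(pedigree_sim):
    matrix, pedigree = pedigree_sim
    result = mendelian_errors(matrix, pedigree)
    assert result.trios.shape[0] == 135
    assert result.errors.sum() == 0


def test_sim_pedigree_cross_of_opposite_homozygotes_gives_hets():
    founders = make_matrix([[0, 2], [2, 0]], sample_ids=["A", "B"])
    cfg = SimConfig(seed=3, family_design=[("f1", "A", "B", 20)])
    matrix, _ = sim_pedigree(cfg, founders)
    offspring = matrix.calls[2:]
    assert (offspring == 1).all()


def test_sim_pedigree_rejects_selfing_and_unknown_founders():
    founders = make_matrix([[0], [2]], sample_ids=["A", "B"])
    with pytest.raises(ValidationError):
        sim_pedigree(SimConfig(family_design=[("f1", "A", "A", 2)]), founders)
    with pytest.raises(ValidationError):
        sim_pedigree(SimConfig(family_design=[("f1", "A", "X", 2)]), founders)


def test_sim_haploids_transmission():
    mothers = make_matrix([[0, 2, 1]], sample_ids=["M"])
    hap = sim_haploids(mothers, ["M"], 2000, seed=11)
    assert (hap.ploidy == 1).all()
    assert (hap.calls[:, 0] == 0).all()       # hom-ref mother: always ref
    assert (hap.calls[:, 1] == 2).all()       # hom-alt mother: always alt
    assert not (hap.calls == 1).any()         # meiosis never yields het
    frac_alt = (hap.calls[:, 2] == 2).mean()  # het mother: fair coin
    assert abs(frac_alt - 0.5) < 2.576 * np.sqrt(0.25 / 2000)


def test_sim_haploids_rejects_haploid_mother():
    mothers = make_matrix([[0, 2]], ploidy=[1], sample_ids=["M"])
    with pytest.raises(ValidationError):
        sim_haploids(mothers, ["M"], 1, seed=0)


class TestParalogInjection:
    def test_fixed_divergence_makes_every_call_het(self):
        m = make_matrix([[0, 2], [2, 0], [1, 2]], ploidy=[2, 2, 1])
        out, truth = inject_paralogs(m, 1.0, "fixed", seed=1)
        assert (out.calls == 1).all()
        assert truth["is_paralog"].all()

    def test_fraction_zero_is_identity(self, small_population):
        out, truth = inject_paralogs(small_population, 0.0, seed=2)
        np.testing.assert_array_equal(out.calls, small_population.calls)
        assert not truth["is_paralog"].any()

    def test_fixed_divergence_fails_hw_at_n50(self):
        from panelforge import hw_exact_test

        # all-het column over 50 diploids: p below any conventional alpha
        assert hw_exact_test(0, 50, 0) < 1e-12

    def test_segregating_mode_superposition(self):
        m = make_matrix([[0], [2]], ploidy=[2, 2])
        out, _ = inject_paralogs(m, 1.0, "segregating", seed=3, paralog_freq=1.0)
        # hidden copy fixed alt: ref-carriers become het, hom-alt stays
        assert out.calls[0, 0] == 1
        assert out.calls[1, 0] == 2


class TestErrorInjection:
    def test_rate_zero_identity(self, small_population):
        out = inject_errors(small_population, 0.0, seed=4)
        np.testing.assert_array_equal(out.calls, small_population.calls)

    def test_haploid_errors_never_het(self):
        m = make_matrix(np.zeros((1, 500), dtype=int), ploidy=[1],
                        position=np.arange(1, 501) * 10)
        out = inject_errors(m, 1.0, seed=5)
        assert not (out.calls == 1).any()

    def test_missing_preserved(self):
        m = make_matrix([[-1, 0]])
        out = inject_errors(m, 1.0, seed=6)
        assert out.calls[0, 0] == -1

    def test_discordance_matches_enumeration_oracle(self):
        """Replicate discordance under the uniform-substitution model.

        Per call each replicate reports the truth w.p. 1-e and a
        uniform draw from {0,1,2} w.p. e; the collision probability
        over the 3x3 outcome table gives the expected mismatch rate.
        """
        e = 0.01
        p_match = (1 - 2 * e / 3) ** 2 + 2 * (e / 3) ** 2
        expect = 1 - p_match
        m = make_matrix(
            np.ones((1, 20_000), dtype=int), position=np.arange(1, 20_001) * 5
        )
        controls, groups = sim_controls(m, ["s0"], 2, e, seed=7)
        rate = replicate_error_rate(
            controls.calls[controls.sample_index("s0_rep1")],
            controls.calls[controls.sample_index("s0_rep2")],
        )
        half_width = 2.576 * np.sqrt(expect * (1 - expect) / 20_000)
        assert abs(rate - expect) < half_width
        assert set(groups["replicate_group"]) == {"s0"}


def test_inject_missing_rate_and_identity(small_population):
    same = inject_missing(small_population, 0.0, seed=8)
    np.testing.assert_array_equal(same.calls, small_population.calls)
    out = inject_missing(small_population, 0.3, seed=8)
    frac = (out.calls == -1).mean()
    assert abs(frac - 0.3) < 0.02


class TestAscertainment:
    def test_threshold_zero_keeps_panel_polymorphic(self, small_population):
        kept, panel = sim_ascertainment(small_population, 10, 0.0, seed=9)
        sub = small_population.take_samples(
            [small_population.sample_index(s) for s in panel]
        )
        maf = maf_per_locus(sub)
        assert set(kept.tolist()) == set(np.flatnonzero(np.nan_to_num(maf) > 0).tolist())

    def test_full_panel_equals_plain_maf_filter(self, small_population):
        kept, _ = sim_ascertainment(
            small_population, small_population.n_samples, 0.05, seed=10
        )
        maf = maf_per_locus(small_population)
        assert set(kept.tolist()) == set(np.flatnonzero(maf >= 0.05).tolist())

    def test_threshold_above_half_rejected(self, small_population):
        with pytest.raises(ValidationError):
            sim_ascertainment(small_population, 5, 0.6, seed=11)


def test_controls_error_free_replicates_identical(small_population):
    controls, _ = sim_controls(small_population, ["S0001"], 2, 0.0, seed=12)
    a = controls.calls[controls.sample_index("S0001_rep1")]
    b = controls.calls[controls.sample_index("S0001_rep2")]
    assert replicate_error_rate(a, b) == 0.0


def test_controls_unknown_id_rejected(small_population):
    with pytest.raises(KeyError):
        sim_controls(small_population, ["nope"], 2, 0.0, seed=13)
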