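"""Synthetic genotype datasets with the structure the pipeline assumes.

The generator emulates the study system end to end: a natural
population under Hardy-Weinberg equilibrium with a neutral-like folded
MAF spectrum, full-sib crossing designs with shared parents, haploid
megagametophytes produced by maternal meiosis, paralog-collapsed loci,
per-call genotyping error and missingness, MAF-threshold ascertainment
in a small discovery panel, and replicated control samples.

Every generator is a pure function of its configuration and seed; the
artifact-injection composition order is fixed as paralogs -> errors ->
missingness, and truth labels survive the composition (they are keyed
by locus/sample id, which injection never rewrites).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix, ValidationError
from .popgen_stats import expected_neutral_folded_sfs

__all__ = [
    "SimConfig",
    "default_family_design",
    "sim_population",
    "sim_structured",
    "sim_pedigree",
    "sim_study_pedigree",
    "sim_haploids",
    "inject_paralogs",
    "inject_errors",
    "inject_missing",
    "sim_ascertainment",
    "sim_controls",
]

#: Priority sources mirroring the array's eight discovery panels.
SOURCE_LABELS = (
    "procogen_haploid",
    "procogen_diploid",
    "uoulu_exome",
    "uoulu_rnaseq",
    "ukceh1",
    "ukceh2",
    "uoulu_candidate",
    "luke_candidate",
)


def default_family_design() -> list[tuple[str, str, str, int]]:
    """The default crossing layout: 10 full-sib families, 18 distinct
    parents, 135 offspring, with two family pairs each sharing one
    parent (f01/f09 and f06/f10)."""
    return [
        ("f01", "P01", "P02", 14),
        ("f02", "P03", "P04", 14),
        ("f03", "P05", "P06", 14),
        ("f04", "P07", "P08", 14),
        ("f05", "P09", "P10", 14),
        ("f06", "P11", "P12", 13),
        ("f07", "P13", "P14", 13),
        ("f08", "P15", "P16", 13),
        ("f09", "P01", "P17", 13),
        ("f10", "P11", "P18", 13),
    ]


@dataclass
class SimConfig:
    """Parameters of a synthetic dataset.

    ``maf_model`` is one of ``("neutral",)``, ``("uniform", lo, hi)``
    or ``("fixed", [f1, f2, ...])``.  Under the neutral model each
    locus draws its minor-allele *count* from the folded neutral class
    weights at the sample's chromosome number and the alleles are
    placed uniformly at random, so the realized spectrum is the neutral
    folded SFS up to multinomial noise.
    """

    seed: int = 0
    n_loci: int = 1000
    n_pop_samples: int = 100
    maf_model: tuple = ("uniform", 0.05, 0.5)
    fst: float = 0.0
    family_design: list[tuple[str, str, str, int]] = field(
        default_factory=default_family_design
    )
    n_haploids_per_mother: int = 1
    error_rate: float = 0.0
    missing_rate: float = 0.0
    paralog_fraction: float = 0.0
    discovery_panel_size: int = 17
    discovery_maf_threshold: float = 0.05
    loci_per_contig: int = 1

    def __post_init__(self) -> None:
        for name in ("error_rate", "missing_rate", "paralog_fraction", "fst"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.fst >= 1.0:
            raise ValidationError("fst must lie in [0, 1)")
        if self.n_loci <= 0:
            raise ValidationError("n_loci must be positive")
        if self.n_pop_samples <= 0:
            raise ValidationError("n_pop_samples must be positive")


# ---------------------------------------------------------------------
# locus scaffolding
# ---------------------------------------------------------------------

def _locus_frame(n_loci: int, loci_per_contig: int) -> tuple[list[str], np.ndarray, np.ndarray]:
    ids = [f"L{i + 1:06d}" for i in range(n_loci)]
    contig_idx = np.arange(n_loci) // max(loci_per_contig, 1)
    contig = np.array([f"ctg{c + 1:05d}" for c in contig_idx], dtype=object)
    within = np.arange(n_loci) % max(loci_per_contig, 1)
    position = (within + 1) * 1000
    return ids, contig, position


def _draw_freqs(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    """Per-locus alternate-allele frequencies (orientation randomized)."""
    model = config.maf_model
    kind = model[0]
    if kind == "uniform":
        maf = rng.uniform(model[1], model[2], size=config.n_loci)
    elif kind == "fixed":
        freqs = np.asarray(model[1], dtype=float)
        maf = freqs[rng.integers(0, len(freqs), size=config.n_loci)]
    elif kind == "neutral":
        raise ValidationError("neutral model draws counts, not frequencies")
    else:
        raise ValidationError(f"unknown maf_model {kind!r}")
    if (maf < 0).any() or (maf > 0.5).any():
        raise ValidationError("MAF draws must lie in [0, 0.5]")
    flip = rng.random(config.n_loci) < 0.5
    return np.where(flip, 1.0 - maf, maf)


def sim_population(config: SimConfig) -> GenotypeMatrix:
    """Simulate an unstructured HWE population sample.

    Frequency-model loci draw genotypes as Binomial(2, p); the neutral
    model realizes an exact minor-allele count per locus and pairs
    chromosomes at random, which is the HWE distribution conditional on
    the allele count.
    """
    rng = np.random.default_rng(config.seed)
    n, L = config.n_pop_samples, config.n_loci
    if config.maf_model[0] == "neutral":
        n_chrom = 2 * n
        props = expected_neutral_folded_sfs(n_chrom)
        classes = rng.choice(len(props), size=L, p=props) + 1
        calls = np.zeros((n, L), dtype=np.int8)
        for j in range(L):
            chroms = np.zeros(n_chrom, dtype=np.int8)
            chroms[rng.choice(n_chrom, size=classes[j], replace=False)] = 1
            if rng.random() < 0.5:  # random minor-allele orientation
                chroms = 1 - chroms
            calls[:, j] = chroms[0::2] + chroms[1::2]
    else:
        p = _draw_freqs(rng, config)
        calls = rng.binomial(2, p[None, :], size=(n, L)).astype(np.int8)
    ids, contig, position = _locus_frame(L, config.loci_per_contig)
    return GenotypeMatrix(
        sample_ids=[f"S{i + 1:04d}" for i in range(n)],
        locus_ids=ids,
        calls=calls,
        ploidy=np.full(n, 2),
        contig=contig,
        position=position,
    )


def sim_structured(config: SimConfig) -> GenotypeMatrix:
    """Two populations diverged by F_ST under the Balding-Nichols model.

    Each population's allele frequency is a Beta draw around the
    ancestral frequency with variance p(1-p)F_ST; sample ids carry the
    population label and ``sample_meta`` records it.
    """
    if not 0.0 < config.fst < 1.0:
        raise ValidationError("sim_structured requires fst in (0, 1)")
    rng = np.random.default_rng(config.seed)
    L = config.n_loci
    n_a = config.n_pop_samples // 2
    n_b = config.n_pop_samples - n_a
    p_anc = _draw_freqs(rng, config)
    f = config.fst
    shape = (1.0 - f) / f
    pops = []
    for n_pop in (n_a, n_b):
        p_pop = rng.beta(np.maximum(p_anc * shape, 1e-12), np.maximum((1 - p_anc) * shape, 1e-12))
        pops.append(rng.binomial(2, p_pop[None, :], size=(n_pop, L)).astype(np.int8))
    calls = np.vstack(pops)
    ids, contig, position = _locus_frame(L, config.loci_per_contig)
    sample_ids = [f"popA_{i + 1:04d}" for i in range(n_a)] + [
        f"popB_{i + 1:04d}" for i in range(n_b)
    ]
    meta = pd.DataFrame(
        {"sample_id": sample_ids, "population": ["A"] * n_a + ["B"] * n_b}
    )
    return GenotypeMatrix(
        sample_ids=sample_ids,
        locus_ids=ids,
        calls=calls,
        ploidy=np.full(config.n_pop_samples, 2),
        contig=contig,
        position=position,
        sample_meta=meta,
    )


# ---------------------------------------------------------------------
# pedigrees and haploids
# ---------------------------------------------------------------------

def _transmit(parent_calls: np.ndarray, rng: np.random.Generator, n_off: int) -> np.ndarray:
    """One gamete per offspring per locus from a diploid parent."""
    L = parent_calls.shape[0]
    het = parent_calls == 1
    base = (parent_calls == 2).astype(np.int8)
    gametes = np.tile(base, (n_off, 1))
    coin = rng.integers(0, 2, size=(n_off, L), dtype=np.int8)
    gametes[:, het] = coin[:, het]
    return gametes


def sim_pedigree(
    config: SimConfig, founders: GenotypeMatrix
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Mate founder pairs per ``config.family_design``.

    Each offspring receives one allele per locus from each parent,
    independently across loci.  The returned matrix holds the founders
    followed by the offspring, with a pedigree table covering both.
    """
    rng = np.random.default_rng(config.seed + 1)
    if (founders.ploidy != 2).any():
        raise ValidationError("founders must all be diploid")
    rows = []
    off_calls = []
    off_ids = []
    for fam, sire, dam, n_off in config.family_design:
        if sire == dam:
            raise ValidationError(f"family {fam}: sire and dam are the same sample")
        try:
            si, di = founders.sample_index(sire), founders.sample_index(dam)
        except KeyError as e:
            raise ValidationError(f"family {fam}: missing founder ({e})") from None
        child = _transmit(founders.calls[si], rng, n_off) + _transmit(
            founders.calls[di], rng, n_off
        )
        # a missing parent call makes the transmitted allele unknown
        bad = (founders.calls[si] == MISSING) | (founders.calls[di] == MISSING)
        child[:, bad] = MISSING
        off_calls.append(child.astype(np.int8))
        for k in range(n_off):
            cid = f"{fam}_o{k + 1:02d}"
            off_ids.append(cid)
            rows.append((cid, fam, sire, dam, "embryo", None))
    parent_ids = sorted({p for _, s, d, _ in config.family_design for p in (s, d)})
    for pid in parent_ids:
        rows.insert(0, (pid, "founder", None, None, "needle", None))
    keep = [founders.sample_index(p) for p in parent_ids]
    matrix = GenotypeMatrix(
        sample_ids=parent_ids + off_ids,
        locus_ids=list(founders.locus_ids),
        calls=np.vstack([founders.calls[keep]] + off_calls),
        ploidy=np.full(len(parent_ids) + len(off_ids), 2),
        contig=founders.contig.copy(),
        position=founders.position.copy(),
        ref=founders.ref.copy(),
        alt=founders.alt.copy(),
    )
    pedigree = pd.DataFrame(
        rows,
        columns=["sample_id", "family_id", "sire_id", "dam_id", "tissue", "replicate_group"],
    )
    return matrix, pedigree


def sim_study_pedigree(config: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Founders plus the configured crossing design in one call.

    Simulates one founder per distinct parent in ``family_design``
    under the population model, then mates them; the default design is
    the 10-family / 18-parent / 135-offspring layout with two
    shared-parent family pairs.
    """
    parents = sorted({p for _, s, d, _ in config.family_design for p in (s, d)})
    fcfg = replace(config, n_pop_samples=len(parents))
    founders = sim_population(fcfg)
    founders.sample_ids[:] = parents
    return sim_pedigree(config, founders)


def sim_haploids(
    mothers: GenotypeMatrix,
    mother_ids: Sequence[str],
    n_per_mother: int,
    seed: int,
) -> GenotypeMatrix:
    """Megagametophytes: one maternal meiotic product per haploid sample.

    Per locus one maternal allele is drawn uniformly; output calls are
    on the haploid dosage scale {0, 2} (never 1 without artifacts).
    """
    rng = np.random.default_rng(seed)
    calls, ids = [], []
    for mid in mother_ids:
        mi = mothers.sample_index(mid)
        if mothers.ploidy[mi] == 1:
            raise ValidationError(f"mother {mid!r} is haploid; megagametophytes need a diploid mother")
        gam = _transmit(mothers.calls[mi], rng, n_per_mother) * 2
        gam[:, mothers.calls[mi] == MISSING] = MISSING
        calls.append(gam.astype(np.int8))
        ids.extend(f"{mid}_mg{k + 1:02d}" for k in range(n_per_mother))
    n_hap = len(ids)
    return GenotypeMatrix(
        sample_ids=ids,
        locus_ids=list(mothers.locus_ids),
        calls=np.vstack(calls) if calls else np.zeros((0, mothers.n_loci), dtype=np.int8),
        ploidy=np.full(n_hap, 1),
        contig=mothers.contig.copy(),
        position=mothers.position.copy(),
        ref=mothers.ref.copy(),
        alt=mothers.alt.copy(),
    )


# ---------------------------------------------------------------------
# artifact injection (fixed order: paralogs -> errors -> missing)
# ---------------------------------------------------------------------

def inject_paralogs(
    matrix: GenotypeMatrix,
    fraction: float,
    divergence_mode: str = "fixed",
    seed: int = 0,
    paralog_freq: float = 0.2,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Collapse a fraction of loci with a hidden duplicate copy.

    ``fixed`` mode models a fixed difference between the two collapsed
    copies: every sample carries both alleles, so every non-missing
    call (any ploidy) becomes heterozygous — the classic spurious-SNP
    signature.  ``segregating`` mode gives the hidden copy its own HWE
    genotype at ``paralog_freq``; the observed call is the superposition
    of the allele sets of both copies.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError("fraction must lie in [0, 1]")
    if divergence_mode not in ("fixed", "segregating"):
        raise ValidationError(f"unknown divergence_mode {divergence_mode!r}")
    out = matrix.copy()
    rng = np.random.default_rng(seed)
    n_par = int(round(fraction * matrix.n_loci))
    chosen = np.sort(rng.choice(matrix.n_loci, size=n_par, replace=False))
    truth = pd.DataFrame(
        {
            "locus_id": matrix.locus_ids,
            "is_paralog": np.isin(np.arange(matrix.n_loci), chosen),
            "divergence_mode": [
                divergence_mode if j in set(chosen.tolist()) else ""
                for j in range(matrix.n_loci)
            ],
        }
    )
    if n_par == 0:
        return out, truth
    calls = out.calls
    hap = out.is_haploid
    for j in chosen:
        col = calls[:, j]
        present = col != MISSING
        if divergence_mode == "fixed":
            calls[present, j] = 1
            continue
        # hidden copy: HWE draw per sample (one allele for haploids)
        copy2 = np.where(
            hap,
            2 * rng.binomial(1, paralog_freq, size=out.n_samples),
            rng.binomial(2, paralog_freq, size=out.n_samples),
        )
        has_ref = (col <= 1) | (copy2 <= 1)  # either copy carries ref
        has_alt = (col >= 1) | (copy2 >= 1)
        merged = np.where(has_ref & has_alt, 1, np.where(has_alt, 2, 0))
        calls[present, j] = merged[present]
    return out, truth


def inject_errors(matrix: GenotypeMatrix, rate: float, seed: int = 0) -> GenotypeMatrix:
    """Uniform-substitution genotyping error.

    Each non-missing call is independently replaced with probability
    ``rate`` by a uniform draw from the sample's valid call space
    (diploid {0, 1, 2}, haploid {0, 2}); the draw may equal the
    original call, so the realized flip rate is 2/3 (diploid) or 1/2
    (haploid) of ``rate``.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValidationError("rate must lie in [0, 1]")
    out = matrix.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    hit = (rng.random(out.calls.shape) < rate) & (out.calls != MISSING)
    dip_draw = rng.integers(0, 3, size=out.calls.shape, dtype=np.int8)
    hap_draw = 2 * rng.integers(0, 2, size=out.calls.shape, dtype=np.int8)
    draw = np.where(out.is_haploid[:, None], hap_draw, dip_draw)
    out.calls = np.where(hit, draw, out.calls).astype(np.int8)
    return out


def inject_missing(matrix: GenotypeMatrix, rate: float, seed: int = 0) -> GenotypeMatrix:
    """Set each call to MISSING independently with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValidationError("rate must lie in [0, 1]")
    out = matrix.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    hit = rng.random(out.calls.shape) < rate
    out.calls = np.where(hit, MISSING, out.calls).astype(np.int8)
    return out


# ---------------------------------------------------------------------
# ascertainment and controls
# ---------------------------------------------------------------------

def sim_ascertainment(
    matrix: GenotypeMatrix,
    panel_size: int,
    maf_threshold: float,
    seed: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """MAF-threshold SNP discovery in a random panel.

    Returns the indices of loci polymorphic in the panel with
    panel-MAF >= threshold, plus the panel member ids.  This is the
    mechanism that depletes rare frequency classes in downstream
    samples (ascertainment bias).
    """
    if maf_threshold > 0.5:
        raise ValidationError("maf_threshold cannot exceed 0.5")
    if panel_size > matrix.n_samples:
        raise ValidationError("panel_size exceeds the number of samples")
    rng = np.random.default_rng(seed)
    panel_idx = np.sort(rng.choice(matrix.n_samples, size=panel_size, replace=False))
    panel = matrix.take_samples(panel_idx)
    from .popgen_stats import maf_per_locus

    maf = maf_per_locus(panel)
    keep = np.flatnonzero(np.nan_to_num(maf) > 0)
    keep = keep[maf[keep] >= maf_threshold]
    return keep, [matrix.sample_ids[i] for i in panel_idx]


def sim_controls(
    matrix: GenotypeMatrix,
    sample_ids: Sequence[str],
    n_replicates: int,
    error_rate: float,
    seed: int = 0,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Replicated control samples with independent per-replicate error.

    Each listed sample is duplicated ``n_replicates`` times; the
    returned table maps every replicate (and the original) to its
    replicate group for concordance analysis.
    """
    rng = np.random.default_rng(seed)
    rows = [(sid, sid) for sid in matrix.sample_ids if sid in set(sample_ids)]
    rep_calls, rep_ids, rep_ploidy = [], [], []
    for sid in sample_ids:
        i = matrix.sample_index(sid)
        for k in range(n_replicates):
            rid = f"{sid}_rep{k + 1}"
            base = matrix.calls[i].copy()
            if error_rate > 0:
                hit = (rng.random(base.shape) < error_rate) & (base != MISSING)
                if matrix.ploidy[i] == 1:
                    draw = 2 * rng.integers(0, 2, size=base.shape, dtype=np.int8)
                else:
                    draw = rng.integers(0, 3, size=base.shape, dtype=np.int8)
                base = np.where(hit, draw, base).astype(np.int8)
            rep_calls.append(base)
            rep_ids.append(rid)
            rep_ploidy.append(matrix.ploidy[i])
            rows.append((rid, sid))
    out = GenotypeMatrix(
        sample_ids=list(matrix.sample_ids) + rep_ids,
        locus_ids=list(matrix.locus_ids),
        calls=np.vstack([matrix.calls] + [c[None, :] for c in rep_calls]),
        ploidy=np.concatenate([matrix.ploidy, np.asarray(rep_ploidy, dtype=np.int8)]),
        contig=matrix.contig.copy(),
        position=matrix.position.copy(),
        ref=matrix.ref.copy(),
        alt=matrix.alt.copy(),
    )
    groups = pd.DataFrame(rows, columns=["sample_id", "replicate_group"])
    return out, groups
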