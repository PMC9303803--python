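"""Core in-memory containers shared by every pipeline stage.

Genotypes are stored as additive dosages of the alternate allele:
0 (hom ref), 1 (het), 2 (hom alt), with :data:`MISSING` (-1) as the
no-call sentinel.  Haploid samples (conifer megagametophytes) use the
same dosage scale restricted to {0, 2}, so a ``1`` in a haploid row is
never a real genotype — it is exactly the artifact signal (collapsed
paralogs, call errors) that the marker filters consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel dosage for a missing / no-call genotype.
MISSING: int = -1

VALID_CALLS = frozenset({0, 1, 2, MISSING})

#: Columns required of a pedigree table.
PEDIGREE_COLUMNS = ("sample_id", "family_id", "sire_id", "dam_id", "tissue")

#: Columns required of a marker metadata table.
MARKER_COLUMNS = ("marker_id", "source", "priority_tier")

#: Marker conversion performance categories (assigned from calls only).
CONVERSION_CLASSES = ("PHR", "NMH", "MHR", "CRBT", "UNCLASSIFIED")

TISSUES = ("needle", "megagametophyte", "embryo")


class ValidationError(ValueError):
    """A container failed its structural invariants."""


class FormatError(ValueError):
    """An input file could not be parsed as the declared format."""


@dataclass
class GenotypeMatrix:
    """Samples x loci matrix of biallelic dosage calls.

    Parameters
    ----------
    sample_ids : ordered sample identifiers (length ``n_samples``).
    locus_ids : ordered locus identifiers (length ``n_loci``).
    calls : ``int8`` array of shape ``(n_samples, n_loci)`` over
        ``{0, 1, 2, MISSING}``.
    ploidy : per-sample ploidy in ``{1, 2}``.
    contig : per-locus contig name.
    position : per-locus 1-based coordinate.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray
    ploidy: np.ndarray
    contig: np.ndarray
    position: np.ndarray
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None
    sample_meta: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.ploidy = np.asarray(self.ploidy, dtype=np.int8)
        self.contig = np.asarray(self.contig, dtype=object)
        self.position = np.asarray(self.position, dtype=np.int64)
        if self.ref is None:
            self.ref = np.full(self.n_loci, "A", dtype=object)
        if self.alt is None:
            self.alt = np.full(self.n_loci, "C", dtype=object)
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def is_haploid(self) -> np.ndarray:
        return self.ploidy == 1

    @property
    def is_diploid(self) -> np.ndarray:
        return self.ploidy == 2

    def validate(self) -> None:
        if self.calls.shape != (self.n_samples, self.n_loci):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"({self.n_samples} samples, {self.n_loci} loci)"
            )
        if len(set(self.sample_ids)) != self.n_samples:
            raise ValidationError("duplicate sample_ids")
        if len(set(self.locus_ids)) != self.n_loci:
            raise ValidationError("duplicate locus_ids")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValidationError(
                f"calls contain invalid codes: {np.unique(self.calls[bad])}"
            )
        if not np.isin(self.ploidy, (1, 2)).all():
            raise ValidationError("ploidy must be 1 or 2")
        if self.ploidy.shape != (self.n_samples,):
            raise ValidationError("ploidy must have one entry per sample")
        if self.contig.shape != (self.n_loci,) or self.position.shape != (self.n_loci,):
            raise ValidationError("contig/position must have one entry per locus")
        coords = list(zip(self.contig.tolist(), self.position.tolist()))
        if len(set(coords)) != self.n_loci:
            raise ValidationError("(contig, position) pairs must be unique")

    # -- indexing helpers ----------------------------------------------
    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample_id {sample_id!r}") from None

    def locus_index(self, locus_id: str) -> int:
        try:
            return self.locus_ids.index(locus_id)
        except ValueError:
            raise KeyError(f"unknown locus_id {locus_id!r}") from None

    def take_samples(self, idx: np.ndarray | list[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            locus_ids=list(self.locus_ids),
            calls=self.calls[idx, :].copy(),
            ploidy=self.ploidy[idx].copy(),
            contig=self.contig.copy(),
            position=self.position.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
        )

    def take_loci(self, idx: np.ndarray | list[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            locus_ids=[self.locus_ids[i] for i in idx],
            calls=self.calls[:, idx].copy(),
            ploidy=self.ploidy.copy(),
            contig=self.contig[idx].copy(),
            position=self.position[idx].copy(),
            ref=self.ref[idx].copy(),
            alt=self.alt[idx].copy(),
        )

    def subset_loci(self, locus_ids: list[str]) -> "GenotypeMatrix":
        return self.take_loci([self.locus_index(l) for l in locus_ids])

    def copy(self) -> "GenotypeMatrix":
        return self.take_samples(np.arange(self.n_samples))


@dataclass
class SFS:
    """Folded site-frequency spectrum.

    ``folded_counts[i]`` is the number of polymorphic loci whose minor
    allele appears ``i + 1`` times among ``n_chromosomes`` sampled
    chromosomes; classes run 1 .. floor(n/2).  Monomorphic loci are
    tallied separately so projection can conserve total mass.
    """

    n_chromosomes: int
    folded_counts: np.ndarray
    monomorphic_count: float = 0.0

    def __post_init__(self) -> None:
        self.folded_counts = np.asarray(self.folded_counts, dtype=float)
        if self.n_chromosomes < 2:
            raise ValidationError("n_chromosomes must be >= 2")
        if len(self.folded_counts) != self.n_chromosomes // 2:
            raise ValidationError(
                f"folded_counts must have length {self.n_chromosomes // 2}"
            )
        if (self.folded_counts < 0).any() or self.monomorphic_count < 0:
            raise ValidationError("SFS counts must be non-negative")

    @property
    def n_polymorphic(self) -> float:
        return float(self.folded_counts.sum())

    def proportions(self) -> np.ndarray:
        total = self.folded_counts.sum()
        if total == 0:
            raise ValidationError("empty spectrum has no proportions")
        return self.folded_counts / total

    def to_frame(self) -> pd.DataFrame:
        classes = np.arange(1, len(self.folded_counts) + 1)
        return pd.DataFrame({"minor_allele_count": classes, "n_loci": self.folded_counts})


def validate_pedigree(pedigree: pd.DataFrame, matrix: GenotypeMatrix | None = None) -> pd.DataFrame:
    """Check structural invariants of a pedigree table.

    Sire/dam entries, when present, must name known samples; tissue
    must be one of the recognized types.  When a genotype matrix is
    supplied, megagametophyte rows must be haploid in it.
    """
    missing_cols = [c for c in PEDIGREE_COLUMNS if c not in pedigree.columns]
    if missing_cols:
        raise ValidationError(f"pedigree table missing columns: {missing_cols}")
    if pedigree["sample_id"].duplicated().any():
        dups = pedigree.loc[pedigree["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample_id in pedigree: {dups}")
    known = set(pedigree["sample_id"])
    for col in ("sire_id", "dam_id"):
        named = pedigree[col].dropna()
        named = named[named.astype(str).str.len() > 0]
        unknown = set(named) - known
        if unknown:
            raise ValidationError(f"{col} references unknown samples: {sorted(unknown)}")
    bad_tissue = set(pedigree["tissue"].dropna()) - set(TISSUES)
    if bad_tissue:
        raise ValidationError(f"unknown tissue values: {sorted(bad_tissue)}")
    if matrix is not None:
        ids = set(matrix.sample_ids)
        linked = pedigree[pedigree["sample_id"].isin(ids)]
        mega = linked[linked["tissue"] == "megagametophyte"]
        for sid in mega["sample_id"]:
            if matrix.ploidy[matrix.sample_index(sid)] != 1:
                raise ValidationError(
                    f"megagametophyte sample {sid!r} is not haploid in the genotype matrix"
                )
    return pedigree


def validate_marker_table(markers: pd.DataFrame) -> pd.DataFrame:
    """Check structural invariants of a marker metadata table."""
    missing_cols = [c for c in MARKER_COLUMNS if c not in markers.columns]
    if missing_cols:
        raise ValidationError(f"marker table missing columns: {missing_cols}")
    if markers["marker_id"].duplicated().any():
        dups = markers.loc[markers["marker_id"].duplicated(), "marker_id"].tolist()
        raise ValidationError(f"duplicate marker_id: {dups}")
    if "maf" in markers.columns:
        maf = markers["maf"].dropna()
        if ((maf < 0) | (maf > 0.5)).any():
            raise ValidationError("maf must lie in [0, 0.5]")
    if "hw_p" in markers.columns:
        p = markers["hw_p"].dropna()
        if ((p <= 0) | (p > 1)).any():
            raise ValidationError("hw_p must lie in (0, 1]")
    if "conversion_class" in markers.columns:
        bad = set(markers["conversion_class"].dropna()) - set(CONVERSION_CLASSES)
        if bad:
            raise ValidationError(f"unknown conversion classes: {sorted(bad)}")
    return markers
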