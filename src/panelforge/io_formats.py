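"""Readers and writers for the formats the pipeline touches.

Genotypes travel as VCF 4.2 (biallelic SNP records); pedigree, marker
metadata and spectra travel as TSV with documented headers.  Dosage
encoding on read: diploid ``0/0 -> 0``, ``0/1 -> 1``, ``1/1 -> 2``,
``./. -> MISSING``; haploid ``0 -> 0``, ``1 -> 2``, ``. -> MISSING``.
Haploid samples may also arrive encoded as homozygous diploids (both
conventions exist in the wild); pass ``haploid_samples`` or let the
writer's header annotation declare them.  An artifact het call at a
haploid sample is written as ``0/1`` so it survives a round-trip.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from cyvcf2 import VCF

from .datatypes import (
    MISSING,
    FormatError,
    GenotypeMatrix,
    ValidationError,
    validate_marker_table,
    validate_pedigree,
)
from .datatypes import SFS

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_tables",
    "write_tables",
    "read_sfs",
    "write_sfs",
]

_HAPLOID_HEADER_KEY = "panelforge_haploid_samples"


def read_vcf(
    path: str | Path,
    haploid_samples: list[str] | None = None,
    skip_multiallelic: bool = True,
) -> GenotypeMatrix:
    """Parse a VCF into a :class:`GenotypeMatrix`.

    Sample ploidy is taken from ``haploid_samples`` when given, else
    from a writer annotation in the header, else inferred from GT
    arity (mixed arity within one sample is a validation error, except
    diploid-encoded calls at declared haploid samples).
    """
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as e:  # cyvcf2 raises bare exceptions on bad headers
        raise FormatError(f"cannot parse VCF {path!r}: {e}") from None
    samples = list(vcf.samples)
    if not samples:
        vcf.close()
        raise FormatError(f"VCF {path!r} declares no samples")
    declared_haploid = set(haploid_samples or [])
    m = re.search(rf"##{_HAPLOID_HEADER_KEY}=(\S+)", vcf.raw_header)
    if m and not declared_haploid:
        declared_haploid = set(m.group(1).split(","))
    calls_rows, loci, contigs, positions, refs, alts = [], [], [], [], [], []
    arity_seen: dict[str, set[int]] = {s: set() for s in samples}
    for v in vcf:
        if len(v.ALT) != 1:
            if skip_multiallelic:
                continue
            raise FormatError(
                f"multiallelic record at {v.CHROM}:{v.POS} (pass skip_multiallelic)"
            )
        row = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(v.genotypes):
            alleles = [a for a in gt[:-1]]  # last entry is the phase flag
            if len(alleles) == 1:
                arity_seen[samples[i]].add(1)
                row[i] = MISSING if alleles[0] < 0 else 2 * alleles[0]
            else:
                if samples[i] not in declared_haploid:
                    arity_seen[samples[i]].add(2)
                if any(a < 0 for a in alleles):
                    row[i] = MISSING
                else:
                    row[i] = sum(alleles)
        calls_rows.append(row)
        loci.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}")
        contigs.append(v.CHROM)
        positions.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
    vcf.close()
    for s, arities in arity_seen.items():
        if len(arities) > 1:
            raise ValidationError(f"sample {s!r} mixes haploid and diploid GT records")
    ploidy = np.array(
        [
            1 if (s in declared_haploid or arity_seen[s] == {1}) else 2
            for s in samples
        ]
    )
    calls = (
        np.vstack(calls_rows).T if calls_rows else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        sample_ids=samples,
        locus_ids=loci,
        calls=calls,
        ploidy=ploidy,
        contig=np.array(contigs, dtype=object),
        position=np.array(positions, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
    )


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a :class:`GenotypeMatrix` as uncompressed VCF 4.2.

    Haploid samples are emitted with single-allele GT (artifact het
    calls as ``0/1``) and declared in a header annotation so
    :func:`read_vcf` restores ploidy on round-trip.
    """
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    hap_ids = [s for s, p in zip(matrix.sample_ids, matrix.ploidy) if p == 1]
    if hap_ids:
        header.add_line(f"##{_HAPLOID_HEADER_KEY}={','.join(hap_ids)}")
    for ctg in dict.fromkeys(matrix.contig.tolist()):
        length = int(matrix.position[matrix.contig == ctg].max()) + 1000
        header.add_line(f"##contig=<ID={ctg},length={length}>")
    for s in matrix.sample_ids:
        header.add_sample(s)
    order = np.lexsort((matrix.position, matrix.contig.astype(str)))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in order:
            rec = out.new_record(
                contig=str(matrix.contig[j]),
                start=int(matrix.position[j]) - 1,
                stop=int(matrix.position[j]),
                alleles=(str(matrix.ref[j]), str(matrix.alt[j])),
                id=str(matrix.locus_ids[j]),
            )
            for i, s in enumerate(matrix.sample_ids):
                c = int(matrix.calls[i, j])
                if matrix.ploidy[i] == 1:
                    gt = {0: (0,), 2: (1,), 1: (0, 1), MISSING: (None,)}[c]
                else:
                    gt = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}[c]
                rec.samples[s]["GT"] = gt
            out.write(rec)


# ---------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------

def read_tables(
    genotype_tsv: str | Path,
    pedigree_tsv: str | Path,
    marker_tsv: str | Path,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Load and cross-validate the three pipeline tables.

    The genotype TSV is wide: ``locus_id contig position ref alt``
    then one dosage column per sample ('.' for missing).  Ploidy comes
    from the pedigree tissue column (megagametophyte -> 1).
    """
    geno = pd.read_csv(genotype_tsv, sep="\t", dtype={"contig": str})
    fixed = ["locus_id", "contig", "position", "ref", "alt"]
    missing_cols = [c for c in fixed if c not in geno.columns]
    if missing_cols:
        raise FormatError(f"genotype table missing columns {missing_cols}")
    sample_cols = [c for c in geno.columns if c not in fixed]
    if not sample_cols:
        raise FormatError("genotype table has no sample columns")
    if geno.empty:
        raise FormatError("genotype table has no loci")
    pedigree = pd.read_csv(pedigree_tsv, sep="\t", dtype=str)
    markers = pd.read_csv(marker_tsv, sep="\t")
    validate_marker_table(markers)
    calls = (
        geno[sample_cols]
        .replace(".", MISSING)
        .apply(pd.to_numeric)
        .to_numpy()
        .T.astype(np.int8)
    )
    tissue = pedigree.set_index("sample_id")["tissue"] if "tissue" in pedigree else pd.Series(dtype=str)
    ploidy = np.array(
        [1 if tissue.get(s) == "megagametophyte" else 2 for s in sample_cols]
    )
    matrix = GenotypeMatrix(
        sample_ids=sample_cols,
        locus_ids=geno["locus_id"].astype(str).tolist(),
        calls=calls,
        ploidy=ploidy,
        contig=geno["contig"].to_numpy(dtype=object),
        position=geno["position"].to_numpy(dtype=np.int64),
        ref=geno["ref"].to_numpy(dtype=object),
        alt=geno["alt"].to_numpy(dtype=object),
    )
    validate_pedigree(pedigree, matrix)
    return matrix, pedigree, markers


def write_tables(
    matrix: GenotypeMatrix,
    pedigree: pd.DataFrame,
    markers: pd.DataFrame,
    genotype_tsv: str | Path,
    pedigree_tsv: str | Path,
    marker_tsv: str | Path,
) -> None:
    """Inverse of :func:`read_tables`."""
    geno = pd.DataFrame(
        {
            "locus_id": matrix.locus_ids,
            "contig": matrix.contig,
            "position": matrix.position,
            "ref": matrix.ref,
            "alt": matrix.alt,
        }
    )
    for i, s in enumerate(matrix.sample_ids):
        col = matrix.calls[i].astype(object)
        col[matrix.calls[i] == MISSING] = "."
        geno[s] = col
    geno.to_csv(genotype_tsv, sep="\t", index=False)
    pedigree.to_csv(pedigree_tsv, sep="\t", index=False)
    markers.to_csv(marker_tsv, sep="\t", index=False)


def write_sfs(sfs: SFS, path: str | Path) -> None:
    """Spectrum as TSV with chromosome count and monomorphic tally in
    comment lines."""
    with open(path, "w") as fh:
        fh.write(f"#n_chromosomes={sfs.n_chromosomes}\n")
        fh.write(f"#monomorphic={sfs.monomorphic_count:g}\n")
        sfs.to_frame().to_csv(fh, sep="\t", index=False)


def read_sfs(path: str | Path) -> SFS:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key] = value
    frame = pd.read_csv(path, sep="\t", comment="#")
    if "n_chromosomes" not in meta:
        raise FormatError(f"{path}: missing #n_chromosomes header")
    return SFS(
        n_chromosomes=int(meta["n_chromosomes"]),
        folded_counts=frame["n_loci"].to_numpy(dtype=float),
        monomorphic_count=float(meta.get("monomorphic", 0)),
    )
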