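"""Readers and writers: VCF, group tables, GFF3, BED and result TSVs.

VCF parsing is delegated to cyvcf2; GFF3 parsing to gffutils.  Only
biallelic SNP records are admitted into a :class:`HaplotypeMatrix` —
everything else is counted in a per-file rejection report, mirroring the
"biallelic SNPs only" entry condition of the scan.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datamodel import (
    MISSING,
    CandidateRegion,
    GeneModel,
    GroupContrast,
    HaplotypeMatrix,
    ValidationError,
    Variant,
)

log = logging.getLogger(__name__)


class PhasingError(ValidationError):
    """Unphased genotype encountered where phased input is required."""


class VcfParseError(ValueError):
    pass


@dataclasses.dataclass
class VcfRejectionReport:
    """Per-record exclusions applied while reading a VCF."""

    n_records: int = 0
    n_kept: int = 0
    n_multiallelic: int = 0
    n_non_snp: int = 0
    rejected: list[tuple[str, int, str]] = dataclasses.field(default_factory=list)


def read_vcf(path: str | Path, require_phased: bool = True
             ) -> tuple[HaplotypeMatrix, VcfRejectionReport]:
    """Read a multi-sample VCF into a haplotype matrix.

    Multiallelic and non-SNP records are excluded and itemised in the
    returned :class:`VcfRejectionReport`.  With ``require_phased`` any
    unphased non-missing diploid genotype raises :class:`PhasingError`
    naming the record and sample.
    """
    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    report = VcfRejectionReport()
    all_phased = True
    for rec in vcf:
        report.n_records += 1
        if len(rec.ALT) != 1:
            report.n_multiallelic += 1
            report.rejected.append((rec.CHROM, rec.POS, "multiallelic"))
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1 or not rec.is_snp:
            report.n_non_snp += 1
            report.rejected.append((rec.CHROM, rec.POS, "not a SNP"))
            continue
        col = np.empty(2 * len(samples), dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            a0, a1, phased = gt[0], gt[1], bool(gt[2])
            if not phased and a0 >= 0 and a1 >= 0:
                if require_phased:
                    raise PhasingError(
                        f"unphased genotype for sample {samples[i]!r} at "
                        f"{rec.CHROM}:{rec.POS}"
                    )
                all_phased = False
            col[2 * i] = a0 if a0 >= 0 else MISSING
            col[2 * i + 1] = a1 if a1 >= 0 else MISSING
        variants.append(Variant(rec.CHROM, rec.POS, rec.REF, rec.ALT[0],
                                rec.ID if rec.ID not in (None, ".") else None))
        columns.append(col)
    report.n_kept = len(variants)
    alleles = (np.stack(columns, axis=1) if columns
               else np.empty((2 * len(samples), 0), dtype=np.int8))
    matrix = HaplotypeMatrix(variants=variants, alleles=alleles,
                             sample_ids=samples,
                             phased=require_phased or all_phased)
    if report.rejected:
        log.info("read_vcf: excluded %d of %d records (%d multiallelic, %d non-SNP)",
                 len(report.rejected), report.n_records,
                 report.n_multiallelic, report.n_non_snp)
    return matrix, report


def write_vcf(matrix: HaplotypeMatrix, path: str | Path,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a haplotype matrix as an uncompressed VCF 4.2 file."""
    sep = "|" if matrix.phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.sample_ids) + "\n")
        geno = matrix.genotypes()
        for j, v in enumerate(matrix.variants):
            gts = []
            for i in range(matrix.n_samples):
                a0, a1 = geno[i, 0, j], geno[i, 1, j]
                gts.append(f"{'.' if a0 < 0 else a0}{sep}{'.' if a1 < 0 else a1}")
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id or '.'}\t{v.ref}\t{v.alt}"
                     f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


def read_groups(path: str | Path, matrix: HaplotypeMatrix) -> list[GroupContrast]:
    """Read a sample-to-group TSV (columns sample_id, contrast, role).

    One :class:`GroupContrast` is built per distinct contrast; every
    sample ID must exist in ``matrix`` and appear in only one role per
    contrast.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "contrast", "role"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"group table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    bad_roles = set(df["role"]) - {"test", "control"}
    if bad_roles:
        raise ValidationError(f"unknown roles in group table: {sorted(bad_roles)}")
    contrasts: list[GroupContrast] = []
    for name, sub in df.groupby("contrast", sort=False):
        test = tuple(sub.loc[sub["role"] == "test", "sample_id"])
        control = tuple(sub.loc[sub["role"] == "control", "sample_id"])
        gc = GroupContrast(name=str(name), test_samples=test, control_samples=control)
        gc.validate_against(matrix)
        contrasts.append(gc)
    return contrasts


def read_gff(path: str | Path) -> list[GeneModel]:
    """Extract gene features from a GFF3 file (non-gene features ignored)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=None):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(GeneModel(gene_id=gene_id, chrom=feat.seqid,
                               start=feat.start, end=feat.end,
                               strand=feat.strand if feat.strand in "+-" else "?"))
    return genes


def read_sequence_regions(path: str | Path) -> dict[str, int]:
    """Chromosome lengths from ``##sequence-region`` GFF3 pragmas."""
    bounds: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    bounds[parts[1]] = int(parts[3])
            elif not line.startswith("#"):
                break
    return bounds


def write_gff(genes: list[GeneModel], path: str | Path,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write gene models as a minimal GFF3 file."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in genes:
            fh.write(f"{g.chrom}\tsweepscan\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand if g.strand in '+-' else '.'}\t.\tID={g.gene_id}\n")


def write_bed(regions: list[CandidateRegion], path: str | Path) -> None:
    """Write candidate regions as BED3+2 (0-based half-open coordinates).

    Columns: chrom, start, end, contrast, comma-joined gene IDs.  The
    writer does not merge; merging is the region builder's job.
    """
    with open(path, "w") as fh:
        for r in regions:
            genes = ",".join(r.genes) if r.genes else "."
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.contrast}\t{genes}\n")


def read_bed(path: str | Path) -> list[CandidateRegion]:
    """Read regions written by :func:`write_bed` back to 1-based inclusive."""
    regions: list[CandidateRegion] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            contrast = parts[3] if len(parts) > 3 else ""
            genes = tuple(parts[4].split(",")) if len(parts) > 4 and parts[4] != "." else ()
            regions.append(CandidateRegion(chrom=chrom, start=start + 1, end=end,
                                           contrast=contrast, support="",
                                           genes=genes))
    return regions


def write_regions_tsv(regions: list[CandidateRegion], path: str | Path) -> None:
    """Region table with columns Chromosome, Position (bp), Group, Genes."""
    rows = [{
        "Chromosome": r.chrom,
        "Position (bp)": f"{r.start}-{r.end}",
        "Group": r.contrast,
        "Genes": ",".join(r.genes) if r.genes else ".",
        "Support": r.support,
        "SourceSNPs": ",".join(str(p) for p in r.source_snps),
    } for r in regions]
    pd.DataFrame(rows, columns=["Chromosome", "Position (bp)", "Group",
                                "Genes", "Support", "SourceSNPs"]
                 ).to_csv(path, sep="\t", index=False)
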