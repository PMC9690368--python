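"""End-to-end orchestration: QC -> Fst / XP-EHH / pi -> outliers -> regions.

A run is a pure function of (inputs, configuration): no clocks, no
hidden state, and any randomness is seeded, so identical configurations
produce byte-identical outputs.  Per-contrast statistic tables, outlier
thresholds, candidate regions (both the Fst-with-XP-EHH tier and the
three-statistic tier) and a machine-readable manifest are written to the
output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datamodel import CandidateRegion, GroupContrast, HaplotypeMatrix, ValidationError
from .diversity import pi_ratio_scan
from .fst import fst_scan
from .haplostats import DEFAULT_CUTOFF, DEFAULT_MAX_GAP, normalize_xpehh, xpehh_scan
from .outliers import (
    DEFAULT_FLANK,
    DEFAULT_TAIL,
    OutlierSet,
    annotate_regions,
    intersect_outliers,
    snps_to_regions,
    top_quantile,
)
from .phenotypes import assign_groups, read_phenotypes
from .qc import QcConfig, QcReport, apply_qc
from .vcfio import (
    read_gff,
    read_groups,
    read_sequence_regions,
    read_vcf,
    write_bed,
    write_regions_tsv,
)

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """One scan run, serialisable to/from YAML."""

    vcf: str = ""
    groups: str | None = None
    phenotypes: str | None = None
    trait: str | None = None
    gff: str | None = None
    out_dir: str = "sweepscan_run"
    qc: QcConfig = field(default_factory=QcConfig)
    max_gap: int = DEFAULT_MAX_GAP
    ehh_cutoff: float = DEFAULT_CUTOFF
    tail_q: float = DEFAULT_TAIL
    flank: int = DEFAULT_FLANK
    overlap_mode: str = "3way"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.tail_q < 0.5:
            raise ValueError("tail_q must be in (0, 0.5)")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")
        if self.overlap_mode not in ("2way", "3way"):
            raise ValueError("overlap_mode must be '2way' or '3way'")
        if isinstance(self.qc, dict):
            qc = dict(self.qc)
            if qc.get("autosome_labels") is not None:
                qc["autosome_labels"] = frozenset(qc["autosome_labels"])
            self.qc = QcConfig(**qc)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["qc"]["autosome_labels"] is not None:
            d["qc"]["autosome_labels"] = sorted(d["qc"]["autosome_labels"])
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class ContrastResult:
    """In-memory results of one contrast's scan."""

    contrast: GroupContrast
    fst: pd.DataFrame
    xpehh: pd.DataFrame
    pi: pd.DataFrame
    outlier_sets: dict[str, OutlierSet]
    snps_2way: frozenset[int]
    snps_3way: frozenset[int] | None
    regions_2way: list[CandidateRegion]
    regions_3way: list[CandidateRegion] | None


def scan_contrast(matrix: HaplotypeMatrix, contrast: GroupContrast,
                  genes=None, chrom_bounds: dict[str, int] | None = None,
                  max_gap: int = DEFAULT_MAX_GAP,
                  ehh_cutoff: float = DEFAULT_CUTOFF,
                  tail_q: float = DEFAULT_TAIL, flank: int = DEFAULT_FLANK,
                  overlap_mode: str = "3way") -> ContrastResult:
    """All three statistics plus outlier/region calling for one contrast.

    This is the library-level entry point the CLI and the pipeline wrap;
    ``matrix`` is expected to be post-QC.
    """
    fst_df = fst_scan(matrix, contrast)
    xp_df = normalize_xpehh(xpehh_scan(matrix, contrast, max_gap=max_gap,
                                       cutoff=ehh_cutoff))
    pi_df = pi_ratio_scan(matrix, contrast)

    sets = {
        "fst": top_quantile(fst_df["fst"].to_numpy(), q=tail_q,
                            statistic="fst"),
        "xpehh": top_quantile(xp_df["xpehh_norm"].to_numpy(), q=tail_q,
                              positive_only=True, statistic="xpehh"),
        "pi_ratio": top_quantile(pi_df["log2_ratio"].to_numpy(), q=tail_q,
                                 statistic="pi_ratio"),
    }
    snps_2way = intersect_outliers([sets["fst"], sets["xpehh"]])
    chroms = matrix.chroms
    positions = matrix.positions

    def build(snps: frozenset[int], support: str) -> list[CandidateRegion]:
        pairs = sorted((chroms[i], int(positions[i])) for i in snps)
        regions = snps_to_regions(pairs, contrast=contrast.name,
                                  support=support, flank=flank,
                                  chrom_bounds=chrom_bounds)
        return annotate_regions(regions, genes) if genes is not None else regions

    regions_2way = build(snps_2way, "2way")
    snps_3way = None
    regions_3way = None
    if overlap_mode == "3way":
        snps_3way = intersect_outliers(
            [sets["fst"], sets["xpehh"], sets["pi_ratio"]])
        regions_3way = build(snps_3way, "3way")
    return ContrastResult(contrast=contrast, fst=fst_df, xpehh=xp_df, pi=pi_df,
                          outlier_sets=sets, snps_2way=snps_2way,
                          snps_3way=snps_3way, regions_2way=regions_2way,
                          regions_3way=regions_3way)


def _write_qc_report(report: QcReport, path: Path) -> None:
    pd.DataFrame(report.as_rows(), columns=["filter", "count"]
                 ).to_csv(path, sep="\t", index=False)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the configured scan; returns the run directory.

    Raises with the failing stage's name on error; outputs include
    per-SNP statistic TSVs, outlier thresholds, candidate-region
    TSV/BED files per tier, the QC report, and ``manifest.json``.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "read_vcf"
    try:
        matrix, vcf_report = read_vcf(cfg.vcf, require_phased=True)

        stage = "read_groups"
        if cfg.groups:
            contrasts = read_groups(cfg.groups, matrix)
        elif cfg.phenotypes and cfg.trait:
            records = read_phenotypes(cfg.phenotypes)
            contrasts = assign_groups(records, cfg.trait)
            for gc in contrasts:
                gc.validate_against(matrix)
        else:
            raise ValidationError(
                "either 'groups' or 'phenotypes' + 'trait' must be configured")

        stage = "read_gff"
        genes = None
        chrom_bounds: dict[str, int] | None = None
        if cfg.gff:
            genes = read_gff(cfg.gff)
            chrom_bounds = read_sequence_regions(cfg.gff) or None

        stage = "qc"
        qc_matrix, qc_report = apply_qc(matrix, cfg.qc)
        _write_qc_report(qc_report, out / "qc_report.tsv")

        manifest: dict = {
            "tool": "sweepscan",
            "version": __version__,
            "config": cfg.to_dict(),
            "n_samples": matrix.n_samples,
            "n_variants_input": matrix.n_variants,
            "n_variants_post_qc": qc_matrix.n_variants,
            "vcf_records_rejected": len(vcf_report.rejected),
            "contrasts": {},
        }

        for gc in contrasts:
            stage = f"scan[{gc.name}]"
            res = scan_contrast(qc_matrix, gc, genes=genes,
                                chrom_bounds=chrom_bounds, max_gap=cfg.max_gap,
                                ehh_cutoff=cfg.ehh_cutoff, tail_q=cfg.tail_q,
                                flank=cfg.flank, overlap_mode=cfg.overlap_mode)
            prefix = out / gc.name
            res.fst.to_csv(f"{prefix}.fst.tsv", sep="\t", index=False,
                           float_format=_FLOAT_FMT)
            res.xpehh.to_csv(f"{prefix}.xpehh.tsv", sep="\t", index=False,
                             float_format=_FLOAT_FMT)
            res.pi.to_csv(f"{prefix}.pi.tsv", sep="\t", index=False,
                          float_format=_FLOAT_FMT)
            write_regions_tsv(res.regions_2way, f"{prefix}.regions_2way.tsv")
            write_bed(res.regions_2way, f"{prefix}.regions_2way.bed")
            info = {
                "test_n": len(gc.test_samples),
                "control_n": len(gc.control_samples),
                "thresholds": {k: s.threshold
                               for k, s in res.outlier_sets.items()},
                "n_outliers": {k: len(s.indices)
                               for k, s in res.outlier_sets.items()},
                "n_snps_2way": len(res.snps_2way),
                "n_regions_2way": len(res.regions_2way),
            }
            if res.regions_3way is not None:
                write_regions_tsv(res.regions_3way, f"{prefix}.regions_3way.tsv")
                write_bed(res.regions_3way, f"{prefix}.regions_3way.bed")
                info["n_snps_3way"] = len(res.snps_3way)
                info["n_regions_3way"] = len(res.regions_3way)
            manifest["contrasts"][gc.name] = info

        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
    return out
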