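"""Synthetic two-population haplotype data with a planted hard sweep.

The generator emulates the structure the scan expects from real data:
two subgroups of diploid individuals, phased biallelic SNPs with a
bounded allele-frequency spectrum, background linkage disequilibrium
created by copying haplotype blocks between individuals, and optionally
one locus where a fraction of the test group carries a single shared
haplotype over a fixed span — a hard sweep at a known carrier frequency.
Known QC violations (low-MAF, missing-call and excess-homozygote sites)
can be planted at recorded positions so QC bookkeeping is checkable
exactly.  Everything is deterministic given the seed.

The default dimensions mirror a desk-scale analogue of a livestock
resequencing contrast: 15 + 15 diploids, two chromosomes of 10 Mb with
2,500 SNPs each, and a 500-kb sweep carried at frequency 0.9.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datamodel import (
    MISSING,
    GeneModel,
    GroupContrast,
    HaplotypeMatrix,
    Variant,
)
from .qc import hwe_exact_test
from .vcfio import write_gff, write_vcf


@dataclass(frozen=True)
class SweepSpec:
    """A hard sweep: one shared haplotype planted in the test group."""

    chrom: str = "chr1"
    position: int = 5_000_000
    carrier_frequency: float = 0.9
    span: int = 500_000

    def __post_init__(self) -> None:
        if not 0.0 < self.carrier_frequency <= 1.0:
            raise ValueError("carrier_frequency must be in (0, 1]")
        if self.span <= 0 or self.position < 1:
            raise ValueError("sweep span and position must be positive")

    @property
    def interval(self) -> tuple[int, int]:
        half = self.span // 2
        return max(1, self.position - half), self.position + half


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    ``maf_dist`` is (beta_a, beta_b, f_min, f_max): background
    alternate-allele frequencies are Beta(a, b) rescaled into
    [f_min, f_max], keeping every background site comfortably clear of
    the MAF filter.  LD comes from ``ld_copy_events`` block-copy events
    per chromosome (geometric block length, mean
    ``ld_mean_block_snps``).  ``n_low_maf``, ``n_missing`` and
    ``n_hwe_violation`` sites are planted outside the sweep span and
    recorded in the truth object.
    """

    seed: int = 0
    n_test: int = 15
    n_control: int = 15
    n_chrom: int = 2
    chrom_length: int = 10_000_000
    n_snps_per_chrom: int = 2_500
    maf_dist: tuple[float, float, float, float] = (0.8, 0.8, 0.1, 0.9)
    ld_copy_events: int = 180
    ld_mean_block_snps: float = 15.0
    sweep: SweepSpec | None = field(default_factory=SweepSpec)
    n_low_maf: int = 0
    n_missing: int = 0
    n_hwe_violation: int = 0
    contrast_name: str = "trait_contrast"
    qc_guard_maf: float = 0.08
    qc_guard_hwe_p: float = 1e-4

    def __post_init__(self) -> None:
        if min(self.n_test, self.n_control, self.n_chrom,
               self.chrom_length, self.n_snps_per_chrom) <= 0:
            raise ValueError("all dimensions must be positive")
        total_planted = self.n_low_maf + self.n_missing + self.n_hwe_violation
        if total_planted > self.n_chrom * self.n_snps_per_chrom // 2:
            raise ValueError("more planted QC violations than available sites")
        if self.sweep is not None:
            if self.sweep.position > self.chrom_length:
                raise ValueError("sweep position outside chromosome")
            if self.sweep.chrom not in self.chrom_labels:
                raise ValueError(f"sweep chromosome {self.sweep.chrom!r} not simulated")

    @property
    def chrom_labels(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    @property
    def n_haplotypes(self) -> int:
        return 2 * (self.n_test + self.n_control)


@dataclass
class SweepTruth:
    """Ground truth of one simulation, for recovery and bookkeeping tests."""

    sweep_chrom: str | None
    sweep_position: int | None
    sweep_span: int | None
    carrier_frequency: float | None
    expected_interval: tuple[int, int] | None
    carrier_haplotype: str | None
    sweep_gene_id: str | None
    chrom_lengths: dict[str, int]
    planted_low_maf: list[tuple[str, int]]
    planted_missing: list[tuple[str, int]]
    planted_hwe: list[tuple[str, int]]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SweepTruth":
        d = json.loads(text)
        for key in ("planted_low_maf", "planted_missing", "planted_hwe"):
            d[key] = [tuple(x) for x in d[key]]
        if d["expected_interval"] is not None:
            d["expected_interval"] = tuple(d["expected_interval"])
        return cls(**d)


def _draw_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n distinct sorted 1-based positions in [1, length]."""
    pool = np.unique(rng.integers(1, length + 1, size=int(n * 1.5) + 16))
    while pool.size < n:
        pool = np.unique(np.concatenate(
            [pool, rng.integers(1, length + 1, size=n)]))
    return np.sort(rng.choice(pool, size=n, replace=False))


def _column_qc_ok(col: np.ndarray, n_samples: int, guard_maf: float,
                  guard_hwe_p: float) -> bool:
    f = col.mean()
    if min(f, 1.0 - f) < guard_maf:
        return False
    pairs = col.reshape(n_samples, 2)
    alt = pairs.sum(axis=1)
    return hwe_exact_test(int((alt == 0).sum()), int((alt == 1).sum()),
                          int((alt == 2).sum())) >= guard_hwe_p


def simulate(cfg: SimConfig) -> tuple[HaplotypeMatrix, list[GroupContrast],
                                      SweepTruth, list[GeneModel]]:
    """Generate a phased two-group dataset with optional planted sweep.

    Returns the haplotype matrix (test samples first), the single
    test/control contrast, the ground truth, and tiled gene models with
    one gene centred on the sweep.
    """
    rng = np.random.default_rng(cfg.seed)
    n_samples = cfg.n_test + cfg.n_control
    n_haps = cfg.n_haplotypes
    beta_a, beta_b, f_min, f_max = cfg.maf_dist

    sample_ids = ([f"T{i:03d}" for i in range(cfg.n_test)]
                  + [f"C{i:03d}" for i in range(cfg.n_control)])
    test_hap_rows = np.arange(2 * cfg.n_test)

    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    sweep_cols_global: set[int] = set()
    carrier_hap: str | None = None

    for chrom in cfg.chrom_labels:
        positions = _draw_positions(rng, cfg.n_snps_per_chrom, cfg.chrom_length)
        freqs = f_min + (f_max - f_min) * rng.beta(beta_a, beta_b,
                                                   size=cfg.n_snps_per_chrom)
        alleles = (rng.random((n_haps, cfg.n_snps_per_chrom))
                   < freqs).astype(np.int8)

        # background LD: copy random haplotype blocks between individuals
        for _ in range(cfg.ld_copy_events):
            donor = int(rng.integers(n_haps))
            n_rec = int(rng.integers(1, 6))
            recipients = rng.choice(n_haps, size=n_rec, replace=False)
            start = int(rng.integers(cfg.n_snps_per_chrom))
            length = int(rng.geometric(1.0 / cfg.ld_mean_block_snps))
            stop = min(cfg.n_snps_per_chrom, start + length)
            alleles[recipients, start:stop] = alleles[donor, start:stop]

        sweep_local: np.ndarray | None = None
        if cfg.sweep is not None and chrom == cfg.sweep.chrom:
            lo, hi = cfg.sweep.interval
            sweep_local = np.flatnonzero((positions >= lo) & (positions <= hi))
            n_carriers = max(1, round(cfg.sweep.carrier_frequency
                                      * test_hap_rows.size))
            donor_row = int(rng.choice(test_hap_rows))
            carriers = rng.choice(test_hap_rows, size=n_carriers, replace=False)
            alleles[np.ix_(carriers, sweep_local)] = alleles[donor_row, sweep_local]
            carrier_hap = f"{sample_ids[donor_row // 2]}/hap{donor_row % 2}"

        # repair: background sites must pass QC with margin, so that the
        # only removals are the planted ones.  Sweep-span sites keep their
        # test-group haplotypes intact; if the pooled site would fail QC,
        # only the control-group alleles are redrawn (best effort).
        protect = set(sweep_local.tolist()) if sweep_local is not None else set()
        control_rows = np.arange(2 * cfg.n_test, n_haps)
        for j in range(cfg.n_snps_per_chrom):
            if j in protect:
                tries = 0
                while tries < 100 and not _column_qc_ok(
                        alleles[:, j], n_samples, cfg.qc_guard_maf, 1e-5):
                    alleles[control_rows, j] = (rng.random(control_rows.size)
                                                < 0.5).astype(np.int8)
                    tries += 1
                continue
            tries = 0
            while not _column_qc_ok(alleles[:, j], n_samples,
                                    cfg.qc_guard_maf, cfg.qc_guard_hwe_p):
                f = rng.uniform(0.25, 0.75)
                alleles[:, j] = (rng.random(n_haps) < f).astype(np.int8)
                tries += 1
                if tries > 200:  # pragma: no cover - probabilistically unreachable
                    raise RuntimeError("could not repair a background site")

        base = len(variants)
        for k, pos in enumerate(positions):
            variants.append(Variant(chrom=chrom, pos=int(pos), ref="A", alt="G"))
        columns.append(alleles)
        if sweep_local is not None:
            sweep_cols_global.update((base + int(j)) for j in sweep_local)

    alleles_all = np.concatenate(columns, axis=1)

    # plant QC violations outside the sweep span
    total_planted = cfg.n_low_maf + cfg.n_missing + cfg.n_hwe_violation
    planted: dict[str, list[tuple[str, int]]] = {
        "low_maf": [], "missing": [], "hwe": []}
    if total_planted:
        eligible = np.array([i for i in range(len(variants))
                             if i not in sweep_cols_global])
        chosen = rng.choice(eligible, size=total_planted, replace=False)
        cursor = 0
        k_alt = max(0, int(np.ceil(0.05 * n_haps)) - 1)
        for i in chosen[cursor:cursor + cfg.n_low_maf]:
            col = np.zeros(n_haps, dtype=np.int8)
            if k_alt:
                hit = rng.choice(n_samples, size=k_alt, replace=False)
                col[2 * hit] = 1  # heterozygous carriers only
            alleles_all[:, i] = col
            planted["low_maf"].append((variants[i].chrom, variants[i].pos))
        cursor += cfg.n_low_maf
        for i in chosen[cursor:cursor + cfg.n_missing]:
            col = np.zeros(n_haps, dtype=np.int8)
            for s in range(n_samples):  # near-exact HWE at f ~ 0.5
                r = s % 4
                col[2 * s] = 1 if r in (2, 3) else 0
                col[2 * s + 1] = 1 if r in (1, 3) else 0
            drop = int(rng.integers(n_samples))
            col[2 * drop] = MISSING
            col[2 * drop + 1] = MISSING
            alleles_all[:, i] = col
            planted["missing"].append((variants[i].chrom, variants[i].pos))
        cursor += cfg.n_missing
        for i in chosen[cursor:cursor + cfg.n_hwe_violation]:
            col = np.zeros(n_haps, dtype=np.int8)
            for s in range(n_samples):  # all homozygotes at f ~ 0.5
                if s % 2 == 0:
                    col[2 * s] = col[2 * s + 1] = 1
            alleles_all[:, i] = col
            planted["hwe"].append((variants[i].chrom, variants[i].pos))

    matrix = HaplotypeMatrix(variants=variants, alleles=alleles_all,
                             sample_ids=sample_ids, phased=True)
    contrast = GroupContrast(
        name=cfg.contrast_name,
        test_samples=tuple(sample_ids[:cfg.n_test]),
        control_samples=tuple(sample_ids[cfg.n_test:]),
        description="synthetic test-vs-control contrast",
    )
    genes = _tile_genes(cfg)
    sweep_gene = next((g.gene_id for g in genes if g.gene_id == "SWEEP_TARGET"),
                      None)
    truth = SweepTruth(
        sweep_chrom=cfg.sweep.chrom if cfg.sweep else None,
        sweep_position=cfg.sweep.position if cfg.sweep else None,
        sweep_span=cfg.sweep.span if cfg.sweep else None,
        carrier_frequency=cfg.sweep.carrier_frequency if cfg.sweep else None,
        expected_interval=cfg.sweep.interval if cfg.sweep else None,
        carrier_haplotype=carrier_hap,
        sweep_gene_id=sweep_gene,
        chrom_lengths={c: cfg.chrom_length for c in cfg.chrom_labels},
        planted_low_maf=planted["low_maf"],
        planted_missing=planted["missing"],
        planted_hwe=planted["hwe"],
    )
    return matrix, [contrast], truth, genes


def _tile_genes(cfg: SimConfig, spacing: int = 400_000,
                length: int = 20_000) -> list[GeneModel]:
    """Genes tiled at fixed spacing, plus one centred on the sweep."""
    genes: list[GeneModel] = []
    for ci, chrom in enumerate(cfg.chrom_labels):
        start = 100_000
        k = 0
        while start + length <= cfg.chrom_length:
            genes.append(GeneModel(gene_id=f"GENE{ci + 1}_{k:04d}", chrom=chrom,
                                   start=start, end=start + length - 1,
                                   strand="+"))
            start += spacing
            k += 1
    if cfg.sweep is not None:
        # the selected gene spans the swept haplotype so that candidate
        # regions anywhere in the differentiated interval annotate to it
        lo, hi = cfg.sweep.interval
        genes.append(GeneModel(
            gene_id="SWEEP_TARGET", chrom=cfg.sweep.chrom,
            start=lo, end=min(cfg.chrom_length, hi), strand="+"))
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def write_fixture(matrix: HaplotypeMatrix, contrasts: list[GroupContrast],
                  truth: SweepTruth, genes: list[GeneModel],
                  directory: str | Path) -> dict[str, Path]:
    """Write VCF + group TSV + GFF3 + truth JSON, pipeline-ready."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": directory / "haplotypes.vcf",
        "groups": directory / "groups.tsv",
        "gff": directory / "genes.gff3",
        "truth": directory / "truth.json",
    }
    write_vcf(matrix, paths["vcf"], contig_lengths=truth.chrom_lengths)
    with open(paths["groups"], "w") as fh:
        fh.write("sample_id\tcontrast\trole\n")
        for gc in contrasts:
            for s in gc.test_samples:
                fh.write(f"{s}\t{gc.name}\ttest\n")
            for s in gc.control_samples:
                fh.write(f"{s}\t{gc.name}\tcontrol\n")
    write_gff(genes, paths["gff"], contig_lengths=truth.chrom_lengths)
    paths["truth"].write_text(truth.to_json())
    return paths
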