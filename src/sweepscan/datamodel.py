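"""Core in-memory data model for the sweep scan.

All genomic coordinates are 1-based inclusive (the VCF/GFF convention).
BED's 0-based half-open convention appears only at the I/O boundary.

Haplotype alleles are stored as an ``int8`` matrix with one row per
haplotype (two consecutive rows per diploid sample, in sample order) and
one column per variant.  ``0`` is the reference allele, ``1`` the single
alternate allele, and :data:`MISSING` (``-1``) an uncalled allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Sentinel for an uncalled allele in a haplotype matrix.
MISSING: int = -1


class ValidationError(ValueError):
    """An input object violates one of the data-model invariants."""


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP.

    Parameters
    ----------
    chrom : str
        Chromosome label (opaque string; assembly-specific).
    pos : int
        1-based base-pair coordinate.
    ref, alt : str
        Single-base reference and alternate alleles; must differ.
    id : str, optional
        Variant identifier (e.g. from the VCF ID column).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"variant position must be >= 1, got {self.pos}")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValidationError(
                f"only single-base SNP alleles are supported, got "
                f"{self.ref!r}>{self.alt!r} at {self.chrom}:{self.pos}"
            )
        if self.ref == self.alt:
            raise ValidationError(
                f"ref and alt alleles are identical at {self.chrom}:{self.pos}"
            )


@dataclass
class HaplotypeMatrix:
    """Phased haplotypes for a set of diploid samples.

    Attributes
    ----------
    variants : list of Variant
        Ordered by (chromosome block, position); positions strictly
        increasing within each chromosome.
    alleles : ndarray of int8, shape (2 * n_samples, n_variants)
        Haplotype rows; sample ``i`` owns rows ``2i`` and ``2i + 1``.
    sample_ids : list of str
    phased : bool
        Whether genotype phase is known (required by haplotype statistics).
    """

    variants: list[Variant]
    alleles: np.ndarray
    sample_ids: list[str]
    phased: bool = True

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValidationError("alleles must be a 2-D matrix")
        if self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise ValidationError(
                f"expected {2 * len(self.sample_ids)} haplotype rows for "
                f"{len(self.sample_ids)} samples, got {self.alleles.shape[0]}"
            )
        if self.alleles.shape[1] != len(self.variants):
            raise ValidationError(
                f"allele matrix has {self.alleles.shape[1]} columns for "
                f"{len(self.variants)} variants"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample IDs")
        bad = (self.alleles > 1) | (self.alleles < MISSING)
        if bad.any():
            raise ValidationError("alleles must be 0, 1 or MISSING (-1)")
        self._check_sorted()

    def _check_sorted(self) -> None:
        seen: dict[str, int] = {}
        last_chrom: str | None = None
        last_pos = 0
        for v in self.variants:
            if v.chrom != last_chrom:
                if v.chrom in seen:
                    raise ValidationError(
                        f"chromosome {v.chrom} appears in two separate blocks"
                    )
                seen[v.chrom] = 1
                last_chrom = v.chrom
                last_pos = 0
            if v.pos <= last_pos:
                raise ValidationError(
                    f"positions not strictly increasing on {v.chrom} near {v.pos}"
                )
            last_pos = v.pos

    # -- basic dimensions ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    # -- derived views ---------------------------------------------------
    @property
    def positions(self) -> np.ndarray:
        """1-based positions, one per variant (int64)."""
        return np.fromiter((v.pos for v in self.variants), dtype=np.int64,
                           count=self.n_variants)

    @property
    def chroms(self) -> list[str]:
        return [v.chrom for v in self.variants]

    def chrom_blocks(self) -> dict[str, slice]:
        """Contiguous variant-index slice per chromosome, in matrix order."""
        blocks: dict[str, slice] = {}
        start = 0
        for i in range(1, self.n_variants + 1):
            if i == self.n_variants or self.variants[i].chrom != self.variants[start].chrom:
                blocks[self.variants[start].chrom] = slice(start, i)
                start = i
        return blocks

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise ValidationError(f"unknown sample ID {sample_id!r}") from None

    def haplotype_rows(self, sample_ids: Iterable[str]) -> np.ndarray:
        """Row indices of the two haplotypes of each named sample."""
        rows: list[int] = []
        for s in sample_ids:
            i = self.sample_index(s)
            rows.extend((2 * i, 2 * i + 1))
        return np.asarray(rows, dtype=np.intp)

    def genotypes(self) -> np.ndarray:
        """View of shape (n_samples, 2, n_variants)."""
        return self.alleles.reshape(self.n_samples, 2, self.n_variants)

    def take_variants(self, index: np.ndarray) -> "HaplotypeMatrix":
        """New matrix restricted to the given variant indices (order kept)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return HaplotypeMatrix(
            variants=[self.variants[i] for i in index],
            alleles=self.alleles[:, index],
            sample_ids=list(self.sample_ids),
            phased=self.phased,
        )


@dataclass(frozen=True)
class GroupContrast:
    """A named test-vs-control sample partition.

    The *test* group is the one in which selection is hypothesised
    (e.g. short nap, large pelt); positive XP-EHH and positive
    log2 diversity ratios point at the test group.
    """

    name: str
    test_samples: tuple[str, ...]
    control_samples: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.test_samples or not self.control_samples:
            raise ValidationError(f"contrast {self.name!r}: both groups must be nonempty")
        overlap = set(self.test_samples) & set(self.control_samples)
        if overlap:
            raise ValidationError(
                f"contrast {self.name!r}: samples in both roles: {sorted(overlap)}"
            )

    def validate_against(self, matrix: HaplotypeMatrix) -> None:
        known = set(matrix.sample_ids)
        missing = (set(self.test_samples) | set(self.control_samples)) - known
        if missing:
            raise ValidationError(
                f"contrast {self.name!r}: samples not in matrix: {sorted(missing)}"
            )


@dataclass(frozen=True)
class GeneModel:
    """A gene span from a GFF3 annotation (1-based inclusive)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "?"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )


@dataclass
class CandidateRegion:
    """A merged candidate interval built from flanked outlier SNPs.

    ``support`` records which statistic tier produced it: ``"2way"``
    (Fst with XP-EHH) or ``"3way"`` (additionally the diversity ratio).
    """

    chrom: str
    start: int
    end: int
    contrast: str
    support: str
    source_snps: tuple[int, ...] = field(default_factory=tuple)
    genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.start > self.end or self.start < 1:
            raise ValidationError(
                f"bad region span {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def span(self) -> int:
        return self.end - self.start + 1
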