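"""Variant quality control.

Filters, applied in a fixed attribution order so the report is
deterministic: biallelic-SNP check (a re-check; reading already enforces
it), autosome whitelist, missing-genotype fraction, minor allele
frequency, and a Hardy-Weinberg exact test on the pooled sample.  Each
removed variant is attributed to the *first* failing filter only, so the
report counts always sum to the input count.

The Hardy-Weinberg test is the conditional exact test on the
heterozygote count given the allele counts: the p-value sums the
probabilities of every attainable heterozygote configuration no more
probable than the observed one (two-sided, no mid-p correction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .datamodel import HaplotypeMatrix

log = logging.getLogger(__name__)

_LN2 = float(np.log(2.0))


@dataclass
class QcConfig:
    """Thresholds for variant-level QC.

    maf_min
        Keep a site iff its minor allele frequency (over non-missing
        alleles, pooled across samples) is >= this value.
    max_missing_fraction
        Maximum tolerated fraction of samples with a missing genotype;
        the default 0 demands complete calls at every retained site.
    hwe_p_min
        Keep a site iff the exact-test p-value is >= this value.
    autosome_labels
        Whitelist of chromosome labels that count as autosomes; ``None``
        accepts every label.
    """

    maf_min: float = 0.05
    max_missing_fraction: float = 0.0
    hwe_p_min: float = 1e-6
    autosome_labels: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError(f"maf_min must be in [0, 0.5], got {self.maf_min}")
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must be in [0, 1]")
        if not 0.0 < self.hwe_p_min < 1.0:
            raise ValueError("hwe_p_min must be in (0, 1)")
        if self.autosome_labels is not None:
            self.autosome_labels = frozenset(self.autosome_labels)


@dataclass
class QcReport:
    """Accounting of QC removals; every input variant appears exactly once."""

    n_input: int = 0
    n_removed_multiallelic: int = 0
    n_removed_nonautosomal: int = 0
    n_removed_missing: int = 0
    n_removed_maf: int = 0
    n_removed_hwe: int = 0
    n_retained: int = 0
    removed_index: dict[str, list[int]] = field(default_factory=dict)

    def check_conservation(self) -> bool:
        return self.n_input == (self.n_retained + self.n_removed_multiallelic
                                + self.n_removed_nonautosomal + self.n_removed_missing
                                + self.n_removed_maf + self.n_removed_hwe)

    def as_rows(self) -> list[tuple[str, int]]:
        return [
            ("input", self.n_input),
            ("removed_multiallelic", self.n_removed_multiallelic),
            ("removed_nonautosomal", self.n_removed_nonautosomal),
            ("removed_missing", self.n_removed_missing),
            ("removed_maf", self.n_removed_maf),
            ("removed_hwe", self.n_removed_hwe),
            ("retained", self.n_retained),
        ]


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg p-value from diploid genotype counts.

    Conditions on the observed allele counts and sums the probabilities
    of all heterozygote counts whose conditional probability does not
    exceed that of the observed count.  Monomorphic sites return 1.

    The conditional probability of ``h`` heterozygotes among ``n``
    diploids carrying ``nA`` copies of allele A is

        P(h) = n! 2^h / (nAA! h! naa!) * nA! na! / (2n)!

    with ``nAA = (nA - h)/2`` and ``naa = (na - h)/2``.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("at least one genotype required")
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n - n_A
    if n_A == 0 or n_a == 0:
        return 1.0
    # attainable het counts share the parity of the minor allele count
    h_max = min(n_A, n_a)
    hs = np.arange(h_max % 2, h_max + 1, 2)
    n_hom_A = (n_A - hs) // 2
    n_hom_a = (n_a - hs) // 2
    logw = (hs * _LN2 - gammaln(n_hom_A + 1) - gammaln(hs + 1)
            - gammaln(n_hom_a + 1))
    logp = logw - logsumexp(logw)
    p_obs = logp[np.searchsorted(hs, n_Aa)]
    # tolerance guards against ties lost to rounding in log space
    p_value = float(np.exp(logsumexp(logp[logp <= p_obs + 1e-12])))
    return min(1.0, p_value)


def genotype_counts(matrix: HaplotypeMatrix) -> np.ndarray:
    """Pooled (n_AA, n_Aa, n_aa) per site over complete diploid calls.

    Returns an array of shape (n_variants, 3); A is the reference allele.
    """
    geno = matrix.genotypes()
    a0, a1 = geno[:, 0, :], geno[:, 1, :]
    complete = (a0 >= 0) & (a1 >= 0)
    alt_sum = np.where(complete, a0 + a1, 0)
    n_aa = ((alt_sum == 2) & complete).sum(axis=0)
    n_Aa = ((alt_sum == 1) & complete).sum(axis=0)
    n_AA = ((alt_sum == 0) & complete).sum(axis=0)
    return np.stack([n_AA, n_Aa, n_aa], axis=1)


def apply_qc(matrix: HaplotypeMatrix, cfg: QcConfig | None = None
             ) -> tuple[HaplotypeMatrix, QcReport]:
    """Filter a haplotype matrix; returns the retained matrix and report.

    Idempotent: applying the same configuration twice changes nothing.
    Zero retained variants is a warning, not an error.
    """
    cfg = cfg or QcConfig()
    n = matrix.n_variants
    report = QcReport(n_input=n)
    reason = np.zeros(n, dtype=np.int8)  # 0 = keep; codes in filter order

    # 1. biallelic SNP re-check: the Variant type enforces this, so the
    #    counter stays 0 unless the model is ever relaxed.
    # 2. autosome whitelist
    if cfg.autosome_labels is not None:
        chroms = np.asarray(matrix.chroms)
        on_autosome = np.isin(chroms, sorted(cfg.autosome_labels))
        reason[(reason == 0) & ~on_autosome] = 2

    geno = matrix.genotypes()
    complete = (geno[:, 0, :] >= 0) & (geno[:, 1, :] >= 0)  # (samples, sites)

    # 3. missing-genotype fraction
    miss_frac = 1.0 - complete.sum(axis=0) / matrix.n_samples
    reason[(reason == 0) & (miss_frac > cfg.max_missing_fraction + 1e-12)] = 3

    # 4. MAF over non-missing alleles
    called = (matrix.alleles >= 0).sum(axis=0)
    alt = (matrix.alleles == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(called > 0, alt / np.maximum(called, 1), np.nan)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    fail_maf = np.isnan(maf) | (maf < cfg.maf_min - 1e-12)
    reason[(reason == 0) & fail_maf] = 4

    # 5. HWE exact test on the pooled sample (sites still alive only)
    counts = genotype_counts(matrix)
    for i in np.flatnonzero(reason == 0):
        if hwe_exact_test(*counts[i]) < cfg.hwe_p_min:
            reason[i] = 5

    names = {1: "multiallelic", 2: "nonautosomal", 3: "missing", 4: "maf", 5: "hwe"}
    for code, name in names.items():
        idx = np.flatnonzero(reason == code)
        setattr(report, f"n_removed_{name}", len(idx))
        if len(idx):
            report.removed_index[name] = idx.tolist()
    keep = reason == 0
    report.n_retained = int(keep.sum())
    if report.n_retained == 0:
        log.warning("apply_qc: no variants retained")
    return matrix.take_variants(keep), report
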