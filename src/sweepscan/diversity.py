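"""Per-site nucleotide diversity and directional log2 ratios.

Per-site pi is the fraction of haplotype pairs that differ at the site:
with j alternate alleles among n non-missing haplotypes,

    pi = 2 j (n - j) / (n (n - 1)).

The contrast statistic is log2(pi_control / pi_test): a site swept in
the test group loses diversity there, so high positive values flag
candidate sweeps in the test group.  Sites monomorphic in either group
(pi = 0) have an undefined ratio and are reported missing; their count
is logged because they silently shape downstream empirical quantiles.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import GroupContrast, HaplotypeMatrix

log = logging.getLogger(__name__)


def pi_site(j: int, n: int) -> float:
    """Per-site diversity: fraction of differing haplotype pairs."""
    if n < 2:
        raise ValueError(f"pi undefined for n={n} haplotypes")
    if not 0 <= j <= n:
        raise ValueError(f"alt count {j} outside [0, {n}]")
    return 2.0 * j * (n - j) / (n * (n - 1.0))


def _group_pi(matrix: HaplotypeMatrix, samples: tuple[str, ...]
              ) -> tuple[np.ndarray, np.ndarray]:
    """(pi, n_called) per site for one group; NaN where n < 2."""
    rows = matrix.haplotype_rows(samples)
    sub = matrix.alleles[rows]
    n = (sub >= 0).sum(axis=0).astype(float)
    j = (sub == 1).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n >= 2, 2.0 * j * (n - j) / (n * np.maximum(n - 1.0, 1.0)),
                      np.nan)
    return pi, n


def pi_ratio_scan(matrix: HaplotypeMatrix, contrast: GroupContrast) -> pd.DataFrame:
    """Per-site pi for both groups plus log2(pi_control / pi_test).

    Returns columns ``chrom, pos, pi_test, pi_control, log2_ratio``;
    the ratio is NaN where either group's pi is zero or undefined.
    """
    contrast.validate_against(matrix)
    pi_t, _ = _group_pi(matrix, contrast.test_samples)
    pi_c, _ = _group_pi(matrix, contrast.control_samples)
    defined = (pi_t > 0) & (pi_c > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(defined, np.log2(np.where(defined, pi_c, 1.0)
                                          / np.where(defined, pi_t, 1.0)), np.nan)
    n_zero = int((~defined).sum())
    if n_zero:
        log.info("pi_ratio_scan[%s]: %d of %d sites have zero/undefined pi "
                 "in a group; ratios set missing", contrast.name, n_zero,
                 matrix.n_variants)
    return pd.DataFrame({
        "chrom": matrix.chroms,
        "pos": matrix.positions,
        "pi_test": pi_t,
        "pi_control": pi_c,
        "log2_ratio": ratio,
    })
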