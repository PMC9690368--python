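"""Per-SNP two-population fixation index (Weir & Cockerham 1984).

The variance-components estimator for r = 2 populations.  With per-group
diploid sample sizes n1, n2 (complete calls at the site), alternate
allele frequencies p1, p2 and observed heterozygote proportions h1, h2:

    n_bar = (n1 + n2) / 2
    n_c   = 2 n_bar - (n1^2 + n2^2) / (2 n_bar)
    p_bar = (n1 p1 + n2 p2) / (2 n_bar)
    s2    = [n1 (p1 - p_bar)^2 + n2 (p2 - p_bar)^2] / n_bar
    h_bar = (n1 h1 + n2 h2) / (2 n_bar)

    a = (n_bar / n_c) [ s2 - (p_bar (1 - p_bar) - s2/2 - h_bar/4) / (n_bar - 1) ]
    b = (n_bar / (n_bar - 1)) [ p_bar (1 - p_bar) - s2/2 - h_bar (2 n_bar - 1) / (4 n_bar) ]
    c = h_bar / 2

and theta-hat = a / (a + b + c).  Negative estimates are clamped to
zero (no biological interpretation); sites with a + b + c = 0 (e.g.
monomorphic in both groups) are reported missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import GroupContrast, HaplotypeMatrix


class FstUndefinedError(ValueError):
    """Estimator undefined: average sample size n_bar <= 1."""


@dataclass(frozen=True)
class FstComponents:
    n1: float
    n2: float
    p1: float
    p2: float
    h1: float
    h2: float
    a: float
    b: float
    c: float

    @property
    def fst_raw(self) -> float:
        denom = self.a + self.b + self.c
        return np.nan if denom == 0 else self.a / denom

    @property
    def fst(self) -> float:
        raw = self.fst_raw
        return raw if np.isnan(raw) else max(raw, 0.0)


def _components_arrays(n1, p1, h1, n2, p2, h2):
    """Vectorised a, b, c; inputs broadcastable arrays."""
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    n_bar = (n1 + n2) / 2.0
    n_c = 2.0 * n_bar - (n1 ** 2 + n2 ** 2) / (2.0 * n_bar)
    p_bar = (n1 * p1 + n2 * p2) / (2.0 * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / n_bar
    h_bar = (n1 * h1 + n2 * h2) / (2.0 * n_bar)
    inner = p_bar * (1.0 - p_bar) - s2 / 2.0
    a = (n_bar / n_c) * (s2 - (inner - h_bar / 4.0) / (n_bar - 1.0))
    b = (n_bar / (n_bar - 1.0)) * (inner - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar))
    c = h_bar / 2.0
    return a, b, c


def fst_components(n1: int, p1: float, h1: float,
                   n2: int, p2: float, h2: float) -> FstComponents:
    """Variance components a, b, c for one site.

    ``n1``/``n2`` are diploid sample sizes with complete calls, ``p``
    alternate-allele frequencies, ``h`` observed heterozygote
    proportions.  Requires n_bar > 1.
    """
    if (n1 + n2) / 2.0 <= 1.0:
        raise FstUndefinedError(
            f"average sample size {(n1 + n2) / 2.0} <= 1; estimator undefined"
        )
    a, b, c = _components_arrays(n1, p1, h1, n2, p2, h2)
    return FstComponents(n1=n1, n2=n2, p1=p1, p2=p2, h1=h1, h2=h2,
                         a=float(a), b=float(b), c=float(c))


def _group_site_stats(matrix: HaplotypeMatrix, samples: tuple[str, ...]):
    """(n, p_alt, h_obs) per site for one group, complete diploid calls only."""
    rows = matrix.haplotype_rows(samples)
    geno = matrix.alleles[rows].reshape(len(samples), 2, matrix.n_variants)
    a0, a1 = geno[:, 0, :].astype(np.int16), geno[:, 1, :].astype(np.int16)
    complete = (a0 >= 0) & (a1 >= 0)
    n = complete.sum(axis=0)
    alt = np.where(complete, a0 + a1, 0).sum(axis=0)
    het = ((a0 != a1) & complete).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(2 * n, 1), np.nan)
        h = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    return n, p, h


def fst_scan(matrix: HaplotypeMatrix, contrast: GroupContrast) -> pd.DataFrame:
    """Per-SNP Weir-Cockerham Fst for one test/control contrast.

    Returns a DataFrame ordered as the matrix (chrom, pos) with columns
    ``chrom, pos, n1, n2, p1, p2, fst_raw, fst``.  ``fst`` is the
    zero-clamped estimate; sites where either group has fewer than two
    complete genotypes, or where a + b + c = 0, carry NaN.
    """
    contrast.validate_against(matrix)
    n1, p1, h1 = _group_site_stats(matrix, contrast.test_samples)
    n2, p2, h2 = _group_site_stats(matrix, contrast.control_samples)
    evaluable = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        a, b, c = _components_arrays(
            np.where(evaluable, n1, 2), p1, h1,
            np.where(evaluable, n2, 2), p2, h2)
        denom = a + b + c
        raw = np.where(evaluable & (denom != 0), a / np.where(denom == 0, 1, denom),
                       np.nan)
    fst = np.where(np.isnan(raw), np.nan, np.maximum(raw, 0.0))
    return pd.DataFrame({
        "chrom": matrix.chroms,
        "pos": matrix.positions,
        "n1": n1, "n2": n2, "p1": p1, "p2": p2,
        "fst_raw": raw, "fst": fst,
    })
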