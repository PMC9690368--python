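"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-derivations — exact rational
enumeration for the Hardy-Weinberg test, pair enumeration for EHH and
per-site diversity, a straight-line transcription of the
variance-components estimator, dense-grid numerical integration, and
all-pairs interval overlap — so that the vectorised implementations are
checked against a genuinely independent path.
"""

from __future__ import annotations

import itertools
import logging
from fractions import Fraction
from math import comb

import numpy as np
import pytest

from sweepscan import (
    GroupContrast,
    HaplotypeMatrix,
    SimConfig,
    Variant,
    apply_qc,
    scan_contrast,
    simulate,
)

logging.getLogger("sweepscan").setLevel(logging.ERROR)


def build_matrix(rows: list[list[int]], positions: list[int] | None = None,
                 chrom: str = "chr1", sample_ids: list[str] | None = None,
                 phased: bool = True) -> HaplotypeMatrix:
    """Hand-build a matrix from haplotype rows (lists over {0,1,-1})."""
    alleles = np.asarray(rows, dtype=np.int8)
    n_var = alleles.shape[1]
    positions = positions or list(range(100, 100 + 10 * n_var, 10))
    n_samples = alleles.shape[0] // 2
    sample_ids = sample_ids or [f"S{i}" for i in range(n_samples)]
    variants = [Variant(chrom=chrom, pos=p, ref="A", alt="G") for p in positions]
    return HaplotypeMatrix(variants=variants, alleles=alleles,
                           sample_ids=sample_ids, phased=phased)


# ---------------------------------------------------------------- oracles

def hwe_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact rational enumeration of the conditional het distribution."""
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n - n_A
    if n_A == 0 or n_a == 0:
        return 1.0
    weights: dict[int, int] = {}
    for h in range(min(n_A, n_a) % 2, min(n_A, n_a) + 1, 2):
        a = (n_A - h) // 2
        b = (n_a - h) // 2
        # multinomial ways of assigning genotypes times 2^h phase choices
        weights[h] = comb(n, a) * comb(n - a, h) * 2 ** h
    total = sum(weights.values())
    probs = {h: Fraction(w, total) for h, w in weights.items()}
    assert sum(probs.values()) == 1  # the conditional distribution is proper
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs))


def wc_fst_oracle(n1, p1, h1, n2, p2, h2):
    """Straight-line Weir-Cockerham (1984) components for r = 2."""
    r = 2
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1 ** 2 + n2 ** 2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (1.0 / (n_bar - 1))
        * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4))
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - ((r - 1) / r) * s2
        - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar)
    c = h_bar / 2
    return a, b, c


def ehh_oracle(haps: np.ndarray, core: int, target: int) -> float:
    """EHH at one site by explicit pair comparison over [core, target]."""
    lo, hi = min(core, target), max(core, target)
    n = haps.shape[0]
    if core == target:
        return 1.0
    identical = 0
    for i, j in itertools.combinations(range(n), 2):
        seg_i = haps[i, lo:hi + 1]
        seg_j = haps[j, lo:hi + 1]
        if np.array_equal(seg_i, seg_j) and not (seg_i < 0).any():
            identical += 1
    return identical / comb(n, 2)


def pi_oracle(j: int, n: int) -> float:
    """Per-site diversity by explicit pair enumeration."""
    alleles = [1] * j + [0] * (n - j)
    diff = sum(1 for a, b in itertools.combinations(alleles, 2) if a != b)
    return diff / comb(n, 2)


def integrate_oracle(dist: np.ndarray, vals: np.ndarray, cutoff: float,
                     n_grid: int = 200_001) -> float:
    """Dense-grid numerical integration of a truncated piecewise-linear arm."""
    if dist.size < 2:
        return 0.0
    grid = np.linspace(dist[0], dist[-1], n_grid)
    curve = np.interp(grid, dist, vals)
    below = np.flatnonzero(curve < cutoff)
    stop = below[0] if below.size else n_grid
    return float(np.trapezoid(curve[:stop], grid[:stop]))


def annotate_oracle(regions, genes):
    """All-pairs closed-interval overlap."""
    out = []
    for r in regions:
        hits = sorted((g.start, g.gene_id) for g in genes
                      if g.chrom == r.chrom and g.start <= r.end and g.end >= r.start)
        out.append(tuple(gid for _, gid in hits))
    return out


# --------------------------------------------------------------- fixtures

PLANTED = dict(n_low_maf=5, n_missing=3, n_hwe_violation=2)


@pytest.fixture(scope="session")
def planted_sim():
    """Default-size simulation with sweep and planted QC violations."""
    cfg = SimConfig(seed=1, **PLANTED)
    matrix, contrasts, truth, genes = simulate(cfg)
    return cfg, matrix, contrasts, truth, genes


@pytest.fixture(scope="session")
def planted_qc(planted_sim):
    _, matrix, _, _, _ = planted_sim
    return apply_qc(matrix)


@pytest.fixture(scope="session")
def sweep_scan(planted_sim, planted_qc):
    """Full scan of the planted fixture (post-QC)."""
    _, _, contrasts, truth, genes = planted_sim
    qc_matrix, _ = planted_qc
    return scan_contrast(qc_matrix, contrasts[0], genes=genes,
                         chrom_bounds=truth.chrom_lengths)


@pytest.fixture
def tiny_matrix():
    """4 diploid samples x 6 sites, phased, complete calls."""
    rows = [
        [0, 1, 0, 0, 1, 0],
        [0, 1, 0, 0, 1, 0],
        [1, 0, 0, 1, 1, 0],
        [0, 0, 1, 1, 0, 1],
        [0, 1, 0, 0, 1, 0],
        [1, 1, 1, 0, 0, 1],
        [0, 0, 0, 1, 1, 0],
        [1, 0, 1, 1, 0, 1],
    ]
    return build_matrix(rows)


@pytest.fixture
def tiny_contrast(tiny_matrix):
    return GroupContrast(name="toy",
                         test_samples=("S0", "S1"),
                         control_samples=("S2", "S3"))
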