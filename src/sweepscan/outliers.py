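"""Empirical outlier calling, intersection, candidate regions, annotation.

The scan's decision rule is empirical: for each statistic the top 1% of
the genome-wide distribution is flagged (for XP-EHH only positive
normalised values are eligible; for Fst and the log2 diversity ratio all
non-missing values are).  SNPs in the top tail of several statistics at
once are the candidates; each gets a 5-kb flanking window on both sides,
overlapping or book-ended windows are merged, and genes overlapping a
merged region by at least one base are attached.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .datamodel import CandidateRegion, GeneModel

DEFAULT_TAIL = 0.01
DEFAULT_FLANK = 5_000


@dataclass
class OutlierSet:
    """Top-tail SNPs of one statistic over one variant universe."""

    statistic: str
    threshold: float
    indices: frozenset[int]


def top_quantile(values: np.ndarray, q: float = DEFAULT_TAIL,
                 positive_only: bool = False,
                 statistic: str = "") -> OutlierSet:
    """Upper-tail outlier set of one per-SNP statistic.

    The threshold is the value of rank ``ceil(q * N)`` from the top
    among eligible (non-missing; positive when ``positive_only``)
    values; every value at or above it is included, so ties at the
    threshold may push the set past exactly q * N members.
    """
    if not 0 < q < 0.5:
        raise ValueError(f"tail fraction must be in (0, 0.5), got {q}")
    values = np.asarray(values, dtype=float)
    eligible = ~np.isnan(values)
    if positive_only:
        eligible &= values > 0
    n = int(eligible.sum())
    if n == 0:
        raise ValueError(f"no eligible values for statistic {statistic!r}")
    if n < 100 / q:
        logging.getLogger(__name__).warning(
            "top_quantile[%s]: only %d eligible values; the %g tail is noisy",
            statistic, n, q)
    k = max(1, math.ceil(q * n))
    threshold = float(np.sort(values[eligible])[-k])
    members = frozenset(np.flatnonzero(eligible & (values >= threshold)).tolist())
    return OutlierSet(statistic=statistic, threshold=threshold, indices=members)


def intersect_outliers(sets: list[OutlierSet]) -> frozenset[int]:
    """SNP indices in the top tail of every given statistic."""
    if not sets:
        return frozenset()
    out = sets[0].indices
    for s in sets[1:]:
        out = out & s.indices
    return out


def snps_to_regions(snp_positions: list[tuple[str, int]], contrast: str,
                    support: str, flank: int = DEFAULT_FLANK,
                    chrom_bounds: dict[str, int] | None = None
                    ) -> list[CandidateRegion]:
    """Flank each outlier SNP by ``flank`` bp and merge into regions.

    Windows are clipped to [1, chromosome length] (right clip only where
    the length is known); overlapping or book-ended windows on one
    chromosome merge into a single region that remembers its source SNP
    positions.  Input pairs are (chrom, 1-based position).
    """
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in snp_positions:
        by_chrom.setdefault(chrom, []).append(pos)
    regions: list[CandidateRegion] = []
    for chrom in by_chrom:
        positions = sorted(by_chrom[chrom])
        bound = (chrom_bounds or {}).get(chrom)
        cur_start = cur_end = None
        cur_snps: list[int] = []
        for pos in positions:
            start = max(1, pos - flank)
            end = pos + flank
            if bound is not None:
                end = min(end, bound)
            if cur_end is not None and start <= cur_end + 1:
                cur_end = max(cur_end, end)
                cur_snps.append(pos)
            else:
                if cur_end is not None:
                    regions.append(CandidateRegion(
                        chrom=chrom, start=cur_start, end=cur_end,
                        contrast=contrast, support=support,
                        source_snps=tuple(cur_snps)))
                cur_start, cur_end, cur_snps = start, end, [pos]
        if cur_end is not None:
            regions.append(CandidateRegion(
                chrom=chrom, start=cur_start, end=cur_end,
                contrast=contrast, support=support,
                source_snps=tuple(cur_snps)))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def annotate_regions(regions: list[CandidateRegion],
                     genes: list[GeneModel]) -> list[CandidateRegion]:
    """Attach genes overlapping each region by >= 1 bp (closed intervals).

    A gene may annotate several regions; a region's gene list may stay
    empty.  Gene order within a region follows (start, gene_id).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom_genes in by_chrom.values():
        chrom_genes.sort(key=lambda g: (g.start, g.gene_id))
    out: list[CandidateRegion] = []
    for r in regions:
        hits = tuple(g.gene_id for g in by_chrom.get(r.chrom, ())
                     if g.start <= r.end and g.end >= r.start)
        out.append(CandidateRegion(chrom=r.chrom, start=r.start, end=r.end,
                                   contrast=r.contrast, support=r.support,
                                   source_snps=r.source_snps, genes=hits))
    return out
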