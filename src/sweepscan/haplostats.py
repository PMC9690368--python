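"""Extended haplotype homozygosity (EHH), its integral, and XP-EHH.

EHH at a site x relative to a core site is the probability that two
haplotypes drawn at random from the group are identical at every variant
between the core and x (both ends inclusive):

    EHH(x) = sum_g C(e_g, 2) / C(n, 2)

over the groups g of haplotypes sharing one sequence on that interval.
By convention EHH at the core itself (offset 0) is 1.  iHH is the area
under the EHH curve over physical distance, both arms summed, truncated
where EHH falls below a cutoff or where consecutive informative sites
are further apart than a maximum gap.

XP-EHH contrasts two groups sharing one integration extent, determined
by the *pooled* sample's EHH falling below the cutoff:

    XP-EHH = ln( iHH_test / iHH_control )

then z-normalised genome-wide.  Positive normalised values mean longer
haplotype homozygosity — a recent sweep — in the test group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import GroupContrast, HaplotypeMatrix, ValidationError

#: Selscan-style defaults: stop integrating when EHH < 0.05, and stop an
#: arm at a gap of more than 200 kb between informative sites.
DEFAULT_CUTOFF = 0.05
DEFAULT_MAX_GAP = 200_000


@dataclass
class EhhCurve:
    """EHH values at signed physical offsets from a core site.

    ``offsets`` are base-pair distances, negative on the left arm,
    ascending, with 0 (EHH = 1) always present.
    """

    core_index: int
    offsets: np.ndarray
    ehh: np.ndarray

    def arm(self, direction: int) -> tuple[np.ndarray, np.ndarray]:
        """(distances, values) for one arm, distances >= 0 ascending."""
        if direction > 0:
            sel = self.offsets >= 0
            return self.offsets[sel], self.ehh[sel]
        sel = self.offsets <= 0
        return -self.offsets[sel][::-1], self.ehh[sel][::-1]


def _pair_fraction(labels: np.ndarray) -> float:
    """Fraction of haplotype pairs with identical labels."""
    n = labels.size
    if n < 2:
        return np.nan
    counts = np.bincount(labels)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def _refine(labels: np.ndarray, alleles: np.ndarray) -> np.ndarray:
    """Split identity classes by the alleles at one more site."""
    # missing (-1) is treated as a distinct symbol: an uncalled allele
    # never extends shared homozygosity
    key = labels * 3 + (alleles + 1)
    _, out = np.unique(key, return_inverse=True)
    return out.astype(np.int64)


def ehh_at_core(haps: np.ndarray, core_index: int, positions: np.ndarray,
                cutoff: float = 0.0, max_gap: int | None = None) -> EhhCurve:
    """EHH curve for one group of haplotypes around a core site.

    ``haps`` is a (n_haplotypes, n_sites) allele matrix for a single
    chromosome, ``positions`` its 1-based coordinates (strictly
    increasing).  Each arm extends outward until EHH drops below
    ``cutoff``, the chromosome ends, or the gap to the next informative
    site exceeds ``max_gap``.  Requires at least two haplotypes.
    """
    haps = np.asarray(haps)
    positions = np.asarray(positions)
    if haps.shape[0] < 2:
        raise ValidationError("EHH is undefined for fewer than 2 haplotypes")
    if np.any(np.diff(positions) <= 0):
        raise ValidationError("positions must be strictly increasing")
    offs: list[int] = [0]
    vals: list[float] = [1.0]
    for direction in (+1, -1):
        labels = _refine(np.zeros(haps.shape[0], dtype=np.int64), haps[:, core_index])
        i = core_index
        while True:
            j = i + direction
            if j < 0 or j >= haps.shape[1]:
                break
            if max_gap is not None and abs(int(positions[j]) - int(positions[i])) > max_gap:
                break
            labels = _refine(labels, haps[:, j])
            e = _pair_fraction(labels)
            if e < cutoff:
                break
            offs.append(int(positions[j]) - int(positions[core_index]))
            vals.append(e)
            if e == 0.0:
                break
            i = j
    order = np.argsort(offs)
    return EhhCurve(core_index=core_index,
                    offsets=np.asarray(offs, dtype=np.int64)[order],
                    ehh=np.asarray(vals, dtype=float)[order])


def _integrate_arm(dist: np.ndarray, vals: np.ndarray, max_gap: int | None,
                   cutoff: float) -> float:
    """Trapezoidal area of one arm with cutoff and gap truncation.

    The arm is truncated at the last site before a gap larger than
    ``max_gap``; where the (piecewise-linear) curve crosses ``cutoff``
    the final partial trapezoid up to the interpolated crossing point is
    included.
    """
    area = 0.0
    for k in range(1, dist.size):
        step = float(dist[k] - dist[k - 1])
        if max_gap is not None and step > max_gap:
            break
        v0, v1 = float(vals[k - 1]), float(vals[k])
        if v0 < cutoff:
            break
        if v1 < cutoff:
            # linear interpolation to the cutoff crossing
            frac = (v0 - cutoff) / (v0 - v1)
            area += step * frac * (v0 + cutoff) / 2.0
            break
        area += step * (v0 + v1) / 2.0
    return area


def integrate_ehh(curve: EhhCurve, max_gap: int | None = DEFAULT_MAX_GAP,
                  cutoff: float = DEFAULT_CUTOFF) -> float:
    """iHH: area (bp) under an EHH curve, both arms, with truncation."""
    total = 0.0
    for direction in (+1, -1):
        dist, vals = curve.arm(direction)
        total += _integrate_arm(dist, vals, max_gap, cutoff)
    return total


def _xpehh_site(alleles: np.ndarray, positions: np.ndarray, core: int,
                test_rows: np.ndarray, control_rows: np.ndarray,
                max_gap: int, cutoff: float) -> tuple[float, float]:
    """(iHH_test, iHH_control) at one core with the pooled stopping rule.

    Both groups are integrated over the same physical extent per arm:
    sites are included while the pooled EHH stays at or above ``cutoff``
    and gaps stay within ``max_gap``; at the pooled cutoff crossing the
    partial trapezoid is interpolated for all three curves.
    """
    n_all = alleles.shape[0]
    ihh_t = 0.0
    ihh_c = 0.0
    for direction in (+1, -1):
        labels = _refine(np.zeros(n_all, dtype=np.int64), alleles[:, core])
        e_pool_prev = 1.0
        e_t_prev = 1.0
        e_c_prev = 1.0
        i = core
        d_prev = 0
        while True:
            j = i + direction
            if j < 0 or j >= alleles.shape[1]:
                break
            d = abs(int(positions[j]) - int(positions[core]))
            step = d - d_prev
            if step > max_gap:
                break
            labels = _refine(labels, alleles[:, j])
            e_pool = _pair_fraction(labels)
            e_t = _pair_fraction(labels[test_rows])
            e_c = _pair_fraction(labels[control_rows])
            if e_pool < cutoff:
                frac = (e_pool_prev - cutoff) / (e_pool_prev - e_pool)
                e_t_x = e_t_prev + frac * (e_t - e_t_prev)
                e_c_x = e_c_prev + frac * (e_c - e_c_prev)
                ihh_t += step * frac * (e_t_prev + e_t_x) / 2.0
                ihh_c += step * frac * (e_c_prev + e_c_x) / 2.0
                break
            ihh_t += step * (e_t_prev + e_t) / 2.0
            ihh_c += step * (e_c_prev + e_c) / 2.0
            if e_pool == 0.0:
                break
            e_pool_prev, e_t_prev, e_c_prev = e_pool, e_t, e_c
            i, d_prev = j, d
    return ihh_t, ihh_c


def xpehh_scan(matrix: HaplotypeMatrix, contrast: GroupContrast,
               max_gap: int = DEFAULT_MAX_GAP,
               cutoff: float = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Raw XP-EHH at every site of a phased matrix.

    Returns a DataFrame with columns ``chrom, pos, ihh_test,
    ihh_control, xpehh_raw`` (NaN where either area is zero, e.g. at
    isolated sites).  Use :func:`normalize_xpehh` to add z-scores.
    """
    if not matrix.phased:
        raise ValidationError("XP-EHH requires phased haplotypes")
    contrast.validate_against(matrix)
    test_rows = matrix.haplotype_rows(contrast.test_samples)
    control_rows = matrix.haplotype_rows(contrast.control_samples)
    all_rows = np.concatenate([test_rows, control_rows])
    t_idx = np.arange(test_rows.size)
    c_idx = np.arange(test_rows.size, all_rows.size)
    positions = matrix.positions
    ihh_t = np.full(matrix.n_variants, np.nan)
    ihh_c = np.full(matrix.n_variants, np.nan)
    for chrom, block in matrix.chrom_blocks().items():
        sub = matrix.alleles[all_rows, block]
        pos = positions[block]
        for local in range(sub.shape[1]):
            t, c = _xpehh_site(sub, pos, local, t_idx, c_idx, max_gap, cutoff)
            ihh_t[block.start + local] = t
            ihh_c[block.start + local] = c
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where((ihh_t > 0) & (ihh_c > 0), np.log(ihh_t / ihh_c), np.nan)
    return pd.DataFrame({
        "chrom": matrix.chroms,
        "pos": positions,
        "ihh_test": ihh_t,
        "ihh_control": ihh_c,
        "xpehh_raw": raw,
    })


def normalize_xpehh(results: pd.DataFrame) -> pd.DataFrame:
    """Add genome-wide z-scores (column ``xpehh_norm``).

    Mean and sample standard deviation (n - 1) are taken over all
    non-missing raw values; requires at least two of them and nonzero
    variance.
    """
    raw = results["xpehh_raw"].to_numpy()
    ok = ~np.isnan(raw)
    if ok.sum() < 2:
        raise ValidationError("need >= 2 non-missing XP-EHH values to normalize")
    mean = raw[ok].mean()
    sd = raw[ok].std(ddof=1)
    if sd == 0:
        raise ValidationError("XP-EHH values have zero variance; cannot normalize")
    out = results.copy()
    out["xpehh_norm"] = (raw - mean) / sd
    return out
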