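"""EHH, iHH integration, and XP-EHH contracts."""

import numpy as np
import pytest

from sweepscan import (
    GroupContrast,
    ValidationError,
    ehh_at_core,
    integrate_ehh,
    normalize_xpehh,
    xpehh_scan,
)
from sweepscan.haplostats import EhhCurve

from conftest import build_matrix, ehh_oracle, integrate_oracle


class TestEhhAtCore:
    def test_value_at_core_is_one(self):
        haps = np.array([[0, 1, 0], [1, 0, 1], [0, 0, 1], [1, 1, 0]], dtype=np.int8)
        curve = ehh_at_core(haps, 1, np.array([100, 200, 300]))
        assert curve.ehh[curve.offsets == 0][0] == 1.0

    def test_partition_of_sizes_2_1_1_gives_one_sixth(self):
        # over [core, x] the four haplotypes split into groups {2,1,1}
        haps = np.array([[0, 0], [0, 0], [0, 1], [1, 0]], dtype=np.int8)
        curve = ehh_at_core(haps, 0, np.array([100, 200]))
        assert curve.ehh[curve.offsets == 100][0] == pytest.approx(1 / 6)

    def test_identical_haplotypes_keep_ehh_at_one(self):
        haps = np.tile(np.array([0, 1, 1, 0, 1], dtype=np.int8), (6, 1))
        pos = np.array([1000, 2000, 5000, 8000, 11000])
        curve = ehh_at_core(haps, 2, pos)
        assert (curve.ehh == 1.0).all()
        area = integrate_ehh(curve, max_gap=None, cutoff=0.0)
        assert area == pytest.approx(pos[-1] - pos[0])  # chromosome span

    def test_fewer_than_two_haplotypes_rejected(self):
        with pytest.raises(ValidationError):
            ehh_at_core(np.array([[0, 1]], dtype=np.int8), 0, np.array([1, 2]))

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_pair_enumeration_oracle_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n_haps = int(rng.integers(2, 13))
        n_sites = int(rng.integers(3, 15))
        haps = rng.integers(0, 2, size=(n_haps, n_sites)).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 10_000), n_sites, replace=False))
        core = int(rng.integers(n_sites))
        curve = ehh_at_core(haps, core, pos)
        for off, val in zip(curve.offsets, curve.ehh):
            target = int(np.flatnonzero(pos == pos[core] + off)[0])
            assert val == ehh_oracle(haps, core, target)

    @pytest.mark.parametrize("seed", range(6))
    def test_non_increasing_within_unit_interval(self, seed):
        rng = np.random.default_rng(100 + seed)
        haps = rng.integers(0, 2, size=(10, 30)).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 100_000), 30, replace=False))
        curve = ehh_at_core(haps, 15, pos)
        assert ((curve.ehh >= 0) & (curve.ehh <= 1)).all()
        for direction in (+1, -1):
            _, vals = curve.arm(direction)
            assert (np.diff(vals) <= 1e-12).all()


class TestIntegrateEhh:
    def test_rectangle(self):
        curve = EhhCurve(core_index=0,
                         offsets=np.array([0, 10_000]),
                         ehh=np.array([1.0, 1.0]))
        assert integrate_ehh(curve, cutoff=0.05) == pytest.approx(10_000)

    def test_max_gap_truncates_arm(self):
        curve = EhhCurve(core_index=0,
                         offsets=np.array([0, 250_000]),
                         ehh=np.array([1.0, 1.0]))
        assert integrate_ehh(curve, max_gap=200_000, cutoff=0.05) == 0.0

    def test_linear_decay_matches_dense_numerical_oracle(self):
        dist = np.arange(0, 10_001, 250)
        vals = 1.0 - dist / 10_000.0
        curve = EhhCurve(core_index=0, offsets=dist, ehh=vals)
        area = integrate_ehh(curve, max_gap=None, cutoff=0.05)
        expected = integrate_oracle(dist.astype(float), vals, cutoff=0.05)
        assert area == pytest.approx(expected, rel=1e-3)

    def test_single_point_curve_has_zero_area(self):
        curve = EhhCurve(core_index=0, offsets=np.array([0]),
                         ehh=np.array([1.0]))
        assert integrate_ehh(curve) == 0.0


class TestXpehh:
    def _contrast(self):
        return GroupContrast(name="c", test_samples=("S0", "S1"),
                             control_samples=("S2", "S3"))

    def test_identical_groups_give_zero(self):
        rng = np.random.default_rng(0)
        block = rng.integers(0, 2, size=(4, 12))
        m = build_matrix(np.vstack([block, block]).tolist())
        df = xpehh_scan(m, self._contrast())
        ok = ~np.isnan(df["xpehh_raw"])
        assert ok.any()
        np.testing.assert_allclose(df.loc[ok, "xpehh_raw"], 0.0, atol=1e-12)

    def test_homogeneous_test_group_scores_positive(self):
        test = np.tile(np.array([0, 1, 0, 1, 1, 0, 0, 1], dtype=np.int8), (4, 1))
        rng = np.random.default_rng(5)
        control = rng.integers(0, 2, size=(4, 8)).astype(np.int8)
        m = build_matrix(np.vstack([test, control]).tolist())
        df = xpehh_scan(m, self._contrast())
        assert np.nanmean(df["xpehh_raw"]) > 0.5

    def test_antisymmetric_under_group_swap(self, tiny_matrix, tiny_contrast):
        fwd = xpehh_scan(tiny_matrix, tiny_contrast)
        rev = xpehh_scan(tiny_matrix, GroupContrast(
            name="r", test_samples=tiny_contrast.control_samples,
            control_samples=tiny_contrast.test_samples))
        np.testing.assert_allclose(fwd["xpehh_raw"], -rev["xpehh_raw"],
                                   atol=1e-12)

    def test_unphased_matrix_rejected(self, tiny_matrix, tiny_contrast):
        tiny_matrix.phased = False
        with pytest.raises(ValidationError, match="phased"):
            xpehh_scan(tiny_matrix, tiny_contrast)

    def test_sweep_region_enriched_over_genome(self, planted_sim, planted_qc,
                                               sweep_scan):
        _, _, _, truth, _ = planted_sim
        df = sweep_scan.xpehh
        lo, hi = truth.expected_interval
        inside = (df["chrom"] == truth.sweep_chrom) & df["pos"].between(lo, hi)
        assert df.loc[inside, "xpehh_norm"].mean() > df["xpehh_norm"].mean()
        # the genome-wide maximum lies on the swept haplotype
        assert inside[df["xpehh_norm"].idxmax()]


class TestNormalize:
    def test_standardized_input_unchanged(self):
        import pandas as pd
        df = pd.DataFrame({"xpehh_raw": [-1.0, 0.0, 1.0]})
        out = normalize_xpehh(df)
        np.testing.assert_allclose(out["xpehh_norm"], [-1, 0, 1], atol=1e-12)

    def test_constant_input_rejected(self):
        import pandas as pd
        with pytest.raises(ValidationError, match="variance"):
            normalize_xpehh(pd.DataFrame({"xpehh_raw": [2.0, 2.0, 2.0]}))

    def test_moments_after_normalization(self, sweep_scan):
        z = sweep_scan.xpehh["xpehh_norm"].dropna()
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1) < 1e-9
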