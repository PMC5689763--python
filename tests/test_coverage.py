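"""Radius-of-action tumor coverage and the homogeneous-placement maximum."""

import numpy as np
import pytest
from scipy import ndimage

from conftest import bruteforce_coverage_pct
from nscquant.coverage import (
    CoverageParams,
    coverage_by_radii,
    coverage_efficiency,
    coverage_fraction,
    disk_union_coverage,
    theoretical_max_coverage,
)
from nscquant.stains import BinaryMask


def _mask(arr, px=1.0, label=""):
    return BinaryMask(np.asarray(arr, dtype=bool), pixel_size_um=px, label=label)


def _random_pair(rng, size):
    """Random blobby tumor mask + sparse NSC points."""
    tumor = ndimage.gaussian_filter(rng.normal(size=(size, size)), sigma=size / 8)
    tumor_mask = tumor > np.percentile(tumor, 60)
    if not tumor_mask.any():
        tumor_mask[size // 2, size // 2] = True
    nsc_mask = np.zeros((size, size), dtype=bool)
    k = rng.integers(0, 12)
    if k:
        idx = rng.integers(0, size, size=(k, 2))
        nsc_mask[idx[:, 0], idx[:, 1]] = True
    return _mask(nsc_mask, label="nsc"), _mask(tumor_mask, label="tumor")


class TestCoverageFraction:
    def test_empty_nsc_mask_gives_zero(self):
        assert coverage_fraction(_mask(np.zeros((10, 10))), _mask(np.ones((10, 10))), 25.0) == 0.0

    def test_tumor_inside_nsc_ring_fully_covered(self):
        nsc = np.zeros((41, 41), dtype=bool)
        nsc[10, 10:30] = nsc[30, 10:30] = nsc[10:31, 10] = nsc[10:31, 30] = True
        tumor = np.zeros((41, 41), dtype=bool)
        tumor[18:23, 18:23] = True
        assert coverage_fraction(_mask(nsc), _mask(tumor), 15.0) == 100.0

    def test_single_center_pixel_lattice_disk(self):
        """Single NSC pixel in an all-tumor frame: covered count equals
        the exhaustively enumerated lattice disk."""
        n = 201
        nsc = np.zeros((n, n), dtype=bool)
        nsc[100, 100] = True
        tumor = np.ones((n, n), dtype=bool)
        expected = 0
        for r in range(n):
            for c in range(n):
                if np.hypot(r - 100, c - 100) <= 50.0:
                    expected += 1
        got = coverage_fraction(_mask(nsc), _mask(tumor), 50.0)
        assert got == 100.0 * expected / n**2

    def test_radius_zero_equals_overlap_fraction(self, rng):
        nsc, tumor = _random_pair(rng, 64)
        overlap = 100.0 * (nsc.mask & tumor.mask).sum() / tumor.mask.sum()
        assert coverage_fraction(nsc, tumor, 0.0) == overlap

    def test_monotone_in_radius(self, rng):
        nsc, tumor = _random_pair(rng, 96)
        covs = [coverage_fraction(nsc, tumor, r) for r in (0, 5, 10, 25, 50, 100)]
        assert covs == sorted(covs)

    def test_monotone_in_nsc_inclusion(self, rng):
        nsc, tumor = _random_pair(rng, 96)
        more = nsc.mask.copy()
        more[rng.integers(0, 96, 5), rng.integers(0, 96, 5)] = True
        assert coverage_fraction(_mask(more), tumor, 25.0) >= coverage_fraction(
            nsc, tumor, 25.0
        )

    def test_empty_tumor_is_an_error(self):
        with pytest.raises(ValueError, match="tumor"):
            coverage_fraction(_mask(np.ones((4, 4))), _mask(np.zeros((4, 4))), 10.0)

    def test_mismatched_masks_rejected(self):
        with pytest.raises(ValueError):
            coverage_fraction(_mask(np.ones((4, 4))), _mask(np.ones((5, 5))), 10.0)

    def test_agrees_with_disk_union_route(self, rng):
        for _ in range(5):
            nsc, tumor = _random_pair(rng, 80)
            for r in (10.0, 25.0):
                assert coverage_fraction(nsc, tumor, r) == disk_union_coverage(
                    nsc, tumor, r
                )

    def test_agrees_with_bruteforce_on_small_images(self, rng):
        for _ in range(3):
            nsc, tumor = _random_pair(rng, 48)
            for r in (7.0, 20.0):
                assert coverage_fraction(nsc, tumor, r) == bruteforce_coverage_pct(
                    nsc.mask, tumor.mask, r
                )

    def test_by_radii_consistent_with_single_radius(self, rng):
        nsc, tumor = _random_pair(rng, 64)
        multi = coverage_by_radii(nsc, tumor, (10.0, 30.0))
        for r, v in multi.items():
            assert v == coverage_fraction(nsc, tumor, r)


class TestTheoreticalMax:
    def test_zero_cells(self):
        assert theoretical_max_coverage(0, 1e4) == 0.0

    def test_cap_at_100(self):
        assert theoretical_max_coverage(1e6, 1.0) == 100.0

    def test_arithmetic(self):
        r_eff = np.sqrt(100.0 / np.pi)
        params = CoverageParams(radius_um=r_eff, cell_radius_um=0.0)
        assert theoretical_max_coverage(10, 10_000.0, params) == pytest.approx(10.0)

    def test_zero_area_undefined(self):
        with pytest.raises(ValueError):
            theoretical_max_coverage(5, 0.0)


class TestEfficiency:
    def test_equal_gives_one(self):
        assert coverage_efficiency(42.0, 42.0) == 1.0

    def test_zero_observed(self):
        assert coverage_efficiency(0.0, 50.0) == 0.0

    def test_zero_theoretical_undefined(self):
        with pytest.raises(ValueError):
            coverage_efficiency(10.0, 0.0)

    def test_widely_spaced_interior_cells_near_unit_efficiency(self):
        """Non-overlapping disks fully inside the tumor: observed
        coverage should be within 2% of the theoretical maximum."""
        size = 300
        tumor = np.ones((size, size), dtype=bool)
        centers = np.array(
            [[75.0, 75.0], [75.0, 225.0], [225.0, 75.0], [225.0, 225.0]]
        )
        nsc = np.zeros((size, size), dtype=bool)
        for x, y in centers:
            nsc[int(y), int(x)] = True
        params = CoverageParams(radius_um=30.0, cell_radius_um=0.0)
        observed = coverage_fraction(_mask(nsc), _mask(tumor), params)
        theoretical = theoretical_max_coverage(4, float(size**2), params)
        assert coverage_efficiency(observed, theoretical) == pytest.approx(1.0, abs=0.02)
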