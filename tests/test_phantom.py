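"""Synthetic-histology phantom generator: determinism, placement, truth."""

import numpy as np
import pytest

from conftest import bruteforce_coverage_pct
from nscquant import stains
from nscquant.coverage import disk_union_coverage
from nscquant.phantom import (
    PhantomSpec,
    _TumorShape,
    generate_phantom,
    generate_section_pattern,
    place_nscs,
    rasterize_disks,
    render_section,
)
from nscquant.spatial import cluster_points
from nscquant.stains import BinaryMask


class TestSpecValidation:
    def test_tumor_must_fit_in_field(self):
        with pytest.raises(ValueError, match="larger than the image field"):
            PhantomSpec(image_size_px=128, tumor_semi_axes_um=(100.0, 80.0, 300.0))

    def test_impossible_proportions_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(cluster_fraction=0.8, edge_bias=0.4)

    def test_probabilities_validated(self):
        with pytest.raises(ValueError):
            PhantomSpec(edge_bias=1.5)


class TestDeterminism:
    def test_same_seed_identical_output(self):
        spec = PhantomSpec(
            image_size_px=96,
            tumor_semi_axes_um=(35.0, 30.0, 200.0),
            n_sections=3,
            n_nsc_total=40,
            seed=9,
        )
        pairs_a, truth_a = generate_phantom(spec)
        pairs_b, truth_b = generate_phantom(spec)
        for (na, ta), (nb, tb) in zip(pairs_a, pairs_b):
            np.testing.assert_array_equal(na.pixels, nb.pixels)
            np.testing.assert_array_equal(ta.pixels, tb.pixels)
        np.testing.assert_array_equal(
            truth_a.nsc_points_xyz_um, truth_b.nsc_points_xyz_um
        )
        for r in truth_a.coverage_pct:
            np.testing.assert_array_equal(
                truth_a.coverage_pct[r], truth_b.coverage_pct[r]
            )

    def test_different_seed_different_realization(self):
        kw = dict(
            image_size_px=96,
            tumor_semi_axes_um=(35.0, 30.0, 200.0),
            n_sections=3,
            n_nsc_total=40,
        )
        _, ta = generate_phantom(PhantomSpec(seed=1, **kw))
        _, tb = generate_phantom(PhantomSpec(seed=2, **kw))
        assert not np.array_equal(ta.nsc_points_xyz_um, tb.nsc_points_xyz_um)


class TestPlacement:
    def _shape_and_spec(self, **kw):
        spec = PhantomSpec(
            image_size_px=160,
            tumor_semi_axes_um=(60.0, 50.0, 300.0),
            n_sections=4,
            seed=11,
            **kw,
        )
        rng = np.random.default_rng(spec.seed)
        return _TumorShape(spec, rng), spec, rng

    def test_exact_requested_count(self):
        shape, spec, rng = self._shape_and_spec(n_nsc_total=137)
        pts = place_nscs(shape, spec, rng)
        assert pts.shape == (137, 3)

    def test_all_points_inside_tumor(self):
        shape, spec, rng = self._shape_and_spec(n_nsc_total=200)
        pts = place_nscs(shape, spec, rng)
        assert shape.contains(pts).all()

    def test_uniform_pattern_is_csr_against_mc_envelope(self):
        """Mean nearest-neighbor distance of the uniform generator falls
        inside a Monte-Carlo envelope built from an independent
        polar-coordinate CSR sampler in the same disk."""
        n, radius = 250, 110.0
        pts, _, _ = generate_section_pattern(
            n,
            tumor_radius_um=radius,
            cluster_fraction=0.0,
            edge_bias=0.0,
            seed=21,
        )

        def mean_nn(points):
            from scipy.spatial import cKDTree

            d, _ = cKDTree(points).query(points, k=2)
            return d[:, 1].mean()

        observed = mean_nn(pts)
        rng = np.random.default_rng(77)
        envelope = []
        for _ in range(200):
            r = radius * np.sqrt(rng.uniform(0, 1, n))
            th = rng.uniform(0, 2 * np.pi, n)
            envelope.append(mean_nn(np.column_stack([r * np.cos(th), r * np.sin(th)])))
        assert min(envelope) <= observed <= max(envelope)

    def test_tight_clusters_reach_ci_maximum(self):
        n = 60
        pts, _, _ = generate_section_pattern(
            n,
            cluster_fraction=1.0,
            clusters_mean_offspring=float(n),
            cluster_sd_um=3.0,
            seed=31,
        )
        ci = cluster_points(pts, 50.0).ci
        assert ci >= (1 - 1 / n) - 0.05

    def test_edge_bias_places_points_in_rim(self):
        pts, _, tumor = generate_section_pattern(
            100,
            tumor_radius_um=100.0,
            cluster_fraction=0.0,
            edge_bias=1.0,
            edge_rim_frac=0.1,
            image_size_px=256,
            seed=41,
        )
        center = 128.0
        radii = np.hypot(pts[:, 0] - center, pts[:, 1] - center)
        assert np.all(radii >= 100.0 * 0.9 - 1e-6)


class TestRendering:
    def test_zero_cells_uniform_counterstain_background(self):
        spec = PhantomSpec(
            image_size_px=96,
            tumor_semi_axes_um=(35.0, 30.0, 200.0),
            n_sections=3,
            n_nsc_total=0,
            noise_sd=0.0,
            seed=13,
        )
        pairs, truth = generate_phantom(spec)
        nsc_img = pairs[1][0]
        # all pixels identical: counterstain only
        assert np.unique(nsc_img.pixels.reshape(-1, 3), axis=0).shape[0] == 1
        for covs in truth.coverage_pct.values():
            assert all(c == 0.0 for c in covs if not np.isnan(c))

    def test_noise_free_unmixing_recovers_concentrations(self):
        spec = PhantomSpec(
            image_size_px=96,
            tumor_semi_axes_um=(35.0, 30.0, 200.0),
            n_sections=3,
            n_nsc_total=0,
            noise_sd=0.0,
            seed=13,
        )
        rng = np.random.default_rng(0)
        tumor_mask = np.zeros((64, 64), dtype=bool)
        tumor_mask[20:40, 20:40] = True
        pts = np.array([[15.0, 15.0], [50.0, 30.0]])
        nsc_img, tumor_img = render_section(tumor_mask, pts, spec, rng)
        conc = stains.deconvolve(stains.rgb_to_od(nsc_img), spec.nsc_stains)
        expected = spec.stain_amplitude * rasterize_disks(
            pts, spec.cell_radius_um, (64, 64), 1.0
        )
        np.testing.assert_allclose(conc[..., 0], expected, atol=1e-9)
        np.testing.assert_allclose(
            conc[..., 1], spec.counterstain_amplitude, atol=1e-9
        )
        tconc = stains.deconvolve(stains.rgb_to_od(tumor_img), spec.tumor_stains)
        np.testing.assert_allclose(tconc[..., 0], tumor_mask.astype(float), atol=1e-9)

    def test_noisy_recovery_within_propagated_tolerance(self):
        spec = PhantomSpec(
            image_size_px=96,
            tumor_semi_axes_um=(35.0, 30.0, 200.0),
            n_sections=3,
            noise_sd=2.0,
            seed=13,
        )
        rng = np.random.default_rng(1)
        tumor_mask = np.zeros((64, 64), dtype=bool)
        tumor_mask[10:50, 10:50] = True
        nsc_img, _ = render_section(tumor_mask, np.array([[32.0, 32.0]]), spec, rng)
        conc = stains.deconvolve(stains.rgb_to_od(nsc_img), spec.nsc_stains)
        truth_conc = rasterize_disks(
            np.array([[32.0, 32.0]]), spec.cell_radius_um, (64, 64), 1.0
        ).astype(float)
        # intensity noise sd -> OD noise <= sd/(I_min*ln10); unmixing
        # amplifies by ||row of M^-1|| <= ~4 here; allow 3 sigma
        i_min = 255.0 * 10 ** (-1.2)
        sigma_conc = 4.0 * 3 * spec.noise_sd / (i_min * np.log(10))
        assert np.max(np.abs(conc[..., 0] - truth_conc)) <= 3 * sigma_conc + 0.05


class TestGroundTruth:
    def test_truth_coverage_two_independent_routes_agree(self, small_phantom):
        _, _, truth = small_phantom
        k = int(np.argmax(truth.section_nsc_counts))
        nsc = BinaryMask(truth.nsc_masks[k], 1.0, "nsc")
        tumor = BinaryMask(truth.tumor_masks[k], 1.0, "tumor")
        for r in (25.0, 50.0):
            assert truth.coverage_pct[r][k] == bruteforce_coverage_pct(
                nsc.mask, tumor.mask, r
            )
            assert truth.coverage_pct[r][k] == disk_union_coverage(nsc, tumor, r)

    def test_voxel_volume_near_analytic(self, small_phantom):
        _, _, truth = small_phantom
        assert truth.volume_voxel_mm3 == pytest.approx(
            truth.volume_analytic_mm3, rel=0.05
        )

    def test_administered_count_from_retention(self, small_phantom):
        spec, _, truth = small_phantom
        assert truth.administered_count == pytest.approx(
            truth.n_nsc_total / spec.retention_fraction
        )

    def test_coverage_increases_with_dose_at_fixed_geometry(self):
        """Nested sub-doses of one realization: more cells never lower
        coverage (dose-coverage trend at fixed geometry)."""
        pts, _, tumor = generate_section_pattern(
            120, tumor_radius_um=100.0, image_size_px=256, seed=51
        )
        from nscquant.coverage import coverage_fraction

        tumor_m = BinaryMask(tumor, 1.0, "tumor")
        covs = []
        for n in (10, 30, 60, 120):
            nsc = rasterize_disks(pts[:n], 4.5, tumor.shape, 1.0)
            covs.append(coverage_fraction(BinaryMask(nsc, 1.0, "nsc"), tumor_m, 50.0))
        assert covs == sorted(covs)


def test_rasterize_disks_respects_radius():
    mask = rasterize_disks(np.array([[10.0, 10.0]]), 3.0, (21, 21), 1.0)
    ys, xs = np.nonzero(mask)
    assert np.all(np.hypot(ys - 10, xs - 10) <= 3.0)
    assert mask[10, 10] and mask[10, 13] and not mask[10, 14]
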