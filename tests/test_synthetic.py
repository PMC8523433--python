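import math

import numpy as np
import pytest
from scipy.spatial import cKDTree

from conemosaic.detection import DetectionParams, detect_cones, to_16bit_sharpened
from conemosaic.geometry import ROISpec, radius_for_eccentricity
from conemosaic.metrics import metrics_from_cones
from conemosaic.synthetic import (
    SyntheticMosaicSpec,
    density_to_spacing_um,
    eccentricity_preset,
    generate_mosaic,
    pathology_preset,
    render_image,
    spacing_to_density_mm2,
)


class TestSpacingDensityConversion:
    def test_roundtrip(self):
        for d in (5000.0, 11452.0, 20022.0):
            assert spacing_to_density_mm2(density_to_spacing_um(d)) == pytest.approx(d, rel=1e-12)

    def test_preset_spacing_closed_form(self):
        # 14946 cones/mm² → s = √(2/(√3·D)) ≈ 8.79 µm
        spec = eccentricity_preset(3.0)
        assert spec.spacing_um == pytest.approx(8.79, abs=0.01)


class TestGenerateMosaic:
    def test_pure_lattice_density_matches_closed_form(self):
        spec = SyntheticMosaicSpec(spacing_um=10.0, jitter_frac=0, dropout_frac=0,
                                   region_um=400.0, seed=0)
        gt = generate_mosaic(spec)
        closed = 2.0 / (math.sqrt(3) * 1e-4)  # 11547 cones/mm²
        # inclusive borders add up to one boundary layer per dimension
        layer = 10.0 / 400.0 + (10.0 * math.sqrt(3) / 2) / 400.0
        assert gt.realized_density_mm2() == pytest.approx(closed, rel=layer)

    def test_dropout_halves_count(self):
        base = SyntheticMosaicSpec(spacing_um=8.0, jitter_frac=0, dropout_frac=0, seed=5)
        half = SyntheticMosaicSpec(spacing_um=8.0, jitter_frac=0, dropout_frac=0.5, seed=5)
        n0 = len(generate_mosaic(base).cones)
        n1 = len(generate_mosaic(half).cones)
        sd = math.sqrt(n0 * 0.25)
        assert abs(n1 - 0.5 * n0) < 4 * sd

    def test_seed_determinism(self):
        spec = eccentricity_preset(5.0, seed=99)
        a = generate_mosaic(spec)
        b = generate_mosaic(spec)
        assert np.array_equal(a.cones.xy, b.cones.xy)

    def test_density_converges_with_region(self):
        target = 11452.0
        err = []
        for region in (120.0, 480.0):
            spec = SyntheticMosaicSpec(target_density_cones_per_mm2=target, jitter_frac=0.1,
                                       dropout_frac=0, region_um=region, seed=3)
            err.append(abs(generate_mosaic(spec).realized_density_mm2() - target) / target)
        assert err[1] < err[0]

    def test_sub_nyquist_spacing_warns(self):
        spec = SyntheticMosaicSpec(spacing_um=2.0, pixel_scale_um=1.5, seed=0)
        with pytest.warns(UserWarning, match="sub-Nyquist"):
            generate_mosaic(spec)

    def test_coordinates_inside_region(self):
        gt = generate_mosaic(eccentricity_preset(2.0, seed=17))
        assert gt.cones.x_um.min() >= 0 and gt.cones.x_um.max() <= gt.spec.region_um
        assert gt.cones.y_um.min() >= 0 and gt.cones.y_um.max() <= gt.spec.region_um


class TestRenderImage:
    def test_single_cone_peak_at_nearest_pixel(self):
        spec = SyntheticMosaicSpec(spacing_um=10.0, jitter_frac=0, dropout_frac=0,
                                   reflectivity_cv=0, background_sd=0, region_um=60.0, seed=0)
        gt = generate_mosaic(spec)
        from conemosaic.detection import ConeSet, crop_cones

        one = ConeSet(x_um=[30.0], y_um=[27.0], intensity=[np.nan], provenance="ground_truth")
        gt.cones = one
        img = render_image(gt)
        iy, ix = np.unravel_index(np.argmax(img.pixels), img.pixels.shape)
        assert (ix, iy) == (round(30.0 / 1.5), round(27.0 / 1.5))

    def test_empty_mosaic_renders_background(self):
        from conemosaic.detection import ConeSet

        spec = SyntheticMosaicSpec(spacing_um=10.0, region_um=60.0, seed=0)
        gt = generate_mosaic(spec)
        gt.cones = ConeSet(x_um=[], y_um=[], intensity=[])
        img = render_image(gt)
        assert img.pixels.mean() == pytest.approx(spec.background_level, abs=1.0)

    def test_renoise_changes_image_but_not_truth(self):
        spec = eccentricity_preset(3.0, seed=4)
        gt = generate_mosaic(spec)
        a = render_image(gt, noise_seed=1)
        b = render_image(gt, noise_seed=2)
        assert not np.array_equal(a.pixels, b.pixels)  # reflectivity re-drawn
        c = render_image(gt, noise_seed=1)
        assert np.array_equal(a.pixels, c.pixels)

    def test_noise_free_lattice_fully_recovered(self):
        """End-to-end: rendering + detection recover every interior cone."""
        spec = SyntheticMosaicSpec(spacing_um=10.0, jitter_frac=0, dropout_frac=0,
                                   reflectivity_cv=0, background_sd=0, region_um=150.0, seed=0)
        gt = generate_mosaic(spec)
        img = render_image(gt)
        r = radius_for_eccentricity(5.0)
        det = detect_cones(to_16bit_sharpened(img), DetectionParams(radius_um=r))
        tree = cKDTree(det.xy)
        margin = 6.0
        interior = gt.cones.xy[
            (gt.cones.xy.min(axis=1) > margin) & (gt.cones.xy.max(axis=1) < 150.0 - margin)
        ]
        dist, _ = tree.query(interior)
        assert np.all(dist <= r / 2)  # recall 1.0 at matching tolerance r/2
        # and precision: no detection far from any true cone
        ttree = cKDTree(gt.cones.xy)
        ddist, _ = ttree.query(det.xy)
        assert np.all(ddist <= r / 2)


class TestPresets:
    @pytest.mark.parametrize("ecc,density", [(2.0, 20022.0), (3.0, 14946.0), (5.0, 11452.0),
                                             (7.0, 10818.0), (9.0, 10790.0)])
    def test_healthy_table_densities(self, ecc, density):
        assert eccentricity_preset(ecc).target_density_cones_per_mm2 == density

    def test_untabulated_eccentricity_interpolates_with_warning(self):
        with pytest.warns(UserWarning, match="interpolated"):
            spec = eccentricity_preset(4.0)
        assert 11452.0 < spec.target_density_cones_per_mm2 < 14946.0

    def test_pathology_density_ordering_and_range(self):
        mild = pathology_preset("mild")
        severe = pathology_preset("severe")
        assert 2461.0 <= severe.target_density_cones_per_mm2 <= 5901.0
        # expected surviving-site density orders mild above severe by construction
        eff_mild = mild.target_density_cones_per_mm2 * (1 - mild.dropout_frac)
        eff_severe = severe.target_density_cones_per_mm2 * (1 - severe.dropout_frac)
        assert eff_mild > eff_severe

    def test_pathology_analyzed_metrics_in_published_ranges(self):
        """Seed-averaged analyzed density and NND of the severe preset fall in
        the ranges reported over atrophic lesions."""
        dens, nnds = [], []
        mild_dens = []
        roi = ROISpec(2.0, "temporal", 240.0)
        params = DetectionParams(radius_um=radius_for_eccentricity(2.0))
        for seed in range(5):
            gt = generate_mosaic(pathology_preset("severe", seed=seed))
            det = detect_cones(to_16bit_sharpened(render_image(gt)), params)
            m = metrics_from_cones(det, roi)
            dens.append(m.density_cones_per_mm2)
            nnds.append(m.nnd_um)
            gtm = generate_mosaic(pathology_preset("mild", seed=seed))
            detm = detect_cones(to_16bit_sharpened(render_image(gtm)), params)
            mild_dens.append(metrics_from_cones(detm, roi).density_cones_per_mm2)
        assert 2461.0 <= np.mean(dens) <= 5901.0
        assert 8.87 <= np.mean(nnds) <= 14.71
        assert np.mean(mild_dens) > np.mean(dens)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            pathology_preset("apocalyptic")
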