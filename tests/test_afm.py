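"""AFM morphometry: flattening, noise, segmentation, measurement, the
dilation-oracle deconvolution round trip and species classification."""

import numpy as np
import pandas as pd
import pytest

from aggresense import afm
from aggresense.simulate import (
    AfmSimConfig,
    ParticleSpec,
    dilate_by_spherical_tip,
    make_rng,
    render_true_surface,
    simulate_afm_map,
)


def _tilted_plane(shape=(120, 120), coeffs=(0.5, 0.01, -0.02)):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    return coeffs[0] + coeffs[1] * rr + coeffs[2] * cc


class TestFlattening:
    def test_pure_tilted_plane_removed_to_numerical_zero(self):
        hm = afm.HeightMap(_tilted_plane(), pixel_size_nm=1.0)
        flat = afm.flatten_height_map(hm)
        assert np.max(np.abs(flat.heights)) < 1e-9

    def test_cap_height_preserved_on_tilted_background(self):
        spec = ParticleSpec("spherical_cap", height_nm=2.0, row_nm=15, col_nm=15, diameter_nm=6.0)
        cfg = AfmSimConfig(map_size=(120, 120), pixel_size_nm=0.25, particles=[spec],
                           roughness_sd_nm=0.0, tilt=(1.0, 0.01, -0.005), seed=0)
        hmap, _, _ = simulate_afm_map(cfg)
        flat = afm.flatten_height_map(hmap)
        assert flat.heights.max() == pytest.approx(2.0, rel=0.01)

    def test_idempotent_on_flat_map(self):
        rng = make_rng(1)
        z = rng.normal(0, 0.05, (80, 80))
        hm = afm.HeightMap(z, pixel_size_nm=1.0)
        once = afm.flatten_height_map(hm)
        twice = afm.flatten_height_map(once)
        np.testing.assert_allclose(twice.heights, once.heights, atol=1e-9)

    def test_overfitting_guard(self):
        hm = afm.HeightMap(np.zeros((20, 20)), pixel_size_nm=1.0)
        with pytest.raises(ValueError, match="order"):
            afm.flatten_height_map(hm, order=4)


class TestNoise:
    def test_noiseless_flat_map_zero(self):
        hm = afm.HeightMap(np.zeros((50, 50)), pixel_size_nm=1.0)
        assert afm.estimate_noise(hm) == 0.0

    def test_recovers_generating_roughness(self):
        rng = make_rng(2)
        hm = afm.HeightMap(rng.normal(0, 0.05, (256, 256)), pixel_size_nm=1.0)
        assert afm.estimate_noise(hm) == pytest.approx(0.05, abs=0.005)

    def test_particles_covering_ten_percent_do_not_bias(self):
        rng = make_rng(3)
        z = rng.normal(0, 0.05, (200, 200))
        # A block of tall pixels emulating ~10% particle coverage.
        z[20:83, 20:83] += 1.5
        hm = afm.HeightMap(z, pixel_size_nm=1.0)
        assert afm.estimate_noise(hm) == pytest.approx(0.05, rel=0.1)


class TestSegmentation:
    def test_three_disjoint_caps(self):
        specs = [
            ParticleSpec("spherical_cap", height_nm=1.5, row_nm=r, col_nm=c, diameter_nm=5.0)
            for r, c in [(15.0, 15.0), (15.0, 45.0), (45.0, 30.0)]
        ]
        cfg = AfmSimConfig(map_size=(240, 240), pixel_size_nm=0.25, particles=specs,
                           roughness_sd_nm=0.05, seed=4)
        hmap, _, _ = simulate_afm_map(cfg)
        flat = afm.flatten_height_map(hmap)
        noise = afm.estimate_noise(flat)
        _, table = afm.segment_particles(flat, noise)
        assert len(table) == 3

    def test_empty_map_zero_regions(self):
        rng = make_rng(5)
        hm = afm.HeightMap(rng.normal(0, 0.05, (100, 100)), pixel_size_nm=1.0)
        _, table = afm.segment_particles(hm, 0.05, k=5.0)
        assert len(table) == 0

    def test_degenerate_threshold_rejected(self):
        hm = afm.HeightMap(np.zeros((50, 50)), pixel_size_nm=1.0)
        with pytest.raises(ValueError, match="degenerate"):
            afm.segment_particles(hm, 0.0)

    def test_monomer_scale_particles_detected_at_experimental_roughness(self):
        """Particles >= 0.3 nm on 0.05 nm roughness (SNR ~ 10 regime): >= 95%
        of a 20-particle field is recovered."""
        rng = make_rng(6)
        specs = []
        rows = np.arange(10, 90, 18)
        cols = np.arange(10, 90, 18)
        for i, (r, c) in enumerate((r, c) for r in rows for c in cols):
            if i >= 20:
                break
            specs.append(
                ParticleSpec("spherical_cap", height_nm=0.3 + 0.1 * (i % 5),
                             row_nm=float(r), col_nm=float(c),
                             diameter_nm=2.0 + 0.4 * (i % 5))
            )
        cfg = AfmSimConfig(map_size=(200, 200), pixel_size_nm=0.5, particles=specs,
                           roughness_sd_nm=0.05, seed=6)
        hmap, truth, _ = simulate_afm_map(cfg)
        df = afm.analyze_height_map(hmap, afm.TipModel(10.0))
        assert len(df) >= 0.95 * len(truth)


class TestMeasurement:
    def test_cap_max_height_and_roundness(self):
        spec = ParticleSpec("spherical_cap", height_nm=2.0, row_nm=20, col_nm=20, diameter_nm=6.0)
        cfg = AfmSimConfig(map_size=(160, 160), pixel_size_nm=0.25, particles=[spec],
                           roughness_sd_nm=0.0, seed=0)
        hmap, _, _ = simulate_afm_map(cfg)
        df = afm.analyze_height_map(hmap, afm.TipModel(10.0))
        assert len(df) == 1
        assert df.max_height_nm[0] == pytest.approx(2.0, abs=0.02)
        assert df.aspect_ratio[0] <= 1.2

    def test_filament_length_and_aspect(self):
        spec = ParticleSpec("filament", height_nm=0.7, row_nm=250, col_nm=250,
                            length_nm=300.0, width_nm=10.0, theta=0.3)
        cfg = AfmSimConfig(map_size=(500, 500), pixel_size_nm=1.0, particles=[spec],
                           roughness_sd_nm=0.05, seed=7)
        hmap, _, _ = simulate_afm_map(cfg)
        df = afm.analyze_height_map(hmap, afm.TipModel(10.0))
        assert len(df) == 1
        assert df.length_nm[0] == pytest.approx(300.0, rel=0.1)
        assert df.aspect_ratio[0] >= 3.0


class TestDeconvolution:
    def test_exact_inversion_of_analytic_apparent_widths(self):
        """For the exact apparent profile of a cap dilated by a spherical tip
        the inversion is algebraically exact at any tip radius, and the
        correction vanishes as R -> 0 (apparent width -> true width)."""
        h, d = 1.0, 4.0
        rs = ((d / 2) ** 2 + h**2) / (2 * h)
        widths = []
        for r_tip in [10.0, 4.0, 1.0, 0.6]:
            rs_app = rs + r_tip
            fwhm = 2 * np.sqrt(rs_app * h - h**2 / 4)  # apparent width at h/2
            widths.append(fwhm)
            got, ok = afm.deconvolve_diameter(fwhm, h, afm.TipModel(r_tip))
            assert ok
            assert got == pytest.approx(d, rel=1e-9)
        true_fwhm = 2 * np.sqrt(rs * h - h**2 / 4)
        # Apparent widths shrink toward the true width as the tip sharpens.
        assert np.all(np.diff(widths) < 0) and widths[-1] > true_fwhm

    def test_tall_feature_outside_model_returns_width_with_flag(self):
        d, ok = afm.deconvolve_diameter(10.0, 25.0, afm.TipModel(10.0))
        assert d == 10.0 and not ok

    def test_round_trip_against_dilation_oracle(self):
        """simulate -> spherical-tip dilation (oracle) -> measure -> deconvolve
        recovers true base diameters within 15% across d in [1, 10] nm, R=10 nm."""
        cases = [(1.0, 0.05), (2.0, 0.1), (3.0, 0.1), (5.0, 0.25), (7.0, 0.25), (10.0, 0.25)]
        for d, px in cases:
            h = 0.3 * d
            n = int(round(max(24.0, 4 * d) / px))
            spec = ParticleSpec("spherical_cap", height_nm=h, row_nm=n * px / 2,
                                col_nm=n * px / 2, diameter_nm=d)
            cfg = AfmSimConfig(map_size=(n, n), pixel_size_nm=px, particles=[spec],
                               roughness_sd_nm=0.0, tilt=(0.2, 0.001, -0.0005), seed=0)
            hmap, _, _ = simulate_afm_map(cfg)
            row = afm.analyze_height_map(hmap, afm.TipModel(10.0)).iloc[0]
            assert row.deconvolved_diameter_nm == pytest.approx(d, rel=0.15), f"d={d}"

    def test_deconvolved_strictly_increasing_in_true_diameter(self):
        recovered = []
        for d in [1.0, 2.0, 5.0, 10.0]:
            h = 0.3 * d
            px = 0.05 if d < 2 else 0.1 if d < 5 else 0.25
            n = int(round(max(24.0, 4 * d) / px))
            spec = ParticleSpec("spherical_cap", height_nm=h, row_nm=n * px / 2,
                                col_nm=n * px / 2, diameter_nm=d)
            cfg = AfmSimConfig(map_size=(n, n), pixel_size_nm=px, particles=[spec],
                               roughness_sd_nm=0.0, seed=0)
            hmap, _, _ = simulate_afm_map(cfg)
            row = afm.analyze_height_map(hmap, afm.TipModel(10.0)).iloc[0]
            recovered.append(row.deconvolved_diameter_nm)
        assert np.all(np.diff(recovered) > 0)


class TestClassification:
    @pytest.mark.parametrize(
        "h,aspect,length,expected",
        [
            (0.4, 1.1, 8.0, "monomer"),
            (0.7, 10.0, 300.0, "protofilament"),
            (3.0, 1.2, 10.0, "higher_order"),
            (1.0, 1.0, 5.0, "oligomer"),
            (0.1, 1.0, 3.0, "unclassified"),
        ],
    )
    def test_height_and_shape_bands(self, h, aspect, length, expected):
        assert afm.classify_particle(h, aspect, length) == expected

    def test_mixed_fixture_classes_match_ground_truth(self):
        rng = make_rng(8)
        specs = []
        # Monomers, oligomers and one protofilament at realistic geometries.
        for i in range(6):
            specs.append(ParticleSpec("spherical_cap", height_nm=0.4, diameter_nm=1.2,
                                      row_nm=40.0 + 60 * i, col_nm=60.0))
        for i in range(6):
            specs.append(ParticleSpec("spherical_cap", height_nm=1.2, diameter_nm=4.0,
                                      row_nm=40.0 + 60 * i, col_nm=160.0))
        specs.append(ParticleSpec("filament", height_nm=0.7, length_nm=300.0, width_nm=10.0,
                                  row_nm=200.0, col_nm=330.0, theta=1.2))
        cfg = AfmSimConfig(map_size=(420, 420), pixel_size_nm=1.0, particles=specs,
                           roughness_sd_nm=0.05, seed=8)
        hmap, truth, _ = simulate_afm_map(cfg)
        df = afm.analyze_height_map(hmap, afm.TipModel(10.0))
        assert len(df) == len(truth)
        # Match measured particles to truth by position.
        from scipy.spatial import cKDTree

        tree = cKDTree(truth[["row_px", "col_px"]].to_numpy())
        _, idx = tree.query(df[["centroid_row", "centroid_col"]].to_numpy())
        agree = (df["class"].to_numpy() == truth.true_class.to_numpy()[idx]).mean()
        assert agree >= 0.95


class TestFractionSummary:
    def test_single_particle_quartiles_collapse(self):
        df = pd.DataFrame(
            {"max_height_nm": [1.5], "deconvolved_diameter_nm": [4.0], "class": ["oligomer"]}
        )
        s = afm.summarize_fraction(df, "20pct")
        assert s.height_quartiles == (1.5, 1.5, 1.5)

    def test_fraction_ordering_by_generating_height(self):
        rng = make_rng(9)
        def frame(mean):
            h = rng.normal(mean, 0.2, 50).clip(0.2)
            return pd.DataFrame({"max_height_nm": h, "deconvolved_diameter_nm": h * 2,
                                 "class": ["oligomer"] * 50})
        a = afm.summarize_fraction(frame(1.0), "A")
        b = afm.summarize_fraction(frame(4.0), "B")
        assert b.height_quartiles[1] > a.height_quartiles[1]

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            afm.summarize_fraction(pd.DataFrame(columns=["max_height_nm"]), "x")
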