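"""Generator-level checks: determinism, construction invariants, ground truth."""

import numpy as np
import pandas as pd
import pytest

from aggresense import simulate as sim
from aggresense.simulate import (
    AfmSimConfig,
    FretPopulation,
    FretSimConfig,
    ParticleSpec,
    SpectralGroup,
    SpectralSimConfig,
    SpotSimConfig,
    VesicleSimConfig,
)


class TestVesicleSim:
    def test_fixed_seed_bit_identical(self):
        cfg = VesicleSimConfig(n_vesicles=10, field_size=(96, 96), seed=7)
        s1, t1, _ = sim.simulate_vesicle_experiment(cfg)
        s2, t2, _ = sim.simulate_vesicle_experiment(cfg)
        for phase in s1:
            np.testing.assert_array_equal(s1[phase].data, s2[phase].data)
        pd.testing.assert_frame_equal(t1, t2)

    def test_noiseless_single_vesicle_obeys_influx_ratio_at_centroid(self):
        cfg = VesicleSimConfig(
            n_vesicles=1,
            field_size=(64, 64),
            background_noise_sd=0.0,
            true_influx_distribution={"name": "fixed", "value": 0.5},
            seed=1,
        )
        stacks, truth, _ = sim.simulate_vesicle_experiment(cfg)
        r = int(round(truth.row[0]))
        c = int(round(truth.col[0]))
        fb = stacks["background"].data[0, r, c]
        fs = stacks["sample"].data[0, r, c]
        fi = stacks["ionomycin"].data[0, r, c]
        assert (fs - fb) / (fi - fb) == pytest.approx(0.5, abs=1e-9)

    def test_zero_vesicles_gives_pure_background_and_empty_truth(self):
        cfg = VesicleSimConfig(n_vesicles=0, field_size=(32, 32), background_noise_sd=0.0)
        stacks, truth, _ = sim.simulate_vesicle_experiment(cfg)
        assert len(truth) == 0
        for phase in stacks:
            np.testing.assert_allclose(stacks[phase].data, cfg.background_level)

    def test_sampled_influx_always_in_unit_interval(self):
        rng = sim.make_rng(3)
        vals = sim.sample_influx(rng, 5000, {"name": "beta_mean_sd", "mean": 0.5, "sd": 0.25})
        assert np.all((vals >= 0) & (vals <= 1))

    def test_overpacked_field_raises(self):
        cfg = VesicleSimConfig(n_vesicles=500, field_size=(48, 48), min_separation=8.0)
        with pytest.raises(ValueError, match="could not place"):
            sim.simulate_vesicle_experiment(cfg)

    def test_truth_ids_unique(self):
        _, truth, _ = sim.simulate_vesicle_experiment(VesicleSimConfig(n_vesicles=25, seed=2))
        assert truth.vesicle_id.is_unique


class TestFretSim:
    def test_counts_are_nonnegative_integers_and_deterministic(self):
        cfg = FretSimConfig(n_bins=5000, seed=11)
        tr1, th1, _ = sim.simulate_fret_trace(cfg)
        tr2, th2, _ = sim.simulate_fret_trace(cfg)
        np.testing.assert_array_equal(tr1.donor, tr2.donor)
        np.testing.assert_array_equal(tr1.acceptor, tr2.acceptor)
        pd.testing.assert_frame_equal(th1, th2)
        assert tr1.donor.dtype.kind == "i" and tr1.donor.min() >= 0

    def test_zero_burst_rate_gives_pure_background(self):
        cfg = FretSimConfig(n_bins=50_000, burst_rate_hz=0.0, seed=5)
        trace, truth, _ = sim.simulate_fret_trace(cfg)
        assert len(truth) == 0
        # Poisson(0.5) background: mean within 5 sd of the generating rate.
        for channel in (trace.donor, trace.acceptor):
            assert channel.mean() == pytest.approx(0.5, abs=5 * np.sqrt(0.5 / 50_000))

    def test_symmetric_population_truth_e_is_half(self):
        cfg = FretSimConfig(populations=[FretPopulation(50.0, 50.0, 1.0)])
        assert cfg.populations[0].true_e == 0.5

    def test_two_population_truth_is_bimodal_at_generating_e(self):
        cfg = FretSimConfig(
            n_bins=100_000,
            burst_rate_hz=20.0,
            populations=[FretPopulation(80, 20, 0.5), FretPopulation(40, 60, 0.5)],
            seed=8,
        )
        _, truth, _ = sim.simulate_fret_trace(cfg)
        observed = sorted(truth.true_e.unique())
        assert observed == [pytest.approx(0.2), pytest.approx(0.6)]
        counts = truth.groupby("true_e").size()
        assert (counts > 0.3 * len(truth)).all()

    def test_weights_must_sum_to_one(self):
        cfg = FretSimConfig(populations=[FretPopulation(50, 50, 0.7)])
        with pytest.raises(ValueError, match="sum to 1"):
            cfg.validate()


class TestAfmSim:
    def test_dilation_preserves_peak_of_isolated_cap(self):
        spec = ParticleSpec("spherical_cap", height_nm=2.0, row_nm=15, col_nm=15, diameter_nm=6.0)
        cfg = AfmSimConfig(map_size=(120, 120), pixel_size_nm=0.25, particles=[spec],
                           roughness_sd_nm=0.0, seed=0)
        true = sim.render_true_surface(cfg)
        dilated = sim.dilate_by_spherical_tip(true, 10.0, 0.25)
        assert dilated.max() == pytest.approx(true.max(), abs=1e-9)
        # Dilation broadens: the apparent support strictly contains the true one.
        assert (dilated > 0.01).sum() > (true > 0.01).sum()

    def test_flat_map_roughness_matches_generating_sd(self):
        cfg = AfmSimConfig(map_size=(300, 300), pixel_size_nm=1.0, particles=[],
                           roughness_sd_nm=0.05, seed=9)
        hmap, _, _ = sim.simulate_afm_map(cfg)
        rms = np.sqrt(np.mean((hmap.heights - hmap.heights.mean()) ** 2))
        assert rms == pytest.approx(0.05, rel=0.05)

    def test_filament_truth_class_is_protofilament(self):
        spec = ParticleSpec("filament", height_nm=0.7, row_nm=250, col_nm=250,
                            length_nm=300.0, width_nm=10.0)
        assert spec.true_class == "protofilament"

    def test_nonpositive_tip_radius_rejected(self):
        with pytest.raises(ValueError, match="tip_radius"):
            sim.dilate_by_spherical_tip(np.zeros((10, 10)), 0.0, 1.0)
        cfg = AfmSimConfig(tip_radius_nm=-1.0)
        with pytest.raises(ValueError):
            cfg.validate()

    def test_seed_reproducibility(self):
        spec = ParticleSpec("spherical_cap", height_nm=1.0, row_nm=20, col_nm=20, diameter_nm=4.0)
        cfg = AfmSimConfig(map_size=(160, 160), pixel_size_nm=0.25, particles=[spec], seed=12)
        h1, _, _ = sim.simulate_afm_map(cfg)
        h2, _, _ = sim.simulate_afm_map(cfg)
        np.testing.assert_array_equal(h1.heights, h2.heights)


class TestSpectralSim:
    def test_zero_spectral_sd_centroids_equal_true_mean(self):
        cfg = SpectralSimConfig(
            groups=[SpectralGroup("g", 5, 635.0)],
            within_aggregate_sd_nm=0.0,
            aggregate_offset_sd_nm=0.0,
            seed=2,
        )
        locs, truth, _ = sim.simulate_spectral_localizations(cfg)
        assert np.allclose(locs.spectral_centroid_nm, 635.0)
        assert np.allclose(truth.true_mean_emission_nm, 635.0)

    def test_group_mean_offset_constructed_as_ten_nm(self):
        cfg = SpectralSimConfig(
            groups=[SpectralGroup("a", 4, 630.0), SpectralGroup("b", 4, 640.0)], seed=3
        )
        _, truth, _ = sim.simulate_spectral_localizations(cfg)
        means = truth.groupby("group").group_mean_emission_nm.first()
        assert means["b"] - means["a"] == pytest.approx(10.0)

    def test_per_aggregate_sample_means_concentrate_around_truth(self):
        cfg = SpectralSimConfig(
            groups=[SpectralGroup("g", 40, 635.0)],
            locs_per_aggregate_mean=50.0,
            aggregate_offset_sd_nm=0.0,
            min_separation_nm=1500.0,
            seed=6,
        )
        locs, truth, _ = sim.simulate_spectral_localizations(cfg)
        # Normal theory: the 50-event sample mean is within 3 sd/sqrt(n) of the
        # aggregate's true mean in >= 99% of aggregates.
        from scipy.spatial import cKDTree

        tree = cKDTree(truth[["x_nm", "y_nm"]].to_numpy())
        _, idx = tree.query(locs[["x_nm", "y_nm"]].to_numpy())
        locs = locs.assign(aggregate_id=truth.aggregate_id.to_numpy()[idx])
        ok = 0
        for agg_id, grp in locs.groupby("aggregate_id"):
            true_mean = truth.loc[truth.aggregate_id == agg_id, "true_mean_emission_nm"].iloc[0]
            bound = 3 * cfg.within_aggregate_sd_nm / np.sqrt(len(grp))
            ok += abs(grp.spectral_centroid_nm.mean() - true_mean) <= bound
        assert ok / len(truth) >= 0.9

    def test_band_violation_rejected(self):
        cfg = SpectralSimConfig(groups=[SpectralGroup("g", 3, 900.0)])
        with pytest.raises(ValueError, match="detection band"):
            cfg.validate()


class TestSpotSim:
    def test_truth_count_and_determinism(self):
        cfg = SpotSimConfig(n_spots=7, seed=4)
        img1, truth, _ = sim.simulate_spot_image(cfg)
        img2, _, _ = sim.simulate_spot_image(cfg)
        np.testing.assert_array_equal(img1, img2)
        assert len(truth) == 7
        assert truth.spot_id.is_unique

    def test_zero_spots_empty_truth(self):
        _, truth, _ = sim.simulate_spot_image(SpotSimConfig(n_spots=0, seed=1))
        assert len(truth) == 0

    def test_spots_honour_min_separation(self):
        cfg = SpotSimConfig(n_spots=20, field_size=(128, 128), min_separation=9.0, seed=5)
        _, truth, _ = sim.simulate_spot_image(cfg)
        pts = truth[["row", "col"]].to_numpy()
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        assert np.sqrt(d2.min()) >= 9.0
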