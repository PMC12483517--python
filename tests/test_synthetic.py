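"""Ground-truth generators: determinism, construction exactness, oracles."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon

from cellmech import synthetic as syn
from cellmech import tracks as tm


class TestTrackGenerator:
    def test_seed_determinism(self):
        cfg = syn.TrackSimConfig(n_tracks=10, n_frames=20, seed=5)
        a = syn.generate_tracks(cfg)
        b = syn.generate_tracks(syn.TrackSimConfig(n_tracks=10, n_frames=20, seed=5))
        pd.testing.assert_frame_equal(a, b)
        c = syn.generate_tracks(syn.TrackSimConfig(n_tracks=10, n_frames=20, seed=6))
        assert not a["x_um"].equals(c["x_um"])

    def test_pure_drift_moves_exactly_along_gradient(self):
        cfg = syn.TrackSimConfig(n_tracks=20, n_frames=30, drift_bias=1.0,
                                 speed_sd=0.0, seed=1)
        m = tm.track_metrics_table(syn.generate_tracks(cfg))
        assert (m["fmi_parallel"] == 1.0).all()

    def test_no_drift_mean_fmi_near_zero(self):
        cfg = syn.TrackSimConfig(n_tracks=500, drift_bias=0.0, seed=2)
        m = tm.track_metrics_table(syn.generate_tracks(cfg))
        se = m["fmi_parallel"].std() / np.sqrt(len(m))
        assert abs(m["fmi_parallel"].mean()) < 2 * se

    def test_mean_fmi_matches_independent_monte_carlo(self):
        """Package output vs a brute-force re-simulation of the same
        heading update rule, written independently track-by-track."""
        cfg = syn.TrackSimConfig(n_tracks=500, drift_bias=0.5, persistence=0.7,
                                 speed_sd=0.0, seed=11)
        m = tm.track_metrics_table(syn.generate_tracks(cfg))

        rng = np.random.default_rng(99)
        p, b, nf = 0.7, 0.5, cfg.n_frames
        fmis = []
        for _ in range(4000):
            ang = rng.uniform(0, 2 * np.pi)
            h = np.array([np.cos(ang), np.sin(ang)])
            pos = np.zeros(2)
            path = 0.0
            for _ in range(nf - 1):
                a = rng.uniform(0, 2 * np.pi)
                v = (1 - b) * (p * h + (1 - p) * np.array([np.cos(a), np.sin(a)]))
                v = v + b * np.array([0.0, 1.0])
                h = v / np.linalg.norm(v)
                pos = pos + h
                path += 1.0
            fmis.append(pos[1] / path)
        assert m["fmi_parallel"].mean() == pytest.approx(np.mean(fmis), abs=0.05)

    def test_recovered_speed_matches_configured(self):
        cfg = syn.TrackSimConfig(n_tracks=20, speed_mean=0.02, speed_sd=0.0, seed=3)
        m = tm.track_metrics_table(syn.generate_tracks(cfg))
        assert m["mean_speed_um_s"].to_numpy() == pytest.approx(0.02)

    def test_arena_reflection_keeps_tracks_inside(self):
        cfg = syn.TrackSimConfig(n_tracks=50, n_frames=60, drift_bias=1.0,
                                 speed_mean=0.05, arena=(100.0, 100.0), seed=4)
        df = syn.generate_tracks(cfg)
        assert df["x_um"].between(0, 100).all()
        assert df["y_um"].between(0, 100).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(syn.ConfigError):
            syn.generate_tracks(syn.TrackSimConfig(n_frames=1))
        with pytest.raises(syn.ConfigError):
            syn.generate_tracks(syn.TrackSimConfig(dt=0.0))
        with pytest.raises(syn.ConfigError):
            syn.generate_tracks(syn.TrackSimConfig(drift_bias=1.5))


class TestPillarGenerator:
    def test_zero_field_zero_noise_is_ideal_lattice(self):
        cfg = syn.PillarSimConfig(n_rows=5, n_cols=5)
        obs, truth = syn.generate_pillar_data(cfg)
        assert np.allclose(obs[["x_um", "y_um"]], truth[["ideal_x_um", "ideal_y_um"]])
        assert obs["is_reference"].all()

    def test_single_displaced_pillar_exact(self):
        cfg = syn.PillarSimConfig(n_rows=6, n_cols=6,
                                  displacement_field={(2, 3): (50.0, 0.0)})
        obs, truth = syn.generate_pillar_data(cfg)
        row = obs[(obs.i == 2) & (obs.j == 3)].iloc[0]
        ideal = truth[(truth.i == 2) & (truth.j == 3)].iloc[0]
        assert (row.x_um - ideal.ideal_x_um) * 1e3 == pytest.approx(50.0)
        assert (row.y_um - ideal.ideal_y_um) * 1e3 == pytest.approx(0.0)
        assert not row.is_reference

    def test_reference_noise_rms_matches_resampling(self):
        cfg = syn.PillarSimConfig(n_rows=20, n_cols=20, localisation_noise_sd=5.0, seed=8)
        obs, truth = syn.generate_pillar_data(cfg)
        dev = (obs[["x_um", "y_um"]].to_numpy()
               - truth[["ideal_x_um", "ideal_y_um"]].to_numpy()) * 1e3
        rms_x = np.sqrt((dev[:, 0] ** 2).mean())
        rms_y = np.sqrt((dev[:, 1] ** 2).mean())
        assert rms_x == pytest.approx(5.0, rel=0.10)
        assert rms_y == pytest.approx(5.0, rel=0.10)

    def test_displacement_outside_lattice_rejected(self):
        with pytest.raises(syn.ConfigError):
            syn.generate_pillar_data(
                syn.PillarSimConfig(n_rows=4, n_cols=4,
                                    displacement_field={(9, 9): (10.0, 0.0)})
            )

    def test_image_mode_renders_spots(self):
        cfg = syn.PillarSimConfig(n_rows=4, n_cols=4, render_mode="image", seed=1)
        img, truth = syn.generate_pillar_data(cfg)
        assert img.ndim == 2
        assert img.max() > cfg.background + 0.5 * cfg.peak_intensity
        assert len(truth) == 16


class TestAdhesionGenerator:
    def make_config(self, foci, **kw):
        cell = Polygon([(2, 2), (23, 2), (23, 23), (2, 23)])
        return syn.AdhesionSimConfig(shape=(256, 256), px_size=0.1,
                                     cell_polygon=cell, foci=foci, **kw)

    def test_one_um2_focus_truth_area(self):
        r = np.sqrt(1.0 / np.pi)
        cfg = self.make_config([syn.FocusSpec((12.0, 12.0), (r, r))])
        _, truth = syn.generate_adhesion_image(cfg)
        assert truth["area_um2"].iloc[0] == pytest.approx(1.0)
        assert truth["pixel_area_um2"].iloc[0] == pytest.approx(1.0, abs=0.05)
        assert not truth["below_min_size"].iloc[0]

    def test_small_focus_flagged_below_min_size(self):
        r = np.sqrt(0.3 / np.pi)
        cfg = self.make_config([syn.FocusSpec((12.0, 12.0), (r, r))])
        _, truth = syn.generate_adhesion_image(cfg)
        assert truth["below_min_size"].iloc[0]

    def test_truth_edge_distances_match_geometric_oracle(self):
        """Analytic truth distances vs dense boundary-point sampling."""
        cell = Polygon([(2, 2), (23, 2), (23, 23), (2, 23)])
        r = 0.5
        foci = [syn.FocusSpec((2.0 + r + d, 12.5), (r, r)) for d in np.arange(1.0, 10.0)]
        cfg = syn.AdhesionSimConfig(shape=(256, 256), px_size=0.1,
                                    cell_polygon=cell, foci=foci)
        _, truth = syn.generate_adhesion_image(cfg)
        for d, (_, row) in zip(np.arange(1.0, 10.0), truth.iterrows()):
            theta = np.linspace(0, 2 * np.pi, 720)
            pts = np.column_stack([row.x_um + r * np.cos(theta), row.y_um + r * np.sin(theta)])
            oracle = min(cell.exterior.distance(Point(p)) for p in pts)
            assert row.min_edge_distance_um == pytest.approx(oracle, abs=1e-3)
            assert row.min_edge_distance_um == pytest.approx(d, abs=1e-3)

    def test_focus_outside_image_rejected(self):
        cell = Polygon([(2, 2), (23, 2), (23, 23), (2, 23)])
        big = syn.FocusSpec((3.0, 3.0), (4.0, 4.0))
        with pytest.raises(syn.ConfigError):
            syn.generate_adhesion_image(
                syn.AdhesionSimConfig(shape=(64, 64), px_size=0.1,
                                      cell_polygon=cell, foci=[big])
            )

    def test_centroid_outside_cell_rejected(self):
        cfg = self.make_config([syn.FocusSpec((0.5, 0.5), (0.3, 0.3))])
        with pytest.raises(syn.ConfigError):
            syn.generate_adhesion_image(cfg)


class TestColocGenerator:
    def test_disjoint_at_zero_fraction(self):
        ch1, ch2, truth = syn.generate_coloc_pair(syn.ColocSimConfig(colocalised_fraction=0.0))
        assert truth["colocalised_fraction"] == 0.0
        assert not np.any((ch1 > truth["threshold1"]) & (ch2 > truth["threshold2"]))

    def test_fully_nested_at_one(self):
        ch1, ch2, truth = syn.generate_coloc_pair(syn.ColocSimConfig(colocalised_fraction=1.0))
        above1 = ch1 > truth["threshold1"]
        assert truth["colocalised_fraction"] == 1.0
        assert np.all(ch2[above1] > truth["threshold2"])

    def test_quarter_fraction_exact_by_pixel_count(self):
        ch1, ch2, truth = syn.generate_coloc_pair(
            syn.ColocSimConfig(colocalised_fraction=0.25, n_signal_px=400)
        )
        above1 = ch1 > truth["threshold1"]
        both = above1 & (ch2 > truth["threshold2"])
        assert ch1[both].sum() / ch1[above1].sum() == 0.25
        assert truth["colocalised_fraction"] == 0.25


class TestTurnoverGenerator:
    def test_static_when_no_events(self):
        stack, truth = syn.generate_fa_timeseries(
            syn.TurnoverSimConfig(n_frames=5, n_initial=20, disappear_prob=0.0,
                                  appear_rate=0.0, seed=1)
        )
        for t in range(1, 5):
            assert np.array_equal(stack[t], stack[0])
        assert (truth["death_frame"] == -1).all()

    def test_complete_replacement_every_frame(self):
        stack, truth = syn.generate_fa_timeseries(
            syn.TurnoverSimConfig(n_frames=4, n_initial=10, disappear_prob=1.0,
                                  appear_rate=10.0, shape=(128, 128), seed=2)
        )
        for t in range(3):
            overlap = (stack[t] > 0) & (stack[t + 1] > 0)
            assert not overlap.any()

    def test_empirical_disappearance_rate_in_binomial_ci(self):
        cfg = syn.TurnoverSimConfig(n_frames=20, n_initial=200, disappear_prob=0.2,
                                    appear_rate=40.0, shape=(512, 512), site_pitch_px=10,
                                    seed=3)
        _, truth = syn.generate_fa_timeseries(cfg)
        trials = deaths = 0
        births = truth["birth_frame"].to_numpy()
        deathf = truth["death_frame"].to_numpy()
        for t in range(1, cfg.n_frames):
            at_risk = ((births <= t - 1) & ((deathf == -1) | (deathf >= t))).sum()
            died = (deathf == t).sum()
            trials += at_risk
            deaths += died
        p_hat = deaths / trials
        se = np.sqrt(0.2 * 0.8 / trials)
        assert abs(p_hat - 0.2) < 3 * se
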