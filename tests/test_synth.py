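"""Tests of the synthetic-data generators (rendering sums, determinism,
scripted ground truth, analytic profiles)."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from transcytokit.kinetics import tubule_fwhm_nm
from transcytokit.synth import (
    EventScript,
    PunctaScene,
    TimecourseTruth,
    draw_event_scripts,
    gen_event_movie,
    gen_pla_stack,
    gen_transwell_timecourse,
    gen_tubule_stack,
    default_kinetics_config,
)
from transcytokit.synth.events import _radius_beta_params, _sample_radii, _stage_frames


class TestPunctaGenerator:
    def test_zero_puncta_is_background_plus_nothing(self):
        sc = PunctaScene(0, shape=(16, 64, 64), shot_noise=False, read_noise_sd=0.0)
        stack, truth = gen_pla_stack(sc)
        assert np.all(stack == sc.background_au)
        assert len(truth) == 0

    def test_noise_free_rendering_sum_equals_scripted_intensities(self):
        sc = PunctaScene(
            5, shape=(16, 128, 128), shot_noise=False, read_noise_sd=0.0, min_separation_um=2.0
        )
        stack, truth = gen_pla_stack(sc)
        rendered = stack.sum() - sc.background_au * stack.size
        assert rendered == pytest.approx(truth.intensity_au.sum(), rel=1e-9)

    def test_noise_free_maxima_at_scripted_centers(self):
        sc = PunctaScene(
            5, shape=(16, 128, 128), shot_noise=False, read_noise_sd=0.0, min_separation_um=3.0
        )
        stack, truth = gen_pla_stack(sc)
        neigh = ndimage.maximum_filter(stack, size=3)
        peaks = np.argwhere((stack == neigh) & (stack > sc.background_au + 1.0))
        vz, vy, vx = sc.voxel_size_um
        centers_vox = truth[["z_um", "y_um", "x_um"]].to_numpy() / [vz, vy, vx]
        # every scripted center has a local maximum at the nearest voxel
        found = 0
        for c in centers_vox:
            d = np.abs(peaks - c).max(axis=1)
            found += bool((d <= 1.0).any())
        assert found == 5

    def test_same_seed_bit_identical(self):
        sc = PunctaScene(10, shape=(16, 96, 96), crosstalk_au=20.0, seed=7)
        a, ta = gen_pla_stack(sc)
        b, tb = gen_pla_stack(sc)
        assert np.array_equal(a, b)
        pd.testing.assert_frame_equal(ta, tb)

    def test_stack_too_small_for_psf_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            gen_pla_stack(PunctaScene(1, shape=(3, 10, 10)))


class TestTubuleGenerator:
    def test_fwhm_matches_diameter_with_negligible_psf(self):
        stack, truth = gen_tubule_stack(
            100.0, psf_sigma_nm=1e-9, shot_noise=False, read_noise_sd=0.0, seed=3
        )
        assert tubule_fwhm_nm(stack, truth["voxel_nm"]) == pytest.approx(100.0, abs=6.0)

    def test_zero_diameter_forbidden(self):
        with pytest.raises(ValueError):
            gen_tubule_stack(0.0)

    def test_two_parallel_tubules_resolved(self):
        sep = 600.0
        stack, truth = gen_tubule_stack(
            100.0, n_tubules=2, separation_nm=sep, shot_noise=False, read_noise_sd=0.0, seed=1
        )
        assert len(truth["axes_zx_nm"]) == 2
        z_best = int(np.argmax(stack.sum(axis=(1, 2))))
        profile = stack[z_best].mean(axis=0)
        # two ridge lines: peaks at the scripted x positions
        x0, x1 = truth["axes_zx_nm"][0][1], truth["axes_zx_nm"][1][1]
        assert abs(x1 - x0) == pytest.approx(sep, abs=truth["voxel_nm"])
        for x in (x0, x1):
            i = int(round(x / truth["voxel_nm"]))
            assert profile[i] > 0.5 * profile.max()
        trough = profile[int(round((x0 + x1) / 2 / truth["voxel_nm"]))]
        assert trough < 0.2 * profile.max()

    def test_determinism(self):
        a, _ = gen_tubule_stack(100.0, seed=5)
        b, _ = gen_tubule_stack(100.0, seed=5)
        assert np.array_equal(a, b)


class TestTimecourseGenerator:
    def test_zero_permeability_zero_mass(self):
        df = gen_transwell_timecourse(TimecourseTruth(0.0), seed=1)
        assert np.all(df.mass_ug.to_numpy() == 0.0)

    def test_scripted_slope_arithmetic(self):
        # P = 19.6 nm/s, C0 = 100 ug/ml, A = 1.12 cm^2 -> dQ/dt = 2.195e-4 ug/s
        truth = TimecourseTruth(19.6)
        df = gen_transwell_timecourse(truth, seed=0)
        slope = np.polyfit(df.time_s, df.mass_ug, 1)[0]
        assert slope == pytest.approx(2.195e-4, rel=1e-3)

    def test_times_must_increase(self):
        with pytest.raises(ValueError):
            TimecourseTruth(1.0, times_s=np.array([0.0, 10.0, 10.0]))


class TestEventScripts:
    def test_fission_is_clustering_plus_tubulation(self):
        sc = EventScript(3, 2, 10, 2, 2.0, 1.8, 10.0, 10.0, frame_interval_s=5.0)
        assert sc.tau_fission_s == sc.tau_clustering_s + sc.tau_tubulation_s
        assert sc.tau_clustering_s == 10.0
        assert sc.tau_tubulation_s == 50.0

    def test_default_fixture_scripts_250_complete_events(self):
        cfg = default_kinetics_config()
        scripts = draw_event_scripts(cfg, seed=0)
        assert len(scripts) == 250

    def test_stage_durations_positive_and_within_movie(self):
        cfg = default_kinetics_config()
        scripts = draw_event_scripts(cfg, seed=3)
        for sc in scripts:
            assert min(sc.clustering_frames, sc.tubulation_frames, sc.crossing_frames) >= 1
            assert sc.birth_frame + sc.lifespan_frames < cfg.n_frames
            # footprint stays inside the field of view
            assert sc.radius_um < sc.x_um < cfg.field_um[1] - sc.radius_um
            assert sc.radius_um < sc.y_um < cfg.field_um[0] - sc.radius_um

    def test_stage_frame_draws_match_scripted_means(self):
        rng = np.random.default_rng(12)
        dt = 8.2
        for mean_s in (13.5, 96.5, 15.0):
            k = _stage_frames(mean_s, dt, 200_000, rng)
            assert k.min() >= 1
            assert k.mean() * dt == pytest.approx(mean_s, rel=0.01)

    def test_radius_distribution_moment_match(self):
        cfg = default_kinetics_config()
        a, b = _radius_beta_params(cfg.mean_radius_um, cfg.mean_area_um2 / math.pi, *cfg.radius_bounds_um)
        assert a > 0 and b > 0
        rng = np.random.default_rng(5)
        r = _sample_radii(cfg, 200_000, rng)
        assert r.mean() == pytest.approx(cfg.mean_radius_um, rel=0.01)
        assert (math.pi * r**2).mean() == pytest.approx(cfg.mean_area_um2, rel=0.015)
        assert r.min() >= cfg.radius_bounds_um[0] and r.max() <= cfg.radius_bounds_um[1]


class TestEventMovie:
    def small_cfg(self, **kw):
        return default_kinetics_config(
            n_events=1,
            duration_s=600.0,
            field_um=(26.0, 26.0),
            site_spacing_um=12.0,
            **kw,
        )

    def test_zero_events_pure_background(self):
        cfg = self.small_cfg()
        movie, truth = gen_event_movie([], cfg, seed=2)
        assert len(truth) == 0
        # Poisson background only: everything near the background level
        assert abs(float(movie.data.mean()) - cfg.background_au) < 1.0
        assert movie.data.max() < cfg.background_au + 60

    def test_single_event_truth_invariant(self):
        cfg = self.small_cfg()
        sc = EventScript(5, 2, 12, 2, 2.5, 1.8, 13.0, 13.0, cfg.frame_interval_s)
        movie, truth = gen_event_movie([sc], cfg, seed=4)
        row = truth.iloc[0]
        assert row.tau_fission_s == row.tau_clustering_s + row.tau_tubulation_s
        assert row.max_area_um2 == pytest.approx(math.pi * 2.5**2)

    def test_determinism(self):
        cfg = self.small_cfg()
        sc = EventScript(5, 2, 8, 2, 2.0, 1.8, 13.0, 13.0, cfg.frame_interval_s)
        a, _ = gen_event_movie([sc], cfg, seed=9)
        b, _ = gen_event_movie([sc], cfg, seed=9)
        assert np.array_equal(a.data, b.data)

    def test_concurrent_overlapping_events_flagged(self):
        cfg = self.small_cfg()
        s1 = EventScript(5, 2, 8, 2, 3.0, 1.8, 13.0, 13.0, cfg.frame_interval_s)
        s2 = EventScript(6, 2, 8, 2, 3.0, 1.8, 15.0, 13.0, cfg.frame_interval_s)  # 2 um apart
        _, truth = gen_event_movie([s1, s2], cfg, seed=0)
        assert truth.overlaps.all()
        s3 = EventScript(40, 2, 8, 2, 3.0, 1.8, 15.0, 13.0, cfg.frame_interval_s)  # later
        _, truth = gen_event_movie([s1, s3], cfg, seed=0)
        assert not truth.overlaps.any()
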