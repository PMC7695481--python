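"""Tests of the PLA puncta-quantification pipeline.

Single-linkage grouping is cross-checked against an independent union-find
clustering; detection quality is checked against generator ground truth.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from transcytokit import pla
from transcytokit.synth import PunctaScene, gen_pla_stack


class TestDenoise:
    def test_sigma_zero_is_identity(self):
        rng = np.random.default_rng(0)
        s = rng.random((32, 32))
        assert np.array_equal(pla.denoise_slice(s, 0.0), s)

    def test_impulse_response_preserves_sum(self):
        s = np.zeros((41, 41))
        s[20, 20] = 7.0
        out = pla.denoise_slice(s, 1.5)
        assert out.sum() == pytest.approx(7.0, abs=1e-6)
        assert out[20, 20] < 7.0

    def test_smoothing_reduces_white_noise_variance(self):
        rng = np.random.default_rng(1)
        s = rng.normal(0, 1, (128, 128))
        assert pla.denoise_slice(s, 1.0).var() < s.var()


class TestRemoveBackground:
    def test_constant_slice_maps_to_zeros(self):
        s = np.full((64, 64), 37.0)
        assert np.allclose(pla.remove_background(s, 15), 0.0)

    def test_window_one_is_identically_zero(self):
        rng = np.random.default_rng(2)
        s = rng.random((32, 32))
        assert np.allclose(pla.remove_background(s, 1), 0.0)

    def test_punctum_survives_broad_gradient(self):
        yy, xx = np.mgrid[0:128, 0:128]
        gradient = 0.5 * xx  # large-scale feature
        punctum = 100.0 * np.exp(-((yy - 64) ** 2 + (xx - 64) ** 2) / (2 * 1.5**2))
        out = pla.remove_background(gradient + punctum, 31)
        # gradient residual well below the punctum peak
        far = out[:40, :40]
        assert np.abs(far).max() < 0.05 * out[64, 64]
        assert out[64, 64] > 0.8 * punctum.max()

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            pla.remove_background(np.zeros((8, 8)), 4)


class TestFindMaxima:
    def test_blank_slice_empty(self):
        assert pla.find_maxima(np.zeros((32, 32)), 3, 0.5).shape == (0, 3)

    def test_two_separated_gaussians_found(self):
        yy, xx = np.mgrid[0:64, 0:64]
        s = 10 * np.exp(-((yy - 20) ** 2 + (xx - 20) ** 2) / 4.0)
        s += 8 * np.exp(-((yy - 45) ** 2 + (xx - 45) ** 2) / 4.0)
        found = pla.find_maxima(s, 5, 1.0)
        assert found.shape[0] == 2
        pos = {tuple(map(int, row[:2])) for row in found}
        assert pos == {(20, 20), (45, 45)}

    def test_equal_maxima_within_separation_keep_one(self):
        s = np.zeros((32, 32))
        s[10, 10] = 5.0
        s[10, 12] = 5.0
        found = pla.find_maxima(s, 4, 1.0)
        assert found.shape[0] == 1
        # tie broken toward the lowest row-major index
        assert tuple(map(int, found[0, :2])) == (10, 10)

    def test_greedy_suppression_matches_brute_force(self):
        """Independent oracle: exhaustive brightest-first suppression."""
        rng = np.random.default_rng(3)
        s = np.zeros((48, 48))
        pts = rng.integers(4, 44, size=(15, 2))
        for k, (y, x) in enumerate(pts):
            s[y, x] = 5.0 + k * 0.1
        min_sep = 6
        found = pla.find_maxima(s, min_sep, 1.0)

        # oracle on strict local maxima of the same image
        from scipy import ndimage

        fp = np.ones((3, 3), bool)
        fp[1, 1] = False
        cand = np.argwhere((s > ndimage.maximum_filter(s, footprint=fp)) & (s > 1.0))
        vals = s[cand[:, 0], cand[:, 1]]
        order = np.lexsort((cand[:, 0] * 48 + cand[:, 1], -vals))
        kept = []
        for i in order:
            if all(np.sum((cand[i] - cand[j]) ** 2) >= min_sep**2 for j in kept):
                kept.append(i)
        expected = {tuple(cand[i]) for i in kept}
        assert {tuple(map(int, r[:2])) for r in found} == expected


def _maxima_frame(points_um, intensities=None):
    points_um = np.asarray(points_um, dtype=float)
    if intensities is None:
        intensities = np.ones(len(points_um))
    return pd.DataFrame(
        {
            "z_um": points_um[:, 0],
            "y_um": points_um[:, 1],
            "x_um": points_um[:, 2],
            "intensity": intensities,
        }
    )


class TestLinkZ:
    def test_column_of_maxima_is_one_punctum(self):
        m = _maxima_frame([[0.0, 5.0, 5.0], [0.3, 5.0, 5.0], [0.6, 5.0, 5.0]], [1.0, 3.0, 1.0])
        puncta = pla.link_z(m, 0.3)
        assert len(puncta) == 1
        assert puncta[0].n_maxima == 3
        assert puncta[0].integrated_intensity == pytest.approx(5.0)

    def test_two_columns_beyond_cutoff_stay_separate(self):
        m = _maxima_frame([[0.0, 5.0, 5.0], [0.3, 5.0, 5.0], [0.0, 5.0, 5.6], [0.3, 5.0, 5.6]])
        assert len(pla.link_z(m, 0.3)) == 2

    def test_single_linkage_chains_through_intermediates(self):
        # chain spacing just under the cutoff spans both columns -> 1 punctum
        m = _maxima_frame(
            [[0.0, 5.0, 5.0], [0.0, 5.0, 5.25], [0.0, 5.0, 5.5], [0.3, 5.0, 5.0], [0.3, 5.0, 5.5]]
        )
        assert len(pla.link_z(m, 0.3)) == 1

    def test_matches_union_find_oracle(self):
        """Single linkage at a distance cutoff equals union-find on all pairs."""
        rng = np.random.default_rng(7)
        pts = np.column_stack(
            [rng.uniform(0, 2, 20), rng.uniform(0, 5, 20), rng.uniform(0, 5, 20)]
        )
        cutoff = 0.8
        puncta = pla.link_z(_maxima_frame(pts), cutoff)

        parent = list(range(20))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i, j in itertools.combinations(range(20), 2):
            if np.linalg.norm(pts[i, 1:] - pts[j, 1:]) < cutoff:
                parent[find(i)] = find(j)
        n_components = len({find(i) for i in range(20)})
        assert len(puncta) == n_components


class TestNormalizationAndSummary:
    def test_normalize_linearity_and_zero(self):
        p = pla.Punctum((0, 0, 0), 10.0, 2)
        assert pla.normalize_intensity(p, 0.003) == pytest.approx(10.0 / 0.003)
        p2 = pla.Punctum((0, 0, 0), 20.0, 2)
        assert pla.normalize_intensity(p2, 0.003) == pytest.approx(2 * 10.0 / 0.003)
        with pytest.raises(ValueError):
            pla.Punctum((0, 0, 0), 0.0, 1)

    def test_sixty_puncta_three_cells(self):
        puncta = [pla.Punctum((0, 0, 0), 1.0, 1) for _ in range(60)]
        s = pla.summarize(puncta, 3, 0.003)
        assert s.events_per_cell == pytest.approx(20.0)

    def test_compare_identical_is_zero_and_fluctuation_band(self):
        a = pla.summarize([pla.Punctum((0, 0, 0), 1.0, 1)] * 30, 3, 1.0)
        out = pla.compare(a, a)
        assert out["deviation_events_per_cell"] == 0.0
        assert out["physiological_fluctuation"]
        b = pla.summarize([pla.Punctum((0, 0, 0), 1.0, 1)] * 60, 3, 1.0)
        out = pla.compare(b, a)
        assert out["deviation_events_per_cell"] == pytest.approx(10.0)
        assert not out["physiological_fluctuation"]
        assert out["ratio_events"] == pytest.approx(2.0)


class TestFullPipeline:
    def test_recall_precision_on_default_scene(self):
        """Recall and precision >= 0.95 at SNR >= 5, separation >= 3 sigma."""
        sc = PunctaScene(n_puncta=120, crosstalk_au=30.0, seed=21)
        stack, truth = gen_pla_stack(sc)
        puncta, _ = pla.quantify_stack(stack, sc.voxel_size_um, n_cells=4)
        tp, fp, fn = pla.match_to_truth(puncta, truth)
        assert tp / (tp + fn) >= 0.95
        assert tp / (tp + fp) >= 0.95

    def test_counts_invariant_signal_linear_under_intensity_scaling(self):
        sc = PunctaScene(n_puncta=40, seed=5)
        stack, _ = gen_pla_stack(sc)
        p1, s1 = pla.quantify_stack(stack, sc.voxel_size_um, n_cells=2)
        p2, s2 = pla.quantify_stack(3.0 * stack, sc.voxel_size_um, n_cells=2)
        assert s1.n_puncta == s2.n_puncta
        assert s2.signal_per_cell == pytest.approx(3.0 * s1.signal_per_cell, rel=0.02)

    def test_scripted_density_ratio_recovered(self):
        dense = PunctaScene(n_puncta=150, seed=31)
        sparse = PunctaScene(n_puncta=15, seed=32)
        summaries = []
        for sc in (dense, sparse):
            stack, _ = gen_pla_stack(sc)
            _, summ = pla.quantify_stack(stack, sc.voxel_size_um, n_cells=5)
            summaries.append(summ)
        ratio = pla.compare(summaries[0], summaries[1])["ratio_events"]
        assert ratio == pytest.approx(10.0, rel=0.1)
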