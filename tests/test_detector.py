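"""Windowed change scoring, baselines and thresholding."""

import numpy as np
import pytest

from fhcdsr import (
    HyperCube,
    detect_change,
    fhcdsr_score,
    spectral_weight,
    threshold_map,
)
from fhcdsr.detector import ChangeScoreMap
from oracles import naive_window_scores


class TestSpectralWeight:
    def test_identical_spectra_reach_pi_over_4(self, rng):
        x = rng.uniform(0.1, 2, 25)
        assert spectral_weight(x, x) == pytest.approx(np.pi / 4, abs=1e-12)
        assert spectral_weight(x, 3.7 * x) == pytest.approx(np.pi / 4, abs=1e-12)

    def test_orthogonal_spectra_give_zero(self):
        assert spectral_weight([1.0, 0.0], [0.0, 1.0]) == 0.0

    def test_halfway_closed_form(self):
        # cos = 1/sqrt(2), cos^2 = 0.5, arctan(0.5)
        assert spectral_weight([1.0, 0.0], [1.0, 1.0]) == pytest.approx(
            np.arctan(0.5), abs=1e-12
        )

    def test_bounded_for_nonnegative_spectra(self, rng):
        for _ in range(50):
            x = rng.uniform(0, 1, 10)
            y = rng.uniform(0, 1, 10)
            if x.any() and y.any():
                assert 0.0 <= spectral_weight(x, y) <= np.pi / 4 + 1e-15

    def test_zero_norm_gives_zero_with_warning(self):
        with pytest.warns(RuntimeWarning, match="zero-norm"):
            assert spectral_weight([0.0, 0.0], [1.0, 1.0]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            spectral_weight([1.0, 2.0], [1.0, 2.0, 3.0])


class TestFhcdsrScore:
    def test_identical_windows_score_zero(self, rng):
        w = rng.uniform(0, 5, (3, 3, 7))
        assert fhcdsr_score(w, w) == 0.0

    def test_orthogonal_centers_annihilate(self):
        w1 = np.zeros((3, 3, 2))
        w2 = np.zeros((3, 3, 2))
        w1[..., 0] = 1.0  # center spectrum (1, 0)
        w2[..., 1] = 5.0  # center spectrum (0, 5): orthogonal, W = 0
        assert fhcdsr_score(w1, w2) == 0.0

    def test_uniform_one_band_worked_value(self):
        w1 = np.ones((3, 3, 1))
        w2 = np.full((3, 3, 1), 2.0)
        # 9 pixels * (4 - 1) energy difference, collinear centers: W = pi/4
        assert fhcdsr_score(w1, w2) == pytest.approx(27 * np.pi / 4, rel=1e-12)
        assert fhcdsr_score(w1, w2) == pytest.approx(21.2058, abs=5e-5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fhcdsr_score(np.ones((3, 3, 2)), np.ones((3, 3, 3)))
        with pytest.raises(ValueError):
            fhcdsr_score(np.ones((2, 2, 2)), np.ones((2, 2, 2)))


class TestDetectChange:
    @pytest.fixture()
    def pair(self, rng):
        t1 = HyperCube(rng.uniform(0.1, 2, (12, 10, 8)))
        t2 = HyperCube(t1.values + rng.uniform(-0.2, 0.2, t1.shape))
        return t1, t2

    @pytest.mark.parametrize("method", ["fhcdsr", "ad", "aad"])
    def test_identical_dates_give_zero_map(self, rng, method):
        cube = HyperCube(rng.uniform(0.1, 3, (9, 8, 6)))
        out = detect_change(cube, cube, method)
        assert out.method == method
        assert np.all(out.scores == 0.0)

    def test_ad_is_euclidean_norm(self):
        t1 = HyperCube(np.full((4, 4, 1), 3.0))
        t2 = HyperCube(np.full((4, 4, 1), 7.0))
        assert np.all(detect_change(t1, t2, "ad").scores == 4.0)

    def test_aad_is_band_mean_absolute_difference(self):
        t1 = HyperCube(np.broadcast_to([1.0, 3.0], (2, 2, 2)).copy())
        t2 = HyperCube(np.broadcast_to([2.0, 5.0], (2, 2, 2)).copy())
        assert np.all(detect_change(t1, t2, "aad").scores == 1.5)

    def test_date_swap_leaves_magnitude_unchanged(self, pair):
        t1, t2 = pair
        fwd = detect_change(t1, t2, "fhcdsr").scores
        rev = detect_change(t2, t1, "fhcdsr").scores
        assert np.allclose(fwd, rev, rtol=1e-12, atol=0)

    def test_power_of_two_scaling_is_exactly_quadratic(self, pair):
        t1, t2 = pair
        base = detect_change(t1, t2, "fhcdsr").scores
        scaled = detect_change(
            HyperCube(2.0 * t1.values), HyperCube(2.0 * t2.values), "fhcdsr"
        ).scores
        assert np.array_equal(scaled, 4.0 * base)

    def test_general_scaling_is_quadratic_to_rounding(self, pair):
        t1, t2 = pair
        s = 1.7
        base = detect_change(t1, t2, "fhcdsr").scores
        scaled = detect_change(
            HyperCube(s * t1.values), HyperCube(s * t2.values), "fhcdsr"
        ).scores
        assert np.allclose(scaled, s**2 * base, rtol=1e-9, atol=1e-12)

    def test_matches_triple_loop_oracle(self, rng):
        from fhcdsr import reconstruct_cube

        t1 = HyperCube(rng.uniform(0.05, 2, (15, 15, 20)))
        t2 = HyperCube(rng.uniform(0.05, 2, (15, 15, 20)))
        got = detect_change(t1, t2, "fhcdsr").scores
        want = naive_window_scores(
            reconstruct_cube(t1).values, reconstruct_cube(t2).values
        )
        assert np.allclose(got, want, rtol=1e-9, atol=1e-12)

    def test_unreconstructed_variant_matches_oracle_on_raw_cubes(self, rng):
        t1 = HyperCube(rng.uniform(0.05, 2, (10, 9, 5)))
        t2 = HyperCube(rng.uniform(0.05, 2, (10, 9, 5)))
        got = detect_change(t1, t2, "fhcdsr", reconstruct=False).scores
        want = naive_window_scores(t1.values, t2.values)
        assert np.allclose(got, want, rtol=1e-9, atol=1e-12)

    def test_normalization_flag(self, pair):
        t1, t2 = pair
        out = detect_change(t1, t2, "fhcdsr", normalize=True)
        assert out.normalized
        assert out.scores.min() == 0.0 and out.scores.max() == 1.0

    def test_coregistration_enforced(self, rng):
        t1 = HyperCube(rng.uniform(0, 1, (4, 4, 3)))
        t2 = HyperCube(rng.uniform(0, 1, (4, 5, 3)))
        with pytest.raises(ValueError, match="co-registered"):
            detect_change(t1, t2)


class TestThresholdMap:
    def test_quantile_marks_exactly_top_fraction(self):
        scores = np.zeros((4, 5))
        scores[2, 3] = 10.0
        mask = threshold_map(ChangeScoreMap(scores, "ad"), "quantile", 1 / 20)
        assert mask.n_changed == 1 and mask.labels[2, 3] == 1

    def test_fixed_above_all_values_gives_empty_mask(self):
        mask = threshold_map(ChangeScoreMap(np.full((3, 3), 2.0), "ad"), "fixed", 5.0)
        assert mask.n_changed == 0

    def test_constant_map_otsu_warns_all_zero(self):
        with pytest.warns(RuntimeWarning, match="constant"):
            mask = threshold_map(ChangeScoreMap(np.ones((4, 4)), "ad"), "otsu")
        assert mask.n_changed == 0

    def test_otsu_separates_bimodal_modes(self, rng):
        low = rng.normal(0.2, 0.02, 600)
        high = rng.normal(0.8, 0.02, 400)
        scores = np.concatenate([low, high]).reshape(25, 40)
        mask = threshold_map(ChangeScoreMap(scores, "ad"), "otsu")
        # brute-force 256-candidate scan oracle on the normalized map
        norm = (scores - scores.min()) / (scores.max() - scores.min())
        best_t, best_var = None, -1.0
        for t in np.linspace(0, 1, 256, endpoint=False):
            fg = norm > t
            if fg.all() or not fg.any():
                continue
            w1, w0 = fg.mean(), 1 - fg.mean()
            var = w0 * w1 * (norm[fg].mean() - norm[~fg].mean()) ** 2
            if var > best_var:
                best_t, best_var = t, var
        assert 0.2 < best_t * (scores.max() - scores.min()) + scores.min() < 0.8
        assert np.array_equal(mask.labels, (norm > best_t).astype(np.uint8))

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError, match="strategy"):
            threshold_map(ChangeScoreMap(np.ones((2, 2)), "ad"), "magic")
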