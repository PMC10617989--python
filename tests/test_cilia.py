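"""Cilium orientation, beat frequency, k-means, Fisher association."""

import numpy as np
import pytest

from fiberkin import synth
from fiberkin.cilia import (
    beat_frequency, cilium_orientation, kmeans2, orientation_vs_fiber,
    polarity_class, sweep_mask, trace_from_movie,
)
from conftest import brute_force_two_partition


def _segment_image(angle_deg, wall, shape=(64, 64), length=30.0):
    """Render a straight segment from a base point at a given angle."""
    h, w = shape
    img = np.zeros(shape)
    if wall == "ventral":
        base = (h - 5, 10)
        canal = -1.0
    else:
        base = (5, 10)
        canal = 1.0
    th = np.deg2rad(angle_deg)
    for s in np.linspace(0, length, 200):
        r = base[0] + canal * s * np.sin(th)
        c = base[1] + s * np.cos(th)
        rows, cols = np.mgrid[0:h, 0:w]
        img += np.exp(-((rows - r) ** 2 + (cols - c) ** 2) / (2 * 1.0**2))
    return img / img.max()


class TestOrientation:
    @pytest.mark.parametrize("wall", ["dorsal", "ventral"])
    def test_vertical_segment_is_90(self, wall):
        img = _segment_image(90.0, wall, length=40.0)
        theta = cilium_orientation(img, np.ones_like(img, bool), wall)
        assert theta == pytest.approx(90.0, abs=1.0)

    def test_unit_diagonal_is_45(self):
        img = _segment_image(45.0, "dorsal")
        theta = cilium_orientation(img, np.ones_like(img, bool), "dorsal")
        assert theta == pytest.approx(45.0, abs=1.5)

    def test_ventral_rostral_tilt_negative(self):
        img = _segment_image(135.0, "ventral")
        theta = cilium_orientation(img, np.ones_like(img, bool), "ventral")
        assert theta == pytest.approx(-45.0, abs=1.5)

    def test_rotation_equivariance(self):
        thetas = [cilium_orientation(_segment_image(a, "dorsal"),
                                     np.ones((64, 64), bool), "dorsal")
                  for a in (30.0, 50.0, 70.0)]
        diffs = np.diff(thetas)
        assert np.allclose(diffs, 20.0, atol=2.0)

    def test_population_mean_recovery(self):
        # dorsal population centered at 64.8 deg: estimator mean within 2 deg
        rng = np.random.default_rng(0)
        angles = np.clip(rng.normal(64.8, 10.0, 25), 5, 89)
        est = [cilium_orientation(_segment_image(a, "dorsal"),
                                  np.ones((64, 64), bool), "dorsal")
               for a in angles]
        assert np.mean(est) == pytest.approx(np.mean(angles), abs=2.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            cilium_orientation(np.zeros((8, 8)), np.ones((8, 8), bool),
                               "dorsal")

    def test_multi_component_rejected(self):
        img = np.zeros((20, 20))
        img[2:5, 2:5] = 1.0
        img[14:17, 14:17] = 1.0
        with pytest.raises(ValueError, match="components"):
            cilium_orientation(img, np.ones((20, 20), bool), "dorsal")


class TestBeatFrequency:
    def test_sinusoid_round_trip_from_movie(self):
        spec = synth.CiliumMovieSpec(seed=4, beat_frequency=12.0,
                                     n_frames=1000)
        seq, truth = synth.make_cilium_movie(spec)
        mask = sweep_mask(seq.shape[1:], truth["base_px"], spec.mean_angle,
                          spec.length / spec.pixel_size, spec.wall)
        bf = beat_frequency(trace_from_movie(seq, mask), 40.0)
        assert bf.frequency_hz == pytest.approx(12.0, abs=0.25)
        assert bf.spectral_peak_hz == pytest.approx(12.0, abs=0.1)

    def test_flat_trace_flagged(self):
        bf = beat_frequency(np.full(100, 5.0), 40.0)
        assert bf.frequency_hz == 0.0 and bf.low_confidence

    @pytest.mark.parametrize("f", [2.0, 5.0, 11.2, 18.0])
    def test_noiseless_sinusoid_unbiased(self, f):
        t = np.arange(1000) / 40.0
        bf = beat_frequency(np.sin(2 * np.pi * f * t + 0.7), 40.0)
        assert bf.frequency_hz == pytest.approx(f, abs=0.25)

    def test_population_mean_recovery(self):
        rng = np.random.default_rng(1)
        t = np.arange(1000) / 40.0
        freqs = np.clip(rng.normal(11.2, 2.4, 40), 2, 19)
        est = [beat_frequency(np.sin(2 * np.pi * f * t + rng.uniform(0, 6)),
                              40.0).frequency_hz for f in freqs]
        assert np.mean(est) == pytest.approx(np.mean(freqs), abs=0.5)

    def test_ceiling_aliasing_warning(self):
        t = np.arange(1000) / 40.0
        bf = beat_frequency(np.sin(2 * np.pi * 19.9 * t), 40.0)
        assert bf.aliasing_warning


class TestPolarity:
    def test_caudal_tilt(self):
        assert polarity_class(30.0, "dorsal") == "caudal"

    def test_z_flag(self):
        assert polarity_class(30.0, "dorsal", z_flag=True) == "z-plane"

    def test_mixture_proportions(self):
        rng = np.random.default_rng(2)
        n = 400
        caudal = rng.normal(50, 12, int(0.9 * n))
        dorsal = rng.normal(87, 1.5, n - int(0.9 * n))
        theta = np.concatenate([caudal, dorsal])
        classes = [polarity_class(t, "dorsal") for t in theta]
        frac = classes.count("caudal") / n
        assert frac == pytest.approx(0.9, abs=3 * np.sqrt(0.09 / n) + 0.02)


class TestKmeans2:
    def test_separated_clouds(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, (10, 2))
        b = rng.normal(5, 0.1, (10, 2))
        clu = kmeans2(np.vstack([a, b]))
        assert len(set(clu.labels[:10])) == 1
        assert len(set(clu.labels[10:])) == 1
        assert clu.labels[0] != clu.labels[10]
        np.testing.assert_allclose(clu.centers[clu.labels[0]], a.mean(0),
                                   atol=1e-9)

    def test_four_patch_hand_case(self):
        X = np.array([[0, 0], [0.1, 0], [5, 5], [5.1, 5]], float)
        clu = kmeans2(X)
        assert clu.labels.tolist() == [0, 0, 1, 1]
        np.testing.assert_allclose(clu.centers,
                                   [[0.05, 0], [5.05, 5]], atol=1e-12)

    def test_permutation_preserves_partition(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 0.2, (6, 3)),
                       rng.normal(4, 0.2, (6, 3))])
        p1 = kmeans2(X).partition()
        perm = rng.permutation(12)
        labels2 = kmeans2(X[perm])
        part2 = frozenset(
            frozenset(int(perm[i]) for i in np.nonzero(labels2.labels == k)[0])
            for k in (0, 1))
        assert p1 == part2

    def test_duplicate_initial_centers_fallback(self):
        X = np.array([[1.0, 1.0], [1.0, 1.0], [9.0, 9.0], [1.1, 1.0]])
        clu = kmeans2(X)
        assert clu.labels[2] != clu.labels[0]

    @pytest.mark.parametrize("n,dim,seed", [(4, 2, 0), (7, 3, 1), (10, 2, 2),
                                            (12, 4, 3)])
    def test_matches_brute_force_on_separable_data(self, n, dim, seed):
        rng = np.random.default_rng(seed)
        half = n // 2
        X = np.vstack([rng.normal(0, 0.3, (half, dim)),
                       rng.normal(5, 0.3, (n - half, dim))])
        order = rng.permutation(n)
        X = X[order]
        clu = kmeans2(X)
        labels, sse = brute_force_two_partition(X)
        assert clu.inertia == pytest.approx(sse, rel=1e-9)

    def test_single_patch_rejected(self):
        with pytest.raises(ValueError):
            kmeans2(np.ones((1, 4)))


class TestOrientationVsFiber:
    def test_identical_distribution_p_one(self):
        # each label class sees the same 40/60 mixture
        theta = np.tile([40.0, 60.0, 40.0, 60.0], 10)
        labels = np.array(["up", "up", "down", "down"] * 10)
        res = orientation_vs_fiber(theta, labels)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_table_p_value(self):
        # 2x2 table [[8,2],[2,8]] -> two-sided Fisher p ~= 0.023
        theta = np.concatenate([np.full(8, 70.0), np.full(2, 70.0),
                                np.full(2, 30.0), np.full(8, 30.0)])
        labels = np.array(["down"] * 8 + ["up"] * 2 + ["down"] * 2 + ["up"] * 8)
        res = orientation_vs_fiber(theta, labels)
        assert res.p_value == pytest.approx(0.02301, abs=2e-4)

    def test_steeper_when_down_significant_at_n1000(self):
        # 60 deg when fiber down vs 48 deg when up (dorsal example shift)
        rng = np.random.default_rng(5)
        n = 1000
        labels = np.array(["down", "up"])[rng.integers(0, 2, n)]
        theta = np.where(labels == "down", rng.normal(60, 10, n),
                         rng.normal(48, 16, n))
        res = orientation_vs_fiber(theta, labels)
        assert res.p_value < 1e-4
        assert (res.mean_theta_by_label["down"]
                > res.mean_theta_by_label["up"])

    def test_missing_label_class_rejected(self):
        with pytest.raises(ValueError):
            orientation_vs_fiber(np.ones(5), np.array(["up"] * 5))
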