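import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from fociquant import (
    MaximaParams,
    brute_force_maxima_oracle,
    find_maxima,
    find_nuclear_foci,
    suggest_noise_tolerance,
)
from conftest import make_map


def P(tol, edge=False):
    return MaximaParams(noise_tolerance=tol, exclude_edge=edge)


class TestFindMaxima:
    def test_single_bright_pixel(self):
        plane = np.zeros((7, 7))
        plane[3, 3] = 100
        assert find_maxima(plane, P(10)) == [(3, 3)]

    def test_two_peaks_merge_at_high_tolerance(self):
        # peaks 100 and 90 with a connecting valley at 50
        plane = np.zeros((3, 7))
        plane[1, 1], plane[1, 5] = 100, 90
        plane[1, 2:5] = 50
        assert find_maxima(plane, P(30)) == [(1, 1), (1, 5)]
        assert find_maxima(plane, P(60)) == [(1, 1)]
        # the brute-force path oracle agrees in both regimes
        for tol in (30, 60):
            assert find_maxima(plane, P(tol)) == brute_force_maxima_oracle(plane, P(tol))

    def test_monotone_ramp_has_single_maximum(self):
        plane = np.tile(np.arange(9, dtype=float), (3, 1))
        assert find_maxima(plane, P(2)) == [(1, 8)]

    def test_constant_plane_has_no_maxima(self):
        assert find_maxima(np.full((5, 5), 3.0), P(0)) == []
        assert brute_force_maxima_oracle(np.full((5, 5), 3.0), P(0)) == []

    def test_plateau_returns_single_centroid_representative(self):
        plane = np.zeros((7, 7))
        plane[2:5, 2:5] = 10.0
        assert find_maxima(plane, P(1)) == [(3, 3)]

    def test_equal_peaks_across_deep_valley_both_kept(self):
        plane = np.zeros((3, 5))
        plane[1, 0], plane[1, 4] = 80, 80
        out = find_maxima(plane, P(20))
        assert sorted(out) == [(1, 0), (1, 4)]
        assert out == brute_force_maxima_oracle(plane, P(20))

    def test_exclude_edge_drops_border_maxima(self):
        plane = np.zeros((5, 5))
        plane[0, 2], plane[2, 2] = 90, 100
        assert find_maxima(plane, P(5, edge=True)) == [(2, 2)]

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            MaximaParams(noise_tolerance=-1)

    def test_oracle_guards_large_planes(self):
        with pytest.raises(ValueError, match="32x32"):
            brute_force_maxima_oracle(np.zeros((64, 64)), P(1))


class TestOracleEquivalence:
    """find_maxima must equal the exhaustive path-search oracle."""

    @pytest.mark.parametrize("tol", [0.0, 4.0, 12.0])
    def test_seeded_random_planes(self, tol):
        rng = np.random.default_rng(123)
        for _ in range(100):
            plane = rng.integers(0, 50, size=(12, 12)).astype(float)
            assert find_maxima(plane, P(tol)) == brute_force_maxima_oracle(plane, P(tol))

    @given(
        plane=hnp.arrays(np.int64, (6, 7), elements=st.integers(0, 12)),
        tol=st.sampled_from([0.0, 1.0, 3.0, 7.0]),
        edge=st.booleans(),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_property_equivalence_with_plateaus(self, plane, tol, edge):
        # narrow value range forces plenty of plateaus and ties
        p = P(tol, edge)
        assert find_maxima(plane.astype(float), p) == brute_force_maxima_oracle(
            plane.astype(float), p
        )

    @given(
        plane=hnp.arrays(np.int64, (8, 8), elements=st.integers(0, 60)),
        domain=hnp.arrays(np.bool_, (8, 8)),
        tol=st.sampled_from([0.0, 5.0, 20.0]),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_property_equivalence_under_masks(self, plane, domain, tol):
        assert find_maxima(plane.astype(float), P(tol), domain=domain) == \
            brute_force_maxima_oracle(plane.astype(float), P(tol), domain=domain)


@pytest.fixture(scope="module")
def noisy_plane():
    return np.random.default_rng(9).normal(50, 10, size=(15, 15))


class TestInvariances:

    def test_increasing_tolerance_never_adds_maxima(self, noisy_plane):
        counts = [len(find_maxima(noisy_plane, P(t))) for t in (0, 2, 5, 10, 20, 40)]
        assert counts == sorted(counts, reverse=True)

    def test_shift_invariance(self, noisy_plane):
        assert find_maxima(noisy_plane, P(8)) == find_maxima(noisy_plane + 77.7, P(8))

    def test_scale_equivariance(self, noisy_plane):
        assert find_maxima(noisy_plane, P(8)) == find_maxima(noisy_plane * 3, P(24))


class TestNuclearFoci:
    def two_spot_scene(self):
        green = np.full((12, 12), 20.0)
        labels = np.zeros((12, 12), dtype=np.int32)
        labels[1:11, 1:11] = 1  # one 10x10 nucleus
        green[3, 3] = 120
        green[8, 8] = 110
        return green, labels

    def test_two_spots_density(self):
        green, labels = self.two_spot_scene()
        res = find_nuclear_foci(green, make_map(labels, green), P(30))
        assert res.foci_count == 2 and res.nuclear_area == 100
        assert res.foci_density == pytest.approx(0.02)
        assert sorted(res.foci) == [(3, 3), (8, 8)]
        assert res.per_nucleus_counts == {1: 2}

    def test_spots_outside_every_nucleus_are_ignored(self):
        green, labels = self.two_spot_scene()
        labels = np.zeros_like(labels)
        labels[5:7, 5:7] = 1  # nucleus avoids both spots
        res = find_nuclear_foci(green, make_map(labels, green), P(30))
        assert res.foci_count == 0

    def test_no_nuclei_flags_density_undefined(self):
        green = np.full((6, 6), 9.0)
        res = find_nuclear_foci(green, make_map(np.zeros((6, 6), dtype=np.int32), green), P(5))
        assert res.foci_count == 0 and res.foci_density is None

    def test_merge_paths_cannot_cross_non_nuclear_territory(self):
        # one label, two disconnected parts, each with a peak; the valley
        # between them lies outside the mask, so both peaks survive a
        # tolerance that would merge them on the unmasked plane
        green = np.full((5, 9), 95.0)
        green[2, 1], green[2, 7] = 100, 98
        labels = np.zeros((5, 9), dtype=np.int32)
        labels[:, :3] = 1
        labels[:, 6:] = 1
        res = find_nuclear_foci(green, make_map(labels, green), P(10))
        assert res.foci_count == 2
        unmasked = find_maxima(green, P(10))
        assert len(unmasked) == 1

    def test_every_focus_lies_on_its_nucleus(self, default_scene):
        from fociquant import DEFAULT_MAXIMA, DEFAULT_THRESHOLDS, segment
        img, _ = default_scene
        cmap = segment(img.blue, img.green, DEFAULT_THRESHOLDS)
        res = find_nuclear_foci(img.green, cmap, DEFAULT_MAXIMA)
        for r, c in res.foci:
            assert cmap.nucleus_labels[r, c] >= 1
        assert sum(res.per_nucleus_counts.values()) == res.foci_count


def test_suggest_noise_tolerance_tracks_noise_scale(default_scene):
    from fociquant import DEFAULT_THRESHOLDS, segment
    img, _ = default_scene
    cmap = segment(img.blue, img.green, DEFAULT_THRESHOLDS)
    tol = suggest_noise_tolerance(img.green, cmap)
    # 2 x robust sigma of intranuclear intensity; generator noise sd is 6
    assert 6 < tol < 30
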