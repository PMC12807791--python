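import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rhsp import CineVolume, InputError
from rhsp.config import ThresholdConfig
from rhsp.threshold import (
    background_peak,
    compute_slab_thresholds,
    mirrored_std,
    segment,
    slab_partition,
    slab_threshold,
)
from conftest import make_ball_mask


class TestSlabPartition:
    def test_exact_division(self):
        ranges = slab_partition(700, 10)
        assert all(r1 - r0 == 70 for r0, r1 in ranges)

    def test_rounding_rule_covers_everything(self):
        # oracle: enumerate round(k*705/10) boundaries independently
        expected = [int(np.floor(k * 705 / 10 + 0.5)) for k in range(11)]
        ranges = slab_partition(705, 10)
        assert [r0 for r0, _ in ranges] == expected[:-1]
        assert [r1 for _, r1 in ranges] == expected[1:]
        assert sum(r1 - r0 for r0, r1 in ranges) == 705

    def test_unit_slabs(self):
        assert slab_partition(25, 25) == [(k, k + 1) for k in range(25)]

    def test_too_few_rows_rejected(self):
        with pytest.raises(InputError):
            slab_partition(9, 10)

    @given(n_rows=st.integers(10, 2000), n_slabs=st.integers(1, 10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_partition_properties(self, n_rows, n_slabs):
        ranges = slab_partition(n_rows, n_slabs)
        assert len(ranges) == n_slabs
        assert ranges[0][0] == 0 and ranges[-1][1] == n_rows
        for (a0, a1), (b0, b1) in zip(ranges, ranges[1:]):
            assert a1 == b0 and a1 > a0  # contiguous, nonempty


class TestBackgroundPeak:
    def test_gaussian_peak_recovered(self):
        rng = np.random.default_rng(0)
        x = rng.normal(100, 10, 100_000)
        counts, edges = np.histogram(x, bins=256)
        mu = background_peak(counts, edges)
        # the argmax bin jitters over the flat top of the mode (~0.2 sigma)
        assert abs(mu - 100) <= 0.2 * 10

    def test_peak_robust_to_sphere_fraction(self):
        # 20% dark component shifts the mean to 92 but not the mode
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(100, 10, 80_000), rng.normal(60, 10, 20_000)])
        counts, edges = np.histogram(x, bins=256)
        mu = background_peak(counts, edges)
        width = edges[1] - edges[0]
        assert abs(mu - 100) <= 0.2 * 10
        assert abs(mu - x.mean()) > 5 * width  # nowhere near the mixture mean

    def test_tie_breaks_to_lowest_bin(self):
        counts = np.array([1, 5, 2, 5, 1])
        edges = np.array([80.0, 85, 95, 105, 115, 120])
        assert background_peak(counts, edges) == pytest.approx(90.0)

    def test_empty_histogram_rejected(self):
        with pytest.raises(InputError):
            background_peak(np.zeros(4), np.linspace(0, 1, 5))


class TestMirroredStd:
    def test_hand_example(self):
        # S = {100, 101}, mu = 100 -> S' = {100,101,100,99}, SD = sqrt(0.5)
        assert mirrored_std(np.array([100.0, 101.0]), 100.0) == pytest.approx(np.sqrt(0.5))

    def test_degenerate_all_equal(self):
        assert mirrored_std(np.full(10, 42.0), 42.0) == 0.0

    def test_symmetric_sample_preserves_sd(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 5, 1_000_000)
        assert mirrored_std(x, 0.0) == pytest.approx(5.0, rel=0.01)

    def test_mu_above_all_voxels_rejected(self):
        with pytest.raises(InputError):
            mirrored_std(np.array([1.0, 2.0]), 10.0)

    @given(st.lists(st.floats(0, 255), min_size=3, max_size=50), st.floats(0, 200))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_equals_explicit_mirrored_set(self, values, mu):
        # oracle: literally build S' and take its population SD
        x = np.array(values)
        upper = x[x >= mu]
        if upper.size == 0:
            return
        mirrored = np.concatenate([upper, 2 * mu - upper])
        assert mirrored_std(x, mu) == pytest.approx(mirrored.std(), abs=1e-9)
        assert mirrored.mean() == pytest.approx(mu, abs=1e-6)


class TestSlabThreshold:
    def test_formula(self):
        assert slab_threshold(100, 10) == 80
        assert slab_threshold(55.5, 0) == 55.5


class TestSegment:
    def _volume(self, arr):
        return CineVolume(np.asarray(arr, dtype=np.float32), 0.14, 0.14)

    def test_isolated_voxel_removed_by_opening(self):
        x = np.full((40, 40, 6), 100.0)
        x[20, 20, 3] = 1.0  # single dark voxel
        x[5:12, 5:12, :] = 1.0  # a real block so thresholds see two classes
        vol = self._volume(x)
        thr = compute_slab_thresholds(vol, ThresholdConfig(n_slabs=2))
        masks = segment(vol, thr)
        assert masks.m0[20, 20, 3]
        assert not masks.m1[20, 20, 3]

    def test_ball_survives_opening_mostly_intact(self):
        x = np.full((40, 40, 20), 100.0)
        ball = make_ball_mask(x.shape, (20, 20, 10), 7)
        x[ball] = 1.0
        vol = self._volume(x)
        thr = compute_slab_thresholds(vol, ThresholdConfig(n_slabs=2))
        masks = segment(vol, thr)
        retained = (masks.m1 & ball).sum() / ball.sum()
        assert retained >= 0.90

    def test_nothing_below_threshold_gives_empty_masks(self):
        rng = np.random.default_rng(3)
        vol = self._volume(rng.normal(100, 5, (60, 40, 6)))
        thr = compute_slab_thresholds(vol)
        for t in thr:
            t.threshold = vol.voxels.min() - 1  # force Tk below all voxels
        masks = segment(vol, thr)
        assert not masks.m0.any() and not masks.m1.any()

    def test_m1_subset_of_m0_and_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        vol = self._volume(rng.normal(100, 10, (60, 40, 8)))
        thr = compute_slab_thresholds(vol)
        masks = segment(vol, thr)
        assert not (masks.m1 & ~masks.m0).any()
        # lowering a threshold can only shrink m0
        for t in thr:
            t.threshold -= 5.0
        smaller = segment(vol, thr)
        assert not (smaller.m0 & ~masks.m0).any()

    def test_incomplete_coverage_rejected(self):
        rng = np.random.default_rng(5)
        vol = self._volume(rng.normal(100, 10, (60, 40, 6)))
        thr = compute_slab_thresholds(vol)
        with pytest.raises(InputError):
            segment(vol, thr[:-1])


def test_mirrored_model_beats_naive_on_dense_phantom_slab():
    """At 20% sphere fraction the peak/mirror estimate recovers the true
    background within 5% while naive all-voxel statistics are biased
    far more (the motivation for not using mean/SD of all pixels)."""
    rng = np.random.default_rng(6)
    bg_mu, bg_sd = 100.0, 10.0
    x = np.concatenate(
        [rng.normal(bg_mu, bg_sd, 400_000), rng.normal(60, bg_sd, 100_000)]
    )
    counts, edges = np.histogram(x, bins=256)
    mu = background_peak(counts, edges)
    sd = mirrored_std(x, mu)
    err_mu = abs(mu - bg_mu) / bg_mu
    err_sd = abs(sd - bg_sd) / bg_sd
    assert err_mu < 0.05 and err_sd < 0.05
    naive_err_mu = abs(x.mean() - bg_mu) / bg_mu
    naive_err_sd = abs(x.std() - bg_sd) / bg_sd
    assert naive_err_mu > 5 * err_mu
    assert naive_err_sd > 5 * err_sd
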