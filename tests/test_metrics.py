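import numpy as np
import pytest

from rhsp import CineVolume, InputError
from rhsp.metrics import (
    LSNRCurve,
    background_stats,
    lsnr,
    lsnr_curve,
    sphere_signal,
    variability,
)
from rhsp.separation import SphereMeasurement


def _vol(arr, spacing=0.14):
    return CineVolume(np.asarray(arr, dtype=np.float64), spacing, spacing)


def _disk_label(shape, center, radius, frame):
    m2 = np.zeros(shape, dtype=np.int32)
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    m2[:, :, frame][(rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2] = 1
    return m2


def _sphere(zi=0, xi=20.0, yi=20.0, depth_cm=1.0, lsnr_val=None):
    s = SphereMeasurement(label=1, zi=zi, si_px=100, si_mm2=3.14, xi=xi, yi=yi,
                          depth_cm=depth_cm, eligible=True)
    s.lsnr = lsnr_val
    return s


class TestSphereSignal:
    def test_constant_disk(self):
        shape = (40, 40, 3)
        m2 = _disk_label(shape, (20, 20), 8, 1)
        x0 = _vol(np.full(shape, 40.0))
        assert sphere_signal(x0, m2, _sphere(zi=1)) == pytest.approx(40.0)

    def test_small_disk_empties_after_erosion(self):
        m2 = _disk_label((40, 40, 3), (20, 20), 2, 1)
        x0 = _vol(np.full((40, 40, 3), 40.0))
        assert sphere_signal(x0, m2, _sphere(zi=1)) is None

    def test_rim_excluded_by_erosion(self):
        shape = (40, 40, 3)
        m2 = _disk_label(shape, (20, 20), 8, 1)
        x = np.full(shape, 70.0)
        rr, cc = np.ogrid[:40, :40]
        inner = (rr - 20) ** 2 + (cc - 20) ** 2 <= 5**2
        x[:, :, 1][inner] = 40.0  # rim (radius 5..8) stays at 70
        assert sphere_signal(_vol(x), m2, _sphere(zi=1)) == pytest.approx(40.0)


class TestBackgroundStats:
    def test_uniform_background(self):
        shape = (60, 60, 5)
        x0 = _vol(np.full(shape, 100.0))
        m0 = np.zeros(shape, dtype=bool)
        out = background_stats(x0, m0, _sphere(zi=2, xi=30, yi=30), d_mm=2.0)
        assert out == (pytest.approx(100.0), pytest.approx(0.0))

    def test_cylinder_radius_is_2d(self):
        # diameter 4d -> radius 2d = 4 mm ~= 28.6 px at 0.14 mm pixels
        shape = (80, 80, 3)
        x = np.full(shape, 50.0)
        x[40, 40 + 30, :] = 500.0  # just outside the cylinder (30 px > 28.6)
        x0 = _vol(x)
        m0 = np.zeros(shape, dtype=bool)
        Sb, sigma_b = background_stats(x0, m0, _sphere(zi=1, xi=40.0, yi=40.0), d_mm=2.0)
        assert Sb == pytest.approx(50.0)
        assert sigma_b == pytest.approx(0.0)

    def test_masked_sphere_voxels_excluded(self):
        # dark sphere voxels inside m0 must not bias the background down
        rng = np.random.default_rng(0)
        shape = (60, 60, 8)
        x = rng.normal(100, 10, shape)
        rr, cc = np.ogrid[:60, :60]
        dark = (rr - 30) ** 2 + (cc - 30) ** 2 <= 7**2
        m0 = np.zeros(shape, dtype=bool)
        m0[:, :, :] = dark[:, :, None]
        x[m0] = 40.0
        x0 = _vol(x)
        s = _sphere(zi=4, xi=30.0, yi=30.0)
        Sb, sigma_b = background_stats(x0, m0, s, d_mm=2.0)
        assert Sb == pytest.approx(100.0, abs=1.0)
        assert sigma_b == pytest.approx(10.0, rel=0.1)
        biased_Sb, _ = background_stats(x0, np.zeros(shape, dtype=bool), s, d_mm=2.0)
        assert biased_Sb < Sb - 2.0

    def test_too_small_background_dropped(self):
        shape = (40, 40, 3)
        x0 = _vol(np.full(shape, 100.0))
        m0 = np.ones(shape, dtype=bool)  # everything masked out
        assert background_stats(x0, m0, _sphere(zi=1), d_mm=2.0) is None


class TestLSNR:
    def test_hand_value(self):
        assert lsnr(40, 100, 10) == pytest.approx(-6.0)

    def test_zero_contrast(self):
        assert lsnr(100, 100, 10) == 0.0

    def test_affine_invariance(self):
        # gain/offset cancel: the basis of gain-independence of the metric
        assert lsnr(2 * 40 + 5, 2 * 100 + 5, 2 * 10) == pytest.approx(-6.0)

    def test_zero_noise_undefined(self):
        assert lsnr(40, 100, 0) is None


class TestLSNRCurve:
    def test_single_slab_hand_example(self):
        spheres = [_sphere(depth_cm=0.5, lsnr_val=v) for v in (-8.0, -10.0, -12.0)]
        curve = lsnr_curve(spheres, (0.0, 1.0), n_slabs=1)
        assert curve.lsnr[0] == pytest.approx(-10.0)
        assert curve.sigma[0] == pytest.approx(2.0)
        assert curve.epsilon[0] == pytest.approx(2.0 / np.sqrt(3.0))

    def test_slab_extent(self):
        curve = lsnr_curve([], (0.0, 10.0), n_slabs=25)
        widths = np.diff(curve.edges_cm)
        assert np.allclose(widths, 0.4)  # 10 cm / 25 slabs

    def test_empty_input_gives_empty_curve(self):
        curve = lsnr_curve([], (0.0, 5.0))
        assert curve.counts.sum() == 0
        assert np.all(np.isnan(curve.lsnr))
        assert curve.peak() is None

    def test_half_open_binning_and_count_conservation(self):
        spheres = [
            _sphere(depth_cm=d, lsnr_val=-5.0) for d in (0.0, 0.399, 0.4, 0.8, 1.19)
        ]
        curve = lsnr_curve(spheres, (0.0, 1.2), n_slabs=3)
        assert list(curve.counts) == [2, 1, 2]  # edge values fall in the upper slab
        assert curve.counts.sum() == len(spheres)

    def test_singleton_slab_has_no_epsilon(self):
        curve = lsnr_curve([_sphere(depth_cm=0.1, lsnr_val=-7.0)], (0.0, 1.0), n_slabs=2)
        assert curve.counts[0] == 1
        assert np.isnan(curve.epsilon[0])

    def test_peak_is_most_negative(self):
        spheres = [_sphere(depth_cm=0.2, lsnr_val=-4.0), _sphere(depth_cm=0.7, lsnr_val=-9.0)]
        depth, value = lsnr_curve(spheres, (0.0, 1.0), n_slabs=2).peak()
        assert value == pytest.approx(-9.0)
        assert depth == pytest.approx(0.75)


def _curve(values, counts=None):
    n = len(values)
    values = np.asarray(values, dtype=float)
    counts = np.asarray(counts if counts is not None else np.ones(n), dtype=int)
    return LSNRCurve(
        edges_cm=np.linspace(0, n * 0.4, n + 1),
        counts=counts,
        lsnr=values,
        sigma=np.zeros(n),
        epsilon=np.zeros(n),
    )


class TestVariability:
    def test_identical_curves_zero_rsd(self):
        c = _curve([-10.0, -8.0], counts=[4, 5])
        rep = variability([c, c])
        assert rep.overall_rsd_lsnr == 0.0
        assert rep.overall_rsd_counts == 0.0

    def test_hand_example_lsnr(self):
        rep = variability([_curve([-10.0]), _curve([-11.0])])
        assert rep.overall_rsd_lsnr == pytest.approx(100 * np.std([10, 11], ddof=1) / 10.5, rel=1e-6)
        assert rep.overall_rsd_lsnr == pytest.approx(6.73, abs=0.01)

    def test_hand_example_counts(self):
        curves = [_curve([-5.0], counts=[c]) for c in (10, 14, 12)]
        rep = variability(curves)
        assert rep.overall_rsd_counts == pytest.approx(100 * 2 / 12, rel=1e-6)

    def test_point_rsd_at_named_depth(self):
        curves = [_curve([-10.0, -20.0]), _curve([-10.0, -22.0])]
        rep = variability(curves, at_depth_cm=0.6)  # second slab
        assert rep.point_rsd_lsnr == pytest.approx(100 * np.std([20, 22], ddof=1) / 21)

    def test_undefined_slabs_excluded_from_overall(self):
        a = _curve([-10.0, np.nan], counts=[3, 0])
        b = _curve([-11.0, -5.0], counts=[3, 1])
        rep = variability([a, b])
        assert rep.overall_rsd_lsnr == pytest.approx(rep.per_depth_rsd_lsnr[0])
        assert np.isnan(rep.per_depth_rsd_lsnr[1])

    def test_single_curve_rejected(self):
        with pytest.raises(InputError):
            variability([_curve([-10.0])])

    def test_mismatched_grids_rejected(self):
        a = _curve([-10.0, -9.0])
        b = LSNRCurve(
            edges_cm=np.linspace(0, 1.0, 3),
            counts=np.array([1, 1]),
            lsnr=np.array([-10.0, -9.0]),
            sigma=np.zeros(2),
            epsilon=np.zeros(2),
        )
        with pytest.raises(InputError):
            variability([a, b])
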