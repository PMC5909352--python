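import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dcemcs import (DCESeries, TimeIntensityCurve, VOI, DegenerateInputError,
                    slice_area, slice_perimeter, compactness_3d,
                    eccentricity_3d, morph_feature_vector, basal_signal,
                    relative_enhancement, re_slope, dyn_feature_vector)


def _block_voi(shape, offset=(0, 0, 0)):
    coords = np.argwhere(np.ones(shape, bool)) + np.asarray(offset)
    return VOI(coords)


class TestSliceFeatures:
    @pytest.mark.parametrize("n, dx, dy, expected", [
        (5, 1.0, 1.0, 5.0),
        (3, 0.5, 0.5, 0.75),
    ])
    def test_area(self, n, dx, dy, expected):
        mask = np.zeros((4, 4), bool)
        mask.ravel()[:n] = True
        assert slice_area(mask, dx, dy) == pytest.approx(expected)

    def test_area_empty_rejected(self):
        with pytest.raises(DegenerateInputError):
            slice_area(np.zeros((3, 3), bool), 1, 1)

    @pytest.mark.parametrize("builder, expected", [
        (lambda: np.ones((1, 1), bool), 1),     # isolated voxel
        (lambda: np.ones((3, 3), bool), 8),     # only the centre is interior
        (lambda: np.ones((1, 3), bool), 3),     # every row voxel touches outside
    ])
    def test_perimeter_enumerated(self, builder, expected):
        assert slice_perimeter(builder()) == expected

    def test_perimeter_border_counts_as_outside(self):
        # a 5x5 block flush against the grid edge: same boundary as padded
        flush = np.ones((5, 5), bool)
        padded = np.zeros((7, 7), bool)
        padded[1:6, 1:6] = True
        assert slice_perimeter(flush) == slice_perimeter(padded) == 16


class TestCompactness:
    @pytest.mark.parametrize("shape, expected", [
        ((1, 1, 1), 1.0),             # S = 1, V = 1
        ((2, 2, 2), 8.0),             # all 8 voxels boundary: 64/8
        ((3, 3, 3), 676.0 / 27.0),    # 26 boundary voxels: 26^2/27
    ])
    def test_unit_cubes_enumerated(self, shape, expected):
        voi = _block_voi(shape)
        assert compactness_3d(voi, 1, 1, 1) == pytest.approx(expected)

    def test_cube_compactness_grows_with_size(self):
        values = [compactness_3d(_block_voi((n, n, n)), 1, 1, 1)
                  for n in range(2, 7)]
        assert np.all(np.diff(values) > 0)
        # boundary count of an n-cube is n^3 - (n-2)^3, so COMP ~ 6n at large n
        n = 6
        boundary = n ** 3 - (n - 2) ** 3
        assert values[-1] == pytest.approx(boundary ** 2 / n ** 3)


class TestEccentricity:
    def test_symmetric_cloud_is_zero(self):
        # 6 octahedron vertices: equal second moments along all axes
        coords = np.array([[2, 1, 1], [0, 1, 1], [1, 2, 1],
                           [1, 0, 1], [1, 1, 2], [1, 1, 0]])
        voi = VOI(coords, validate_connectivity=False)
        assert eccentricity_3d(voi, 1, 1, 1) == pytest.approx(0.0, abs=1e-12)

    def test_known_axis_ratio(self):
        # corners of a box: semi-axes are the full half-extents scaled by 2,
        # here (5, 4, 3) -> sqrt(25 - 9)/5 = 0.8
        corners = np.array([[x, y, z] for x in (0, 5) for y in (0, 5)
                            for z in (0, 5)])
        voi = VOI(corners, validate_connectivity=False)
        assert eccentricity_3d(voi, 1.0, 0.8, 0.6) == pytest.approx(0.8, rel=1e-12)

    def test_discrete_ball_is_nearly_spherical(self):
        idx = np.indices((15, 15, 15))
        dist = np.sqrt(((idx - 7.0) ** 2).sum(axis=0))
        voi = VOI.from_mask(dist <= 6)
        assert eccentricity_3d(voi, 1, 1, 1) < 0.15

    def test_planar_cloud_rejected(self):
        coords = np.argwhere(np.ones((4, 4, 1), bool))
        with pytest.raises(DegenerateInputError, match="degenerate"):
            eccentricity_3d(VOI(coords), 1, 1, 1)


class TestMorphVector:
    def test_cube_medians(self):
        voi = _block_voi((3, 3, 3))
        mf = morph_feature_vector(voi, 1, 1, 1)
        assert mf.area_median == pytest.approx(9.0)
        assert mf.perimeter_median == pytest.approx(8.0)
        assert mf.compactness == pytest.approx(676.0 / 27.0)

    def test_odd_and_even_median_rules(self):
        # stacked blocks of 2x2, 3x3, 5x5 -> slice areas {4, 9, 25}
        coords = []
        for k, side in enumerate((2, 3, 5)):
            block = np.argwhere(np.ones((side, side), bool))
            coords += [[x, y, k] for x, y in block]
        voi = VOI(np.array(coords), validate_connectivity=False)
        assert morph_feature_vector(voi, 1, 1, 1).area_median == pytest.approx(9.0)
        # even count {4, 16} -> mean of the middle two = 10
        coords = []
        for k, side in enumerate((2, 4)):
            block = np.argwhere(np.ones((side, side), bool))
            coords += [[x, y, k] for x, y in block]
        voi = VOI(np.array(coords), validate_connectivity=False)
        assert morph_feature_vector(voi, 1, 1, 1).area_median == pytest.approx(10.0)

    @settings(deadline=None, max_examples=20)
    @given(shift=st.tuples(st.integers(0, 8), st.integers(0, 8), st.integers(0, 8)))
    def test_translation_invariance(self, shift):
        base = _block_voi((3, 4, 3))
        moved = VOI(base.coords + np.asarray(shift))
        a = morph_feature_vector(base, 1.3, 1.3, 2.0)
        b = morph_feature_vector(moved, 1.3, 1.3, 2.0)
        for name in ("area_median", "perimeter_median", "compactness", "eccentricity"):
            assert getattr(a, name) == pytest.approx(getattr(b, name), rel=1e-12)


class TestDynamicFeatures:
    def test_basal_signal(self):
        assert basal_signal(TimeIntensityCurve(100, [120, 130])) == 100
        with pytest.warns(UserWarning, match="zero basal"):
            assert basal_signal(TimeIntensityCurve(0, [10, 20])) == 0

    @pytest.mark.parametrize("si, expected", [(100, 0.0), (150, 0.5)])
    def test_relative_enhancement(self, si, expected):
        tic = TimeIntensityCurve(100, [si, si])
        assert relative_enhancement(tic, 1) == pytest.approx(expected)

    def test_relative_enhancement_zero_baseline(self):
        with pytest.raises(DegenerateInputError):
            relative_enhancement(TimeIntensityCurve(0, [10, 20]), 1)

    def test_re_slope_closed_forms(self):
        # RE = [0.1, 0.2, 0.3] at t = [60, 120, 180] -> slope 0.1/60
        tic = TimeIntensityCurve(100, [110, 120, 130])
        assert re_slope(tic, [60, 120, 180]) == pytest.approx(0.1 / 60)
        flat = TimeIntensityCurve(100, [120, 120, 120])
        assert re_slope(flat, [60, 120, 180]) == pytest.approx(0.0)
        two = TimeIntensityCurve(100, [110, 140])
        assert re_slope(two, [60, 180]) == pytest.approx((0.4 - 0.1) / 120)

    def test_time_offset_and_intensity_scaling_equivariance(self):
        tic = TimeIntensityCurve(100, [140, 170, 160, 150])
        t = np.array([60.0, 120, 180, 240])
        assert re_slope(tic, t + 300) == pytest.approx(re_slope(tic, t))
        scaled = TimeIntensityCurve(250, [350, 425, 400, 375])   # 2.5x
        assert re_slope(scaled, t) == pytest.approx(re_slope(tic, t))
        from dcemcs import sod_voxel
        assert sod_voxel(scaled) == pytest.approx(2.5 * sod_voxel(tic))

    def test_vector_per_voxel(self):
        rng = np.random.default_rng(8)
        voxels = rng.uniform(50, 200, size=(4, 4, 3, 6))
        series = DCESeries(voxels, dx=1, dy=1, slice_th=1, times=np.arange(6) * 60.0)
        voi = VOI(np.argwhere(np.ones((2, 3, 1), bool)) + [1, 0, 1])
        dyn = dyn_feature_vector(voi, series)
        assert len(dyn) == voi.n_voxels
        x, y, z = voi.coords[3]
        tic = series.tic(x, y, z)
        from dcemcs import sod_voxel
        assert dyn[3].sod == pytest.approx(sod_voxel(tic))
        assert dyn[3].bs == pytest.approx(tic.pre)
        assert dyn[3].re_slope == pytest.approx(re_slope(tic, series.post_times))

    def test_flat_series_gives_sod_bs_and_zero_slope(self):
        series = DCESeries(np.full((3, 3, 2, 5), 80.0), dx=1, dy=1, slice_th=1,
                           times=np.arange(5) * 60.0)
        dyn = dyn_feature_vector(VOI.from_mask(np.ones((3, 3, 2), bool)), series)
        assert all(d.sod == pytest.approx(d.bs) for d in dyn)
        assert all(d.re_slope == pytest.approx(0.0) for d in dyn)
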