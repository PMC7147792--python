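"""ROI statistics, Bland-Altman agreement, AHA segmentation, line profiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sashamap import (
    DataError,
    T1Map,
    aha_summary,
    bland_altman,
    line_profile,
    make_cardiac_phantom,
    precision_improvement,
    roi_stats,
)

VOX = (1.4, 1.4, 8.0)


def t1map_from(t1_volume, converged=None):
    t1_volume = np.asarray(t1_volume, dtype=float)
    if converged is None:
        converged = t1_volume > 0
    z = np.zeros_like(t1_volume)
    return T1Map(
        t1_volume=t1_volume, amplitude_volume=z, efficiency_volume=z,
        residual_volume=z, converged_mask=np.asarray(converged, dtype=bool), voxel_size=VOX,
    )


class TestRoiStats:
    def test_constant_region(self):
        vol = np.full((8, 8, 2), 1000.0)
        st_ = roi_stats(t1map_from(vol), np.ones((8, 8, 2), dtype=bool))
        assert st_.mean_t1 == 1000.0 and st_.sd_t1 == 0.0 and st_.n_voxels == 128

    def test_nonconverged_voxels_excluded(self):
        vol = np.full((4, 4, 1), 1000.0)
        conv = np.ones((4, 4, 1), dtype=bool)
        vol[0, 0, 0] = 9999.0
        conv[0, 0, 0] = False
        st_ = roi_stats(t1map_from(vol, conv), np.ones((4, 4, 1), dtype=bool))
        assert st_.mean_t1 == 1000.0 and st_.n_voxels == 15

    def test_fully_nonconverged_roi_is_an_error(self):
        vol = np.full((4, 4, 1), 1000.0)
        with pytest.raises(DataError):
            roi_stats(t1map_from(vol, np.zeros((4, 4, 1), bool)), np.ones((4, 4, 1), bool))


class TestBlandAltman:
    def test_identical_vectors_give_zero_bias_and_zero_limits(self):
        s = bland_altman([100.0, 200.0, 300.0], [100.0, 200.0, 300.0])
        assert s.bias == 0.0 and s.loa_low == 0.0 and s.loa_high == 0.0

    def test_hand_computed_example(self):
        # diffs = [-10, 10]: bias 0, sample SD 14.142, limits +/- 27.718
        s = bland_altman([100.0, 200.0], [110.0, 190.0])
        assert s.bias == pytest.approx(0.0)
        assert s.sd_diff == pytest.approx(14.1421356, rel=1e-6)
        assert s.loa_high == pytest.approx(27.7185858, rel=1e-6)
        assert s.loa_low == pytest.approx(-27.7185858, rel=1e-6)

    def test_single_pair_rejected(self):
        with pytest.raises(DataError):
            bland_altman([100.0], [90.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            bland_altman([1.0, 2.0], [1.0, 2.0, 3.0])

    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=20),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=40, deadline=None)
    def test_antisymmetric_under_swapping(self, a, seed):
        rng = np.random.default_rng(seed)
        b = list(rng.uniform(-1e3, 1e3, size=len(a)))
        s_ab = bland_altman(a, b)
        s_ba = bland_altman(b, a)
        assert s_ab.bias == pytest.approx(-s_ba.bias, abs=1e-9)
        assert s_ab.loa_low == pytest.approx(-s_ba.loa_high, abs=1e-9)
        assert s_ab.loa_high == pytest.approx(-s_ba.loa_low, abs=1e-9)
        assert s_ab.loa_low <= s_ab.bias <= s_ab.loa_high


class TestPrecisionImprovement:
    @pytest.mark.parametrize(
        "before,after,expected", [(10.0, 10.0, 0.0), (10.0, 8.8, 12.0), (10.0, 12.0, -20.0)]
    )
    def test_signed_percentage(self, before, after, expected):
        assert precision_improvement(before, after) == pytest.approx(expected)

    def test_nonpositive_before_rejected(self):
        with pytest.raises(DataError):
            precision_improvement(0.0, 1.0)


class TestLineProfile:
    def test_constant_volume_gives_constant_profile(self):
        vol = np.full((10, 10, 3), 42.0)
        prof = line_profile(vol, (0, 0, 0), (9, 9, 2), 25)
        np.testing.assert_allclose(prof, 42.0)

    def test_two_samples_are_exactly_the_endpoints(self):
        vol = np.arange(60, dtype=float).reshape(5, 4, 3)
        prof = line_profile(vol, (0, 0, 0), (4, 3, 2), 2)
        assert prof[0] == vol[0, 0, 0] and prof[1] == vol[4, 3, 2]

    def test_step_volume_crossing_position(self):
        vol = np.zeros((40, 8, 2))
        vol[20:, :, :] = 100.0  # edge midpoint at x = 19.5
        prof = line_profile(vol, (0, 4, 1), (39, 4, 1), 79)  # step 0.5 voxel
        x = np.linspace(0, 39, 79)
        idx = int(np.argmax(prof >= 50.0))
        cross = x[idx - 1] + (50.0 - prof[idx - 1]) / (prof[idx] - prof[idx - 1]) * (x[idx] - x[idx - 1])
        assert cross == pytest.approx(19.5, abs=0.5)
        mid = prof[(x > 5) & (x < 35)]
        assert np.all(np.diff(mid) >= -1e-9)  # monotone between plateaus

    def test_out_of_bounds_endpoint_rejected(self):
        vol = np.zeros((5, 5, 2))
        with pytest.raises(DataError):
            line_profile(vol, (0, 0, 0), (5, 0, 0), 10)


def brute_force_aha(t1, conv, myo, blood, centers, angle0, bands):
    """Independent per-voxel angular binning of the 17-segment model."""
    import math

    values = {s: [] for s in range(1, 18)}
    layout = [(bands[0], 1, 6), (bands[1], 7, 6), (bands[2], 13, 4)]
    nx, ny, nz = t1.shape
    for (z0, z1), seg0, nsec in layout:
        for z in range(z0, z1):
            for x in range(nx):
                for y in range(ny):
                    if myo[x, y, z] and conv[x, y, z]:
                        cx, cy = centers[z]
                        th = (math.degrees(math.atan2(y - cy, x - cx)) - angle0) % 360.0
                        s = min(int(th // (360.0 / nsec)), nsec - 1)
                        values[seg0 + s].append(t1[x, y, z])
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if blood[x, y, z] and conv[x, y, z]:
                    values[17].append(t1[x, y, z])
    return {s: (float(np.mean(v)) if v else np.nan, len(v)) for s, v in values.items()}


@pytest.fixture(scope="module")
def ring():
    p = make_cardiac_phantom((48, 48, 12), myo_t1=1078.0, blood_t1=1507.0, ring_radii=(8.0, 14.0))
    t1, _, _ = p.parameter_volumes()
    return p, t1


class TestAhaSummary:

    def test_uniform_ring_reports_1078_everywhere_with_zero_sd(self, ring):
        p, t1 = ring
        summary = aha_summary(
            t1map_from(t1), lv_center=(23.5, 23.5), rv_insertion_angle=0.0,
            slice_bands=((0, 4), (4, 8), (8, 12)),
            myo_mask=p.region_mask(1), blood_mask=p.region_mask(2),
        )
        tab = summary.table
        assert len(tab) == 17
        myo_rows = tab[tab.segment <= 16]
        assert np.allclose(myo_rows.mean_t1, 1078.0)
        assert np.allclose(myo_rows.sd_t1, 0.0)
        assert (myo_rows.n_voxels > 0).all()
        blood = tab[tab.segment == 17].iloc[0]
        assert blood.mean_t1 == pytest.approx(1507.0) and blood.sd_t1 == 0.0

    def test_elevated_sector_matches_brute_force_binning(self, ring):
        p, t1 = ring
        t1 = t1.copy()
        # one 60-degree wedge (counterclockwise from the insertion angle) at 1200 ms
        cx = cy = 23.5
        xs, ys = np.meshgrid(np.arange(48), np.arange(48), indexing="ij")
        theta = (np.degrees(np.arctan2(ys - cy, xs - cx)) - 30.0) % 360.0
        wedge = (theta < 60.0)[:, :, None] & p.region_mask(1)
        t1[wedge] = 1200.0
        bands = ((0, 4), (4, 8), (8, 12))
        centers = [(cx, cy)] * 12
        summary = aha_summary(
            t1map_from(t1), lv_center=(cx, cy), rv_insertion_angle=30.0,
            slice_bands=bands, myo_mask=p.region_mask(1), blood_mask=p.region_mask(2),
        )
        oracle = brute_force_aha(t1, t1 > 0, p.region_mask(1), p.region_mask(2), centers, 30.0, bands)
        for _, row in summary.table.iterrows():
            mean, n = oracle[row.segment]
            assert row.n_voxels == n
            assert row.mean_t1 == pytest.approx(mean, rel=1e-12)
        # exactly the first basal and first mid segment are fully elevated
        tab = summary.table.set_index("segment")
        assert tab.loc[1].mean_t1 == pytest.approx(1200.0)
        assert tab.loc[7].mean_t1 == pytest.approx(1200.0)
        for s in (2, 3, 4, 5, 6, 8, 9, 10, 11, 12):
            assert tab.loc[s].mean_t1 == pytest.approx(1078.0)

    def test_empty_band_is_flagged_not_fatal(self, ring):
        p, t1 = ring
        conv = np.zeros_like(t1, dtype=bool)
        conv[:, :, 4:] = t1[:, :, 4:] > 0  # basal slices entirely non-converged
        summary = aha_summary(
            t1map_from(t1, conv), lv_center=(23.5, 23.5), rv_insertion_angle=0.0,
            slice_bands=((0, 4), (4, 8), (8, 12)),
            myo_mask=p.region_mask(1), blood_mask=p.region_mask(2),
        )
        basal = summary.table[summary.table.segment <= 6]
        assert (basal.n_voxels == 0).all()
        assert basal.mean_t1.isna().all()

    def test_invalid_insertion_angle_rejected(self, ring):
        p, t1 = ring
        with pytest.raises(DataError):
            aha_summary(
                t1map_from(t1), lv_center=(23.5, 23.5), rv_insertion_angle=400.0,
                slice_bands=((0, 4), (4, 8), (8, 12)),
                myo_mask=p.region_mask(1), blood_mask=p.region_mask(2),
            )
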