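"""Spatial-coding metrics against hand-computed and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import opmplace as op
from opmplace.metrics import ComPoint

from conftest import make_rate_map, random_masked_map


def occupancy_from(dwell, bin_size=2.0):
    dwell = np.asarray(dwell, dtype=float)
    n = dwell.shape[0]
    return op.OccupancyMap(
        dwell=dwell,
        grid=op.GridSpec(side_length=n * bin_size, bin_size=bin_size),
        total_duration=float(dwell.sum()),
    )


def si_oracle(rates, probs):
    """Plain-Python Skaggs summation (bits/s, bits/spike)."""
    F = sum(p * f for p, f in zip(probs, rates))
    bps = sum(p * f * math.log2(f / F) for p, f in zip(probs, rates) if f > 0)
    return bps, bps / F


class TestRateSummary:
    def test_constant_map(self):
        rmap = make_rate_map(np.full((4, 4), 4.0))
        occ = occupancy_from(np.ones((4, 4)))
        s = op.summarize_rates(rmap, occ)
        assert s.peak_rate == 4.0 and s.mean_rate == pytest.approx(4.0)

    def test_single_active_pixel_uniform_occupancy(self):
        rate = np.zeros((2, 2))
        rate[0, 0] = 8.0
        s = op.summarize_rates(make_rate_map(rate), occupancy_from(np.ones((2, 2))))
        assert s.peak_rate == 8.0 and s.mean_rate == pytest.approx(2.0)

    def test_matches_loop_oracle_on_random_maps(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            rmap = random_masked_map(rng)
            occ = occupancy_from(rmap.dwell)
            s = op.summarize_rates(rmap, occ)
            total = rmap.dwell[rmap.valid].sum()
            mean = sum(
                rmap.dwell[i, j] / total * rmap.rate[i, j]
                for i, j in zip(*np.nonzero(rmap.valid))
            )
            assert s.mean_rate == pytest.approx(mean, rel=1e-12)
            assert s.peak_rate == np.nanmax(rmap.rate)


class TestSpatialInformation:
    def test_uniform_map_has_zero_information(self):
        rmap = make_rate_map(np.full((5, 5), 2.0))
        si = op.spatial_information(rmap, occupancy_from(np.random.default_rng(0).uniform(0.5, 2, (5, 5))))
        assert si.bits_per_spike == pytest.approx(0.0, abs=1e-12)

    def test_single_pixel_firing_four_pixels(self):
        """One of four equi-occupied pixels firing at 8 Hz: 4 bits/s, 2 bits/spike."""
        rate = np.zeros((2, 2))
        rate[0, 0] = 8.0
        si = op.spatial_information(make_rate_map(rate), occupancy_from(np.ones((2, 2))))
        assert si.bits_per_second == pytest.approx(4.0)
        assert si.bits_per_spike == pytest.approx(2.0)

    def test_three_pixel_hand_computation(self):
        """Occupancy (0.5, 0.25, 0.25), rates (1, 2, 4): F=2, 0.5 bits/s, 0.25 bits/spike."""
        rate = np.array([[1.0, 2.0], [4.0, 0.0]])
        valid = np.array([[True, True], [True, False]])
        dwell = np.array([[2.0, 1.0], [1.0, 0.0]])
        si = op.spatial_information(make_rate_map(rate, valid), occupancy_from(dwell))
        assert si.bits_per_second == pytest.approx(0.5)
        assert si.bits_per_spike == pytest.approx(0.25)

    def test_silent_unit_is_error(self):
        rmap = make_rate_map(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="silent"):
            op.spatial_information(rmap, occupancy_from(np.ones((3, 3))))

    def test_matches_loop_oracle_and_is_nonnegative(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            rmap = random_masked_map(rng)
            occ = occupancy_from(rmap.dwell)
            si = op.spatial_information(rmap, occ)
            total = rmap.dwell[rmap.valid].sum()
            probs = [rmap.dwell[i, j] / total for i, j in zip(*np.nonzero(rmap.valid))]
            rates = [rmap.rate[i, j] for i, j in zip(*np.nonzero(rmap.valid))]
            bps, bpsk = si_oracle(rates, probs)
            assert si.bits_per_second == pytest.approx(bps, rel=1e-9, abs=1e-12)
            assert si.bits_per_spike == pytest.approx(bpsk, rel=1e-9, abs=1e-12)
            assert si.bits_per_spike >= -1e-12  # scaled KL divergence

    def test_zero_only_for_constant_rate(self):
        rate = np.full((4, 4), 3.0)
        rate[0, 0] = 3.0001
        si = op.spatial_information(make_rate_map(rate), occupancy_from(np.ones((4, 4))))
        assert si.bits_per_spike > 0


class TestPlaceField:
    def test_three_by_three_block(self):
        rate = np.zeros((20, 20))
        rate[5:8, 5:8] = 10.0
        field = op.detect_place_field(make_rate_map(rate))
        assert field is not None
        assert field.n_pixels == 9
        assert field.size_cm2 == pytest.approx(36.0)

    def test_six_pixel_blob_rejected(self):
        rate = np.zeros((20, 20))
        rate[5:7, 5:8] = 10.0  # 6 pixels < 8 minimum
        assert op.detect_place_field(make_rate_map(rate)) is None

    def test_secondary_blob_discarded(self):
        rate = np.zeros((20, 20))
        rate[2:5, 2:5] = 10.0  # contains the peak
        rate[12:15, 12:15] = 8.0  # elevated but peak-free
        field = op.detect_place_field(make_rate_map(rate))
        assert field is not None
        assert field.pixels == frozenset((i, j) for i in range(2, 5) for j in range(2, 5))

    def test_threshold_is_ten_percent_inclusive(self):
        rate = np.zeros((20, 20))
        rate[5:8, 5:8] = 1.0  # exactly 10% of the 10-Hz peak
        rate[6, 6] = 10.0
        field = op.detect_place_field(make_rate_map(rate))
        assert field is not None and field.n_pixels == 9

    def test_diagonal_pixels_not_contiguous(self):
        rate = np.zeros((20, 20))
        for k in range(8):  # 8 suprathreshold pixels, but only diagonally touching
            rate[2 + k, 2 + k] = 10.0
        assert op.detect_place_field(make_rate_map(rate)) is None

    def test_all_zero_map_returns_none(self):
        assert op.detect_place_field(make_rate_map(np.zeros((20, 20)))) is None

    def test_size_invariant_to_positive_scaling(self):
        rng = np.random.default_rng(23)
        rate = rng.uniform(0, 10, (20, 20))
        f1 = op.detect_place_field(make_rate_map(rate))
        f2 = op.detect_place_field(make_rate_map(rate * 7.3))
        assert (f1 is None) == (f2 is None)
        if f1 is not None:
            assert f1.pixels == f2.pixels

    def test_matches_exhaustive_component_search(self):
        """Field detection equals a brute-force BFS over suprathreshold pixels."""
        rng = np.random.default_rng(31)
        for _ in range(200):
            rmap = random_masked_map(rng)
            rates = np.where(rmap.valid, rmap.rate, -np.inf)
            peak_px = np.unravel_index(np.argmax(rates), rates.shape)
            thr = 0.1 * rates[peak_px]
            supra = rmap.valid & (np.nan_to_num(rmap.rate, nan=-1) >= thr)
            # BFS from the peak pixel over edge neighbours
            seen = {peak_px}
            frontier = [peak_px]
            while frontier:
                i, j = frontier.pop()
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    q = (i + di, j + dj)
                    if (
                        0 <= q[0] < 20 and 0 <= q[1] < 20
                        and q not in seen and supra[q]
                    ):
                        seen.add(q)
                        frontier.append(q)
            expected = frozenset(seen) if len(seen) >= 8 else None
            field = op.detect_place_field(rmap)
            if expected is None:
                assert field is None
            else:
                assert field is not None and field.pixels == expected


class TestCenterOfMass:
    def test_single_active_pixel(self):
        rate = np.zeros((20, 20))
        rate[3, 7] = 5.0  # pixel center x=15, y=7
        com = op.center_of_mass(make_rate_map(rate))
        assert (com.x, com.y) == (15.0, 7.0)

    def test_two_pixel_weighted_mean(self):
        rate = np.zeros((20, 20))
        rate[0, 0] = 1.0  # x center 1
        rate[0, 1] = 3.0  # x center 3
        com = op.center_of_mass(make_rate_map(rate))
        assert com.x == pytest.approx(2.5)
        assert com.y == pytest.approx(1.0)

    def test_symmetric_field_com_at_center(self, long_trajectory):
        spec = op.TuningSpec(center=(10, 10), width_sigma=4, peak_rate=12)
        spikes = op.simulate_spikes(spec, long_trajectory, seed=7)
        grid = op.GridSpec()
        occ = op.bin_occupancy(long_trajectory, grid)
        smap = op.smooth_rate_map(
            op.compute_rate_map(occ, op.bin_spikes(spikes, long_trajectory, grid))
        )
        com = op.center_of_mass(smap, scope="field-restricted")
        assert math.hypot(com.x - 10, com.y - 10) < 1.0

    def test_zero_rate_scope_is_error(self):
        with pytest.raises(ValueError, match="zero total rate"):
            op.center_of_mass(make_rate_map(np.zeros((20, 20))))

    def test_matches_weighted_mean_oracle(self):
        rng = np.random.default_rng(41)
        for _ in range(100):
            rmap = random_masked_map(rng)
            com = op.center_of_mass(rmap)
            xs = ys = ws = 0.0
            for i, j in zip(*np.nonzero(rmap.valid)):
                w = rmap.rate[i, j]
                ws += w
                xs += w * (j + 0.5) * 2.0
                ys += w * (i + 0.5) * 2.0
            assert com.x == pytest.approx(xs / ws, rel=1e-12)
            assert com.y == pytest.approx(ys / ws, rel=1e-12)


class TestComShift:
    def test_identical_maps_zero_shift(self):
        rng = np.random.default_rng(2)
        rmap = random_masked_map(rng)
        shift = op.com_shift(rmap, rmap, scope="full-map")
        assert shift["distance"] == pytest.approx(0.0, abs=1e-12)

    def test_pixel_translation_recovered_exactly(self):
        rate = np.zeros((20, 20))
        rate[4:7, 4:7] = 8.0
        a = make_rate_map(rate)
        moved = np.zeros((20, 20))
        moved[6:9, 7:10] = 8.0  # +2 rows, +3 cols = (dx, dy) = (6, 4) cm
        shift = op.com_shift(a, make_rate_map(moved), scope="full-map")
        assert shift["vector"] == pytest.approx((6.0, 4.0))
        assert shift["distance"] == pytest.approx(math.hypot(6, 4))

    def test_vector_norm_and_components(self):
        com_a = ComPoint(10.0, 10.0, "full-map")
        com_b = ComPoint(13.0, 14.0, "full-map")
        assert com_a.distance_to(com_b) == pytest.approx(5.0)

    def test_matches_independent_coms(self):
        rng = np.random.default_rng(9)
        a, b = random_masked_map(rng), random_masked_map(rng)
        mask = a.valid & b.valid
        if not mask.any():
            pytest.skip("random masks disjoint")
        shift = op.com_shift(a, b, scope="full-map")
        ca = op.center_of_mass(a.masked(mask))
        cb = op.center_of_mass(b.masked(mask))
        assert shift["distance"] == pytest.approx(ca.distance_to(cb), rel=1e-12)


class TestSimilarity:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(3)
        rmap = random_masked_map(rng)
        assert op.similarity_score(rmap, rmap).r == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        rmap = random_masked_map(rng)
        other = make_rate_map(np.nan_to_num(rmap.rate, nan=0) * 2 + 1, rmap.valid)
        assert op.similarity_score(rmap, other).r == pytest.approx(1.0)

    def test_negation_gives_minus_one(self):
        rng = np.random.default_rng(5)
        rmap = random_masked_map(rng)
        neg = make_rate_map(-np.nan_to_num(rmap.rate, nan=0), rmap.valid)
        assert op.similarity_score(rmap, neg).r == pytest.approx(-1.0)

    def test_constant_map_not_computable(self):
        a = make_rate_map(np.ones((20, 20)))
        b = make_rate_map(np.random.default_rng(0).uniform(0, 1, (20, 20)))
        res = op.similarity_score(a, b)
        assert math.isnan(res.r) and "constant" in res.reason


class TestObjectProximity:
    def test_nearest_object(self):
        com = ComPoint(10.0, 10.0, "full-map")
        objs = [op.ObjectSpec("a", (10, 30)), op.ObjectSpec("b", (30, 30))]
        res = op.object_proximity(com, objs)
        assert res["label"] == "a" and res["distance"] == pytest.approx(20.0)

    def test_com_at_object_center(self):
        com = ComPoint(30.0, 30.0, "full-map")
        res = op.object_proximity(com, [op.ObjectSpec("a", (30, 30))])
        assert res["distance"] == 0.0

    def test_tie_reports_both_labels(self):
        com = ComPoint(20.0, 20.0, "full-map")
        objs = [op.ObjectSpec("a", (10, 10)), op.ObjectSpec("b", (30, 30))]
        res = op.object_proximity(com, objs)
        assert set(res["labels"]) == {"a", "b"}
        assert res["distance"] == pytest.approx(10 * math.sqrt(2))

    def test_empty_layout_is_error(self):
        with pytest.raises(ValueError):
            op.object_proximity(ComPoint(1, 1, "full-map"), [])


class TestUnitScreen:
    @pytest.mark.parametrize(
        "width,gap,expected",
        [
            (250.0, True, "putative_pyramidal"),  # boundary inclusive
            (320.0, True, "putative_pyramidal"),
            (200.0, True, "putative_interneuron"),
            (300.0, False, "rejected"),
            (None, True, "rejected"),
        ],
    )
    def test_screen(self, width, gap, expected):
        assert op.screen_unit(width, gap) == expected

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            op.screen_unit(-10.0, True)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(scale=st.floats(0.1, 50.0), data=st.integers(0, 2**31 - 1))
def test_field_and_si_scale_behaviour(scale, data):
    """Field pixel set is scale-invariant; SI bits/spike too (F cancels)."""
    rng = np.random.default_rng(data)
    rate = rng.uniform(0, 10, (10, 10))
    occ = occupancy_from(rng.uniform(0.2, 1.0, (10, 10)))
    a = make_rate_map(rate)
    b = make_rate_map(rate * scale)
    fa, fb = op.detect_place_field(a), op.detect_place_field(b)
    assert (fa is None) == (fb is None)
    if fa is not None:
        assert fa.pixels == fb.pixels
    sia = op.spatial_information(a, occ)
    sib = op.spatial_information(b, occ)
    assert sib.bits_per_spike == pytest.approx(sia.bits_per_spike, rel=1e-9)
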