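"""Core prefix-sum index: worked examples, oracles, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prefixome.sparse import (
    DataSpace,
    PointRecord,
    RectRecord,
    build_point_index,
    build_rect_index,
    choose_box_count,
    load_index,
    predict_index_size,
    rect_space,
    save_index,
)


@pytest.fixture(scope="module")
def worked_example():
    """Genome of size 8 with interactions at {1, 3, 3, 7}."""
    return build_point_index([(1,), (3,), (3,), (7,)], DataSpace((8,)))


class TestWorkedExample:
    def test_prefix_at_position_6_is_3(self, worked_example):
        assert worked_example.prefix_at((6,)) == 3

    def test_bin_2_to_6_counts_2_by_prefix_difference(self, worked_example):
        idx = worked_example
        assert idx.prefix_at((6,)) - idx.prefix_at((2,)) == 2
        assert idx.range_count((3,), (6,)) == 2

    def test_total_and_below_everything(self, worked_example):
        assert worked_example.total == 4
        assert worked_example.prefix_at((-1,)) == 0
        assert worked_example.prefix_at((7,)) == 4

    def test_clamping_beyond_extent(self, worked_example):
        assert worked_example.prefix_at((100,)) == 4


class TestBuildValidation:
    def test_point_outside_space_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            build_point_index([(9,)], DataSpace((8,)))

    def test_zero_dimensional_space_rejected(self):
        with pytest.raises(ValueError):
            DataSpace(())

    def test_empty_index_all_queries_zero(self):
        idx = build_point_index([], DataSpace((10, 10)), 2)
        assert idx.total == 0
        assert idx.range_count((0, 0), (9, 9)) == 0

    def test_multiplicity(self):
        idx = build_point_index([PointRecord((3,), 5)], DataSpace((8,)))
        assert idx.prefix_at((3,)) == 5


@pytest.mark.parametrize("d,extent,n", [(1, 64, 300), (2, 24, 300), (3, 10, 250),
                                        (4, 7, 200), (5, 5, 200)])
def test_point_oracle_and_grid_independence(d, extent, n):
    """range_count equals brute force for any box grid, d = 1..5."""
    rng = np.random.default_rng(d)
    pts = rng.integers(0, extent, size=(n, d))
    space = DataSpace((extent,) * d)
    indices = [build_point_index(pts, space, b) for b in (1, 2, 3)]
    for _ in range(100):
        lo = rng.integers(0, extent, size=d)
        hi = rng.integers(0, extent, size=d)
        lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
        truth = int(np.all((pts >= lo) & (pts <= hi), axis=1).sum())
        for idx in indices:
            assert idx.range_count(lo, hi) == truth


def test_prefix_monotone_along_every_axis():
    rng = np.random.default_rng(7)
    pts = rng.integers(0, 12, size=(150, 3))
    idx = build_point_index(pts, DataSpace((12, 12, 12)), (2, 3, 1))
    base = rng.integers(0, 12, size=(40, 3))
    for q in base:
        v = idx.prefix_at(q)
        for j in range(3):
            if q[j] + 1 < 12:
                q2 = q.copy()
                q2[j] += 1
                assert idx.prefix_at(q2) >= v


def test_disjoint_tiling_conserves_total():
    rng = np.random.default_rng(3)
    pts = rng.integers(0, 30, size=(400, 2))
    idx = build_point_index(pts, DataSpace((30, 30)), 2)
    total = 0
    for x0 in range(0, 30, 10):
        for y0 in range(0, 30, 10):
            total += idx.range_count((x0, y0), (x0 + 9, y0 + 9))
    assert total == idx.total == 400


class TestLookupCounter:
    def test_range_count_uses_at_most_2_to_the_d(self):
        rng = np.random.default_rng(0)
        pts = rng.integers(0, 16, size=(100, 3))
        idx = build_point_index(pts, DataSpace((16, 16, 16)), 2)
        idx.reset_lookups()
        idx.range_count((1, 2, 3), (10, 11, 12))
        assert idx.lookups <= 8

    def test_inverted_filter_query_is_4_lookups(self):
        """Quality filtering via an inverted axis touches only the top face."""
        rng = np.random.default_rng(1)
        n = 400
        xy = rng.integers(0, 20, size=(n, 2))
        mapq = rng.integers(0, 64, size=n)
        inv = np.column_stack([xy, 255 - mapq])
        idx = build_point_index(inv, DataSpace((20, 20, 256), (False, False, True)), (2, 2, 1))
        naive = build_point_index(np.column_stack([xy, mapq]), DataSpace((20, 20, 256)), (2, 2, 1))
        for _ in range(50):
            lo = rng.integers(1, 20, size=2)
            hi = rng.integers(1, 20, size=2)
            lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
            q = int(rng.integers(1, 64))
            idx.reset_lookups()
            kept = idx.range_count_filtered(lo, hi, (255 - q,))
            assert idx.lookups == 4
            naive.reset_lookups()
            assert naive.range_count((*lo, q), (*hi, 255)) == kept
            assert naive.lookups == 8

    def test_filter_bound_on_non_inverted_axis_rejected(self):
        idx = build_point_index([(1, 1, 1)], DataSpace((4, 4, 4)))
        with pytest.raises(ValueError, match="inverted"):
            idx.range_count_filtered((0, 0), (3, 3), (3,))

    def test_excluding_all_qualities_gives_zero(self):
        idx = build_point_index([(1, 1, 255)], DataSpace((4, 4, 256), (False, False, True)))
        assert idx.range_count((0, 0, 0), (3, 3, 254)) == 0


class TestRectangles:
    def test_interval_examples(self):
        """Intervals {[2,4],[1,6],[5,5]} against bin [2,5]."""
        sp = rect_space((8,))
        idx = build_rect_index(
            [RectRecord((2,), (4,)), RectRecord((1,), (6,)), RectRecord((5,), (5,))], sp
        )
        assert idx.count_enclosed((2,), (5,)) == 2  # [1,6] crosses the edge
        assert idx.count_overlapping((2,), (5,)) == 3

    def test_interval_wider_than_bin_filtered_out(self):
        idx = build_rect_index([RectRecord((0,), (7,))], rect_space((8,)))
        assert idx.count_enclosed((2,), (5,)) == 0
        assert idx.count_overlapping((2,), (5,)) == 1

    def test_degenerate_rectangle_behaves_as_point(self):
        idx = build_rect_index([RectRecord((3, 4), (3, 4))], rect_space((8, 8)))
        assert idx.count_enclosed((3, 4), (3, 4)) == 1
        assert idx.count_enclosed((0, 0), (7, 7)) == 1
        assert idx.count_overlapping((3, 0), (3, 7)) == 1

    @pytest.mark.parametrize("boxes", [1, (2, 2, 1, 1)])
    def test_2d_oracle(self, boxes):
        rng = np.random.default_rng(5)
        E = 16
        lows = rng.integers(0, E, size=(300, 2))
        spans = rng.integers(0, 6, size=(300, 2))
        highs = np.minimum(lows + spans, E - 1)
        idx = build_rect_index(
            [RectRecord(tuple(l), tuple(h)) for l, h in zip(lows, highs)],
            rect_space((E, E)), boxes,
        )
        for _ in range(100):
            a = rng.integers(0, E, size=2)
            b = rng.integers(0, E, size=2)
            a, b = np.minimum(a, b), np.maximum(a, b)
            enc = int((np.all(lows >= a, axis=1) & np.all(highs <= b, axis=1)).sum())
            ov = int((np.all(lows <= b, axis=1) & np.all(highs >= a, axis=1)).sum())
            assert idx.count_enclosed(a, b) == enc
            assert idx.count_overlapping(a, b) == ov

    def test_full_space_overlap_returns_total(self):
        rng = np.random.default_rng(9)
        lows = rng.integers(0, 10, size=(50, 2))
        highs = np.minimum(lows + rng.integers(0, 4, size=(50, 2)), 9)
        idx = build_rect_index(
            [RectRecord(tuple(l), tuple(h)) for l, h in zip(lows, highs)],
            rect_space((10, 10)),
        )
        assert idx.count_overlapping((0, 0), (9, 9)) == idx.total == 50

    def test_filtered_rect_oracle(self):
        """Joint mapq range + annotation flag filters match brute force."""
        rng = np.random.default_rng(13)
        E, n = 12, 200
        lows = rng.integers(0, E, size=(n, 2))
        highs = np.minimum(lows + rng.integers(0, 4, size=(n, 2)), E - 1)
        mq = rng.integers(0, 60, size=n)
        flag = rng.integers(0, 2, size=n)
        idx = build_rect_index(
            [RectRecord(tuple(l), tuple(h), (255 - q, f))
             for l, h, q, f in zip(lows, highs, mq, flag)],
            rect_space((E, E), (256, 2), (True, False)),
        )
        for _ in range(60):
            a = rng.integers(0, E, size=2)
            b = rng.integers(0, E, size=2)
            a, b = np.minimum(a, b), np.maximum(a, b)
            qmin = int(rng.integers(0, 60))
            franges = [(0, 255 - qmin), (1, 1)]
            keep = (mq >= qmin) & (flag == 1)
            enc = int((np.all(lows >= a, axis=1) & np.all(highs <= b, axis=1) & keep).sum())
            assert idx.count_enclosed(a, b, franges) == enc


class TestSizePrediction:
    def test_exhaustive_probing_is_exact(self):
        rng = np.random.default_rng(2)
        pts = rng.integers(0, 40, size=(200, 2))
        space = DataSpace((40, 40))
        idx = build_point_index(pts, space, 4)
        est = predict_index_size(pts, space, 4, n_probes=10**6, seed=0)
        assert est == idx.materialized_size_bytes()

    def test_two_seeds_agree_within_20_percent(self):
        rng = np.random.default_rng(4)
        pts = rng.integers(0, 128, size=(2000, 2))
        space = DataSpace((128, 128))
        a = predict_index_size(pts, space, 16, n_probes=40, seed=1)
        b = predict_index_size(pts, space, 16, n_probes=40, seed=2)
        assert abs(a - b) / max(a, b) < 0.20

    def test_empty_data_costs_lut_overhead_only(self):
        space = DataSpace((64,))
        est = predict_index_size(np.empty((0, 1), dtype=np.int64), space, 4, seed=0)
        idx = build_point_index([], space, 4)
        assert est == idx.materialized_size_bytes()

    def test_single_candidate_returned(self):
        pts = np.array([[1, 1]])
        assert choose_box_count(pts, DataSpace((8, 8)), [3]) == 3

    def test_diagonal_data_benefits_from_boxes(self):
        diag = np.column_stack([np.arange(128), np.arange(128)])
        space = DataSpace((128, 128))
        best = choose_box_count(diag, space, [1, 2, 4, 8, 16], seed=0)
        size_best = build_point_index(diag, space, best).materialized_size_bytes()
        size_one = build_point_index(diag, space, 1).materialized_size_bytes()
        assert size_best <= size_one

    def test_predicted_minimum_close_to_true_minimum(self):
        """On clustered data the probe-predicted optimum is near-optimal."""
        rng = np.random.default_rng(8)
        centers = rng.integers(10, 110, size=(6, 2))
        pts = np.clip(
            centers[rng.integers(0, 6, 600)] + rng.normal(0, 3, size=(600, 2)).astype(int),
            0, 119,
        )
        space = DataSpace((120, 120))
        cands = [1, 2, 4, 8]
        actual = {c: build_point_index(pts, space, c).materialized_size_bytes() for c in cands}
        best_pred = choose_box_count(pts, space, cands, n_probes=20, seed=0)
        assert actual[best_pred] <= 1.25 * min(actual.values())


def test_save_load_round_trip(tmp_path):
    import h5py

    rng = np.random.default_rng(6)
    pts = rng.integers(0, 20, size=(150, 3))
    idx = build_point_index(pts, DataSpace((20, 20, 20)), (2, 1, 2))
    path = tmp_path / "idx.h5"
    with h5py.File(path, "w") as f:
        save_index(idx, f.create_group("i"))
    with h5py.File(path) as f:
        loaded = load_index(f["i"])
    for _ in range(80):
        q = rng.integers(-1, 20, size=3)
        assert loaded.prefix_at(q) == idx.prefix_at(q)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    st.lists(st.tuples(st.integers(0, 15), st.integers(0, 15)), min_size=0, max_size=40),
    st.integers(1, 3),
)
def test_property_full_space_query_equals_total(points, boxes):
    idx = build_point_index(
        [PointRecord(p) for p in points], DataSpace((16, 16)), boxes
    )
    assert idx.range_count((0, 0), (15, 15)) == len(points)
    assert idx.prefix_at((-1, 5)) == 0
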