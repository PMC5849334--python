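import numpy as np
import pandas as pd
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from sklearn.metrics import adjusted_rand_score

from conftest import make_group, make_peaks
from nmrpeaks.grouping import (
    GroupingParams,
    enforce_single_peak,
    gower_distance,
    group_peaks,
    groups_from_frame,
    groups_to_frame,
)


def brute_gower(x):
    x = np.asarray(x, float)
    n, v = x.shape
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            acc = 0.0
            for k in range(v):
                rng = x[:, k].max() - x[:, k].min()
                if rng > 0:
                    acc += abs(x[i, k] - x[j, k]) / rng
            d[i, j] = acc / v
    return d


class TestGower:
    def test_identical_points_distance_zero(self):
        d = gower_distance(pd.DataFrame({"ppm": [1.0, 1.0], "snr": [5.0, 5.0]}))
        np.testing.assert_array_equal(d, 0.0)

    def test_range_normalization_forces_extremes_to_one(self):
        d = gower_distance(pd.DataFrame({"ppm": [0.0, 10.0]}))
        assert d[0, 1] == 1.0

    def test_matches_brute_force_oracle(self):
        pts = pd.DataFrame({"ppm": [1.0, 2.0, 3.0], "snr": [5.0, 5.0, 9.0]})
        np.testing.assert_allclose(gower_distance(pts), brute_gower(pts), atol=1e-15)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(arrays(float, (6, 3), elements=st.floats(-100, 100)))
    def test_symmetry_bounds_and_oracle_on_random_tables(self, x):
        d = gower_distance(pd.DataFrame(x))
        np.testing.assert_allclose(d, d.T, atol=1e-12)
        assert np.all(d >= 0) and np.all(d <= 1 + 1e-12)
        np.testing.assert_allclose(d, brute_gower(x), atol=1e-12)


class TestEnforceSinglePeak:
    def test_clean_group_unchanged(self):
        g = make_group(0, [("a", 100), ("b", 101)])
        out = enforce_single_peak(g)
        assert out.n_members == 2 and len(out.deleted) == 0

    def test_keeps_peak_nearest_group_median(self):
        g = make_group(0, [("a", 100), ("a", 108), ("b", 101), ("c", 101), ("d", 102)])
        out = enforce_single_peak(g)
        kept = out.members.loc[out.members.sample_id == "a", "peak_index"].item()
        assert kept == 100
        assert out.deleted["peak_index"].tolist() == [108]

    def test_equidistant_tie_broken_by_larger_value(self):
        # median of {98, 102, 100, 100} = 100; a's peaks both 2 away
        g = make_group(0, [("a", 98, 5.0), ("a", 102, 9.0), ("b", 100), ("c", 100)])
        out = enforce_single_peak(g)
        kept = out.members.loc[out.members.sample_id == "a"]
        assert kept["peak_index"].item() == 102 and kept["peak_value"].item() == 9.0


class TestGroupPeaks:
    def test_coincident_peaks_form_one_group(self):
        res = group_peaks(make_peaks([(f"s{i}", 500) for i in range(5)]))
        assert len(res.groups) == 1 and res.groups[0].n_members == 5

    def test_two_planted_resonances_recovered(self, rng):
        rows = []
        for c in (1000, 1100):
            for i in range(20):
                rows.append((f"s{i}", c + rng.integers(-3, 4)))
        res = group_peaks(make_peaks(rows), GroupingParams(max_group_span=20))
        assert len(res.groups) == 2
        for g, c in zip(res.groups, (1000, 1100)):
            assert g.n_members == 20
            assert abs(g.center_index - c) <= 3

    def test_adjusted_rand_index_one_under_small_jitter(self, rng):
        """Jitter below half the minimum inter-resonance gap: exact recovery."""
        centers = np.arange(500, 2000, 100)  # gap 100, jitter within +-4
        rows, truth = [], []
        for k, c in enumerate(centers):
            for i in range(20):
                rows.append((f"s{i}", c + rng.integers(-4, 5)))
                truth.append(k)
        res = group_peaks(make_peaks(rows), GroupingParams(max_group_span=10))
        flat = groups_to_frame(res.groups).sort_values(["peak_index", "sample_id"])
        df = make_peaks(rows).assign(truth=truth).sort_values(["peak_index", "sample_id"])
        assert adjusted_rand_score(df["truth"], flat["feature_id"]) == 1.0

    def test_matches_sort_and_cut_oracle_when_shifts_small(self, rng):
        rows = []
        for c in (300, 420, 560, 800):
            for i in range(10):
                rows.append((f"s{i}", c + rng.integers(-2, 3)))
        peaks = make_peaks(rows)
        res = group_peaks(peaks)
        # oracle: sort by index, cut where the gap exceeds the span limit
        idx = np.sort(peaks["peak_index"].to_numpy())
        oracle_labels = np.concatenate([[0], np.cumsum(np.diff(idx) > 10)])
        flat = groups_to_frame(res.groups).sort_values("peak_index")
        assert adjusted_rand_score(oracle_labels, flat["feature_id"]) == 1.0

    def test_partition_covers_input_exactly_once(self, rng):
        rows = [(f"s{i % 7}", int(rng.integers(100, 400))) for i in range(60)]
        peaks = make_peaks(rows)
        res = group_peaks(peaks, GroupingParams(min_samples=2))
        flat = pd.concat([groups_to_frame(res.groups)[peaks.columns], res.dropped[peaks.columns]])
        key = ["sample_id", "peak_index", "peak_value"]
        left = peaks.sort_values(key).reset_index(drop=True)
        right = flat.sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(left, right.astype(left.dtypes.to_dict()))

    def test_order_invariance(self, rng):
        rows = [(f"s{i % 5}", int(rng.integers(100, 300))) for i in range(40)]
        peaks = make_peaks(rows)
        shuffled = peaks.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = groups_to_frame(group_peaks(peaks).groups)
        b = groups_to_frame(group_peaks(shuffled).groups)
        key = ["feature_id", "sample_id", "peak_index"]
        pd.testing.assert_frame_equal(
            a.sort_values(key).reset_index(drop=True),
            b.sort_values(key).reset_index(drop=True),
        )

    def test_group_spans_bounded(self, rng):
        rows = [(f"s{i % 9}", int(rng.integers(0, 500))) for i in range(200)]
        res = group_peaks(make_peaks(rows), GroupingParams(max_group_span=10))
        for g in res.groups:
            assert g.span <= 10

    def test_round_trip_through_flat_frame(self, sim_groups):
        flat = groups_to_frame(sim_groups)
        back = groups_from_frame(flat)
        assert [g.center_index for g in back] == [g.center_index for g in sim_groups]
        assert [g.n_members for g in back] == [g.n_members for g in sim_groups]
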