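from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import thermoapos as ta
from thermoapos import granulation as gr
from thermoapos.errors import DegenerateROIError, ParameterError, ThermoAposError


class TestKSelection:
    def test_background_forces_k4(self):
        assert ta.select_k(np.array([0.0, 30.1, 33.2])) == 4

    def test_no_background_k3(self):
        assert ta.select_k(np.array([29.5, 31.0, 33.0])) == 3

    def test_all_zero_roi_degenerates_downstream(self):
        vals = np.zeros(3)
        assert ta.select_k(vals) == 4
        with pytest.raises(DegenerateROIError):
            ta.init_centers(vals, 4)


class TestInitCenters:
    def test_k4_order_statistics(self):
        centers = ta.init_centers(np.array([0.0, 28.0, 30.0, 34.0]), 4)
        assert centers == pytest.approx((0.0, 28.0, 92.0 / 3.0, 34.0))

    def test_k3_order_statistics(self):
        centers = ta.init_centers(np.array([28.0, 30.0, 34.0]), 3)
        assert centers == pytest.approx((28.0, 92.0 / 3.0, 34.0))

    def test_invalid_k(self):
        with pytest.raises(ParameterError):
            ta.init_centers(np.array([1.0, 2.0]), 2)


def contiguous_partition_oracle(values, k):
    """Exhaustive 1-D clustering oracle: the globally SSE-optimal partition
    of the sorted values into k contiguous blocks (optimal clusters in 1-D
    are contiguous). Returns the sorted block means of nonempty blocks."""
    x = np.sort(np.asarray(values, float))
    n = len(x)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    csq = np.concatenate(([0.0], np.cumsum(x**2)))

    def sse(i, j):  # block x[i:j]
        if j <= i:
            return 0.0
        s = csum[j] - csum[i]
        return (csq[j] - csq[i]) - s * s / (j - i)

    best, best_cuts = np.inf, None
    for cuts in combinations(range(1, n), k - 1):
        bounds = (0, *cuts, n)
        total = sum(sse(bounds[t], bounds[t + 1]) for t in range(k))
        if total < best - 1e-12:
            best, best_cuts = total, bounds
    means = [
        (csum[best_cuts[t + 1]] - csum[best_cuts[t]]) / (best_cuts[t + 1] - best_cuts[t])
        for t in range(k)
        if best_cuts[t + 1] > best_cuts[t]
    ]
    return np.sort(means)


class TestKMeans1D:
    def test_fixed_point_converges_immediately(self):
        vals = np.array([28.0, 28.0, 31.0, 31.0, 34.0, 34.0])
        spec = gr.ClusterSpec(k=3, initial_centers=(28.0, 31.0, 34.0))
        out = ta.kmeans_1d(vals, spec)
        np.testing.assert_allclose(np.sort(out.centers), [28.0, 31.0, 34.0])

    def test_small_vector_cluster_means(self):
        vals = np.array([0.0, 0.0, 27.9, 28.1, 30.0, 33.9, 34.1])
        out = ta.cluster_roi(vals)
        np.testing.assert_allclose(out.nonzero_cluster_means, [28.0, 30.0, 34.0])
        oracle = contiguous_partition_oracle(vals, 4)
        np.testing.assert_allclose(np.sort(out.cluster_means[out.sizes > 0]), oracle)

    def test_bitwise_determinism(self):
        rng = np.random.default_rng(9)
        vals = np.concatenate([np.zeros(10), rng.normal(32, 1.5, 90)])
        a, b = ta.cluster_roi(vals), ta.cluster_roi(vals)
        assert a.centers.tobytes() == b.centers.tobytes()
        assert a.labels.tobytes() == b.labels.tobytes()

    def test_non_finite_rejected(self):
        with pytest.raises(ParameterError):
            ta.kmeans_1d(np.array([1.0, np.nan]), gr.ClusterSpec(2, (0.0, 1.0)))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_partition_oracle(self, seed):
        """On separated clumps (the regime ROIs live in), the deterministic
        Lloyd run reaches the globally optimal contiguous partition."""
        rng = np.random.default_rng(seed)
        with_background = seed % 2 == 0
        if with_background:
            n = 120
            vals = np.concatenate([
                np.zeros(rng.integers(5, 25)),
                rng.normal(28.5, 0.3, 35),
                rng.normal(31.5, 0.3, 35),
                rng.normal(34.5, 0.3, 25),
            ])[:n]
        else:
            vals = np.concatenate([
                rng.normal(28.5, 0.3, 70),
                rng.normal(31.5, 0.3, 70),
                rng.normal(34.5, 0.3, 60),
            ])
        assert vals.size <= 200
        out = ta.cluster_roi(vals)
        k = gr.select_k(vals)
        oracle = contiguous_partition_oracle(vals, k)
        got = np.sort(out.cluster_means[out.sizes > 0])
        np.testing.assert_allclose(got, oracle, atol=1e-8)


class TestGlobalThresholds:
    @staticmethod
    def _outcome(values):
        return ta.cluster_roi(np.asarray(values, float))

    def test_identical_rois(self):
        vals = [28.0, 28.0, 30.0, 30.0, 34.0, 34.0]
        outcomes = {label: self._outcome(vals) for label in gr.ROI_LABELS}
        thr = ta.global_thresholds(outcomes)
        assert thr.tbar_min == pytest.approx(28.0)
        assert thr.tbar_max == pytest.approx(34.0)

    def test_single_distinct_roi_hand_computed(self):
        base = [28.0, 28.0, 30.0, 30.0, 34.0, 34.0]
        outcomes = {label: self._outcome(base) for label in gr.ROI_LABELS}
        outcomes["ROI5"] = self._outcome([26.0, 26.0, 29.0, 29.0, 37.0, 37.0])
        thr = ta.global_thresholds(outcomes)
        assert thr.tbar_min == pytest.approx((17 * 28.0 + 26.0) / 18.0)
        assert thr.tbar_max == pytest.approx((17 * 34.0 + 37.0) / 18.0)

    def test_missing_roi_named(self):
        outcomes = {label: self._outcome([28.0, 30.0, 34.0]) for label in gr.ROI_LABELS}
        del outcomes["ROI7"]
        with pytest.raises(ThermoAposError, match="ROI7"):
            ta.global_thresholds(outcomes)

    @given(st.lists(
        st.lists(st.floats(20.0, 40.0), min_size=3, max_size=12),
        min_size=18, max_size=18,
    ))
    @settings(max_examples=40, deadline=None)
    def test_tbar_min_never_exceeds_tbar_max(self, roi_values):
        outcomes = {}
        for label, vals in zip(gr.ROI_LABELS, roi_values):
            outcomes[label] = self._outcome(vals)
        thr = ta.global_thresholds(outcomes)
        assert thr.tbar_min <= thr.tbar_max + 1e-12


class TestGranulationRule:
    def test_inclusive_boundaries(self):
        out = ta.cluster_roi(np.array([28.0, 28.0, 31.0, 31.0, 34.0, 34.0]))
        thr = gr.GlobalThresholds(tbar_min=28.0, tbar_max=35.0)
        pair = ta.granulate_roi(out, thr)
        assert pair.roi_low == 1  # min(T_roi) == tbar_min counts
        assert pair.roi_high == 0

    def test_identical_body_lights_both_attributes(self):
        vals = [28.0, 28.0, 30.0, 30.0, 34.0, 34.0]
        outcomes = {label: ta.cluster_roi(np.array(vals)) for label in gr.ROI_LABELS}
        thr = ta.global_thresholds(outcomes)
        for label in gr.ROI_LABELS:
            pair = ta.granulate_roi(outcomes[label], thr)
            assert (pair.roi_low, pair.roi_high) == (1, 1)

    def test_interior_roi_gets_neither(self):
        out = ta.cluster_roi(np.array([29.0, 29.0, 31.0, 31.0]))
        np.testing.assert_allclose(out.nonzero_cluster_means[[0, -1]], [29.0, 31.0])
        thr = gr.GlobalThresholds(tbar_min=28.5, tbar_max=33.0)
        pair = ta.granulate_roi(out, thr)
        assert (pair.roi_low, pair.roi_high) == (0, 0)


class TestFormalContext:
    @staticmethod
    def _pairs(bits=(1, 0)):
        return {label: gr.AttributePair(roi_low=bits[1], roi_high=bits[0])
                for label in gr.ROI_LABELS}

    def test_cohort_shape_and_column_order(self):
        ctx = ta.build_formal_context([(f"s{i}", self._pairs()) for i in range(43)])
        assert ctx.shape == (43, 36)
        assert ctx.attributes[:4] == ("ROI1-H", "ROI1-L", "ROI2-H", "ROI2-L")
        assert ctx.attributes[-1] == "ROI18-L"

    def test_single_participant(self):
        ctx = ta.build_formal_context([("only", self._pairs((0, 1)))])
        assert ctx.shape == (1, 36)
        assert ctx.intent("only") == tuple(f"{l}-L" for l in gr.ROI_LABELS)

    def test_missing_roi_rejected(self):
        pairs = self._pairs()
        del pairs["ROI12"]
        with pytest.raises(ThermoAposError, match="ROI12"):
            ta.build_formal_context([("s", pairs)])

    def test_csv_round_trip(self, tmp_path):
        ctx = ta.build_formal_context(
            [("a", self._pairs((1, 0))), ("b", self._pairs((0, 1)))]
        )
        path = tmp_path / "ctx.csv"
        ctx.to_csv(path)
        back = gr.FormalContext.from_csv(path)
        pd.testing.assert_frame_equal(back.table, ctx.table)

    def test_burmeister_export(self, tmp_path):
        ctx = ta.build_formal_context([("a", self._pairs((1, 0)))])
        path = tmp_path / "ctx.cxt"
        ctx.to_burmeister(path)
        lines = path.read_text().splitlines()
        assert lines[0] == "B"
        assert lines[2] == "1" and lines[3] == "36"
        assert lines[-1].count("X") == 18 and lines[-1].count(".") == 18

    def test_non_binary_rejected(self):
        table = pd.DataFrame([[2, 0]], columns=["a", "b"], index=["x"])
        with pytest.raises(ParameterError):
            gr.FormalContext(table)


class TestEndToEndDeterminism:
    def test_whole_subject_granulation_reproducible(self, roiset):
        a = ta.granulate_roiset(roiset)
        b = ta.granulate_roiset(roiset)
        assert a == b
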