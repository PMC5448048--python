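"""RA-CUSUM trace arithmetic, change-point detection, era annotation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alrisk.errors import ConfigurationError, DataError, DomainError
from alrisk.cusum import (
    annotate_eras,
    detect_changepoints,
    ra_cusum_trace,
    segment_summary,
)


class TestTrace:
    def test_leak_at_lowest_reported_risk_moves_up_0_984(self):
        trace = ra_cusum_trace([0.016], [1])
        assert trace.increments[0] == pytest.approx(0.984, abs=1e-12)

    def test_nonleak_at_risk_030_moves_down_by_p(self):
        trace = ra_cusum_trace([0.30], [0])
        assert trace.increments[0] == pytest.approx(-0.30, abs=1e-12)

    def test_final_value_is_leaks_minus_risk_sum(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.01, 0.5, 300)
        x = (rng.random(300) < p).astype(int)
        trace = ra_cusum_trace(p, x)
        assert trace.final_value == pytest.approx(x.sum() - p.sum(), abs=1e-9)

    def test_cumulative_sum_identity_and_bounds(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.01, 0.99, 200)
        x = (rng.random(200) < p).astype(int)
        trace = ra_cusum_trace(p, x)
        assert np.allclose(trace.s, np.cumsum(trace.increments), atol=1e-9)
        assert ((trace.increments > -1) & (trace.increments < 1)).all()

    def test_risk_adjustment_ordering(self):
        """A leak in a low-risk case lifts the curve more than in a high-risk case."""
        low = ra_cusum_trace([0.05], [1]).increments[0]
        high = ra_cusum_trace([0.60], [1]).increments[0]
        assert low > high

    def test_length_mismatch_and_domain_errors(self):
        with pytest.raises(DataError):
            ra_cusum_trace([0.1, 0.2], [1])
        with pytest.raises(DomainError):
            ra_cusum_trace([0.0], [0])
        with pytest.raises(DomainError):
            ra_cusum_trace([0.5], [2])

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_martingale_property_single_trace(self, seed):
        """Outcomes drawn from their own p0: increments have mean zero in
        expectation, so |S_n| stays within 4 sd of its null distribution."""
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.02, 0.3, 400)
        x = (rng.random(400) < p).astype(int)
        trace = ra_cusum_trace(p, x)
        sd = np.sqrt((p * (1 - p)).sum())
        assert abs(trace.final_value) <= 4 * sd


class TestChangePoints:
    def test_noiseless_kink_recovered_exactly(self):
        """Two-slope deterministic trace: increments 0.3 then -0.2, kink at 120."""
        inc = np.concatenate([np.full(120, 0.3), np.full(180, -0.2)])
        p0 = np.full(300, 0.5)
        x = np.zeros(300, dtype=int)
        trace = ra_cusum_trace(p0, x)
        trace.frame["increment"] = inc
        trace.frame["s"] = np.cumsum(inc)
        cps = detect_changepoints(trace, max_segments=4, min_segment_len=30)
        assert cps.indices == (120,)
        assert cps.segment_slopes[0] == pytest.approx(0.3, abs=1e-12)
        assert cps.segment_slopes[1] == pytest.approx(-0.2, abs=1e-12)

    def test_strong_shift_detected(self):
        """Outcome rate jumps 0.1 -> 0.5 at case 250 of 500: detection is easy
        and the knot lands close to the truth."""
        rng = np.random.default_rng(3)
        p0 = np.full(500, 0.1)
        x = (rng.random(500) < np.where(np.arange(500) < 250, 0.1, 0.5)).astype(int)
        cps = detect_changepoints(ra_cusum_trace(p0, x))
        assert len(cps.indices) >= 1
        assert min(abs(i - 250) for i in cps.indices) <= 20

    def test_null_trace_selects_single_segment(self):
        rng = np.random.default_rng(11)
        p0 = rng.uniform(0.05, 0.15, 600)
        x = (rng.random(600) < p0).astype(int)
        cps = detect_changepoints(ra_cusum_trace(p0, x))
        assert cps.indices == ()
        assert cps.n_segments == 1

    def test_infeasible_constraints_rejected(self):
        trace = ra_cusum_trace([0.1] * 40, [0] * 40)
        with pytest.raises(ConfigurationError):
            detect_changepoints(trace, min_segment_len=30)

    def test_segments_partition_the_trace(self):
        rng = np.random.default_rng(5)
        p0 = rng.uniform(0.05, 0.3, 300)
        x = (rng.random(300) < p0).astype(int)
        cps = detect_changepoints(ra_cusum_trace(p0, x))
        segs = cps.segments(300)
        assert segs[0][0] == 1 and segs[-1][1] == 300
        for (a1, b1), (a2, b2) in zip(segs, segs[1:]):
            assert a2 == b1 + 1


class TestEras:
    def test_case_500_carries_first_three_strategies(self):
        trace = ra_cusum_trace([0.1] * 736, [0] * 736)
        ann = annotate_eras(trace, [155, 397, 480, 584], ["A", "B", "C", "D"])
        assert ann.frame.loc[ann.frame["seq"] == 500, "eras"].iloc[0] == "A+B+C"

    def test_case_1_unlabeled_when_starts_later(self):
        trace = ra_cusum_trace([0.1] * 200, [0] * 200)
        ann = annotate_eras(trace, [155], ["A"])
        assert ann.frame.loc[ann.frame["seq"] == 1, "eras"].iloc[0] == ""

    def test_empty_era_list_passthrough(self):
        trace = ra_cusum_trace([0.1] * 50, [0] * 50)
        ann = annotate_eras(trace, [], [])
        assert (ann.frame["eras"] == "").all()
        assert ann.frame.drop(columns="eras").equals(trace.frame)

    def test_out_of_range_start_rejected(self):
        trace = ra_cusum_trace([0.1] * 50, [0] * 50)
        with pytest.raises(DataError):
            annotate_eras(trace, [60], ["A"])


class TestSegmentSummary:
    def test_slope_identity_and_totals(self):
        rng = np.random.default_rng(21)
        p0 = rng.uniform(0.05, 0.3, 400)
        x = (rng.random(400) < np.where(np.arange(400) < 200, p0, np.minimum(3 * p0, 0.9))).astype(int)
        trace = ra_cusum_trace(p0, x)
        cps = detect_changepoints(trace)
        table = segment_summary(trace, cps)
        for _, row in table.iterrows():
            assert row["slope"] == pytest.approx(
                (row["events"] - row["expected_events"]) / row["n_cases"], abs=1e-9
            )
        assert table["n_cases"].sum() == 400
        assert table["events"].sum() == x.sum()

    def test_single_segment_reproduces_whole_trace_totals(self):
        p0 = np.full(100, 0.2)
        x = np.zeros(100, dtype=int)
        x[::10] = 1
        trace = ra_cusum_trace(p0, x)
        cps = detect_changepoints(trace)
        table = segment_summary(trace, cps)
        assert len(table) == 1
        assert table.loc[0, "observed_minus_expected"] == pytest.approx(trace.final_value, abs=1e-9)

    def test_post_shift_slope_exceeds_pre_shift(self):
        rng = np.random.default_rng(2)
        p0 = np.full(400, 0.1)
        x = (rng.random(400) < np.where(np.arange(400) < 200, 0.1, 0.45)).astype(int)
        trace = ra_cusum_trace(p0, x)
        cps = detect_changepoints(trace)
        table = segment_summary(trace, cps)
        assert len(table) >= 2
        assert table["slope"].iloc[-1] > table["slope"].iloc[0]
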