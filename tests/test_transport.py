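import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from axoshed import transport
from axoshed.kymo import Kymograph
from axoshed.transport import (Trace, classify_movement, detect_kymo_objects,
                               link_traces, match_traces, summarize_movement,
                               trace_velocity, traces_to_table)


def make_kymo(ridges, n_t=30, n_s=200, pitch_um=0.2, amp=30.0, noise=0.0,
              seed=0):
    """Ridges: list of (s0_um, v_um_s); Gaussian profiles of width 1.5 px."""
    rng = np.random.default_rng(seed)
    K = np.zeros((n_t, n_s))
    s = np.arange(n_s) * pitch_um
    for s0, v in ridges:
        for t in range(n_t):
            c = s0 + v * t
            K[t] += amp * np.exp(-((s - c) ** 2) / (2 * (1.5 * pitch_um) ** 2))
    if noise:
        K += rng.normal(0, noise, K.shape)
    return Kymograph(K=np.clip(K, 0, None), s_positions_um=s, dt_s=1.0,
                     source="swath_0")


def make_trace(v_um_s, n=30, s0=10.0, dt=1.0, **kw):
    pts = [(t * dt, s0 + v_um_s * t * dt) for t in range(n)]
    tr = Trace(trace_id=0, channel_role="mito", points=pts, **kw)
    tr.net_velocity_um_s = trace_velocity(tr)
    tr.movement_class = classify_movement(tr.net_velocity_um_s)
    return tr


class TestDetection:
    def test_single_ridge_one_peak_per_row(self):
        kg = make_kymo([(10.0, 0.3)])
        peaks = detect_kymo_objects(kg, min_prominence=5.0)
        assert all(len(p) == 1 for p in peaks)
        for t, p in enumerate(peaks):
            assert p[0] == pytest.approx(10.0 + 0.3 * t, abs=0.05)

    def test_blank_kymograph_no_peaks(self):
        kg = Kymograph(K=np.zeros((10, 50)),
                       s_positions_um=np.arange(50) * 0.2, dt_s=1.0)
        peaks = detect_kymo_objects(kg, min_prominence=1.0)
        assert all(len(p) == 0 for p in peaks)

    def test_two_ridges_order_preserved(self):
        kg = make_kymo([(5.0, 0.0), (10.0, 0.0)])
        peaks = detect_kymo_objects(kg, min_prominence=5.0)
        for p in peaks:
            assert len(p) == 2
            assert p[0] < p[1]


class TestLinking:
    def test_single_ridge_single_full_trace(self):
        kg = make_kymo([(10.0, 0.3)])
        peaks = detect_kymo_objects(kg, min_prominence=5.0)
        traces, _ = link_traces(peaks, kg.dt_s)
        assert len(traces) == 1
        assert traces[0].n_frames_observed == 30

    def test_crossing_ridges_resolved_by_velocity(self):
        kg = make_kymo([(5.0, 0.6), (25.0, -0.6)], n_t=40)
        peaks = detect_kymo_objects(kg, min_prominence=5.0)
        traces, _ = link_traces(peaks, kg.dt_s)
        vs = sorted(t.net_velocity_um_s for t in traces)
        assert len(traces) == 2
        assert vs[0] == pytest.approx(-0.6, rel=0.10)
        assert vs[1] == pytest.approx(0.6, rel=0.10)

    def test_dropout_bridged_by_gap_rule(self):
        kg = make_kymo([(10.0, 0.3)])
        peaks = detect_kymo_objects(kg, min_prominence=5.0)
        peaks[15] = np.array([])  # one-frame dropout
        traces, _ = link_traces(peaks, kg.dt_s, max_gap_frames=2)
        assert len(traces) == 1

    def test_short_traces_discarded_and_counted(self):
        peaks = [np.array([5.0])] * 3 + [np.array([])] * 27
        traces, n_discarded = link_traces(peaks, 1.0, min_trace_len=5,
                                          max_gap_frames=1)
        assert traces == [] and n_discarded == 1

    def test_residual_gate_drops_chimeric_tracks(self):
        # a zig-zag of peaks from two hopping objects is not one object
        peaks = [np.array([5.0 + 1.5 * (t % 2)]) for t in range(20)]
        traces, n_discarded = link_traces(peaks, 1.0)
        assert traces == [] and n_discarded >= 1


class TestVelocityAndClass:
    def test_velocity_arithmetic(self):
        tr = Trace(0, "mito", [(0.0, 0.0), (60.0, 6.0)])
        assert trace_velocity(tr) == pytest.approx(0.1)
        tr = Trace(0, "mito", [(0.0, 10.0), (60.0, 10.0)])
        assert trace_velocity(tr) == 0.0

    def test_velocity_errors(self):
        with pytest.raises(ValueError):
            trace_velocity(Trace(0, "mito", [(0.0, 1.0)]))
        with pytest.raises(ValueError, match="duration"):
            trace_velocity(Trace(0, "mito", [(1.0, 1.0), (1.0, 2.0)]))

    @pytest.mark.parametrize("v,expected", [
        (0.1, "anterograde"),       # boundary inclusive: 0.1 is moving
        (-0.1, "retrograde"),
        (-0.099, "stationary"),
        (0.099, "stationary"),
        (0.0, "stationary"),
        (-0.78, "retrograde"),
        (0.63, "anterograde"),
    ])
    def test_boundary_classification(self, v, expected):
        assert classify_movement(v) == expected

    @given(st.floats(-2.0, 2.0, allow_nan=False))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_flip_symmetry(self, v):
        """Mirroring the s axis swaps antero/retro; stationary invariant."""
        swap = {"anterograde": "retrograde", "retrograde": "anterograde",
                "stationary": "stationary"}
        assert classify_movement(-v) == swap[classify_movement(v)]

    @given(st.floats(-2.0, 2.0, allow_nan=False),
           st.floats(0.01, 0.5), st.floats(0.01, 0.5))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_threshold_monotonicity(self, v, th1, th2):
        """Raising the threshold never turns stationary into moving."""
        lo, hi = sorted([th1, th2])
        if classify_movement(v, lo) == "stationary":
            assert classify_movement(v, hi) == "stationary"


class TestSummaries:
    def test_counting_percentages(self):
        traces = ([make_trace(0.0)] * 5 + [make_trace(0.5)] * 3
                  + [make_trace(-0.5)] * 2)
        table = traces_to_table(traces)
        summ = summarize_movement(table)
        row = summ.per_animal.iloc[0]
        assert row["pct_stationary"] == 50.0
        assert row["pct_anterograde"] == 30.0
        assert row["pct_retrograde"] == 20.0

    def test_percentages_sum_to_100_per_animal(self, rng):
        rows = []
        for a in range(4):
            for _ in range(int(rng.integers(3, 30))):
                rows.append({"animal": f"a{a}", "condition": "c",
                             "movement_class": rng.choice(
                                 ["stationary", "anterograde", "retrograde"]),
                             "velocity_um_s": float(rng.normal())})
        summ = summarize_movement(pd.DataFrame(rows))
        total = (summ.per_animal["pct_stationary"]
                 + summ.per_animal["pct_anterograde"]
                 + summ.per_animal["pct_retrograde"])
        np.testing.assert_allclose(total, 100.0, atol=1e-9)

    def test_speeds_over_moving_traces_only_unsigned(self):
        traces = [make_trace(0.0), make_trace(0.6), make_trace(-0.8)]
        summ = summarize_movement(traces_to_table(traces))
        row = summ.per_animal.iloc[0]
        assert row["speed_antero_um_s"] == pytest.approx(0.6)
        assert row["speed_retro_um_s"] == pytest.approx(0.8)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            summarize_movement(pd.DataFrame({"animal": []}))


class TestColoc:
    def test_identical_channels_fully_colocalized(self):
        a = [make_trace(0.0, s0=5.0, source="swath_0"),
             make_trace(0.5, s0=15.0, source="swath_0")]
        b = [make_trace(0.0, s0=5.0, source="swath_0"),
             make_trace(0.5, s0=15.0, source="swath_0")]
        summ = match_traces(a, b)
        per = summ.per_class.set_index("movement_class")
        assert per.loc["stationary", "frac_coloc"] == 1.0
        assert per.loc["anterograde", "frac_coloc"] == 1.0

    def test_empty_partner_channel_zero(self):
        a = [make_trace(0.0, source="swath_0")]
        summ = match_traces(a, [])
        per = summ.per_class.set_index("movement_class")
        assert per.loc["stationary", "frac_coloc"] == 0.0

    def test_distance_criterion_excludes_far_traces(self):
        a = [make_trace(0.0, s0=5.0, source="swath_0")]
        b = [make_trace(0.0, s0=7.0, source="swath_0")]  # 2 um away
        summ = match_traces(a, b, max_dist_um=0.5)
        assert summ.per_class.set_index("movement_class").loc[
            "stationary", "n_coloc"] == 0

    def test_one_to_one_assignment(self):
        # two A traces, one B trace: only one A can be co-localized
        a = [make_trace(0.0, s0=5.0, source="swath_0"),
             make_trace(0.0, s0=5.2, source="swath_0")]
        b = [make_trace(0.0, s0=5.0, source="swath_0")]
        summ = match_traces(a, b)
        assert summ.per_class.set_index("movement_class").loc[
            "stationary", "n_coloc"] == 1

    def test_cross_swath_traces_never_match(self):
        a = [make_trace(0.0, s0=5.0, source="swath_0")]
        b = [make_trace(0.0, s0=5.0, source="swath_1")]
        summ = match_traces(a, b)
        assert summ.per_class["n_coloc"].sum() == 0


class TestDedup:
    def test_adjacent_swath_stationary_duplicates_collapsed(self):
        a = make_trace(0.0, s0=5.0, source="swath_0")
        dup = make_trace(0.0, s0=5.1, source="swath_1")
        far = make_trace(0.0, s0=50.0, source="swath_1")
        kept = transport.deduplicate_stationary([a, dup, far])
        assert len(kept) == 2

    def test_movers_never_collapsed(self):
        a = make_trace(0.5, s0=5.0, source="swath_0")
        b = make_trace(0.5, s0=5.0, source="swath_1")
        assert len(transport.deduplicate_stationary([a, b])) == 2
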