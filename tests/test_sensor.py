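import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from phytosense.design import CONTROL, STRESSED
from phytosense.sensor import (
    best_breakpoints,
    compute_response,
    daily_mean,
    detect_onset,
    normalize_nr,
    piecewise_linear_fit,
    recovery_deficit,
    segment_phases,
    subdaily_nr,
)


def _trace(i_ds, i_ds0, interval_min=15, plant="P1", group=CONTROL):
    n = len(i_ds)
    return pd.DataFrame(
        {
            "plant_id": plant,
            "group": group,
            "time_min": np.arange(n) * interval_min,
            "i_ds_uA": i_ds,
            "i_ds0_uA": i_ds0,
        }
    )


class TestComputeResponse:
    def test_identity_currents_give_zero(self):
        out = compute_response(_trace([-5.0, -5.0], [-5.0, -5.0]))
        assert np.allclose(out["r"], 0.0)

    def test_printed_expression(self):
        out = compute_response(_trace([-6.0], [-5.0]))
        assert out["r"].iloc[0] == pytest.approx(0.2)

    def test_zero_gate_off_sample_dropped(self):
        out = compute_response(_trace([-6.0, -6.0, -6.0], [-5.0, 0.0, -5.0]))
        assert len(out) == 2

    def test_empty_trace_raises(self):
        with pytest.raises(ValueError, match="empty"):
            compute_response(_trace([], []))

    def test_all_dropped_raises(self):
        with pytest.raises(ValueError, match="dropped"):
            compute_response(_trace([-6.0], [0.0]))

    @given(
        c=st.floats(min_value=1e-3, max_value=1e3).filter(lambda v: v != 0),
        ids=st.floats(min_value=-10, max_value=-1),
        ids0=st.floats(min_value=-10, max_value=-1),
    )
    def test_scale_invariance(self, c, ids, ids0):
        base = compute_response(_trace([ids], [ids0]))["r"].iloc[0]
        scaled = compute_response(_trace([c * ids], [c * ids0]))["r"].iloc[0]
        assert scaled == pytest.approx(base, rel=1e-9)


class TestDailyMean:
    def test_constant_series(self, main_design):
        n = 3 * 96
        out = daily_mean(
            compute_response(_trace([-7.5] * n, [-5.0] * n)), main_design
        )
        assert np.allclose(out["r_mean"], 0.5)
        assert list(out["day"]) == [0, 1, 2]

    def test_zero_mean_sinusoid_averages_out(self, main_design):
        t = np.arange(2 * 96) * 15  # minutes, exact-period sampling
        r = 0.3 * np.sin(2 * np.pi * t / 1440.0)
        resp = pd.DataFrame({"plant_id": "P1", "time_min": t, "r": r})
        out = daily_mean(resp, main_design)
        assert np.all(np.abs(out["r_mean"]) < 1e-6)

    def test_partial_day_flagged_and_excluded(self, main_design):
        n = 96 + 24  # one full day plus 6 h
        resp = pd.DataFrame(
            {"plant_id": "P1", "time_min": np.arange(n) * 15, "r": 0.1}
        )
        out = daily_mean(resp, main_design)
        assert list(out["day"]) == [0]
        kept = daily_mean(resp, main_design, keep_incomplete=True)
        assert not kept.loc[kept["day"] == 1, "complete"].iloc[0]


class TestNormalizeNR:
    @staticmethod
    def _daily(values_by_plant, group):
        rows = []
        for pid, vals in values_by_plant.items():
            for d, v in enumerate(vals):
                rows.append((pid, group, d, v))
        return pd.DataFrame(rows, columns=["plant_id", "group", "day", "r_mean"])

    def test_identical_groups_give_unity(self):
        a = self._daily({"C1": [-0.5, -0.4], "C2": [-0.3, -0.6]}, CONTROL)
        b = self._daily({"S1": [-0.5, -0.4], "S2": [-0.3, -0.6]}, STRESSED)
        out = normalize_nr(pd.concat([a, b]))
        assert np.allclose(out["nr"], 1.0)
        assert list(out["n_stressed"]) == [2, 2]

    def test_direct_ratio(self):
        a = self._daily({"C1": [-0.2]}, CONTROL)
        b = self._daily({"S1": [-0.3]}, STRESSED)
        out = normalize_nr(pd.concat([a, b]))
        assert out["nr"].iloc[0] == pytest.approx(1.5)

    def test_zero_control_day_masked(self):
        a = self._daily({"C1": [-0.2, 0.0]}, CONTROL)
        b = self._daily({"S1": [-0.3, -0.3]}, STRESSED)
        out = normalize_nr(pd.concat([a, b]))
        assert list(out["day"]) == [0]

    def test_disjoint_days_raise(self):
        a = self._daily({"C1": [-0.2]}, CONTROL)
        b = self._daily({"S1": [-0.3]}, STRESSED)
        b["day"] = 5
        with pytest.raises(ValueError, match="disjoint"):
            normalize_nr(pd.concat([a, b]))


def _pwl(x, breaks, slopes, y0=1.0):
    """Evaluate a continuous piecewise-linear curve from initial slope list."""
    x = np.asarray(x, dtype=float)
    y = np.full_like(x, y0)
    start = x.min()
    level = y0
    edges = [start] + list(breaks) + [x.max()]
    for (b0, b1), s in zip(zip(edges, edges[1:]), slopes):
        seg = (x >= b0) & (x <= b1)
        y[seg] = level + s * (x[seg] - b0)
        level = level + s * (b1 - b0)
    return y


class TestSegmentation:
    def test_noiseless_breakpoints_recovered_exactly(self, main_design):
        days = np.arange(14)
        y = _pwl(days, [4, 9], [0.0, -0.1, 0.05])
        nr = pd.DataFrame({"day": days, "nr": y})
        seg = segment_phases(nr, main_design)
        assert seg.breakpoints == (4.0, 9.0)
        assert seg.k == 2

    def test_constant_series_selects_no_breaks(self, main_design):
        nr = pd.DataFrame({"day": np.arange(10), "nr": 1.0})
        seg = segment_phases(nr, main_design)
        assert seg.k == 0
        assert seg.segments[0].slope == pytest.approx(0.0, abs=1e-12)

    def test_default_run_contains_pii_da_piii_in_order(self, main_run, main_design):
        seg = segment_phases(main_run["nr"], main_design)
        labels = seg.labels()
        slopes = {s.label: s.slope for s in seg.segments}
        i_pii = labels.index("PII")
        i_da = labels.index("DA")
        i_piii = labels.index("PIII")
        assert i_pii < i_da < i_piii
        assert slopes["DA"] > 0
        assert slopes["PIII"] > 0
        assert seg.segments[i_pii].slope < 0

    def test_rss_non_increasing_in_breakpoint_count(self, rng):
        days = np.arange(18)
        y = _pwl(days, [5, 11], [0.0, -0.08, 0.04]) + 0.01 * rng.standard_normal(18)
        last = np.inf
        for k in range(0, 4):
            _, rss = best_breakpoints(days, y, k)
            assert rss <= last + 1e-12
            last = rss

    def test_too_short_series_rejected(self, main_design):
        nr = pd.DataFrame({"day": np.arange(4), "nr": 1.0})
        with pytest.raises(ValueError, match="6 days"):
            segment_phases(nr, main_design)


def _nr_with_break(onset_h, slope_per_day, noise_sd, seed, total_h=24 * 6, step_min=15):
    t_min = np.arange(0, total_h * 60, step_min)
    t_h = t_min / 60.0
    nr = np.where(t_h < onset_h, 1.0, 1.0 + slope_per_day * (t_h - onset_h) / 24.0)
    rng = np.random.default_rng(seed)
    nr = nr + noise_sd * rng.standard_normal(len(nr))
    return pd.DataFrame({"time_min": t_min, "nr": nr})


class TestOnsetDetection:
    # MAIN design: stress starts at 24 h, so a 30 h lag breaks at t = 54 h
    def test_constant_noisy_series_not_detected(self, main_design):
        nr = _nr_with_break(1e9, 0.0, 0.01, seed=2)
        rep = detect_onset(nr, main_design)
        assert not rep.detected

    def test_noiseless_break_detected_at_grid_resolution(self, main_design):
        nr = _nr_with_break(54.0, -0.1, 0.0, seed=0)
        rep = detect_onset(nr, main_design)
        assert rep.detected
        assert 30.0 < rep.onset_h <= 30.0 + 2 * 15 / 60.0

    def test_noisy_break_detected_within_18h(self, main_design):
        nr = _nr_with_break(54.0, -0.12, 0.01, seed=7)
        rep = detect_onset(nr, main_design)
        assert rep.detected
        assert 30.0 <= rep.onset_h <= 48.0

    def test_insufficient_baseline_rejected(self, main_design):
        nr = _nr_with_break(54.0, -0.1, 0.0, seed=0)
        nr = nr[nr["time_min"] >= 20 * 60]  # baseline starts at 20 h < 24 h pre-stress
        with pytest.raises(ValueError, match="baseline"):
            detect_onset(nr, main_design)


class TestRecovery:
    def test_full_recovery_is_unity(self, main_design):
        days = np.arange(24)
        y = _pwl(days, [2, 9, 17, 19], [0.0, -0.1, 0.0, 0.35, 0.0])
        nr = pd.DataFrame({"day": days, "nr": y})
        seg = segment_phases(nr, main_design)
        value = recovery_deficit(nr, seg)
        assert value == pytest.approx(1.0, abs=0.05)

    def test_partial_plateau_measured_directly(self, main_design):
        days = np.arange(24)
        # flat pre-stress level 1.0, decline to a 0.4 floor, rise after
        # rewatering to a 0.6 plateau (60% of the PI level)
        y = _pwl(days, [2, 5, 17, 19], [0.0, -0.2, 0.0, 0.1, 0.0])
        nr = pd.DataFrame({"day": days, "nr": y})
        seg = segment_phases(nr, main_design)
        value = recovery_deficit(nr, seg)
        assert value == pytest.approx(0.6, abs=0.05)

    def test_default_run_recovers_configured_fraction(
        self, main_run, main_design, gen_config
    ):
        seg = segment_phases(main_run["nr"], main_design)
        value = recovery_deficit(main_run["nr"], seg)
        assert value == pytest.approx(gen_config.recovery_fraction, abs=0.1)
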