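import math

import numpy as np
import pandas as pd
import pytest

from cytoquant import knockdown as kd
from cytoquant import synthkit
from oracles import fourpl_literal


def _well_traces(n_controls=6, n_frames=200, bleach=0.995, egfp0=100.0,
                 event_cell_curve=None, event_frame=24):
    """Build a trace table: controls bleach only; one event cell optionally
    multiplies in a knockdown curve aligned at event_frame."""
    rows = []
    frames = np.arange(n_frames)
    decay = bleach ** frames
    for tid in range(n_controls):
        for f in frames:
            rows.append((tid, f, egfp0 * decay[f]))
    tid_event = n_controls
    curve = np.ones(n_frames) if event_cell_curve is None else event_cell_curve
    for f in frames:
        rows.append((tid_event, f, egfp0 * decay[f] * curve[f]))
    traces = pd.DataFrame(rows, columns=["track_id", "frame", "median_eGFP_nucleusmask"])
    events = pd.DataFrame({"track_id": [tid_event], "frame": [event_frame]})
    return traces, events, tid_event


class TestCorrectExpression:
    def test_no_knockdown_same_bleaching_is_flat_one(self):
        traces, events, tid = _well_traces()
        out = kd.correct_expression(traces, events)
        cell = out[out.track_id == tid]
        assert np.allclose(cell["rel_expression"], 1.0, atol=1e-9)

    def test_t0_normalization_exact(self):
        rng = np.random.default_rng(0)
        curve = 1.0 + 0.1 * rng.standard_normal(200)
        traces, events, tid = _well_traces(event_cell_curve=curve)
        out = kd.correct_expression(traces, events)
        at0 = out[(out.track_id == tid) & (out.rel_frame == 0)]["rel_expression"]
        assert at0.iloc[0] == 1.0

    def test_half_knockdown_at_10h_under_bleaching(self):
        m = kd.KineticModel()
        d50 = m.absolute_ic50(10.0)
        frames = np.arange(200)
        ev = 24
        t_h = np.clip(frames - ev, 0, None) / 12.0
        curve = m.relative_expression(d50, t_h)
        traces, events, tid = _well_traces(bleach=0.99, event_cell_curve=curve, event_frame=ev)
        out = kd.correct_expression(traces, events)
        at10h = out[(out.track_id == tid) & (out.rel_frame == 120)]["rel_expression"]
        assert at10h.iloc[0] == pytest.approx(0.5, abs=0.02)

    def test_apoptosis_masked_20_frames_before_death(self):
        traces, events, tid = _well_traces()
        out = kd.correct_expression(traces, events, apoptosis={tid: 100})
        cell = out[out.track_id == tid]
        assert (cell["rel_frame"] + 24 < 80).all()

    def test_second_event_masks_tail(self):
        traces, events, tid = _well_traces()
        two = pd.concat([events, pd.DataFrame({"track_id": [tid], "frame": [100]})])
        out_one = kd.correct_expression(traces, events)
        out_two = kd.correct_expression(traces, two)
        assert out_two[out_two.track_id == tid]["rel_frame"].max() < \
            out_one[out_one.track_id == tid]["rel_frame"].max()

    def test_late_entry_excluded(self):
        traces, events, tid = _well_traces()
        traces = traces[(traces.track_id != tid) | (traces.frame >= 10)]
        out = kd.correct_expression(traces, events)
        assert tid not in set(out["track_id"])
        assert tid in out.attrs["excluded"]["late_entry"]

    def test_no_controls_warns(self):
        traces, events, tid = _well_traces(n_controls=1)
        with pytest.warns(UserWarning, match="control"):
            kd.correct_expression(traces, events)


class TestGroupByMagnitude:
    def _inputs(self, n=100, r2=1.0):
        releases = pd.DataFrame({
            "track_id": np.arange(n),
            "peak_conc_nM": np.arange(1.0, n + 1.0),
            "r_squared": np.full(n, r2),
        })
        rows = [(tid, rf, rf * 5.0, 1.0) for tid in range(n) for rf in range(11)]
        corrected = pd.DataFrame(rows, columns=["track_id", "rel_frame", "time_min", "rel_expression"])
        return releases, corrected

    def test_five_groups_of_twenty(self):
        releases, corrected = self._inputs()
        groups = kd.group_by_magnitude(releases, corrected)
        assert [len(g.track_ids) for g in groups] == [20] * 5

    def test_rank_medians(self):
        releases, corrected = self._inputs()
        groups = kd.group_by_magnitude(releases, corrected)
        assert [g.median_conc for g in groups] == [10.5, 30.5, 50.5, 70.5, 90.5]

    def test_r2_threshold_filters(self):
        releases, corrected = self._inputs()
        releases.loc[releases.track_id < 10, "r_squared"] = 0.2
        groups = kd.group_by_magnitude(releases, corrected, r2_threshold=0.3)
        kept = {tid for g in groups for tid in g.track_ids}
        assert kept == set(range(10, 100))

    def test_too_few_cells_raises(self):
        releases, corrected = self._inputs(n=3)
        with pytest.raises(ValueError):
            kd.group_by_magnitude(releases, corrected, n_groups=5)


class TestFourPL:
    def test_noiseless_recovery(self, rng):
        d = 10 ** rng.uniform(-2, 2, 300)
        y = np.array([fourpl_literal(x, 0.0, 1.0, -1.0) for x in d])
        fit = kd.fit_4pl(d, y)
        assert fit.ic50_relative == pytest.approx(1.0, abs=1e-3)
        assert fit.ic50_absolute == pytest.approx(1.0, abs=1e-3)
        assert fit.hillslope == pytest.approx(-1.0, abs=1e-3)

    def test_absolute_ic50_closed_form_with_nonzero_bottom(self, rng):
        bottom, ic50, hill = 0.3, 2.0, -1.2
        d = 10 ** rng.uniform(-2, 2, 400)
        y = np.array([fourpl_literal(x, bottom, ic50, hill) for x in d])
        fit = kd.fit_4pl(d, y)
        # closed-form inversion of the 4PL at y = 0.5
        expected_abs = 10 ** (math.log10(ic50) - math.log10(0.5 / (0.5 - bottom)) / hill)
        assert fit.ic50_absolute == pytest.approx(expected_abs, rel=1e-3)
        # the fitted curve really is at 0.5 there...
        assert fourpl_literal(fit.ic50_absolute, bottom, ic50, hill) == pytest.approx(0.5, abs=1e-6)
        # ...and for a descending curve with bottom > 0 the 0.5 crossing sits
        # at a HIGHER dose than the midpoint (relative) IC50
        assert fit.ic50_absolute > fit.ic50_relative

    def test_asymptote_is_bottom(self):
        assert fourpl_literal(1e9, 0.25, 1.0, -1.0) == pytest.approx(0.25, abs=1e-6)
        assert kd._fourpl(9.0, 0.25, 0.0, -1.0) == pytest.approx(0.25, abs=1e-6)

    def test_bottom_above_half_no_absolute_ic50(self, rng):
        d = 10 ** rng.uniform(-2, 2, 200)
        y = np.array([fourpl_literal(x, 0.7, 1.0, -1.0) for x in d])
        fit = kd.fit_4pl(d, y)
        assert math.isnan(fit.ic50_absolute)

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError):
            kd.fit_4pl([1.0, 2.0, 3.0], [0.9, 0.5, 0.1])


class TestIC50Timecourse:
    def test_time_invariant_response_constant_ic50(self, rng):
        n = 60
        doses = 10 ** rng.uniform(-1.5, 1.5, n)
        rows = []
        for tid, d in enumerate(doses):
            y = fourpl_literal(d, 0.0, 1.0, -1.0)
            for tp in (2.0, 6.0, 10.0):
                rows.append((tid, tp * 60.0, y + rng.normal(0, 0.02), d))
        cells = pd.DataFrame(rows, columns=["track_id", "time_min", "rel_expression", "peak_conc_nM"])
        fits = kd.ic50_timecourse(cells, [2.0, 6.0, 10.0], bootstrap_reps=0)
        vals = [f.ic50_relative for f in fits]
        assert len(vals) == 3
        assert max(vals) / min(vals) < 1.3

    def test_sparse_timepoint_skipped(self):
        cells = pd.DataFrame({"track_id": [0], "time_min": [600.0],
                              "rel_expression": [0.5], "peak_conc_nM": [1.0]})
        with pytest.warns(UserWarning, match="skipped"):
            fits = kd.ic50_timecourse(cells, [10.0])
        assert fits == []


class TestKineticModel:
    def test_delta_p_closed_form(self):
        assert kd.DEFAULT_DELTA_P == pytest.approx(math.log(2) / 0.8)

    def test_dose_zero_steady_state(self):
        m = kd.KineticModel()
        assert np.allclose(m.relative_expression(0.0, np.linspace(0, 20, 10)), 1.0)

    def test_monotone_nadir_and_duration(self):
        m = kd.KineticModel()
        times = np.linspace(0, 20, 81)
        lo = m.relative_expression(0.5, times)
        hi = m.relative_expression(5.0, times)
        assert hi.min() <= lo.min()
        assert (hi < 0.8).sum() >= (lo < 0.8).sum()  # longer time below threshold

    def test_negative_params_rejected(self):
        with pytest.raises(ValueError):
            kd.KineticModel(delta_m=-0.1)

    def test_parameter_recovery(self):
        true = kd.KineticModel(delta_m=0.35, v_max=3.0, K=1.0, n=1.0, lambda_s=0.05)
        rng = np.random.default_rng(11)
        doses = np.exp(rng.uniform(np.log(0.05), np.log(20), 500))
        times = np.arange(0.0, 20.1, 0.5)
        curves = np.vstack([true.relative_expression(d, times) for d in doses])
        order = np.argsort(doses)
        groups = []
        for chunk in np.array_split(order, 5):
            noisy = curves[chunk] * np.exp(rng.normal(0, 0.1, curves[chunk].shape))
            groups.append({"median_conc": float(np.median(doses[chunk])),
                           "times": times, "mean_curve": noisy.mean(axis=0)})
        res = kd.fit_kinetic_model(groups, bootstrap_reps=0)
        assert res["model"].K == pytest.approx(1.0, rel=0.2)
        assert res["ic50_absolute"] == pytest.approx(true.absolute_ic50(10.0), rel=0.1)

    def test_flat_curves_warn(self):
        groups = [{"median_conc": d, "times": np.linspace(0, 10, 5),
                   "mean_curve": np.ones(5)} for d in (0.1, 1.0, 10.0)]
        with pytest.warns(UserWarning, match="non-identifiable"):
            kd.fit_kinetic_model(groups, bootstrap_reps=0)
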