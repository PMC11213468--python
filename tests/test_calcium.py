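"""Index-of-dispersion activity calling, trace extraction, peak detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flowpol as fp
from flowpol.calcium import call_activity, trace_table

from conftest import interior

FLOW_X = fp.FlowField((1.0, 0.0))


def trace(vals, dt=3.0, region="whole"):
    return fp.IntensityTrace(np.asarray(vals, float), dt, 1, region)


class TestIndexOfDispersion:
    def test_constant_trace_is_zero(self):
        assert fp.index_of_dispersion(trace([5.0] * 20)) == 0.0

    def test_hand_computed_oracle(self):
        # values (10, 10, 10, 40): sample variance 225, mean 17.5
        got = fp.index_of_dispersion(trace([10, 10, 10, 40]))
        assert got == pytest.approx(225 / 17.5, abs=1e-9)

    def test_poisson_traces_have_unit_dispersion(self):
        """Mean IoD over 1,000 Poisson(50) traces of length 600 is 1.0
        within 0.06 (dispersion of a Poisson process is its defining
        property)."""
        rng = np.random.default_rng(50)
        x = rng.poisson(50, (1000, 600)).astype(float)
        iods = x.var(axis=1, ddof=1) / x.mean(axis=1)
        assert iods.mean() == pytest.approx(1.0, abs=0.06)

    def test_nonpositive_mean_flagged(self):
        assert np.isnan(fp.index_of_dispersion(trace([-1.0, -2.0, 3.0, 0.0])))

    @settings(max_examples=25, deadline=None)
    @given(st.floats(0.01, 100), st.integers(0, 2 ** 31 - 1))
    def test_scaling_property(self, c, seed):
        """IoD(c*x) = c*IoD(x): the statistic is unit-dependent, which is
        why traces stay in fixed camera units before thresholding."""
        rng = np.random.default_rng(seed)
        v = rng.uniform(1, 10, 50)
        t1 = fp.index_of_dispersion(trace(v))
        t2 = fp.index_of_dispersion(trace(c * v))
        assert t2 == pytest.approx(c * t1, rel=1e-9)


class TestTraceContainer:
    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            fp.IntensityTrace(np.array([1.0]))

    def test_nonfinite_frames_rejected(self):
        with pytest.raises(ValueError):
            fp.IntensityTrace(np.array([1.0, np.nan, 2.0]))

    def test_times_use_frame_interval(self):
        t = trace([1, 2, 3], dt=3.0)
        assert np.array_equal(t.times, [0.0, 3.0, 6.0])


class TestExtractTraces:
    def _movie_setup(self):
        lab = np.zeros((30, 62), int)
        lab[5:25, 1:31] = 1
        lab[5:25, 32:61] = 2
        lab[:, 31] = 0
        lm = fp.CellLabelMap(lab, FLOW_X)
        return lm, fp.measure_geometry(lm)

    def test_constant_movie_gives_constant_traces(self):
        lm, geos = self._movie_setup()
        movie = np.full((5, 30, 62), 100.0)
        movie[:, lm.labels == 0] = 0.0
        traces = fp.extract_traces(movie, lm, geos)
        for regs in traces.values():
            for tr in regs.values():
                assert np.allclose(tr.values, 100.0)

    def test_whole_trace_is_area_weighted_segment_mean(self):
        lm, geos = self._movie_setup()
        rng = np.random.default_rng(3)
        movie = rng.uniform(50, 150, (8, 30, 62))
        traces = fp.extract_traces(movie, lm, geos)
        for g in geos:
            regs = traces[g.cell_id]
            areas = np.array([m.sum() for m in g.segment_masks])
            weighted = sum(a * regs[r].values for a, r in
                           zip(areas, ("upstream", "mid_body", "downstream")))
            assert np.allclose(regs["whole"].values,
                               weighted / areas.sum(), atol=1e-9)

    def test_injected_oscillation_confined_to_source_segment(self):
        lm, geos = self._movie_setup()
        g = geos[0]
        n = 40
        movie = np.full((n, 30, 62), 100.0)
        movie[:, lm.labels == 0] = 0.0
        wave = 50 * (1 + np.sin(2 * np.pi * np.arange(n) / 10))
        down = g.segment_masks[2]
        for t in range(n):
            movie[t][down] += wave[t]
        traces = fp.extract_traces(movie, lm, geos)[g.cell_id]
        assert np.ptp(traces["upstream"].values) < 1e-9
        # injected period visible downstream: dominant FFT component at 10 frames
        v = traces["downstream"].values - traces["downstream"].values.mean()
        freqs = np.fft.rfftfreq(n)
        assert freqs[np.abs(np.fft.rfft(v)).argmax()] == pytest.approx(0.1)

    def test_shape_mismatch_and_short_movie_rejected(self):
        lm, geos = self._movie_setup()
        with pytest.raises(ValueError):
            fp.extract_traces(np.zeros((5, 10, 10)), lm, geos)
        with pytest.raises(ValueError):
            fp.extract_traces(np.zeros((1, 30, 62)), lm, geos)


class TestDetrend:
    def test_constant_trace_unchanged(self):
        t = trace([7.0] * 10)
        for mode in ("none", "linear", "exponential"):
            assert np.allclose(fp.detrend(t, mode).values, 7.0)

    def test_linear_ramp_removed_exactly(self):
        ramp = np.linspace(10, 50, 20)
        out = fp.detrend(trace(ramp), "linear")
        assert np.allclose(out.values, ramp.mean(), atol=1e-9)
        assert out.values.std() < 1e-9

    def test_bleached_oscillation_amplitude_recovered(self):
        """Sine x exponential bleach: after exponential detrending the
        peak-to-trough amplitude is recovered within 10%."""
        dt, n, amp = 3.0, 300, 40.0
        t = np.arange(n) * dt
        tau = 5 * t[-1]
        v = (100 + amp / 2 * (1 + np.sin(2 * np.pi * t / 60))) * np.exp(-t / tau)
        out = fp.detrend(trace(v, dt), "exponential")
        est = np.sqrt(8) * (out.values - out.values.mean()).std()
        assert est == pytest.approx(amp, rel=0.10)

    def test_mean_preserved(self):
        rng = np.random.default_rng(4)
        v = rng.uniform(50, 150, 60)
        for mode in ("linear", "exponential"):
            out = fp.detrend(trace(v), mode)
            assert out.values.mean() == pytest.approx(v.mean(), rel=1e-6)


class TestClassifyActivity:
    def test_single_hot_segment_named(self):
        cat = fp.classify_activity(
            {"upstream": 0.5, "mid_body": 0.7, "downstream": 8.1})
        assert cat == "downstream"

    def test_all_hot_is_whole_cell(self):
        assert fp.classify_activity(
            {"upstream": 3.0, "mid_body": 3.0, "downstream": 3.0}) == "whole_cell"

    def test_none_hot_is_inactive(self):
        assert fp.classify_activity(
            {"upstream": 0.1, "mid_body": 0.2, "downstream": 1.9}) == "inactive"

    def test_missing_segment_rejected(self):
        with pytest.raises(ValueError):
            fp.classify_activity({"upstream": 1.0, "downstream": 1.0})

    def test_threshold_is_strict(self):
        assert fp.classify_activity(
            {"upstream": 2.0, "mid_body": 2.0, "downstream": 2.0}) == "inactive"


class TestDetectPeaks:
    def test_constant_trace_has_no_peaks(self):
        times, n = fp.detect_peaks(trace([5.0] * 30))
        assert n == 0

    def test_transient_train_recovered_at_injected_times(self):
        """7 large transients are all found within one frame of the
        injected times."""
        spec = fp.MovieSpec(waveform="transients", seed=0)
        dt, dur = 3.0, 600.0
        t = np.arange(0, dur, dt)
        rng = np.random.default_rng(60)
        true_times = np.linspace(40, 560, 7)
        v = 100 + rng.normal(0, 1.0, t.size)
        for c in true_times:
            v += 10 * 1.0 * np.exp(-((t - c) ** 2) / (2 * 6.0 ** 2))
        times, n = fp.detect_peaks(trace(v, dt))
        assert n == 7
        assert np.all(np.abs(times - true_times) <= dt)

    def test_min_separation_merges_close_events(self):
        v = np.zeros(40)
        v[10] = 50.0
        v[11] = 50.0  # 1 frame apart
        times, n = fp.detect_peaks(trace(v + 100, dt=1.0),
                                   min_separation_s=5.0)
        assert n == 1


class TestActivitySummaryAndCalls:
    def _call(self, cid, active, cat, iod_down=5.0):
        iod = {"whole": 1.0, "upstream": 0.1, "mid_body": 0.1,
               "downstream": iod_down if active else 0.1}
        return fp.ActivityCall(cell_id=cid, iod=iod, active=active,
                               category=cat if active else "inactive")

    def test_fraction_arithmetic(self):
        calls = ([self._call(i, True, "downstream") for i in range(4)]
                 + [self._call(4, True, "whole_cell")]
                 + [self._call(i, False, "inactive") for i in range(5, 10)])
        s = fp.activity_summary(calls)
        assert s["fraction_active"] == 0.5
        assert s["category_shares_among_active"]["downstream"] == 0.8

    def test_all_inactive_shares_undefined(self):
        calls = [self._call(i, False, "inactive") for i in range(5)]
        s = fp.activity_summary(calls)
        assert s["fraction_active"] == 0.0
        assert all(np.isnan(v)
                   for v in s["category_shares_among_active"].values())

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fp.activity_summary([])

    def test_category_shares_sum_to_one_among_active(self):
        mv = fp.generate_gcamp_movie(fp.MovieSpec(
            scene=fp.SceneSpec(n_cells=40, fov=(260, 340), seed=61),
            n_frames=100, seed=61))
        geos = [g for g in mv.geometries if not g.border_touching]
        traces = fp.extract_traces(mv.frames, mv.label_map, geos)
        calls = [call_activity(tr) for tr in traces.values()]
        s = fp.activity_summary(calls)
        if s["n_active"]:
            assert sum(s["category_shares_among_active"].values()) == \
                pytest.approx(1.0)

    def test_flow_reversal_swaps_categories(self):
        mv = fp.generate_gcamp_movie(fp.MovieSpec(
            scene=fp.SceneSpec(n_cells=30, fov=(220, 300), seed=62),
            n_frames=80, seed=62))
        lm = mv.label_map
        geos = [g for g in mv.geometries if not g.border_touching]
        calls = {c.cell_id: c for c in
                 (call_activity(tr) for tr in
                  fp.extract_traces(mv.frames, lm, geos).values())}
        lm_rev = fp.CellLabelMap(lm.labels, lm.flow.reversed())
        geos_rev = [g for g in fp.measure_geometry(lm_rev)
                    if g.cell_id in calls]
        calls_rev = {c.cell_id: c for c in
                     (call_activity(tr) for tr in
                      fp.extract_traces(mv.frames, lm_rev, geos_rev).values())}
        swap = {"upstream": "downstream", "downstream": "upstream"}
        for cid, c in calls.items():
            assert calls_rev[cid].category == swap.get(c.category, c.category)

    def test_iod_monotone_in_oscillation_amplitude(self):
        """Increasing injected amplitude never decreases the source-segment
        IoD (amplitude ladder, fixed seed)."""
        iods = []
        for amp in (0.0, 25.0, 50.0, 100.0, 200.0):
            mv = fp.generate_gcamp_movie(fp.MovieSpec(
                scene=fp.SceneSpec(n_cells=12, fov=(200, 260), seed=63),
                n_frames=100, active_fraction=1.0,
                localization_probs={"downstream": 1.0},
                oscillation_amplitude=amp, seed=63))
            traces = fp.extract_traces(mv.frames, mv.label_map, mv.geometries)
            vals = [fp.index_of_dispersion(tr["downstream"])
                    for tr in traces.values()]
            iods.append(np.mean(vals))
        assert all(b >= a - 0.05 for a, b in zip(iods, iods[1:]))

    def test_trace_table_long_format(self):
        lab = np.zeros((20, 42), int)
        lab[5:15, 5:37] = 1
        lm = fp.CellLabelMap(lab, FLOW_X)
        geos = fp.measure_geometry(lm)
        traces = fp.extract_traces(np.full((4, 20, 42), 50.0), lm, geos)
        tab = trace_table(traces)
        assert set(tab.columns) == {"cell_id", "region", "frame", "time_s",
                                    "intensity"}
        assert len(tab) == 4 * 4  # 4 regions x 4 frames


class TestCorrelation:
    def _geo(self, cid, ar):
        mask = np.zeros((10, 30), bool)
        mask[2:8, 2:28] = True
        segs = fp.partition_cell(mask, FLOW_X)
        return fp.CellGeometry(cell_id=cid, mask=mask, area=int(mask.sum()),
                               centroid=(5, 15), aspect_ratio=ar,
                               proj_min=2, proj_max=27, segment_masks=segs)

    def _call(self, cid, iod_down):
        return fp.ActivityCall(cell_id=cid,
                               iod={"whole": 1.0, "upstream": 0.1,
                                    "mid_body": 0.1, "downstream": iod_down},
                               active=iod_down > 2, category="downstream")

    def test_exact_linear_relation_gives_r_one(self):
        geos = [self._geo(i, 1.0 + i) for i in range(10)]
        calls = [self._call(i, 2.0 * (1.0 + i)) for i in range(10)]
        res = fp.correlate_aspect_activity(geos, calls)
        assert res["r"] == pytest.approx(1.0)

    def test_independent_noise_has_small_r(self):
        rng = np.random.default_rng(70)
        n = 1000
        geos = [self._geo(i, float(rng.uniform(1, 5))) for i in range(n)]
        calls = [self._call(i, float(rng.uniform(0, 10))) for i in range(n)]
        res = fp.correlate_aspect_activity(geos, calls)
        assert abs(res["r"]) < 0.08

    def test_zero_variance_flagged(self):
        geos = [self._geo(i, 2.0) for i in range(5)]
        calls = [self._call(i, float(i)) for i in range(5)]
        res = fp.correlate_aspect_activity(geos, calls)
        assert not res["defined"]

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            fp.correlate_aspect_activity([self._geo(0, 2.0)],
                                         [self._call(0, 1.0)])

    def test_aspect_coupled_oscillation_detected(self):
        """When oscillation probability rises with aspect ratio (logistic
        link), aspect ratio and downstream IoD correlate positively."""
        rng = np.random.default_rng(71)
        n = 300
        geos, calls = [], []
        for i in range(n):
            ar = float(rng.uniform(1.5, 6.0))
            p_active = 1.0 / (1.0 + np.exp(-(ar - 3.5) * 1.5))
            active = rng.random() < p_active
            iod_down = float(rng.uniform(4, 12)) if active \
                else float(rng.uniform(0, 0.5))
            geos.append(self._geo(i, ar))
            calls.append(self._call(i, iod_down))
        res = fp.correlate_aspect_activity(geos, calls)
        assert res["r"] > 0 and res["p"] < 0.01
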