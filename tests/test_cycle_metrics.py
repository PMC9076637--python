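"""Landmark location and parameter extraction against analytic truth."""

import math

import numpy as np
import pytest

import coroflow as cf
from coroflow.ecg_segmentation import CardiacCycle
from coroflow.envelope_extraction import VelocityTrace

CAL = cf.Calibration(scale_max_v=400.0, ms_per_px=0.5, baseline_row=200)


def make_cycle(v, ms_per_px=0.5, index=0):
    v = np.asarray(v, dtype=float)
    return CardiacCycle(start_col=0, end_col=v.size, index=index,
                        trace=VelocityTrace(v=v, t=np.arange(v.size)
                                            * ms_per_px))


def analytic_cycle(seed=0):
    """A clean (noise-free) sampled cycle plus its spec."""
    spec = cf.default_cycle(duration_ms=165.0, peak_v=290.0)
    n = int(round(165.0 / 0.5))
    t = (np.arange(n) + 0.5) * 0.5
    return spec, make_cycle(spec.velocity_at(t))


class TestLocateLandmarks:
    def test_vertices_recovered_on_clean_cycle(self):
        spec, cycle = analytic_cycle()
        lm = cf.locate_landmarks(cycle)
        tv, _ = spec.vertices()
        cols = {k: int(round(tv[i] / 0.5 - 0.5))
                for k, i in (("systolic_peak", 1), ("diastolic_onset", 2),
                             ("peak", 3), ("decay_point", 4))}
        assert abs(lm.systolic_peak[0] - cols["systolic_peak"]) <= 2
        assert abs(lm.diastolic_onset[0] - cols["diastolic_onset"]) <= 2
        assert abs(lm.peak[0] - cols["peak"]) <= 2
        assert abs(lm.decay_point[0] - cols["decay_point"]) <= 2
        assert lm.end_col == cycle.n_columns

    def test_landmark_ordering_invariant(self):
        _, cycle = analytic_cycle()
        lm = cf.locate_landmarks(cycle)
        assert (lm.systolic_peak[0] <= lm.diastolic_onset[0]
                <= lm.peak[0] <= lm.decay_point[0]
                <= lm.peak_decel[0] < lm.end_col)

    def test_rendered_strip_vertices_within_three_pixels(self,
                                                         baseline_analysis,
                                                         baseline_strip):
        _, _, truth = baseline_strip
        a = baseline_analysis
        for lm, tc in zip(a.landmarks, truth.landmark_cols):
            assert abs(lm.systolic_peak[0] - tc["systolic_peak"]) <= 3
            assert abs(lm.diastolic_onset[0] - tc["diastolic_onset"]) <= 3
            assert abs(lm.peak[0] - tc["peak"]) <= 3
            assert abs(lm.decay_point[0] - tc["decay_point"]) <= 3

    def test_symmetric_triangle_peak_at_apex(self):
        v = np.concatenate([np.linspace(0, 300, 40),
                            np.linspace(300, 0, 40)[1:]])
        lm = cf.locate_landmarks(make_cycle(v))
        assert abs(lm.peak[0] - 39) <= 2
        assert lm.peak_decel[0] > lm.peak[0]   # on the falling limb

    def test_flat_trace_is_flagged_undefined(self):
        lm = cf.locate_landmarks(make_cycle(np.zeros(50)))
        assert not lm.defined

    def test_too_short_cycle_rejected(self):
        with pytest.raises(cf.ValidationError):
            cf.locate_landmarks(make_cycle(np.arange(5.0)))


class TestComputeMetrics:
    def test_heart_rate_from_duration(self):
        _, cycle = analytic_cycle()
        n_cols = int(round(150.0 / 0.5))
        cyc = make_cycle(np.ones(n_cols) * 100.0)
        lm = cf.locate_landmarks(cyc)
        m = cf.compute_metrics(cyc, lm, CAL)
        assert m.heart_rate == pytest.approx(400.0)

    def test_rectangular_envelope_vti_is_v_times_t(self):
        n_cols = int(round(100.0 / 0.5))
        cyc = make_cycle(np.full(n_cols, 300.0))
        assert cf.compute_vti(cyc) == pytest.approx(30.0)

    def test_rise_slope_is_delta_v_over_delta_t(self):
        # 100 -> 500 mm/s over 20 ms within a well-formed cycle
        v = np.concatenate([
            np.full(20, 100.0),
            np.linspace(100, 500, 41)[1:],
            np.linspace(500, 480, 60)[1:],
            np.linspace(480, 100, 21)[1:],
        ])
        cyc = make_cycle(v)
        lm = cf.locate_landmarks(cyc)
        m = cf.compute_metrics(cyc, lm, CAL)
        assert m.diastolic_slope == pytest.approx(20000.0, rel=0.12)

    def test_undefined_landmarks_leave_metrics_nan(self):
        cyc = make_cycle(np.zeros(60))
        lm = cf.locate_landmarks(cyc)
        m = cf.compute_metrics(cyc, lm, CAL)
        assert math.isnan(m.peak_velocity)
        assert math.isnan(m.vti)
        assert m.heart_rate > 0    # duration-only metric still defined

    def test_segment_times_partition_the_cycle(self):
        """Rise + decay segments account for the whole diastolic span."""
        _, cycle = analytic_cycle()
        lm = cf.locate_landmarks(cycle)
        m = cf.compute_metrics(cycle, lm, CAL)
        onset_ms = lm.diastolic_onset[0] * cycle.ms_per_px
        total = (onset_ms + m.diastolic_rise_time + m.diastolic_decay_time_1
                 + m.diastolic_decay_time_2)
        assert total == pytest.approx(cycle.duration_ms)


class TestComputeVti:
    def test_zero_trace(self):
        assert cf.compute_vti(make_cycle(np.zeros(40))) == 0.0

    def test_triangle_is_half_base_times_height(self):
        n_cols = int(round(100.0 / 0.5))
        t = (np.arange(n_cols) + 0.5) * 0.5
        v = np.interp(t, [0, 50, 100], [0, 400, 0])
        assert cf.compute_vti(make_cycle(v)) == pytest.approx(20.0, rel=1e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_midpoint_oracle_on_random_traces(self, seed):
        rng = np.random.default_rng(seed)
        v = np.abs(rng.normal(200, 80, 300))
        got = cf.compute_vti(make_cycle(v))
        oracle = sum(float(x) * 0.5 for x in v) / 1000
        assert got == pytest.approx(oracle, rel=0.01)

    def test_negative_velocity_rejected(self):
        with pytest.raises(cf.ValidationError):
            cf.compute_vti(make_cycle(np.array([1.0, -2.0] * 10)))

    def test_dimensional_rescaling_invariance(self):
        """Halving ms_per_px while doubling columns preserves VTI."""
        rng = np.random.default_rng(8)
        v = np.abs(rng.normal(200, 50, 200))
        a = cf.compute_vti(make_cycle(v, ms_per_px=0.5))
        b = cf.compute_vti(make_cycle(np.repeat(v, 2), ms_per_px=0.25))
        assert a == pytest.approx(b, rel=1e-9)


def test_parameter_recovery_on_seeded_strips():
    """Median relative errors across strips stay within tight bounds."""
    errs = {k: [] for k in ("peak_velocity", "heart_rate", "vti",
                            "diastolic_slope", "decay_slope_1")}
    for seed in range(20, 25):
        spec = cf.default_strip_spec("baseline", seed=seed)
        strip, truth = cf.generate_strip(spec)
        a = cf.analyze_strip(strip)
        assert len(a.metrics) == truth.n_cycles
        for tm, mm in zip(truth.metrics, a.metrics):
            for k in errs:
                t = getattr(tm, k)
                errs[k].append(abs(getattr(mm, k) - t) / abs(t))
    assert np.median(errs["peak_velocity"]) <= 0.02
    assert np.median(errs["heart_rate"]) <= 0.02
    assert np.median(errs["vti"]) <= 0.05
    assert np.median(errs["diastolic_slope"]) <= 0.08
    assert np.median(errs["decay_slope_1"]) <= 0.08
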