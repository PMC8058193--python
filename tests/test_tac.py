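import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcifkit import (
    FrameSchedule,
    TimeActivityCurve,
    BloodSampleSeries,
    build_frame_schedule,
    frame_average,
    peak_of_tac,
    read_tac,
    write_tac,
    read_samples,
    write_samples,
)
from mcifkit.expsum import ExpPolySum


class TestBuildFrameSchedule:
    def test_standard_23_bin_protocol(self):
        sched = build_frame_schedule([(11, 8), (1, 12), (2, 60), (1, 180), (8, 400)])
        assert len(sched) == 23
        assert sched.frames[0] == (0.0, 8 / 60)
        assert sched.total_minutes == pytest.approx(60.0)

    @pytest.mark.parametrize(
        "spec, n, total_s",
        [([(1, 60)], 1, 60), ([(2, 30), (1, 60)], 3, 120)],
    )
    def test_contiguity_and_total_duration(self, spec, n, total_s):
        sched = build_frame_schedule(spec)
        assert len(sched) == n
        assert sched.total_minutes * 60 == pytest.approx(total_s)
        assert np.allclose(sched.starts[1:], sched.ends[:-1])

    @pytest.mark.parametrize("bad", [[], [(0, 8)], [(2, -1)]])
    def test_invalid_specification(self, bad):
        with pytest.raises(ValueError):
            build_frame_schedule(bad)


class TestFrameAverage:
    def test_constant_and_linear(self):
        assert frame_average(lambda t: 3.0, (2.0, 5.0)) == pytest.approx(3.0)
        assert frame_average(lambda t: t, (0.0, 1.0)) == pytest.approx(0.5)

    def test_exponential_closed_form(self):
        # int_0^1 e^-t = 1 - 1/e, both via quadrature and the analytic path
        expected = 1 - math.exp(-1)
        assert frame_average(lambda t: math.exp(-t), (0.0, 1.0)) == pytest.approx(expected, rel=1e-9)
        curve = ExpPolySum(((1.0, 0, 1.0),))
        assert frame_average(curve, (0.0, 1.0)) == pytest.approx(expected, rel=1e-12)

    def test_invalid_frame(self):
        with pytest.raises(ValueError):
            frame_average(lambda t: 1.0, (1.0, 1.0))

    @settings(deadline=None, derandomize=True)
    @given(
        a=st.floats(-5, 5), b=st.floats(-5, 5),
        l1=st.floats(0.01, 3), l2=st.floats(0.01, 3),
    )
    def test_linearity_on_exponential_mixtures(self, a, b, l1, l2):
        f = ExpPolySum(((1.0, 0, l1),))
        g = ExpPolySum(((1.0, 0, l2),))
        mix = ExpPolySum(((a, 0, l1), (b, 0, l2)))
        frame = (0.3, 2.7)
        assert frame_average(mix, frame) == pytest.approx(
            a * frame_average(f, frame) + b * frame_average(g, frame), rel=1e-9, abs=1e-12
        )

    def test_mean_within_range_for_monotone_curve(self):
        curve = ExpPolySum(((2.0, 0, 0.7),))
        avg = frame_average(curve, (1.0, 4.0))
        assert curve(4.0) <= avg <= curve(1.0)


class TestPeakOfTac:
    def test_monotone_decreasing_takes_first_frame(self, schedule23):
        vals = np.linspace(10, 1, 23)
        t, v = peak_of_tac(TimeActivityCurve(schedule23, vals))
        assert v == 10 and t == pytest.approx(schedule23.midpoints[0])

    def test_tie_broken_by_earliest_frame(self):
        sched = build_frame_schedule([(4, 60)])
        t, v = peak_of_tac(TimeActivityCurve(sched, [1, 5, 5, 2]))
        assert v == 5 and t == pytest.approx(1.5)

    def test_window_restricts_by_midpoint(self, schedule23):
        vals = np.linspace(1, 23, 23)  # rising to the last frame
        mids = schedule23.midpoints
        t, v = peak_of_tac(TimeActivityCurve(schedule23, vals), (0.0, 10.0))
        expected = vals[mids <= 10].max()  # brute force over the windowed subset
        assert v == pytest.approx(expected) and t <= 10
        with pytest.raises(ValueError):
            peak_of_tac(TimeActivityCurve(schedule23, vals), (100.0, 200.0))


class TestTacIO:
    def test_round_trip_identity(self, schedule23, tmp_path):
        rng = np.random.default_rng(3)
        tac = TimeActivityCurve(schedule23, rng.uniform(0, 300, 23), "blood")
        write_tac(tac, tmp_path / "t.csv")
        back = read_tac(tmp_path / "t.csv")
        assert np.allclose(back.values, tac.values, rtol=1e-9)
        assert np.allclose(back.schedule.starts, schedule23.starts)

    def test_overlapping_frames_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "frame_start_min,frame_end_min,activity_kBq_cc\n0,1,5\n0.5,2,4\n"
        )
        with pytest.raises(ValueError, match="row 1"):
            read_tac(p)

    def test_bq_per_cc_units_converted(self, tmp_path):
        p = tmp_path / "bq.csv"
        p.write_text(
            "# units=Bq/cc\nframe_start_min,frame_end_min,activity_kBq_cc\n0,1,5000\n"
        )
        assert read_tac(p).values[0] == pytest.approx(5.0)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("frame_start_min,activity_kBq_cc\n0,5\n")
        with pytest.raises(ValueError, match="missing"):
            read_tac(p)

    def test_samples_round_trip(self, sample_times, tmp_path):
        s = BloodSampleSeries(sample_times, np.linspace(50, 5, len(sample_times)))
        write_samples(s, tmp_path / "s.csv")
        back = read_samples(tmp_path / "s.csv")
        assert np.allclose(back.times, s.times) and np.allclose(back.activities, s.activities)


class TestInvariants:
    def test_negative_values_need_flag(self, schedule23):
        vals = np.ones(23)
        vals[5] = -0.1
        with pytest.raises(ValueError):
            TimeActivityCurve(schedule23, vals)
        TimeActivityCurve(schedule23, vals, allow_negative=True)

    def test_sample_times_must_ascend(self):
        with pytest.raises(ValueError):
            BloodSampleSeries([1.0, 0.5], [1.0, 1.0])

    def test_schedule_rejects_overlap(self):
        with pytest.raises(ValueError):
            FrameSchedule(((0.0, 1.0), (0.5, 2.0)))
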