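import numpy as np
import pytest
from conftest import constant_trace, ramp_trace

import limbintent as li
from limbintent.segmentation import SegmentLabel, per_sample_labels

#: 18-vector rebuilt from the printed single-trial socks columns
#: (unit-1 then unit-2, each upper_arm/lower_arm/hand x roll/pitch/yaw).
SOCKS_TRIAL_VECTOR = [
    0.253, -0.761, 0.779, 0.887, 0.622, -0.481, 0.196, 0.511, -1.273,
    0.232, -0.050, -0.504, 0.177, -0.436, 0.125, 0.039, 0.141, -0.204,
]


def make_units(d1, d2):
    return [
        li.MotionUnit(1, 0, 10, np.asarray(d1, dtype=float)),
        li.MotionUnit(2, 20, 30, np.asarray(d2, dtype=float)),
    ]


class TestLabelWindow:
    def window(self, trace):
        return li.slide_windows(trace, length=10)[0]

    def test_small_wiggle_is_static(self):
        trace = ramp_trace(hold=5, ramp=5, step=0.1)
        assert li.label_window(self.window(trace)) is SegmentLabel.STATIC

    def test_single_large_step_is_movement(self):
        trace = ramp_trace(hold=5, ramp=5, step=1.5)
        assert li.label_window(self.window(trace)) is SegmentLabel.MOVEMENT

    def test_mid_band_is_indeterminate(self):
        trace = ramp_trace(hold=5, ramp=5, step=0.5)
        assert li.label_window(self.window(trace)) is SegmentLabel.INDETERMINATE

    def test_threshold_ordering_enforced(self):
        trace = constant_trace(12)
        with pytest.raises(ValueError):
            li.label_window(self.window(trace), static_thresh=1.0, move_thresh=0.3)


class TestSegmentTrace:
    def test_constant_trace_single_static_segment(self):
        segments = li.segment_trace(constant_trace(80))
        assert len(segments) == 1
        assert segments[0].label is SegmentLabel.STATIC
        assert (segments[0].start_idx, segments[0].end_idx) == (0, 79)

    def test_hold_ramp_hold_structure(self):
        segments = li.segment_trace(ramp_trace(hold=40, ramp=20, step=1.2))
        assert [s.label for s in segments] == [
            SegmentLabel.STATIC, SegmentLabel.MOVEMENT, SegmentLabel.STATIC
        ]

    def test_canonical_socks_structure(self, socks_trace_noisy):
        trace, _ = socks_trace_noisy
        segments = li.segment_trace(li.filter_trace(trace))
        labels = [s.label for s in segments]
        assert labels.count(SegmentLabel.STATIC) == 5
        assert labels.count(SegmentLabel.MOVEMENT) == 4

    def test_partition_and_alternation(self, socks_trace_noisy):
        trace, _ = socks_trace_noisy
        segments = li.segment_trace(li.filter_trace(trace))
        assert segments[0].start_idx == 0
        assert segments[-1].end_idx == trace.n_samples - 1
        for a, b in zip(segments, segments[1:]):
            assert b.start_idx == a.end_idx + 1  # disjoint cover, no gaps
            assert a.label is not b.label  # alternating

    def test_raising_move_thresh_is_monotone(self, socks_trace_noisy):
        trace, _ = socks_trace_noisy
        filt = li.filter_trace(trace)
        counts = []
        for move_thresh in (0.5, 1.0, 2.0, 5.0):
            segs = li.segment_trace(filt, move_thresh=move_thresh)
            counts.append(sum(s.label is SegmentLabel.MOVEMENT for s in segs))
        assert counts == sorted(counts, reverse=True)

    def test_deterministic(self, socks_trace_noisy):
        trace, _ = socks_trace_noisy
        filt = li.filter_trace(trace)
        assert li.segment_trace(filt) == li.segment_trace(filt)

    def test_leading_samples_inherit_first_window(self):
        labels = per_sample_labels(ramp_trace(hold=40, ramp=20, step=1.2))
        assert all(lbl is SegmentLabel.STATIC for lbl in labels[:9])


class TestExtractMotionUnits:
    def test_single_ramp_only_moves_one_channel(self):
        trace = ramp_trace(hold=40, ramp=2, step=1.1)  # +2.2 deg on hand.yaw
        segments = [
            li.Segment(SegmentLabel.STATIC, 0, 38),
            li.Segment(SegmentLabel.MOVEMENT, 39, 45),
            li.Segment(SegmentLabel.STATIC, 46, trace.n_samples - 1),
        ]
        units = li.extract_motion_units(trace, segments)
        assert len(units) == 1
        by_part = units[0].deltas_by_part()
        assert by_part["hand"]["yaw"] == pytest.approx(2.2, abs=1e-9)
        others = [
            by_part[p][a]
            for p in li.PARTS for a in li.ANGLE_AXES
            if (p, a) != ("hand", "yaw")
        ]
        np.testing.assert_allclose(others, 0, atol=1e-9)

    def test_all_static_trace_yields_no_units(self):
        trace = constant_trace(80)
        assert li.extract_motion_units(trace, li.segment_trace(trace)) == []

    def test_canonical_socks_units_match_script(self, socks_trace_noisy):
        trace, truth = socks_trace_noisy
        filt = li.filter_trace(trace)
        units = li.extract_motion_units(filt, li.segment_trace(filt))
        assert len(units) == 4
        for unit, expected in zip(units, truth.unit_deltas):
            np.testing.assert_allclose(unit.deltas, expected, atol=0.25)

    def test_delta_consistency_zero_noise(self, socks_trace_zero):
        # unit deltas plus hold drift (zero here) telescope to the total change
        trace, truth = socks_trace_zero
        units = li.extract_motion_units(trace, truth.segments())
        total = trace.angle_matrix()[-1] - trace.angle_matrix()[0]
        np.testing.assert_allclose(
            np.sum([u.deltas for u in units], axis=0), total, atol=1e-6
        )


class TestActionVector:
    def test_concatenation_order(self):
        d1, d2 = np.arange(9.0), np.arange(9.0, 18.0)
        np.testing.assert_array_equal(
            li.build_action_vector(make_units(d1, d2)), np.arange(18.0)
        )

    def test_single_unit_not_ready(self):
        units = make_units(np.zeros(9), np.zeros(9))[:1]
        with pytest.raises(li.NotReadyError):
            li.build_action_vector(units)

    def test_printed_socks_trial_vector(self):
        d1 = SOCKS_TRIAL_VECTOR[:9]
        d2 = SOCKS_TRIAL_VECTOR[9:]
        np.testing.assert_allclose(
            li.build_action_vector(make_units(d1, d2)), SOCKS_TRIAL_VECTOR
        )
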