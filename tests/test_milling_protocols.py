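import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lamellakit.exceptions import InvalidGeometry, InvalidTarget, ParseError
from lamellakit.milling_protocols import (
    LamellaTarget,
    MillingStep,
    PatternSequence,
    Protocol,
    SampleStats,
    SessionPolicy,
    SessionStats,
    compile_lamella_patterns,
    compile_trench_patterns,
    electron_dose,
    expansion_joint_patterns,
    parse_pattern_sequence,
    parse_protocol,
    retention_rate,
    success_rate,
    volume_imaging_plan,
    write_pattern_sequence,
    write_protocol,
)

MINIMAL = """\
name: demo
stage: rough

[step]
current: 300
time: 120
pattern_distance: 1
pattern_height: 5
overtilt: 0
"""


class TestProtocolFormat:
    def test_minimal_roundtrip_byte_identical(self):
        assert write_protocol(parse_protocol(MINIMAL)) == MINIMAL

    def test_three_step_rough_currents(self):
        text = "name: rough3\n" + "".join(
            f"[step]\ncurrent: {c}\ntime: 60\n" for c in (1000, 500, 300))
        proto = parse_protocol(text)
        assert [s.current for s in proto.steps] == [1000, 500, 300]
        assert proto.stage == "rough"

    def test_missing_current_named_in_error(self):
        with pytest.raises(ParseError, match="current"):
            parse_protocol("name: x\n[step]\ntime: 10\n")

    def test_malformed_line_has_line_number(self):
        with pytest.raises(ParseError, match="line 3"):
            parse_protocol("name: x\n[step]\nnonsense\n")

    @given(st.lists(st.tuples(st.floats(1, 5000), st.floats(0.1, 3600),
                              st.floats(0, 20), st.floats(0.1, 30)),
                    min_size=1, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_fuzzed_roundtrip(self, rows):
        steps = tuple(MillingStep(c, t, d, h) for c, t, d, h in rows)
        proto = Protocol("fuzz", steps, "fine")
        text = write_protocol(proto)
        assert write_protocol(parse_protocol(text)) == text

    def test_pattern_sequence_roundtrip(self):
        seq = compile_trench_patterns()
        text = write_pattern_sequence(seq)
        assert parse_pattern_sequence(text) == seq


class TestLamellaCompilation:
    TARGET = LamellaTarget(position=(0.0, 0.0), width=10.0, extremes=(-6.0, 6.0))
    PROTO = Protocol("rough", (
        MillingStep(1000, 60, pattern_distance=3.0, pattern_height=4.0),
        MillingStep(500, 60, pattern_distance=2.0, pattern_height=4.0),
        MillingStep(300, 60, pattern_distance=1.0, pattern_height=4.0)), "rough")

    def test_three_steps_give_six_commands_with_decreasing_gaps(self):
        seq = compile_lamella_patterns(self.PROTO, self.TARGET)
        assert len(seq) == 6
        gaps = []
        for i in range(0, 6, 2):
            upper, lower = seq.commands[i], seq.commands[i + 1]
            gaps.append((lower.center[1] - lower.height / 2)
                        - (upper.center[1] + upper.height / 2))
        assert gaps == sorted(gaps, reverse=True)
        assert np.allclose(gaps, [3.0, 2.0, 1.0])
        assert all(c.width == 10.0 for c in seq.commands)

    def test_height_clipped_at_extremes(self):
        target = LamellaTarget(position=(0.0, 0.0), width=8.0,
                               extremes=(-1.5, 6.0))
        proto = Protocol("p", (MillingStep(300, 30, 1.0, 5.0),), "rough")
        seq = compile_lamella_patterns(proto, target)
        upper = seq.commands[0]
        assert upper.height == pytest.approx(1.0)  # 1.5 - gap/2
        assert upper.center[1] - upper.height / 2 == pytest.approx(-1.5)

    def test_no_footprint_crosses_extremes(self):
        seq = compile_lamella_patterns(self.PROTO, self.TARGET)
        for c in seq.commands:
            _, _, y0, y1 = c.footprint
            assert y0 >= -6.0 - 1e-9 and y1 <= 6.0 + 1e-9

    def test_inverted_extremes_rejected(self):
        with pytest.raises(InvalidTarget):
            LamellaTarget(position=(0, 0), width=5, extremes=(3.0, -3.0))


class TestExpansionJoints:
    def test_mirror_symmetric_pair(self):
        target = LamellaTarget((0, 0), 10.0, (-5, 5), expansion_joints=True,
                               joint_offset=2.0)
        seq = expansion_joint_patterns(target)
        assert len(seq) == 2
        xs = sorted(c.center[0] for c in seq.commands)
        assert xs == [-7.0, 7.0]  # +-(width/2 + offset)

    def test_disabled_gives_empty(self):
        target = LamellaTarget((0, 0), 10.0, (-5, 5), expansion_joints=False)
        assert len(expansion_joint_patterns(target)) == 0


class TestTrenchPatterns:
    def test_published_geometry(self):
        seq = compile_trench_patterns(chunk_width=20, chunk_depth_y=20,
                                      trench_w=40, trench_h=15, side_offset=15,
                                      side_trench_w=10, side_trench_h=40)
        assert len(seq) == 3
        upper, lower, side = seq.commands
        gap = (lower.center[1] - lower.height / 2) \
            - (upper.center[1] + upper.height / 2)
        assert gap == pytest.approx(20.0)
        assert (upper.width, upper.height) == (40, 15)
        assert (side.width, side.height) == (10, 40)

    def test_zero_separation_rejected(self):
        with pytest.raises(InvalidGeometry):
            compile_trench_patterns(chunk_depth_y=0)

    def test_mirrored_layout(self):
        left = compile_trench_patterns(side="left")
        right = compile_trench_patterns(side="right")
        assert right.commands[2].center[0] == -left.commands[2].center[0]


class TestVolumePlan:
    def test_single_slice(self):
        plan = volume_imaging_plan((10, 5), 100.0, 1)
        assert [a.kind for a in plan] == ["mill", "acquire"]

    def test_130_slices_advance_13_um(self):
        plan = volume_imaging_plan((14.3, 2.0), 100.0, 130)
        assert len(plan) == 260
        assert sum(a.front_advance_nm for a in plan) == pytest.approx(13000.0)

    def test_empty_plan(self):
        assert volume_imaging_plan((10, 5), 100.0, 0) == []


class TestDose:
    @pytest.mark.parametrize("args, expected, tol", [
        ((50, 1.0, 16, 10.377), 0.464, 5e-4),
        ((50, 1.0, 16, 19.271), 0.134, 5e-4),
        ((13, 0.25, 64, 3.4), 1.12, 5e-3),
    ])
    def test_published_doses(self, args, expected, tol):
        assert electron_dose(*args) == pytest.approx(expected, abs=tol)

    def test_zero_current(self):
        assert electron_dose(0, 1, 16, 10) == 0.0

    @given(st.floats(1, 1000), st.floats(0.01, 10), st.integers(1, 64),
           st.floats(1, 50), st.floats(1.5, 4.0))
    @settings(max_examples=50, deadline=None)
    def test_scaling_laws(self, cur, dwell, li, px, k):
        base = electron_dose(cur, dwell, li, px)
        assert electron_dose(k * cur, dwell, li, px) == pytest.approx(k * base, rel=1e-9)
        assert electron_dose(cur, dwell, li, k * px) == pytest.approx(base / k ** 2, rel=1e-9)


class TestSessionBookkeeping:
    TABLE = SessionStats([
        SampleStats("Sum159", 22, 19, 17, (70, 410)),
        SampleStats("HeLa", 22, 18, 18, (100, 450)),
        SampleStats("E. huxleyi", 9, 9, 9, (175, 470)),
        SampleStats("C. reinhardtii", 16, 10, None, (140, 350)),
        SampleStats("S. cerevisiae", 8, 8, 8, (190, 300)),
    ])

    def test_overall_success_rate(self):
        assert success_rate(self.TABLE) == 83.1

    def test_single_sample_rate(self):
        only = SessionStats([SampleStats("C. reinhardtii", 16, 10)])
        assert success_rate(only) == 62.5

    def test_all_successful(self):
        assert success_rate(SessionStats([SampleStats("x", 5, 5)])) == 100.0

    def test_zero_sites_raises(self):
        with pytest.raises(ZeroDivisionError):
            success_rate(SessionStats([]))

    def test_retention(self):
        assert retention_rate(7, 10) == 70.0
        with pytest.raises(ZeroDivisionError):
            retention_rate(0, 0)

    def test_contamination_bookkeeping(self):
        policy = SessionPolicy()
        assert policy.contamination_nm(3600.0) == pytest.approx(50.0)
        assert policy.contamination_nm(1800.0) == pytest.approx(25.0)
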