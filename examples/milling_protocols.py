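"""Compile a staged milling protocol into pattern sequences; dose accounting.

Shows the text protocol format, compilation against a lamella target with
extreme milling points, micro-expansion joints, the lift-out trench layout,
and the electron-dose arithmetic for SEM volume imaging conditions.
"""

from lamellakit.milling_protocols import (
    LamellaTarget,
    compile_lamella_patterns,
    compile_trench_patterns,
    electron_dose,
    expansion_joint_patterns,
    parse_protocol,
    write_pattern_sequence,
)

PROTOCOL = """\
name: rough_standard
stage: rough

[step]
current: 1000
time: 300
pattern_distance: 3
pattern_height: 4

[step]
current: 500
time: 300
pattern_distance: 2
pattern_height: 1.5

[step]
current: 300
time: 300
pattern_distance: 1
pattern_height: 1
"""

proto = parse_protocol(PROTOCOL)
target = LamellaTarget(position=(0.0, 0.0), width=10.0, extremes=(-5.0, 5.0),
                       expansion_joints=True)
print("expansion joints (milled first):")
print(write_pattern_sequence(expansion_joint_patterns(target)))
print("lamella pattern sequence (two patterns per step, gaps 3 -> 2 -> 1 um):")
print(write_pattern_sequence(compile_lamella_patterns(proto, target)))
print("lift-out trench layout (two 40x15 um trenches around a 20 um block,"
      " 10x40 um side trench):")
print(write_pattern_sequence(compile_trench_patterns()))

dose = electron_dose(current_pA=50, dwell_us=1.0, line_integration=16,
                     pixel_size_nm=10.377)
print(f"SEM dose at 50 pA, 1 us dwell, 16x line integration, 10.377 nm px: "
      f"{dose:.3f} e/A^2 per image")
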