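"""Simulate hip-abduction trials, clean and with injected faults.

Generates one correct execution and one with a mid-hold balance wobble,
and prints the trial structure and the ground truth each carries.
"""

from rehabmotion import SyntheticMotionSpec, inject_faults, simulate_abduction

spec = SyntheticMotionSpec(seed=42)
seq, truth = simulate_abduction(spec)
print(f"clean trial: {len(seq)} frames at {seq.frame_rate:.0f} Hz "
      f"({len(seq) / seq.frame_rate:.1f} s)")
print(f"  phases (frames): rest {spec.rest_before}, raise {truth.rise_frames}, "
      f"hold {spec.hold}, return {truth.fall_frames}, rest {spec.rest_after}")
print(f"  peak abduction {spec.peak_abduction:.0f} deg at frame {truth.peak_frame}; "
      f"faults: {truth.faults or 'none'}")

wobbly = inject_faults(spec, [("wobble", 0.04)])
_, truth_w = simulate_abduction(wobbly)
print(f"wobble trial: lateral jolt of {wobbly.wobble_at[1] * 100:.0f} cm at "
      f"frame {wobbly.wobble_at[0]}; faults recorded: {truth_w.faults}")
# The jolt adds a third speed bump to the trunk sway - the signature the
# assessment flags as an extra state transition.
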