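"""Segment a wheel-velocity trace into behavioral-state windows.

Builds a trace with two running bouts and extracts the five 10-s window
classes (onset, locomotion, offset, initial rest, sustained rest) defined
by duration rules around each bout.
"""

from intflex.segmentation import segment_pipeline
from intflex.synthetic import BoutSpec, gen_wheel_velocity

FS = 20.0
bouts = [
    BoutSpec(pre_rest=70.0, run_duration=30.0, post_rest=40.0,
             run_speed=2.0, noise_sd=0.05),
    BoutSpec(pre_rest=30.0, run_duration=25.0, post_rest=70.0,
             run_speed=1.5, noise_sd=0.05),
]
velocity = gen_wheel_velocity(bouts, fs=FS, seed=0)
segments = segment_pipeline(velocity, FS, threshold=0.25)

print(segments.to_string(index=False))
print()
print("Each row is one 10-s analysis window; a bout emits every class whose")
print("duration preconditions it meets (both bouts qualify for locomotion")
print("windows because each is preceded by at least 60 s of rest). Offset")
print("and initial-rest windows of one bout overlap by rule.")
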