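"""Render a synthetic swim, run the full pipeline, print the four features.

A hemisected animal (right half of the spinal cord cut) drags its right
hindlimb: expect near-zero synchronization, a symmetry slope near 0.5,
and a right-foot range roughly half the left.
"""

from frogswim import default_motion_model, generate_traces, render_video
from frogswim.pipeline import run_pipeline

model = default_motion_model("hemisected", seed=1)
traces = generate_traces(model, n_frames=200, fps=60, seed=11)
frames, ground_truth = render_video(traces)

result = run_pipeline(frames)
f = result.features
print(f"frames with a valid angle-pair: {f.n_valid_frames}")
print(f"F1 synchronization : {f.f1_synchronization:+.3f}   (~0: feet move independently)")
print(f"F2 symmetry slope  : {f.f2_symmetry:.3f}    (~0.5: right stroke half of left)")
print(f"F3 right foot range: {f.f3_range_right:6.1f} deg (lesioned side)")
print(f"F4 left foot range : {f.f4_range_left:6.1f} deg (healthy side)")
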