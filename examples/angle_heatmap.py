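"""Build the 180x180 angle-pair histogram of a swim and save the heatmap.

The heatmap is the standard visualization of hindlimb coordination: red
marks the most common (alpha_R, alpha_L) posture, blue postures never
seen, and the white diagonal is perfect mirror symmetry.  An uninjured
animal's mass hugs the diagonal; a hemisected animal's sits along a line
of slope ~0.5.
"""

import matplotlib

matplotlib.use("Agg")

from frogswim import (
    build_histogram,
    default_motion_model,
    features_from_traces,
    generate_traces,
)
from frogswim.kinematics import AnglePair, plot_heatmap

for label in ("uninjured", "hemisected"):
    model = default_motion_model(label, seed=3)
    traces = generate_traces(model, n_frames=600, fps=60, seed=4)
    pairs = [
        AnglePair(r, l)
        for r, l in zip(traces.frames.alpha_right, traces.frames.alpha_left)
    ]
    hist = build_histogram(pairs)
    feats = features_from_traces(traces)
    ax = plot_heatmap(hist, slope=feats.f2_symmetry, title=label)
    out = f"heatmap_{label}.png"
    ax.figure.savefig(out, dpi=120)
    print(f"{label}: beta={feats.f2_symmetry:.2f}, total counts={hist.total} -> {out}")
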