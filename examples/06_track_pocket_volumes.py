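"""Track pocket volumes across trajectory frames.

A model with three cavities — cytoplasmic, mid-membrane and lumenal, in
decreasing size — is jittered over five frames; pockets are re-detected per
frame and matched across time by centroid proximity, yielding a
volume-versus-time table per pocket.
"""

import numpy as np

import memstab
from memstab import fixtures as fx

frame = memstab.MembraneFrame(np.zeros(3), np.array([0.0, 0.0, 1.0]), 15.0)
model = fx.make_multi_cavity_model(
    [(4.5, (0, 0, 10)), (4.0, (11, 0, 0)), (2.5, (0, 0, -10))]
)
frames = fx.make_frames(model, n_frames=5, motion="jitter", sigma=0.08, seed=1)
series = memstab.track_volumes(model, frames, frame, spacing=1.0)

first = series.per_frame[0]
print("pockets in frame 0 (volume A^3, membrane side):")
for p in first.pockets:
    print(f"  {p.volume:7.1f}  {p.side_label}")
print("\nvolume vs time (A^3):")
print(series.volume_vs_time.round(1).to_string())
print("\nmean volumes:", {k: round(v, 1) for k, v in series.mean_volumes.items()})
# Three pockets persist across all frames with small volume fluctuations
# from the coordinate jitter; the cytoplasmic pocket stays the largest.
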