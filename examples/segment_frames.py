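"""Run the full segmentation chain on noisy grayscale frames.

Renders a recording as grayscale video frames (bright birds on a dark
floor plus sensor noise), then applies the measurement chain: low-pass
filter -> Otsu threshold -> connected-component labelling -> blob table.
"""

from hensight import FlockSimConfig, binarize, lowpass, measure_sequence, simulate_flock
from hensight.flock import render_grayscale

cfg = FlockSimConfig(n_birds=12, step_sigma=4.0, duration_s=10, seed=7)
traj = simulate_flock(cfg)
frames = render_grayscale(traj, cfg, fg=200, bg=30, noise_sd=5)

masks = [
    binarize(lowpass(f, sigma_px=1.0), method="otsu", frame_index=i, timestamp_s=float(i))
    for i, f in enumerate(frames)
]
shapes = measure_sequence(masks, min_area=50)

print(shapes.head(6).to_string(index=False))
print()
per_frame = shapes.groupby("frame").size()
print(f"blobs per frame: {per_frame.min()}-{per_frame.max()} (12 birds simulated)")
print("Each row is one blob: a bird, or a touching group, with its area,")
print("boundary-edge perimeter and center of mass in pixels.")
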