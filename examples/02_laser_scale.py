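"""Detect the red laser dots and recover each frame's scale in px/cm.

The detector thresholds redness (R - max(G, B)), keeps blobs in an area
band, and averages pairwise dot distances divided by the calibrated
separation.  On noise-free synthetic frames the recovered scale should
match the ground truth to well under 2%.
"""

from benthic_ready.laserscale import detect_laser_points, estimate_scale
from benthic_ready.synthetic import SceneParams, generate_transect

scenes = generate_transect(n=5, seed=11, params=SceneParams(noise_sd=0.0))

print(f"{'true px/cm':>10s} {'estimated':>10s} {'rel. error':>10s}")
for record, truth in scenes:
    detection = detect_laser_points(record)
    estimate = estimate_scale(detection, truth.laser_separation_cm)
    rel = abs(estimate.px_per_cm - truth.true_scale_px_per_cm) / truth.true_scale_px_per_cm
    print(f"{truth.true_scale_px_per_cm:10.3f} {estimate.px_per_cm:10.3f} {rel:10.4%}")
print()
print("Each estimate uses all three detected dot centroids; sub-pixel")
print("centroiding keeps the error far below the 2% recovery target.")
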