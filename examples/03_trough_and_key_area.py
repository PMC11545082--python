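"""Locate the feeding trough two ways and derive the key area.

The trough is a depth-flat band: the variance method finds rows whose
depth variance is tiny; the keypoint-sparsity method finds the band that
attracts no interest points. Both should agree within a few rows, and the
key area hangs beneath the band with height k1 x (trough height).
"""

from cagepose import (
    SceneConfig,
    compute_key_area,
    generate_scene,
    locate_trough_features,
    locate_trough_variance,
)

frame, _ = generate_scene(SceneConfig(seed=3, roll_angle_deg=0.0))
print("true trough rows: [180, 260)")

by_variance = locate_trough_variance(frame.depth, variance_threshold=400.0)
print(f"variance method : rows [{by_variance.row_top}, {by_variance.row_bottom})")

by_features = locate_trough_features(frame.depth, hessian_threshold=400.0)
print(f"keypoint method : rows [{by_features.row_top}, {by_features.row_bottom})")

key = compute_key_area(by_variance, (frame.width, frame.height), k1=0.6, side_margin=25)
print(f"key area: x={key.x} y={key.y} w={key.w} h={key.h}")
# w is 590 for a 640-wide frame (25-px margins); h = round(0.6 x trough
# height), the region where a lying bird's body profile is visible.
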