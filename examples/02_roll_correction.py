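"""Measure and undo the camera roll from the trough's edge lines.

A scene is rendered with a 2° counterclockwise roll. The estimator finds
the trough edge via Sobel + double Hough and reports the tilt; the
rotation matrix built from that angle deskews the frame, after which the
residual tilt should be near zero.
"""

from cagepose import SceneConfig, correct_frame, estimate_tilt, generate_scene, rotation_matrix

frame, _ = generate_scene(SceneConfig(seed=11, roll_angle_deg=2.0))

tilt = estimate_tilt(frame)
print(f"injected roll: +2.000 deg, estimated: {tilt.angle_deg:+.3f} deg")

m = rotation_matrix(tilt.angle_deg, center=(320, 240))
print("correction matrix (rotates the content back by the measured tilt):")
for row in m:
    print("  [" + ", ".join(f"{v:8.3f}" for v in row) + "]")

corrected, _ = correct_frame(frame)
residual = estimate_tilt(corrected)
print(f"residual tilt after correction: {residual.angle_deg:+.3f} deg")
# The residual should be within a few hundredths of a degree — small
# enough that the trough band is horizontal for the downstream stages.
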