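"""Generate one synthetic cage scene and detect the lying birds.

The scene holds two lying birds (flat-wide ellipses beneath the feeding
trough), one standing bird (only its legs reach below the trough) and one
cage pillar, viewed with a 1° camera roll. The detector should box the
two lying birds and nothing else.
"""

from cagepose import SceneConfig, detect_lying, generate_scene, iou

frame, truth = generate_scene(SceneConfig(seed=1))
detections = detect_lying(frame)

print("ground truth:")
for box in truth.boxes:
    print(f"  {box.label:9s} x={box.x:3d} y={box.y:3d} w={box.w:3d} h={box.h:3d}")

print("detections (lying only by design):")
for det in detections:
    best = max(iou(det, b) for b in truth.with_label("lying"))
    x, y, w, h = det.box
    print(f"  {det.posture:9s} x={x:3d} y={y:3d} w={w:3d} h={h:3d}  IoU vs truth {best:.2f}")

# Each detection should overlap one lying annotation with IoU well above
# 0.5; the standing bird's legs and the pillar must not be boxed.
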