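"""Synthetic cage scenes with ground truth.

The farm footage behind this method is not redistributable, so the
package ships a generator that emulates the structure every pipeline
stage depends on:

* a horizontal trough band of near-constant depth with sharp depth steps
  at its edges (drives both the roll estimator and the trough locators);
* a textured background plane (smooth depth undulation plus small hard
  bumps) far enough behind the trough that it can never fall inside the
  lying-bird depth band;
* lying birds as flat-wide filled ellipses directly beneath the trough at
  a depth offset drawn inside the segmentation band;
* standing birds as thin short leg strokes (too few foreground pixels per
  column to survive the column-fill test);
* cage pillars as tall-thin rectangles at lying-compatible depth (survive
  the column test, die at the aspect-ratio test);
* an injected camera roll, additive Gaussian depth noise, zero-valued
  dropout, and the sensor's black registration borders.

The color channel is a dim depth-shaded rendering — deliberately too dark
and featureless for color-only detection, as in a broiler house lit below
10 lux — but with a strong step at the trough edges so the roll estimator
has something to work with. Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .correction import apply_correction, rotation_matrix
from .frame_io import MergedFrame, write_merged

__all__ = ["SceneConfig", "Box", "Annotation", "generate_scene", "generate_dataset"]


@dataclass(frozen=True)
class Box:
    x: int
    y: int
    w: int
    h: int
    label: str  # lying | standing | pillar

    def as_tuple(self):
        return (self.x, self.y, self.w, self.h)


@dataclass(frozen=True)
class Annotation:
    frame_id: str
    boxes: tuple

    def with_label(self, label: str):
        return [b for b in self.boxes if b.label == label]

    def to_dict(self) -> dict:
        return {
            "frame": self.frame_id,
            "boxes": [asdict(b) for b in self.boxes],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Annotation":
        return cls(frame_id=d["frame"], boxes=tuple(Box(**b) for b in d["boxes"]))


@dataclass(frozen=True)
class SceneConfig:
    width: int = 640
    height: int = 480
    trough_rows: tuple = (180, 260)
    trough_depth_mm: float = 600.0
    background_depth_mm: float = 1100.0
    background_texture_sd_mm: float = 50.0  # smooth undulation amplitude
    n_bumps: int = 300  # hard texture bumps (litter, mesh, far birds)
    bump_depth_range_mm: tuple = (60.0, 140.0)  # behind the background plane
    bump_radius_range_px: tuple = (3, 8)
    n_lying: int = 2
    n_standing: int = 1
    n_pillars: int = 1
    lying_offset_range_mm: tuple = (80.0, 220.0)  # behind the trough plane
    lying_half_axes_px: tuple = (52.0, 20.0)  # (horizontal, vertical): flat-wide
    bird_scale_range: tuple = (0.9, 1.1)
    leg_size_px: tuple = (5, 16)  # (width, height) of one standing-bird leg
    standing_body_in_key: bool = False  # small-bird failure mode: body shows
    pillar_width_px: int = 24
    pillar_offset_mm: float = 150.0
    roll_angle_deg: float = 1.0
    depth_noise_sd_mm: float = 5.0
    dropout_fraction: float = 0.02
    border_cols: int = 50
    color_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        top, bottom = self.trough_rows
        if not (0 < top < bottom < self.height):
            raise ValueError(f"trough_rows {self.trough_rows} outside the image")
        if not self.trough_depth_mm < self.background_depth_mm:
            raise ValueError("trough must be closer than the background")
        lo, hi = self.lying_offset_range_mm
        limit = self.background_depth_mm - self.trough_depth_mm
        if not (0 < lo < hi < limit):
            raise ValueError(
                f"lying offsets {self.lying_offset_range_mm} must lie strictly "
                f"inside (0, {limit})"
            )
        if not 0 <= self.dropout_fraction < 1:
            raise ValueError("dropout_fraction must be in [0, 1)")

    def replace(self, **kw) -> "SceneConfig":
        return replace(self, **kw)


def _smooth_field(rng, shape, sd, cell=20):
    """Smooth random depth undulation with ~cell-px correlation length."""
    from scipy.ndimage import zoom

    h, w = shape
    coarse = rng.normal(0.0, 1.0, (h // cell + 2, w // cell + 2))
    fine = zoom(coarse, (h / coarse.shape[0], w / coarse.shape[1]), order=3)
    fine = fine[:h, :w]
    return fine / fine.std() * sd


def _place_objects(rng, widths, lo, hi, min_gap=25):
    """Non-overlapping left edges for objects of the given widths.

    Objects are laid out left to right in a random order with at least
    ``min_gap`` px between edges; the leftover span is split randomly
    among the gaps, so any feasible layout can occur.
    """
    n = len(widths)
    if n == 0:
        return []
    order = rng.permutation(n)
    free = (hi - lo) - sum(widths) - min_gap * (n - 1)
    if free < 0:
        raise RuntimeError("scene objects do not fit in the available span; "
                           "reduce counts or sizes")
    extras = np.diff(np.concatenate([[0.0], np.sort(rng.uniform(0, free, n))]))
    lefts = np.empty(n)
    x = float(lo)
    for slot, k in enumerate(order):
        x += extras[slot]
        lefts[k] = x
        x += widths[k] + min_gap
    return lefts


def _shade(depth, trough_depth):
    """Dim depth-shaded color rendering (yellowish artificial light)."""
    gray = np.clip(90.0 - (depth - trough_depth) * (40.0 / 300.0), 10.0, 160.0)
    return np.stack([gray, 0.85 * gray, 0.55 * gray], axis=-1)


def generate_scene(config: SceneConfig | None = None, frame_id: str = "frame_0000"):
    """Render one scene; returns (MergedFrame, Annotation).

    Annotation boxes are in deskewed (roll-free) coordinates — the frame
    the correction stage recovers — with lying boxes inside the nominal
    key area.
    """
    config = config or SceneConfig()
    rng = np.random.default_rng(config.seed)
    H, W = config.height, config.width
    top, bottom = config.trough_rows
    trough_h = bottom - top

    depth = np.full((H, W), config.background_depth_mm, dtype=np.float64)
    depth += _smooth_field(rng, (H, W), config.background_texture_sd_mm)

    # hard bumps: strong interest points for the keypoint-sparsity locator
    r_lo, r_hi = config.bump_radius_range_px
    d_lo, d_hi = config.bump_depth_range_mm
    for _ in range(config.n_bumps):
        r = rng.uniform(0, H)
        c = rng.uniform(0, W)
        if top - r_hi <= r <= bottom + r_hi:
            continue  # keep the trough band pristine
        rad = rng.uniform(r_lo, r_hi)
        amp = rng.uniform(d_lo, d_hi)
        rr, cc = draw_disk((r, c), rad, shape=(H, W))
        depth[rr, cc] += amp

    depth[top:bottom, :] = config.trough_depth_mm

    # --- objects beneath the trough -------------------------------------
    key_h = max(1, round(0.6 * trough_h))  # nominal key area for placement
    boxes = []
    specs = []  # (kind, width)
    a0, b0 = config.lying_half_axes_px
    scales = rng.uniform(*config.bird_scale_range, size=config.n_lying + config.n_standing)
    for i in range(config.n_lying):
        specs.append(("lying", 2 * a0 * scales[i] + 2))
    leg_w, leg_h = config.leg_size_px
    for i in range(config.n_standing):
        specs.append(("standing", 2 * leg_w + 18))
    for _ in range(config.n_pillars):
        specs.append(("pillar", config.pillar_width_px))

    margin = config.border_cols + 20
    lefts = (
        _place_objects(rng, [w for _, w in specs], margin, W - margin)
        if specs else []
    )

    si = 0  # scale index
    for (kind, width), left in zip(specs, lefts):
        if kind == "lying":
            a = a0 * scales[si]
            b = b0 * scales[si]
            si += 1
            offset = rng.uniform(*config.lying_offset_range_mm)
            cy = bottom + 2 + b
            cx = left + a + 1
            rr, cc = draw_ellipse(cy, cx, b, a, shape=(H, W))
            depth[rr, cc] = config.trough_depth_mm + offset
            x0, x1 = int(cc.min()), int(cc.max())
            y0, y1 = int(rr.min()), int(rr.max())
            boxes.append(Box(x0, y0, x1 - x0 + 1, y1 - y0 + 1, "lying"))
        elif kind == "standing":
            scale = scales[si]
            si += 1
            offset = rng.uniform(*config.lying_offset_range_mm)
            x0 = int(left)
            for leg in range(2):
                lx = x0 + leg * (leg_w + 18)
                depth[bottom : bottom + leg_h, lx : lx + leg_w] = (
                    config.trough_depth_mm + offset
                )
            boxes.append(Box(x0, bottom, 2 * leg_w + 18, leg_h, "standing"))
            if config.standing_body_in_key:
                # small-bird failure mode: part of the body dips below the
                # trough even when the bird stands
                ba, bb = 32 * scale, 14 * scale
                rr, cc = draw_ellipse(bottom + 4, x0 + leg_w + 9, bb, ba, shape=(H, W))
                keep = rr >= bottom
                depth[rr[keep], cc[keep]] = config.trough_depth_mm + offset
        else:  # pillar
            x0 = int(left)
            w = config.pillar_width_px
            depth[bottom:H, x0 : x0 + w] = (
                config.trough_depth_mm + config.pillar_offset_mm
            )
            boxes.append(Box(x0, bottom, w, H - bottom, "pillar"))

    color = _shade(depth, config.trough_depth_mm)
    frame = MergedFrame(
        color=np.clip(np.rint(color), 0, 255).astype(np.uint8),
        depth=np.clip(np.rint(depth), 0, 65535).astype(np.uint16),
    )

    # --- camera and sensor effects --------------------------------------
    if config.roll_angle_deg != 0.0:
        m = rotation_matrix(-config.roll_angle_deg, center=(W / 2.0, H / 2.0))
        frame = apply_correction(frame, m)

    d = frame.depth.astype(np.float64)
    nz = d > 0
    d[nz] += rng.normal(0.0, config.depth_noise_sd_mm, size=int(nz.sum()))
    d[nz] = np.maximum(d[nz], 1.0)

    if config.dropout_fraction > 0:
        drop = rng.random((H, W)) < config.dropout_fraction
        d[drop] = 0.0

    c = frame.color.astype(np.float64)
    if config.color_noise_sd > 0:
        c += rng.normal(0.0, config.color_noise_sd, size=c.shape)

    b = config.border_cols
    d[:, :b] = 0.0
    d[:, W - b :] = 0.0
    c[:, :b] = 0.0
    c[:, W - b :] = 0.0

    out = MergedFrame(
        color=np.clip(np.rint(c), 0, 255).astype(np.uint8),
        depth=np.clip(np.rint(d), 0, 65535).astype(np.uint16),
    )
    return out, Annotation(frame_id=frame_id, boxes=tuple(boxes))


def frame_seed(master_seed: int, index: int) -> int:
    """Stable per-frame seed derived from the dataset master seed."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


def generate_frames(n_frames: int, config: SceneConfig | None = None):
    """Yield (MergedFrame, Annotation) pairs with per-frame derived seeds."""
    config = config or SceneConfig()
    for i in range(n_frames):
        cfg = config.replace(seed=frame_seed(config.seed, i))
        yield generate_scene(cfg, frame_id=f"frame_{i:04d}")


def generate_dataset(n_frames: int, config: SceneConfig | None = None, out_dir=None) -> dict:
    """Write merged PNGs plus a JSON annotation manifest; returns the manifest."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    config = config or SceneConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = []
    for i, (frame, ann) in enumerate(generate_frames(n_frames, config)):
        fname = f"{ann.frame_id}.png"
        write_merged(frame, out_dir / fname)
        entry = ann.to_dict()
        entry["file"] = fname
        frames.append(entry)
    manifest = {
        "frames": frames,
        "config": asdict(config),
        "seed": config.seed,
    }
    manifest = json.loads(json.dumps(manifest))  # JSON-canonical (tuples→lists)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
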