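"""Camera roll estimation and correction.

The depth camera rides a moving carriage, so frames arrive with a small
roll angle and the feeding trough — the geometric anchor of the whole
pipeline — is not horizontal. The trough's edges are long, straight and
high-contrast, so the roll is measured from them:

gray → y-direction 3×3 Sobel → 3×3 median → binarize (threshold 100) →
probabilistic Hough inside a preset ROI, redrawing the found segments on a
black canvas → second Hough on the canvas → the longest segment's
inclination is the roll angle.

The double Hough pass exists because a single pass tends to fragment one
physical edge into several collinear pieces; redrawing and re-extracting
fuses them so "longest" means the full edge. The frame is then rotated by
the negated angle about the image center with a standard 2×3 affine
matrix. Sign convention: positive angle = scene tilted counterclockwise
(as displayed); the correction rotates clockwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.transform import probabilistic_hough_line

from .frame_io import MergedFrame
from .params import CorrectionConfig, HoughParams

__all__ = [
    "TiltEstimate",
    "estimate_tilt",
    "rotation_matrix",
    "apply_correction",
    "correct_frame",
]

# probabilistic_hough_line samples pixels in random order; a fixed seed
# keeps the whole pipeline deterministic.
_HOUGH_SEED = 12345


@dataclass(frozen=True)
class TiltEstimate:
    """Measured roll: signed degrees, positive = counterclockwise tilt."""

    angle_deg: float
    line: tuple  # (x1, y1, x2, y2) of the longest detected segment
    found: bool


def _theta(hough: HoughParams) -> np.ndarray:
    step = math.radians(hough.angle_step_deg)
    return np.arange(-math.pi / 2, math.pi / 2, step)


def _hough_segments(binary: np.ndarray, hough: HoughParams):
    return probabilistic_hough_line(
        binary,
        threshold=hough.threshold,
        line_length=hough.min_line_length,
        line_gap=hough.max_line_gap,
        theta=_theta(hough),
        rng=np.random.default_rng(_HOUGH_SEED),
    )


def longest_segment(segments):
    """Longest segment; ties broken by scan order (first encountered)."""
    best, best_len = None, -1.0
    for (x1, y1), (x2, y2) in segments:
        length = math.hypot(x2 - x1, y2 - y1)
        if length > best_len + 1e-12:
            best, best_len = (x1, y1, x2, y2), length
    return best


def _segment_angle_deg(x1, y1, x2, y2) -> float:
    # Image rows grow downward, so a scene tilted counterclockwise (as
    # displayed) has its trough edge rising with x: y decreases as x grows.
    angle = math.degrees(math.atan2(-(y2 - y1), x2 - x1))
    if angle > 90:
        angle -= 180
    elif angle <= -90:
        angle += 180
    return angle


def _refine_angle(canvas: np.ndarray, seg, band_px: float = 3.0) -> float:
    """Inclination of the longest segment, measured over its support.

    Hough segment endpoints follow the accumulator's quantized direction,
    so the endpoint angle carries the angular grid's bias and the segment
    may cover only part of the physical edge. The edge pixels themselves
    do not: a total-least-squares (principal axis) fit over the canvas
    pixels within ``band_px`` of the segment's line recovers the
    inclination at sub-quantization accuracy.
    """
    x1, y1, x2, y2 = seg
    fallback = _segment_angle_deg(x1, y1, x2, y2)
    dx, dy = x2 - x1, y2 - y1
    norm = math.hypot(dx, dy)
    if norm == 0:
        return fallback
    pts = np.argwhere(canvas)  # (row, col)
    px, py = pts[:, 1], pts[:, 0]
    dist = np.abs(dy * (px - x1) - dx * (py - y1)) / norm
    sel = dist <= band_px
    if sel.sum() < 2:
        return fallback
    x = px[sel].astype(np.float64)
    y = py[sel].astype(np.float64)
    cov = np.cov(np.stack([x - x.mean(), y - y.mean()]))
    _, vecs = np.linalg.eigh(cov)
    vx, vy = vecs[:, -1]  # principal direction
    angle = math.degrees(math.atan2(-vy, vx))
    if angle > 90:
        angle -= 180
    elif angle <= -90:
        angle += 180
    return angle


def estimate_tilt(
    frame: MergedFrame,
    roi: tuple | None = None,
    binarize_threshold: int = 100,
    config: CorrectionConfig | None = None,
) -> TiltEstimate:
    """Measure the roll angle from the trough edges in the color image."""
    config = config or CorrectionConfig()
    if roi is None:
        roi = config.roi
    if binarize_threshold is None:
        binarize_threshold = config.binarize_threshold
    if frame.width == 0 or frame.height == 0:
        raise ValueError("empty image")

    gray = frame.color.astype(np.float64) @ np.array([0.299, 0.587, 0.114])
    sob = ndimage.sobel(gray, axis=0, mode="reflect")  # y-direction, 3×3
    mag = np.clip(np.abs(sob), 0, 255)
    med = ndimage.median_filter(mag, size=config.median_ksize, mode="reflect")
    binary = med > binarize_threshold

    x0, y0, x1, y1 = roi
    x0, y0 = max(0, x0), max(0, y0)
    x1, y1 = min(frame.width, x1), min(frame.height, y1)
    if x1 <= x0 or y1 <= y0:
        raise ValueError(f"ROI {roi} is outside the image bounds")

    segments = _hough_segments(binary[y0:y1, x0:x1], config.hough)
    if not segments:
        return TiltEstimate(angle_deg=0.0, line=(0, 0, 0, 0), found=False)

    canvas = np.zeros((frame.height, frame.width), dtype=bool)
    for (sx1, sy1), (sx2, sy2) in segments:
        rr, cc = draw_line(sy1 + y0, sx1 + x0, sy2 + y0, sx2 + x0)
        canvas[rr, cc] = True

    fused = _hough_segments(canvas, config.hough)
    if not fused:
        return TiltEstimate(angle_deg=0.0, line=(0, 0, 0, 0), found=False)

    seg = longest_segment(fused)
    angle = _refine_angle(canvas, seg)
    if abs(angle) >= 45:  # not a near-horizontal structure; treat as miss
        return TiltEstimate(angle_deg=0.0, line=seg, found=False)
    return TiltEstimate(angle_deg=angle, line=seg, found=True)


def rotation_matrix(angle_deg: float, center: tuple = (320.0, 240.0)) -> np.ndarray:
    """2×3 affine matrix that rotates image content by −angle_deg about center.

    Applying it to a frame whose scene is tilted ``angle_deg``
    counterclockwise makes the trough horizontal again. The upper-left 2×2
    block is a pure rotation.
    """
    if not math.isfinite(angle_deg):
        raise ValueError("angle must be finite")
    cx, cy = center
    a = math.radians(-angle_deg)
    al, be = math.cos(a), math.sin(a)
    return np.array(
        [
            [al, be, (1 - al) * cx - be * cy],
            [-be, al, be * cx + (1 - al) * cy],
        ]
    )


def _inverse_affine(m: np.ndarray) -> np.ndarray:
    full = np.vstack([m, [0.0, 0.0, 1.0]])
    return np.linalg.inv(full)[:2]


def apply_correction(frame: MergedFrame, m: np.ndarray) -> MergedFrame:
    """Warp color and depth with the same affine matrix.

    Color uses bilinear interpolation; depth uses nearest-neighbour so no
    depth values are invented at object boundaries. Out-of-frame regions
    are filled with 0 (the "no reading" code).
    """
    m = np.asarray(m, dtype=np.float64)
    if m.shape != (2, 3):
        raise ValueError(f"expected 2×3 affine matrix, got shape {m.shape}")
    inv = _inverse_affine(m)  # maps output (x, y) → input (x, y)
    # scipy's affine_transform works in (row, col): swap axes of the map.
    matrix_rc = np.array([[inv[1, 1], inv[1, 0]], [inv[0, 1], inv[0, 0]]])
    offset_rc = (inv[1, 2], inv[0, 2])

    color = np.stack(
        [
            ndimage.affine_transform(
                frame.color[:, :, ch].astype(np.float64),
                matrix_rc,
                offset=offset_rc,
                order=1,
                mode="constant",
                cval=0.0,
            )
            for ch in range(3)
        ],
        axis=-1,
    )
    depth = ndimage.affine_transform(
        frame.depth, matrix_rc, offset=offset_rc, order=0, mode="constant", cval=0
    )
    return MergedFrame(
        color=np.clip(np.rint(color), 0, 255).astype(np.uint8),
        depth=depth.astype(np.uint16),
    )


def correct_frame(
    frame: MergedFrame, config: CorrectionConfig | None = None
) -> tuple[MergedFrame, TiltEstimate]:
    """Estimate the roll and return the deskewed frame (or the frame
    unchanged when no trough edge is found)."""
    config = config or CorrectionConfig()
    tilt = estimate_tilt(frame, config=config)
    if not tilt.found:
        return frame, tilt
    center = config.center or (frame.width / 2.0, frame.height / 2.0)
    m = rotation_matrix(tilt.angle_deg, center=center)
    return apply_correction(frame, m), tilt
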