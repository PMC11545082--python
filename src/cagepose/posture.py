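"""Lying-bird detection by dynamic depth-threshold segmentation.

The trough occludes a standing bird almost completely — only the legs show
beneath it — while a lying bird's whole body profile fills the key area.
Because the camera–cage distance varies along the carriage run (and with
yaw, across each frame), a single global depth threshold cannot separate
the birds from the background. Instead each key-area column c is
segmented against the trough's own depth in that column: with d_c the
depth at the trough's middle row and d' a key-area pixel's depth, the
pixel is foreground iff

    d_c + k2 < d' < d_c + k3        (strict on both sides)

i.e. the body lies a bounded distance behind the trough plane. The binary
mask is then cleaned (morphological opening/closing + median filter),
columns with too few foreground pixels are erased (N_c > H_roi/k4 to
survive — legs of standing birds die here), nearby fragments of one body
are fused (contour-to-contour distance < 20 px), and finally each
candidate's bounding box must be flat-wide (W/H > k5) — tall-thin cage
pillars die here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.draw import line as draw_line
from skimage.measure import label, regionprops
from skimage.morphology import disk

from .correction import correct_frame
from .frame_io import MergedFrame
from .params import DetectionParams, PipelineConfig
from .trough import KeyArea, TroughLocation, TroughNotFoundError, compute_key_area, locate_trough

__all__ = [
    "Detection",
    "segment_key_area",
    "denoise_mask",
    "filter_columns",
    "merge_contours",
    "extract_boxes",
    "detect_lying",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Detection:
    """A lying-bird bounding box (x, y, w, h) in corrected-image pixels."""

    box: tuple
    posture: str = "lying"
    source_frame: str | None = None

    @property
    def x(self):
        return self.box[0]

    @property
    def y(self):
        return self.box[1]

    @property
    def w(self):
        return self.box[2]

    @property
    def h(self):
        return self.box[3]


def segment_key_area(
    depth: np.ndarray,
    trough: TroughLocation,
    key: KeyArea,
    k2: float = 65.0,
    k3: float = 250.0,
) -> np.ndarray:
    """Per-column dynamic threshold segmentation of the key area.

    Returns a full-frame boolean mask whose foreground is confined to the
    key area. Columns where the trough depth reads 0 (dropout) are skipped
    entirely, and zero-depth pixels are never foreground.
    """
    depth = np.asarray(depth)
    if key.h < 1 or key.w < 1:
        raise ValueError("key area is empty")
    mask = np.zeros(depth.shape, dtype=bool)
    ref = depth[trough.mid_row, key.x : key.x + key.w].astype(np.float64)
    sub = depth[key.y : key.y + key.h, key.x : key.x + key.w].astype(np.float64)
    fg = (sub > ref + k2) & (sub < ref + k3) & (sub > 0) & (ref > 0)
    mask[key.y : key.y + key.h, key.x : key.x + key.w] = fg
    return mask


def denoise_mask(mask: np.ndarray, params: DetectionParams | None = None) -> np.ndarray:
    """Morphological opening, closing, then median filtering."""
    params = params or DetectionParams()
    footprint = disk(params.morph_kernel_px // 2)  # 3×3 elliptical kernel
    out = ndimage.binary_opening(mask, structure=footprint)
    out = ndimage.binary_closing(out, structure=footprint)
    out = ndimage.median_filter(out.astype(np.uint8), size=params.median_ksize) > 0
    return out


def filter_columns(mask: np.ndarray, h_roi: int, k4: float = 2.0) -> np.ndarray:
    """Erase whole columns whose foreground count N_c fails N_c > H_roi/k4."""
    counts = mask.sum(axis=0)
    out = mask.copy()
    out[:, ~(counts > h_roi / k4)] = False
    return out


def _component_boundaries(labels: np.ndarray, n: int) -> list:
    """Edge-contour pixel coordinates of each connected component."""
    eroded = ndimage.grey_erosion(labels, size=(3, 3))
    boundary = (labels > 0) & (eroded != labels)
    pts = np.argwhere(boundary)
    lab_of = labels[pts[:, 0], pts[:, 1]]
    return [pts[lab_of == i] for i in range(1, n + 1)]


def merge_contours(mask: np.ndarray, gap: float = 20.0) -> np.ndarray:
    """Fuse components whose contours come within ``gap`` pixels.

    Distance is the shortest point-to-point distance between the two edge
    contours — never between centroids, which would fail to fuse two
    large nearly-touching fragments of the same body. The closest pair is
    connected with a 1-px line, components are re-extracted, and the
    process repeats until no pair qualifies; the result is idempotent.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    out = np.asarray(mask).copy()
    while True:
        labels, n = label(out, connectivity=2, return_num=True)
        if n < 2:
            return out
        contours = _component_boundaries(labels, n)
        best = None  # (dist, i, j, point_i, point_j)
        for i in range(n):
            tree = cKDTree(contours[i])
            for j in range(i + 1, n):
                dists, idx = tree.query(contours[j])
                kj = int(np.argmin(dists))
                d = float(dists[kj])
                if d < gap and (best is None or d < best[0]):
                    best = (d, contours[i][idx[kj]], contours[j][kj])
        if best is None:
            return out
        (r1, c1), (r2, c2) = best[1], best[2]
        rr, cc = draw_line(int(r1), int(c1), int(r2), int(c2))
        out[rr, cc] = True


def extract_boxes(
    mask: np.ndarray,
    min_area: int = 50,
    k5: float = 1.7,
    source_frame: str | None = None,
) -> list:
    """Bounding boxes of foreground regions, keeping flat-wide ones only.

    Regions below ``min_area`` pixels are discarded as noise; surviving
    boxes must satisfy W/H > k5 (strict) — the lying-bird shape test.
    """
    labels = label(mask, connectivity=2)
    detections = []
    for region in regionprops(labels):
        if region.area < min_area:
            continue
        minr, minc, maxr, maxc = region.bbox
        w, h = maxc - minc, maxr - minr
        if w / h > k5:
            detections.append(
                Detection(box=(minc, minr, w, h), posture="lying", source_frame=source_frame)
            )
    detections.sort(key=lambda d: (d.x, d.y))
    return detections


def detect_lying(
    frame: MergedFrame,
    params: DetectionParams | None = None,
    config: PipelineConfig | None = None,
    source_frame: str | None = None,
    detector=None,
) -> list:
    """Full pipeline: deskew → locate trough → key area → segment → filter.

    Returns the list of lying-bird detections; an unfindable trough is not
    an error — the frame is skipped with a log message and an empty list.
    """
    config = config or PipelineConfig()
    params = params or config.params

    corrected, tilt = correct_frame(frame, config.correction)
    if not tilt.found:
        logger.info("frame %s: no trough edge found, skipping roll correction", source_frame)
    try:
        trough = locate_trough(corrected.depth, config.trough, detector=detector)
    except TroughNotFoundError as exc:
        logger.info("frame %s: trough not found (%s), skipping", source_frame, exc)
        return []
    try:
        key = compute_key_area(
            trough,
            (corrected.width, corrected.height),
            k1=params.k1,
            side_margin=config.key_area_side_margin,
        )
    except ValueError as exc:
        logger.info("frame %s: degenerate key area (%s), skipping", source_frame, exc)
        return []

    mask = segment_key_area(corrected.depth, trough, key, k2=params.k2, k3=params.k3)
    mask = denoise_mask(mask, params)
    mask = filter_columns(mask, key.h, k4=params.k4)
    mask = merge_contours(mask, gap=params.merge_gap_px)
    return extract_boxes(
        mask, min_area=params.min_contour_area_px, k5=params.k5, source_frame=source_frame
    )
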