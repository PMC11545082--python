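"""Locating the feeding trough and deriving the key area.

The trough is a flat band spanning the cage front: in the depth image its
rows have near-constant depth, while background rows (litter, mesh, birds)
vary. Two locators exploit this:

* **variance method** — rows whose depth variance (zero/no-reading pixels
  excluded, registration border columns excluded) falls below a threshold
  are marked; the midpoint pixel of each marked row is set white on a
  black canvas, a probabilistic Hough pass extracts segments from the
  resulting dotted vertical line, and the row-span of the longest segment
  is the trough band.

* **keypoint-sparsity method** — an interest-point detector is run on the
  depth image rendered to 8 bits; textured regions attract keypoints but
  the flat trough attracts none, so after marking every keypoint row and
  its immediate neighbours the *unmarked* rows trace the trough. The same
  midpoint/Hough machinery turns them into a band. The detector is
  pluggable; the default is a determinant-of-Hessian blob detector, the
  same response family as SURF's interest operator.

The key area — where a lying bird's body profile is visible — hangs
directly below the trough. Its height scales with the trough height
(``h = round(k1 · l_AB)``) so that frames shot closer to the cage, where
the trough appears taller, get a proportionally taller search area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import blob_doh

from .correction import _hough_segments, longest_segment
from .params import HoughParams, TroughConfig

__all__ = [
    "TroughLocation",
    "KeyArea",
    "TroughNotFoundError",
    "HessianBlobDetector",
    "locate_trough_variance",
    "locate_trough_features",
    "locate_trough",
    "compute_key_area",
    "depth_to_8bit",
]


class TroughNotFoundError(RuntimeError):
    """No trough band could be identified; the caller may skip the frame."""


@dataclass(frozen=True)
class TroughLocation:
    """Half-open row band [row_top, row_bottom) holding the trough."""

    row_top: int
    row_bottom: int
    col_left: int
    col_right: int

    def __post_init__(self):
        if not (0 <= self.row_top < self.row_bottom):
            raise ValueError(f"invalid trough band [{self.row_top}, {self.row_bottom})")

    @property
    def height_px(self) -> int:
        return self.row_bottom - self.row_top

    @property
    def mid_row(self) -> int:
        return (self.row_top + self.row_bottom) // 2


@dataclass(frozen=True)
class KeyArea:
    """Axis-aligned rectangle (x, y, w, h) beneath the trough."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self):
        if self.w < 1 or self.h < 1:
            raise ValueError(f"degenerate key area {self!r}")


def depth_to_8bit(depth: np.ndarray) -> np.ndarray:
    """Min–max normalize nonzero depth to uint8; no-reading pixels map to 0."""
    depth = np.asarray(depth)
    valid = depth > 0
    if not valid.any():
        return np.zeros(depth.shape, dtype=np.uint8)
    lo = int(depth[valid].min())
    hi = int(depth[valid].max())
    if hi == lo:
        out = np.where(valid, 255, 0)
        return out.astype(np.uint8)
    out = np.zeros(depth.shape, dtype=np.uint8)
    out[valid] = np.rint((depth[valid].astype(np.float64) - lo) / (hi - lo) * 255)
    return out


class HessianBlobDetector:
    """Determinant-of-Hessian interest-point detector on 8-bit images.

    The response threshold follows the SURF convention for 8-bit imagery
    (default 400) and is rescaled internally to the unit-intensity scale
    the scale-space implementation works on; the calibration factor was
    chosen so the default threshold yields keypoint densities comparable
    to a SURF detector at its default setting on textured depth renderings.
    """

    _RESPONSE_SCALE = 2 * 255.0**2

    def __init__(self, hessian_threshold: float = 400.0, min_sigma: float = 2.0,
                 max_sigma: float = 12.0, num_sigma: int = 6):
        self.hessian_threshold = hessian_threshold
        self.min_sigma = min_sigma
        self.max_sigma = max_sigma
        self.num_sigma = num_sigma

    def __call__(self, image8: np.ndarray) -> np.ndarray:
        blobs = blob_doh(
            image8.astype(np.float64) / 255.0,
            min_sigma=self.min_sigma,
            max_sigma=self.max_sigma,
            num_sigma=self.num_sigma,
            threshold=self.hessian_threshold / self._RESPONSE_SCALE,
        )
        return blobs[:, :2]  # (row, col) per keypoint


def _row_variances(depth: np.ndarray, col_left: int, col_right: int) -> np.ndarray:
    """Per-row depth variance over the analysed columns, ignoring zeros.

    Rows with fewer than two valid pixels get +inf (never marked flat).
    """
    region = depth[:, col_left:col_right].astype(np.float64)
    valid = region > 0
    n = valid.sum(axis=1)
    s = np.where(valid, region, 0.0).sum(axis=1)
    ss = np.where(valid, region * region, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = ss / n - (s / n) ** 2
    var[n < 2] = np.inf
    return np.maximum(var, 0.0)


def _band_from_marked_rows(
    marked: np.ndarray, shape: tuple, col_left: int, col_right: int, hough: HoughParams
) -> TroughLocation:
    """Dotted-line → Hough → longest segment → row band."""
    height, width = shape
    canvas = np.zeros((height, width), dtype=bool)
    mid_col = width // 2
    canvas[np.flatnonzero(marked), mid_col] = True
    if not canvas.any():
        raise TroughNotFoundError("no candidate trough rows")
    segments = _hough_segments(canvas, hough)
    if not segments:
        raise TroughNotFoundError("no line segment through candidate rows")
    x1, y1, x2, y2 = longest_segment(segments)
    row_top, row_bottom = min(y1, y2), max(y1, y2) + 1
    return TroughLocation(row_top=row_top, row_bottom=row_bottom,
                          col_left=col_left, col_right=col_right)


def locate_trough_variance(
    depth: np.ndarray,
    variance_threshold: float = 400.0,
    border_cols: int = 50,
    hough: HoughParams | None = None,
) -> TroughLocation:
    """Find the trough as the longest run of depth-flat rows."""
    if variance_threshold <= 0:
        raise ValueError("variance_threshold must be > 0")
    depth = np.asarray(depth)
    height, width = depth.shape
    col_left, col_right = border_cols, width - border_cols
    var = _row_variances(depth, col_left, col_right)
    marked = var < variance_threshold
    hough = hough or TroughConfig().hough
    return _band_from_marked_rows(marked, depth.shape, col_left, col_right, hough)


def locate_trough_features(
    depth: np.ndarray,
    detector=None,
    hessian_threshold: float = 400.0,
    border_cols: int = 50,
    hough: HoughParams | None = None,
) -> TroughLocation:
    """Find the trough as the longest keypoint-free run of rows."""
    depth = np.asarray(depth)
    height, width = depth.shape
    col_left, col_right = border_cols, width - border_cols
    if detector is None:
        detector = HessianBlobDetector(hessian_threshold=hessian_threshold)
    keypoints = np.asarray(detector(depth_to_8bit(depth)))
    keypoint_rows = np.zeros(height, dtype=bool)
    if keypoints.size:
        cols = keypoints[:, 1]
        rows = keypoints[(cols >= col_left) & (cols < col_right), 0]
        rows = np.rint(rows).astype(int)
        for offset in (-1, 0, 1):  # mark the row and its immediate neighbours
            shifted = np.clip(rows + offset, 0, height - 1)
            keypoint_rows[shifted] = True
    unmarked = ~keypoint_rows
    hough = hough or TroughConfig().hough
    return _band_from_marked_rows(unmarked, depth.shape, col_left, col_right, hough)


def locate_trough(depth: np.ndarray, config: TroughConfig | None = None,
                  detector=None) -> TroughLocation:
    """Dispatch to the configured locator method."""
    config = config or TroughConfig()
    if config.method == "variance":
        return locate_trough_variance(
            depth,
            variance_threshold=config.variance_threshold,
            border_cols=config.border_cols,
            hough=config.hough,
        )
    return locate_trough_features(
        depth,
        detector=detector,
        hessian_threshold=config.hessian_threshold,
        border_cols=config.border_cols,
        hough=config.hough,
    )


def compute_key_area(
    trough: TroughLocation,
    image_size: tuple,
    k1: float = 0.6,
    side_margin: int = 25,
) -> KeyArea:
    """Rectangle beneath the trough: height k1·(trough height), clipped.

    ``image_size`` is (width, height). The width is the full frame minus a
    side margin on each edge (590 px for the default 640-wide frame).
    """
    if k1 <= 0:
        raise ValueError("k1 must be > 0")
    width, height = image_size
    h = max(1, round(k1 * trough.height_px))
    y = trough.row_bottom
    h = min(h, height - y)
    if h < 1:
        raise ValueError("trough touches the image bottom; key area is empty")
    return KeyArea(x=side_margin, y=y, w=width - 2 * side_margin, h=h)
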