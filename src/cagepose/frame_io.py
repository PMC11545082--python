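"""Reading and writing registered color+depth frames.

A structured-light depth camera delivers a registered pair per frame: an
8-bit 3-channel color image and a 16-bit single-channel depth map (in
millimetres, 0 = no reading). For storage the pair is merged into a single
16-bit 4-channel PNG: the color planes are scaled 8→16 bit by ×257 (so
0→0 and 255→65535, invertible by rounding division) and stored in
channels 0–2 in R,G,B order; the depth map is stored verbatim in channel
3. The round-trip is lossless.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from ._png16 import PngFormatError, read_rgba16, write_rgba16

__all__ = ["MergedFrame", "PngFormatError", "write_merged", "read_merged", "load_pair"]

_COLOR_SCALE = 257  # 8-bit → 16-bit, full range, lossless


@dataclass(frozen=True)
class MergedFrame:
    """A registered color (uint8, H×W×3) + depth (uint16 mm, H×W) pair.

    Depth value 0 encodes "no reading" (sensor dropout or the black
    registration borders). The pipeline defaults assume 640×480 frames;
    other sizes are accepted but geometric parameters are the caller's
    responsibility to rescale.
    """

    color: np.ndarray
    depth: np.ndarray

    def __post_init__(self):
        color = np.asarray(self.color)
        depth = np.asarray(self.depth)
        if color.ndim != 3 or color.shape[2] != 3:
            raise ValueError(f"color must be H×W×3, got shape {color.shape}")
        if color.dtype != np.uint8:
            raise ValueError(f"color must be uint8, got {color.dtype}")
        if depth.ndim != 2:
            raise ValueError(f"depth must be H×W, got shape {depth.shape}")
        if depth.dtype != np.uint16:
            raise ValueError(f"depth must be uint16, got {depth.dtype}")
        if color.shape[:2] != depth.shape:
            raise ValueError(
                f"color {color.shape[:2]} and depth {depth.shape} dimensions differ"
            )
        object.__setattr__(self, "color", color)
        object.__setattr__(self, "depth", depth)

    @property
    def width(self) -> int:
        return self.depth.shape[1]

    @property
    def height(self) -> int:
        return self.depth.shape[0]


def write_merged(frame: MergedFrame, path) -> None:
    """Write a frame as a merged 16-bit 4-channel PNG (R,G,B,depth)."""
    merged = np.empty((frame.height, frame.width, 4), dtype=np.uint16)
    merged[:, :, :3] = frame.color.astype(np.uint16) * _COLOR_SCALE
    merged[:, :, 3] = frame.depth
    write_rgba16(path, merged)


def read_merged(path) -> MergedFrame:
    """Read a merged 16-bit 4-channel PNG back into a frame.

    Inverse of :func:`write_merged`; the round-trip is bit-identical.
    """
    merged = read_rgba16(path)
    color = ((merged[:, :, :3].astype(np.uint32) + _COLOR_SCALE // 2) // _COLOR_SCALE)
    return MergedFrame(color=color.astype(np.uint8), depth=merged[:, :, 3].copy())


def load_pair(color_path, depth_path) -> MergedFrame:
    """Load separate color (8-bit 3-channel) and depth (16-bit) images."""
    color = np.asarray(iio.imread(Path(color_path)))
    depth = np.asarray(iio.imread(Path(depth_path)))
    if color.ndim == 3 and color.shape[2] == 4:  # tolerate RGBA color files
        color = color[:, :, :3]
    if color.ndim != 3 or color.shape[2] != 3 or color.dtype != np.uint8:
        raise ValueError(
            f"{color_path}: expected 8-bit 3-channel color image, "
            f"got dtype {color.dtype}, shape {color.shape}"
        )
    if depth.ndim != 2 or depth.dtype != np.uint16:
        raise ValueError(
            f"{depth_path}: expected 16-bit single-channel depth image, "
            f"got dtype {depth.dtype}, shape {depth.shape}"
        )
    return MergedFrame(color=color, depth=depth)
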