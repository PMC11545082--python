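"""Minimal PNG codec for 16-bit RGBA (color type 6) images.

The merged-frame storage format is a 16-bit 4-channel PNG, which the
common Python imaging stacks cannot round-trip losslessly (Pillow decodes
16-bit RGBA down to 8 bits and refuses to encode it). This module
implements exactly the subset of the PNG standard the format needs:
non-interlaced, bit depth 16, color type 6 (RGBA), all five scanline
filters on decode, filter 0 on encode. Everything else is rejected with a
clear error.
"""

from __future__ import annotations

import struct
import zlib

import numpy as np

_SIGNATURE = b"\x89PNG\r\n\x1a\n"


class PngFormatError(ValueError):
    """Raised when a file is not a PNG of the expected layout."""


def _chunk(tag: bytes, payload: bytes) -> bytes:
    body = tag + payload
    return struct.pack(">I", len(payload)) + body + struct.pack(
        ">I", zlib.crc32(body) & 0xFFFFFFFF
    )


def write_rgba16(path, array: np.ndarray) -> None:
    """Write an H×W×4 uint16 array as a 16-bit RGBA PNG."""
    arr = np.asarray(array)
    if arr.ndim != 3 or arr.shape[2] != 4:
        raise ValueError(f"expected H×W×4 array, got shape {arr.shape}")
    if arr.dtype != np.uint16:
        raise ValueError(f"expected uint16 array, got {arr.dtype}")
    height, width = arr.shape[:2]
    big = arr.astype(">u2")
    raw = b"".join(b"\x00" + big[r].tobytes() for r in range(height))
    with open(path, "wb") as fh:
        fh.write(_SIGNATURE)
        fh.write(_chunk(b"IHDR", struct.pack(">IIBBBBB", width, height, 16, 6, 0, 0, 0)))
        fh.write(_chunk(b"IDAT", zlib.compress(raw, level=6)))
        fh.write(_chunk(b"IEND", b""))


def _unfilter(kind: int, line: np.ndarray, prev: np.ndarray, bpp: int) -> np.ndarray:
    # line, prev: uint8 vectors of one scanline (already unfiltered for prev)
    if kind == 0:
        return line
    out = line.copy()
    n = len(line)
    if kind == 1:  # Sub
        for i in range(bpp, n):
            out[i] = (out[i] + out[i - bpp]) & 0xFF
    elif kind == 2:  # Up
        out += prev
    elif kind == 3:  # Average
        for i in range(n):
            left = int(out[i - bpp]) if i >= bpp else 0
            out[i] = (int(line[i]) + (left + int(prev[i])) // 2) & 0xFF
    elif kind == 4:  # Paeth
        for i in range(n):
            a = int(out[i - bpp]) if i >= bpp else 0
            b = int(prev[i])
            c = int(prev[i - bpp]) if i >= bpp else 0
            p = a + b - c
            pa, pb, pc = abs(p - a), abs(p - b), abs(p - c)
            if pa <= pb and pa <= pc:
                pred = a
            elif pb <= pc:
                pred = b
            else:
                pred = c
            out[i] = (int(line[i]) + pred) & 0xFF
    else:
        raise PngFormatError(f"unknown scanline filter {kind}")
    return out


def read_rgba16(path) -> np.ndarray:
    """Read a 16-bit RGBA PNG into an H×W×4 uint16 array.

    Raises :class:`PngFormatError` for non-PNG files and for PNGs that are
    not 16-bit 4-channel (naming the offending property).
    """
    with open(path, "rb") as fh:
        data = fh.read()
    if data[:8] != _SIGNATURE:
        raise PngFormatError(f"{path}: not a PNG file")
    pos = 8
    width = height = None
    idat = []
    while pos < len(data):
        (length,) = struct.unpack(">I", data[pos : pos + 4])
        tag = data[pos + 4 : pos + 8]
        payload = data[pos + 8 : pos + 8 + length]
        pos += 12 + length
        if tag == b"IHDR":
            width, height, bit_depth, color_type, _, _, interlace = struct.unpack(
                ">IIBBBBB", payload
            )
            if bit_depth != 16:
                raise PngFormatError(
                    f"{path}: expected bit depth 16, found {bit_depth}"
                )
            if color_type != 6:
                raise PngFormatError(
                    f"{path}: expected 4-channel RGBA (color type 6), "
                    f"found color type {color_type}"
                )
            if interlace != 0:
                raise PngFormatError(f"{path}: interlaced PNG not supported")
        elif tag == b"IDAT":
            idat.append(payload)
        elif tag == b"IEND":
            break
    if width is None:
        raise PngFormatError(f"{path}: missing IHDR chunk")
    raw = zlib.decompress(b"".join(idat))
    stride = width * 8  # 4 channels × 2 bytes
    if len(raw) != height * (stride + 1):
        raise PngFormatError(f"{path}: IDAT length does not match dimensions")
    rows = np.frombuffer(raw, dtype=np.uint8).reshape(height, stride + 1)
    kinds = rows[:, 0]
    out = np.empty((height, stride), dtype=np.uint8)
    if np.all(kinds == 0):  # fast path: our own writer
        out[:] = rows[:, 1:]
    else:
        prev = np.zeros(stride, dtype=np.uint8)
        for r in range(height):
            prev = _unfilter(int(kinds[r]), rows[r, 1:].copy(), prev, bpp=8)
            out[r] = prev
    return out.view(">u2").astype(np.uint16).reshape(height, width, 4)
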