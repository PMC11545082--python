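"""Tunable parameters for the detection pipeline.

The five core tunables follow the field convention for this method:

* ``k1`` — key-area height as a fraction of the trough height (unitless).
* ``k2``, ``k3`` — depth-offset band (mm) behind the per-column trough
  depth within which a lying bird's body is expected: a key-area pixel is
  foreground iff ``d_c + k2 < d' < d_c + k3`` (strict).
* ``k4`` — column-fill divisor: a mask column survives iff its white-pixel
  count exceeds ``H_roi / k4``.
* ``k5`` — aspect-ratio threshold: a candidate box is a lying bird iff
  ``W/H > k5`` (lying birds are flat-wide; cage pillars are tall-thin).

Defaults are the grid-search optimum for this method: k1=0.6, k2=65,
k3=250, k4=2.0, k5=1.7.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml

__all__ = [
    "HoughParams",
    "DetectionParams",
    "CorrectionConfig",
    "TroughConfig",
    "PipelineConfig",
]


@dataclass(frozen=True)
class HoughParams:
    """Probabilistic Hough transform settings (1 px distance resolution).

    The edge passes use a 0.25° angular step: segment endpoints follow the
    accumulator's quantized direction, so a coarser step biases the
    recovered roll angle toward the grid.
    """

    threshold: int = 50  # accumulator votes
    min_line_length: int = 100  # px
    max_line_gap: int = 10  # px
    angle_step_deg: float = 0.25


@dataclass(frozen=True)
class DetectionParams:
    k1: float = 0.6
    k2: float = 65.0  # mm
    k3: float = 250.0  # mm
    k4: float = 2.0
    k5: float = 1.7
    merge_gap_px: float = 20.0
    min_contour_area_px: int = 50
    morph_kernel_px: int = 3  # elliptical opening/closing footprint
    median_ksize: int = 3

    def __post_init__(self):
        if not (0 < self.k2 < self.k3):
            raise ValueError(f"need 0 < k2 < k3, got k2={self.k2}, k3={self.k3}")
        if self.k1 <= 0 or self.k4 <= 0 or self.k5 <= 0:
            raise ValueError("k1, k4, k5 must be positive")
        if self.merge_gap_px < 0:
            raise ValueError("merge_gap_px must be >= 0")

    def replace(self, **kw) -> "DetectionParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class CorrectionConfig:
    """Roll-correction settings: ROI for the trough edge and the edge chain."""

    roi: tuple = (25, 80, 615, 300)  # x0, y0, x1, y1
    binarize_threshold: int = 100
    sobel_ksize: int = 3
    median_ksize: int = 3
    hough: HoughParams = field(default_factory=HoughParams)
    center: tuple | None = None  # rotation center; None → image center


@dataclass(frozen=True)
class TroughConfig:
    method: str = "variance"  # "variance" | "features"
    variance_threshold: float = 400.0  # mm², per-row depth variance cutoff
    hessian_threshold: float = 400.0  # keypoint response, 8-bit scale
    border_cols: int = 50  # registration borders excluded from analysis
    # The point image fed to this Hough pass is a 1-px-wide dotted vertical
    # line, so the accumulator/line-length scales differ from the edge pass.
    hough: HoughParams = field(
        default_factory=lambda: HoughParams(
            threshold=10, min_line_length=20, max_line_gap=5, angle_step_deg=1.0
        )
    )

    def __post_init__(self):
        if self.method not in ("variance", "features"):
            raise ValueError(f"unknown trough method {self.method!r}")


@dataclass(frozen=True)
class PipelineConfig:
    correction: CorrectionConfig = field(default_factory=CorrectionConfig)
    trough: TroughConfig = field(default_factory=TroughConfig)
    key_area_side_margin: int = 25  # px left/right of the key area
    params: DetectionParams = field(default_factory=DetectionParams)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["correction"]["roi"] = list(self.correction.roi)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        corr = dict(d.get("correction", {}))
        if "hough" in corr:
            corr["hough"] = HoughParams(**corr["hough"])
        if "roi" in corr:
            corr["roi"] = tuple(corr["roi"])
        trough = dict(d.get("trough", {}))
        if "hough" in trough:
            trough["hough"] = HoughParams(**trough["hough"])
        params = DetectionParams(**d.get("params", {}))
        return cls(
            correction=CorrectionConfig(**corr),
            trough=TroughConfig(**trough),
            key_area_side_margin=d.get("key_area_side_margin", 25),
            params=params,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(Path(path)) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(Path(path), "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
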