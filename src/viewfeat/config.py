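"""Configuration for feature extraction, loadable from TOML.

All thresholds are heuristic defaults: the underlying pixel classifiers
(green/blue hue bands, grey/white sky test, edge/line detector settings,
box-counting grid) have no single canonical parameterisation, so every
value here can be overridden from a ``[extraction]`` table in a TOML file.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunable parameters of the low-level visual feature extractor.

    Hue bands are in degrees on the standard 0-360 colour wheel
    (red = 0, green ~ 120, blue ~ 240); all other thresholds live on
    the unit-scaled HSV planes.
    """

    #: hue band counted as green, degrees, half-open [lo, hi)
    green_band: tuple[float, float] = (70.0, 170.0)
    #: hue band counted as blue, degrees, half-open [lo, hi)
    blue_band: tuple[float, float] = (170.0, 260.0)
    #: minimum saturation for a pixel to count as chromatic
    chroma_s_min: float = 0.15
    #: minimum value (brightness) for a pixel to count as chromatic
    chroma_v_min: float = 0.10
    #: grey/white sky classifier: saturation at most this ...
    grey_s_max: float = 0.15
    #: ... and value at least this
    grey_v_min: float = 0.55
    #: pixels darker than this value are treated as mask black
    mask_black_v: float = 0.02
    #: Gaussian smoothing scale of the edge detector, pixels
    canny_sigma: float = 1.4
    #: hysteresis thresholds on the gradient of the unit-range luma
    canny_low: float = 0.10
    canny_high: float = 0.20
    #: Hough vote threshold, as a fraction of the image diagonal
    hough_vote_frac: float = 0.05
    #: minimum pixel support of an accepted line, fraction of the diagonal
    hough_min_len_frac: float = 0.05
    #: distance (pixels) within which an edge pixel belongs to a line
    hough_pixel_tol: float = 1.0
    #: explicit box sizes for box counting; None = dyadic 2..min(H,W)//4
    box_sizes: tuple[int, ...] | None = None
    #: number of grid offsets per box size; 1 = origin-anchored grid,
    #: >1 takes the minimum count over shifted grids (FracLac-style)
    box_grid_offsets: int = 1
    #: optional resize so that max(H, W) <= this, for cross-camera use
    resize_max_dim: int | None = None

    def __post_init__(self) -> None:
        for name in ("green_band", "blue_band"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo < 360.0 and 0.0 <= hi <= 360.0):
                raise ValueError(f"{name} must lie within [0, 360)")
            if lo == hi:
                raise ValueError(f"{name} is empty")
        if self.box_sizes is not None:
            sizes = tuple(self.box_sizes)
            if len(sizes) < 2 or any(s < 2 for s in sizes):
                raise ValueError("box_sizes must contain sizes >= 2")
            if any(b <= a for a, b in zip(sizes, sizes[1:])):
                raise ValueError("box_sizes must be strictly increasing")

    @classmethod
    def from_toml(cls, path: str | Path) -> "ExtractionConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls.from_dict(data.get("extraction", data))

    @classmethod
    def from_dict(cls, data: dict) -> "ExtractionConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown extraction options: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("green_band", "blue_band", "box_sizes"):
            if kwargs.get(key) is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)
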