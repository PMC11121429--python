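"""Low-level visual features (LLVFs) of window-view photographs.

Fourteen pixel-statistic descriptors are computed per image, without any
object recognition: circular hue statistics, saturation and brightness
moments, green/blue/sky pixel ratios, gray-level entropy, Canny edge
density split into straight and non-straight components by a Hough line
detector, and a box-counting fractal dimension.  Per-participant
exposure is the unweighted average of these features over all window
images of that participant (hue averaged circularly).

The sky pixel ratio is computed from a companion image in which every
non-sky pixel has been blackened; producing that mask (a manual
segmentation step in practice) is outside the scope of this package.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from skimage import transform
from skimage.color import rgb2hsv
from skimage.feature import canny
from skimage.filters import threshold_otsu
from skimage.transform import hough_line, hough_line_peaks

from .config import ExtractionConfig

#: ITU-R BT.601 luma weights, used for all grayscale reductions
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: resultant lengths below this flag the circular hue mean as unstable
_RESULTANT_EPS = 1e-6

#: FeatureVector field order; follows the conventional LLVF numbering
FEATURE_FIELDS = (
    "hue_mean",
    "hue_sd",
    "sat_mean",
    "sat_sd",
    "bright_mean",
    "bright_sd",
    "green_ratio",
    "blue_ratio",
    "sky_ratio",
    "edge_density",
    "straight_edge_density",
    "nonstraight_edge_density",
    "entropy",
    "fractal_dim",
)


class ImageFormatError(ValueError):
    """Raised when an input array is not a valid 8-bit RGB image."""


@dataclass(frozen=True)
class HSVImage:
    """Per-pixel cylindrical colour coordinates.

    ``hue`` is angular in radians on (-pi, pi] with red at 0 and cyan at
    +/-pi; ``sat`` and ``val`` are the unit-scaled saturation and value
    planes of the standard hexcone model.  Saturation-zero pixels carry
    an arbitrary hue and are excluded from hue statistics.
    """

    hue: np.ndarray
    sat: np.ndarray
    val: np.ndarray


@dataclass
class FeatureVector:
    """The 14 LLVFs of one image (or a per-participant average).

    ``flags`` records quality annotations: an unstable circular hue mean
    (near-zero resultant), a missing sky mask, a fractal dimension
    outside the [1, 2] range expected of natural scenes, and the
    standing caveat that objective brightness of uncontrolled photographs
    is unreliable across cameras and lighting.
    """

    hue_mean: float
    hue_sd: float
    sat_mean: float
    sat_sd: float
    bright_mean: float
    bright_sd: float
    green_ratio: float
    blue_ratio: float
    sky_ratio: float
    edge_density: float
    straight_edge_density: float
    nonstraight_edge_density: float
    entropy: float
    fractal_dim: float
    flags: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in FEATURE_FIELDS}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_FIELDS])


def _validate_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ImageFormatError(
            f"expected an HxWx3 RGB image, got shape {img.shape}"
        )
    if img.dtype != np.uint8:
        if np.issubdtype(img.dtype, np.integer) and img.min() >= 0 and img.max() <= 255:
            img = img.astype(np.uint8)
        else:
            raise ImageFormatError("expected 8-bit channel intensities")
    return img


def luma(img: np.ndarray) -> np.ndarray:
    """BT.601 grayscale reduction, float in [0, 255]."""
    img = _validate_rgb(img)
    return img.astype(float) @ LUMA_WEIGHTS


def to_hsv(img: np.ndarray) -> HSVImage:
    """Convert 8-bit RGB to the angular-hue HSV representation.

    The standard 0-360 degree hue (red at 0, cyan at 180) is mapped to
    radians and wrapped to (-pi, pi], so red sits at 0 and cyan at the
    +/-pi seam where the circle closes.
    """
    img = _validate_rgb(img)
    hsv = rgb2hsv(img)
    theta = hsv[..., 0] * (2.0 * np.pi)
    theta = np.where(theta > np.pi, theta - 2.0 * np.pi, theta)
    return HSVImage(hue=theta, sat=hsv[..., 1], val=hsv[..., 2])


def hue_stats(hsv: HSVImage) -> tuple[float, float, dict]:
    """Circular mean and angular deviation of the hue plane.

    Saturation-zero (achromatic) pixels are excluded: their hue is
    undefined in the hexcone model.  Returns ``(mean, sd, flags)`` where
    the mean is the angle of the mean unit vector and the dispersion is
    the angular deviation sqrt(2 * (1 - R)) with R the mean resultant
    length.  An all-achromatic image yields NaN statistics with
    ``flags["hue_undefined"]``; a near-zero resultant (e.g. equal red
    and cyan mass) yields ``flags["hue_mean_unstable"]``.
    """
    chromatic = hsv.sat > 0
    flags: dict = {}
    if not chromatic.any():
        flags["hue_undefined"] = True
        return float("nan"), float("nan"), flags
    theta = hsv.hue[chromatic]
    c, s = np.cos(theta).mean(), np.sin(theta).mean()
    resultant = float(np.hypot(c, s))
    sd = float(np.sqrt(max(2.0 * (1.0 - resultant), 0.0)))
    if resultant < _RESULTANT_EPS:
        flags["hue_mean_unstable"] = True
        return float("nan"), sd, flags
    return float(np.arctan2(s, c)), sd, flags


def channel_stats(hsv: HSVImage) -> tuple[float, float, float, float]:
    """Mean and population SD of the saturation and value planes."""
    return (
        float(hsv.sat.mean()),
        float(hsv.sat.std()),
        float(hsv.val.mean()),
        float(hsv.val.std()),
    )


def _hue_in_band(hue_rad: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    """Half-open degree-band membership [lo, hi), tolerant of wraparound."""
    deg = np.degrees(hue_rad) % 360.0
    lo, hi = band
    if lo < hi:
        return (deg >= lo) & (deg < hi)
    return (deg >= lo) | (deg < hi)


def color_ratio(
    img: np.ndarray, band: tuple[float, float], cfg: ExtractionConfig | None = None
) -> float:
    """Fraction of all pixels whose hue falls in ``band`` and that are
    chromatic (saturation and value above the config minima)."""
    cfg = cfg or ExtractionConfig()
    hsv = img if isinstance(img, HSVImage) else to_hsv(img)
    member = (
        _hue_in_band(hsv.hue, band)
        & (hsv.sat >= cfg.chroma_s_min)
        & (hsv.val >= cfg.chroma_v_min)
    )
    return float(member.mean())


def sky_ratio(masked: np.ndarray, cfg: ExtractionConfig | None = None) -> float:
    """Sky pixel ratio from a sky-masked companion image.

    Non-sky content must already be blackened; pixels darker than the
    mask-black tolerance are excluded.  Sky pixels are those in the blue
    hue band (clear sky) or grey/white (overcast: low saturation, high
    value).  The denominator is the full pixel count of the image, so
    the ratio is the fraction of the whole view occupied by sky.
    """
    cfg = cfg or ExtractionConfig()
    hsv = masked if isinstance(masked, HSVImage) else to_hsv(masked)
    visible = hsv.val >= cfg.mask_black_v
    blue = (
        _hue_in_band(hsv.hue, cfg.blue_band)
        & (hsv.sat >= cfg.chroma_s_min)
        & (hsv.val >= cfg.chroma_v_min)
    )
    grey = (hsv.sat <= cfg.grey_s_max) & (hsv.val >= cfg.grey_v_min)
    return float((visible & (blue | grey)).mean())


def entropy(img: np.ndarray) -> float:
    """Shannon entropy (bits) of the 256-bin gray-level histogram.

    Ranges from 0 (constant image) to 8 (uniform histogram).
    """
    levels = np.clip(np.rint(luma(img)), 0, 255).astype(np.intp)
    counts = np.bincount(levels.ravel(), minlength=256)
    p = counts[counts > 0] / levels.size
    return float(-(p * np.log2(p)).sum())


def edge_map(img: np.ndarray, cfg: ExtractionConfig | None = None) -> np.ndarray:
    """Canny edge detection on the unit-scaled luma plane.

    Gaussian smoothing at ``canny_sigma``, gradient magnitude,
    non-maximum suppression and hysteresis with absolute thresholds
    ``canny_low``/``canny_high`` on the unit-range gradient.
    Deterministic for fixed input and config.
    """
    cfg = cfg or ExtractionConfig()
    g = luma(img) / 255.0
    if min(g.shape) <= 2:
        raise ValueError("image too small for edge detection (min side <= 2)")
    return canny(
        g,
        sigma=cfg.canny_sigma,
        low_threshold=cfg.canny_low,
        high_threshold=cfg.canny_high,
    )


def straight_edge_mask(
    edges: np.ndarray, cfg: ExtractionConfig | None = None
) -> np.ndarray:
    """Edge pixels lying on detected straight lines.

    A standard (deterministic) Hough transform accumulates votes over
    the edge raster; peaks with at least ``hough_vote_frac`` * diagonal
    votes propose lines, and a proposed line is accepted when at least
    ``hough_min_len_frac`` * diagonal edge pixels lie within
    ``hough_pixel_tol`` of it.  The returned mask is the union of the
    accepted lines' supporting pixels.
    """
    cfg = cfg or ExtractionConfig()
    edges = np.asarray(edges, bool)
    straight = np.zeros_like(edges)
    if not edges.any():
        return straight
    h, w = edges.shape
    diag = float(np.hypot(h, w))
    vote_min = max(int(np.ceil(cfg.hough_vote_frac * diag)), 2)
    support_min = max(int(np.ceil(cfg.hough_min_len_frac * diag)), 2)
    accum, thetas, dists = hough_line(edges)
    if accum.max() < vote_min:
        return straight
    _, angles, rhos = hough_line_peaks(accum, thetas, dists, threshold=vote_min)
    rows, cols = np.nonzero(edges)
    for angle, rho in zip(angles, rhos):
        dist = np.abs(cols * np.cos(angle) + rows * np.sin(angle) - rho)
        near = dist <= cfg.hough_pixel_tol
        if near.sum() >= support_min:
            straight[rows[near], cols[near]] = True
    return straight


def edge_densities(
    edges: np.ndarray, cfg: ExtractionConfig | None = None
) -> tuple[float, float, float]:
    """Overall, straight, and non-straight edge density.

    Edge pixels are partitioned: straight pixels belong to a detected
    line segment, every other edge pixel is non-straight, so
    straight + non-straight = overall exactly.
    """
    edges = np.asarray(edges, bool)
    total = edges.size
    n_edge = int(edges.sum())
    if n_edge == 0:
        return 0.0, 0.0, 0.0
    n_straight = int(straight_edge_mask(edges, cfg).sum())
    ed = n_edge / total
    sed = n_straight / total
    return ed, sed, ed - sed


def default_box_sizes(shape: tuple[int, int]) -> tuple[int, ...]:
    """Dyadic box sizes 2, 4, ... up to min(H, W) // 4."""
    cap = min(shape) // 4
    sizes = []
    s = 2
    while s <= cap:
        sizes.append(s)
        s *= 2
    return tuple(sizes)


def box_count(binary: np.ndarray, size: int, offset: tuple[int, int] = (0, 0)) -> int:
    """Number of size x size grid boxes containing >= 1 foreground pixel.

    The grid is anchored at ``offset`` (shifting it left/up, with the
    first partial boxes included), the origin by default.
    """
    binary = np.asarray(binary, bool)
    oy, ox = offset
    h, w = binary.shape
    pad_top, pad_left = oy % size, ox % size
    ph = int(np.ceil((h + pad_top) / size)) * size
    pw = int(np.ceil((w + pad_left) / size)) * size
    padded = np.zeros((ph, pw), bool)
    padded[pad_top : pad_top + h, pad_left : pad_left + w] = binary
    blocks = padded.reshape(ph // size, size, pw // size, size)
    return int(blocks.any(axis=(1, 3)).sum())


def fractal_dimension_binary(
    binary: np.ndarray, cfg: ExtractionConfig | None = None
) -> tuple[float, dict]:
    """Box-counting dimension of a binary raster.

    For each box size the grid count N(s) is taken (minimum over
    ``box_grid_offsets`` shifted grids when configured, emulating
    FracLac's grid scan); the dimension is the negative slope of the
    least-squares fit of log N(s) against log s.  Returns the estimate
    and flags: NaN + ``fd_undefined`` when there is no foreground, and
    ``fd_out_of_range`` when the estimate leaves [1, 2].
    """
    cfg = cfg or ExtractionConfig()
    binary = np.asarray(binary, bool)
    sizes = cfg.box_sizes or default_box_sizes(binary.shape)
    if len(sizes) < 3:
        raise ValueError(
            f"need >= 3 box sizes for a slope fit, got {len(sizes)} "
            f"for image shape {binary.shape}"
        )
    flags: dict = {}
    if not binary.any():
        flags["fd_undefined"] = True
        return float("nan"), flags
    counts = []
    for s in sizes:
        if cfg.box_grid_offsets > 1:
            shifts = np.linspace(0, s, cfg.box_grid_offsets, endpoint=False).astype(int)
            n = min(box_count(binary, s, (dy, dx)) for dy in shifts for dx in shifts)
        else:
            n = box_count(binary, s)
        counts.append(n)
    slope = np.polyfit(np.log(sizes), np.log(counts), 1)[0]
    fd = float(-slope)
    if not (1.0 <= fd <= 2.0):
        flags["fd_out_of_range"] = True
    return fd, flags


def fractal_dimension(
    img: np.ndarray, cfg: ExtractionConfig | None = None
) -> tuple[float, dict]:
    """Box-counting dimension of an RGB image.

    The luma plane is binarised at the Otsu threshold with the darker
    side as foreground (scene structure is typically dark against a
    bright sky); the dimension of the foreground set is then estimated
    as in :func:`fractal_dimension_binary`.
    """
    g = luma(img)
    if np.ptp(g) == 0:
        return float("nan"), {"fd_undefined": True}
    binary = g < threshold_otsu(g)
    return fractal_dimension_binary(binary, cfg)


def extract_features(
    img: np.ndarray,
    masked: np.ndarray | None = None,
    cfg: ExtractionConfig | None = None,
) -> FeatureVector:
    """Compute all 14 LLVFs of one image (plus its optional sky mask).

    ``masked`` is the companion image with non-sky pixels blackened;
    when absent the sky ratio is NaN and flagged.  Deterministic for
    fixed inputs and config.
    """
    cfg = cfg or ExtractionConfig()
    img = _validate_rgb(img)
    if min(img.shape[:2]) < 8:
        raise ImageFormatError("image must be at least 8x8 for feature validity")
    if cfg.resize_max_dim and max(img.shape[:2]) > cfg.resize_max_dim:
        scale = cfg.resize_max_dim / max(img.shape[:2])
        img = (
            transform.rescale(img, scale, channel_axis=2, anti_aliasing=True) * 255
        ).astype(np.uint8)
        if masked is not None:
            masked = (
                transform.rescale(masked, scale, channel_axis=2, anti_aliasing=True)
                * 255
            ).astype(np.uint8)
    flags: dict = {"brightness_unreliable_for_photos": True}

    hsv = to_hsv(img)
    hmean, hsd, hflags = hue_stats(hsv)
    flags.update(hflags)
    smean, ssd, vmean, vsd = channel_stats(hsv)
    green = color_ratio(hsv, cfg.green_band, cfg)
    blue = color_ratio(hsv, cfg.blue_band, cfg)
    if masked is None:
        sky = float("nan")
        flags["sky_mask_missing"] = True
    else:
        masked = _validate_rgb(masked)
        if masked.shape != img.shape:
            raise ImageFormatError(
                f"sky mask shape {masked.shape} != image shape {img.shape}"
            )
        sky = sky_ratio(masked, cfg)
    edges = edge_map(img, cfg)
    ed, sed, nsed = edge_densities(edges, cfg)
    ent = entropy(img)
    fd, fd_flags = fractal_dimension(img, cfg)
    flags.update(fd_flags)
    return FeatureVector(
        hue_mean=hmean,
        hue_sd=hsd,
        sat_mean=smean,
        sat_sd=ssd,
        bright_mean=vmean,
        bright_sd=vsd,
        green_ratio=green,
        blue_ratio=blue,
        sky_ratio=sky,
        edge_density=ed,
        straight_edge_density=sed,
        nonstraight_edge_density=nsed,
        entropy=ent,
        fractal_dim=fd,
        flags=flags,
    )


def aggregate_participant(features: list[FeatureVector]) -> FeatureVector:
    """Average feature vectors over a participant's window images.

    Plain unweighted means per field, except the circular hue mean which
    is averaged as the angle of the summed unit vectors.  NaN fields
    (e.g. missing sky masks, undefined hue) are skipped per-field.
    """
    if not features:
        raise ValueError("cannot aggregate an empty feature list")
    values: dict = {}
    with np.errstate(invalid="ignore"):
        for name in FEATURE_FIELDS:
            col = np.array([getattr(f, name) for f in features], float)
            if name == "hue_mean":
                ok = ~np.isnan(col)
                if ok.any():
                    values[name] = float(
                        np.arctan2(np.sin(col[ok]).mean(), np.cos(col[ok]).mean())
                    )
                else:
                    values[name] = float("nan")
            else:
                values[name] = (
                    float(np.nanmean(col)) if not np.isnan(col).all() else float("nan")
                )
    flags: dict = {}
    for f in features:
        flags.update(f.flags)
    return FeatureVector(**values, flags=flags)


def features_to_frame(features: dict[str, FeatureVector]):
    """Tabulate ``{row_id: FeatureVector}`` as a DataFrame in stable
    column order (the conventional LLVF numbering)."""
    import pandas as pd

    return pd.DataFrame(
        {rid: fv.as_dict() for rid, fv in features.items()}
    ).T.loc[:, list(FEATURE_FIELDS)]
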