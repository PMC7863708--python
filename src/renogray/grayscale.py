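"""First-order gray-level analysis of a segmented region.

A B-mode image carries up to 256 shades of gray while the human eye
separates perhaps 16-32, so regional statistics are computed numerically:
the gray-scale median (GSM — the intensity splitting the region's pixels
into a brighter and a darker half), the proportional distribution of
pixels over 14 pre-established brightness ranges ("virtual histology"),
and a pseudocolor rendering that replaces each in-region pixel by its
band's display color.

Polygons are rasterized with the even-odd rule sampled at pixel centers,
boundary-center pixels included: deterministic, orientation-independent
and standard.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, EmptyRegionError, ValidationError
from .image_io import GrayImage, PolygonROI


@dataclass
class RegionMask:
    """A rasterized ROI: boolean ``inside`` per pixel, image-shaped."""

    inside: np.ndarray  # (height, width) bool

    def __post_init__(self) -> None:
        arr = np.asarray(self.inside, dtype=bool)
        if arr.ndim != 2:
            raise ValidationError(f"mask must be 2-D, got shape {arr.shape}")
        self.inside = arr

    @property
    def width(self) -> int:
        return self.inside.shape[1]

    @property
    def height(self) -> int:
        return self.inside.shape[0]

    @property
    def n_inside(self) -> int:
        return int(self.inside.sum())


@dataclass(frozen=True)
class GSMResult:
    """Descriptive gray-level statistics of one region.

    ``gsm`` is the sample median: the middle order statistic for odd n,
    the mean of the two middle order statistics for even n (so x.0 or x.5
    exactly); it is never rounded before downstream use.
    """

    gsm: float
    n: int
    min: int
    max: int
    mean: float
    sd: float


@dataclass(frozen=True)
class Band:
    """One brightness range: closed interval [lo, hi] of gray levels with a
    probable-tissue label and a display color."""

    lo: int
    hi: int
    tissue_label: str
    color: tuple[int, int, int]

    def __post_init__(self) -> None:
        if not (0 <= self.lo <= self.hi <= 255):
            raise ConfigurationError(f"band [{self.lo}, {self.hi}] out of [0, 255]")
        if len(self.color) != 3 or any(not (0 <= c <= 255) for c in self.color):
            raise ConfigurationError(f"bad display color {self.color!r}")


@dataclass
class BrightnessRanges:
    """An ordered, non-overlapping set of bands tiling [0, 255] exactly.

    ``source`` records where the boundaries came from ("config" when loaded
    from a user configuration file, "fallback-uniform" for the built-in
    default of 14 contiguous equal-width bands).
    """

    bands: Sequence[Band]
    source: str = "config"

    def __post_init__(self) -> None:
        bands = list(self.bands)
        if not bands:
            raise ConfigurationError("at least one band is required")
        if bands[0].lo != 0 or bands[-1].hi != 255:
            raise ConfigurationError("bands must start at 0 and end at 255")
        for a, b in zip(bands, bands[1:]):
            if b.lo != a.hi + 1:
                raise ConfigurationError(
                    f"bands [{a.lo},{a.hi}] and [{b.lo},{b.hi}] do not tile [0,255]"
                )
        self.bands = bands

    def __len__(self) -> int:
        return len(self.bands)

    @property
    def lower_bounds(self) -> np.ndarray:
        return np.array([b.lo for b in self.bands])

    def band_index(self, values: np.ndarray) -> np.ndarray:
        """Index of the unique band containing each gray level."""
        return np.searchsorted(self.lower_bounds, np.asarray(values), side="right") - 1


@dataclass(frozen=True)
class BrightnessDistribution:
    """Per-band pixel counts and percentages for one region."""

    counts: np.ndarray
    percentages: np.ndarray
    n: int
    ranges: BrightnessRanges


# Fallback boundaries: 14 contiguous bands, cut points at round(256*i/14).
_FALLBACK_EDGES = [round(256 * i / 14) for i in range(15)]

# Probable-tissue labels for the fallback bands, darkest to brightest,
# adapted from the carotid virtual-histology convention to renal anatomy.
_FALLBACK_LABELS = [
    "anechoic (urine/fluid)",
    "blood-like",
    "very hypoechoic",
    "medullary pyramid",
    "hypoechoic parenchyma",
    "renal cortex (dark)",
    "renal cortex",
    "renal cortex (bright)",
    "liver-comparable",
    "mildly hyperechoic",
    "fibrous tissue",
    "renal sinus fat",
    "fascia/capsule",
    "calcification-like",
]

# Dark-to-bright pseudocolor ramp, one display color per fallback band.
_FALLBACK_COLORS = [
    (0, 0, 0),
    (40, 0, 100),
    (0, 0, 255),
    (0, 110, 255),
    (0, 200, 200),
    (0, 160, 60),
    (90, 200, 0),
    (190, 220, 0),
    (255, 255, 0),
    (255, 180, 0),
    (255, 120, 0),
    (255, 60, 0),
    (255, 0, 0),
    (255, 255, 255),
]


def default_ranges() -> BrightnessRanges:
    """The built-in 14-band configuration (equal-width fallback tiling).

    The prototype's exact range boundaries are configurable because they
    were established pictorially; this fallback is flagged
    ``source="fallback-uniform"`` in all output metadata.
    """
    bands = [
        Band(
            lo=_FALLBACK_EDGES[i],
            hi=_FALLBACK_EDGES[i + 1] - 1,
            tissue_label=_FALLBACK_LABELS[i],
            color=_FALLBACK_COLORS[i],
        )
        for i in range(14)
    ]
    return BrightnessRanges(bands=bands, source="fallback-uniform")


def _point_on_segment(px, py, x1, y1, x2, y2, eps=1e-9):
    """Vectorized test: does pixel center (px, py) lie on segment
    (x1,y1)-(x2,y2)?"""
    cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
    seg_len = np.hypot(x2 - x1, y2 - y1)
    if seg_len == 0:
        return (np.abs(px - x1) < eps) & (np.abs(py - y1) < eps)
    on_line = np.abs(cross) <= eps * max(seg_len, 1.0)
    within = (
        (px >= min(x1, x2) - eps)
        & (px <= max(x1, x2) + eps)
        & (py >= min(y1, y2) - eps)
        & (py <= max(y1, y2) + eps)
    )
    return on_line & within


def rasterize_polygon(roi: PolygonROI, width: int, height: int) -> RegionMask:
    """Rasterize a polygon to the pixels whose centers it encloses.

    A pixel center (integer coordinates) is inside iff it satisfies the
    even-odd rule; centers exactly on the boundary count as inside.
    Raises :class:`EmptyRegionError` if no center is enclosed.
    """
    roi.check_within(width, height)
    verts = np.asarray(roi.vertices, dtype=float)
    nv = len(verts)

    x0 = max(0, int(np.floor(verts[:, 0].min())))
    x1 = min(width - 1, int(np.ceil(verts[:, 0].max())))
    y0 = max(0, int(np.floor(verts[:, 1].min())))
    y1 = min(height - 1, int(np.ceil(verts[:, 1].max())))

    px, py = np.meshgrid(
        np.arange(x0, x1 + 1, dtype=float), np.arange(y0, y1 + 1, dtype=float)
    )
    parity = np.zeros(px.shape, dtype=bool)
    boundary = np.zeros(px.shape, dtype=bool)
    for i in range(nv):
        ax, ay = verts[i]
        bx, by = verts[(i + 1) % nv]
        boundary |= _point_on_segment(px, py, ax, ay, bx, by)
        if ay == by:
            continue  # horizontal edges never cross the test ray
        crosses = (ay > py) != (by > py)
        with np.errstate(invalid="ignore", divide="ignore"):
            xint = ax + (py - ay) * (bx - ax) / (by - ay)
        parity ^= crosses & (px < xint)

    inside = np.zeros((height, width), dtype=bool)
    inside[y0 : y1 + 1, x0 : x1 + 1] = parity | boundary
    if not inside.any():
        raise EmptyRegionError(
            f"polygon {roi.label!r} encloses no pixel center on a "
            f"{width}x{height} grid"
        )
    return RegionMask(inside=inside)


def region_pixels(image: GrayImage, mask: RegionMask) -> np.ndarray:
    """Intensities of the inside pixels in deterministic row-major order."""
    if (mask.height, mask.width) != (image.height, image.width):
        raise ValidationError(
            f"mask {mask.width}x{mask.height} does not match image "
            f"{image.width}x{image.height}"
        )
    if mask.n_inside == 0:
        raise EmptyRegionError("mask contains no pixels")
    return image.pixels[mask.inside]


def compute_gsm(pixels: Sequence[int] | np.ndarray) -> GSMResult:
    """Gray-scale median and descriptive statistics of a pixel multiset.

    The GSM marks the division between the brighter and the darker half of
    the region; unlike the mean it is insensitive to the tails.
    """
    arr = np.asarray(pixels)
    if arr.size == 0:
        raise EmptyRegionError("cannot compute GSM of an empty region")
    arr = arr.astype(float)
    gsm = float(np.median(arr))
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return GSMResult(
        gsm=gsm,
        n=int(arr.size),
        min=int(arr.min()),
        max=int(arr.max()),
        mean=float(arr.mean()),
        sd=sd,
    )


def brightness_distribution(
    pixels: Sequence[int] | np.ndarray, ranges: BrightnessRanges
) -> BrightnessDistribution:
    """Proportional distribution of a region's pixels over the brightness
    ranges; every pixel falls in exactly one band, counts sum to n and
    percentages to 100."""
    arr = np.asarray(pixels)
    if arr.size == 0:
        raise EmptyRegionError("cannot bin an empty region")
    idx = ranges.band_index(arr)
    counts = np.bincount(idx, minlength=len(ranges)).astype(int)
    percentages = 100.0 * counts / arr.size
    return BrightnessDistribution(
        counts=counts, percentages=percentages, n=int(arr.size), ranges=ranges
    )


def pseudocolor_render(
    image: GrayImage, mask: RegionMask, ranges: BrightnessRanges
) -> np.ndarray:
    """Render the region in pseudocolor over the gray background.

    Pixels inside the mask are replaced by their band's display color;
    pixels outside keep their original gray. Returns an (H, W, 3) uint8
    raster.
    """
    if (mask.height, mask.width) != (image.height, image.width):
        raise ValidationError(
            f"mask {mask.width}x{mask.height} does not match image "
            f"{image.width}x{image.height}"
        )
    out = np.repeat(image.pixels[:, :, None], 3, axis=2).astype(np.uint8)
    lut = np.array([b.color for b in ranges.bands], dtype=np.uint8)
    idx = ranges.band_index(image.pixels[mask.inside])
    out[mask.inside] = lut[idx]
    return out
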