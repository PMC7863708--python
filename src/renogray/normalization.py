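"""Fascia-anchored one-point image normalization.

Renal echogenicity read off a B-mode image depends on the console's gain,
TGC and dynamic-range settings, so gray levels from different operators or
devices are not directly comparable.  The normalization implemented here
stabilizes every image against a single bright reference structure, the
posterior renal fascia: a normalization factor

    Fn = |medF0 - 200| / medF0

is computed from the fascia region's original gray-scale median medF0, and
a linear transfer function rescales every pixel of the image so that the
fascia GSM lands on the anchor level 200:

    medF0 <= 200:  f(r) = r (1 + Fn)
    medF0  > 200:  f(r) = r (1 - Fn)

Both branches are the single map r -> r * 200 / medF0.  (The signed form
(medF0 - 200)/medF0, which darkens low-fascia images instead of brightening
them, is available behind ``signed_literal=True`` for auditing only.)

Two rounding policies exist: ``exact_factor`` (default) applies the factor
at full precision; ``paper_compat`` first rounds Fn to 2 decimal places,
matching the prototype's printed worked example (medF0 = 220 gives
Fn = 0.09 and f(50) = 50 * 0.91 = 45.5 -> 46).  Pixel values are always
rounded half away from zero and clipped to [0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import DegenerateFasciaError, ValidationError
from .grayscale import compute_gsm, rasterize_polygon, region_pixels
from .image_io import GrayImage, PolygonROI

TARGET_LEVEL = 200

PolicyMode = Literal["exact_factor", "paper_compat"]


@dataclass(frozen=True)
class RoundingPolicy:
    """How the factor and the pixels are rounded during normalization.

    ``exact_factor`` uses Fn at full precision; ``paper_compat`` rounds Fn
    to 2 decimals before the transfer.  Pixels are always rounded half away
    from zero and clipped to [0, 255].
    """

    mode: PolicyMode = "exact_factor"

    def __post_init__(self) -> None:
        if self.mode not in ("exact_factor", "paper_compat"):
            raise ValidationError(f"unknown rounding policy {self.mode!r}")


EXACT_FACTOR = RoundingPolicy("exact_factor")
PAPER_COMPAT = RoundingPolicy("paper_compat")


@dataclass
class NormalizationFactor:
    """The factor anchoring a fascia of median ``medF0`` to level 200.

    ``fn`` is dimensionless and non-negative under the default absolute-
    value convention; ``scale`` (= 200/medF0) is the slope of the unified
    transfer map.  ``signed_literal`` marks factors computed with the
    literal signed formula.  ``clip_count`` is filled in by
    :func:`normalize_image` with the number of saturated pixels.
    """

    medF0: float
    fn: float
    target_level: int = TARGET_LEVEL
    signed_literal: bool = False
    policy_mode: PolicyMode | None = None
    clip_count: int | None = None

    @property
    def scale(self) -> float:
        return self.target_level / self.medF0

    def fn_rounded(self, decimals: int = 2) -> float:
        return round(self.fn, decimals)


def compute_normalization_factor(
    medF0: float, signed_literal: bool = False
) -> NormalizationFactor:
    """Compute the normalization factor for an original fascia GSM.

    Raises :class:`DegenerateFasciaError` for medF0 <= 0 (an all-black
    fascia cannot anchor a multiplicative rescale).
    """
    medF0 = float(medF0)
    if medF0 <= 0:
        raise DegenerateFasciaError(
            f"fascia GSM must be positive to serve as reference, got {medF0}"
        )
    if signed_literal:
        fn = (medF0 - TARGET_LEVEL) / medF0
    else:
        fn = abs(medF0 - TARGET_LEVEL) / medF0
    return NormalizationFactor(medF0=medF0, fn=fn, signed_literal=signed_literal)


def _effective_scale(factor: NormalizationFactor, policy: RoundingPolicy) -> float:
    # Under the absolute-value convention the branch forms 1+Fn / 1-Fn
    # reduce algebraically to the single slope 200/medF0; evaluating that
    # form directly keeps half-integer rounding boundaries exact.  The
    # 2-decimal policy and the signed literal form go through the branch
    # expressions as printed.
    if not factor.signed_literal and policy.mode == "exact_factor":
        return TARGET_LEVEL / factor.medF0
    fn = factor.fn_rounded(2) if policy.mode == "paper_compat" else factor.fn
    return 1.0 + fn if factor.medF0 <= TARGET_LEVEL else 1.0 - fn


def build_transfer_lut(
    factor: NormalizationFactor, policy: RoundingPolicy = EXACT_FACTOR
) -> np.ndarray:
    """The transfer function tabulated over all 256 gray levels.

    Monotone non-decreasing; values rounded half away from zero and
    clipped to [0, 255]."""
    scale = _effective_scale(factor, policy)
    r = np.arange(256, dtype=float)
    out = np.floor(r * scale + 0.5)  # half away from zero; r*scale >= 0
    return np.clip(out, 0, 255).astype(np.uint8)


def transfer(
    r: int, factor: NormalizationFactor, policy: RoundingPolicy = EXACT_FACTOR
) -> int:
    """Normalized value of one gray level under the transfer function."""
    if not (0 <= r <= 255):
        raise ValidationError(f"gray level {r} outside [0, 255]")
    return int(build_transfer_lut(factor, policy)[int(r)])


def normalize_image(
    image: GrayImage,
    fascia_roi: PolygonROI,
    policy: RoundingPolicy = EXACT_FACTOR,
) -> tuple[GrayImage, NormalizationFactor]:
    """Anchor an image's fascia GSM to 200 by rescaling every pixel.

    The factor comes from the fascia region's GSM; the transfer is applied
    to the whole image, not just the segmented fascia, so all tissues move
    coherently with the reference.  Returns the normalized image and the
    factor (with ``policy_mode`` and ``clip_count`` recorded).
    """
    if fascia_roi.label != "fascia":
        raise ValidationError(
            f"normalization reference must be a fascia ROI, got {fascia_roi.label!r}"
        )
    mask = rasterize_polygon(fascia_roi, image.width, image.height)
    med = compute_gsm(region_pixels(image, mask)).gsm
    if med <= 0:
        raise DegenerateFasciaError(
            "fascia region GSM is 0; cannot normalize against a black reference"
        )
    factor = compute_normalization_factor(med)
    lut = build_transfer_lut(factor, policy)
    scale = _effective_scale(factor, policy)
    exact = image.pixels.astype(float) * scale
    factor.clip_count = int(np.count_nonzero(exact > 255.0))
    factor.policy_mode = policy.mode
    out = GrayImage(
        pixels=lut[image.pixels],
        source_id=(image.source_id + "+normalized") if image.source_id else "normalized",
    )
    return out, factor
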