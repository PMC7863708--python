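"""Synthetic renal ultrasound phantoms and multi-operator study simulation.

No public image set accompanies the renal gray-scale workflow, so the
pipeline is validated on synthetic phantoms: a speckle-textured raster with
a kidney ellipse (cortex around a brighter central sinus), a bright
posterior fascia band, and a dark background.  Speckle is multiplicative
with unit mean: ``s = (1 - a) + a * R`` where R is a unit-mean Rayleigh
variate and ``a = speckle_scale`` interpolates between the noiseless limit
(a = 0) and fully developed Rayleigh speckle (a = 1).  Each pixel is
``clip(round(region_mean * s))``.

Operator and device variability is modelled as a linear gain and offset on
the synthesized echo amplitudes.  Under the ``random`` acquisition method
each physician's own gain/offset applies; under ``standardized`` they are
replaced by fixed study-wide preset values, emulating a console preset with
locked gain, TGC and dynamic range.  Seeding is hierarchical (study ->
patient -> side -> physician) so adding a physician never changes another
physician's images, and a null operator effect makes the random and
standardized acquisitions bit-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .errors import ValidationError
from .image_io import (
    AcquisitionRecord,
    GrayImage,
    PolygonROI,
    write_gray_bmp,
    write_manifest,
    write_roi,
)
from .grayscale import compute_gsm, rasterize_polygon, region_pixels

_RAYLEIGH_MEAN = float(np.sqrt(np.pi / 2.0))  # mean of Rayleigh(scale=1)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, echogenicity and texture of one synthetic phantom.

    Region means are gray levels in (0, 255); geometric parameters are
    fractions of the image size so a spec scales cleanly.  The default
    raster is 800x600, the resolution ultrasound consoles typically
    export.  The fascia band is a horizontal rectangle posterior to
    (below) the kidney and is forced to an odd x odd pixel footprint so
    its rasterized pixel count is always odd (the GSM of an odd-count
    region is a single order statistic, which downstream invariants rely
    on).
    """

    width: int = 800
    height: int = 600
    kidney_center: tuple[float, float] = (0.5, 0.45)  # fraction of (w, h)
    kidney_axes: tuple[float, float] = (0.28, 0.18)  # semi-axes, fraction of (w, h)
    sinus_axes: tuple[float, float] = (0.12, 0.08)
    fascia_top: float = 0.78  # fraction of h
    fascia_thickness: float = 0.05  # fraction of h
    fascia_margin: float = 0.10  # left/right margin, fraction of w
    mean_background: float = 40.0
    mean_cortex: float = 90.0
    mean_sinus: float = 150.0
    mean_fascia: float = 220.0
    speckle_scale: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 16 or self.height < 16:
            raise ValidationError("phantom raster must be at least 16x16")
        for name in ("mean_background", "mean_cortex", "mean_sinus", "mean_fascia"):
            v = getattr(self, name)
            if not (0 < v < 255):
                raise ValidationError(f"{name}={v} must lie in (0, 255)")
        if not (0 <= self.speckle_scale <= 1):
            raise ValidationError("speckle_scale must lie in [0, 1]")
        if self._fascia_rect()[1] <= self._kidney_bottom():
            raise ValidationError("fascia band intersects the kidney ellipse")
        for ax, tot in zip(self.kidney_axes, (self.width, self.height)):
            if ax * tot < 2:
                raise ValidationError("kidney ellipse is degenerate")

    def _kidney_bottom(self) -> float:
        return (self.kidney_center[1] + self.kidney_axes[1]) * self.height

    def _fascia_rect(self) -> tuple[int, int, int, int]:
        """(x0, y0, x1, y1) of the fascia band, odd width and odd height."""
        x0 = int(round(self.fascia_margin * self.width))
        x1 = int(round((1 - self.fascia_margin) * self.width)) - 1
        y0 = int(round(self.fascia_top * self.height))
        y1 = min(
            self.height - 1,
            y0 + max(3, int(round(self.fascia_thickness * self.height))) - 1,
        )
        if (x1 - x0) % 2 == 1:  # make width odd
            x1 -= 1
        if (y1 - y0) % 2 == 1:  # make height odd
            y1 -= 1
        if x1 <= x0 or y1 <= y0:
            raise ValidationError("fascia band is degenerate")
        return x0, y0, x1, y1


@dataclass(frozen=True)
class OperatorEffect:
    """One physician/device combination's systematic acquisition bias.

    ``gain_multiplier`` and ``offset`` apply in full under the random
    method; under the standardized method they are replaced by the fixed
    study-wide preset (gain 1, offset 0), which is what locking the
    console's gain/TGC/dynamic-range preset achieves.
    """

    physician_id: str
    device_id: str
    gain_multiplier: float = 1.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.gain_multiplier <= 0:
            raise ValidationError("gain_multiplier must be positive")


#: Fixed study-wide acquisition settings used for the standardized method.
STANDARDIZED_GAIN = 1.0
STANDARDIZED_OFFSET = 0.0


def _region_mean_map(spec: PhantomSpec, means: dict[str, float]) -> np.ndarray:
    """Per-pixel echogenicity mean implied by the phantom geometry."""
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cx, cy = spec.kidney_center[0] * w, spec.kidney_center[1] * h
    kax, kay = spec.kidney_axes[0] * w, spec.kidney_axes[1] * h
    sax, say = spec.sinus_axes[0] * w, spec.sinus_axes[1] * h
    kidney = ((xx - cx) / kax) ** 2 + ((yy - cy) / kay) ** 2 <= 1.0
    sinus = ((xx - cx) / sax) ** 2 + ((yy - cy) / say) ** 2 <= 1.0
    x0, y0, x1, y1 = spec._fascia_rect()
    out = np.full((h, w), means["background"], dtype=float)
    out[kidney] = means["cortex"]
    out[sinus] = means["sinus"]
    out[y0 : y1 + 1, x0 : x1 + 1] = means["fascia"]
    return out


def _speckle_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Unit-mean multiplicative texture; ``speckle_scale`` = 0 is exactly 1."""
    if spec.speckle_scale == 0:
        return np.ones((spec.height, spec.width))
    unit_rayleigh = rng.rayleigh(scale=1.0, size=(spec.height, spec.width)) / _RAYLEIGH_MEAN
    return (1.0 - spec.speckle_scale) + spec.speckle_scale * unit_rayleigh


def _fascia_roi(spec: PhantomSpec) -> PolygonROI:
    x0, y0, x1, y1 = spec._fascia_rect()
    return PolygonROI("fascia", [(x0, y0), (x1, y0), (x1, y1), (x0, y1)])


def _kidney_roi(spec: PhantomSpec, n_vertices: int = 72) -> PolygonROI:
    cx = spec.kidney_center[0] * spec.width
    cy = spec.kidney_center[1] * spec.height
    ax = spec.kidney_axes[0] * spec.width * 0.99
    ay = spec.kidney_axes[1] * spec.height * 0.99
    t = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    verts = [(cx + ax * np.cos(a), cy + ay * np.sin(a)) for a in t]
    return PolygonROI("kidney", verts)


def generate_phantom(
    spec: PhantomSpec,
    rng: np.random.Generator | None = None,
    *,
    means: dict[str, float] | None = None,
    gain: float = 1.0,
    offset: float = 0.0,
) -> tuple[GrayImage, PolygonROI, PolygonROI]:
    """Synthesize one phantom image with its fascia and kidney ROIs.

    Deterministic for a given ``spec.seed`` (or caller-supplied ``rng``).
    ``means``, ``gain`` and ``offset`` let the study generator inject
    patient- and operator-level perturbations without touching the spec.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if means is None:
        means = {
            "background": spec.mean_background,
            "cortex": spec.mean_cortex,
            "sinus": spec.mean_sinus,
            "fascia": spec.mean_fascia,
        }
    mean_map = _region_mean_map(spec, means)
    speckle = _speckle_field(spec, rng)
    raw = gain * (mean_map * speckle) + offset
    pixels = np.clip(np.floor(raw + 0.5), 0, 255).astype(np.uint8)
    image = GrayImage(pixels=pixels, source_id=f"phantom(seed={spec.seed})")
    return image, _fascia_roi(spec), _kidney_roi(spec)


def phantom_with_fascia_gsm(
    spec: PhantomSpec,
    target_gsm: int = 220,
    max_iter: int = 60,
) -> tuple[GrayImage, PolygonROI, PolygonROI]:
    """A phantom whose realized fascia sample GSM equals ``target_gsm`` exactly.

    The speckle field is fixed by the spec's seed, and the fascia mean is
    bisected until the realized (integer) sample median of the fascia
    region lands on the target — i.e. the stated input condition is
    constructed deterministically.  The fascia pixel count is odd by
    construction.
    """
    fascia = _fascia_roi(spec)

    def realized(mean_fascia: float) -> tuple[int, tuple]:
        s = replace(spec, mean_fascia=mean_fascia)
        img, f_roi, k_roi = generate_phantom(s)
        mask = rasterize_polygon(f_roi, img.width, img.height)
        g = compute_gsm(region_pixels(img, mask))
        return int(g.gsm) if g.gsm == int(g.gsm) else -1, (img, f_roi, k_roi)

    lo, hi = max(1.0, target_gsm - 40.0), min(254.0, target_gsm + 40.0)
    g_lo, _ = realized(lo)
    g_hi, _ = realized(hi)
    if not (g_lo <= target_gsm <= g_hi):
        raise ValidationError(
            f"target fascia GSM {target_gsm} unreachable in mean range [{lo}, {hi}]"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        g_mid, result = realized(mid)
        if g_mid == target_gsm:
            return result
        if g_mid < target_gsm:
            lo = mid
        else:
            hi = mid
    raise ValidationError(
        f"bisection failed to realize fascia GSM {target_gsm} in {max_iter} steps"
    )


def _substream(
    seed: int, patient_idx: int, side: str, physician_id: str
) -> np.random.Generator:
    """Hierarchical per-(patient, side, physician) random stream.

    The physician enters through a CRC of its id, not its list position, so
    extending the physician roster leaves existing images untouched.  The
    acquisition method is deliberately absent: the speckle field of one
    physician's scan of one kidney is shared between the random and the
    standardized acquisition, so a null operator effect makes the two
    methods produce identical images.
    """
    keys = [
        seed,
        patient_idx,
        0 if side == "left" else 1,
        zlib.crc32(physician_id.encode()),
    ]
    return np.random.default_rng(np.random.SeedSequence(keys))


@dataclass(frozen=True)
class StudyImage:
    """One simulated acquisition, in memory."""

    record: AcquisitionRecord
    image: GrayImage
    fascia_roi: PolygonROI
    kidney_roi: PolygonROI


def iter_study_images(
    n_patients: int,
    effects: Sequence[OperatorEffect],
    spec: PhantomSpec,
    seed: int,
    patient_mean_sd: float = 6.0,
) -> Iterator[StudyImage]:
    """Lazily generate every acquisition of a simulated study.

    One image per patient x side x physician x method.  Each patient gets
    a persistent normal perturbation of the region means (their anatomy,
    shared across all acquisitions of that patient); each acquisition gets
    its own speckle realization, and the operator's gain/offset apply only
    under the random method.
    """
    if n_patients < 1:
        raise ValidationError("n_patients must be >= 1")
    if len(effects) < 2:
        raise ValidationError("at least 2 operator effects are required")
    ids = [e.physician_id for e in effects]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate physician_id in effects: {ids}")

    base_means = {
        "background": spec.mean_background,
        "cortex": spec.mean_cortex,
        "sinus": spec.mean_sinus,
        "fascia": spec.mean_fascia,
    }
    for p in range(n_patients):
        patient_id = f"P{p + 1:03d}"
        patient_rng = np.random.default_rng(np.random.SeedSequence([seed, p, 999]))
        deltas = patient_rng.normal(0.0, patient_mean_sd, size=4)
        means = {
            k: float(np.clip(v + d, 1.0, 254.0))
            for (k, v), d in zip(base_means.items(), deltas)
        }
        for side in ("left", "right"):
            for eff in effects:
                for method in ("random", "standardized"):
                    if method == "random":
                        gain, offset = eff.gain_multiplier, eff.offset
                    else:
                        gain, offset = STANDARDIZED_GAIN, STANDARDIZED_OFFSET
                    rng = _substream(seed, p, side, eff.physician_id)
                    image, f_roi, k_roi = generate_phantom(
                        spec, rng, means=means, gain=gain, offset=offset
                    )
                    stem = f"{patient_id}_{side}_{eff.physician_id}_{method}"
                    record = AcquisitionRecord(
                        patient_id=patient_id,
                        side=side,
                        physician_id=eff.physician_id,
                        device_id=eff.device_id,
                        method=method,
                        normalized=False,
                        image_path=f"{stem}.bmp",
                        fascia_roi_path=f"{stem}_fascia.json",
                        kidney_roi_path=f"{stem}_kidney.json",
                    )
                    yield StudyImage(record, image, f_roi, k_roi)


def generate_study(
    n_patients: int,
    effects: Sequence[OperatorEffect],
    spec: PhantomSpec,
    seed: int,
    out_dir: str | Path,
    patient_mean_sd: float = 6.0,
) -> list[AcquisitionRecord]:
    """Materialize a simulated study on disk: BMP images, ROI JSON files
    and a ``manifest.csv``; returns the manifest records."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for item in iter_study_images(n_patients, effects, spec, seed, patient_mean_sd):
        write_gray_bmp(item.image, out_dir / item.record.image_path)
        write_roi(item.fascia_roi, out_dir / item.record.fascia_roi_path)
        write_roi(item.kidney_roi, out_dir / item.record.kidney_roi_path)
        records.append(item.record)
    write_manifest(records, out_dir / "manifest.csv")
    return records
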